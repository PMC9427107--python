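"""Shared statistical machinery.

Group comparisons between attentional rules use the paired Wilcoxon
signed-rank (WSR) test, corrected across the six depth x waveform groups by
the Benjamini-Hochberg false-discovery-rate step-up procedure at q = 0.05
(q = 0.01 for per-unit responsiveness tests).  Kruskal-Wallis serves
multi-group contrasts, and a generic split-half reliability engine backs
both STRF reliability and multi-unit responsiveness screening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

GROUP_Q = 0.05
PER_UNIT_Q = 0.01


@dataclass(frozen=True)
class GroupTestResult:
    group: str
    statistic: float  # Z (WSR) or H (Kruskal-Wallis)
    p_raw: float
    p_adjusted: float
    n: int
    median_fold_change: float
    significant: bool


def wilcoxon_signed_rank(
    x,
    y=None,
    mu: float = 0.0,
    alternative: str = "two-sided",
    mode: str = "auto",
) -> tuple:
    """Paired (or one-sample) Wilcoxon signed-rank test; returns (Z, p).

    Differences ``x - y`` (or ``x - mu``) with zeros dropped.  The normal
    approximation with tie and continuity correction is the default for
    n > 25; exact enumeration otherwise (``mode`` forces either).  The
    one-sample form supports tests against a fixed value, e.g. fold change
    vs 1 or accuracy vs chance.
    """
    x = np.asarray(x, dtype=float)
    d = x - (mu if y is None else np.asarray(y, dtype=float))
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    # tie-corrected variance of W+
    _, tie_counts = np.unique(ranks, return_counts=True)
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if var_w <= 0:
        return 0.0, 1.0
    cc = 0.5 * np.sign(w_plus - mean_w)
    z = (w_plus - mean_w - cc) / np.sqrt(var_w)
    use_exact = mode == "exact" or (mode == "auto" and n <= 25 and tie_counts.max() == 1)
    if use_exact:
        res = sps.wilcoxon(d, alternative=alternative, method="exact")
        p = float(res.pvalue)
    else:
        if alternative == "two-sided":
            p = float(2 * sps.norm.sf(abs(z)))
        elif alternative == "greater":
            p = float(sps.norm.sf(z))
        elif alternative == "less":
            p = float(sps.norm.cdf(z))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    return float(z), min(p, 1.0)


def bh_fdr(p_values, q: float = GROUP_Q) -> tuple:
    """Benjamini-Hochberg step-up FDR: returns (adjusted p, rejection flags)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def kruskal_wallis(*groups) -> tuple:
    """Rank-based Kruskal-Wallis H test with tie correction; returns (H, p)."""
    if len(groups) < 2 or any(len(g) < 3 for g in groups):
        raise ValueError("need >= 2 groups with >= 3 observations each")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def split_half_reliability(
    observations: np.ndarray,
    n_reps: int = 1000,
    seed: int = 0,
    null_generator=None,
    n_null: int | None = None,
) -> tuple:
    """Mean split-half Pearson correlation of repeated observations, with an
    optional null distribution.

    ``observations`` is (n_obs, ...); each repetition randomly halves the
    observations (odd counts drop one at random), averages each half, and
    correlates the flattened means.  If ``null_generator(rng) -> obs`` is
    given, a null sample of the same statistic is built from ``n_null``
    fresh null draws (one split each) and the returned p is the fraction of
    null values strictly greater than the observed mean.

    Returns ``(mean_r, p, null_r)`` (p and null_r are None without a null).
    """
    obs = np.asarray(observations, dtype=float)
    if obs.shape[0] < 4:
        raise ValueError("need >= 4 observations for split-half reliability")
    rng = np.random.default_rng(seed)
    mean_r = mean_split_half_r(obs, n_reps, rng)
    if null_generator is None:
        return mean_r, None, None
    n_null = n_reps if n_null is None else n_null
    null_r = np.empty(n_null)
    for i in range(n_null):
        null_obs = np.asarray(null_generator(rng), dtype=float)
        null_r[i] = _one_split_r(null_obs, rng)
    p = float(np.mean(null_r > mean_r))
    return mean_r, p, null_r


def _one_split_r(obs: np.ndarray, rng: np.random.Generator) -> float:
    n = obs.shape[0]
    idx = rng.permutation(n)
    if n % 2:
        idx = idx[:-1]
    half = idx.size // 2
    a = obs[idx[:half]].mean(axis=0).ravel()
    b = obs[idx[half:]].mean(axis=0).ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def mean_split_half_r(obs: np.ndarray, n_reps: int, rng: np.random.Generator) -> float:
    """Mean over ``n_reps`` random half-splits of the Pearson correlation
    between the two half-averages."""
    return float(np.mean([_one_split_r(obs, rng) for _ in range(n_reps)]))
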