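"""Windowed firing-rate computation and rule-contrast analyses.

Evoked rates are counted in the first 300 ms after decision-stimulus onset,
pre-stimulus rates in the 300 ms before onset; windows are half-open
[start, stop) and onset-relative, in seconds.  Per-unit attentional
modulation is the fold change FC = mean A-rule FR / mean V-rule FR (defined
only when both means are nonzero), tested per unit with an unpaired t-test
at p < 0.01.  Baseline normalization divides each rule's evoked rate by that
rule's mean pre-stimulus rate, which removes any rule effect that is a pure
multiplicative gain shared by baseline and evoked activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

EVOKED_WINDOW = (0.0, 0.3)
PRESTIM_WINDOW = (-0.3, 0.0)
MIN_TRIALS = 10
PER_UNIT_ALPHA = 0.01


@dataclass
class TrialRates:
    """Per-trial firing rates of one unit in a named onset-relative window."""

    unit_id: int
    condition: str
    rates: np.ndarray  # Hz, one per trial
    window: tuple  # (start, stop) s relative to onset

    @property
    def n_trials(self) -> int:
        return self.rates.size

    @property
    def mean(self) -> float:
        return float(self.rates.mean()) if self.rates.size else np.nan


@dataclass
class RuleModulation:
    unit_id: int
    mean_fr_a: float
    mean_fr_v: float
    fold_change: float
    per_unit_p: float
    significant: bool
    direction: str  # "suppressed" (FC < 1) or "enhanced"
    excluded: bool = False
    exclusion_reason: str = ""


def window_counts(spike_times: np.ndarray, onsets: np.ndarray, window: tuple) -> np.ndarray:
    """Spike counts per trial in the half-open window [onset+a, onset+b)."""
    spikes = np.asarray(spike_times)
    onsets = np.asarray(onsets, dtype=float)
    a, b = window
    lo = np.searchsorted(spikes, onsets + a, side="left")
    hi = np.searchsorted(spikes, onsets + b, side="left")
    return (hi - lo).astype(int)


def window_rates(
    spike_times: np.ndarray,
    onsets,
    window: tuple = EVOKED_WINDOW,
    unit_id: int = -1,
    condition: str = "",
) -> TrialRates:
    """Per-trial firing rates (Hz) in an onset-relative half-open window."""
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("empty onset list")
    a, b = window
    if b <= a:
        raise ValueError("window stop must exceed start")
    counts = window_counts(spike_times, onsets, window)
    return TrialRates(unit_id=unit_id, condition=condition, rates=counts / (b - a), window=window)


def collapse_stimuli(trials: pd.DataFrame, auditory_class: str) -> pd.DataFrame:
    """Pool bimodal trials by auditory identity across visual pairings.

    ``auditory_class`` is ``"A_R*"`` or ``"A_U*"``: e.g. A_R* pools A_RV_R
    and A_RV_U.  Unimodal trials are not collapsible and are excluded.
    """
    if auditory_class not in ("A_R*", "A_U*"):
        raise ValueError(f"unknown auditory class {auditory_class!r}")
    aud = auditory_class[:3]  # "A_R" or "A_U"
    av = trials[trials.modality == "AV"]
    return av[av.stimulus.str.startswith(aud)].copy()


def unit_rule_modulation(
    rates_a: TrialRates,
    rates_v: TrialRates,
    min_trials: int = MIN_TRIALS,
    alpha: float = PER_UNIT_ALPHA,
    paired: bool = False,
) -> RuleModulation:
    """Fold change (A/V) and per-unit significance of rule modulation.

    Units with fewer than ``min_trials`` per condition or a zero mean rate
    in either rule are excluded (flagged, not silently dropped).  The
    default per-unit test is the unpaired t-test at p < 0.01; a paired
    variant is available for matched trial sets.
    """

    def _excluded(reason):
        return RuleModulation(
            unit_id=rates_a.unit_id,
            mean_fr_a=rates_a.mean,
            mean_fr_v=rates_v.mean,
            fold_change=np.nan,
            per_unit_p=np.nan,
            significant=False,
            direction="",
            excluded=True,
            exclusion_reason=reason,
        )

    if rates_a.n_trials < min_trials or rates_v.n_trials < min_trials:
        return _excluded(f"fewer than {min_trials} trials in a condition")
    ma, mv = rates_a.mean, rates_v.mean
    if ma == 0 or mv == 0:
        return _excluded("zero firing rate in one rule")
    if np.array_equal(rates_a.rates, rates_v.rates):
        p = 1.0
    elif paired:
        p = float(sps.ttest_rel(rates_a.rates, rates_v.rates).pvalue)
    else:
        p = float(sps.ttest_ind(rates_a.rates, rates_v.rates).pvalue)
    fc = ma / mv
    return RuleModulation(
        unit_id=rates_a.unit_id,
        mean_fr_a=ma,
        mean_fr_v=mv,
        fold_change=fc,
        per_unit_p=p,
        significant=bool(p < alpha),
        direction="suppressed" if fc < 1 else "enhanced",
    )


def baseline_normalize(evoked: TrialRates, prestim: TrialRates) -> TrialRates:
    """Express evoked rates as multiples of the condition's mean pre-stimulus
    rate.  Undefined (raises) when the pre-stimulus mean is zero; callers
    exclude such units from the normalized analysis."""
    m = prestim.mean
    if not m > 0:
        raise ValueError("zero pre-stimulus mean rate: unit excluded from normalization")
    return TrialRates(
        unit_id=evoked.unit_id,
        condition=evoked.condition + "/prestim",
        rates=evoked.rates / m,
        window=evoked.window,
    )


def responsiveness_test(prestim: TrialRates, evoked: TrialRates, min_pairs: int = MIN_TRIALS):
    """Paired t-test of evoked vs pre-stimulus rate across trials.

    Returns (p, mean difference).  Identical zero-variance pairs give p = 1
    by convention.  Significance flags are assigned by the caller after
    BH-FDR across units (q = 0.01).
    """
    if prestim.n_trials != evoked.n_trials:
        raise ValueError("responsiveness test requires paired trials")
    if prestim.n_trials < min_pairs:
        raise ValueError(f"fewer than {min_pairs} paired trials")
    d = evoked.rates - prestim.rates
    if np.all(d == d[0]) and d[0] == 0:
        return 1.0, 0.0
    if np.all(d == d[0]):  # nonzero constant difference: infinitely significant
        return 0.0, float(d[0])
    res = sps.ttest_rel(evoked.rates, prestim.rates)
    return float(res.pvalue), float(d.mean())


def fr_match_subsample(
    group_a_fr: np.ndarray,
    group_b_fr: np.ndarray,
    seed: int = 0,
    max_retries: int = 20,
    check_alpha: float = 0.05,
) -> np.ndarray:
    """Indices into group B matched to group A on log mean firing rate.

    Greedy nearest-neighbor matching without replacement on log FR, in a
    seeded random order.  A post-hoc paired Wilcoxon check must not reject
    (p > ``check_alpha``); otherwise the match is redrawn with a new order,
    up to ``max_retries`` times.
    """
    from .stats import wilcoxon_signed_rank

    a = np.log(np.asarray(group_a_fr, dtype=float))
    b = np.log(np.asarray(group_b_fr, dtype=float))
    if b.size < a.size:
        raise ValueError("group B must be at least as large as group A")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        order = rng.permutation(a.size)
        avail = np.ones(b.size, dtype=bool)
        chosen = np.empty(a.size, dtype=int)
        for i in order:
            free = np.flatnonzero(avail)
            j = free[np.argmin(np.abs(b[free] - a[i]))]
            chosen[i] = j
            avail[j] = False
        d = a - b[chosen]
        if np.all(d == 0):
            return chosen
        _, p = wilcoxon_signed_rank(a, b[chosen])
        if p > check_alpha:
            return chosen
    raise RuntimeError(
        "fr_match_subsample: matched distributions still differ after "
        f"{max_retries} retries (disjoint FR supports?)"
    )


def fa_cr_prestim_contrast(
    spike_times_by_unit: list,
    trials: pd.DataFrame,
    rule: str,
    unit_ids=None,
    window: tuple = PRESTIM_WINDOW,
    min_trials: int = MIN_TRIALS,
) -> pd.DataFrame:
    """Per-unit FA-minus-CR pre-stimulus firing-rate contrast in one rule.

    ``trials`` should already be filtered to the error-contrast path (false
    alarms and correct rejects, lick filters applied).  Sessions with fewer
    than 10 FA or 10 CR trials in the rule are excluded (raises).  Group
    inference on the returned per-unit differences is delegated to
    :mod:`avattn.stats`.
    """
    sub = trials[(trials.rule == rule) & trials.outcome.isin(["fa", "cr"])]
    fa_on = sub[sub.outcome == "fa"].t_onset.to_numpy()
    cr_on = sub[sub.outcome == "cr"].t_onset.to_numpy()
    if fa_on.size < min_trials or cr_on.size < min_trials:
        raise ValueError(
            f"insufficient error trials in rule {rule}: "
            f"{fa_on.size} FA, {cr_on.size} CR (need {min_trials} each)"
        )
    if unit_ids is None:
        unit_ids = range(len(spike_times_by_unit))
    rows = []
    for uid in unit_ids:
        st = spike_times_by_unit[uid]
        fa_mean = window_rates(st, fa_on, window).mean
        cr_mean = window_rates(st, cr_on, window).mean
        rows.append({"unit_id": uid, "fa_mean": fa_mean, "cr_mean": cr_mean,
                     "contrast_hz": fa_mean - cr_mean})
    return pd.DataFrame(rows)
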