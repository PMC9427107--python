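"""Spectrotemporal receptive fields by reverse correlation.

STRFs are estimated from responses to the inter-trial random double sweep:
the spike-triggered average (STA) of the time-frequency stimulus over a
window of 200 ms before to 50 ms after each spike (the acausal 50 ms
estimates the chance level implied by stimulus and spike-train statistics).
The first 200 ms of every epoch's response is dropped to avoid onset
transients, and total stimulus time is equated between rules by truncating
the rule with more mapping time.

Tuning is assessed by split-half reliability: the mean Pearson correlation
between STRFs re-averaged from random epoch halves, compared with a null
distribution built from circularly shuffled spike trains (which preserve
spike count and the circular interspike-interval multiset while breaking
the spike-stimulus timing relationship).  The p-value is the fraction of
null reliabilities exceeding the observed mean; a unit counts as tuned at
p < 0.05 in either rule.

Projection mutual information measures how well an STRF predicts its spike
train: stimulus windows are projected onto the STRF, standardized by the
moments of the all-window distribution, and MI is the divergence

    MI = sum_x P(x|spike) log2( P(x|spike) / P(x) )   [bits/spike].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .lnp import lag_grid
from .stimuli import TFMatrix

MIN_STRF_SPIKES = 50
EPOCH_DROP_S = 0.200  # response dropped at the start of every RDS epoch
BF_LAG_WINDOW = (-0.100, 0.0)
MIN_RELIABILITY_EPOCHS = 4
MIN_SHUFFLE_ROTATION_S = 0.5


@dataclass
class STRFGrid:
    """Lag x frequency kernel with its estimation metadata."""

    values: np.ndarray  # (n_lag, n_freq), firing-rate deviation units (Hz)
    lags: np.ndarray  # s, covering [-0.200, +0.050]
    freq_edges: np.ndarray  # log2(Hz)
    n_spikes: int
    total_duration: float  # s of stimulus entering the estimate
    rule: str = ""
    # per-band affine map from the raw STA: values = band_scale * (STA - band_mean);
    # lets projection analyses remove each spike's own contribution exactly
    band_mean: np.ndarray | None = None
    band_scale: np.ndarray | None = None

    @property
    def freq_centers_log2(self) -> np.ndarray:
        return 0.5 * (self.freq_edges[:-1] + self.freq_edges[1:])

    @property
    def freq_centers_hz(self) -> np.ndarray:
        return 2.0 ** self.freq_centers_log2


@dataclass
class ReliabilityResult:
    mean_r: float
    null_r: np.ndarray
    p: float
    tuned: bool


@dataclass
class ProjectionDistributions:
    """Standardized STRF-projection distributions P(x) and P(x|spike)."""

    p_x: np.ndarray
    p_x_given_spike: np.ndarray
    bin_edges: np.ndarray
    mu: float  # raw-projection mean used for standardization
    sigma: float  # raw-projection SD
    n_spikes: int


def equate_rule_durations(
    epochs_by_rule: dict,
    drop_initial: float = EPOCH_DROP_S,
) -> dict:
    """Equalize total RDS analysis time across rules.

    ``epochs_by_rule`` maps rule -> list of (start, stop) seconds.  The
    first ``drop_initial`` seconds of every epoch are removed, then the rule
    with more total time is truncated from its last epoch backwards (whole
    epochs removed, then one partial trim) until totals match.
    """
    trimmed = {}
    for rule, eps in epochs_by_rule.items():
        kept = [(s + drop_initial, e) for s, e in eps if e - s > drop_initial]
        if not kept:
            raise ValueError(f"rule {rule!r} has no RDS time after the onset drop")
        trimmed[rule] = kept
    totals = {r: sum(e - s for s, e in eps) for r, eps in trimmed.items()}
    target = min(totals.values())
    out = {}
    for rule, eps in trimmed.items():
        excess = totals[rule] - target
        kept = list(eps)
        while excess > 1e-9 and kept:
            s, e = kept[-1]
            if e - s <= excess + 1e-12:
                kept.pop()
                excess -= e - s
            else:
                kept[-1] = (s, e - excess)
                excess = 0.0
        out[rule] = kept
    return out


def _spike_bins(tf: TFMatrix, spikes: np.ndarray) -> np.ndarray:
    rel = np.asarray(spikes) - tf.t0
    return np.floor(rel / tf.dt).astype(int)


def spike_triggered_windows(
    tf: TFMatrix, spikes: np.ndarray, lags: np.ndarray | None = None
) -> np.ndarray:
    """Stimulus windows around each spike, shape (n_valid, n_lag, n_freq).

    Spikes whose full lag window falls outside the stimulus segment are
    dropped.
    """
    if lags is None:
        lags = lag_grid(tf.dt)
    offsets = np.round(lags / tf.dt).astype(int)
    bins = _spike_bins(tf, spikes)
    valid = (bins + offsets[0] >= 0) & (bins + offsets[-1] < tf.n_time)
    idx = bins[valid][:, None] + offsets[None, :]
    return tf.values[idx]


def estimate_strf(
    epochs: list,
    min_spikes: int = MIN_STRF_SPIKES,
    rule: str = "",
    rate_units: bool = True,
):
    """Reverse-correlation STRF from a list of (TFMatrix, spike_times) epochs.

    Returns ``(pooled: STRFGrid, per_epoch_stas: list[np.ndarray | None])``.
    Per-epoch STAs are raw stimulus averages (an epoch with no usable spike
    yields None); the pooled estimate is spike-count weighted and, with
    ``rate_units``, converted to firing-rate deviation:

        STRF(l, f) = rbar * (STA(l, f) - m(f)) / sqrt(m(f) * mbar)

    with m(f) the mean stimulus energy per band (floored at 10% of its
    across-band average mbar) and rbar the mean firing rate.  Centering
    removes each band's mean stimulus footprint; the square-root occupancy
    weighting compensates for uneven stimulus coverage of the band axis
    without letting rarely visited edge bands amplify estimation noise, as
    full per-band division would.  The conversion is per-band affine, so
    reliability, per-bin significance and projection analyses are unaffected
    by the choice (they are invariant to per-band affine maps shared by
    observed and null estimates).
    """
    if not epochs:
        raise ValueError("no epochs supplied")
    lags = lag_grid(epochs[0][0].dt)
    per_epoch = []
    sum_windows = 0.0
    n_spk = 0
    total_dur = 0.0
    band_sum = 0.0
    n_time_total = 0
    for tf, spikes in epochs:
        w = spike_triggered_windows(tf, spikes, lags)
        per_epoch.append(w.mean(axis=0) if w.shape[0] else None)
        if w.shape[0]:
            sum_windows = sum_windows + w.sum(axis=0)
            n_spk += w.shape[0]
        total_dur += tf.duration
        band_sum = band_sum + tf.values.sum(axis=0)
        n_time_total += tf.n_time
    if n_spk < min_spikes:
        raise ValueError(f"{n_spk} usable spikes < minimum {min_spikes}: unit excluded")
    sta = sum_windows / n_spk
    if rate_units:
        m = band_sum / n_time_total  # mean stimulus energy per band per time bin
        rbar = n_spk / total_dur
        denom = np.sqrt(np.maximum(m, 0.1 * m.mean()) * m.mean())
        band_mean = m
        band_scale = rbar / denom
        values = band_scale[None, :] * (sta - band_mean[None, :])
    else:
        band_mean = np.zeros(sta.shape[1])
        band_scale = np.ones(sta.shape[1])
        values = sta
    pooled = STRFGrid(
        values=values,
        lags=lags,
        freq_edges=epochs[0][0].freq_edges,
        n_spikes=n_spk,
        total_duration=total_dur,
        rule=rule,
        band_mean=band_mean,
        band_scale=band_scale,
    )
    return pooled, per_epoch


def circular_shuffle(
    spikes: np.ndarray,
    epoch: tuple,
    rng: np.random.Generator,
    min_rotation: float = MIN_SHUFFLE_ROTATION_S,
) -> np.ndarray:
    """Rotate all of an epoch's spikes by one random offset, modulo duration.

    The offset is drawn uniformly from [min_rotation, duration -
    min_rotation], so the identity rotation is never drawn; spike count and
    the circular interspike-interval multiset are preserved exactly.  Epochs
    shorter than twice the minimum rotation are returned unshuffled with a
    warning.
    """
    start, stop = epoch
    dur = stop - start
    if dur <= 2 * min_rotation:
        warnings.warn(f"epoch of {dur:.2f} s too short to shuffle; skipped")
        return np.asarray(spikes).copy()
    off = rng.uniform(min_rotation, dur - min_rotation)
    out = np.mod(np.asarray(spikes) - start + off, dur) + start
    out.sort()
    return out


def _epoch_stas_from_spikes(epochs: list, spike_sets: list, lags: np.ndarray):
    stas = []
    for (tf, _), spk in zip(epochs, spike_sets):
        w = spike_triggered_windows(tf, spk, lags)
        if w.shape[0]:
            stas.append(w.mean(axis=0))
    return stas


def strf_reliability(
    epochs: list,
    n_reps: int = 1000,
    seed: int = 0,
    n_null: int | None = None,
    alpha: float = 0.05,
) -> ReliabilityResult:
    """Split-half reliability of per-epoch STRFs against a circular-shuffle null.

    The observed statistic is the mean over ``n_reps`` random half-splits of
    the Pearson correlation between the two half-averaged STRFs (an odd
    epoch count drops one epoch at random per split).  Each of the
    ``n_null`` null values repeats the identical procedure on a fresh
    circular shuffle of every epoch's spikes, so that under the null the
    observed statistic is exchangeable with the null sample and the
    resulting p-value is calibrated.  p is the fraction of null values
    strictly greater than the observed mean.
    """
    from .stats import mean_split_half_r

    lags = lag_grid(epochs[0][0].dt)
    obs_stas = _epoch_stas_from_spikes(epochs, [spk for _, spk in epochs], lags)
    if len(obs_stas) < MIN_RELIABILITY_EPOCHS:
        raise ValueError(
            f"{len(obs_stas)} epochs with spikes < {MIN_RELIABILITY_EPOCHS}: "
            "reliability undefined for this unit"
        )
    rng = np.random.default_rng(seed)
    obs = np.stack(obs_stas)
    mean_r = mean_split_half_r(obs, n_reps, rng)
    n_null = n_reps if n_null is None else n_null
    null_r = np.empty(n_null)
    bounds = [(tf.t0, tf.t0 + tf.duration) for tf, _ in epochs]
    for i in range(n_null):
        shuffled = [
            circular_shuffle(spk, bounds[k], rng) for k, (_, spk) in enumerate(epochs)
        ]
        stas = _epoch_stas_from_spikes(epochs, shuffled, lags)
        if len(stas) < 2:
            null_r[i] = 0.0
            continue
        null_r[i] = mean_split_half_r(np.stack(stas), n_reps, rng)
    p = float(np.mean(null_r > mean_r))
    return ReliabilityResult(mean_r=mean_r, null_r=null_r, p=p, tuned=bool(p < alpha))


def null_strf_sample(
    epochs: list,
    n_null: int,
    seed: int = 0,
    rate_units: bool = True,
) -> np.ndarray:
    """Pooled STRFs from circularly shuffled spike trains, shape
    (n_null, n_lag, n_freq), using the same estimator as the observed STRF."""
    rng = np.random.default_rng(seed)
    bounds = [(tf.t0, tf.t0 + tf.duration) for tf, _ in epochs]
    out = []
    for _ in range(n_null):
        shuffled = [
            (tf, circular_shuffle(spk, bounds[k], rng))
            for k, (tf, spk) in enumerate(epochs)
        ]
        grid, _ = estimate_strf(shuffled, min_spikes=1, rate_units=rate_units)
        out.append(grid.values)
    return np.stack(out)


def significant_bins(
    strf: STRFGrid, null_strfs: np.ndarray, alpha: float = 0.01
) -> np.ndarray:
    """Two-sided empirical per-bin significance mask against the shuffle null."""
    if null_strfs.shape[0] < 100:
        raise ValueError("need >= 100 null STRFs for per-bin significance")
    lo = np.quantile(null_strfs, alpha / 2, axis=0)
    hi = np.quantile(null_strfs, 1 - alpha / 2, axis=0)
    return (strf.values < lo) | (strf.values > hi)


def best_frequency(
    strf: STRFGrid,
    mask: np.ndarray,
    lag_window: tuple = BF_LAG_WINDOW,
) -> float | None:
    """Best frequency (Hz): the band maximizing summed |STRF| over
    significant bins with lags in [-100, 0] ms.  Ties resolve to the lower
    frequency; returns None when no bin in the window is significant."""
    in_win = (strf.lags >= lag_window[0] - 1e-9) & (strf.lags <= lag_window[1] + 1e-9)
    scores = (np.abs(strf.values) * mask)[in_win].sum(axis=0)
    if not np.any(mask[in_win]):
        return None
    return float(strf.freq_centers_hz[int(np.argmax(scores))])


def projection_distributions(
    epochs: list,
    strf: STRFGrid,
    n_bins: int = 40,
    sd_range: float = 5.0,
    self_estimated: bool = True,
) -> ProjectionDistributions:
    """Distributions of standardized stimulus-STRF projections.

    ``P(x|spike)`` uses the stimulus windows preceding each spike (full
    -200/+50 ms window); ``P(x)`` uses all possible windowed stimulus
    segments (every time-bin offset within each epoch).  Projections are
    standardized by the mean and SD of the all-window distribution, then
    histogrammed on shared edges spanning +-``sd_range`` SD with outliers
    clipped into the edge bins.  ``P(x)`` gets a Laplace pseudocount so the
    MI ratio is always defined.

    With ``self_estimated`` (the default), each spike's projection uses the
    STRF re-estimated without that spike's own stimulus window (exact
    leave-one-out via the per-band affine coefficients the estimator stores
    on the grid).  Projecting spikes onto an average that includes their own
    windows would otherwise inflate P(x|spike) even for stimulus-independent
    spike trains.
    """
    lags = strf.lags
    n_lag = lags.size
    k = strf.values
    if not np.any(k):
        raise ValueError("all-zero STRF: projections degenerate")
    loo = self_estimated and strf.band_scale is not None and strf.n_spikes > 1
    z_spk_parts, z_all_parts = [], []
    for tf, spikes in epochs:
        w = spike_triggered_windows(tf, spikes, lags)
        if w.shape[0]:
            z = np.tensordot(w, k, axes=2)
            if loo:
                # K_{-i} = band_scale * (STA_{-i} - band_mean) with
                # STA_{-i} = (N STA - w_i) / (N - 1); exact identity:
                n = strf.n_spikes
                a, m = strf.band_scale, strf.band_mean
                w_am = w @ (a * m)  # (n_spk, n_lag) -> sum over lags below
                wi_am = w_am.sum(axis=1)
                wi_awi = np.einsum("ilf,f,ilf->i", w, a, w)
                z = z + (z + wi_am - wi_awi) / (n - 1)
            z_spk_parts.append(z)
        if tf.n_time >= n_lag:
            sliding = np.lib.stride_tricks.sliding_window_view(
                tf.values, n_lag, axis=0
            )  # (n_windows, n_freq, n_lag)
            z_all_parts.append(np.einsum("wfl,lf->w", sliding, k))
    if not z_spk_parts:
        raise ValueError("no spikes available for projection distributions")
    z_spk = np.concatenate(z_spk_parts)
    z_all = np.concatenate(z_all_parts)
    mu, sigma = float(z_all.mean()), float(z_all.std())
    if sigma == 0:
        raise ValueError("zero projection variance: cannot standardize")
    edges = np.linspace(-sd_range, sd_range, n_bins + 1)
    eps = 1e-9
    x_spk = np.clip((z_spk - mu) / sigma, -sd_range + eps, sd_range - eps)
    x_all = np.clip((z_all - mu) / sigma, -sd_range + eps, sd_range - eps)
    c_spk, _ = np.histogram(x_spk, bins=edges)
    c_all, _ = np.histogram(x_all, bins=edges)
    p_spk = c_spk / c_spk.sum()
    p_all = (c_all + 1.0) / (c_all.sum() + n_bins)  # Laplace floor
    return ProjectionDistributions(
        p_x=p_all,
        p_x_given_spike=p_spk,
        bin_edges=edges,
        mu=mu,
        sigma=sigma,
        n_spikes=int(z_spk.size),
    )


def strf_spike_mi(dists: ProjectionDistributions) -> float:
    """Spike-count-normalized mutual information (bits/spike):
    sum over bins of P(x|spike) log2(P(x|spike) / P(x)), with 0 log 0 = 0."""
    p, q = dists.p_x_given_spike, dists.p_x
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / q[nz])))
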