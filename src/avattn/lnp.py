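"""Linear-nonlinear Poisson (LNP) ground-truth units and spike simulation.

A ground-truth unit owns an optional spectrotemporal kernel on the analysis
lag/frequency grid, per-rule baseline rates and evoked gains (attentional
modulation is multiplicative: factor 1.0 means no rule effect), and a
decision-stimulus response profile.  Spikes are drawn as an inhomogeneous
Poisson process by per-bin thinning at 1 ms resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimuli import TFMatrix

# STRF lag window: 200 ms before to 50 ms after each spike.
STRF_LAG_MIN_S = -0.200
STRF_LAG_MAX_S = 0.050


def lag_grid(dt: float = 0.005) -> np.ndarray:
    """Lag bin centers (s) covering [-0.200, +0.050] at step dt."""
    n_neg = int(round(-STRF_LAG_MIN_S / dt))
    n_pos = int(round(STRF_LAG_MAX_S / dt))
    return np.arange(-n_neg, n_pos + 1) * dt


@dataclass
class GroundTruthUnit:
    """Generative parameters for one synthetic unit."""

    unit_id: int
    strf_truth: np.ndarray | None  # (n_lag, n_freq) or None for untuned
    baseline_rate_by_rule: dict  # rule -> Hz
    evoked_gain_by_rule: dict  # rule -> dimensionless
    decision_response_profile: dict  # stimulus element -> (n_psth_bins,) Hz
    depth_fraction: float = 0.5
    trough_peak_ms: float = 0.8
    peak_channel: int = 0
    rds_drive_gain: float = 1.0  # Hz per unit of standardized stimulus drive
    fa_prestim_delta_hz: float = 0.0  # pre-stimulus rate boost on A-rule FA trials

    def baseline(self, rule: str) -> float:
        return float(self.baseline_rate_by_rule[rule])

    def evoked_gain(self, rule: str) -> float:
        return float(self.evoked_gain_by_rule[rule])


def make_gabor_strf(
    lags: np.ndarray,
    freq_centers_log2: np.ndarray,
    bf_log2: float,
    peak_lag: float = -0.05,
    sigma_t: float = 0.035,
    sigma_f_oct: float = 0.45,
    temporal_freq_hz: float = 12.0,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Gabor-shaped spectrotemporal kernel: Gaussian in frequency around the
    best frequency, damped oscillation in lag peaking at ``peak_lag``.
    Acausal lags (> 0) are zeroed: the kernel drives future spikes only."""
    t = lags[:, None]
    f = freq_centers_log2[None, :] - bf_log2
    env = np.exp(-0.5 * ((t - peak_lag) / sigma_t) ** 2 - 0.5 * (f / sigma_f_oct) ** 2)
    carrier = np.cos(2 * np.pi * temporal_freq_hz * (t - peak_lag))
    k = amplitude * env * carrier
    k[lags > 0, :] = 0.0
    return k


def linear_drive(tf: TFMatrix, kernel: np.ndarray, lags: np.ndarray | None = None) -> np.ndarray:
    """Convolve a lag x frequency kernel with the (per-band mean-centered)
    stimulus: drive[t] = sum_{l,f} K[l,f] * (S[t + l/dt, f] - mean_f).

    Negative lags index the stimulus past.  Out-of-range stimulus samples
    contribute zero, so the drive has the same length as the stimulus.
    """
    if lags is None:
        lags = lag_grid(tf.dt)
    if kernel.shape != (lags.size, tf.n_freq):
        raise ValueError(
            f"kernel shape {kernel.shape} does not match grid "
            f"({lags.size}, {tf.n_freq})"
        )
    s = tf.values - tf.values.mean(axis=0, keepdims=True)
    n_t = tf.n_time
    drive = np.zeros(n_t)
    offsets = np.round(lags / tf.dt).astype(int)
    for row, off in enumerate(offsets):
        # spike at t sees stimulus at t + off (off < 0: past)
        lo_t = max(0, -off)
        hi_t = min(n_t, n_t - off)
        if hi_t <= lo_t:
            continue
        drive[lo_t:hi_t] += s[lo_t + off : hi_t + off] @ kernel[row]
    return drive


def rectify(x: np.ndarray, kind: str = "relu") -> np.ndarray:
    """Output nonlinearity of the LNP cascade."""
    if kind == "relu":
        return np.maximum(x, 0.0)
    if kind == "exp":
        return np.exp(np.minimum(x, 50.0))
    raise ValueError(f"unknown rectifier {kind!r}")


def poisson_spikes_from_rate(
    rate_hz: np.ndarray,
    dt: float,
    rng: np.random.Generator,
    t0: float = 0.0,
) -> np.ndarray:
    """Draw spike times from a binned rate profile by per-bin Poisson counts,
    placing each spike uniformly within its bin.  Sorted times (s)."""
    lam = np.maximum(rate_hz, 0.0) * dt
    counts = rng.poisson(lam)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    bins = np.repeat(np.arange(counts.size), counts)
    times = t0 + (bins + rng.random(total)) * dt
    times.sort()
    return times


def simulate_lnp_spikes(
    tf: TFMatrix,
    unit: GroundTruthUnit,
    rule: str,
    seed: int,
    dt_spike: float = 0.001,
    rectifier: str = "relu",
) -> np.ndarray:
    """Simulate spike times of one unit responding to a stimulus segment.

    rate(t) = rectify(baseline[rule] + gain[rule] * (strf_truth * stimulus)(t));
    untuned units (strf_truth None) fire at their baseline rate.  Spikes are
    drawn by Poisson thinning in ``dt_spike`` bins; deterministic given seed.
    Returned times are absolute (offset by ``tf.t0``).
    """
    base = unit.baseline(rule)
    if unit.strf_truth is None:
        drive = np.zeros(tf.n_time)
    else:
        drive = linear_drive(tf, unit.strf_truth)
    gain = unit.evoked_gain(rule) * unit.rds_drive_gain
    rate_tf = rectify(base + gain * drive, rectifier)
    # upsample the tf-resolution rate to the spiking resolution
    per = int(round(tf.dt / dt_spike))
    if per < 1:
        raise ValueError("dt_spike must not exceed the tf time step")
    rate_ms = np.repeat(rate_tf, per)
    rng = np.random.default_rng(seed)
    return poisson_spikes_from_rate(rate_ms, dt_spike, rng, t0=tf.t0)
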