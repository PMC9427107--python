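"""Synthetic behavioral-physiology sessions.

A generated session emulates the structure the downstream analyses assume:

* a four-block go/no-go task (unimodal cue block then audiovisual block, for
  each rule in the configured order), with trial outcomes drawn from
  configured hit/false-alarm rates and lick latencies from a lognormal
  matched to the observed median (611 ms);
* random-double-sweep (RDS) mapping stimuli filling inter-trial intervals,
  always ending before the silent pre-stimulus window of the next trial;
* a population of linear-nonlinear Poisson units with laminar depths,
  bimodal waveform widths, optional Gabor spectrotemporal kernels, and
  multiplicative rule-dependent gain on baseline and evoked rates (factor
  1.0 = no attentional effect; the deep-layer default emulates auditory-rule
  suppression);
* a 64-channel laminar profile (LFP amplitude and multi-unit
  tone-responsiveness) from which the cortical span can be re-estimated.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lnp, stimuli
from .lnp import GroundTruthUnit, lag_grid, make_gabor_strf, poisson_spikes_from_rate
from .stimuli import LOG2_F_HI, LOG2_F_LO, RDSStimulus, generate_rds, rds_to_tf

RULES = ("A", "V")
AV_STIMULI = ("A_RV_R", "A_RV_U", "A_UV_R", "A_UV_U")
DEPTH_GROUPS = ("superficial", "middle", "deep")
WAVEFORM_CLASSES = ("BS", "NS")

DT_SPIKE = 0.001  # spike simulation resolution, s
PSTH_NBINS = 10  # 0-300 ms evoked window at 30 ms


def _default_unit_counts() -> dict:
    return {
        ("superficial", "BS"): 8,
        ("middle", "BS"): 8,
        ("deep", "BS"): 12,
        ("superficial", "NS"): 3,
        ("middle", "NS"): 3,
        ("deep", "NS"): 3,
    }


def _default_a_rule_factors() -> dict:
    # auditory attention suppresses deep-layer rates multiplicatively
    return {"superficial": 1.0, "middle": 1.0, "deep": 0.85}


@dataclass
class SessionConfig:
    """Generative parameters of a synthetic session (defaults = study conditions)."""

    rule_order: str = "A-first"  # or "V-first"
    n_unimodal_trials: int = 30
    n_av_trials: int = 100
    hit_rate: dict = field(default_factory=lambda: {"A": 0.90, "V": 0.90})
    fa_rate: dict = field(default_factory=lambda: {"A": 0.15, "V": 0.15})
    lick_latency_median_s: float = 0.611
    lick_latency_sigma: float = 0.35
    early_lick_rate: float = 0.02
    prestim_lick_rate: float = 0.02
    iti_range_s: tuple = (3.0, 9.0)
    stim_dur_s: float = 1.0
    post_stim_gap_s: float = 1.0
    rds_start_gap_s: float = 0.2
    rds_end_gap_s: float = 0.35  # RDS ends at least this long before next onset
    min_rds_epoch_s: float = 1.0
    # units
    unit_counts: dict = field(default_factory=_default_unit_counts)
    a_rule_factor_by_group: dict = field(default_factory=_default_a_rule_factors)
    baseline_rate_mean_hz: float = 6.0
    evoked_rate_mean_hz: float = 16.0
    tuned_fraction: float = 0.5
    rds_drive_gain_hz: float = 3.0
    fa_prestim_delta_hz: float = 0.0  # boost on A-rule FA trials (suppressed deep units)
    include_rds_drive: bool = True
    # probe
    n_channels: int = 64
    cortex_top_channel: int = 10
    cortex_bottom_channel: int = 50
    channel_noise: float = 0.05
    depth_boundaries: tuple = (0.365, 0.505)

    def validate(self) -> None:
        if self.rule_order not in ("A-first", "V-first"):
            raise ValueError(f"unknown rule_order {self.rule_order!r}")
        for rule in RULES:
            for name, d in (("hit_rate", self.hit_rate), ("fa_rate", self.fa_rate)):
                v = d[rule]
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}[{rule}]={v} outside [0, 1]")
        if self.n_unimodal_trials <= 0 or self.n_av_trials <= 0:
            raise ValueError("trial counts must be positive")
        if any(n < 0 for n in self.unit_counts.values()):
            raise ValueError("unit counts must be non-negative")
        if any(f < 0 for f in self.a_rule_factor_by_group.values()):
            raise ValueError("rule factors must be non-negative")
        if not 0 <= self.cortex_top_channel < self.cortex_bottom_channel < self.n_channels:
            raise ValueError("cortical span outside channel range")


@dataclass
class RDSEpoch:
    """One inter-trial RDS presentation."""

    start: float  # absolute s
    stop: float
    rule: str
    block: int
    stimulus: RDSStimulus

    @property
    def duration(self) -> float:
        return self.stop - self.start


@dataclass
class ChannelProfile:
    """Per-channel laminar summaries; index 0 = shallowest channel."""

    lfp_amp: np.ndarray  # max LFP amplitude per channel (arbitrary units)
    mua_responsive: np.ndarray  # bool: reliable tone-evoked MUA response


@dataclass
class SessionData:
    """Full synthetic session: spikes, trials, mapping stimuli, channels."""

    spike_times: list  # per unit, sorted np.ndarray of absolute times (s)
    unit_table: pd.DataFrame  # unit_id, trough_peak_ms, peak_channel, ...
    trials: pd.DataFrame
    rds_epochs: list  # of RDSEpoch
    channel_profile: ChannelProfile
    meta: dict

    @property
    def duration(self) -> float:
        return float(self.meta["duration"])


def generate_channel_profiles(config: SessionConfig, seed: int) -> ChannelProfile:
    """Simulate the laminar probe summaries used for span estimation.

    LFP amplitude sits at the probe noise floor above the pia and is large
    within cortex (and, attenuated, in white matter below); multi-unit
    tone-responsiveness is reliable only between the pia and the
    white-matter border, with a small mislabel probability per channel.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_channels
    top, bot = config.cortex_top_channel, config.cortex_bottom_channel
    noise = config.channel_noise
    floor, cortical = 1.0, 6.0
    amp = np.full(n, floor)
    amp[top:] = cortical
    if bot + 1 < n:
        amp[bot + 1 :] = 0.55 * cortical  # white matter: attenuated but not at floor
    amp = amp * (1.0 + noise * rng.standard_normal(n))
    mua = np.zeros(n, dtype=bool)
    mua[top : bot + 1] = True
    if noise > 0:
        flip_in = rng.random(n) < 0.01  # occasional unresponsive cortical channel
        flip_out = rng.random(n) < 0.001
        mua[top : bot + 1] ^= flip_in[top : bot + 1]
        mua[: max(top - 1, 0)] |= flip_out[: max(top - 1, 0)]
        mua[min(bot + 2, n) :] |= flip_out[min(bot + 2, n) :]
        mua[bot] = True  # border channel responds by construction
        mua[top] = True
    return ChannelProfile(lfp_amp=amp, mua_responsive=mua)


def _block_sequence(rule_order: str) -> list:
    first = "A" if rule_order == "A-first" else "V"
    second = "V" if first == "A" else "A"
    return [(first, "uni"), (first, "AV"), (second, "uni"), (second, "AV")]


def _draw_trials(config: SessionConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    t = 5.0
    for block_idx, (rule, modality) in enumerate(_block_sequence(config.rule_order)):
        n_tr = config.n_unimodal_trials if modality == "uni" else config.n_av_trials
        for _ in range(n_tr):
            iti = rng.uniform(*config.iti_range_s)
            onset = t + iti
            if modality == "uni":
                stim = f"{rule}_{'R' if rng.random() < 0.5 else 'U'}"
            else:
                stim = AV_STIMULI[rng.integers(4)]
            # reward relevance under the block's rule
            idx = stim.index(rule + "_")
            is_target = stim[idx + 2] == "R"
            if is_target:
                outcome = "hit" if rng.random() < config.hit_rate[rule] else "miss"
            else:
                outcome = "fa" if rng.random() < config.fa_rate[rule] else "cr"
            if outcome in ("hit", "fa"):
                first_lick = rng.lognormal(
                    np.log(config.lick_latency_median_s), config.lick_latency_sigma
                )
            else:
                first_lick = np.nan
            early = rng.uniform(0.05, 0.295) if rng.random() < config.early_lick_rate else np.nan
            pre = rng.uniform(-0.5, -0.01) if rng.random() < config.prestim_lick_rate else np.nan
            rows.append(
                {
                    "trial": len(rows),
                    "block": block_idx,
                    "rule": rule,
                    "modality": modality,
                    "stimulus": stim,
                    "is_target": is_target,
                    "outcome": outcome,
                    "t_onset": onset,
                    "first_lick": first_lick,
                    "early_lick": early,
                    "prestim_lick": pre,
                }
            )
            t = onset + config.stim_dur_s + config.post_stim_gap_s
    return pd.DataFrame(rows)


def _draw_rds_epochs(
    config: SessionConfig, trials: pd.DataFrame, rng: np.random.Generator
) -> list:
    epochs = []
    prev_end = 0.0
    prev_block = {}
    for _, tr in trials.iterrows():
        start = prev_end + config.rds_start_gap_s
        stop = tr.t_onset - config.rds_end_gap_s
        if stop - start >= config.min_rds_epoch_s:
            stim = generate_rds(stop - start, seed=int(rng.integers(2**31)))
            epochs.append(
                RDSEpoch(
                    start=start,
                    stop=start + stim.duration,
                    rule=tr.rule,
                    block=int(tr.block),
                    stimulus=stim,
                )
            )
        prev_end = tr.t_onset + config.stim_dur_s
    return epochs


def _depth_band(group: str, boundaries: tuple) -> tuple:
    b1, b2 = boundaries
    if group == "superficial":
        return (0.03, b1 - 0.02)
    if group == "middle":
        return (b1 + 0.01, b2 - 0.005)
    return (b2 + 0.015, 0.98)


def _draw_units(config: SessionConfig, rng: np.random.Generator) -> list:
    lags = lag_grid()
    n_freq = int(round((LOG2_F_HI - LOG2_F_LO) / 0.2))
    fc = LOG2_F_LO + 0.2 * (np.arange(n_freq) + 0.5)
    units = []
    uid = 0
    for (group, wf), count in sorted(config.unit_counts.items()):
        for _ in range(count):
            frac = rng.uniform(*_depth_band(group, config.depth_boundaries))
            top, bot = config.cortex_top_channel, config.cortex_bottom_channel
            peak_ch = int(round(top + frac * (bot - top)))
            tp = rng.uniform(0.25, 0.55) if wf == "NS" else rng.uniform(0.65, 1.10)
            base = float(
                np.clip(config.baseline_rate_mean_hz * rng.lognormal(0.0, 0.4), 0.5, 40.0)
            )
            factor = config.a_rule_factor_by_group[group]
            profile = {}
            # auditory amplitudes widely dispersed: the two tone clouds sit an
            # octave apart, so frequency-tuned units respond very unequally
            for el, scale, sd in (("A_R", 1.0, 1.0), ("A_U", 1.0, 1.0),
                                  ("V_R", 0.3, 0.5), ("V_U", 0.3, 0.5)):
                amp = scale * config.evoked_rate_mean_hz * rng.lognormal(0.0, sd)
                shape = np.exp(-np.arange(PSTH_NBINS) / rng.uniform(2.0, 6.0))
                shape *= rng.lognormal(0.0, 0.3, PSTH_NBINS)
                profile[el] = amp * shape / shape.mean()
            tuned = rng.random() < config.tuned_fraction
            if tuned:
                bf = rng.uniform(LOG2_F_LO + 0.7, LOG2_F_HI - 0.7)
                k = make_gabor_strf(lags, fc, bf_log2=bf, peak_lag=rng.uniform(-0.07, -0.03))
                k /= np.linalg.norm(k)
                strf_truth = k
            else:
                strf_truth = None
            delta = config.fa_prestim_delta_hz if (group == "deep" and factor < 1.0) else 0.0
            units.append(
                GroundTruthUnit(
                    unit_id=uid,
                    strf_truth=strf_truth,
                    baseline_rate_by_rule={"A": base * factor, "V": base},
                    evoked_gain_by_rule={"A": factor, "V": 1.0},
                    decision_response_profile=profile,
                    depth_fraction=frac,
                    trough_peak_ms=tp,
                    peak_channel=peak_ch,
                    rds_drive_gain=config.rds_drive_gain_hz,
                    fa_prestim_delta_hz=delta,
                )
            )
            uid += 1
    return units


def _unit_rate_profile(
    unit: GroundTruthUnit,
    config: SessionConfig,
    trials: pd.DataFrame,
    epochs: list,
    block_rules: list,
    block_bounds: np.ndarray,
    n_bins: int,
    drive_cache: dict,
) -> np.ndarray:
    rate = np.zeros(n_bins)
    # rule-dependent baseline over block spans
    for b, rule in enumerate(block_rules):
        i0 = int(block_bounds[b] / DT_SPIKE)
        i1 = int(block_bounds[b + 1] / DT_SPIKE)
        rate[i0:i1] = unit.baseline(rule)
    # decision-stimulus responses over the 0-300 ms evoked window
    bin_per_psth = int(round(0.030 / DT_SPIKE))
    for _, tr in trials.iterrows():
        i0 = int(round(tr.t_onset / DT_SPIKE))
        prof = np.zeros(PSTH_NBINS)
        for el, p in unit.decision_response_profile.items():
            if el in tr.stimulus:
                prof = prof + p
        evoked = unit.evoked_gain(tr.rule) * np.repeat(prof, bin_per_psth)
        rate[i0 : i0 + evoked.size] += evoked[: max(0, min(evoked.size, n_bins - i0))]
        if (
            unit.fa_prestim_delta_hz > 0
            and tr.rule == "A"
            and tr.outcome == "fa"
        ):
            j0 = int(round((tr.t_onset - 0.3) / DT_SPIKE))
            rate[j0:i0] += unit.fa_prestim_delta_hz
    # RDS-driven modulation for tuned units
    if unit.strf_truth is not None and config.include_rds_drive:
        for k, ep in enumerate(epochs):
            tf = drive_cache[k]
            drive = lnp.linear_drive(tf, unit.strf_truth)
            g = unit.evoked_gain(ep.rule) * unit.rds_drive_gain
            per = int(round(tf.dt / DT_SPIKE))
            seg = np.repeat(g * drive, per)
            i0 = int(round(ep.start / DT_SPIKE))
            i1 = min(i0 + seg.size, n_bins)
            rate[i0:i1] += seg[: i1 - i0]
    return np.maximum(rate, 0.0)


def generate_session(config: SessionConfig, seed: int):
    """Generate a full synthetic session.

    Returns ``(SessionData, list[GroundTruthUnit])``.  Deterministic: the
    same (config, seed) always yields an identical session.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    trials = _draw_trials(config, rng)
    epochs = _draw_rds_epochs(config, trials, rng)
    channels = generate_channel_profiles(config, seed=int(rng.integers(2**31)))
    units = _draw_units(config, rng)

    duration = float(trials.t_onset.iloc[-1] + config.stim_dur_s + config.post_stim_gap_s + 2.0)
    n_bins = int(np.ceil(duration / DT_SPIKE))
    block_rules = [r for r, _ in _block_sequence(config.rule_order)]
    # block bounds: midpoint between the end of one block's last stimulus and
    # the next block's first onset
    starts = trials.groupby("block").t_onset.min().to_numpy()
    ends = trials.groupby("block").t_onset.max().to_numpy() + config.stim_dur_s
    bounds = [0.0]
    for b in range(len(starts) - 1):
        bounds.append(0.5 * (ends[b] + starts[b + 1]))
    bounds.append(duration)
    block_bounds = np.asarray(bounds)

    drive_cache = {}
    if config.include_rds_drive and any(u.strf_truth is not None for u in units):
        for k, ep in enumerate(epochs):
            drive_cache[k] = rds_to_tf(ep.stimulus, smooth_sigma_oct=0.1, t0=ep.start)

    spike_times = []
    for unit in units:
        rate = _unit_rate_profile(
            unit, config, trials, epochs, block_rules, block_bounds, n_bins, drive_cache
        )
        unit_rng = np.random.default_rng(int(rng.integers(2**31)))
        spike_times.append(poisson_spikes_from_rate(rate, DT_SPIKE, unit_rng))

    unit_table = pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in units],
            "trough_peak_ms": [u.trough_peak_ms for u in units],
            "peak_channel": [u.peak_channel for u in units],
            "depth_fraction_true": [u.depth_fraction for u in units],
            "tuned_true": [u.strf_truth is not None for u in units],
            "a_rule_factor_true": [u.evoked_gain_by_rule["A"] for u in units],
        }
    )
    meta = {
        "rule_order": config.rule_order,
        "seed": seed,
        "duration": duration,
        "block_bounds": block_bounds.tolist(),
        "block_rules": block_rules,
        "rds_seconds_by_rule": {
            r: float(sum(ep.duration for ep in epochs if ep.rule == r)) for r in RULES
        },
    }
    data = SessionData(
        spike_times=spike_times,
        unit_table=unit_table,
        trials=trials,
        rds_epochs=epochs,
        channel_profile=channels,
        meta=meta,
    )
    return data, units
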