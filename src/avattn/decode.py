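"""Leave-one-out PSTH-template decoding with confusion-matrix information.

Single-trial responses are binned spike counts over the 0-300 ms evoked
window at a 30 ms binwidth (10 bins).  Each test trial is classified to the
nearest class-template PSTH in Euclidean space, where only the test trial's
own class template is recomputed without it; ties break uniformly at random
under an explicit seed.  Decoding accuracy is the fraction of correctly
assigned trials; mutual information is the plug-in MI of the confusion
matrix

    MI = sum_ij P(Xi, Yj) log2( P(Xi, Yj) / (P(Xi) P(Yj)) )

(X = prediction, Y = actual class), and encoding efficiency divides MI by
the joint mean spikes per trial of the responses submitted to the decoder.
Units enter a decode only with >= 10 qualifying trials and a mean rate of
at least 1 Hz in the window for every class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rates import window_counts

DECODE_WINDOW = (0.0, 0.300)
PSTH_BINWIDTH = 0.030
MIN_CLASS_TRIALS = 10
MIN_CLASS_RATE_HZ = 1.0


@dataclass
class BinnedTrialMatrix:
    """Per-trial binned spike counts with class labels."""

    counts: np.ndarray  # (n_trials, n_bins) non-negative integers
    labels: np.ndarray  # (n_trials,) class label per trial
    classes: np.ndarray  # unique class labels, fixed order
    window: tuple = DECODE_WINDOW
    binwidth: float = PSTH_BINWIDTH
    included: bool = True
    exclusion_reason: str = ""

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


@dataclass
class DecodeResult:
    """Confusion matrix (predicted x actual) and its summary statistics."""

    confusion: np.ndarray  # (k, k) counts, rows = predicted, cols = actual
    classes: np.ndarray
    accuracy: float
    mi_bits: float
    mean_spikes_per_trial: float
    efficiency: float  # bits/spike
    n_trials_per_class: np.ndarray


def bin_trials(
    spike_times: np.ndarray,
    onsets_by_class: dict,
    window: tuple = DECODE_WINDOW,
    binwidth: float = PSTH_BINWIDTH,
    min_trials: int = MIN_CLASS_TRIALS,
    min_rate_hz: float = MIN_CLASS_RATE_HZ,
) -> BinnedTrialMatrix:
    """Bin one unit's responses to labeled trial onsets.

    Inclusion requires every class to carry ``min_trials`` trials and a
    class-mean firing rate of ``min_rate_hz`` in the window; failures are
    recorded on the returned matrix (``included=False``), not raised, so
    callers can report exclusions.
    """
    a, b = window
    n_bins = int(round((b - a) / binwidth))
    classes = np.array(sorted(onsets_by_class))
    mats, labels = [], []
    reasons = []
    win_len = b - a
    for c in classes:
        onsets = np.asarray(onsets_by_class[c], dtype=float)
        m = np.stack(
            [
                window_counts(spike_times, onsets, (a + i * binwidth, a + (i + 1) * binwidth))
                for i in range(n_bins)
            ],
            axis=1,
        ) if onsets.size else np.zeros((0, n_bins), dtype=int)
        mats.append(m)
        labels.extend([c] * m.shape[0])
        if m.shape[0] < min_trials:
            reasons.append(f"class {c}: {m.shape[0]} trials < {min_trials}")
        elif m.sum() / (m.shape[0] * win_len) < min_rate_hz:
            reasons.append(f"class {c}: mean rate below {min_rate_hz} Hz")
    counts = np.concatenate(mats, axis=0)
    return BinnedTrialMatrix(
        counts=counts,
        labels=np.array(labels),
        classes=classes,
        window=window,
        binwidth=binwidth,
        included=not reasons,
        exclusion_reason="; ".join(reasons),
    )


def confusion_mi(confusion: np.ndarray) -> float:
    """Plug-in mutual information (bits) of a confusion-matrix contingency
    table, with 0 log 0 = 0.  Bounded by log2(k)."""
    c = np.asarray(confusion, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p = c / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def loo_classify(data: BinnedTrialMatrix, seed: int = 0) -> DecodeResult:
    """Leave-one-out nearest-template classification.

    For each test trial, its own class's template is the mean PSTH of that
    class excluding the trial; other classes use their full-class means.
    The trial is assigned to the template at minimal Euclidean distance,
    ties broken uniformly at random (seeded).
    """
    k = data.classes.size
    if k < 2:
        raise ValueError("need >= 2 classes to decode")
    counts = data.counts.astype(float)
    labels = data.labels
    class_idx = {c: i for i, c in enumerate(data.classes)}
    sums = np.zeros((k, data.n_bins))
    ns = np.zeros(k, dtype=int)
    for c, i in class_idx.items():
        rows = counts[labels == c]
        if rows.shape[0] < 2:
            raise ValueError(f"class {c} has fewer than 2 trials")
        sums[i] = rows.sum(axis=0)
        ns[i] = rows.shape[0]
    rng = np.random.default_rng(seed)
    confusion = np.zeros((k, k), dtype=int)
    for t in range(counts.shape[0]):
        actual = class_idx[labels[t]]
        templates = sums / ns[:, None]
        templates[actual] = (sums[actual] - counts[t]) / (ns[actual] - 1)
        d2 = ((templates - counts[t]) ** 2).sum(axis=1)
        # ties detected with a tiny tolerance: exact distance ties between
        # integer-count PSTHs survive float summation-order differences
        best = np.flatnonzero(d2 <= d2.min() * (1 + 1e-9) + 1e-12)
        pred = int(best[0] if best.size == 1 else rng.choice(best))
        confusion[pred, actual] += 1
    total = confusion.sum()
    accuracy = float(np.trace(confusion) / total)
    mi = confusion_mi(confusion)
    mean_spikes = float(counts.sum(axis=1).mean())
    return DecodeResult(
        confusion=confusion,
        classes=data.classes,
        accuracy=accuracy,
        mi_bits=mi,
        mean_spikes_per_trial=mean_spikes,
        efficiency=encoding_efficiency(mi, mean_spikes),
        n_trials_per_class=ns,
    )


def encoding_efficiency(mi_bits: float, mean_spikes_per_trial: float) -> float:
    """Bits per spike: MI normalized by the joint mean spikes per trial."""
    if mean_spikes_per_trial <= 0:
        raise ValueError("mean spikes per trial must be positive")
    return float(mi_bits / mean_spikes_per_trial)


STIMULUS_RUNS = {
    # within each rule, decode the auditory element holding the visual fixed
    "V_R": ("A_RV_R", "A_UV_R"),
    "V_U": ("A_RV_U", "A_UV_U"),
}


def _onsets(trials: pd.DataFrame, rule: str, stimulus: str) -> np.ndarray:
    sub = trials[(trials.rule == rule) & (trials.stimulus == stimulus)]
    return sub.t_onset.to_numpy()


def decode_stimulus_across_rules(
    spike_times: np.ndarray,
    trials: pd.DataFrame,
    seed: int = 0,
    **bin_kwargs,
):
    """Auditory-element decoding within each rule, averaged over the two
    visual pairings.

    For each rule, two decoder runs (A_RV_R vs A_UV_R, and A_RV_U vs
    A_UV_U) are executed and their accuracy/MI/efficiency averaged.
    Returns ``(per_rule_mean: dict, runs: dict, excluded_reason)``; a unit
    failing inclusion in any of the four conditions is excluded.
    """
    runs, reasons = {}, []
    for rule in ("A", "V"):
        for vis, (s1, s2) in STIMULUS_RUNS.items():
            data = bin_trials(
                spike_times,
                {s1: _onsets(trials, rule, s1), s2: _onsets(trials, rule, s2)},
                **bin_kwargs,
            )
            if not data.included:
                reasons.append(f"rule {rule}, run {vis}: {data.exclusion_reason}")
                continue
            runs[(rule, vis)] = loo_classify(data, seed=seed)
    if reasons:
        return None, runs, "; ".join(reasons)
    per_rule = {}
    for rule in ("A", "V"):
        rr = [runs[(rule, v)] for v in STIMULUS_RUNS]
        per_rule[rule] = {
            "accuracy": float(np.mean([r.accuracy for r in rr])),
            "mi_bits": float(np.mean([r.mi_bits for r in rr])),
            "efficiency": float(np.mean([r.efficiency for r in rr])),
            "mean_spikes_per_trial": float(np.mean([r.mean_spikes_per_trial for r in rr])),
        }
    return per_rule, runs, ""


def decode_rule(
    spike_times: np.ndarray,
    trials: pd.DataFrame,
    stimulus: str,
    seed: int = 0,
    **bin_kwargs,
):
    """Decode task rule (A vs V) from responses to one AV stimulus.

    Returns ``(DecodeResult | None, exclusion_reason)``.
    """
    data = bin_trials(
        spike_times,
        {"A": _onsets(trials, "A", stimulus), "V": _onsets(trials, "V", stimulus)},
        **bin_kwargs,
    )
    if not data.included:
        return None, data.exclusion_reason
    return loo_classify(data, seed=seed), ""
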