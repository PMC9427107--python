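"""Behavioral sensitivity, session inclusion, and trial filters.

Go/no-go performance is summarized with the sensitivity index

    d' = Z(H) - Z(F)

where Z is the inverse normal transform and H, F are hit and false-alarm
rates after the log-linear correction (0.5 added to every cell of the 2x2
outcome table), which keeps both rates strictly inside (0, 1) even for
perfect performance:

    H = (hits + 0.5) / (hits + misses + 1)
    F = (FA + 0.5) / (FA + CR + 1)

Sessions qualify for physiological analysis only when d' > 1.5 under both
rules and the false-alarm rate to conflict stimuli (A_UV_R in the A-rule,
A_RV_U in the V-rule — stimuli whose reward valence flips between rules) is
below 0.5 in both rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

D_PRIME_THRESHOLD = 1.5
FAR_CONFLICT_THRESHOLD = 0.5
CONFLICT_STIMULUS = {"A": "A_UV_R", "V": "A_RV_U"}
EARLY_LICK_WINDOW = (0.0, 0.3)  # licks before 300 ms post-onset
PRESTIM_LICK_WINDOW = (-0.5, 0.0)  # licks within 500 ms pre-onset


@dataclass(frozen=True)
class OutcomeCounts:
    hits: int
    misses: int
    false_alarms: int
    correct_rejects: int

    def __post_init__(self):
        for name in ("hits", "misses", "false_alarms", "correct_rejects"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.hits + self.misses + self.false_alarms + self.correct_rejects

    def swapped(self) -> "OutcomeCounts":
        """Exchange the target and distractor rows of the contingency table."""
        return OutcomeCounts(self.false_alarms, self.correct_rejects, self.hits, self.misses)


@dataclass(frozen=True)
class SessionInclusion:
    d_prime_by_rule: dict
    far_conflict_by_rule: dict
    included: bool


def loglinear_rates(counts: OutcomeCounts) -> tuple:
    """Hit and false-alarm rates with the log-linear correction; both in (0, 1)."""
    h = (counts.hits + 0.5) / (counts.hits + counts.misses + 1)
    f = (counts.false_alarms + 0.5) / (counts.false_alarms + counts.correct_rejects + 1)
    return h, f


def d_prime(counts: OutcomeCounts) -> float:
    """Sensitivity index Z(H) - Z(F) on log-linear-corrected rates.

    Antisymmetric under swapping the target and distractor rows.
    """
    h, f = loglinear_rates(counts)
    return float(norm.ppf(h) - norm.ppf(f))


def outcome_counts(trials: pd.DataFrame) -> OutcomeCounts:
    """Tally the 2x2 outcome table from a trial-table subset."""
    oc = trials.outcome.value_counts()
    return OutcomeCounts(
        hits=int(oc.get("hit", 0)),
        misses=int(oc.get("miss", 0)),
        false_alarms=int(oc.get("fa", 0)),
        correct_rejects=int(oc.get("cr", 0)),
    )


def session_inclusion(
    trials: pd.DataFrame,
    d_prime_threshold: float = D_PRIME_THRESHOLD,
    far_threshold: float = FAR_CONFLICT_THRESHOLD,
    bimodal_only: bool = True,
) -> SessionInclusion:
    """Evaluate the physiology inclusion criteria on a session's trials.

    d' is computed per rule (by default from that rule's bimodal-block
    trials); the conflict false-alarm rate uses only the stimulus whose
    reward valence conflicts across rules.
    """
    dp, far = {}, {}
    for rule in ("A", "V"):
        sub = trials[trials.rule == rule]
        if bimodal_only:
            sub = sub[sub.modality == "AV"]
        if len(sub) == 0:
            raise ValueError(f"no trials for rule {rule}")
        dp[rule] = d_prime(outcome_counts(sub))
        conf = sub[sub.stimulus == CONFLICT_STIMULUS[rule]]
        n_fa = int((conf.outcome == "fa").sum())
        n_cr = int((conf.outcome == "cr").sum())
        far[rule] = n_fa / (n_fa + n_cr) if (n_fa + n_cr) > 0 else np.nan
    included = all(dp[r] > d_prime_threshold for r in ("A", "V")) and all(
        not np.isnan(far[r]) and far[r] < far_threshold for r in ("A", "V")
    )
    return SessionInclusion(d_prime_by_rule=dp, far_conflict_by_rule=far, included=included)


def _lick_violation(trials: pd.DataFrame) -> pd.Series:
    """True for trials with a lick in the early post-onset or pre-onset window."""
    licks = [c for c in ("first_lick", "early_lick", "prestim_lick") if c in trials]
    bad = pd.Series(False, index=trials.index)
    for col in licks:
        t = trials[col]
        bad |= (t >= EARLY_LICK_WINDOW[0]) & (t < EARLY_LICK_WINDOW[1])
        bad |= (t >= PRESTIM_LICK_WINDOW[0]) & (t < PRESTIM_LICK_WINDOW[1])
    return bad


def filter_trials(trials: pd.DataFrame, mode: str = "correct") -> pd.DataFrame:
    """Select trials usable for physiology windows.

    All modes drop trials with a lick earlier than 300 ms post-onset or
    within 500 ms pre-onset (lick times are onset-relative).  Modes:

    * ``"correct"`` — hits and correct rejects only (the default for
      decision-stimulus analyses);
    * ``"fa_cr"`` — false alarms and correct rejects (the error-contrast
      path; misses are excluded as too rare to analyze);
    * ``"all"`` — lick filters only.

    Idempotent: filtering a filtered table changes nothing.
    """
    keep = ~_lick_violation(trials)
    if mode == "correct":
        keep &= trials.outcome.isin(["hit", "cr"])
    elif mode == "fa_cr":
        keep &= trials.outcome.isin(["fa", "cr"])
    elif mode != "all":
        raise ValueError(f"unknown mode {mode!r}")
    return trials[keep].copy()
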