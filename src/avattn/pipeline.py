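"""End-to-end analysis pipeline over a session container.

Stages: behavioral inclusion -> unit QC (waveform, depth, stability) ->
rule-contrast firing-rate analyses (raw and baseline-normalized, with
group-level paired Wilcoxon tests BH-corrected across the six depth x
waveform groups) -> PSTH-template decoding across rules -> optional STRF
estimation with reliability and projection information -> false-alarm vs
correct-reject pre-stimulus contrast.  Every unit exclusion is recorded
with the rule that triggered it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import behavior, decode, qc, rates, stats, strf
from .session import DEPTH_GROUPS, SessionData, WAVEFORM_CLASSES
from .stimuli import rds_to_tf


@dataclass
class PipelineParams:
    """Analysis thresholds; defaults echo the study's values."""

    d_prime_threshold: float = 1.5
    far_conflict_threshold: float = 0.5
    min_trials: int = 10
    per_unit_alpha: float = 0.01
    group_q: float = 0.05
    waveform_boundary_ms: float = 0.6
    depth_boundaries: tuple = (0.365, 0.505)
    max_unstable_fraction: float = 0.10
    run_strf: bool = False
    strf_n_reps: int = 100
    strf_min_spikes: int = 50
    tf_smooth_sigma_oct: float = 0.1
    seed: int = 0


def qc_table(data: SessionData, params: PipelineParams) -> pd.DataFrame:
    """Per-unit QC: waveform class, laminar depth, stability fraction."""
    top, bottom = qc.estimate_cortical_span(
        data.channel_profile.lfp_amp, data.channel_profile.mua_responsive
    )
    rows = []
    for _, u in data.unit_table.iterrows():
        wf = qc.classify_waveform(u.trough_peak_ms, params.waveform_boundary_ms)
        ch = int(np.clip(u.peak_channel, top, bottom))
        frac, group = qc.assign_depth(ch, (top, bottom), params.depth_boundaries)
        stab = qc.stability_screen(data.spike_times[int(u.unit_id)], data.duration)
        rows.append(
            {
                "unit_id": int(u.unit_id),
                "waveform_class": wf,
                "depth_fraction": frac,
                "depth_group": group,
                "unstable_fraction": stab.unstable_fraction,
                "strf_eligible": stab.unstable_fraction <= params.max_unstable_fraction,
                "span_top": top,
                "span_bottom": bottom,
            }
        )
    return pd.DataFrame(rows)


def _rule_trial_onsets(trials: pd.DataFrame, rule: str) -> dict:
    """Correct AV-trial onsets of one rule, keyed by collapsed auditory class."""
    out = {}
    for cls in ("A_R*", "A_U*"):
        pool = rates.collapse_stimuli(trials, cls)
        out[cls] = pool[pool.rule == rule].t_onset.to_numpy()
    return out


def rule_modulation_table(
    data: SessionData,
    trials: pd.DataFrame,
    params: PipelineParams,
    window: tuple = rates.EVOKED_WINDOW,
    normalize: bool = False,
) -> pd.DataFrame:
    """Per-unit A/V fold change of evoked rate over correct AV trials.

    The mean per rule averages the two collapsed auditory-class means so
    rule comparisons are not biased by the different stimulus composition
    of correct trials under each rule.  With ``normalize``, each rule's
    rates are first divided by that rule's mean pre-stimulus rate.
    """
    onsets = {r: _rule_trial_onsets(trials, r) for r in ("A", "V")}
    rows = []
    for uid, st in enumerate(data.spike_times):
        per_rule = {}
        reason = ""
        for rule in ("A", "V"):
            cls_rates = []
            for cls, on in onsets[rule].items():
                if on.size < params.min_trials:
                    reason = f"fewer than {params.min_trials} {cls} trials in rule {rule}"
                    break
                tr = rates.window_rates(st, on, window, unit_id=uid, condition=f"{rule} {cls}")
                if normalize:
                    pre = rates.window_rates(st, on, rates.PRESTIM_WINDOW, unit_id=uid)
                    if not pre.mean > 0:
                        reason = f"zero pre-stimulus rate in rule {rule}"
                        break
                    tr = rates.baseline_normalize(tr, pre)
                cls_rates.append(tr)
            if reason:
                break
            per_rule[rule] = cls_rates
        if reason:
            rows.append({"unit_id": uid, "excluded": True, "exclusion_reason": reason})
            continue
        pooled = {
            r: rates.TrialRates(
                unit_id=uid,
                condition=r,
                rates=np.concatenate([t.rates for t in per_rule[r]]),
                window=window,
            )
            for r in ("A", "V")
        }
        mod = rates.unit_rule_modulation(
            pooled["A"], pooled["V"], min_trials=params.min_trials, alpha=params.per_unit_alpha
        )
        mean_a = float(np.mean([t.mean for t in per_rule["A"]]))
        mean_v = float(np.mean([t.mean for t in per_rule["V"]]))
        fc = mean_a / mean_v if (mean_a > 0 and mean_v > 0) else np.nan
        rows.append(
            {
                "unit_id": uid,
                "mean_fr_a": mean_a,
                "mean_fr_v": mean_v,
                "fold_change": fc,
                "per_unit_p": mod.per_unit_p,
                "per_unit_significant": mod.significant,
                "excluded": mod.excluded or not np.isfinite(fc),
                "exclusion_reason": mod.exclusion_reason,
            }
        )
    return pd.DataFrame(rows)


def group_rule_tests(
    mod_table: pd.DataFrame, qc_tab: pd.DataFrame, q: float = 0.05
) -> pd.DataFrame:
    """Paired WSR (A vs V) per depth x waveform group, BH-corrected."""
    merged = mod_table.merge(qc_tab, on="unit_id")
    ok = merged[~merged.excluded.astype(bool)]
    rows = []
    for dg in DEPTH_GROUPS:
        for wf in WAVEFORM_CLASSES:
            g = ok[(ok.depth_group == dg) & (ok.waveform_class == wf)]
            label = f"{dg}/{wf}"
            if len(g) < 6:
                rows.append(
                    {"group": label, "n": len(g), "statistic": np.nan,
                     "p_raw": np.nan, "median_fold_change": np.nan}
                )
                continue
            z, p = stats.wilcoxon_signed_rank(g.mean_fr_a.to_numpy(), g.mean_fr_v.to_numpy())
            rows.append(
                {"group": label, "n": len(g), "statistic": z, "p_raw": p,
                 "median_fold_change": float(g.fold_change.median())}
            )
    out = pd.DataFrame(rows)
    tested = out.p_raw.notna()
    p_adj = np.full(len(out), np.nan)
    rej = np.zeros(len(out), dtype=bool)
    if tested.any():
        adj, flags = stats.bh_fdr(out.p_raw[tested].to_numpy(), q=q)
        p_adj[tested.to_numpy()] = adj
        rej[tested.to_numpy()] = flags
    out["p_adjusted"] = p_adj
    out["significant"] = rej
    return out


def decode_table(
    data: SessionData, trials: pd.DataFrame, params: PipelineParams
) -> pd.DataFrame:
    """Per-unit cross-rule stimulus decoding: accuracy/MI/efficiency per
    rule and their A/V fold changes."""
    rows = []
    for uid, st in enumerate(data.spike_times):
        per_rule, _, reason = decode.decode_stimulus_across_rules(
            st, trials, seed=params.seed + uid, min_trials=params.min_trials
        )
        if per_rule is None:
            rows.append({"unit_id": uid, "excluded": True, "exclusion_reason": reason})
            continue
        a, v = per_rule["A"], per_rule["V"]
        rows.append(
            {
                "unit_id": uid,
                "acc_a": a["accuracy"], "acc_v": v["accuracy"],
                "mi_a": a["mi_bits"], "mi_v": v["mi_bits"],
                "eff_a": a["efficiency"], "eff_v": v["efficiency"],
                "acc_fc": a["accuracy"] / v["accuracy"] if v["accuracy"] > 0 else np.nan,
                "eff_fc": a["efficiency"] / v["efficiency"] if v["efficiency"] > 0 else np.nan,
                "excluded": False,
                "exclusion_reason": "",
            }
        )
    return pd.DataFrame(rows)


def strf_table(data: SessionData, qc_tab: pd.DataFrame, params: PipelineParams) -> pd.DataFrame:
    """Per-unit, per-rule STRF reliability, best frequency, and projection MI.

    Uses rule-equated RDS epochs; only stability-screened units with enough
    spikes enter.  Null sample sizes follow ``params.strf_n_reps``.
    """
    eq = strf.equate_rule_durations(
        {
            r: [(ep.start, ep.stop) for ep in data.rds_epochs if ep.rule == r]
            for r in ("A", "V")
        }
    )
    tf_by_rule = {}
    for rule, spans in eq.items():
        tfs = []
        for ep in data.rds_epochs:
            for s, e in spans:
                if ep.start <= s < ep.stop:
                    seg = ep.stimulus.slice(s - ep.start, e - ep.start)
                    tfs.append(
                        rds_to_tf(seg, smooth_sigma_oct=params.tf_smooth_sigma_oct, t0=s)
                    )
        tf_by_rule[rule] = tfs
    rows = []
    for _, u in qc_tab.iterrows():
        uid = int(u.unit_id)
        row = {"unit_id": uid}
        if not u.strf_eligible:
            row.update(excluded=True, exclusion_reason="unstable > 10% of recording")
            rows.append(row)
            continue
        st = data.spike_times[uid]
        for rule, tfs in tf_by_rule.items():
            epochs = [
                (tf, st[(st >= tf.t0) & (st < tf.t0 + tf.duration)]) for tf in tfs
            ]
            try:
                grid, _ = strf.estimate_strf(
                    epochs, min_spikes=params.strf_min_spikes, rule=rule
                )
                rel = strf.strf_reliability(
                    epochs, n_reps=params.strf_n_reps, seed=params.seed + uid
                )
                nulls = strf.null_strf_sample(
                    epochs, n_null=max(100, params.strf_n_reps), seed=params.seed + uid + 1
                )
                mask = strf.significant_bins(grid, nulls)
                bf = strf.best_frequency(grid, mask)
                dists = strf.projection_distributions(epochs, grid)
                mi = strf.strf_spike_mi(dists)
                row.update(
                    {
                        f"reliability_{rule}": rel.mean_r,
                        f"reliability_p_{rule}": rel.p,
                        f"bf_hz_{rule}": bf,
                        f"mi_bits_per_spike_{rule}": mi,
                        f"n_spikes_{rule}": grid.n_spikes,
                    }
                )
            except ValueError as err:
                row.update({f"excluded_{rule}": True, f"reason_{rule}": str(err)})
        pa, pv = row.get("reliability_p_A"), row.get("reliability_p_V")
        row["tuned"] = bool(
            (pa is not None and pa < 0.05) or (pv is not None and pv < 0.05)
        )
        rows.append(row)
    return pd.DataFrame(rows)


def fa_cr_table(
    data: SessionData, qc_tab: pd.DataFrame, mod_table: pd.DataFrame, params: PipelineParams
) -> pd.DataFrame:
    """Pre-stimulus FA-vs-CR contrast per rule, split by each unit's
    attentional direction (suppressed FC < 1 vs enhanced)."""
    err_trials = behavior.filter_trials(data.trials, mode="fa_cr")
    merged = qc_tab.merge(mod_table[["unit_id", "fold_change"]], on="unit_id")
    out = []
    for rule in ("A", "V"):
        try:
            tab = rates.fa_cr_prestim_contrast(
                data.spike_times, err_trials, rule, min_trials=params.min_trials
            )
        except ValueError as err:
            out.append(pd.DataFrame([{"rule": rule, "excluded_reason": str(err)}]))
            continue
        tab = tab.merge(merged, on="unit_id")
        tab["rule"] = rule
        tab["direction"] = np.where(tab.fold_change < 1, "suppressed", "enhanced")
        out.append(tab)
    return pd.concat(out, ignore_index=True)


def analyze_session(data: SessionData, params: PipelineParams | None = None) -> dict:
    """Run the full analysis battery; returns a dict of result tables.

    Halts after the behavior stage (with the inclusion report) when the
    session fails the d'/conflict-FAR criteria.
    """
    params = params or PipelineParams()
    incl = behavior.session_inclusion(
        data.trials, params.d_prime_threshold, params.far_conflict_threshold
    )
    results = {
        "inclusion": pd.DataFrame(
            [
                {
                    "rule": r,
                    "d_prime": incl.d_prime_by_rule[r],
                    "far_conflict": incl.far_conflict_by_rule[r],
                    "included": incl.included,
                }
                for r in ("A", "V")
            ]
        )
    }
    if not incl.included:
        return results
    qc_tab = qc_table(data, params)
    results["qc"] = qc_tab
    trials = behavior.filter_trials(data.trials, mode="correct")
    mod = rule_modulation_table(data, trials, params)
    results["rule_modulation"] = mod
    results["group_tests"] = group_rule_tests(mod, qc_tab, q=params.group_q)
    mod_norm = rule_modulation_table(data, trials, params, normalize=True)
    results["rule_modulation_normalized"] = mod_norm
    results["group_tests_normalized"] = group_rule_tests(mod_norm, qc_tab, q=params.group_q)
    results["decoding"] = decode_table(data, trials, params)
    try:
        results["fa_cr"] = fa_cr_table(data, qc_tab, mod, params)
    except ValueError:
        pass
    if params.run_strf:
        results["strf"] = strf_table(data, qc_tab, params)
    return results
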