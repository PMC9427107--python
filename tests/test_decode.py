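"""PSTH-template decoder: oracle equivalence, MI, efficiency, invariances."""

import numpy as np
import pandas as pd
import pytest

from avattn.decode import (
    BinnedTrialMatrix,
    bin_trials,
    confusion_mi,
    decode_rule,
    decode_stimulus_across_rules,
    encoding_efficiency,
    loo_classify,
)


def brute_force_loo(counts, labels, classes, seed):
    """Independent reimplementation: plain python loops, explicit templates."""
    rng = np.random.default_rng(seed)
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((k, k), dtype=int)
    for t in range(len(counts)):
        dists = []
        for c in classes:
            members = [i for i in range(len(counts)) if labels[i] == c]
            if labels[t] == c:
                members = [i for i in members if i != t]
            template = [
                sum(counts[i][b] for i in members) / len(members)
                for b in range(len(counts[t]))
            ]
            d2 = sum((counts[t][b] - template[b]) ** 2 for b in range(len(template)))
            dists.append(d2)
        best = [i for i, d in enumerate(dists)
                if d <= min(dists) * (1 + 1e-9) + 1e-12]
        pred = best[0] if len(best) == 1 else int(rng.choice(best))
        confusion[pred, idx[labels[t]]] += 1
    return confusion


def _matrix(counts, labels):
    counts = np.asarray(counts)
    labels = np.asarray(labels)
    return BinnedTrialMatrix(counts=counts, labels=labels,
                             classes=np.unique(labels))


class TestConfusionMI:
    def test_perfect_two_class_one_bit(self):
        assert confusion_mi([[10, 0], [0, 10]]) == pytest.approx(1.0)

    def test_independence_zero_bits(self):
        assert confusion_mi([[7, 7], [7, 7]]) == pytest.approx(0.0)

    def test_direct_summation_oracle(self):
        # [[3,1],[1,3]]: MI = 0.75 log2(1.5) + 0.25 log2(0.5)
        expected = 0.75 * np.log2(1.5) + 0.25 * np.log2(0.5)
        assert expected == pytest.approx(0.1887, abs=1e-4)
        assert confusion_mi([[3, 1], [1, 3]]) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_matrices_match_plugin_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 5)
        c = rng.integers(0, 30, size=(k, k))
        c[0, 0] += 1  # non-empty
        total = c.sum()
        mi = 0.0
        for i in range(k):
            for j in range(k):
                pij = c[i, j] / total
                pi = c[i, :].sum() / total
                pj = c[:, j].sum() / total
                if pij > 0:
                    mi += pij * np.log2(pij / (pi * pj))
        assert confusion_mi(c) == pytest.approx(mi, abs=1e-12)
        assert -1e-12 <= confusion_mi(c) <= np.log2(k) + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_mi(np.zeros((2, 2)))


class TestLooClassify:
    def test_disjoint_active_bins_perfect(self):
        a = np.tile([5, 0], (6, 1))
        b = np.tile([0, 5], (6, 1))
        data = _matrix(np.vstack([a, b]), ["a"] * 6 + ["b"] * 6)
        res = loo_classify(data, seed=0)
        assert res.accuracy == 1.0
        assert res.mi_bits == pytest.approx(1.0)

    def test_identical_constant_trials_chance(self):
        data = _matrix(np.full((20, 4), 3), ["a"] * 10 + ["b"] * 10)
        accs = [loo_classify(data, seed=s).accuracy for s in range(30)]
        assert np.mean(accs) == pytest.approx(0.5, abs=0.1)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n_per = int(rng.integers(2, 9))
        n_bins = int(rng.integers(1, 5))
        k = int(rng.integers(2, 4))
        counts = rng.integers(0, 4, size=(n_per * k, n_bins))
        labels = np.repeat([f"c{i}" for i in range(k)], n_per)
        data = _matrix(counts, labels)
        res = loo_classify(data, seed=seed)
        oracle = brute_force_loo(
            counts.tolist(), list(labels), list(data.classes), seed
        )
        np.testing.assert_array_equal(res.confusion, oracle)

    def test_confusion_columns_sum_to_class_counts(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2, size=(24, 10))
        data = _matrix(counts, ["a"] * 12 + ["b"] * 12)
        res = loo_classify(data, seed=1)
        np.testing.assert_array_equal(res.confusion.sum(axis=0), [12, 12])

    def test_whole_bin_shift_invariance(self):
        """Shifting every trial's counts by a whole bin does not change
        the decode (distances are permutation-invariant over bins)."""
        rng = np.random.default_rng(2)
        counts = rng.poisson(3, size=(20, 6))
        labels = ["a"] * 10 + ["b"] * 10
        res1 = loo_classify(_matrix(counts, labels), seed=3)
        res2 = loo_classify(_matrix(np.roll(counts, 1, axis=1), labels), seed=3)
        np.testing.assert_array_equal(res1.confusion, res2.confusion)

    def test_label_permutation_chance_level(self):
        rng = np.random.default_rng(4)
        accs, mis = [], []
        for rep in range(60):
            counts = rng.poisson(3, size=(30, 10))
            labels = rng.permutation(["a"] * 15 + ["b"] * 15)
            res = loo_classify(_matrix(counts, labels), seed=rep)
            accs.append(res.accuracy)
            mis.append(res.mi_bits)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)
        assert np.mean(mis) < 0.1  # plug-in bias level for n=30

    def test_separation_monotonicity(self):
        """Mean accuracy and MI increase with Poisson class separation."""
        rng = np.random.default_rng(5)
        mean_acc, mean_mi = [], []
        for delta in (0.0, 1.0, 3.0):
            accs, mis = [], []
            for rep in range(200):
                a = rng.poisson(3.0, size=(12, 10))
                b = rng.poisson(3.0 + delta, size=(12, 10))
                res = loo_classify(
                    _matrix(np.vstack([a, b]), ["a"] * 12 + ["b"] * 12), seed=rep
                )
                accs.append(res.accuracy)
                mis.append(res.mi_bits)
            mean_acc.append(np.mean(accs))
            mean_mi.append(np.mean(mis))
        assert mean_acc[0] < mean_acc[1] < mean_acc[2]
        assert mean_mi[0] < mean_mi[1] < mean_mi[2]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            loo_classify(_matrix(np.ones((5, 3)), ["a"] * 5))


class TestBinningAndEfficiency:
    def test_ten_bins_and_count_conservation(self):
        spikes = np.array([10.01, 10.05, 10.16, 10.29, 10.31, 11.0])
        data = bin_trials(spikes, {"a": [10.0] * 0 + [10.0], "b": [11.0]},
                          min_trials=1, min_rate_hz=0.0)
        assert data.counts.shape[1] == 10
        # spikes at +0.31 and beyond fall outside the 0-300 ms window
        assert data.counts[data.labels == "a"].sum() == 4

    def test_low_rate_class_excluded(self):
        rng = np.random.default_rng(1)
        spikes = np.sort(rng.uniform(0, 100, 80))  # 0.8 Hz
        onsets = {"a": np.arange(1.0, 40, 2.0), "b": np.arange(41.0, 80, 2.0)}
        data = bin_trials(spikes, onsets)
        assert not data.included
        assert "1.0 Hz" in data.exclusion_reason or "below" in data.exclusion_reason

    def test_efficiency_arithmetic(self):
        assert encoding_efficiency(0.5, 5.0) == pytest.approx(0.1)

    def test_spike_duplication_halves_efficiency(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(3, size=(24, 10))
        counts[:12] += 2  # separable classes
        labels = ["a"] * 12 + ["b"] * 12
        r1 = loo_classify(_matrix(counts, labels), seed=0)
        r2 = loo_classify(_matrix(counts * 2, labels), seed=0)
        assert r2.mi_bits == pytest.approx(r1.mi_bits)
        assert r2.efficiency == pytest.approx(r1.efficiency / 2)

    def test_zero_spikes_efficiency_undefined(self):
        with pytest.raises(ValueError):
            encoding_efficiency(0.5, 0.0)


class TestSessionDecodes:
    def _toy_trials(self):
        rows = []
        t = 10.0
        for rule in ("A", "V"):
            for stim in ("A_RV_R", "A_RV_U", "A_UV_R", "A_UV_U"):
                for _ in range(12):
                    rows.append({"rule": rule, "stimulus": stim, "modality": "AV",
                                 "t_onset": t})
                    t += 2.0
        return pd.DataFrame(rows)

    def _spikes_for(self, trials, rate_by_aud, seed=0):
        rng = np.random.default_rng(seed)
        spikes = []
        for _, tr in trials.iterrows():
            r = rate_by_aud["A_R" if tr.stimulus.startswith("A_R") else "A_U"]
            n = rng.poisson(r * 0.3)
            spikes.append(rng.uniform(tr.t_onset, tr.t_onset + 0.3, n))
        return np.sort(np.concatenate(spikes))

    def test_selective_unit_decodes_above_chance(self):
        trials = self._toy_trials()
        spikes = self._spikes_for(trials, {"A_R": 25.0, "A_U": 5.0})
        per_rule, runs, reason = decode_stimulus_across_rules(spikes, trials, seed=0)
        assert reason == ""
        assert per_rule["A"]["accuracy"] > 0.8
        assert per_rule["V"]["accuracy"] > 0.8
        assert len(runs) == 4

    def test_unselective_unit_near_chance_rule_decode(self):
        trials = self._toy_trials()
        spikes = self._spikes_for(trials, {"A_R": 8.0, "A_U": 8.0}, seed=3)
        res, reason = decode_rule(spikes, trials, "A_RV_R", seed=1)
        assert reason == ""
        assert 0.1 <= res.accuracy <= 0.9  # single unit: noisy but bounded

    def test_deterministic_given_seed(self):
        trials = self._toy_trials()
        spikes = self._spikes_for(trials, {"A_R": 10.0, "A_U": 6.0}, seed=4)
        r1, _ = decode_rule(spikes, trials, "A_UV_U", seed=7)
        r2, _ = decode_rule(spikes, trials, "A_UV_U", seed=7)
        np.testing.assert_array_equal(r1.confusion, r2.confusion)
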