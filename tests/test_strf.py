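"""Reverse correlation, reliability null, significance, BF, projection MI."""

import numpy as np
import pytest

from avattn.lnp import GroundTruthUnit, lag_grid, make_gabor_strf, simulate_lnp_spikes
from avattn.stimuli import RDSStimulus, generate_rds, rds_to_tf
from avattn.strf import (
    STRFGrid,
    best_frequency,
    circular_shuffle,
    equate_rule_durations,
    estimate_strf,
    null_strf_sample,
    projection_distributions,
    significant_bins,
    strf_reliability,
    strf_spike_mi,
)


def _epochs(n_ep, ep_dur, seed, unit=None, rule="V", rate=5.0):
    """RDS epochs with spikes from an LNP unit (Poisson baseline if None)."""
    rng = np.random.default_rng(seed)
    out = []
    for e in range(n_ep):
        rds = generate_rds(ep_dur, int(rng.integers(2**31)))
        tf = rds_to_tf(rds, smooth_sigma_oct=0.1, t0=e * (ep_dur + 1.0))
        if unit is None:
            n = rng.poisson(rate * ep_dur)
            spk = np.sort(tf.t0 + rng.uniform(0, ep_dur, n))
        else:
            spk = simulate_lnp_spikes(tf, unit, rule, seed=int(rng.integers(2**31)))
        out.append((tf, spk))
    return out


def _tuned_unit(fc, bf_log2=None, gain=18.0, base=5.0):
    lags = lag_grid()
    bf = np.log2(16000) if bf_log2 is None else bf_log2
    k = make_gabor_strf(lags, fc, bf_log2=bf, temporal_freq_hz=0.0,
                        sigma_t=0.045, sigma_f_oct=0.5)
    k /= np.linalg.norm(k)
    return GroundTruthUnit(0, k, {"V": base}, {"V": 1.0}, {}, rds_drive_gain=gain)


class TestEquateRuleDurations:
    def test_truncates_longer_rule(self):
        eq = equate_rule_durations(
            {"A": [(0, 100), (200, 300), (400, 600)], "V": [(1000, 1300)]},
            drop_initial=0.0,
        )
        assert sum(e - s for s, e in eq["A"]) == pytest.approx(300.0)
        assert sum(e - s for s, e in eq["V"]) == pytest.approx(300.0)

    def test_equal_totals_unchanged_and_idempotent(self):
        eps = {"A": [(0.0, 50.0)], "V": [(100.0, 150.0)]}
        eq = equate_rule_durations(eps, drop_initial=0.0)
        assert eq == eps
        assert equate_rule_durations(eq, drop_initial=0.0) == eq

    def test_onset_drop_applied_per_epoch(self):
        eq = equate_rule_durations({"A": [(0.0, 10.0)], "V": [(20.0, 30.0)]})
        assert eq["A"][0][0] == pytest.approx(0.2)
        assert eq["V"][0][0] == pytest.approx(20.2)

    def test_partial_tail_trim_bookkeeping(self):
        eq = equate_rule_durations(
            {"A": [(0, 100), (200, 230), (300, 340)], "V": [(500, 620)]},
            drop_initial=0.0,
        )
        total_a = sum(e - s for s, e in eq["A"])
        assert total_a == pytest.approx(120.0)
        assert len(eq["A"]) == 2  # last epoch removed, second trimmed

    def test_empty_rule_rejected(self):
        with pytest.raises(ValueError):
            equate_rule_durations({"A": [(0.0, 0.1)], "V": [(5.0, 50.0)]})


class TestEstimateSTRF:
    def test_deterministic_lagged_spiking_peaks_at_lag(self):
        """A unit that spikes 50 ms after energy at 16 kHz produces an STRF
        peaking at (-50 ms, 16 kHz)."""
        rds = generate_rds(200, seed=0)
        tf = rds_to_tf(rds, smooth_sigma_oct=0.0)
        band = np.searchsorted(tf.freq_edges, np.log2(16000)) - 1
        hot = np.flatnonzero(tf.values[:, band] > 0.8)
        spikes = (hot + 0.5) * tf.dt + 0.050
        grid, _ = estimate_strf([(tf, spikes)])
        i, j = np.unravel_index(np.argmax(grid.values), grid.values.shape)
        assert grid.lags[i] == pytest.approx(-0.050, abs=tf.dt)
        assert j == band

    def test_null_unit_stays_within_shuffle_band(self):
        eps = _epochs(20, 5.0, seed=1, rate=6.0)
        grid, _ = estimate_strf(eps)
        nulls = null_strf_sample(eps, 100, seed=2)
        assert np.abs(grid.values).max() <= np.abs(nulls).max() * 1.5

    def test_lnp_recovery_single_instance(self):
        eps0 = _epochs(1, 1.0, seed=0)
        fc = eps0[0][0].freq_centers_log2
        unit = _tuned_unit(fc, bf_log2=np.log2(11000))
        eps = _epochs(100, 5.0, seed=3, unit=unit)
        grid, per = estimate_strf(eps)
        r = np.corrcoef(grid.values.ravel(), unit.strf_truth.ravel())[0, 1]
        assert r >= 0.6
        assert sum(p is not None for p in per) >= 90

    def test_min_spike_exclusion(self):
        eps = _epochs(4, 2.0, seed=4, rate=1.0)
        with pytest.raises(ValueError):
            estimate_strf(eps, min_spikes=500)


class TestCircularShuffle:
    def test_count_and_circular_isi_preserved(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(10, 20, 50))
        out = circular_shuffle(spikes, (10.0, 20.0), rng)
        assert out.size == spikes.size
        assert np.all((out >= 10) & (out < 20))

        def circ_isi(s):
            d = np.diff(np.sort(s))
            wrap = 10.0 - (np.max(s) - np.min(s))
            return np.sort(np.append(d, wrap))

        np.testing.assert_allclose(circ_isi(out), circ_isi(spikes), atol=1e-9)

    def test_identity_rotation_never_drawn(self):
        rng = np.random.default_rng(1)
        spikes = np.sort(rng.uniform(0, 10, 30))
        for _ in range(50):
            out = circular_shuffle(spikes, (0.0, 10.0), rng)
            assert not np.allclose(out, spikes)

    def test_short_epoch_skipped_with_warning(self):
        spikes = np.array([0.1, 0.5])
        with pytest.warns(UserWarning):
            out = circular_shuffle(spikes, (0.0, 0.8), np.random.default_rng(0))
        np.testing.assert_array_equal(out, spikes)


class TestReliability:
    def test_noiseless_identical_epochs_r_one(self):
        rds = generate_rds(5.0, seed=0)
        tf = rds_to_tf(rds, smooth_sigma_oct=0.1)
        band = np.argmax(tf.values.sum(axis=0))
        hot = np.flatnonzero(tf.values[:, band] > 0.5)
        spikes = (hot + 0.5) * tf.dt
        # same stimulus and same deterministic spikes in every epoch
        eps = []
        for e in range(6):
            t0 = e * 6.0
            tf_e = rds_to_tf(rds, smooth_sigma_oct=0.1, t0=t0)
            eps.append((tf_e, spikes + t0))
        rel = strf_reliability(eps, n_reps=50, seed=1, n_null=50)
        assert rel.mean_r == pytest.approx(1.0)
        assert rel.p <= 0.05 and rel.tuned

    def test_tuned_unit_detected(self):
        eps0 = _epochs(1, 1.0, seed=0)
        fc = eps0[0][0].freq_centers_log2
        unit = _tuned_unit(fc)
        eps = _epochs(30, 4.0, seed=5, unit=unit)
        rel = strf_reliability(eps, n_reps=100, seed=6, n_null=100)
        assert rel.p < 0.05

    def test_too_few_epochs_rejected(self):
        eps = _epochs(3, 4.0, seed=7, rate=6.0)
        with pytest.raises(ValueError):
            strf_reliability(eps, n_reps=10, seed=0)


class TestSignificantBinsAndBF:
    def test_null_unit_false_positive_rate(self):
        eps = _epochs(25, 5.0, seed=8, rate=6.0)
        grid, _ = estimate_strf(eps)
        nulls = null_strf_sample(eps, 200, seed=9)
        mask = significant_bins(grid, nulls, alpha=0.01)
        assert mask.shape == grid.values.shape
        assert mask.mean() < 0.05  # near the nominal 1%

    def test_injected_field_flagged_and_bf_recovered(self):
        eps0 = _epochs(1, 1.0, seed=0)
        fc = eps0[0][0].freq_centers_log2
        unit = _tuned_unit(fc, bf_log2=np.log2(11000))
        eps = _epochs(80, 5.0, seed=10, unit=unit)
        grid, _ = estimate_strf(eps)
        nulls = null_strf_sample(eps, 100, seed=11)
        mask = significant_bins(grid, nulls, alpha=0.01)
        assert mask.mean() > 0.02
        bf = best_frequency(grid, mask)
        assert abs(np.log2(bf / 11000)) <= 0.2

    def test_single_bin_and_tie_rules(self):
        lags = lag_grid()
        values = np.zeros((lags.size, 20))
        edges = np.log2(4000) + 0.2 * np.arange(21)
        grid = STRFGrid(values, lags, edges, 100, 100.0)
        mask = np.zeros_like(values, dtype=bool)
        grid.values[30, 10] = 5.0
        mask[30, 10] = True
        assert best_frequency(grid, mask) == pytest.approx(
            grid.freq_centers_hz[10]
        )
        # tie between bands 8 and 12: lower frequency wins
        grid.values[30, 8] = 5.0
        grid.values[30, 12] = 5.0
        mask[30, [8, 12]] = True
        grid.values[30, 10] = 0.0
        mask[30, 10] = False
        assert best_frequency(grid, mask) == pytest.approx(grid.freq_centers_hz[8])

    def test_no_significant_bins_undefined(self):
        lags = lag_grid()
        grid = STRFGrid(np.ones((lags.size, 20)), lags,
                        np.log2(4000) + 0.2 * np.arange(21), 100, 100.0)
        assert best_frequency(grid, np.zeros_like(grid.values, bool)) is None

    def test_too_few_nulls_rejected(self):
        eps = _epochs(5, 3.0, seed=12, rate=6.0)
        grid, _ = estimate_strf(eps, min_spikes=10)
        with pytest.raises(ValueError):
            significant_bins(grid, null_strf_sample(eps, 20, seed=0))


class TestProjectionMI:
    def test_zero_strf_rejected(self):
        eps = _epochs(5, 3.0, seed=13, rate=6.0)
        lags = lag_grid()
        grid = STRFGrid(np.zeros((lags.size, 20)), lags,
                        eps[0][0].freq_edges, 50, 15.0)
        with pytest.raises(ValueError):
            projection_distributions(eps, grid)

    def test_p_x_standardized(self):
        eps = _epochs(20, 5.0, seed=14, rate=6.0)
        grid, _ = estimate_strf(eps)
        d = projection_distributions(eps, grid)
        centers = 0.5 * (d.bin_edges[:-1] + d.bin_edges[1:])
        mean = (d.p_x * centers).sum()
        sd = np.sqrt((d.p_x * centers**2).sum() - mean**2)
        assert abs(mean) < 0.1
        assert sd == pytest.approx(1.0, abs=0.15)
        assert d.p_x.sum() == pytest.approx(1.0)
        assert d.p_x_given_spike.sum() == pytest.approx(1.0)

    def test_identical_distributions_zero_mi(self):
        from avattn.strf import ProjectionDistributions

        p = np.full(40, 1 / 40)
        dists = ProjectionDistributions(p, p.copy(), np.linspace(-5, 5, 41), 0, 1, 100)
        assert strf_spike_mi(dists) == pytest.approx(0.0)

    def test_concentrated_spike_bin_closed_form(self):
        from avattn.strf import ProjectionDistributions

        p_x = np.full(10, 0.1)
        p_spk = np.zeros(10)
        p_spk[3] = 1.0
        dists = ProjectionDistributions(p_x, p_spk, np.linspace(-5, 5, 11), 0, 1, 50)
        assert strf_spike_mi(dists) == pytest.approx(np.log2(10))

    def test_tuned_unit_shifts_prespike_projections(self):
        eps0 = _epochs(1, 1.0, seed=0)
        fc = eps0[0][0].freq_centers_log2
        unit = _tuned_unit(fc)
        eps = _epochs(40, 5.0, seed=15, unit=unit)
        grid, _ = estimate_strf(eps)
        d = projection_distributions(eps, grid)
        centers = 0.5 * (d.bin_edges[:-1] + d.bin_edges[1:])
        assert (d.p_x_given_spike * centers).sum() > 0.3
        assert strf_spike_mi(d) > 0.05

    def test_null_unit_mi_below_bias_bound(self):
        """Stimulus-independent spikes: plug-in MI stays below twice the
        analytic bias bound (n_bins - 1) / (2 N ln 2)."""
        eps = _epochs(30, 5.0, seed=16, rate=6.0)
        grid, _ = estimate_strf(eps)
        d = projection_distributions(eps, grid)
        bound = 2 * (d.p_x.size - 1) / (2 * d.n_spikes * np.log(2))
        assert strf_spike_mi(d) < bound

    def test_scale_invariance(self):
        eps = _epochs(15, 5.0, seed=17, rate=6.0)
        grid, _ = estimate_strf(eps)
        d1 = projection_distributions(eps, grid)
        grid2 = STRFGrid(3.0 * grid.values, grid.lags, grid.freq_edges,
                         grid.n_spikes, grid.total_duration,
                         band_mean=grid.band_mean, band_scale=3.0 * grid.band_scale)
        d2 = projection_distributions(eps, grid2)
        assert strf_spike_mi(d1) == pytest.approx(strf_spike_mi(d2), abs=1e-9)
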