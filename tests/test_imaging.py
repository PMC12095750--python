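"""Dedup, z-scoring, alignment, classification, cross-correlation."""

import numpy as np
import pytest

from ctmotor import imaging, synth
from ctmotor.core import ActivityMatrix


def _aligned_from_trace(trace, fs=16.0):
    """Wrap a single peri-event trace as a one-unit, one-event alignment."""
    n = trace.size
    times = -2.0 + np.arange(n) / fs
    return imaging.AlignedActivity(trace[None, None, :], times, fs)


class TestDeduplicate:
    def test_exact_copy_removed(self, rng):
        x = rng.normal(size=1000)
        act = ActivityMatrix(np.vstack([x, x]), 16.0)
        out, info = imaging.deduplicate_units(act, 0.8)
        assert out.n_units == 1

    def test_constant_unit_dropped_with_warning(self, rng):
        act = ActivityMatrix(np.vstack([rng.normal(size=100), np.zeros(100)]), 16.0)
        with pytest.warns(UserWarning):
            out, info = imaging.deduplicate_units(act)
        assert out.n_units == 1
        assert list(info["dropped_constant_ids"]) == [1]

    def test_synthetic_parents_survive(self, session_noisy):
        pop = synth.PopulationConfig(n_units=20, n_duplicate_branches=6, duplicate_correlation=0.9)
        act, gt = synth.generate_activity(session_noisy, pop, seed=9)
        out, info = imaging.deduplicate_units(act, 0.8)
        kept = set(out.unit_ids)
        parents = set(gt[gt.duplicate_of < 0].unit_id)
        assert kept == parents

    def test_independent_units_all_kept(self, rng):
        act = ActivityMatrix(rng.normal(size=(10, 10_000)), 16.0)
        out, _ = imaging.deduplicate_units(act, 0.8)
        assert out.n_units == 10

    def test_no_remaining_pair_above_threshold(self, session_noisy):
        pop = synth.PopulationConfig(n_units=30, n_duplicate_branches=10)
        act, _ = synth.generate_activity(session_noisy, pop, seed=10)
        out, _ = imaging.deduplicate_units(act, 0.8)
        corr = np.corrcoef(out.dff)
        off = corr[~np.eye(out.n_units, dtype=bool)]
        assert np.all(np.abs(off) <= 0.8)


class TestZscore:
    def test_whole_session_standardizes(self, rng):
        act = ActivityMatrix(rng.normal(2.0, 3.0, size=(4, 500)), 16.0)
        z, valid = imaging.zscore(act)
        assert valid.all()
        np.testing.assert_allclose(z.dff.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.dff.std(axis=1), 1.0, atol=1e-12)

    def test_constant_trace_flagged(self):
        act = ActivityMatrix(np.ones((1, 100)), 16.0)
        with pytest.warns(UserWarning):
            _, valid = imaging.zscore(act)
        assert not valid[0]

    def test_baseline_mode_arithmetic(self):
        # baseline samples mean 1, SD 0.5; a value of 2 must map to z = 2
        fs = 16.0
        x = np.ones(int(6 * fs))
        base = slice(int(0.0 * fs), int(0.5 * fs))
        x[base] = np.tile([0.5, 1.5], (base.stop - base.start) // 2)
        x[int(4 * fs)] = 2.0
        act = ActivityMatrix(x[None, :], fs)
        z, valid = imaging.zscore(act, mode="baseline", events=[2.0], baseline_window=(-2.0, -1.5))
        assert valid[0]
        assert z.dff[0, int(4 * fs)] == pytest.approx(2.0)


class TestAlign:
    def test_sample_count(self, rng):
        act = ActivityMatrix(rng.normal(size=(2, 160)), 16.0)
        al = imaging.align_to_events(act, [5.0], window=(-1.0, 1.0))
        assert al.tensor.shape == (2, 1, 32)

    def test_identical_snippets_zero_sem(self):
        x = np.tile(np.sin(np.arange(320) / 10.0), (3, 1))
        act = ActivityMatrix(x, 16.0)
        al = imaging.align_to_events(act, [6.0, 6.0], window=(-1.0, 1.0))
        np.testing.assert_allclose(al.population_sem, 0.0, atol=1e-12)

    def test_out_of_range_events_dropped(self, rng):
        act = ActivityMatrix(rng.normal(size=(1, 160)), 16.0)
        al = imaging.align_to_events(act, [0.5, 5.0, 9.9], window=(-1.0, 1.0))
        assert al.n_dropped == 2 and al.tensor.shape[1] == 1

    def test_empty_event_list(self, rng):
        act = ActivityMatrix(rng.normal(size=(1, 160)), 16.0)
        al = imaging.align_to_events(act, [], window=(-1.0, 1.0))
        assert al.tensor.shape[1] == 0

    def test_down_population_mean_has_trough(self, population, pull_peaks):
        act, gt = population
        z, _ = imaging.zscore(act)
        down = z.select((gt.label == "down").to_numpy())
        al = imaging.align_to_events(down, pull_peaks)
        m = al.population_mean
        base = m[al.times < -1.5].mean()
        assert m.min() < base - 0.5


class TestClassify:
    def test_flat_trace_no_mod(self):
        al = _aligned_from_trace(np.zeros(64))
        cls = imaging.classify_modulation(al)
        assert cls.labels[0] == "no_mod" and cls.degenerate[0]

    def test_constructed_down_plateau(self):
        fs = 16.0
        trace = np.random.default_rng(1).normal(0, 0.05, 64)
        t = -2.0 + np.arange(64) / fs
        trace[(t >= -0.3) & (t < 0.3)] = -3.0  # 600 ms plateau straddling pull max
        cls = imaging.classify_modulation(_aligned_from_trace(trace))
        assert cls.labels[0] == "down"

    def test_constructed_up_plateau(self):
        fs = 16.0
        trace = np.random.default_rng(2).normal(0, 0.05, 64)
        t = -2.0 + np.arange(64) / fs
        trace[(t >= -0.3) & (t < 0.3)] = 3.0
        cls = imaging.classify_modulation(_aligned_from_trace(trace))
        assert cls.labels[0] == "up"

    def test_specificity_on_pure_noise(self, session_noisy, pull_peaks):
        pop = synth.PopulationConfig(n_units=500, class_proportions=(0, 0, 1.0))
        act, _ = synth.generate_activity(session_noisy, pop, seed=21)
        z, _ = imaging.zscore(act)
        al = imaging.align_to_events(z, pull_peaks)
        cls = imaging.classify_modulation(al)
        assert (cls.labels == "no_mod").mean() > 0.95

    def test_recovers_class_proportions(self, session_noisy, pull_peaks):
        act, gt = synth.generate_activity(
            session_noisy, synth.PopulationConfig(n_units=1000), seed=22
        )
        z, _ = imaging.zscore(act)
        al = imaging.align_to_events(z, pull_peaks)
        cls = imaging.classify_modulation(al)
        for label in ("down", "up", "no_mod"):
            true_pct = 100.0 * (gt.label == label).mean()
            est_pct = 100.0 * (cls.labels == label).mean()
            assert abs(true_pct - est_pct) <= 3.0

    def test_wrong_window_rejected(self, rng):
        act = ActivityMatrix(rng.normal(size=(1, 160)), 16.0)
        al = imaging.align_to_events(act, [5.0], window=(-1.0, 1.0))
        with pytest.raises(ValueError):
            imaging.classify_modulation(al)


class TestSummarize:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"down": 740, "up": 168, "no_mod": 168}, {"down": 69}),
            ({"down": 1, "up": 0, "no_mod": 0}, {"down": 100}),
            ({"down": 1, "up": 1, "no_mod": 2}, {"down": 25, "up": 25, "no_mod": 50}),
        ],
    )
    def test_percentages(self, counts, expected):
        pct = imaging.summarize_classification(counts)
        for k, v in expected.items():
            assert round(pct[k]) == v

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            imaging.summarize_classification({"down": 0, "up": 0, "no_mod": 0})


class TestCrossCorrelate:
    def test_autocorrelation_unity_at_zero(self, rng):
        x = rng.normal(size=2000)
        cg = imaging.cross_correlate(x, x, 16.0)
        assert cg.values[cg.lags == 0][0] == pytest.approx(1.0)

    def test_negation_gives_minus_one(self, rng):
        x = rng.normal(size=2000)
        cg = imaging.cross_correlate(x, -x, 16.0)
        assert cg.values[cg.lags == 0][0] == pytest.approx(-1.0)
        assert cg.min_value == pytest.approx(-1.0)
        assert cg.lag_of_min == pytest.approx(0.0)

    def test_delayed_sine_extremum_at_injected_lag(self):
        fs, delay = 16.0, 0.5
        t = np.arange(0, 200, 1 / fs)
        v = np.sin(2 * np.pi * 0.2 * t)
        a = np.sin(2 * np.pi * 0.2 * (t - delay))  # activity delayed by 0.5 s
        cg = imaging.cross_correlate(a, v, fs, max_lag=2.0)
        peak_lag = cg.lags[np.argmax(cg.values)]
        assert abs(peak_lag - delay) <= 1 / fs

    def test_affine_invariance(self, rng):
        a, v = rng.normal(size=1000), rng.normal(size=1000)
        c1 = imaging.cross_correlate(a, v, 16.0)
        c2 = imaging.cross_correlate(3 * a + 7, 0.1 * v - 2, 16.0)
        np.testing.assert_allclose(c1.values, c2.values, atol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            imaging.cross_correlate(np.ones(100), np.arange(100.0), 16.0)


class TestShuffleControl:
    def test_null_band_centered_on_zero(self, rng):
        n = 10_000
        a, v = rng.normal(size=n), rng.normal(size=n)
        nb = imaging.shuffle_control(a, v, 16.0, n_shuffles=100, seed=1)
        assert np.abs(nb.mean).max() < 0.05

    def test_deterministic_given_seed(self, rng):
        a, v = rng.normal(size=2000), rng.normal(size=2000)
        n1 = imaging.shuffle_control(a, v, 16.0, n_shuffles=10, seed=7)
        n2 = imaging.shuffle_control(a, v, 16.0, n_shuffles=10, seed=7)
        np.testing.assert_array_equal(n1.mean, n2.mean)

    def test_true_anticorrelation_below_null(self, session_noisy, pull_peaks):
        pop = synth.PopulationConfig(n_units=1, class_proportions=(1.0, 0, 0))
        act, _ = synth.generate_activity(session_noisy, pop, seed=30)
        v = session_noisy.velocity.resample(act.sample_rate).samples[: act.dff.shape[1]]
        a = act.dff[0, : v.size]
        obs = imaging.cross_correlate(a, v, act.sample_rate)
        nb = imaging.shuffle_control(a, v, act.sample_rate, n_shuffles=100, seed=2)
        assert obs.min_value < nb.lower.min()

    def test_short_trace_rejected(self, rng):
        with pytest.raises(ValueError):
            imaging.shuffle_control(rng.normal(size=100), rng.normal(size=100), 16.0)


class TestBinnedMinSummary:
    def test_single_bin_occupied(self):
        cgs = [imaging.CrossCorrelogram(np.array([-0.1, 0.0]), np.array([-0.5, 0.1]))] * 5
        out = imaging.binned_min_summary(cgs)
        assert (out["counts"] > 0).sum() == 1

    def test_uniform_minima_occupy_expected_bins(self):
        lags = np.linspace(-1, 1, 41)
        cgs = []
        for lag in lags:
            vals = np.zeros(41)
            vals[np.argmin(np.abs(np.linspace(-1, 1, 41) - lag))] = -1.0
            cgs.append(imaging.CrossCorrelogram(np.linspace(-1, 1, 41), vals))
        out = imaging.binned_min_summary(cgs, bin_width=0.05)
        assert 38 <= (out["counts"] > 0).sum() <= 41

    def test_edge_value_goes_right(self):
        cg = imaging.CrossCorrelogram(np.array([0.05, 0.1]), np.array([-1.0, 0.0]))
        out = imaging.binned_min_summary([cg], bin_width=0.05)
        i = np.flatnonzero(out["counts"])[0]
        assert out["bin_edges"][i] == pytest.approx(0.05)


class TestModulationRange:
    def test_flat_zero(self):
        al = _aligned_from_trace(np.zeros(64))
        assert imaging.modulation_range(al)[0] == 0.0

    def test_span_arithmetic(self):
        tr = np.zeros(64)
        tr[10], tr[40] = 1.0, -3.0
        al = _aligned_from_trace(tr)
        assert imaging.modulation_range(al)[0] == pytest.approx(4.0)

    def test_larger_gain_larger_range(self, session_noisy, pull_peaks):
        ranges = []
        for gain in (0.03, 0.09):  # early vs late training suppression
            pop = synth.PopulationConfig(
                n_units=50, class_proportions=(1.0, 0, 0), suppression_gain=gain
            )
            act, _ = synth.generate_activity(session_noisy, pop, seed=31)
            z, _ = imaging.zscore(act)
            al = imaging.align_to_events(z, pull_peaks)
            ranges.append(imaging.modulation_range(al).mean())
        assert ranges[1] > ranges[0]
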