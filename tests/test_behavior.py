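"""Wheel decoding, trial gating, pull detection, velocity binning."""

import numpy as np
import pandas as pd
import pytest

from ctmotor import behavior, synth
from ctmotor.core import VelocityTrace


class TestDecodeVelocity:
    def test_constant_position_zero_velocity(self):
        v = behavior.decode_velocity(np.full(4000, 512), 1024, 60.0, 2000.0)
        assert np.allclose(v.samples, 0.0)

    def test_one_rev_per_second(self):
        # 1024-count encoder advancing 1024 counts/s on a 60 mm wheel:
        # one rev/s = pi * 6 cm/s = 18.85 cm/s
        fs, res = 2000.0, 1024
        t = np.arange(int(4 * fs)) / fs
        counts = np.floor(res * t) % res
        v = behavior.decode_velocity(counts, res, 60.0, fs)
        mid = v.samples[1000:-1000]
        assert np.allclose(mid.mean(), np.pi * 6.0, rtol=1e-3)

    def test_wraparound_no_spike(self):
        fs, res = 2000.0, 1024
        t = np.arange(int(4 * fs)) / fs
        counts = (np.floor(res * t) + 1000) % res  # wraps 1023 -> 0 mid-trace
        v = behavior.decode_velocity(counts, res, 60.0, fs)
        mid = v.samples[1000:-1000]
        assert mid.max() - mid.min() < 0.5  # continuous, no unwrap spike

    def test_out_of_range_positions_rejected(self):
        with pytest.raises(ValueError):
            behavior.decode_velocity(np.array([0, 1024]), 1024, 60.0, 2000.0)
        with pytest.raises(ValueError):
            behavior.decode_velocity(np.array([0, 1]), 1, 60.0, 2000.0)


class TestDetectTrials:
    def _trace(self, v, fs=100.0):
        return VelocityTrace(np.asarray(v, float), fs)

    def test_all_gates_required(self):
        v = self._trace([0, 0, 5, 5, 0])
        beam = np.array([1, 1, 1, 1, 1], bool)
        cap = np.array([0, 0, 0, 0, 0], bool)
        assert behavior.detect_trials(v, beam, cap, 2.0).size == 0  # no contact
        cap[:] = True
        starts = behavior.detect_trials(v, beam, cap, 2.0)
        assert starts.size == 1 and starts[0] == pytest.approx(2 / 100.0)

    def test_refractory_suppresses_double_trigger(self):
        fs = 100.0
        v = np.zeros(300)
        v[50:60] = 5.0
        v[70:80] = 5.0  # 0.2 s later: inside 1 s refractory
        on = np.ones(300, bool)
        starts = behavior.detect_trials(self._trace(v, fs), on, on, 2.0, refractory=1.0)
        assert starts.size == 1

    def test_mismatched_channels_rejected(self):
        v = self._trace([0, 0, 5])
        with pytest.raises(ValueError):
            behavior.detect_trials(v, np.ones(2, bool), np.ones(3, bool), 2.0)

    def test_groundtruth_roundtrip_noiseless(self, session_small):
        s = session_small
        starts = behavior.detect_trials(
            s.velocity, s.beam, s.capacitance, s.config.trial_min_velocity
        )
        gt = s.trials.onset_s.to_numpy()
        assert starts.size == gt.size
        # within one behavior sample
        assert np.abs(starts - gt).max() <= 1.0 / s.config.sample_rate_behavior


class TestScoreTrials:
    def _scored(self, v, fs, trials, thr, window=0.2):
        return behavior.score_trials(trials, VelocityTrace(v, fs), thr, window)

    def test_success_within_window(self):
        fs = 1000.0
        v = np.zeros(1000)
        v[150:200] = 10.0  # crosses threshold 150 ms after start
        tr = pd.DataFrame({"start": [0.0], "end": [1.0]})
        out = self._scored(v, fs, tr, 8.0)
        assert bool(out.success[0])

    def test_late_crossing_fails(self):
        fs = 1000.0
        v = np.zeros(1000)
        v[250:300] = 10.0  # only at 250 ms
        tr = pd.DataFrame({"start": [0.0], "end": [1.0]})
        out = self._scored(v, fs, tr, 8.0)
        assert not bool(out.success[0])

    def test_distance_closed_form(self):
        fs, vconst, T = 1000.0, 4.0, 0.5
        v = np.full(1000, vconst)
        tr = pd.DataFrame({"start": [0.0], "end": [T]})
        out = self._scored(v, fs, tr, 99.0)
        assert out.pull_distance[0] == pytest.approx(vconst * T)
        assert out.peak_velocity[0] == pytest.approx(vconst)

    def test_nonpositive_window_rejected(self):
        tr = pd.DataFrame({"start": [0.0], "end": [1.0]})
        with pytest.raises(ValueError):
            self._scored(np.zeros(10), 10.0, tr, 1.0, window=0.0)

    def test_distance_additive_over_partition(self, session_small):
        s = session_small
        tr = s.trials.rename(columns={"onset_s": "start", "offset_s": "end"})
        whole = behavior.score_trials(tr, s.velocity, 8.0)
        mid = (tr.start + tr.end) / 2
        first = behavior.score_trials(
            tr.assign(end=mid), s.velocity, 8.0
        )
        second = behavior.score_trials(tr.assign(start=mid), s.velocity, 8.0)
        np.testing.assert_allclose(
            whole.pull_distance, first.pull_distance + second.pull_distance, atol=1e-9
        )


class TestDetectPulls:
    def test_single_bump(self):
        fs = 100.0
        t = np.arange(0, 4, 1 / fs)
        v = 8.0 * np.exp(-((t - 2) ** 2) / 0.02)
        pulls = behavior.detect_pulls(VelocityTrace(v, fs), min_peak=2.0)
        assert len(pulls) == 1
        assert pulls.peak_velocity[0] == pytest.approx(8.0, rel=1e-3)
        assert pulls.onset[0] <= pulls.peak_time[0] <= pulls.offset[0]

    def test_flat_trace_no_pulls(self):
        pulls = behavior.detect_pulls(VelocityTrace(np.zeros(100), 100.0), min_peak=2.0)
        assert pulls.empty

    def test_refractory_keeps_higher_peak(self):
        fs = 1000.0
        v = np.zeros(2000)
        v[500:520] = 5.0
        v[600:620] = 9.0  # 100 ms later, higher
        pulls = behavior.detect_pulls(VelocityTrace(v, fs), min_peak=2.0, refractory=0.3)
        assert len(pulls) == 1
        assert pulls.peak_velocity[0] == pytest.approx(9.0)

    def test_recovers_embedded_pulls(self, session_small):
        s = session_small
        pulls = behavior.detect_pulls(s.velocity, min_peak=2.0)
        gt = s.pulls[s.pulls.value >= 2.0]
        assert len(pulls) == len(gt)


class TestVelocityBins:
    @pytest.mark.parametrize(
        "peak,expected",
        [(7.0, "6-10"), (2.0, "2-6"), (6.0, "6-10"), (10.0, "10-14"),
         (14.0, "14+"), (25.0, "14+"), (1.0, None)],
    )
    def test_bin_assignment(self, peak, expected):
        df = behavior.bin_pulls_by_velocity(pd.DataFrame({"peak_velocity": [peak]}))
        got = df.velocity_bin[0]
        if expected is None:
            assert pd.isna(got)
        else:
            assert got == expected


class TestMatchVelocityDistributions:
    def _pulls(self, peaks):
        return pd.DataFrame({"peak_velocity": np.asarray(peaks, float)})

    def test_identical_groups_returned_whole(self):
        a = self._pulls([3, 7, 11, 15])
        ma, mb = behavior.match_velocity_distributions(a, a.copy(), seed=0)
        assert len(ma) == len(mb) == 4

    def test_min_count_rule(self):
        a = self._pulls([3] * 10)
        b = self._pulls([3] * 4)
        with pytest.warns(UserWarning):
            ma, mb = behavior.match_velocity_distributions(a, b, seed=0)
        assert len(ma) == len(mb) == 4

    def test_equal_bin_histograms(self, rng):
        a = self._pulls(rng.uniform(2, 20, 80))
        b = self._pulls(rng.uniform(2, 20, 50))
        ma, mb = behavior.match_velocity_distributions(a, b, seed=1)
        ha = ma.velocity_bin.value_counts()
        hb = mb.velocity_bin.value_counts()
        assert (ha == hb).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            behavior.match_velocity_distributions(self._pulls([]), self._pulls([3]))
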