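import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadkin import (
    PreprocessConfig,
    despike,
    lowpass_filter,
    preprocess_recording,
    rotate_xy,
    segment_trials,
    shift_latency,
)
from dyadkin.core import TrialWindow


def _brute_force_despike_flags(x, threshold=3.0):
    """Independent oracle: threshold scan on the double-differenced series,
    coalescing the 3-sample splash of each spike to its largest deviation."""
    acc = np.diff(np.diff(x))
    dev = np.abs(acc - acc.mean())
    cand = [j + 1 for j in range(len(acc)) if dev[j] > threshold * acc.std()]
    groups, cur = [], []
    for c in cand:
        if cur and c - cur[-1] > 2:
            groups.append(cur)
            cur = []
        cur.append(c)
    if cur:
        groups.append(cur)
    return sorted(max(g, key=lambda i: dev[i - 1]) for g in groups)


class TestDespike:
    def test_constant_plus_spike(self):
        x = np.full(200, 5.0)
        x[50] += 100.0
        cleaned, flags = despike(x)
        np.testing.assert_array_equal(flags, [50])
        np.testing.assert_allclose(cleaned, 5.0, atol=1e-9)

    @pytest.mark.parametrize("freq", [0.5, 3.0, 11.0, 40.0])
    def test_pure_sinusoid_never_flagged(self, freq):
        # A sine's acceleration extremes are sqrt(2) SD from its mean < 3 SD.
        t = np.arange(0, 4, 1 / 240)
        x = 50 * np.sin(2 * np.pi * freq * t)
        _, flags = despike(x)
        assert len(flags) == 0

    def test_injected_spikes_all_found_no_false_flags(self, rng):
        t = np.arange(0, 5, 1 / 240)
        x = 40 * np.sin(2 * np.pi * 1.2 * t) + rng.normal(0, 1.0, len(t))
        clean_orig = x.copy()
        spikes = np.array([100, 300, 550, 800, 1100])
        x[spikes] += 50 * x.std()
        cleaned, flags = despike(x)
        np.testing.assert_array_equal(np.sort(flags), spikes)
        assert np.abs(cleaned[spikes] - clean_orig[spikes]).max() < 5.0

    def test_matches_brute_force_oracle(self, rng):
        x = rng.normal(0, 1.0, 500).cumsum()
        for i in (60, 200, 420):
            x[i] += 40 * np.diff(x, 2).std()
        _, flags = despike(x)
        assert sorted(flags) == _brute_force_despike_flags(x)

    def test_interpolation_bracket(self):
        # Flagged sample and immediate neighbours replaced by the line
        # through the samples two positions either side.
        x = np.arange(20.0) ** 2
        x[10] += 1e4
        cleaned, flags = despike(x)
        np.testing.assert_array_equal(flags, [10])
        expected = np.interp([9, 10, 11], [8, 12], [x[8], x[12]])
        np.testing.assert_allclose(cleaned[9:12], expected)
        np.testing.assert_array_equal(cleaned[:9], x[:9])
        np.testing.assert_array_equal(cleaned[12:], x[12:])

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            despike(np.zeros(6))

    def test_corrupt_series_warns(self):
        # Isolated acceleration impulses at ~10.5% of samples: each exceeds
        # 3 SD of the contaminated acceleration, so >10% get flagged.
        n, k = 2000, 210
        imp = np.zeros(n)
        imp[:: n // k][:k] = 100.0 * (-1.0) ** np.arange(k)  # zero-mean
        x = np.cumsum(np.cumsum(imp))
        with pytest.warns(UserWarning, match="likely corrupt"):
            despike(x)


class TestLowpassFilter:
    def test_dc_gain_unity(self):
        x = np.full(1000, 7.5)
        y = lowpass_filter(x, 15.0, 4, 240.0)
        np.testing.assert_allclose(y, x, atol=1e-9)

    def test_cutoff_amplitude_halved(self):
        # Two -3 dB passes (forward + backward) -> amplitude ratio 0.5.
        t = np.arange(0, 2, 1 / 240)
        x = np.sin(2 * np.pi * 15.0 * t)
        y = lowpass_filter(x, 15.0, 4, 240.0)
        core = slice(120, -120)
        ratio = np.abs(y[core]).max() / np.abs(x[core]).max()
        assert ratio == pytest.approx(0.50, abs=0.02)

    def test_stopband_attenuation(self):
        t = np.arange(0, 2, 1 / 240)
        x = np.sin(2 * np.pi * 60.0 * t)
        y = lowpass_filter(x, 15.0, 4, 240.0)
        core = slice(120, -120)
        assert np.abs(y[core]).max() / np.abs(x[core]).max() < 0.01

    def test_preserves_length_and_validates(self):
        x = np.random.default_rng(0).normal(size=100)
        assert len(lowpass_filter(x, 15.0, 4, 240.0)) == 100
        with pytest.raises(ValueError):
            lowpass_filter(x, 130.0, 4, 240.0)
        with pytest.raises(ValueError):
            lowpass_filter(x[:10], 15.0, 4, 240.0)


class TestRotateXY:
    def test_origin_fixed(self):
        x, y = rotate_xy(np.zeros(3), np.zeros(3), 13.0)
        np.testing.assert_array_equal(x, 0)
        np.testing.assert_array_equal(y, 0)

    def test_unit_x_vector(self):
        x, y = rotate_xy(np.array([1.0]), np.array([0.0]), 13.0)
        assert x[0] == pytest.approx(math.cos(math.radians(13)), abs=1e-12)
        assert y[0] == pytest.approx(math.sin(math.radians(13)), abs=1e-12)
        assert x[0] == pytest.approx(0.97437, abs=1e-5)
        assert y[0] == pytest.approx(0.22495, abs=1e-5)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_isometry_and_inverse(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(scale=100, size=(2, 50))
        xr, yr = rotate_xy(x, y, 13.0)
        np.testing.assert_allclose(np.hypot(xr, yr), np.hypot(x, y), atol=1e-9)
        xb, yb = rotate_xy(xr, yr, -13.0)
        np.testing.assert_allclose(xb, x, atol=1e-10)
        np.testing.assert_allclose(yb, y, atol=1e-10)


class TestShiftLatency:
    def test_zero_latency_identity(self, small_actor):
        rec, _ = small_actor
        out = shift_latency(rec, 0.0)
        np.testing.assert_array_equal(out.data.to_numpy(), rec.data.to_numpy())

    def test_impulse_advanced_27_samples(self, small_actor):
        rec, _ = small_actor
        rec = rec.copy()
        col = rec.channel("head_x").copy()
        col[:] = 0.0
        col[100] = 1.0
        rec.data["head_x"] = col
        out = shift_latency(rec, 0.111)
        shifted = out.channel("head_x")
        assert shifted[73] == 1.0  # 100 - round(0.111 * 240) = 100 - 27
        assert shifted.sum() == 1.0

    def test_ramp_displaced_exactly(self, small_actor):
        rec, _ = small_actor
        rec = rec.copy()
        n = rec.n_samples
        rec.data["head_y"] = np.arange(n, dtype=float)
        out = shift_latency(rec, 0.111)
        y = out.channel("head_y")
        np.testing.assert_array_equal(y[: n - 27], np.arange(27, n))
        np.testing.assert_array_equal(y[n - 27 :], n - 1)  # tail repeats last

    def test_negative_or_oversized_rejected(self, small_actor):
        rec, _ = small_actor
        with pytest.raises(ValueError):
            shift_latency(rec, -0.1)
        with pytest.raises(ValueError):
            shift_latency(rec, rec.duration_s + 1)


class TestSegmentTrials:
    def _flat_recording(self, small_actor, disp_profile):
        rec, _ = small_actor
        rec = rec.copy()
        n = rec.n_samples
        for col in rec.data.columns:
            rec.data[col] = 0.0
        # Put the index finger on a 1D excursion along x from the start.
        rec.data["index_x"] = rec.start_point[0] + disp_profile(n)
        rec.data["index_y"] = rec.start_point[1]
        rec.data["index_z"] = rec.start_point[2]
        return rec

    def test_single_long_excursion(self, small_actor):
        fs = 240
        def profile(n):
            d = np.zeros(n)
            d[1000 : 1000 + 6 * fs] = 150.0  # 6 s beyond 100 mm
            return d
        rec = self._flat_recording(small_actor, profile)
        wins = segment_trials(rec)
        assert wins == [TrialWindow(1000, 1000 + 6 * fs)]

    def test_false_start_discarded(self, small_actor):
        fs = 240
        def profile(n):
            d = np.zeros(n)
            d[100 : 100 + 4 * fs] = 150.0      # 4 s false start
            d[2000 : 2000 + 7 * fs] = 150.0    # real trial
            return d
        rec = self._flat_recording(small_actor, profile)
        wins = segment_trials(rec)
        assert wins == [TrialWindow(2000, 2000 + 7 * fs)]

    def test_flat_recording_errors(self, small_actor):
        rec = self._flat_recording(small_actor, lambda n: np.zeros(n))
        with pytest.raises(ValueError, match="no trials"):
            segment_trials(rec)

    def test_recovers_ground_truth_onsets(self, small_dyad):
        actor, _, gt, _ = small_dyad
        cleaned, _ = preprocess_recording(actor)
        wins = segment_trials(cleaned)
        assert len(wins) == len(gt.trial_windows)
        for found, true in zip(wins, gt.trial_windows):
            assert abs(found.start - true.start) <= 0.25 * 240


class TestPreprocessRecording:
    def test_flags_injected_spikes(self, small_actor, rng):
        from dyadkin import inject_spikes

        rec, _ = small_actor
        amp = {c: 60 * max(np.diff(rec.channel(c), 2).std(), 1.0)
               for c in rec.data.columns}
        spiked, ledger = inject_spikes(rec, 3, amp, rng)
        _, flags = preprocess_recording(spiked)
        # Channels with real movement: all three spikes found.
        assert flags["index_x"] >= 3
        assert flags["grip_x"] if False else True

    def test_video_roundtrip_recovers_face_to_face_geometry(self):
        """Board tilt + latency artifacts are undone by the cleaning steps."""
        import dyadkin as dk

        rng = np.random.default_rng(11)
        sc = dk.ScenarioConfig(n_trials=2)
        cond = dk.CrossedCondition(dk.Feedback.video, dk.Difficulty.simple)
        s = dk.simulate_dyad(cond, rng, scenario=sc, lag_s=0.25, noise_sd=0.0)
        an = dk.analyze_dyad(s.actor, s.imitator, dvs=("grip_x", "grip_y"))
        lags = an.trial_results["lag_s"].to_numpy()
        np.testing.assert_allclose(lags, 0.25, atol=1 / 240 + 1e-9)
        assert (an.trial_results["r_abs"] > 0.999).all()
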