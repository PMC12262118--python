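import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import erplearn as el
from erplearn.preprocess import MONTAGE_21
from erplearn.sequences import DEV_LARGE, DEV_SMALL, STANDARD

FS = 500.0


def _rec(data, fs=FS, names=None):
    names = names or tuple(f"ch{i}" for i in range(data.shape[0]))
    return el.ContinuousRecording(data=data, fs=fs, channel_names=names)


def _sine(freq, fs=FS, dur_s=4.0, amp=1.0):
    t = np.arange(int(dur_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestResample:
    def test_halves_sample_count(self):
        rec = _rec(np.zeros((2, 1000)))
        out = el.resample(rec, 250.0)
        assert out.fs == 250.0
        assert out.n_samples == 500

    def test_identity_at_same_rate(self):
        rec = _rec(np.random.default_rng(0).normal(size=(1, 400)))
        out = el.resample(rec, FS)
        assert np.allclose(out.data, rec.data)

    def test_sinusoid_amplitude_preserved(self):
        rec = _rec(_sine(10.0)[None, :])
        out = el.resample(rec, 250.0)
        mid = out.data[0, 100:-100]  # skip filter edge effects
        assert np.ptp(mid) / 2 == pytest.approx(1.0, rel=0.01)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="upsampling"):
            el.resample(_rec(np.zeros((1, 100))), 1000.0)


class TestFilter:
    def test_notch_attenuates_50hz_by_20db(self):
        rec = _rec(_sine(50.0)[None, :])
        out = el.filter_recording(rec)
        mid = out.data[0, 200:-200]
        atten_db = 20 * np.log10(np.ptp(mid) / 2.0)
        assert atten_db < -20.0

    def test_constant_signal_unchanged(self):
        rec = _rec(np.full((2, 1000), 3.5))
        out = el.filter_recording(rec)
        assert np.allclose(out.data, 3.5, atol=1e-6)

    def test_passband_5hz_preserved(self):
        rec = _rec(_sine(5.0)[None, :])
        out = el.filter_recording(rec)
        mid = out.data[0, 300:-300]
        assert np.ptp(mid) / 2 == pytest.approx(1.0, rel=0.02)

    def test_cutoff_at_nyquist_rejected(self):
        rec = _rec(np.zeros((1, 100)), fs=50.0)
        with pytest.raises(ValueError, match="Nyquist"):
            el.filter_recording(rec, lowpass_hz=30.0, notch_hz=None)


class TestMuscleArtifacts:
    def test_stationary_noise_barely_flagged(self):
        rng = np.random.default_rng(1)
        rec = _rec(rng.normal(size=(3, 20_000)))
        mask = el.detect_muscle_artifacts(rec)
        assert mask.mean() < 0.02

    def test_injected_high_band_burst_flagged(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(1, 20_000))
        burst = slice(10_000, 10_250)
        t = np.arange(250) / FS
        band_rms = np.sqrt(np.mean(data[0, burst] ** 2))
        data[0, burst] += 100 * band_rms * np.sin(2 * np.pi * 80.0 * t)
        mask = el.detect_muscle_artifacts(_rec(data), threshold_db=10.0)
        assert mask[burst].any()
        assert mask.mean() < 0.1

    def test_infinite_threshold_flags_nothing(self):
        rec = _rec(np.random.default_rng(3).normal(size=(2, 10_000)))
        mask = el.detect_muscle_artifacts(rec, threshold_db=np.inf)
        assert not mask.any()

    def test_band_above_nyquist_rejected(self):
        rec = _rec(np.zeros((1, 1000)), fs=250.0)
        with pytest.raises(ValueError, match="infeasible"):
            el.detect_muscle_artifacts(rec)


class TestSegment:
    def _events(self, onsets_s, labels):
        return pd.DataFrame({"onset": onsets_s,
                             "duration": 0.2,
                             "trial_type": labels})

    def test_one_epoch_per_event_and_grid_size(self):
        rec = _rec(np.zeros((2, 5000)), fs=250.0)
        ev = self._events([2.0, 4.0, 6.0], [STANDARD] * 3)
        out = el.segment(rec, ev)
        assert out.n_trials == 3
        assert out.epochs.shape[2] == 176  # closed [-100, 600] ms at 250 Hz
        assert out.times_ms[0] == -100.0 and out.times_ms[-1] == 600.0

    def test_empty_event_table(self):
        rec = _rec(np.zeros((2, 1000)), fs=250.0)
        out = el.segment(rec, self._events([], []))
        assert out.n_trials == 0

    def test_event_outside_recording_dropped_with_warning(self):
        rec = _rec(np.zeros((1, 500)), fs=250.0)
        ev = self._events([1.0, 100.0], [STANDARD, STANDARD])
        with pytest.warns(UserWarning, match="outside"):
            out = el.segment(rec, ev)
        assert out.n_trials == 1

    def test_artifact_overlap_drops_epoch(self):
        rec = _rec(np.zeros((1, 5000)), fs=250.0)
        mask = np.zeros(5000, dtype=bool)
        mask[1000:1010] = True
        ev = self._events([4.0, 8.0], [STANDARD, STANDARD])
        out = el.segment(rec, ev, artifact_mask=mask)
        assert out.n_trials == 1
        assert out.trial_ids.tolist() == [1]


class TestBaseline:
    def _epochs(self, data):
        n = data.shape[0]
        return el.EpochSet(epochs=data, times_ms=el.epoch_grid(250.0),
                           labels=np.array([STANDARD] * n, dtype=object),
                           trial_ids=np.arange(n),
                           channel_names=tuple(f"c{i}" for i in range(data.shape[1])))

    def test_constant_epoch_becomes_zero(self):
        out = el.baseline_correct(self._epochs(np.full((2, 1, 176), 7.0)))
        assert np.allclose(out.epochs, 0.0)

    def test_linear_ramp_closed_form(self):
        times = el.epoch_grid(250.0)
        ramp = 0.01 * times  # uV per ms
        out = el.baseline_correct(self._epochs(ramp[None, None, :]))
        base_mean = 0.01 * times[times <= 0].mean()
        assert np.allclose(out.epochs[0, 0], ramp - base_mean, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        eps = self._epochs(rng.normal(size=(3, 2, 176)))
        once = el.baseline_correct(eps)
        twice = el.baseline_correct(once)
        assert np.allclose(once.epochs, twice.epochs, atol=1e-12)

    def test_baseline_mean_is_zero(self):
        rng = np.random.default_rng(5)
        out = el.baseline_correct(self._epochs(rng.normal(size=(4, 3, 176))))
        m = out.times_ms <= 0
        assert np.allclose(out.epochs[:, :, m].mean(axis=2), 0.0, atol=1e-9)


class TestPairing:
    def _epochs(self, labels, drop=()):
        labels = np.array(labels, dtype=object)
        keep = np.array([i for i in range(len(labels)) if i not in drop])
        data = np.arange(len(labels), dtype=float)[keep, None, None] * \
            np.ones((1, 1, 176))
        return el.EpochSet(epochs=data, times_ms=el.epoch_grid(250.0),
                           labels=labels[keep], trial_ids=keep,
                           channel_names=("Fz",))

    def test_s_s_d_gives_one_pair(self):
        pairs = el.pair_standards(self._epochs([STANDARD, STANDARD, DEV_LARGE]))
        assert pairs.n_pairs == 1
        assert pairs.deviant_trial_ids.tolist() == [2]
        assert pairs.standard_trial_ids.tolist() == [1]

    def test_dropped_predecessor_excludes_pair(self):
        pairs = el.pair_standards(
            self._epochs([STANDARD, STANDARD, DEV_LARGE], drop=(1,)))
        assert pairs.n_pairs == 0

    def test_pairing_uses_original_sequence_ids(self):
        # drop an early standard: later pair indices must be unaffected
        labels = [STANDARD, STANDARD, DEV_SMALL, STANDARD, STANDARD, DEV_LARGE]
        pairs = el.pair_standards(self._epochs(labels, drop=(0,)))
        assert pairs.deviant_trial_ids.tolist() == [2, 5]
        assert pairs.standard_trial_ids.tolist() == [1, 4]

    def test_counts_balanced_per_type(self, small_study_pairs):
        for pairs in small_study_pairs.values():
            for dtype in (DEV_SMALL, DEV_LARGE):
                sub = pairs.select_type(dtype)
                assert sub.deviants.shape[0] == sub.standards.shape[0]


class TestRejection:
    def _pairs(self, dev_amp, std_amp):
        from conftest import make_pairs
        n = len(dev_amp)
        shape = (n, 4, 176)
        dev = np.ones(shape) * np.asarray(dev_amp)[:, None, None]
        std = np.ones(shape) * np.asarray(std_amp)[:, None, None]
        return make_pairs(dev, std)

    def test_identity_below_threshold(self):
        pairs = self._pairs([50.0, -100.0], [10.0, 20.0])
        out = el.reject_pairs(pairs, threshold_uv=200.0)
        assert out.n_pairs == 2

    def test_either_member_over_threshold_removes_pair(self):
        pairs = self._pairs([250.0, 10.0, 10.0], [5.0, 5.0, -300.0])
        out = el.reject_pairs(pairs, threshold_uv=200.0)
        assert out.n_pairs == 1
        assert out.deviants[0, 0, 0] == 10.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-400, 400), st.floats(-400, 400)),
                    min_size=1, max_size=12))
    def test_balance_preserved_under_any_rejection_pattern(self, amps):
        dev_amp = [a for a, _ in amps]
        std_amp = [b for _, b in amps]
        pairs = self._pairs(dev_amp, std_amp)
        out = el.reject_pairs(pairs, threshold_uv=200.0)
        assert out.deviants.shape[0] == out.standards.shape[0]
        kept = [i for i, (a, b) in enumerate(amps)
                if abs(a) <= 200.0 and abs(b) <= 200.0]
        assert out.n_pairs == len(kept)


class TestRereference:
    def _epochs(self, a2_value, scalp_value=5.0):
        data = np.full((2, 3, 176), scalp_value)
        data[:, 2, :] = a2_value
        return el.EpochSet(epochs=data, times_ms=el.epoch_grid(250.0),
                           labels=np.array([STANDARD] * 2, dtype=object),
                           trial_ids=np.arange(2),
                           channel_names=("F3", "Fz", "A2"))

    def test_zero_a2_is_identity(self):
        out = el.rereference_linked_mastoids(self._epochs(0.0))
        assert np.allclose(out.epochs, 5.0)
        assert "A2" not in out.channel_names

    def test_constant_a2_shifts_all_channels(self):
        out = el.rereference_linked_mastoids(self._epochs(2.0))
        assert np.allclose(out.epochs, 5.0 - 1.0)

    def test_double_application_guarded(self):
        out = el.rereference_linked_mastoids(self._epochs(2.0))
        with pytest.raises(ValueError, match="already"):
            el.rereference_linked_mastoids(out)


def test_full_chain_keeps_montage_and_balance(small_study_pairs):
    pairs = small_study_pairs[("sub-01", 1)]
    assert pairs.reference == "linked mastoids"
    assert "A2" not in pairs.channel_names
    assert set(pairs.channel_names) == set(MONTAGE_21) - {"A2"}
    assert pairs.deviants.shape == pairs.standards.shape


class TestSpatialProjectionHook:
    def test_identity_projection_is_noop(self, small_study_pairs):
        rng = np.random.default_rng(8)
        rec = el.ContinuousRecording(rng.normal(size=(4, 500)), 500.0,
                                     ("F3", "Fz", "F4", "A2"))
        out = el.apply_spatial_projection(rec, np.eye(4))
        assert np.allclose(out.data, rec.data)

    def test_projection_removes_targeted_component(self):
        rng = np.random.default_rng(9)
        source = rng.normal(size=(2, 1000))         # brain + ocular sources
        mixing = np.array([[1.0, 0.8], [0.5, 1.0], [0.2, 0.3]])
        rec = el.ContinuousRecording(mixing @ source, 500.0,
                                     ("Fp1", "Fz", "Oz"))
        unmix = np.linalg.pinv(mixing)
        keep = np.diag([1.0, 0.0])                  # zero the ocular source
        P = mixing @ keep @ unmix
        out = el.apply_spatial_projection(rec, P)
        clean = mixing[:, :1] @ source[:1]
        assert np.allclose(out.data, clean, atol=1e-10)

    def test_wrong_shape_rejected(self):
        rec = el.ContinuousRecording(np.zeros((3, 100)), 500.0, ("a", "b", "c"))
        with pytest.raises(ValueError, match="3x3"):
            el.apply_spatial_projection(rec, np.eye(2))
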