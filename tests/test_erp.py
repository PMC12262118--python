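import numpy as np
import pytest

import erplearn as el
from conftest import make_pairs
from erplearn.erp import MMN, P3A
from erplearn.sequences import DEV_LARGE


def _wave(values, times=None):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = el.epoch_grid(250.0)
    return el.ErpWaveform(values=values, times_ms=np.asarray(times, float))


@pytest.fixture
def template_pairs():
    """Pairs whose differential is exactly a -2 uV MMN-like bell at 224 ms."""
    times = el.epoch_grid(250.0)
    tpl = el.ComponentTemplate(MMN, 224.0, 50.0, -2.0)
    trace = tpl.evaluate(times)
    n = 10
    dev = np.tile(trace, (n, 4, 1))
    std = np.zeros_like(dev)
    return make_pairs(dev, std), tpl, times


class TestAverageDifferential:
    def test_identical_populations_give_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 4, 176))
        pairs = make_pairs(x, x)
        wave = el.average_differential(pairs)
        assert np.allclose(wave.values, 0.0, atol=1e-12)

    def test_template_amplitude_recovered(self, template_pairs):
        pairs, tpl, times = template_pairs
        wave = el.average_differential(pairs)
        assert wave.values.min() == pytest.approx(-2.0)
        assert times[np.argmin(wave.values)] == tpl.center_ms

    def test_linearity_diff_of_means_equals_mean_of_diffs(self):
        rng = np.random.default_rng(1)
        dev = rng.normal(size=(12, 4, 176))
        std = rng.normal(size=(12, 4, 176))
        pairs = make_pairs(dev, std)
        wave = el.average_differential(pairs, channels=("F3", "Fz", "F4"))
        per_pair = (dev[:, :3] - std[:, :3]).mean(axis=1)  # channel mean
        assert np.allclose(wave.values, per_pair.mean(axis=0), atol=1e-12)


class TestGrandAverage:
    def test_single_input_identity(self):
        w = _wave(np.arange(176.0))
        g = el.grand_average([w])
        assert np.array_equal(g.values, w.values)

    def test_two_traces_mean(self):
        a, b = _wave(np.ones(176)), _wave(3 * np.ones(176))
        assert np.allclose(el.grand_average([a, b]).values, 2.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        waves = [_wave(rng.normal(size=176)) for _ in range(5)]
        g1 = el.grand_average(waves)
        g2 = el.grand_average(waves[::-1])
        assert np.allclose(g1.values, g2.values)


class TestSelectWindows:
    def _bimodal(self, mmn_center=224.0, p3a_center=320.0):
        times = el.epoch_grid(250.0)
        v = (el.ComponentTemplate(MMN, mmn_center, 40.0, -2.0).evaluate(times)
             + el.ComponentTemplate(P3A, p3a_center, 40.0, 1.5).evaluate(times))
        return _wave(v, times)

    def test_windows_have_stated_half_width(self):
        mmn, p3a = el.select_windows(self._bimodal(), half_width_ms=35.0)
        assert (mmn.component, p3a.component) == (MMN, P3A)
        assert mmn.peak_ms == 224.0 and p3a.peak_ms == 320.0
        assert mmn.width_ms == 70.0 and p3a.width_ms == 70.0
        assert (mmn.start_ms, mmn.end_ms) == (189.0, 259.0)

    def test_negation_swaps_centers(self):
        w = self._bimodal()
        mmn, p3a = el.select_windows(w)
        mmn2, p3a2 = el.select_windows(_wave(-w.values, w.times_ms))
        assert mmn2.peak_ms == p3a.peak_ms
        assert p3a2.peak_ms == mmn.peak_ms

    def test_monotone_trace_forces_extremes(self):
        times = el.epoch_grid(250.0)
        with pytest.warns(UserWarning, match="clipped"):
            mmn, p3a = el.select_windows(_wave(times.copy(), times))
        assert mmn.peak_ms == 0.0     # search is post-stimulus only
        assert p3a.peak_ms == 600.0

    def test_baseline_extrema_ignored(self):
        times = el.epoch_grid(250.0)
        v = self._bimodal().values.copy()
        v[times < 0] = -50.0  # absurd baseline excursion
        mmn, _ = el.select_windows(_wave(v, times))
        assert mmn.peak_ms == 224.0

    def test_overlapping_peaks_raise(self):
        times = el.epoch_grid(250.0)
        v = (el.ComponentTemplate(MMN, 220.0, 20.0, -2.0).evaluate(times)
             + el.ComponentTemplate(P3A, 260.0, 20.0, 1.5).evaluate(times))
        with pytest.raises(ValueError, match="overlap"):
            el.select_windows(_wave(v, times), half_width_ms=35.0)

    def test_flat_trace_warns_and_ties_to_earliest(self):
        with pytest.warns(UserWarning, match="flat"):
            mmn, p3a = el.select_windows(_wave(np.zeros(176)))
        assert mmn.peak_ms == p3a.peak_ms == 0.0


class TestMeasures:
    def _win(self, start=200.0, end=248.0, component=MMN):
        return el.AnalysisWindow(component, start, end, (start + end) / 2)

    def test_constant_mean_amplitude(self):
        assert el.mean_amplitude(_wave(np.full(176, 2.5)), self._win()) == 2.5

    def test_ramp_mean_is_midpoint(self):
        times = el.epoch_grid(250.0)
        w = _wave(0.1 * times, times)
        win = self._win(200.0, 248.0)  # symmetric sample coverage
        assert el.mean_amplitude(w, win) == pytest.approx(0.1 * 224.0)

    def test_single_sample_window(self):
        times = el.epoch_grid(250.0)
        v = np.arange(176.0)
        win = el.AnalysisWindow(MMN, 200.0, 200.0, 200.0)
        assert el.mean_amplitude(_wave(v, times), win) == v[times == 200.0][0]

    def test_peak_latency_at_template_center(self, template_pairs):
        pairs, tpl, _ = template_pairs
        wave = el.average_differential(pairs)
        win = el.AnalysisWindow(MMN, 189.0, 259.0, 224.0)
        assert el.peak_latency(wave, win) == tpl.center_ms

    def test_tie_breaks_to_earliest(self):
        times = el.epoch_grid(250.0)
        v = np.zeros(176)
        v[(times == 208.0) | (times == 240.0)] = -3.0
        win = el.AnalysisWindow(MMN, 189.0, 259.0, 224.0)
        assert el.peak_latency(_wave(v, times), win) == 208.0

    def test_latency_always_inside_window(self):
        rng = np.random.default_rng(3)
        times = el.epoch_grid(250.0)
        win = el.AnalysisWindow(P3A, 281.0, 351.0, 316.0)
        for _ in range(20):
            lat = el.peak_latency(_wave(rng.normal(size=176), times), win)
            assert win.start_ms <= lat <= win.end_ms


class TestNoiselessRecovery:
    def test_amplitude_and_latency_match_generator(self, noiseless_pairs):
        """On noise-free synthetic data, the measured window amplitude equals
        the analytic template window mean and latency hits the template
        center to within one sample."""
        templates = el.default_templates()
        pairs = noiseless_pairs.select_type(DEV_LARGE)
        wave = el.average_differential(pairs)
        mmn_tpl, p3a_tpl = templates.deviant[DEV_LARGE]
        mmn, p3a = el.select_windows(wave)
        dt = 1000.0 / 250.0
        assert abs(mmn.peak_ms - mmn_tpl.center_ms) <= dt
        assert abs(p3a.peak_ms - p3a_tpl.center_ms) <= dt
        # sampled window mean vs analytic integral of the template
        amp = el.mean_amplitude(wave, mmn)
        expect = np.mean(mmn_tpl.evaluate(
            wave.times_ms[(wave.times_ms >= mmn.start_ms)
                          & (wave.times_ms <= mmn.end_ms)]))
        assert amp == pytest.approx(expect, rel=0.02)
        assert el.peak_latency(wave, mmn) == pytest.approx(
            mmn_tpl.center_ms, abs=dt)

    def test_measure_components_table(self, noiseless_pairs):
        wave = el.average_differential(noiseless_pairs.select_type(DEV_LARGE))
        windows = el.select_windows(wave)
        ms = el.measure_components([noiseless_pairs], windows)
        assert len(ms) == 4  # 2 deviant types x 2 components
        large_mmn = [m for m in ms if m.deviant_type == DEV_LARGE
                     and m.component == MMN][0]
        assert large_mmn.amplitude_uv < -1.0
        assert windows[0].start_ms <= large_mmn.latency_ms <= windows[0].end_ms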