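"""Baseline correction, integration, subtraction, sqrt normalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import iphplc as ip
from iphplc.errors import WindowError
from tests.conftest import make_trace

WINDOW = ip.PeakWindow(10.0, 14.0)


def gaussian_trace(amplitude=20.0, center_min=12.0, sd_s=12.0, step_s=1.0,
                   slope=0.0, offset=0.0, duration=30.0):
    t = np.arange(0, duration + 1e-9, step_s / 60.0)
    g = amplitude * np.exp(-0.5 * (((t - center_min) * 60.0) / sd_s) ** 2)
    return make_trace(t, g + offset + slope * t)


class TestCorrectBaseline:
    def test_flat_baseline_removed(self):
        t = np.linspace(0, 30, 301)
        corrected = ip.correct_baseline(make_trace(t, np.full(301, 5.0)), WINDOW)
        inside = (t >= 10) & (t <= 14)
        np.testing.assert_allclose(corrected.absorbance_mAU[inside], 0, atol=1e-12)
        np.testing.assert_allclose(corrected.absorbance_mAU[~inside], 5.0)

    def test_linear_ramp_removed_exactly(self):
        t = np.linspace(0, 30, 301)
        corrected = ip.correct_baseline(make_trace(t, 1.0 + 0.3 * t), WINDOW)
        inside = (t >= 10) & (t <= 14)
        np.testing.assert_allclose(corrected.absorbance_mAU[inside], 0, atol=1e-12)

    def test_gaussian_on_ramp_recovered(self):
        # window at ±7 SD so the Gaussian tails at the endpoints are < 1e-9
        trace = gaussian_trace(amplitude=20.0, sd_s=12.0, slope=0.4, offset=2.0)
        window = ip.PeakWindow(12.0 - 7 * 12 / 60, 12.0 + 7 * 12 / 60)
        corrected = ip.correct_baseline(trace, window)
        t = trace.time_min
        inside = (t >= window.start_min) & (t <= window.end_min)
        pure = 20.0 * np.exp(-0.5 * (((t - 12.0) * 60.0) / 12.0) ** 2)
        np.testing.assert_allclose(
            corrected.absorbance_mAU[inside], pure[inside], atol=1e-8
        )

    def test_window_outside_trace_rejected(self):
        trace = gaussian_trace(duration=20.0)
        with pytest.raises(WindowError):
            ip.correct_baseline(trace, ip.PeakWindow(18.0, 25.0))


class TestIntegrateWindow:
    def test_rectangle(self):
        t = np.linspace(0, 30, 3001)
        area = ip.integrate_window(
            make_trace(t, np.ones_like(t)), ip.PeakWindow(10.0, 11.0)
        )
        assert area == pytest.approx(60.0, rel=1e-9)  # 1 mAU × 60 s

    def test_gaussian_matches_closed_form(self):
        # amplitude A, SD w seconds: area = A·w·√(2π)
        for a, w in [(20.0, 12.0), (5.0, 30.0)]:
            trace = gaussian_trace(amplitude=a, sd_s=w, step_s=w / 10)
            area = ip.integrate_window(trace, ip.PeakWindow(5.0, 19.0))
            assert area == pytest.approx(a * w * math.sqrt(2 * math.pi), rel=1e-3)

    def test_convergence_under_refinement(self):
        coarse = ip.integrate_window(gaussian_trace(step_s=1.0), WINDOW)
        fine = ip.integrate_window(gaussian_trace(step_s=0.5), WINDOW)
        assert abs(coarse - fine) / fine < 5e-4

    def test_zero_trace(self):
        t = np.linspace(0, 30, 301)
        assert ip.integrate_window(make_trace(t, np.zeros_like(t)), WINDOW) == 0.0

    def test_too_few_samples_rejected(self):
        t = np.linspace(0, 30, 16)
        with pytest.raises(WindowError, match="fewer than 2"):
            ip.integrate_window(make_trace(t, np.ones(16)), ip.PeakWindow(10.0, 10.5))


class TestNetAreaAndLevel:
    @pytest.mark.parametrize(
        "raw,neg,expect",
        [((500.0, 100.0), None, (400.0, False)),
         ((100.0, 100.0), None, (0.0, False)),
         ((80.0, 100.0), None, (0.0, True))],
    )
    def test_subtraction_and_clamp(self, raw, neg, expect):
        r, n = raw
        assert ip.net_peak_area(r, n) == expect

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            ip.net_peak_area(-1.0, 0.0)
        with pytest.raises(ValueError):
            ip.expression_level(-0.1)

    def test_sqrt_values(self):
        assert ip.expression_level(400.0) == 20.0
        assert ip.expression_level(0.0) == 0.0
        assert ip.expression_level(2.0) == pytest.approx(math.sqrt(2), abs=1e-9)

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    @settings(max_examples=100, derandomize=True)
    def test_monotonicity(self, raw, neg):
        base, _ = ip.net_peak_area(raw, neg)
        more_raw, _ = ip.net_peak_area(raw + 10, neg)
        more_neg, _ = ip.net_peak_area(raw, neg + 10)
        assert more_raw >= base >= more_neg


class TestScaleBehaviour:
    @pytest.mark.parametrize("c", [0.25, 4.0, 100.0])
    def test_area_and_level_equivariance(self, c):
        trace = gaussian_trace()
        a1 = ip.integrate_window(trace, WINDOW)
        a2 = ip.integrate_window(trace.scaled(c), WINDOW)
        assert a2 == pytest.approx(c * a1, rel=1e-12)
        assert ip.expression_level(a2) == pytest.approx(
            math.sqrt(c) * ip.expression_level(a1), rel=1e-12
        )

    @given(st.floats(1e-3, 1e6), st.floats(1e-3, 1e6))
    @settings(max_examples=100, derandomize=True)
    def test_sqrt_compresses_ratios(self, a, b):
        ratio = ip.expression_level(a) / ip.expression_level(b)
        assert ratio == pytest.approx(math.sqrt(a / b), rel=1e-9)


def test_quantify_trace_full_chain():
    trace = gaussian_trace(amplitude=20.0, sd_s=12.0, slope=0.1, offset=2.0)
    record, level = ip.quantify_trace(trace, WINDOW, negative_control_area=60.0)
    expected_raw = 20.0 * 12.0 * math.sqrt(2 * math.pi)
    assert record.raw_area_mAU_s == pytest.approx(expected_raw, rel=1e-3)
    assert level.net_area_mAU_s == pytest.approx(expected_raw - 60.0, rel=1e-3)
    assert level.level == pytest.approx(math.sqrt(expected_raw - 60.0), rel=1e-3)
    assert not level.clamped
    assert record.baseline_model == "linear-endpoints"
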