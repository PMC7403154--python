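"""Generator math: step function, triangular carrier, duty-cycle law."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pwmillusion import (FIG_PARAMS, HalftoneParams, SourceImage,
                         demodulate_lowpass, heaviside, render, triangle)
from pwmillusion.halftone import carrier

from conftest import pearson


def triangle_scalar(x, y, f, alpha, r_hw):
    """Independent scalar transcription of the carrier formula (math module
    only), used as the oracle for the vectorized implementation."""
    shift = r_hw * (math.pi - 2.0 * math.asin(math.cos(2.0 * math.pi * f * y / r_hw))) \
        / (4.0 * math.pi * f * math.tan(alpha))
    return math.asin(math.sin(2.0 * math.pi * f * (x - shift))) / math.pi + 0.5


class TestHeaviside:
    @pytest.mark.parametrize("n,expected", [(-0.1, 0), (0.0, 1), (5.0, 1),
                                            (-1e-300, 0)])
    def test_step_convention(self, n, expected):
        assert heaviside(n) == expected

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            heaviside(float("nan"))
        with pytest.raises(ValueError):
            heaviside(float("inf"))


class TestTriangle:
    def test_peak_and_trough_at_zero_phase(self):
        # at y=0 the phase shift vanishes; quarter period -> peak, three
        # quarters -> trough
        f = 0.05
        for alpha in (math.pi / 4, 1.0, 2.0):
            assert triangle(1 / (4 * f), 0.0, f, alpha, 4.0) == pytest.approx(1.0)
            assert triangle(3 / (4 * f), 0.0, f, alpha, 4.0) == pytest.approx(0.0)

    def test_scalar_oracle_single_point(self):
        v = triangle(0.0, 7.3, 0.05, math.pi / 4, 4.0)
        assert v == pytest.approx(triangle_scalar(0.0, 7.3, 0.05, math.pi / 4, 4.0),
                                  abs=1e-12)

    @given(x=st.floats(-100, 100), y=st.floats(-100, 100),
           f=st.floats(0.01, 0.5), alpha=st.floats(0.2, math.pi - 0.2),
           r_hw=st.floats(0.5, 8.0))
    @settings(max_examples=200, deadline=None)
    def test_range_and_x_periodicity(self, x, y, f, alpha, r_hw):
        v = triangle(x, y, f, alpha, r_hw)
        assert 0.0 <= v <= 1.0
        assert triangle(x + 1.0 / f, y, f, alpha, r_hw) == pytest.approx(v, abs=1e-9)

    def test_phase_shift_periodic_in_y(self):
        # the zigzag phase term repeats every r_hw / f pixels of y
        f, alpha, r_hw = 0.05, math.pi / 4, 4.0
        y_period = r_hw / f
        xs = np.linspace(0, 40, 50)
        v0 = triangle(xs, 3.0, f, alpha, r_hw)
        v1 = triangle(xs, 3.0 + y_period, f, alpha, r_hw)
        np.testing.assert_allclose(v0, v1, atol=1e-9)

    def test_singular_angle_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            triangle(1.0, 1.0, 0.05, math.pi, 4.0)


class TestCarrier:
    @pytest.mark.parametrize("tri,expected", [(0.5, 0.0), (0.6, 1.0), (1.0, 5.0)])
    def test_duty_rescaling(self, tri, expected):
        # invert the triangle value to an x at y=0, then check the scaling
        f = 0.05
        x = math.asin(math.sin(math.pi * (tri - 0.5))) / (2 * math.pi * f)
        p = HalftoneParams(f=f, alpha=math.pi / 4, r_hw=4.0, d_on=0.6, d_off=0.5)
        assert carrier(x, 0.0, p) == pytest.approx(expected, abs=1e-9)

    def test_degenerate_duty_rejected(self):
        with pytest.raises(ValueError, match="d_on"):
            HalftoneParams(f=0.05, alpha=1.0, r_hw=4.0, d_on=0.5, d_off=0.5)


class TestRender:
    @pytest.mark.parametrize("s,expected", [(1.0, 0.6), (0.0, 0.5), (0.5, 0.55)])
    def test_duty_cycle_law(self, s, expected):
        # 400 px at f=0.05 -> 20 periods/row, 400 rows -> >=100 periods total
        img = render(SourceImage.constant(s, (400, 400)), FIG_PARAMS)
        assert img.ink_fraction == pytest.approx(expected, abs=0.02)

    def test_output_binary_and_deterministic(self, disc_silhouette):
        a = render(disc_silhouette, FIG_PARAMS)
        b = render(disc_silhouette, FIG_PARAMS)
        assert set(np.unique(a.values)) <= {0.0, 1.0}
        np.testing.assert_array_equal(a.values, b.values)

    def test_row_spectrum_peaks_at_carrier_frequency(self):
        img = render(SourceImage.constant(0.5, (400, 400)), FIG_PARAMS)
        spec = np.abs(np.fft.rfft(img.values, axis=1)).mean(axis=0)
        freqs = np.fft.rfftfreq(400)
        assert freqs[1 + int(np.argmax(spec[1:]))] == pytest.approx(0.05)

    def test_scalar_oracle_equivalence_64x64(self):
        p = FIG_PARAMS
        src = SourceImage(np.tile(np.linspace(0, 1, 64), (64, 1)))
        img = render(src, p)
        for yy in range(0, 64, 7):
            for xx in range(0, 64, 7):
                tri = triangle_scalar(xx + 0.5, yy + 0.5, p.f, p.alpha, p.r_hw)
                c = (tri - p.d_off) / (p.d_on - p.d_off)
                expected = 0.0 if c - src.values[yy, xx] < 0 else 1.0
                assert img.values[yy, xx] == expected

    def test_vanishing_duty_gap_converges(self):
        # as d_on - d_off -> 0+, figure and background patterns coincide
        eps = 1e-9
        p = HalftoneParams(f=0.05, alpha=math.pi / 4, r_hw=4.0,
                           d_on=0.55 + eps, d_off=0.55)
        on = render(SourceImage.constant(1.0, (100, 100)), p)
        off = render(SourceImage.constant(0.0, (100, 100)), p)
        assert np.mean(on.values != off.values) < 1e-3

    def test_invert_flag_swaps_polarity(self, disc_silhouette):
        inv = SourceImage(1.0 - disc_silhouette.values)
        a = render(disc_silhouette, FIG_PARAMS)
        b = render(inv, FIG_PARAMS, invert_source=True)
        np.testing.assert_array_equal(a.values, b.values)

    def test_too_narrow_image_rejected(self):
        with pytest.raises(ValueError, match="periods"):
            render(SourceImage.constant(1.0, (10, 10)), FIG_PARAMS)

    def test_out_of_range_source_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            src = SourceImage(np.full((50, 50), 1.5))
        assert src.values.max() == 1.0


class TestDemodulateLowpass:
    def test_constant_image_unchanged(self):
        const = np.full((64, 64), 0.37)
        for ft in ("gaussian", "ideal"):
            out = demodulate_lowpass(const, 0.02, filter_type=ft)
            np.testing.assert_allclose(out, const, atol=1e-9)

    def test_dc_gain_unity(self, disc_stimulus):
        out = demodulate_lowpass(disc_stimulus, 0.01)
        assert out.mean() == pytest.approx(disc_stimulus.values.mean(), abs=1e-9)

    def test_lowpass_reveals_figure(self, disc_silhouette, disc_stimulus):
        # filtering below the carrier raises correlation with the source
        figure_map = 1.0 - disc_silhouette.values  # ink polarity
        raw = pearson(disc_stimulus.values, figure_map)
        filt = pearson(demodulate_lowpass(disc_stimulus, 0.01), figure_map)
        assert abs(filt) > abs(raw)
        assert filt > 0.5

    def test_ideal_allpass_identity(self, disc_stimulus):
        out = demodulate_lowpass(disc_stimulus, 0.75, filter_type="ideal")
        np.testing.assert_allclose(out, disc_stimulus.values, atol=1e-6)

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            demodulate_lowpass(np.zeros((8, 8)), 0.0)
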