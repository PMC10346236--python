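"""Exp/Hypot coefficient maps and the decompose-map-reconstruct pipelines."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from profilex import (
    ExpParams,
    GrayImage,
    HypotParams,
    SanitizePolicy,
    WaveletSpec,
    apply_filter,
    decompose,
    exp_map,
    hypot_map,
    michelson_contrast,
    profile_extract,
    reconstruct,
    sweep,
)
from profilex.metrics import compute_metrics


def scalar_exp(u, p):
    """Independent scalar evaluation of the Exp map."""
    base = p.a * math.exp(p.d * u - p.b) / p.g
    if float(p.nn).is_integer():
        x = base**p.nn
    else:
        x = math.copysign(abs(base) ** p.nn, base)
    return x if math.isfinite(x) else 0.0


def scalar_hypot(u, p):
    """Independent scalar evaluation of the Hypot map (sanitize-to-0)."""

    def safe(fn, *args):
        try:
            v = fn(*args)
        except (ValueError, OverflowError, ZeroDivisionError):
            return 0.0
        return v if math.isfinite(v) else 0.0

    u1 = safe(lambda: p.a1 * (1.0 / math.tan(p.a2 * u + p.a3)) + p.a4 * math.sinh(p.a5 * u + p.a6))
    u2 = safe(lambda: p.a7 * math.acosh(1.0 / (p.a8 * u + p.a9)))
    u3 = safe(
        lambda: p.a10 * math.sin(u + p.a12)
        + p.a13 * math.acosh(p.a14 * u + p.a15)
        + p.a16 * math.tanh(u + p.a17)
    )
    u4 = safe(lambda: p.a18 * math.tanh(p.a19 * u + p.a20))
    u5 = safe(lambda: p.a21 * math.hypot(u1, u2) * (1.0 + u4))
    if float(p.a22).is_integer():
        u6 = safe(lambda: (u5 / u3) ** p.a22)
    else:
        u6 = safe(lambda: math.copysign(abs(u5 / u3) ** p.a22, u5 / u3))
    return u6


class TestExpMap:
    def test_zero_coefficient_maps_to_one(self):
        p = ExpParams(a=1, d=1, b=0, g=1, nn=1)
        assert exp_map(np.zeros((3, 3)), p) == pytest.approx(np.ones((3, 3)))

    def test_scalar_anchor_value(self):
        # e^(0.0078 * 100) = e^0.78
        p = ExpParams(a=1, d=0.0078, b=0, g=1, nn=1)
        assert exp_map(np.array([[100.0]]), p)[0, 0] == pytest.approx(
            math.exp(0.78), rel=1e-12
        )

    def test_matches_scalar_double_loop(self, rng):
        u = rng.normal(scale=50.0, size=(16, 16))
        p = ExpParams(a=2.0, d=0.02, b=0.3, g=1.5, nn=3)
        expected = np.array([[scalar_exp(v, p) for v in row] for row in u])
        assert np.allclose(exp_map(u, p), expected, rtol=1e-10)

    def test_noninteger_power_uses_signed_semantics(self, rng):
        u = rng.normal(size=(8, 8))
        p = ExpParams(a=-1.0, d=1.0, b=0.0, g=1.0, nn=2.5)
        expected = np.array([[scalar_exp(v, p) for v in row] for row in u])
        out = exp_map(u, p)
        assert np.all(np.isfinite(out))
        assert np.allclose(out, expected, rtol=1e-10)

    def test_zeroth_power_is_all_ones(self, rng):
        out = exp_map(rng.normal(size=(4, 4)), ExpParams(nn=0))
        assert np.array_equal(out, np.ones((4, 4)))

    def test_monotone_for_first_power(self):
        u = np.linspace(-100, 100, 201)
        out = exp_map(u, ExpParams(a=1.0, d=0.01, b=0.0, g=2.0, nn=1))
        assert np.all(np.diff(out) > 0)

    def test_zero_divisor_rejected(self):
        with pytest.raises(ValueError, match="g"):
            ExpParams(g=0.0)


class TestHypotMap:
    # a1=a4=0 kills u1; a8=0, a9=0.5 pins u2 = asech(0.5); a10=1, a12=pi/2,
    # a13=a16=0 pins u3 = 1; a18=0 kills u4.
    CLOSED_FORM = dict(
        a1=0, a4=0, a7=1, a8=0, a9=0.5, a10=1, a12=math.pi / 2,
        a13=0, a16=0, a18=0, a21=1, a22=1,
    )

    def test_closed_form_scalar_value(self):
        p = HypotParams(**self.CLOSED_FORM)
        # asech(0.5) = ln(2 + sqrt(3))
        expected = math.log(2 + math.sqrt(3))
        assert hypot_map(np.array([[0.0]]), p)[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_closed_form_tenth_power(self):
        p = HypotParams(**{**self.CLOSED_FORM, "a22": 10})
        expected = math.log(2 + math.sqrt(3)) ** 10
        assert hypot_map(np.array([[0.0]]), p)[0, 0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(15.69347, rel=1e-5)

    def test_zero_u3_sanitized_to_zero(self):
        # a10=a13=a16=0 makes u3 identically 0 -> division blows up -> 0
        p = HypotParams(a10=0, a13=0, a16=0)
        assert np.all(hypot_map(np.array([[0.0, 1.0]]), p) == 0.0)

    def test_matches_scalar_double_loop(self, rng):
        u = rng.normal(scale=2.0, size=(16, 16))
        p = HypotParams()
        expected = np.array([[scalar_hypot(v, p) for v in row] for row in u])
        assert np.allclose(hypot_map(u, p), expected, rtol=1e-10, atol=1e-300)

    def test_matches_scalar_double_loop_display_scale(self, rng):
        u = rng.normal(scale=200.0, size=(16, 16))
        p = HypotParams()
        expected = np.array([[scalar_hypot(v, p) for v in row] for row in u])
        got = hypot_map(u, p)
        finite = np.isfinite(expected)
        assert finite.all()
        assert np.allclose(got, expected, rtol=1e-10, atol=1e-300)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.integers(min_value=1, max_value=6),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_even_power_output_nonnegative(self, half_power, seed):
        u = np.random.default_rng(seed).normal(scale=100.0, size=(8, 8))
        out = hypot_map(u, HypotParams(a22=2 * half_power))
        assert np.all(np.isfinite(out))
        assert np.all(out >= 0.0)

    def test_custom_replacement_value(self):
        p = HypotParams(a10=0, a13=0, a16=0)  # forces non-finite u6
        out = hypot_map(np.array([[0.0]]), p, SanitizePolicy(replacement_value=-1.0))
        assert out[0, 0] == -1.0

    def test_nonfinite_replacement_rejected(self):
        with pytest.raises(ValueError):
            SanitizePolicy(replacement_value=math.inf)


class TestApplyFilter:
    def test_identity_coefficient_treatment_roundtrips(self, rng):
        px = rng.random((32, 32)) * 255
        coeffs = decompose(GrayImage(px), WaveletSpec("haar", 2))
        back = reconstruct(coeffs.map_subbands(lambda u: u))
        assert np.allclose(back.pixels, px, atol=1e-8)

    def test_constant_one_coefficients_match_library_oracle(self):
        """Exp with a=1, d=0, b=0, g=1, nn=1 maps every coefficient to 1;
        the pipeline output must equal a direct reconstruction of all-ones
        coefficients."""
        import pywt

        px = np.arange(64, dtype=float).reshape(8, 8)
        spec = WaveletSpec("haar", 1)
        out = apply_filter(
            GrayImage(px), "exp", ExpParams(a=1, d=0, b=0, g=1, nn=1), spec
        )
        coeffs = pywt.wavedec2(px, "haar", mode="symmetric", level=1)
        ones = [np.ones_like(coeffs[0])] + [
            tuple(np.ones_like(b) for b in lvl) for lvl in coeffs[1:]
        ]
        oracle = pywt.waverec2(ones, "haar", mode="symmetric")
        assert np.allclose(out.pixels, oracle, atol=1e-10)

    def test_exp_pipeline_working_geometry(self, blob_image):
        out = profile_extract(blob_image, "exp", working_shape=(64, 96))
        assert out.shape == (64, 96)
        assert np.all(np.isfinite(out.pixels))

    def test_hypot_pipeline_skips_resize_by_default(self, noisy_blob_8bit):
        out = profile_extract(noisy_blob_8bit, "hypot")
        assert out.shape == noisy_blob_8bit.shape

    def test_hypot_output_floored_at_zero(self, noisy_blob_8bit):
        out = apply_filter(noisy_blob_8bit, "hypot")
        assert out.pixels.min() == 0.0
        assert out.pixels.max() > 0.0

    def test_hypot_michelson_contrast_is_one_on_noisy_fixture(self, noisy_blob_8bit):
        out = apply_filter(noisy_blob_8bit, "hypot")
        assert michelson_contrast(out) == 1.0

    def test_unknown_map_kind_rejected(self, blob_image):
        with pytest.raises(ValueError, match="map kind"):
            apply_filter(blob_image, "sobel")


class TestSweep:
    def test_singleton_sweep_equals_single_run(self, noisy_blob_8bit):
        base = ExpParams()
        results = sweep(noisy_blob_8bit, "exp", base, "nn", [1])
        assert len(results) == 1
        value, img, report = results[0]
        direct = apply_filter(noisy_blob_8bit, "exp", ExpParams(nn=1))
        assert value == 1
        assert np.array_equal(img.pixels, direct.pixels)
        assert report == compute_metrics(direct)

    def test_published_nn_values_run(self, noisy_blob_8bit):
        values = [1, 2, 3, 6, 10, 44, 50, 60, 90]
        results = sweep(noisy_blob_8bit, "exp", ExpParams(), "nn", values)
        assert [v for v, _, _ in results] == values
        for _, img, report in results:
            assert np.all(np.isfinite(img.pixels))
            assert math.isfinite(report.me)

    def test_a22_sweep_keeps_contrast_at_one(self, noisy_blob_8bit):
        results = sweep(noisy_blob_8bit, "hypot", HypotParams(), "a22", [10, 20, 30, 180, 220, 400])
        assert [r.mc for _, _, r in results] == [1.0] * 6

    def test_unknown_parameter_rejected(self, noisy_blob_8bit):
        with pytest.raises(ValueError, match="zz"):
            sweep(noisy_blob_8bit, "exp", ExpParams(), "zz", [1.0])
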