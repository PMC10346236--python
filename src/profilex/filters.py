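"""The Exp and Hypot wavelet-coefficient maps and their full pipelines.

Both filters share one skeleton: decompose the gray image into wavelet
subbands, push every selected coefficient ``u`` through an elementwise
nonlinear map, and reconstruct. The map is where the profile extraction
happens — smooth regions produce near-constant coefficients that the map
flattens, while edges produce outliers that survive (or blow up and get
sanitised to zero, which carves dark contours into the reconstruction).

Exp map
    ``x = (a * exp(d*u - b) / g) ** nn``

Hypot map (all elementwise, constants a1..a22)::

    u1 = a1*cot(a2*u + a3) + a4*sinh(a5*u + a6)
    u2 = a7*asech(a8*u + a9)
    u3 = a10*sin(u + a12) + a13*acosh(a14*u + a15) + a16*tanh(u + a17)
    u4 = a18*tanh(a19*u + a20)
    u5 = a21*hypot(u1, u2) * (1 + u4)
    u6 = (u5 / u3) ** a22

cot poles, asech outside (0, 1], acosh below 1 and division by zero all
produce non-finite intermediates; the :class:`SanitizePolicy` replaces them
(default: with 0) after every stage so the pipeline is total. With an even
``a22`` every surviving coefficient is non-negative, and the Hypot
reconstruction is additionally floored at zero — which is why its Michelson
contrast is identically 1 on any output that has both a zero and a positive
pixel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .io import GrayImage, resize_to_working, to_gray
from .metrics import BlockSpec, MetricReport, compute_metrics
from .wavelet import CoefficientSet, WaveletSpec, decompose, reconstruct

__all__ = [
    "ExpParams",
    "HypotParams",
    "SanitizePolicy",
    "exp_map",
    "hypot_map",
    "apply_filter",
    "profile_extract",
    "sweep",
]


@dataclass(frozen=True)
class ExpParams:
    """Constants of the Exp map ``x = (a * exp(d*u - b) / g) ** nn``.

    Defaults put ``d`` at 0.0078 and ``nn`` at 2, anchor values of the
    published parameter sweeps; they are starting points, not recommendations
    — the maps are meant to be tuned per image.
    """

    a: float = 1.0
    d: float = 0.0078
    b: float = 0.0
    g: float = 1.0
    nn: float = 2.0

    def __post_init__(self) -> None:
        if self.g == 0:
            raise ValueError("divisor g must be nonzero")


@dataclass(frozen=True)
class HypotParams:
    """Constants a1..a22 of the Hypot map.

    ``a11`` is carried for completeness but enters no equation (the map's
    published form skips from a10 to a12). ``a3`` and ``a9`` default to 0.5
    so that cot and asech are in-domain at u = 0; ``a22`` defaults to an even
    power, which makes every sanitised output coefficient non-negative.
    """

    a1: float = 1.0
    a2: float = 1.0
    a3: float = 0.5
    a4: float = 1.0
    a5: float = 1.0
    a6: float = 1.0
    a7: float = 1.0
    a8: float = 1.0
    a9: float = 0.5
    a10: float = 1.0
    a11: float = 1.0  # stored but unused
    a12: float = 1.0
    a13: float = 1.0
    a14: float = 1.0
    a15: float = 1.0
    a16: float = 1.0
    a17: float = 1.0
    a18: float = 7.0
    a19: float = 1.0
    a20: float = 1.0
    a21: float = 1.0
    a22: float = 10.0


@dataclass(frozen=True)
class SanitizePolicy:
    """How non-finite intermediates/outputs are replaced."""

    replacement_value: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.replacement_value):
            raise ValueError("replacement value must be finite")

    def __call__(self, arr: np.ndarray) -> np.ndarray:
        out = np.asarray(arr, dtype=float)
        return np.where(np.isfinite(out), out, self.replacement_value)


def _signed_power(x: np.ndarray, p: float) -> np.ndarray:
    """x**p, with sign(x)*|x|**p semantics for non-integer p.

    Keeps negative bases real instead of producing complex or NaN results;
    integer exponents use the plain power.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        if float(p).is_integer():
            return np.power(x, p)
        return np.sign(x) * np.power(np.abs(x), p)


def exp_map(u: np.ndarray, p: ExpParams = ExpParams()) -> np.ndarray:
    """Apply the Exp coefficient map elementwise; non-finite results -> 0."""
    u = np.asarray(u, dtype=float)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        x = _signed_power(p.a * np.exp(p.d * u - p.b) / p.g, p.nn)
    return SanitizePolicy()(x)


def hypot_map(
    u: np.ndarray,
    p: HypotParams = HypotParams(),
    s: SanitizePolicy = SanitizePolicy(),
) -> np.ndarray:
    """Apply the Hypot coefficient map elementwise.

    Every intermediate stage is sanitised per ``s``, so cot poles, inverse
    hyperbolic functions evaluated off-domain, overflow and division by zero
    never propagate: they become the replacement value (default 0).
    """
    u = np.asarray(u, dtype=float)
    with np.errstate(all="ignore"):
        u1 = s(p.a1 / np.tan(p.a2 * u + p.a3) + p.a4 * np.sinh(p.a5 * u + p.a6))
        u2 = s(p.a7 * _asech(p.a8 * u + p.a9))
        u3 = s(
            p.a10 * np.sin(u + p.a12)
            + p.a13 * _acosh(p.a14 * u + p.a15)
            + p.a16 * np.tanh(u + p.a17)
        )
        u4 = s(p.a18 * np.tanh(p.a19 * u + p.a20))
        u5 = s(p.a21 * np.hypot(u1, u2) * (1.0 + u4))
        u6 = _signed_power(np.divide(u5, u3), p.a22)
    return s(u6)


def _asech(x: np.ndarray) -> np.ndarray:
    """Inverse hyperbolic secant; NaN/Inf outside its domain (0, 1]."""
    with np.errstate(all="ignore"):
        return np.arccosh(1.0 / np.asarray(x, dtype=float))


def _acosh(x: np.ndarray) -> np.ndarray:
    with np.errstate(all="ignore"):
        return np.arccosh(np.asarray(x, dtype=float))


def _coefficient_map(map_kind: str, params, sanitize: SanitizePolicy):
    if map_kind == "exp":
        p = params if params is not None else ExpParams()
        return lambda u: exp_map(u, p)
    if map_kind == "hypot":
        p = params if params is not None else HypotParams()
        return lambda u: hypot_map(u, p, sanitize)
    raise ValueError(f"unknown map kind {map_kind!r}; expected 'exp' or 'hypot'")


def apply_filter(
    img: GrayImage,
    map_kind: str,
    params: ExpParams | HypotParams | None = None,
    wspec: WaveletSpec = WaveletSpec(),
    subband_scope: str = "all",
    sanitize: SanitizePolicy = SanitizePolicy(),
) -> GrayImage:
    """decompose -> coefficient map -> reconstruct; returns raw float output.

    ``subband_scope`` selects which subbands the map touches: ``all``
    (default), ``details-only`` or ``approx-only``. For the Hypot map the
    reconstruction is floored at zero, pinning its raw minimum to 0 whenever
    any pixel would have gone negative; the Exp output is returned unclipped
    (its raw minimum may be negative, and its Michelson contrast may exceed
    1).
    """
    fn = _coefficient_map(map_kind, params, sanitize)
    coeffs = decompose(img, wspec)
    mapped = coeffs.map_subbands(fn, scope=subband_scope)
    out = reconstruct(mapped)
    if map_kind == "hypot":
        out = GrayImage(np.maximum(out.pixels, 0.0), value_domain="raw-float")
    return out


def profile_extract(
    img,
    map_kind: str,
    params: ExpParams | HypotParams | None = None,
    wspec: WaveletSpec = WaveletSpec(),
    subband_scope: str = "all",
    resize: bool | None = None,
    working_shape: tuple[int, int] | None = None,
) -> GrayImage:
    """Full pipeline: gray conversion, optional resize, then the filter.

    ``resize`` defaults to True for the Exp pipeline (whose published recipe
    fixes a 1440 x 2560 working geometry) and False for the Hypot pipeline;
    pass a bool to override, and ``working_shape`` to change the geometry.
    """
    gray = to_gray(img)
    if resize is None:
        resize = map_kind == "exp"
    if resize:
        rows, cols = working_shape or (1440, 2560)
        gray = resize_to_working(gray, rows, cols)
    return apply_filter(gray, map_kind, params, wspec, subband_scope)


def sweep(
    img: GrayImage,
    map_kind: str,
    base_params: ExpParams | HypotParams,
    param_name: str,
    values: list,
    wspec: WaveletSpec = WaveletSpec(),
    subband_scope: str = "all",
    block_spec: BlockSpec = BlockSpec(),
) -> list[tuple[float, GrayImage, MetricReport]]:
    """Re-run the filter for each value of one parameter, with metrics.

    Returns one ``(value, raw_output, MetricReport)`` triple per entry of
    ``values``, in order — the layout of the published tuning tables.
    """
    if param_name not in {f.name for f in dataclasses.fields(base_params)}:
        raise ValueError(
            f"{param_name!r} is not a parameter of {type(base_params).__name__}"
        )
    results = []
    for v in values:
        p = dataclasses.replace(base_params, **{param_name: v})
        out = apply_filter(img, map_kind, p, wspec, subband_scope)
        results.append((v, out, compute_metrics(out, block_spec)))
    return results
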