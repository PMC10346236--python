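"""The 2-D wavelet decompose/reconstruct contract both filters build on.

The transform itself is delegated to PyWavelets; this module owns the
container (:class:`CoefficientSet`) that the coefficient maps operate on and
guarantees the round-trip contract ``reconstruct(decompose(x)) == x`` to
within 1e-8.

The filters never specify a particular mother wavelet, so the family, the
number of decomposition levels and the boundary extension are all part of
:class:`WaveletSpec`; the defaults (Haar, one level, symmetric extension)
are the simplest choice with trivially consistent subband geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pywt

from .io import GrayImage

__all__ = ["WaveletSpec", "CoefficientSet", "decompose", "reconstruct"]


@dataclass(frozen=True)
class WaveletSpec:
    """Which wavelet transform to use.

    family : any PyWavelets discrete wavelet name ("haar", "db2", "bior2.2",
        "coif1", "sym4", ...).
    levels : decomposition depth, >= 1.
    boundary : signal extension mode at the image borders.
    """

    family: str = "haar"
    levels: int = 1
    boundary: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError(f"levels must be >= 1, got {self.levels}")
        if self.family not in pywt.wavelist(kind="discrete"):
            raise ValueError(f"unknown or non-discrete wavelet family {self.family!r}")


@dataclass
class CoefficientSet:
    """Approximation + per-level detail subbands of one decomposition.

    ``details`` is ordered coarsest-first; each entry is the
    (horizontal, vertical, diagonal) triplet of that level.
    """

    approximation: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    spec: WaveletSpec
    original_shape: tuple[int, int]

    def subbands(self, scope: str = "all") -> list[np.ndarray]:
        """The subband arrays selected by ``scope`` (views, not copies)."""
        if scope == "all":
            return [self.approximation] + [b for lvl in self.details for b in lvl]
        if scope == "details-only":
            return [b for lvl in self.details for b in lvl]
        if scope == "approx-only":
            return [self.approximation]
        raise ValueError(f"unknown subband scope {scope!r}")

    def map_subbands(self, fn, scope: str = "all") -> "CoefficientSet":
        """Return a new set with ``fn`` applied to the selected subbands."""
        if scope not in ("all", "details-only", "approx-only"):
            raise ValueError(f"unknown subband scope {scope!r}")
        approx = self.approximation
        details = self.details
        if scope in ("all", "approx-only"):
            approx = fn(approx)
        if scope in ("all", "details-only"):
            details = [tuple(fn(b) for b in lvl) for lvl in details]
        else:
            details = [tuple(b.copy() for b in lvl) for lvl in details]
        return replace(self, approximation=np.asarray(approx), details=details)


def decompose(img: GrayImage | np.ndarray, spec: WaveletSpec = WaveletSpec()) -> CoefficientSet:
    """Multilevel 2-D forward wavelet transform of a gray image."""
    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=float)
    rows, cols = px.shape
    if min(rows, cols) < 2**spec.levels:
        raise ValueError(
            f"image of shape {px.shape} too small for {spec.levels} decomposition level(s)"
        )
    coeffs = pywt.wavedec2(px, spec.family, mode=spec.boundary, level=spec.levels)
    return CoefficientSet(
        approximation=coeffs[0],
        details=[tuple(lvl) for lvl in coeffs[1:]],
        spec=spec,
        original_shape=(rows, cols),
    )


def reconstruct(coeffs: CoefficientSet) -> GrayImage:
    """Inverse transform; output is trimmed to the original image shape.

    The result is tagged ``raw-float`` because mapped coefficients can
    reconstruct to arbitrary signed values.
    """
    approx = coeffs.approximation
    for lvl, triplet in enumerate(coeffs.details):
        if len(triplet) != 3:
            raise ValueError(f"detail level {lvl} is not a (H, V, D) triplet")
        if any(b.shape != triplet[0].shape for b in triplet):
            raise ValueError(f"detail level {lvl} has mismatched subband shapes")
    try:
        out = pywt.waverec2(
            [approx] + [tuple(lvl) for lvl in coeffs.details],
            coeffs.spec.family,
            mode=coeffs.spec.boundary,
        )
    except ValueError as exc:
        raise ValueError(f"inconsistent subband shapes: {exc}") from exc
    rows, cols = coeffs.original_shape
    if out.shape[0] < rows or out.shape[1] < cols:
        raise ValueError(
            f"reconstruction of shape {out.shape} cannot cover original {coeffs.original_shape}"
        )
    return GrayImage(out[:rows, :cols], value_domain="raw-float")
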