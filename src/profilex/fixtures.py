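"""Synthetic microscopy-like test images.

Real counterparts of the scenes the filters target (rock-like blob fields,
weak-light interiors, fluorescent spot fields, TEM nanoparticle fields,
near-infrared low-contrast scenes, nested ring structures) are not
distributable, so this module builds seeded stand-ins with the geometric
features that matter to profile extraction: closed contours, known object
counts, controlled intensity span. Every fixture is bit-reproducible from
``(kind, rows, cols, seed, density, contrast)``.

All fixtures are returned on the unit interval with min/max exactly
``lo``/``lo + contrast`` for the kind's base level ``lo``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import gaussian as _gaussian_blur

from .io import GrayImage

__all__ = ["FixtureSpec", "FIXTURE_KINDS", "make_fixture"]

FIXTURE_KINDS = (
    "blob-field",
    "weak-light-scene",
    "fluorescent-spots",
    "particle-field",
    "nir-scene",
    "nested-rings",
)

# (base intensity lo, default span, default object count) per kind
_KIND_DEFAULTS = {
    "blob-field": (0.10, 0.80, 12),
    "weak-light-scene": (0.01, 0.12, 3),
    "fluorescent-spots": (0.02, 0.90, 15),
    "particle-field": (0.20, 0.50, 40),
    "nir-scene": (0.35, 0.25, 3),
    "nested-rings": (0.00, 1.00, 4),
}


@dataclass(frozen=True)
class FixtureSpec:
    """What to synthesise.

    density : object count (blobs, spots, particles, rings); ``None`` picks
        the kind's default.
    contrast : the exact max - min intensity span of the output; ``None``
        picks the kind's default.
    """

    kind: str
    rows: int = 256
    cols: int = 256
    seed: int = 0
    density: int | None = None
    contrast: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {FIXTURE_KINDS}")
        if self.rows < 32 or self.cols < 32:
            raise ValueError("fixtures must be at least 32 x 32")

    def resolved(self) -> tuple[float, float, int]:
        lo, span, count = _KIND_DEFAULTS[self.kind]
        if self.contrast is not None:
            span = self.contrast
        if self.density is not None:
            count = self.density
        return lo, span, count


def make_fixture(spec: FixtureSpec) -> GrayImage:
    """Build the requested fixture, deterministic for a fixed spec."""
    rng = np.random.default_rng(spec.seed)
    lo, span, count = spec.resolved()
    builder = {
        "blob-field": _blob_field,
        "weak-light-scene": _weak_light_scene,
        "fluorescent-spots": _fluorescent_spots,
        "particle-field": _particle_field,
        "nir-scene": _nir_scene,
        "nested-rings": _nested_rings,
    }[spec.kind]
    base = builder(spec.rows, spec.cols, count, rng)
    return GrayImage(_rescale(base, lo, lo + span), value_domain="unit-interval")


def _rescale(arr: np.ndarray, lo: float, hi: float) -> np.ndarray:
    amin, amax = arr.min(), arr.max()
    if amax == amin:  # degenerate pattern; pin to lo
        return np.full_like(arr, lo)
    return lo + (arr - amin) * ((hi - lo) / (amax - amin))


def _grid(rows: int, cols: int) -> tuple[np.ndarray, np.ndarray]:
    return np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")


def _disc(canvas: np.ndarray, r0: float, c0: float, radius: float, value: float) -> None:
    rr, cc = _grid(*canvas.shape)
    mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    canvas[mask] = value


def _blob_field(rows: int, cols: int, count: int, rng) -> np.ndarray:
    """Rounded rock-like blobs of varied size on a dark ground."""
    img = np.zeros((rows, cols))
    rmax = max(6, min(rows, cols) // 12)
    for _ in range(count):
        _disc(
            img,
            rng.uniform(0, rows),
            rng.uniform(0, cols),
            rng.uniform(rmax / 2, rmax),
            rng.uniform(0.6, 1.0),
        )
    return _gaussian_blur(img, sigma=2.0, preserve_range=True)


def _weak_light_scene(rows: int, cols: int, count: int, rng) -> np.ndarray:
    """A dim indoor scene: large box-like objects barely above background."""
    img = np.zeros((rows, cols))
    # one dominant appliance-sized rectangle with a circular feature
    r0, c0 = rows // 5, cols // 5
    img[r0 : rows - r0, c0 : cols - c0] = 0.5
    _disc(img, rows / 2, cols / 2, min(rows, cols) / 6, 0.85)
    for _ in range(max(count - 1, 0)):  # smaller clutter
        h = int(rng.integers(rows // 16, rows // 6))
        w = int(rng.integers(cols // 16, cols // 6))
        r = int(rng.integers(0, rows - h))
        c = int(rng.integers(0, cols - w))
        img[r : r + h, c : c + w] += 0.3
    img = _gaussian_blur(img, sigma=1.5, preserve_range=True)
    return img + rng.normal(0.0, 0.02, img.shape)


def _fluorescent_spots(rows: int, cols: int, count: int, rng) -> np.ndarray:
    """Point-spread-like bright spots on a dark field."""
    rr, cc = _grid(rows, cols)
    img = np.zeros((rows, cols))
    for _ in range(count):
        r0 = rng.uniform(0, rows)
        c0 = rng.uniform(0, cols)
        sig = rng.uniform(2.0, 5.0)
        amp = rng.uniform(0.4, 1.0)
        img += amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sig**2))
    return img + rng.normal(0.0, 0.01, img.shape)


def _particle_field(rows: int, cols: int, count: int, rng) -> np.ndarray:
    """TEM-like field: small dark discs (3-8 px radius) on a bright ground."""
    img = np.ones((rows, cols))
    for _ in range(count):
        _disc(
            img,
            rng.uniform(0, rows),
            rng.uniform(0, cols),
            rng.uniform(3.0, 8.0),
            rng.uniform(0.0, 0.3),
        )
    img = _gaussian_blur(img, sigma=1.0, preserve_range=True)
    return img + rng.normal(0.0, 0.02, img.shape)


def _nir_scene(rows: int, cols: int, count: int, rng) -> np.ndarray:
    """Low-contrast hazy scene: smooth illumination plus faint objects."""
    rr, cc = _grid(rows, cols)
    img = 0.5 + 0.2 * np.sin(np.pi * rr / rows) * np.cos(np.pi * cc / cols)
    for _ in range(count):
        h = int(rng.integers(rows // 8, rows // 3))
        w = int(rng.integers(cols // 8, cols // 3))
        r = int(rng.integers(0, rows - h))
        c = int(rng.integers(0, cols - w))
        img[r : r + h, c : c + w] += rng.choice([-0.15, 0.15])
    img = _gaussian_blur(img, sigma=3.0, preserve_range=True)
    return img + rng.normal(0.0, 0.015, img.shape)


def _nested_rings(rows: int, cols: int, count: int, rng) -> np.ndarray:
    """Exactly ``count`` concentric closed annuli, 2 px thick."""
    rr, cc = _grid(rows, cols)
    radius = np.sqrt((rr - (rows - 1) / 2) ** 2 + (cc - (cols - 1) / 2) ** 2)
    rmax = min(rows, cols) / 2.0 - 2.0
    img = np.zeros((rows, cols))
    for k in range(1, count + 1):
        rk = k * rmax / (count + 1)
        img[np.abs(radius - rk) <= 1.0] = 1.0
    return img
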