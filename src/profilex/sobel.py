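"""Two-point diagonal Sobel-variant gradient and binary edge map.

The gradient here is the two-point diagonal difference form

    gx(x, y) = [f(x+1, y+1) - f(x-1, y+1)] / 2
    gy(x, y) = [f(x+1, y+1) - f(x+1, y-1)] / 2

with ``x`` indexing rows and ``y`` columns. Note this is *not* the
classical 3 x 3 Sobel kernel pair (which weights a 3 x 3 neighbourhood and
differences across the centre column/row); both partials here are sampled
one pixel off-centre along the other axis. It is kept in this exact form
because it is the baseline the filters are evaluated against; use
``skimage.filters.sobel`` if you want the classical operator. Border pixels,
where the stencil leaves the image, are set to zero.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu

from .io import GrayImage

__all__ = ["diagonal_sobel_gradient", "sobel_edge_map"]


def diagonal_sobel_gradient(img: GrayImage | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """The (gx, gy) diagonal-difference gradient fields, borders zeroed."""
    f = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=float)
    if f.shape[0] < 3 or f.shape[1] < 3:
        raise ValueError(f"image of shape {f.shape} too small; need at least 3 x 3")
    gx = np.zeros_like(f)
    gy = np.zeros_like(f)
    # interior: x in [1, rows-2], y in [1, cols-2]
    gx[1:-1, 1:-1] = (f[2:, 2:] - f[:-2, 2:]) / 2.0
    gy[1:-1, 1:-1] = (f[2:, 2:] - f[2:, :-2]) / 2.0
    return gx, gy


def sobel_edge_map(
    img: GrayImage | np.ndarray,
    threshold_policy: str = "otsu",
    threshold: float | None = None,
) -> GrayImage:
    """Binary {0, 1} edge map from the diagonal-difference gradient magnitude.

    ``threshold_policy`` is ``"otsu"`` (default) or ``"fixed"``; a fixed
    policy requires ``threshold``. A blank (constant-gradient-free) image
    yields an all-zero map.
    """
    gx, gy = diagonal_sobel_gradient(img)
    mag = np.hypot(gx, gy)
    if threshold_policy == "otsu":
        if mag.max() == mag.min():
            return GrayImage(np.zeros_like(mag), value_domain="raw-float")
        thr = threshold_otsu(mag)
    elif threshold_policy == "fixed":
        if threshold is None:
            raise ValueError("fixed threshold policy requires a threshold value")
        thr = threshold
    else:
        raise ValueError(f"unknown threshold policy {threshold_policy!r}")
    return GrayImage((mag > thr).astype(float), value_domain="raw-float")
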