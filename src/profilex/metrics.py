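"""Block-entropy and Michelson-contrast quality statistics.

Both statistics are computed on the *raw* (possibly signed) filter output,
never on a display-normalised copy — min–max normalisation would force the
Michelson contrast to 1 and destroy the information the metrics carry.

Measurement by entropy (ME): partition the image into non-overlapping
blocks (8 x 8 by default); per block i with minimum m1 and maximum m2,

    U_i = 20 * log10(m2 / m1)    if m1 > 0, else 0,

and ME is the mean of U_i over blocks. The 20x prefactor is the decibel
convention, so U_i is the block's dynamic range in dB. Blocks whose minimum
is <= 0 contribute zero (the ratio is undefined there); one consequence is
that ME of any binary {0, 1} image is exactly 0, since every block either
contains a 0 or is constant.

Michelson contrast (MC): (m3 - m4) / (m3 + m4) with m3/m4 the global
max/min. On non-negative images MC lies in [0, 1]; it exceeds 1 exactly
when the minimum is negative while m3 + m4 > 0, which is how signed filter
outputs can score contrasts above 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .io import GrayImage

__all__ = [
    "BlockSpec",
    "MetricReport",
    "UndefinedContrastError",
    "measurement_by_entropy",
    "michelson_contrast",
    "compute_metrics",
]


class UndefinedContrastError(ValueError):
    """Michelson contrast is undefined when max + min == 0."""


@dataclass(frozen=True)
class BlockSpec:
    """Block geometry of the entropy measure."""

    block_rows: int = 8
    block_cols: int = 8
    incomplete_edge_policy: str = "discard"

    def __post_init__(self) -> None:
        if self.block_rows < 1 or self.block_cols < 1:
            raise ValueError("block dimensions must be >= 1")
        if self.incomplete_edge_policy not in ("discard", "include"):
            raise ValueError(
                f"unknown edge policy {self.incomplete_edge_policy!r}"
            )


@dataclass(frozen=True)
class MetricReport:
    """ME and MC values plus block bookkeeping.

    ``n_blocks`` counts the blocks entering the ME average (its divisor n);
    ``n_blocks_skipped`` counts incomplete edge blocks discarded by the
    block policy.
    """

    me: float
    mc: float
    n_blocks: int
    n_blocks_skipped: int

    def to_dict(self) -> dict:
        return asdict(self)


def _as_array(img: GrayImage | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=float)


def _iter_blocks(arr: np.ndarray, spec: BlockSpec):
    rows, cols = arr.shape
    br, bc = spec.block_rows, spec.block_cols
    include = spec.incomplete_edge_policy == "include"
    r_stops = range(0, rows if include else rows - br + 1, br)
    c_stops = range(0, cols if include else cols - bc + 1, bc)
    for r in r_stops:
        for c in c_stops:
            yield arr[r : r + br, c : c + bc]


def measurement_by_entropy(
    img: GrayImage | np.ndarray, spec: BlockSpec = BlockSpec()
) -> float:
    """Mean per-block dynamic range in dB (see module docstring)."""
    report = compute_metrics(img, spec, want_mc=False)
    return report.me


def michelson_contrast(img: GrayImage | np.ndarray) -> float:
    """(max - min) / (max + min) over the finite pixels of the raw image."""
    arr = _as_array(img)
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise ValueError("image has no finite pixels")
    m3 = float(finite.max())
    m4 = float(finite.min())
    if m3 + m4 == 0:
        raise UndefinedContrastError(
            f"contrast undefined: max ({m3}) + min ({m4}) is zero"
        )
    return (m3 - m4) / (m3 + m4)


def compute_metrics(
    img: GrayImage | np.ndarray,
    spec: BlockSpec = BlockSpec(),
    want_mc: bool = True,
) -> MetricReport:
    """Both statistics plus block bookkeeping in one pass."""
    arr = _as_array(img)
    if arr.size == 0:
        raise ValueError("empty image")
    total = 0.0
    n_blocks = 0
    for block in _iter_blocks(arr, spec):
        n_blocks += 1
        m1 = block.min()
        m2 = block.max()
        if m1 <= 0:
            continue  # contributes U_i = 0
        total += 20.0 * np.log10(m2 / m1)
    if n_blocks == 0:
        raise ValueError(
            "image smaller than one block; use incomplete_edge_policy='include'"
        )
    rows, cols = arr.shape
    n_grid = math.ceil(rows / spec.block_rows) * math.ceil(cols / spec.block_cols)
    me = total / n_blocks
    mc = michelson_contrast(arr) if want_mc else float("nan")
    return MetricReport(
        me=me, mc=mc, n_blocks=n_blocks, n_blocks_skipped=n_grid - n_blocks
    )
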