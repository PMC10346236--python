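"""Seeded Gaussian degradation of unit-interval images.

The degradation protocol adds i.i.d. Gaussian noise with a *large mean*
(0.9 or 0.5) to an image on the [0, 1] scale and clips back to [0, 1].
A mean of 0.9 drives most pixels into saturation, leaving only faint
structure — the "very noisy" regime the coefficient filters are built for.
The pre-clip noise field is returned alongside so its sample moments can be
verified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GrayImage, to_unit_interval

__all__ = ["NoiseSpec", "add_gaussian_noise"]


@dataclass(frozen=True)
class NoiseSpec:
    """Mean/variance/seed of the additive Gaussian degradation.

    The variance default of 0.01 is the conventional default of common image
    degradation routines; the mean is the knob the protocol varies.
    """

    mean: float = 0.9
    variance: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError(f"variance must be >= 0, got {self.variance}")


def add_gaussian_noise(
    img: GrayImage, spec: NoiseSpec = NoiseSpec()
) -> tuple[GrayImage, np.ndarray]:
    """Corrupt a unit-interval image with seeded additive Gaussian noise.

    The image is first brought onto [0, 1] by its declared domain; the
    noisy result is ``clip(img + N(mean, variance), 0, 1)``. Returns the
    noisy image and the pre-clip noise field. Same spec, same output,
    bit for bit.
    """
    unit = to_unit_interval(img)
    rng = np.random.default_rng(spec.seed)
    noise_field = rng.normal(spec.mean, np.sqrt(spec.variance), size=unit.shape)
    noisy = np.clip(unit.pixels + noise_field, 0.0, 1.0)
    return GrayImage(noisy, value_domain="unit-interval"), noise_field
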