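# Methods

## The model

Both filters share one pipeline: gray conversion → (optional resize) →
2-D discrete wavelet transform → elementwise nonlinear map of the
coefficients → inverse transform. The nonlinear map is the whole method.
On the 0–255 intensity scale the transform produces large coefficients
wherever the scene is bright or smooth (the approximation subband) and
small signed coefficients at edges and texture (the detail subbands). The
maps are designed so that large coefficients either saturate or leave the
functions' domains, while small ones are amplified enormously; after
sanitisation and reconstruction what survives is the edge morphology — the
"profile" — of the objects.

This is also why degrading an image with *high-mean* (0.9) Gaussian noise
can improve extraction: the offset pushes smooth-region intensities into
saturation (clipping at 1.0 on the unit interval), flattening the
approximation band into exactly the regime the maps null out, while edges
keep nonzero detail coefficients.

### Scale convention

The maps act on wavelet coefficients of pixel values *as read from 8-bit
files* (0–255). This matters numerically: the Exp rate default d = 0.0078
(≈ 2/256) and the Hypot map's sinh/power stages are calibrated to that
scale. Images synthesised or degraded on [0, 1] are brought up with
`to_display_scale` (a pure ×255, not a min–max stretch) before filtering.
Running the Hypot map on unit-scale data keeps every coefficient in the
smooth regime and its output min strictly positive (MC < 1) — a sign the
scale convention was skipped.

### Exp map

`x = (a · exp(d·u − b) / g)^nn`. The typeset source of this formula is
ambiguous about whether *b* and *g* sit inside the exponent; this grouping
(b inside, g as a plain divisor) keeps every constant meaningful and is
documented here so it can be revisited. Non-integer `nn` uses signed-power
semantics `sign(x)·|x|^nn` to stay real; `nn = 0` returns all ones;
non-finite results sanitise to 0. `g = 0` is rejected.

### Hypot map

The six stages listed in the README, evaluated with NumPy ufuncs under
`errstate(ignore)`; every stage is sanitised (non-finite → 0, configurable
via `SanitizePolicy`) before feeding the next. Consequences worth knowing:

* `a22` even (default 10) makes every surviving u₆ non-negative.
* u₃ = 0 or overflow in the power stage zeroes the coefficient — the
  dominant mechanism on 8-bit-scale smooth regions, where sinh(u) is
  astronomically large and `(u₅/u₃)^a22` overflows.
* `a11` is stored on `HypotParams` but enters no equation: the map's
  published constant list includes it while the equations skip from a₁₀ to
  a₁₂. It is kept so configs listing all 22 constants round-trip.

### Zero floor and the MC = 1 invariant

The Hypot reconstruction is floored at 0 (the Exp output is *not*). With
the approximation band largely nulled and huge non-negative detail
coefficients, the inverse transform necessarily swings negative somewhere;
the floor pins the raw minimum at exactly 0, so MC = (max−0)/(max+0) = 1
identically — across the entire published a₁₈/a₂₁/a₂₂ sweep ranges. The
Exp map preserves sign information, so its raw minimum may be positive
(MC < 1) or negative (MC > 1) depending on the scene.

## Wavelet choice

The method never pins a mother wavelet; the published candidates span Haar
through Coiflets. Default: Haar, 1 level, symmetric extension — the
simplest member of the candidate set, with subband geometry trivially
consistent and an exactly orthogonal transform. Family, level and boundary
are all exposed on `WaveletSpec`; round-trip identity to 1e−8 is enforced
for all of them. Odd-sized images are boundary-extended by PyWavelets and
the reconstruction is trimmed back to the original shape.

The subband scope of the map defaults to `all` (approximation + details),
with `details-only` / `approx-only` exposed, since the method speaks only
of "the coefficient value u(m,n)" with no restriction.

## Quality statistics

* **ME**: 8 × 8 non-overlapping blocks, row-major, incomplete edge blocks
  discarded by default (`include` keeps them as partial blocks). The log is
  base 10 — the 20× prefactor is the decibel convention. Blocks whose
  minimum is ≤ 0 contribute Uᵢ = 0 rather than ±∞; this totality convention
  is what makes ME of any binary edge map exactly 0. The summation bound
  and the divisor of the block average are treated as the same count.
* **MC**: global max/min of the *raw* output. Computing it on
  display-normalised data would force MC = 1 always; the raw convention is
  what lets MC exceed 1 (negative minimum) and carry information.
* Published block geometry and noise variance are unstated, so absolute ME
  values of any external tables are not reproducible bit-for-bit; the
  statistics here are exact for the conventions stated above, which the
  brute-force oracle tests pin down.

## Baseline and degradation

The Sobel-variant gradient is implemented exactly as printed in its source
form — two-point diagonal differences, *not* the classical 3 × 3 kernels;
`skimage.filters.sobel` is the classical alternative if wanted. Borders
where the stencil leaves the image are zero. Binarization uses Otsu by
default (no threshold is published; the reference outputs look binary).

Degradation: i.i.d. `N(mean, variance)` added on the unit interval, then
clipped to [0, 1]. Mean is the protocol's knob (0.9 "very noisy", 0.5
moderate); variance defaults to 0.01, the common default of standard
degradation routines, as no value is published. The pre-clip noise field is
returned so sample moments can be verified (tested at 4σ on a 1440 × 2560
field).

## Synthetic fixtures

`make_fixture` emulates the target scenes: `blob-field` (rounded rock-like
blobs), `weak-light-scene` (box-like objects barely above black, max
intensity ≤ 0.13 by default), `fluorescent-spots` (Gaussian point spreads),
`particle-field` (dark 3–8 px discs on a bright ground, nanoparticles at
TEM scale), `nir-scene` (smooth illumination, faint rectangles),
`nested-rings` (exactly *n* concentric 2 px annuli). All are deterministic
functions of `(kind, rows, cols, seed, density, contrast)`; `contrast` is
the exact output intensity span. They reproduce the *geometry* that matters
to profile extraction (closed contours, known object counts, controlled
span) but none of the physics of real acquisition — no Poisson shot noise,
no detector PSF beyond a Gaussian blur, no TEM contrast-transfer effects —
so passing tests demonstrate the pipeline's numerical behaviour, not
field-ready performance on real micrographs.

Default problem sizes: 256 × 256 fixtures for end-to-end runs and the
acceptance script, 16 × 16 – 64 × 64 arrays for oracle comparisons, one
full 1440 × 2560 field for the noise-moment and geometry checks — small
enough to iterate on quickly, large enough that the block statistics and
sample moments are meaningful.

## Known limitations

* Filter constants must be tuned per image class; no adaptive selection.
* Absolute ME values are convention-dependent (block size, log base,
  m₁ ≤ 0 handling) and not comparable across implementations.
* Gray output only; 16-bit microscopy formats beyond plain TIFF are out of
  scope.
* The Hypot map's interesting regime relies on double-precision overflow
  semantics; running it in float32 would change where coefficients null
  out.
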