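"""High-mean noise can help: filter a particle field with and without it.

Counter-intuitively, on clean TEM-like particle fields the coefficient
filters barely respond, while after degradation with mean-0.9 Gaussian
noise the particle outlines emerge clearly. The added offset pushes the
wavelet approximation coefficients into the regime where the nonlinear map
saturates and sanitises them to zero, leaving the detail (edge)
coefficients to dominate the reconstruction. This script saves the four
outputs side by side so the effect can be inspected.
"""

from pathlib import Path

from profilex import (
    FixtureSpec,
    NoiseSpec,
    add_gaussian_noise,
    apply_filter,
    compute_metrics,
    make_fixture,
    normalize_for_display,
    save_image,
    to_display_scale,
)

out = Path("demo-output")
out.mkdir(exist_ok=True)

clean = make_fixture(FixtureSpec("particle-field", 256, 256, seed=3))
degraded, _ = add_gaussian_noise(clean, NoiseSpec(mean=0.9, variance=0.01, seed=3))

for tag, img in (("clean", clean), ("degraded", degraded)):
    work = to_display_scale(img)
    for kind in ("exp", "hypot"):
        result = apply_filter(work, kind)
        report = compute_metrics(result)
        name = f"{tag}_{kind}.png"
        save_image(normalize_for_display(result), out / name)
        print(f"{name:22s} ME={report.me:10.4f}  MC={report.mc:.4f}")

print(f"\nCompare degraded_*.png with clean_*.png in {out}/: the particle "
      "outlines are far more legible after degradation.")
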