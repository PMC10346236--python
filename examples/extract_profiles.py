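"""Extract object profiles from a noisy blob field with both filters.

Builds a synthetic rock-like blob scene, degrades it with mean-0.9 Gaussian
noise, runs the Exp and Hypot wavelet-coefficient filters, and prints the
block-entropy (ME) and Michelson-contrast (MC) scores of each raw output.
ME is the mean per-block dynamic range in decibels (higher = more local
structure retained); MC is (max-min)/(max+min) of the raw output — exactly
1 whenever the minimum is pinned at zero, above 1 when the raw minimum is
negative.
"""

from pathlib import Path

from profilex import (
    ExpParams,
    FixtureSpec,
    HypotParams,
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

clean = make_fixture(FixtureSpec("blob-field", 256, 256, seed=1))
noisy, _ = add_gaussian_noise(clean, NoiseSpec(mean=0.9, variance=0.01, seed=1))
work = to_display_scale(noisy)  # the filters transform 0-255 pixel values
save_image(normalize_for_display(work), out / "degraded_input.png")

for kind, params in (("exp", ExpParams()), ("hypot", HypotParams())):
    result = apply_filter(work, kind, params)
    report = compute_metrics(result)
    save_image(normalize_for_display(result), out / f"profile_{kind}.png")
    print(f"{kind:5s}  ME={report.me:10.4f}  MC={report.mc:.4f}  "
          f"raw range [{result.pixels.min():.3g}, {result.pixels.max():.3g}]")

print(f"\nImages written to {out}/ — the filter outputs trace the blob "
      "boundaries that are invisible in the degraded input.")
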