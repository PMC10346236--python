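"""Sweep the key filter constants and tabulate ME/MC per setting.

Re-runs the Exp filter over its outer power nn and the Hypot filter over
its a22 exponent on one degraded scene, printing a (value, ME, MC) table.
The ME column moves nonlinearly with the parameter — the knob genuinely
reshapes the output — while the MC column is frozen at 1 for the Hypot
filter (its raw minimum is pinned to zero by the sanitise-and-floor
conventions, whatever the constants).
"""

from profilex import (
    ExpParams,
    FixtureSpec,
    GrayImage,
    HypotParams,
    NoiseSpec,
    add_gaussian_noise,
    make_fixture,
    sweep,
)

clean = make_fixture(FixtureSpec("blob-field", 256, 256, seed=1))
noisy, _ = add_gaussian_noise(clean, NoiseSpec(mean=0.9, variance=0.01, seed=1))
work = GrayImage(noisy.pixels * 255.0, value_domain="display-8bit")

for kind, base, name, values in (
    ("exp", ExpParams(), "nn", [1, 2, 3, 6, 10, 44, 50, 60, 90]),
    ("hypot", HypotParams(), "a22", [10, 20, 30, 180, 220, 400]),
):
    print(f"\n{kind} filter, sweeping {name}:")
    print(f"{name:>8s} {'ME':>12s} {'MC':>8s}")
    for value, _, report in sweep(work, kind, base, name, values):
        print(f"{value:8g} {report.me:12.4f} {report.mc:8.4f}")
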