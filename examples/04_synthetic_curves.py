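"""Synthetic mass-loss curves and worst-case window extraction.

Generates the three supported degradation shapes and reports each curve's
worst fractional mass loss over a sliding 7-day window (DR_max) — the
quantity that drives degradation-informed exposure refinement.
"""

from degradose import FixtureSpec, generate_fixture_curve, max_window_loss

for shape in ("linear", "logistic", "biphasic_late_acceleration"):
    spec = FixtureSpec(curve_shape=shape, seed=42)
    curve = generate_fixture_curve(spec)
    dr7 = max_window_loss(curve, 7.0)
    first_week = float(curve.interpolate(7.0))
    print(
        f"{shape:<30} loss in first 7 d: {first_week:6.4f}   "
        f"worst 7-d window (DR_max): {dr7:6.4f}"
    )

print(
    "\nFor the bulk-erosion (logistic) shape the worst window sits mid-curve; "
    "for the biphasic shape it sits in the late acceleration phase — refining "
    "only early windows would miss it, which is why the extractor slides the "
    "window over the whole observed range."
)
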