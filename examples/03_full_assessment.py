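"""The full screen-then-refine assessment with degradation-informed refinement.

Margins of safety (tolerable intake / exposure dose) are screened per
constituent and window; the one cell below 1 — glycolic acid, acute, driven
by the bolus assumption of the default release model — is refined with the
observed worst 7-day mass loss of the glycolide copolymer (2%), compressed
conservatively into a 24-hour bolus.
"""

from degradose import SCENARIOS, assess_device
from degradose.case_study import load_case_study
from degradose.reporting import format_mos

bom, _, hazards, curves = load_case_study()
report = assess_device(bom, hazards, curves)

print("Margins of safety (refinement triggers marked *):")
print(f"{'constituent':<26}" + "".join(f"{s.window_text:>12}" for s in SCENARIOS))
for rec in report.mos_records:
    cells = ""
    for s in SCENARIOS:
        mark = "*" if rec.flags[s].value == "refine_needed" else ""
        cells += f"{format_mos(rec.mos[s]) + mark:>12}"
    print(f"{rec.constituent_name:<26}{cells}")

print()
for line in report.narratives:
    print(line)
print(
    "\nA margin below 1 means the default (complete-release) exposure exceeds "
    "the tolerable intake; the refined margin of 25 shows the default acute "
    "model overestimated the first-day release fifty-fold."
)
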