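"""Duration-stratified exposure doses and tolerable intakes.

Each per-patient total quantity is spread over the minimum duration of the
four exposure windows (1, 2, 31, 366 days) at a 60 kg body weight to give
estimated exposure doses; each point of departure is divided by its
per-window modifying factor to give tolerable intakes. Both are in µg/kg/day.
"""

from degradose import SCENARIOS, decompose_device, exposure_record, tolerable_intake
from degradose.case_study import load_case_study
from degradose.reporting import format_sig3

bom, _, hazards, _ = load_case_study()

print("Estimated exposure doses (µg/kg/day), 3 significant figures:")
print(f"{'constituent':<26}" + "".join(f"{s.window_text:>12}" for s in SCENARIOS))
for q in decompose_device(bom):
    rec = exposure_record(q)
    cells = "".join(f"{format_sig3(rec.eed_ug_per_kg_day[s]):>12}" for s in SCENARIOS)
    print(f"{q.constituent_name:<26}{cells}")

print("\nTolerable intakes (µg/kg/day):")
print(f"{'constituent':<26}" + "".join(f"{s.window_text:>12}" for s in SCENARIOS))
for cas, hrec in hazards.records.items():
    ti = tolerable_intake(hrec.pod, hrec.ufs_by_scenario)
    cells = "".join(f"{format_sig3(ti.ti_ug_per_kg_day[s]):>12}" for s in SCENARIOS)
    print(f"{hrec.pod.constituent_name:<26}{cells}")

print(
    "\nA dose above its same-window tolerable intake (margin of safety < 1) "
    "flags the constituent for exposure refinement."
)
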