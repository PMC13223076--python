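"""Decompose a device bill of materials into worst-case monomer quantities.

The vessel-closure device carries 100 mg of a 75:25 glycolide-lactide suture,
30 mg of a 50:25:25 glycolide-caprolactone-trimethylene carbonate copolymer
and 5 mg of polyethylene glycol; a scaling factor of 2 covers bilateral use.
Assuming complete hydrolysis, each polymer mass is split by component weight
fraction and summed by hydrolysis-product CAS — note glycolic acid collects
contributions from two different polymers.
"""

from degradose import decompose_device
from degradose.case_study import load_case_study

bom, _, _, _ = load_case_study()
print(f"{bom.device_name} (scaling factor {bom.scaling_factor})\n")
print(f"{'constituent':<26}{'CAS RN':<12}{'mg/device':>10}{'mg/patient':>12}  sources")
for q in decompose_device(bom):
    print(
        f"{q.constituent_name:<26}{q.constituent_cas:<12}"
        f"{q.tq_comp_mg:>10.1f}{q.tq_max_mg:>12.1f}  {', '.join(q.source_polymers)}"
    )
print(
    "\nmg/device is the worst-case total quantity of each hydrolysis product "
    "per device (TQ_comp); mg/patient applies the scaling factor (TQ_max)."
)
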