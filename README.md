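# degradose

Compositional profiling and degradation-informed toxicological risk
assessment (TRA) for biodegradable medical devices.

Implantable devices built from biodegradable polymers (PLGA sutures,
glycolide–caprolactone–trimethylene carbonate anchors, PEG sealants, …) are
awkward subjects for the exhaustive extraction studies that chemical
characterization standards expect: the materials are designed to fall apart,
and they tolerate aggressive solvents poorly. `degradose` implements the
screening alternative used by device toxicologists: treat the device's
polymers as if they hydrolyze completely into their monomeric constituents,
bound the systemic exposure from those worst-case quantities, and only where
the resulting margins of safety are low, refine the exposure with empirical
degradation (mass-loss) kinetics. It is written for toxicologists and
regulatory scientists assembling ISO 10993-17–style systemic risk
assessments.

## The model

For each terminal hydrolysis product (aggregated by CAS RN across polymers):

- **Total quantity.** TQ_comp = Σ (polymer mass × component weight
  fraction); TQ_max = TQ_comp × SF, where SF is a patient scaling factor
  (e.g. 2 for bilateral use).
- **Estimated exposure dose** (assumed-release model, ISO 10993-17:2023):
  EED_max = TQ_max / BW_L / R_d in µg/kg/day, with BW_L = 60 kg and
  R_d = 1, 2, 31, 366 days for the acute (≤1 d), subacute (2–30 d),
  subchronic (31–365 d) and chronic (≥366 d) windows.
- **Tolerable intake.** TI = POD / MF, where the POD is a point of
  departure (typically an oral NOAEL, mg/kg/day) and MF is the product of
  uncertainty factors (interindividual, interspecies, duration, data
  quality/applicability).
- **Margin of safety.** MOS = TI / EED_max, per window, from unrounded
  values. MOS < 1 triggers refinement; margins between 1 and 10 are flagged
  for review.
- **Refinement.** DR_max, the worst fractional mass loss over a sliding
  window (default 7 days) of an in vitro / in vivo mass-loss curve, replaces
  the bolus assumption: EED_max,rk = TQ_max × DR_max / BW_L, i.e. the worst
  week's release modeled conservatively as a 24-h bolus.

## Worked example

The shipped case study is a biodegradable vessel closure system: 100 mg of a
75:25 glycolide-lactide suture, 30 mg of a 50:25:25
glycolide-caprolactone-trimethylene carbonate copolymer, 5 mg of PEG, SF = 2.

```python
from degradose import assess_device
from degradose.case_study import load_case_study

bom, registry, hazards, curves = load_case_study()
report = assess_device(bom, hazards, curves)
```

`python examples/03_full_assessment.py` prints:

```
Margins of safety (refinement triggers marked *):
constituent                       ≤1 d    2 d–30 d  31 d–365 d      ≥366 d
Glycolic acid                     0.5*         1.0          16          46
Lactic acid                        3.0         6.0          93         275
ε-Caprolactone                      10          20         310         366
Trimethylene carbonate              10          20         310       3,660
1,2-Ethanediol                     9.0          18         279       1,647

Glycolic acid: acute MOS 0.5 < 1 triggered refinement; DR_max(7 d) = 0.02
from in_vivo data gives refined EED 60 ug/kg/day and refined MOS 25
```

Every margin is a tolerable intake divided by an exposure dose. The single
starred cell — glycolic acid in the acute window — is the bolus artifact of
the default release model: 180 mg of glycolic-acid equivalents "released" in
one day would exceed the acute tolerable intake two-fold. The observed
degradation kinetics (2% mass loss in the worst 7-day stretch, compressed
into a 24-h bolus) give a refined acute dose of 60 µg/kg/day and a
comfortable margin of 25.

The other examples show the decomposition table (`01`), the exposure and
tolerable-intake tables (`02`), and synthetic degradation-curve generation
with worst-window extraction (`04`). A thin CLI wraps the same stages:

```sh
degradose assess --bom bom.yaml --registry polymers.yaml \
    --hazards hazards.yaml --curves curves/ -o report.md
```

`assess` exits nonzero while any margin below 1 remains unresolved, so it
can gate automated pipelines.

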