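# Methods

## Scope and model

`degradose` performs screening-level systemic toxicological risk assessment
for devices whose exposure is dominated by the hydrolytic degradation of
biodegradable polymers. The chain is:

1. **Compositional decomposition.** Each polymer in the bill of materials is
   split into monomeric constituents by component weight fraction, under the
   worst-case assumption of complete hydrolysis to terminal monomeric
   products. Monomers are taken as the toxicologically governing species
   (smaller, more membrane-permeant, more reactive than their oligomers);
   oligomer-specific hazards are handled as annotation fields
   (`endpoint_note`, `surrogate_of`, `citation`) on the hazard records, not
   modeled. Quantities are aggregated across polymers by hydrolysis-product
   CAS RN — names are display-only. The per-patient quantity applies an
   integer scaling factor for multi-device use.
2. **Assumed-release exposure.** EED_max = TQ_max × 1000 / (BW_L × R_d)
   µg/kg/day with fixed R_d ∈ {1, 2, 31, 366} days for the four exposure
   windows and BW_L defaulting to 60 kg (conservative unisex adult).
3. **Tolerable intake.** TI = POD × 1000 / MF µg/kg/day; MF is the product
   of four uncertainty factors, all ≥ 1. A POD from a study of equal or
   longer duration than the protected window is used directly; protecting a
   longer window requires a duration factor > 1.
4. **Screening.** MOS = TI / EED from unrounded values. Flags: MOS < 1 →
   refinement needed; 1 ≤ MOS < 10 → low-margin review (the boundary MOS = 1
   falls in the review band); otherwise acceptable. The review-band upper
   bound of 10 is this package's choice of a conventional screening margin
   and is configurable; the trigger at 1 is not.
5. **Refinement.** For a flagged cell with degradation data, the worst
   fractional mass loss over a sliding window (DR_max) bounds the release:
   EED = TQ_max × DR_max × 1000 / (BW_L × R_d). For the acute window
   (R_d = 1) this is the 24-h bolus model; for longer windows the window
   loss is spread over that window's R_d. Refinement is exposure-side only;
   tolerable intakes are never refined. A refined dose can never exceed the
   assumed-release dose (DR_max ≤ 1); a guard retains the default with a
   warning if numerical inputs ever violate that.

## Composition ratios: mass vs molar basis

Printed copolymer ratios such as "75:25 PLGA" are treated as weight
fractions by default (`ratio_basis: mass`), which is how the shipped
case-study arithmetic reconciles (75 mg of glycolide equivalents from 100 mg
of 75:25 material). A molar basis is fully supported: mole fractions rᵢ are
converted with repeat-unit masses Mᵢ as rᵢMᵢ / Σ rⱼMⱼ, and every component
must then carry `repeat_unit_mass`.

By default the mass of each hydrolysis product is equated with the mass of
its polymer component ("water correction" off), so decomposition conserves
polymer mass exactly. This understates product mass slightly — hydrolysis
adds water — and the optional correction multiplies each component by
hydrolysis_product_mass × units_per_repeat / repeat_unit_mass (≥ 1 for
ester/ring opening, e.g. 2 × 76.05 / 116.07 ≈ 1.31 for glycolide →
glycolic acid). The default is off because the conventional screening
arithmetic, and the shipped case study, equate the two; turning it on makes
the screen slightly more conservative.

## Sliding-window mass loss

Mass-loss curves are piecewise-linear interpolations of (t, cumulative
fraction lost) samples, validated strictly increasing in time and
non-decreasing in fraction within [0, 1]. Linear interpolation is the
simplest monotone-preserving choice. DR_max maximises F(t+w) − F(t) over
all admissible t; because that difference is piecewise linear in t, the
implementation evaluates it exactly at the interpolation knots and the
knots shifted back by w, and the tests check it against a brute-force dense
grid to 1e-6. The window slides over the whole observed range rather than
anchoring at t = 0, so late-phase acceleration (autocatalysis, bulk-erosion
collapse) is caught. A window longer than the observed range is an error
instructing the caller to extend the data, never silently extrapolated.
When several curves exist for one constituent (in vitro and in vivo), the
one with the largest DR_max governs — in practice usually the in vivo
curve. When replicate curves are supplied the maximum, not the mean, is
taken, and the provenance note in the refined record says so.

## The shipped case study

The packaged inputs describe a biodegradable vessel closure system
(PLGA 75:25 suture 100 mg; GA-CL-TMC 50:25:25 copolymer 30 mg; PEG 5 mg;
scaling factor 2) with hazard records for the five terminal hydrolysis
products. PODs are oral NOAELs (150, 500, 150, 1000, 1000 mg/kg/day); the
caprolactone POD is γ-caprolactone read-across and the trimethylene
carbonate POD belongs to its hydrolysis/metabolic product 1,3-propanediol —
both disclosed via `surrogate_of`. Source dossiers report modifying factors
as products (100–4000) plus the two conventional factors of 10; the
unreported residual (duration × quality) is stored as a single combined
factor MF/100 in the `uf_duration` slot rather than inventing a split, and
reports disclose this.

The single mass-loss curve is a **synthetic** reconstruction (so labelled in
filename and header) spanning 0–7 days with linear loss to exactly 2%, the
worst first-week in vivo loss reported for the glycolide copolymer; the
underlying replicate curves are not public. It is deliberately not extended
past day 7: the 2% figure is a first-week observation, and any longer curve
consistent with the material's later bulk-erosion phase would have a steeper
mid-curve 7-day window, which would change the refined acute dose the
reconstruction is meant to encode.

## Synthetic curve generator

`generate_fixture_curve` emulates three degradation regimes: constant-rate
(linear), bulk erosion (logistic, defaults midpoint 35 d, plateau 0.9 at
180 d, steepness 0.15 /d — chosen so the first week loses under 2.5%,
mimicking a slow-starting glycolide copolymer), and biphasic late
acceleration (a slow linear phase carrying 10% of the plateau plus a steep
sigmoid centred at 80% of the duration). Optional Gaussian noise is applied
per sample, then monotonicity is restored by a running maximum and values
are clamped to [0, 1]; generation is deterministic for a fixed seed. These
synthetic curves exercise the window extractor and refinement logic; they do
not model autocatalysis mechanistically, sample-to-sample correlation of
real gravimetric data, or explant-handling artifacts, so passing tests
demonstrate correctness of the exposure arithmetic on valid curves, not
predictive accuracy for any particular polymer.

## Numerical and display conventions

All screening and refinement comparisons use unrounded doubles. Display
rounding (the `regulatory` rounding profile) is applied only when rendering:
doses to 3 significant figures, margins to one decimal below 10 and to
half-up integers at and above 10, thousands separators in rendered text
only. Half-up rounding is guarded with a 1e-12 relative nudge so a value
whose exact rational form sits on a .5 boundary but lands a few ulps low in
floating point (e.g. 1500/(180000/1860) = 15.5 exactly) still rounds up;
the nudge cannot move any digit of a non-boundary value. Margins are always
recomputed from unrounded TI and EED rather than transcribed from any
tabulation, so a rendered margin can legitimately differ from the quotient
of the two rendered numbers beside it. Zero exposure yields "NA" (not
applicable), never an infinite margin. Machine-readable CSV output is
full-precision, comma-separated, UTF-8, '.' decimal separator.

## Known limitations

- Systemic exposure only: no local/tissue tolerance, sensitization,
  irritation or genotoxicity triage.
- Degradation products only: manufacturing residues, additives and
  extractables/leachables need complementary chemistry.
- No mechanistic erosion modeling or in vivo pharmacokinetics; the mass-loss
  curve is used purely as a release-rate bound.
- Hazard data (PODs, factors, read-across choices) are expert inputs; the
  package validates and propagates them but performs no literature
  retrieval or POD selection.
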