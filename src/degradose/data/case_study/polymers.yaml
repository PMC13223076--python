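# Polymer registry for the biodegradable vessel-closure case study.
# Monomer CAS numbers follow the monomer/hydrolysis-product convention of
# compositional profiling (the acid form of each cyclic ester).
# Composition ratios are weight fractions (ratio_basis: mass).
monomers:
  - name: glycolide
    cas_rn: "79-14-1"
    hydrolysis_product_name: Glycolic acid
    hydrolysis_product_cas: "79-14-1"
    repeat_unit_mass: 116.07
    hydrolysis_product_mass: 76.05
    hydrolysis_units_per_repeat: 2
  - name: lactide
    cas_rn: "50-21-5"
    hydrolysis_product_name: Lactic acid
    hydrolysis_product_cas: "50-21-5"
    repeat_unit_mass: 144.13
    hydrolysis_product_mass: 90.08
    hydrolysis_units_per_repeat: 2
  - name: caprolactone
    cas_rn: "502-44-3"
    hydrolysis_product_name: "ε-Caprolactone"
    hydrolysis_product_cas: "502-44-3"
  - name: trimethylene carbonate
    cas_rn: "2453-03-4"
    hydrolysis_product_name: Trimethylene carbonate
    hydrolysis_product_cas: "2453-03-4"
  - name: ethylene oxide unit
    cas_rn: "107-21-1"
    hydrolysis_product_name: "1,2-Ethanediol"
    hydrolysis_product_cas: "107-21-1"
    repeat_unit_mass: 44.05
    hydrolysis_product_mass: 62.07
polymers:
  - name: "PLGA 75:25"
    cas_rn: "26780-50-7"
    ratio_basis: mass
    components:
      - monomer: glycolide
        ratio: 0.75
      - monomer: lactide
        ratio: 0.25
  - name: "GA-CL-TMC 50:25:25"
    ratio_basis: mass
    components:
      - monomer: glycolide
        ratio: 0.50
      - monomer: caprolactone
        ratio: 0.25
      - monomer: trimethylene carbonate
        ratio: 0.25
  - name: PEG
    ratio_basis: mass
    components:
      - monomer: ethylene oxide unit
        ratio: 1.0
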