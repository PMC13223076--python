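# Hazard database for the vessel-closure case study: per-constituent points
# of departure (oral NOAELs, mg/kg/day) and modifying factors per exposure
# window (acute / subacute / subchronic / chronic). Modifying factors are the
# product of all applicable uncertainty factors: 10 (interindividual) x 10
# (animal-to-human) x a residual for duration extrapolation, read-across and
# data quality.
records:
  - constituent_cas: "107-21-1"
    constituent_name: "1,2-Ethanediol"
    pod_mg_per_kg_day: 150
    study_duration_class: chronic
    endpoint_note: chronic oral NOAEL (OECD 452, Wistar rats)
    citation: OECD 452 chronic oral study
    mf: {acute: 100, subacute: 100, subchronic: 100, chronic: 200}
  - constituent_cas: "50-21-5"
    constituent_name: Lactic acid
    pod_mg_per_kg_day: 500
    study_duration_class: subchronic
    endpoint_note: subchronic oral NOAEL (OECD SIDS)
    citation: OECD SIDS dossier
    mf: {acute: 200, subacute: 200, subchronic: 200, chronic: 800}
  - constituent_cas: "79-14-1"
    constituent_name: Glycolic acid
    pod_mg_per_kg_day: 150
    study_duration_class: subchronic
    endpoint_note: subchronic oral NOAEL (OECD TG 408)
    citation: OECD TG 408 study
    mf: {acute: 100, subacute: 100, subchronic: 100, chronic: 400}
  - constituent_cas: "502-44-3"
    constituent_name: Caprolactone
    pod_mg_per_kg_day: 1000
    study_duration_class: subacute
    endpoint_note: "subacute oral NOAEL for γ-caprolactone (OECD 407)"
    surrogate_of: "γ-caprolactone (read-across)"
    citation: OECD 407 study
    mf: {acute: 400, subacute: 400, subchronic: 400, chronic: 4000}
  - constituent_cas: "2453-03-4"
    constituent_name: Trimethylene carbonate
    pod_mg_per_kg_day: 1000
    study_duration_class: subchronic
    endpoint_note: >-
      subchronic oral NOAEL for 1,3-propanediol, the predominant metabolic and
      hydrolysis product of trimethylene carbonate (OECD TG 408, SD rats;
      highest dose tested); supported by longer-duration studies on cyclic
      carbonate analogs, so no additional duration factor for the chronic
      window
    surrogate_of: "1,3-Propanediol (CAS 504-63-2)"
    citation: OECD TG 408 study
    mf: {acute: 400, subacute: 400, subchronic: 400, chronic: 400}
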