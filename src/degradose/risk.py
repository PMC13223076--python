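"""Margin-of-safety screening and the full screen-then-refine assessment.

The margin of safety for each constituent and exposure window is

    MOS = TI / EED_max

computed from unrounded tolerable intakes and exposure doses. MOS < 1 flags
potential risk and triggers refinement of the exposure assumption with
degradation-kinetics data; margins modestly above 1 (below a configurable
review band, default 10) are flagged for additional scrutiny.

A full assessment runs decompose -> EED -> TI -> MOS -> screen, applies
curve-based refinement to each low-margin cell with available data, and
records an audit chain so every reported value can be recomputed from its
inputs.
"""

from __future__ import annotations

from enum import Enum

from pydantic import BaseModel, Field

from .composition import ConstituentQuantity, DeviceBOM, decompose_device
from .config import AssessmentConfig
from .errors import ConfigurationError
from .exposure import (
    SCENARIOS,
    BodyWeightAssumption,
    ExposureRecord,
    MassLossCurve,
    Scenario,
    exposure_record,
    max_window_loss,
    refine_exposure,
    select_worst_case_curve,
)
from .hazard import HazardDatabase, TIRecord, tolerable_intake


class ScreenFlag(str, Enum):
    acceptable = "acceptable"
    refine_needed = "refine_needed"
    low_margin_review = "low_margin_review"


class MOSRecord(BaseModel):
    """Margins of safety for one constituent across the four windows.

    ``mos`` values are unrounded; ``None`` marks a cell with no exposure
    (EED = 0), reported as "not applicable" rather than infinity.
    ``refined_mos`` holds degradation-informed recomputations for cells that
    screened low.
    """

    constituent_cas: str
    constituent_name: str = ""
    mos: dict[Scenario, float | None]
    flags: dict[Scenario, ScreenFlag] = Field(default_factory=dict)
    refined_mos: dict[Scenario, float] = Field(default_factory=dict)


class AuditEntry(BaseModel):
    """One computed value with the formula and inputs that produced it.

    ``formula`` is a key understood by :func:`recompute_audit_entry`, so the
    chain is mechanically verifiable.
    """

    quantity: str
    formula: str
    inputs: dict[str, float]
    value: float

    model_config = {"frozen": True}


_FORMULAS = {
    "tq_max = tq_comp * sf": lambda i: i["tq_comp"] * i["sf"],
    "eed = tq_max * 1000 / (bw * rd)": lambda i: i["tq_max"] * 1000.0 / (i["bw"] * i["rd"]),
    "ti = pod * 1000 / mf": lambda i: i["pod"] * 1000.0 / i["mf"],
    "mos = ti / eed": lambda i: i["ti"] / i["eed"],
    "eed_rk = tq_max * dr_max * 1000 / (bw * rd)": lambda i: i["tq_max"]
    * i["dr_max"]
    * 1000.0
    / (i["bw"] * i["rd"]),
}


def recompute_audit_entry(entry: AuditEntry) -> float:
    """Re-evaluate an audit entry's formula from its recorded inputs."""
    try:
        fn = _FORMULAS[entry.formula]
    except KeyError:
        raise ConfigurationError(f"unknown audit formula {entry.formula!r}") from None
    return fn(entry.inputs)


class RiskReport(BaseModel):
    """Complete device assessment: all tabular surfaces plus audit chain."""

    device: DeviceBOM
    config: AssessmentConfig
    constituents: list[ConstituentQuantity]
    exposures: list[ExposureRecord]
    tis: list[TIRecord]
    mos_records: list[MOSRecord]
    refined_exposures: dict[str, ExposureRecord] = Field(default_factory=dict)
    unresolved: list[tuple[str, Scenario]] = Field(default_factory=list)
    narratives: list[str] = Field(default_factory=list)
    audit: list[AuditEntry] = Field(default_factory=list)


def margin_of_safety(ti: float, eed: float) -> float | None:
    """TI / EED, unrounded; ``None`` ("not applicable") when there is no exposure."""
    if eed < 0 or ti < 0:
        raise ValueError("TI and EED must be non-negative")
    if eed == 0:
        return None
    return ti / eed


def screen(
    mos_records: list[MOSRecord], review_band_upper: float = 10.0
) -> list[MOSRecord]:
    """Assign screening flags per cell.

    MOS < 1: refine_needed. 1 <= MOS < review_band_upper: low_margin_review
    (the boundary MOS = 1 falls in the review band). Otherwise, or with no
    exposure, acceptable.
    """
    out = []
    for rec in mos_records:
        flags = {}
        for s, m in rec.mos.items():
            if m is None or m >= review_band_upper:
                flags[s] = ScreenFlag.acceptable
            elif m < 1.0:
                flags[s] = ScreenFlag.refine_needed
            else:
                flags[s] = ScreenFlag.low_margin_review
        out.append(rec.model_copy(update={"flags": flags}))
    return out


def assess_device(
    bom: DeviceBOM,
    hazard_db: HazardDatabase,
    curves: dict[str, list[MassLossCurve]] | None = None,
    config: AssessmentConfig | None = None,
) -> RiskReport:
    """Run the full screen-then-refine assessment for one device.

    ``curves`` maps constituent CAS to available mass-loss curves (in vitro
    and/or in vivo); the worst-case (largest window loss) curve governs each
    refinement. Cells that screen below MOS 1 and cannot be refined — or
    remain below 1 after refinement — are listed in ``unresolved``.

    Raises
    ------
    ConfigurationError
        If any decomposed constituent lacks a hazard record (all orphan CAS
        are listed).
    """
    cfg = config or AssessmentConfig()
    if cfg.scaling_factor_override is not None:
        bom = bom.model_copy(update={"scaling_factor": cfg.scaling_factor_override})
    bw = BodyWeightAssumption(bw_kg=cfg.body_weight_kg)
    curves = curves or {}
    audit: list[AuditEntry] = []
    narratives: list[str] = []

    constituents = decompose_device(bom, water_correction=cfg.water_correction)
    orphans = [c.constituent_cas for c in constituents if c.constituent_cas not in hazard_db.records]
    if orphans:
        raise ConfigurationError(
            "no hazard record for constituent CAS: " + ", ".join(sorted(orphans))
        )
    for c in constituents:
        audit.append(
            AuditEntry(
                quantity=f"TQ_max[{c.constituent_cas}]",
                formula="tq_max = tq_comp * sf",
                inputs={"tq_comp": c.tq_comp_mg, "sf": bom.scaling_factor},
                value=c.tq_max_mg,
            )
        )

    exposures = [exposure_record(c, bw) for c in constituents]
    for rec in exposures:
        for s in SCENARIOS:
            audit.append(
                AuditEntry(
                    quantity=f"EED[{rec.constituent_cas}][{s.value}]",
                    formula="eed = tq_max * 1000 / (bw * rd)",
                    inputs={
                        "tq_max": rec.tq_max_mg,
                        "bw": bw.bw_kg,
                        "rd": s.release_duration_days,
                    },
                    value=rec.eed_ug_per_kg_day[s],
                )
            )

    tis = []
    for c in constituents:
        hrec = hazard_db.get(c.constituent_cas)
        ti = tolerable_intake(hrec.pod, hrec.ufs_by_scenario)
        tis.append(ti)
        for s in SCENARIOS:
            audit.append(
                AuditEntry(
                    quantity=f"TI[{c.constituent_cas}][{s.value}]",
                    formula="ti = pod * 1000 / mf",
                    inputs={"pod": hrec.pod.pod_mg_per_kg_day, "mf": ti.mf[s]},
                    value=ti.ti_ug_per_kg_day[s],
                )
            )

    mos_records = []
    for c, exp, ti in zip(constituents, exposures, tis):
        mos = {}
        for s in SCENARIOS:
            m = margin_of_safety(ti.ti_ug_per_kg_day[s], exp.eed_ug_per_kg_day[s])
            mos[s] = m
            if m is not None:
                audit.append(
                    AuditEntry(
                        quantity=f"MOS[{c.constituent_cas}][{s.value}]",
                        formula="mos = ti / eed",
                        inputs={
                            "ti": ti.ti_ug_per_kg_day[s],
                            "eed": exp.eed_ug_per_kg_day[s],
                        },
                        value=m,
                    )
                )
        mos_records.append(
            MOSRecord(
                constituent_cas=c.constituent_cas,
                constituent_name=c.constituent_name,
                mos=mos,
            )
        )
    mos_records = screen(mos_records, cfg.review_band_upper)

    refined_exposures: dict[str, ExposureRecord] = {}
    unresolved: list[tuple[str, Scenario]] = []
    ti_by_cas = {t.constituent_cas: t for t in tis}
    exp_by_cas = {e.constituent_cas: e for e in exposures}
    for i, rec in enumerate(mos_records):
        cas = rec.constituent_cas
        for s in SCENARIOS:
            if rec.flags.get(s) is not ScreenFlag.refine_needed:
                continue
            available = curves.get(cas, [])
            if isinstance(available, MassLossCurve):
                available = [available]
            if not available:
                unresolved.append((cas, s))
                narratives.append(
                    f"{rec.constituent_name or cas}: {s.value} MOS "
                    f"{rec.mos[s]:.3g} < 1 with no degradation data available — "
                    "unresolved risk, refinement data required"
                )
                continue
            curve = select_worst_case_curve(available, cfg.refinement_window_days)
            base = refined_exposures.get(cas, exp_by_cas[cas])
            refined = refine_exposure(
                base, curve, cfg.refinement_window_days, s, bw
            )
            refined_exposures[cas] = refined
            dr = max_window_loss(curve, cfg.refinement_window_days)
            refined_eed = refined.eed_ug_per_kg_day[s]
            audit.append(
                AuditEntry(
                    quantity=f"EED_rk[{cas}][{s.value}]",
                    formula="eed_rk = tq_max * dr_max * 1000 / (bw * rd)",
                    inputs={
                        "tq_max": refined.tq_max_mg,
                        "dr_max": dr,
                        "bw": bw.bw_kg,
                        "rd": s.release_duration_days,
                    },
                    value=refined_eed,
                )
            )
            r_mos = margin_of_safety(ti_by_cas[cas].ti_ug_per_kg_day[s], refined_eed)
            if r_mos is not None:
                refined_mos = dict(rec.refined_mos)
                refined_mos[s] = r_mos
                rec = rec.model_copy(update={"refined_mos": refined_mos})
                mos_records[i] = rec
                audit.append(
                    AuditEntry(
                        quantity=f"MOS_refined[{cas}][{s.value}]",
                        formula="mos = ti / eed",
                        inputs={
                            "ti": ti_by_cas[cas].ti_ug_per_kg_day[s],
                            "eed": refined_eed,
                        },
                        value=r_mos,
                    )
                )
                narratives.append(
                    f"{rec.constituent_name or cas}: {s.value} MOS "
                    f"{rec.mos[s]:.3g} < 1 triggered refinement; "
                    f"DR_max({cfg.refinement_window_days:g} d) = {dr:.4g} from "
                    f"{curve.provenance.value} data gives refined EED "
                    f"{refined_eed:.4g} ug/kg/day and refined MOS {r_mos:.4g}"
                )
                if r_mos < 1.0:
                    unresolved.append((cas, s))

    return RiskReport(
        device=bom,
        config=cfg,
        constituents=constituents,
        exposures=exposures,
        tis=tis,
        mos_records=mos_records,
        refined_exposures=refined_exposures,
        unresolved=unresolved,
        narratives=narratives,
        audit=audit,
    )
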