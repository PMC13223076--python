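"""Tolerable intakes from points of departure and uncertainty factors.

For each constituent a point of departure (POD, typically a NOAEL in
mg/kg/day) is divided by a modifying factor MF — the product of uncertainty
factors for interindividual variability, animal-to-human extrapolation,
study-duration extrapolation and data quality/applicability — to give a
tolerable intake in ug/kg/day:

    TI = POD x 1000 / MF

Four TIs are derived per constituent, protective respectively of the acute,
subacute, subchronic and chronic exposure windows. A POD from a study of
equal or longer duration than the window being protected is usable directly;
protecting a longer window from a shorter study requires a duration
uncertainty factor > 1.
"""

from __future__ import annotations

import math
from enum import Enum

from pydantic import BaseModel, Field, PositiveFloat

from .errors import ConfigurationError
from .exposure import SCENARIOS, Scenario

POD_TO_TI_UNIT_FACTOR = 1000.0  # mg/kg/day -> ug/kg/day


class StudyDurationClass(str, Enum):
    subacute = "subacute"
    subchronic = "subchronic"
    chronic = "chronic"


class PODRecord(BaseModel):
    """Point of departure for one constituent.

    ``surrogate_of`` discloses read-across (the POD belongs to a structurally
    or metabolically related surrogate, e.g. 1,3-propanediol standing in for
    trimethylene carbonate) so reports can state it explicitly.
    """

    constituent_cas: str
    constituent_name: str = ""
    pod_mg_per_kg_day: PositiveFloat
    study_duration_class: StudyDurationClass
    endpoint_note: str = ""
    surrogate_of: str | None = None
    citation: str = ""

    model_config = {"frozen": True}


class UFSet(BaseModel):
    """Uncertainty factors whose product is the modifying factor MF.

    When a source database reports only the MF product (plus the two
    conventional base factors of 10), the residual MF/100 is carried in
    ``uf_duration`` with ``uf_quality_applicability`` = 1 and disclosed in
    reports as a combined duration/quality residual.
    """

    uf_interindividual: float = Field(default=10.0, ge=1.0)
    uf_interspecies: float = Field(default=10.0, ge=1.0)
    uf_duration: float = Field(default=1.0, ge=1.0)
    uf_quality_applicability: float = Field(default=1.0, ge=1.0)

    model_config = {"frozen": True}


class TIRecord(BaseModel):
    """Duration-stratified tolerable intakes for one constituent."""

    constituent_cas: str
    ti_ug_per_kg_day: dict[Scenario, float]
    mf: dict[Scenario, float]
    pod_source: PODRecord

    model_config = {"frozen": True}


class HazardRecord(BaseModel):
    """POD plus per-window uncertainty factors for one constituent."""

    pod: PODRecord
    ufs_by_scenario: dict[Scenario, UFSet]

    model_config = {"frozen": True}


class HazardDatabase(BaseModel):
    """Hazard records keyed by constituent CAS RN."""

    records: dict[str, HazardRecord]

    model_config = {"frozen": True}

    def get(self, cas: str) -> HazardRecord:
        try:
            return self.records[cas]
        except KeyError:
            raise ConfigurationError(f"no hazard record for CAS {cas}") from None


def modifying_factor(ufs: UFSet) -> float:
    """Product of the four uncertainty factors."""
    return math.prod(
        (
            ufs.uf_interindividual,
            ufs.uf_interspecies,
            ufs.uf_duration,
            ufs.uf_quality_applicability,
        )
    )


def tolerable_intake(
    pod: PODRecord, ufs_by_scenario: dict[Scenario, UFSet]
) -> TIRecord:
    """Derive the four duration-protective tolerable intakes for one constituent.

    Raises
    ------
    ConfigurationError
        If any exposure window lacks an uncertainty-factor set.
    """
    missing = [s.value for s in SCENARIOS if s not in ufs_by_scenario]
    if missing:
        raise ConfigurationError(
            f"constituent {pod.constituent_cas}: no uncertainty factors for "
            f"scenario(s) {', '.join(missing)}"
        )
    mfs = {s: modifying_factor(ufs_by_scenario[s]) for s in SCENARIOS}
    tis = {
        s: pod.pod_mg_per_kg_day * POD_TO_TI_UNIT_FACTOR / mfs[s] for s in SCENARIOS
    }
    return TIRecord(
        constituent_cas=pod.constituent_cas,
        ti_ug_per_kg_day=tis,
        mf=mfs,
        pod_source=pod,
    )
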