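"""Compositional profiling: polymer bill of materials -> worst-case monomer quantities.

A biodegradable device is described as a bill of materials (BOM) of polymer
masses. Each polymer is decomposed into its monomeric constituents under the
worst-case assumption of complete hydrolysis, yielding per-device total
quantities (TQ_comp, mg) and per-patient total quantities
(TQ_max = TQ_comp x scaling factor) of each terminal hydrolysis product.
Quantities sharing a hydrolysis-product CAS registry number are aggregated
across polymers, since e.g. glycolic acid can be liberated from more than one
copolymer in the same device.
"""

from __future__ import annotations

from enum import Enum

from pydantic import BaseModel, Field, NonNegativeFloat, PositiveFloat, model_validator

from .errors import ConfigurationError

RATIO_SUM_TOL = 1e-9


class RatioBasis(str, Enum):
    """Interpretation of copolymer composition ratios."""

    mass = "mass"
    molar = "molar"


class Monomer(BaseModel):
    """A monomeric constituent of a polymer and its terminal hydrolysis product.

    ``repeat_unit_mass`` (g/mol) is the mass of the monomer's repeat unit in
    the polymer chain; it is only required when composition ratios are given
    on a molar basis or when the stoichiometric water correction is applied.
    ``hydrolysis_units_per_repeat`` counts hydrolysis-product molecules
    released per repeat unit (e.g. 2 glycolic acids per glycolide).
    """

    name: str
    cas_rn: str = Field(min_length=1)
    hydrolysis_product_name: str
    hydrolysis_product_cas: str = Field(min_length=1)
    repeat_unit_mass: PositiveFloat | None = None
    hydrolysis_product_mass: PositiveFloat | None = None
    hydrolysis_units_per_repeat: int = Field(default=1, ge=1)

    model_config = {"frozen": True}


class PolymerComponent(BaseModel):
    monomer: Monomer
    ratio: PositiveFloat

    model_config = {"frozen": True}


class PolymerSpec(BaseModel):
    """A (co)polymer as a list of monomer components with composition ratios.

    Ratios must be strictly positive and sum to 1; whether they are weight
    fractions or mole fractions is set by ``ratio_basis`` (default mass,
    which is how printed copolymer ratios such as "75:25 PLGA" are treated
    throughout the shipped case study).
    """

    name: str
    components: list[PolymerComponent] = Field(min_length=1)
    ratio_basis: RatioBasis = RatioBasis.mass
    cas_rn: str | None = None

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _ratios_sum_to_one(self) -> "PolymerSpec":
        total = sum(c.ratio for c in self.components)
        if abs(total - 1.0) > RATIO_SUM_TOL:
            raise ValueError(
                f"component ratios of polymer {self.name!r} sum to {total!r}, expected 1"
            )
        return self


class BOMEntry(BaseModel):
    polymer: PolymerSpec
    mass_mg: PositiveFloat

    model_config = {"frozen": True}


class DeviceBOM(BaseModel):
    """Device bill of materials: polymer masses plus a patient scaling factor.

    ``scaling_factor`` accounts for multi-device clinical use (e.g. 2 for
    bilateral application); per-patient quantities are per-device quantities
    times this factor.
    """

    device_name: str
    entries: list[BOMEntry]
    scaling_factor: int = Field(default=1, ge=1)

    model_config = {"frozen": True}


class ConstituentQuantity(BaseModel):
    """Aggregated worst-case quantity of one hydrolysis product.

    ``tq_comp_mg`` is per device, ``tq_max_mg`` per patient
    (tq_comp x scaling factor). ``source_polymers`` lists the polymers that
    contribute, for report traceability.
    """

    constituent_cas: str
    constituent_name: str
    tq_comp_mg: NonNegativeFloat
    tq_max_mg: NonNegativeFloat
    source_polymers: list[str]

    model_config = {"frozen": True}


def component_weight_fractions(polymer: PolymerSpec) -> dict[str, float]:
    """Weight fraction of each monomer component, keyed by hydrolysis-product CAS.

    Mass-basis ratios are returned unchanged; molar-basis ratios r_i are
    converted with repeat-unit masses M_i as r_i M_i / sum_j r_j M_j.

    Raises
    ------
    ConfigurationError
        If the basis is molar and a component lacks ``repeat_unit_mass``.
    """
    if polymer.ratio_basis is RatioBasis.mass:
        weights = [c.ratio for c in polymer.components]
    else:
        weights = []
        for c in polymer.components:
            if c.monomer.repeat_unit_mass is None:
                raise ConfigurationError(
                    f"molar-basis polymer {polymer.name!r}: monomer "
                    f"{c.monomer.name!r} has no repeat_unit_mass"
                )
            weights.append(c.ratio * c.monomer.repeat_unit_mass)
    total = sum(weights)
    fractions: dict[str, float] = {}
    for c, w in zip(polymer.components, weights):
        cas = c.monomer.hydrolysis_product_cas
        fractions[cas] = fractions.get(cas, 0.0) + w / total
    return fractions


def _hydrolysis_mass_gain(monomer: Monomer) -> float:
    """Stoichiometric mass-gain factor of hydrolysis (water uptake).

    product_mass x units_per_repeat / repeat_unit_mass; >= 1 for hydrolytic
    ester/ring opening. Requires both molar masses.
    """
    if monomer.repeat_unit_mass is None or monomer.hydrolysis_product_mass is None:
        raise ConfigurationError(
            f"water correction needs repeat_unit_mass and hydrolysis_product_mass "
            f"for monomer {monomer.name!r}"
        )
    return (
        monomer.hydrolysis_product_mass
        * monomer.hydrolysis_units_per_repeat
        / monomer.repeat_unit_mass
    )


def decompose_device(
    bom: DeviceBOM, water_correction: bool = False
) -> list[ConstituentQuantity]:
    """Decompose a device BOM into aggregated worst-case constituent quantities.

    Each polymer mass is split by component weight fractions; masses sharing a
    hydrolysis-product CAS are summed across polymers; TQ_max applies the BOM
    scaling factor. With ``water_correction`` off (the default, matching the
    compositional-profiling convention of equating component mass with
    hydrolysis-product mass), total TQ_comp conserves total polymer mass.
    With it on, each monomer mass is multiplied by the stoichiometric
    hydrolysis mass gain.

    Constituents are returned in order of first appearance in the BOM.
    """
    totals: dict[str, float] = {}
    names: dict[str, str] = {}
    sources: dict[str, list[str]] = {}
    for entry in bom.entries:
        polymer = entry.polymer
        if polymer.ratio_basis is RatioBasis.mass:
            weights = [c.ratio for c in polymer.components]
        else:
            # reuse the molar -> weight conversion (validates repeat masses)
            component_weight_fractions(polymer)
            weights = [c.ratio * c.monomer.repeat_unit_mass for c in polymer.components]
        weight_total = sum(weights)
        for comp, w in zip(polymer.components, weights):
            cas = comp.monomer.hydrolysis_product_cas
            mass = entry.mass_mg * w / weight_total
            if water_correction:
                mass *= _hydrolysis_mass_gain(comp.monomer)
            totals[cas] = totals.get(cas, 0.0) + mass
            names.setdefault(cas, comp.monomer.hydrolysis_product_name)
            sources.setdefault(cas, [])
            if polymer.name not in sources[cas]:
                sources[cas].append(polymer.name)
    return [
        ConstituentQuantity(
            constituent_cas=cas,
            constituent_name=names[cas],
            tq_comp_mg=tq,
            tq_max_mg=tq * bom.scaling_factor,
            source_polymers=sources[cas],
        )
        for cas, tq in totals.items()
    ]
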