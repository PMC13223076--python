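"""Polymer decomposition into worst-case monomeric quantities."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from degradose import (
    BOMEntry,
    ConfigurationError,
    DeviceBOM,
    Monomer,
    PolymerComponent,
    PolymerSpec,
    component_weight_fractions,
    decompose_device,
)


def _monomer(name, cas, repeat_mass=None, product_mass=None, units=1):
    return Monomer(
        name=name,
        cas_rn=cas,
        hydrolysis_product_name=name + " product",
        hydrolysis_product_cas=cas,
        repeat_unit_mass=repeat_mass,
        hydrolysis_product_mass=product_mass,
        hydrolysis_units_per_repeat=units,
    )


GA = _monomer("glycolide", "79-14-1", 116.07, 76.05, 2)
LA = _monomer("lactide", "50-21-5", 144.13, 90.08, 2)
EG = _monomer("ethylene oxide unit", "107-21-1", 44.05, 62.07, 1)


def _polymer(name, comps, basis="mass"):
    return PolymerSpec(
        name=name,
        components=[PolymerComponent(monomer=m, ratio=r) for m, r in comps],
        ratio_basis=basis,
    )


class TestWeightFractions:
    def test_mass_basis_returns_ratios_unchanged(self):
        plga = _polymer("PLGA 75:25", [(GA, 0.75), (LA, 0.25)])
        assert component_weight_fractions(plga) == {"79-14-1": 0.75, "50-21-5": 0.25}

    def test_single_component_polymer_is_identity(self):
        peg = _polymer("PEG", [(EG, 1.0)])
        assert component_weight_fractions(peg) == {"107-21-1": 1.0}

    def test_molar_basis_weights_by_repeat_unit_mass(self):
        # 50:50 molar glycolide:lactide -> 116.07 / (116.07 + 144.13)
        p = _polymer("PLGA 50:50 molar", [(GA, 0.5), (LA, 0.5)], basis="molar")
        fr = component_weight_fractions(p)
        assert fr["79-14-1"] == pytest.approx(0.44608, abs=1e-4)
        assert fr["50-21-5"] == pytest.approx(0.55392, abs=1e-4)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)

    def test_molar_basis_without_repeat_mass_names_the_monomer(self):
        bare = _monomer("mystery", "0-00-0")
        p = _polymer("bad", [(bare, 0.5), (GA, 0.5)], basis="molar")
        with pytest.raises(ConfigurationError, match="mystery"):
            component_weight_fractions(p)

    def test_ratios_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            _polymer("bad", [(GA, 0.6), (LA, 0.25)])


class TestDecompose:
    def test_case_study_aggregates_glycolic_acid_across_polymers(self, bom):
        quantities = {q.constituent_cas: q for q in decompose_device(bom)}
        ga = quantities["79-14-1"]
        assert ga.tq_comp_mg == pytest.approx(90.0)
        assert ga.tq_max_mg == pytest.approx(180.0)
        assert set(ga.source_polymers) == {"PLGA 75:25", "GA-CL-TMC 50:25:25"}

    def test_case_study_constituent_totals(self, bom):
        expected = {  # mg/patient at scaling factor 2
            "107-21-1": 10.0,
            "50-21-5": 50.0,
            "79-14-1": 180.0,
            "502-44-3": 15.0,
            "2453-03-4": 15.0,
        }
        got = {q.constituent_cas: q.tq_max_mg for q in decompose_device(bom)}
        assert got == pytest.approx(expected)

    def test_unit_scaling_factor_is_identity(self):
        peg = _polymer("PEG", [(EG, 1.0)])
        bom = DeviceBOM(
            device_name="d",
            entries=[BOMEntry(polymer=peg, mass_mg=10.0)],
            scaling_factor=1,
        )
        (q,) = decompose_device(bom)
        assert q.tq_comp_mg == q.tq_max_mg == pytest.approx(10.0)

    def test_water_correction_applies_stoichiometric_gain(self):
        peg = _polymer("PEG", [(EG, 1.0)])
        bom = DeviceBOM(
            device_name="d", entries=[BOMEntry(polymer=peg, mass_mg=44.05)]
        )
        (q,) = decompose_device(bom, water_correction=True)
        # one 62.07 g/mol diol per 44.05 g/mol ether repeat unit
        assert q.tq_comp_mg == pytest.approx(62.07)

    def test_water_correction_without_masses_is_configuration_error(self):
        bare = _monomer("mystery", "0-00-0")
        bom = DeviceBOM(
            device_name="d",
            entries=[BOMEntry(polymer=_polymer("p", [(bare, 1.0)]), mass_mg=1.0)],
        )
        with pytest.raises(ConfigurationError):
            decompose_device(bom, water_correction=True)


# --- property tests ----------------------------------------------------------

_CAS_POOL = ("79-14-1", "50-21-5", "502-44-3", "2453-03-4", "107-21-1")


@st.composite
def random_boms(draw):
    monomers = [
        _monomer(f"m{i}", cas, repeat_mass=draw(st.floats(40.0, 200.0)))
        for i, cas in enumerate(_CAS_POOL)
    ]
    n_poly = draw(st.integers(1, 4))
    entries = []
    for p in range(n_poly):
        n_comp = draw(st.integers(1, 4))
        picks = draw(
            st.lists(st.sampled_from(monomers), min_size=n_comp, max_size=n_comp)
        )
        raw = draw(
            st.lists(st.floats(0.05, 10.0), min_size=n_comp, max_size=n_comp)
        )
        total = sum(raw)
        comps = [
            PolymerComponent(monomer=m, ratio=r / total)
            for m, r in zip(picks, raw)
        ]
        spec = PolymerSpec(name=f"poly{p}", components=comps)
        entries.append(
            BOMEntry(polymer=spec, mass_mg=draw(st.floats(0.1, 500.0)))
        )
    sf = draw(st.integers(1, 5))
    return DeviceBOM(device_name="synthetic", entries=entries, scaling_factor=sf)


@given(random_boms())
def test_mass_conservation_without_water_correction(bom):
    """Total constituent mass equals total polymer mass (no water uptake)."""
    quantities = decompose_device(bom)
    total_in = sum(e.mass_mg for e in bom.entries)
    total_out = sum(q.tq_comp_mg for q in quantities)
    assert total_out == pytest.approx(total_in, rel=1e-9)


@given(random_boms())
def test_decomposition_aggregates_like_per_polymer_sums(bom):
    """Decomposing polymers separately and summing by CAS matches one pass."""
    combined = {q.constituent_cas: q.tq_comp_mg for q in decompose_device(bom)}
    separate: dict[str, float] = {}
    for entry in bom.entries:
        sub = DeviceBOM(
            device_name="one", entries=[entry], scaling_factor=bom.scaling_factor
        )
        for q in decompose_device(sub):
            separate[q.constituent_cas] = (
                separate.get(q.constituent_cas, 0.0) + q.tq_comp_mg
            )
    assert combined == pytest.approx(separate, rel=1e-12)


@given(random_boms(), st.integers(1, 6))
def test_scaling_factor_is_linear(bom, k):
    base = {
        q.constituent_cas: q.tq_max_mg
        for q in decompose_device(bom.model_copy(update={"scaling_factor": 1}))
    }
    scaled = {
        q.constituent_cas: q.tq_max_mg
        for q in decompose_device(bom.model_copy(update={"scaling_factor": k}))
    }
    assert scaled == pytest.approx({cas: k * v for cas, v in base.items()})


@given(st.floats(40.0, 200.0), st.floats(0.0, 30.0), st.integers(1, 2))
def test_water_correction_never_loses_mass(repeat_mass, water_gain, units):
    """Hydrolytic chain scission adds water: corrected mass >= polymer mass."""
    product_mass = repeat_mass / units + water_gain
    m = _monomer("m", "79-14-1", repeat_mass, product_mass, units)
    bom = DeviceBOM(
        device_name="d",
        entries=[BOMEntry(polymer=_polymer("p", [(m, 1.0)]), mass_mg=100.0)],
    )
    (corrected,) = decompose_device(bom, water_correction=True)
    (plain,) = decompose_device(bom, water_correction=False)
    assert corrected.tq_comp_mg >= plain.tq_comp_mg - 1e-12
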