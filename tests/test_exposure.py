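"""Assumed-release exposure doses, sliding-window mass loss, and refinement."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from degradose import (
    SCENARIOS,
    BodyWeightAssumption,
    CurveWindowError,
    ExposureRecord,
    MassLossCurve,
    Scenario,
    eed_max,
    eed_refined_bolus,
    max_window_loss,
    refine_exposure,
    select_worst_case_curve,
)

from conftest import brute_force_window_loss

BW60 = BodyWeightAssumption()


@st.composite
def random_curves(draw):
    n = draw(st.integers(2, 12))
    gaps = draw(st.lists(st.floats(0.1, 25.0), min_size=n, max_size=n))
    times = np.concatenate([[0.0], np.cumsum(gaps)])
    incs = draw(st.lists(st.floats(0.0, 0.3), min_size=n, max_size=n))
    fractions = np.clip(np.concatenate([[0.0], np.cumsum(incs)]), 0.0, 1.0)
    return MassLossCurve(samples=list(zip(times.tolist(), fractions.tolist())))


class TestEEDMax:
    @pytest.mark.parametrize(
        "tq, scenario, expected",
        [
            (10.0, Scenario.acute, 10000.0 / 60.0),  # 166.67, displayed 167
            (180.0, Scenario.acute, 3000.0),
            (180.0, Scenario.subacute, 1500.0),
            (10.0, Scenario.chronic, 10000.0 / (60.0 * 366.0)),
            (0.0, Scenario.subchronic, 0.0),
        ],
    )
    def test_assumed_release_formula(self, tq, scenario, expected):
        assert eed_max(tq, BW60, scenario) == pytest.approx(expected)

    def test_negative_quantity_rejected(self):
        with pytest.raises(ValueError):
            eed_max(-1.0, BW60, Scenario.acute)

    @given(st.floats(0.01, 1e4))
    def test_eed_strictly_decreases_with_release_duration(self, tq):
        eeds = [eed_max(tq, BW60, s) for s in SCENARIOS]
        assert all(a > b for a, b in zip(eeds, eeds[1:]))


class TestMaxWindowLoss:
    def test_linear_curve_loss_is_proportional_to_window(self):
        curve = MassLossCurve(samples=[(0.0, 0.0), (30.0, 0.3)])  # 1%/day
        assert max_window_loss(curve, 7.0) == pytest.approx(0.07)

    def test_total_loss_bounds_the_window(self):
        curve = MassLossCurve(samples=[(0.0, 0.0), (10.0, 1.0)])
        assert max_window_loss(curve, 10.0) == pytest.approx(1.0)

    def test_sliding_maximum_on_convex_then_concave_curve(self):
        curve = MassLossCurve(
            samples=[(0.0, 0.0), (7.0, 0.02), (35.0, 0.5), (180.0, 0.9)]
        )
        got = max_window_loss(curve, 7.0)
        assert got >= 0.02
        # steepest stretch is the 7 d -> 35 d segment: 7 * 0.48/28
        assert got == pytest.approx(0.12)
        assert got == pytest.approx(brute_force_window_loss(curve, 7.0), abs=1e-6)

    def test_window_longer_than_observations_is_an_error(self):
        curve = MassLossCurve(samples=[(0.0, 0.0), (5.0, 0.1)])
        with pytest.raises(CurveWindowError, match="extend"):
            max_window_loss(curve, 7.0)

    @given(random_curves(), st.floats(0.05, 1.0))
    def test_agrees_with_dense_grid_oracle(self, curve, wfrac):
        window = wfrac * (curve.times[-1] - curve.times[0])
        assert max_window_loss(curve, window) == pytest.approx(
            brute_force_window_loss(curve, window), abs=1e-6
        )

    @given(random_curves(), st.floats(0.05, 0.5), st.floats(1.0, 2.0))
    def test_monotone_in_window_length(self, curve, wfrac, grow):
        span = curve.times[-1] - curve.times[0]
        w1 = wfrac * span
        w2 = min(w1 * grow, span)
        assert max_window_loss(curve, w2) >= max_window_loss(curve, w1) - 1e-12

    @given(random_curves(), st.floats(0.05, 1.0))
    def test_invariant_to_redundant_collinear_samples(self, curve, wfrac):
        window = wfrac * (curve.times[-1] - curve.times[0])
        t, f = curve.times, curve.fractions
        mid_t = (t[:-1] + t[1:]) / 2.0
        mid_f = np.interp(mid_t, t, f)
        all_t = np.concatenate([t, mid_t])
        order = np.argsort(all_t)
        dense = MassLossCurve(
            samples=list(
                zip(all_t[order].tolist(), np.concatenate([f, mid_f])[order].tolist())
            )
        )
        assert max_window_loss(dense, window) == pytest.approx(
            max_window_loss(curve, window), abs=1e-12
        )


class TestRefinedBolus:
    def test_worked_example_two_percent_of_180_mg(self):
        assert eed_refined_bolus(180.0, 0.02, BW60) == pytest.approx(60.0)

    @given(st.floats(0.0, 1e4))
    def test_complete_bolus_recovers_assumed_acute_dose(self, tq):
        assert eed_refined_bolus(tq, 1.0, BW60) == pytest.approx(
            eed_max(tq, BW60, Scenario.acute)
        )

    def test_zero_degradation_means_zero_dose(self):
        assert eed_refined_bolus(180.0, 0.0, BW60) == 0.0

    @pytest.mark.parametrize("dr", [-0.1, 1.1])
    def test_fraction_outside_unit_interval_rejected(self, dr):
        with pytest.raises(ValueError):
            eed_refined_bolus(180.0, dr, BW60)


def _record(tq: float) -> ExposureRecord:
    return ExposureRecord(
        constituent_cas="79-14-1",
        constituent_name="Glycolic acid",
        tq_max_mg=tq,
        eed_ug_per_kg_day={s: eed_max(tq, BW60, s) for s in SCENARIOS},
    )


class TestRefineExposure:
    def test_acute_refinement_with_seven_day_two_percent_loss(self):
        curve = MassLossCurve(samples=[(0.0, 0.0), (7.0, 0.02)], provenance="in_vivo")
        refined = refine_exposure(_record(180.0), curve, 7.0, Scenario.acute)
        assert refined.eed_ug_per_kg_day[Scenario.acute] == pytest.approx(60.0)
        assert refined.refined
        assert "DR_max" in refined.refinement_note
        assert "in_vivo" in refined.refinement_note
        # other windows untouched
        assert refined.eed_ug_per_kg_day[Scenario.chronic] == pytest.approx(
            _record(180.0).eed_ug_per_kg_day[Scenario.chronic]
        )

    def test_complete_release_leaves_default_unchanged(self):
        curve = MassLossCurve(samples=[(0.0, 0.0), (7.0, 1.0)])
        refined = refine_exposure(_record(180.0), curve, 7.0, Scenario.acute)
        assert refined.eed_ug_per_kg_day[Scenario.acute] == pytest.approx(3000.0)

    def test_subacute_refinement_spreads_window_loss_over_release_duration(self):
        from degradose import FixtureSpec, generate_fixture_curve

        curve = generate_fixture_curve(FixtureSpec(curve_shape="logistic", seed=3))
        refined = refine_exposure(_record(180.0), curve, 2.0, Scenario.subacute)
        dr = brute_force_window_loss(curve, 2.0)
        assert refined.eed_ug_per_kg_day[Scenario.subacute] == pytest.approx(
            180.0 * dr * 1000.0 / 60.0 / 2.0
        )

    @given(random_curves(), st.floats(0.1, 500.0))
    def test_refined_never_exceeds_default(self, curve, tq):
        window = curve.times[-1] - curve.times[0]
        record = _record(tq)
        refined = refine_exposure(record, curve, window, Scenario.acute)
        assert (
            refined.eed_ug_per_kg_day[Scenario.acute]
            <= record.eed_ug_per_kg_day[Scenario.acute] + 1e-9
        )


def test_worst_case_curve_selection_prefers_faster_degradation():
    slow = MassLossCurve(samples=[(0.0, 0.0), (7.0, 0.01)], provenance="in_vitro")
    fast = MassLossCurve(samples=[(0.0, 0.0), (7.0, 0.02)], provenance="in_vivo")
    assert select_worst_case_curve([slow, fast], 7.0) is fast
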