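"""DALY health-impact chain: elementary operations, the assembled
assessment against the calibrated provincial parameter set, and model
invariants on randomized self-consistent parameters."""
import math

import numpy as np
import pytest

from ofswheat.health import (
    DemographicGroup,
    Economics,
    HealthModelError,
    HealthParams,
    NutrientParams,
    Scenario,
    additional_intake,
    dalys_lost,
    dalys_saved,
    discounted_life_years,
    economic_benefit,
    gap_closure,
    intake_with_ofs,
    load_health_params,
    pct_burden_reduction,
    pct_rni,
    run_health_assessment,
)


class TestElementaryOps:
    def test_additional_intake_hand_value(self):
        assert additional_intake(1.0, 300.0, 0.31) == pytest.approx(0.093)

    def test_additional_intake_identity_scaling(self):
        assert additional_intake(2.5, 1000.0, 1.0) == pytest.approx(2.5)
        assert additional_intake(0.0, 300.0, 0.31) == 0.0

    def test_recovery_bounds(self):
        with pytest.raises(HealthModelError):
            additional_intake(1.0, 300.0, 1.2)

    def test_intake_with_ofs(self):
        assert intake_with_ofs(4.90, 0.06) == pytest.approx(4.96)
        assert intake_with_ofs(6.00, 0.12) == pytest.approx(6.12)
        assert intake_with_ofs(5.0, 0.0) == 5.0
        assert intake_with_ofs(0.5, -1.0) == 0.0  # floored at zero

    def test_pct_rni(self):
        assert pct_rni(6.9, 6.9) == 100.0
        assert pct_rni(0.0, 6.9) == 0.0
        assert pct_rni(4.96, 6.90) == pytest.approx(71.88, abs=0.01)
        with pytest.raises(HealthModelError):
            pct_rni(1.0, 0.0)

    def test_gap_closure(self):
        assert gap_closure(4.90, 0.06, 6.90) == pytest.approx(0.03)
        assert gap_closure(4.0, 0.0, 6.0) == 0.0
        assert gap_closure(4.0, 2.0, 6.0) == 1.0  # full closure
        assert gap_closure(4.0, 5.0, 6.0) == 1.0  # capped
        assert gap_closure(7.0, 1.0, 6.0) == 0.0  # already above RNI

    def test_dalys_saved_linearity_and_bounds(self):
        assert dalys_saved(1000.0, 0.0, 0.5) == 0.0
        assert dalys_saved(1000.0, 0.6, 0.5) == pytest.approx(3 * dalys_saved(1000.0, 0.2, 0.5))
        with pytest.raises(HealthModelError):
            dalys_saved(1000.0, 1.5, 0.5)
        with pytest.raises(HealthModelError):
            dalys_saved(1000.0, 0.5, -0.1)

    def test_pct_burden_reduction(self):
        assert pct_burden_reduction(0.0, 100.0) == 0.0
        assert pct_burden_reduction(100.0, 100.0) == 100.0
        with pytest.raises(HealthModelError):
            pct_burden_reduction(1.0, 0.0)

    def test_economic_benefit_arithmetic(self):
        assert economic_benefit(0.0, 10000.0, 0.0, 0.0) == 0.0
        # net negative allowed
        assert economic_benefit(1000.0, 10000.0, 900.0, 1e6) == pytest.approx(1e7 - 9e8)

    def test_discounting_closed_form(self):
        assert discounted_life_years(30.0, 0.0) == 30.0
        assert discounted_life_years(30.0, 0.03) == pytest.approx(
            (1 - math.exp(-0.9)) / 0.03
        )
        assert discounted_life_years(30.0, 0.03) == pytest.approx(19.781, abs=0.001)

    def test_dalys_lost(self):
        assert dalys_lost(1e6, 0.0, 30.0) == 0.0
        assert dalys_lost(1e6, 0.0, 30.0, [(0.01, 1.0, 0.1)]) == pytest.approx(1000.0)
        with pytest.raises(HealthModelError):
            dalys_lost(1e6, -0.1, 30.0)


@pytest.fixture(scope="module")
def results(default_params):
    a = run_health_assessment(default_params)
    return {(r.nutrient, r.treatment, r.scenario): r for r in a.results}


class TestCalibratedAssessment:
    """The packaged parameter set reproduces the published 15%OF impact
    column of the provincial assessment."""

    def test_infant_zn_row(self, results):
        res = results[("Zn", "OF15", "pessimistic")]
        infants = next(g for g in res.groups if g.group == "Infants")
        assert round(infants.intake_with_ofs, 2) == 4.96
        assert round(infants.pct_rni, 2) == 71.88
        assert round(infants.dalys_saved) == 771
        opt = results[("Zn", "OF15", "optimistic")]
        infants_opt = next(g for g in opt.groups if g.group == "Infants")
        assert round(infants_opt.dalys_saved) == 2313

    def test_men_fe_row(self, results):
        res = results[("Fe", "OF15", "pessimistic")]
        men = next(g for g in res.groups if g.group == "Men 15+")
        assert round(men.intake_with_ofs, 2) == 24.66
        assert round(men.pct_rni, 2) == 90.00
        assert round(men.dalys_saved) == 49304

    def test_burden_reductions(self, results):
        assert round(results[("Zn", "OF15", "pessimistic")].pct_burden_reduction, 2) == 2.28
        assert round(results[("Zn", "OF15", "optimistic")].pct_burden_reduction, 2) == 6.84
        assert round(results[("Fe", "OF15", "pessimistic")].pct_burden_reduction, 2) == 1.50
        assert round(results[("Fe", "OF15", "optimistic")].pct_burden_reduction, 2) == 4.50


def _random_params(rng, n_groups=4):
    """Self-consistent random parameter set (denominator = sum of burdens)."""
    groups = []
    for i in range(n_groups):
        rni = rng.uniform(5, 30)
        groups.append(
            DemographicGroup(
                name=f"g{i}",
                wheat_intake=rng.uniform(50, 400),
                baseline_intake=rni * rng.uniform(0.3, 1.2),  # some above RNI
                rni=rni,
                baseline_burden=rng.uniform(1e3, 1e6),
            )
        )
    opt = rng.uniform(20, 40)
    content = {"OPT": opt, "OF15": opt + rng.uniform(0, 10), "OF30": opt + rng.uniform(0, 10)}
    nut = NutrientParams("Zn", recovery=rng.uniform(0.1, 1.0), grain_content=content,
                         groups=tuple(groups))
    return HealthParams(
        nutrients={"Zn": nut},
        scenarios=(Scenario("pessimistic", 0.2), Scenario("optimistic", 0.6)),
        economics=Economics(pcni=rng.uniform(1e3, 5e4)),
    )


class TestModelInvariants:
    def test_zero_delta_fixed_point(self, default_params):
        contents = {
            n: {t: 30.0 for t in ("OPT", "OF15", "OF30")} for n in default_params.nutrients
        }
        a = run_health_assessment(default_params, contents=contents)
        for r in a.results:
            assert r.total_dalys_saved == 0.0
            assert r.pct_burden_reduction == 0.0
            for g in r.groups:
                assert g.additional_intake == 0.0

    def test_coverage_linearity_below_cap(self, default_params):
        a = run_health_assessment(default_params)
        by_key = {(r.nutrient, r.treatment, r.scenario): r for r in a.results}
        for (nutrient, treatment, scenario), r in by_key.items():
            if scenario != "pessimistic":
                continue
            opt = by_key[(nutrient, treatment, "optimistic")]
            if all(g.gap_closure < 1.0 for g in r.groups):
                assert opt.total_dalys_saved == pytest.approx(3 * r.total_dalys_saved, rel=1e-9)
                assert opt.pct_burden_reduction == pytest.approx(
                    3 * r.pct_burden_reduction, rel=1e-9
                )

    def test_monotonicity_and_conservation_on_random_sweeps(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            params = _random_params(rng)
            a = run_health_assessment(params)
            for r in a.results:
                total_burden = sum(g.baseline_burden for g in params.nutrients[r.nutrient].groups)
                assert 0 <= r.pct_burden_reduction <= 100
                assert r.total_dalys_saved <= total_burden + 1e-9
                for g in r.groups:
                    assert g.dalys_saved >= 0

    def test_saved_monotone_in_delta_coverage_intake_recovery(self):
        base = dict(baseline_burden=1e5, baseline_intake=5.0, rni=9.0)

        def saved(delta, cov, wheat, rec):
            add = additional_intake(delta, wheat, rec)
            return dalys_saved(base["baseline_burden"], cov,
                               gap_closure(base["baseline_intake"], add, base["rni"]))

        s0 = saved(1.0, 0.2, 200.0, 0.3)
        assert saved(2.0, 0.2, 200.0, 0.3) >= s0
        assert saved(1.0, 0.4, 200.0, 0.3) >= s0
        assert saved(1.0, 0.2, 300.0, 0.3) >= s0
        assert saved(1.0, 0.2, 200.0, 0.5) >= s0


class TestParameterLoading:
    def test_packaged_defaults_load(self, default_params):
        assert set(default_params.nutrients) == {"Zn", "Fe"}
        assert default_params.nutrients["Zn"].recovery == 0.310
        assert default_params.nutrients["Fe"].recovery == 0.217
        assert {s.coverage for s in default_params.scenarios} == {0.2, 0.6}
        assert default_params.economics.fertilizer_cost_per_ha == 900.0
        assert default_params.economics.area_ha == 4.0e6

    def test_missing_field_names_it(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text(
            "nutrients:\n  Zn:\n    recovery: 0.3\n    grain_content: {OPT: 25}\n"
            "    groups:\n      - name: Infants\n        wheat_intake: 100\n"
            "        baseline_intake: 4.9\n        baseline_burden: 1000\n"
            "scenarios: [{name: p, coverage: 0.2}]\n"
            "economics: {pcni: 8758}\n"
        )
        with pytest.raises(HealthModelError, match="rni"):
            load_health_params(bad)

    def test_missing_treatment_content_names_treatment(self, default_params):
        with pytest.raises(HealthModelError, match="OF45"):
            run_health_assessment(default_params, treatments=("OF45",))
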