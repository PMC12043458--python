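"""Ex-ante DALY health and economic impact of mineral-enriched grain.

The model follows the standard ex-ante biofortification chain: a content
increase in the consumed staple raises daily mineral intake (after milling
losses), which closes part of each demographic group's intake gap to its
recommended nutrient intake (RNI); the closed gap fraction, scaled by the
coverage rate (share of the population eating the improved grain), converts
the group's current deficiency burden (DALYs lost per year) into DALYs
saved.  Monetized benefit is DALYs saved times the per capita net income
(PCNI), less the extra fertilizer cost.

The dose-response is the simplest defensible form: a linear deficit
fraction capped at one,

    gap_closure = min(1, additional_intake / (RNI - baseline_intake))

isolated in one function so alternative dose-response curves can be swapped
in.  Everything downstream is linear in coverage below the cap, so a 60%
coverage scenario saves exactly three times a 20% one.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml


class HealthModelError(ValueError):
    """Invalid health-model input (rates outside [0,1], missing fields...)."""


# ---------------------------------------------------------------------------
# elementary operations

def additional_intake(delta_content: float, wheat_intake: float, recovery: float) -> float:
    """Extra daily mineral intake, mg day^-1.

    ``delta_content`` mg kg^-1 grain (may be negative for decreases),
    ``wheat_intake`` g day^-1 flour-equivalent, ``recovery`` milling
    retention fraction in [0, 1].
    """
    if not 0 <= recovery <= 1:
        raise HealthModelError(f"recovery must be in [0, 1], got {recovery}")
    if wheat_intake < 0:
        raise HealthModelError(f"wheat_intake must be >= 0, got {wheat_intake}")
    return delta_content * (wheat_intake / 1000.0) * recovery


def intake_with_ofs(baseline_intake: float, additional: float) -> float:
    """Daily intake with the improved grain, floored at zero."""
    if baseline_intake < 0:
        raise HealthModelError(f"baseline_intake must be >= 0, got {baseline_intake}")
    return max(0.0, baseline_intake + additional)


def pct_rni(intake: float, rni: float) -> float:
    """Intake as a percentage of the recommended nutrient intake."""
    if rni <= 0:
        raise HealthModelError(f"rni must be > 0, got {rni}")
    return 100.0 * intake / rni


def gap_closure(baseline_intake: float, additional: float, rni: float) -> float:
    """Fraction of the intake gap to the RNI closed by the extra intake.

    Linear in the deficit, clipped to [0, 1]; groups already at or above
    the RNI have no gap and return 0.
    """
    if rni <= 0:
        raise HealthModelError(f"rni must be > 0, got {rni}")
    if baseline_intake < 0:
        raise HealthModelError(f"baseline_intake must be >= 0, got {baseline_intake}")
    deficit = rni - baseline_intake
    if deficit <= 0:
        return 0.0
    return min(1.0, max(0.0, additional / deficit))


def dalys_saved(baseline_burden: float, coverage: float, closure: float) -> float:
    """DALYs averted: burden x coverage x gap closure (linear in coverage)."""
    if not 0 <= coverage <= 1:
        raise HealthModelError(f"coverage must be in [0, 1], got {coverage}")
    if not 0 <= closure <= 1:
        raise HealthModelError(f"gap closure must be in [0, 1], got {closure}")
    if baseline_burden < 0:
        raise HealthModelError(f"baseline_burden must be >= 0, got {baseline_burden}")
    return baseline_burden * coverage * closure


def pct_burden_reduction(saved: float, baseline_burden: float) -> float:
    """Saved burden as a percentage of the burden without intervention."""
    if baseline_burden <= 0:
        raise HealthModelError(f"baseline_burden must be > 0, got {baseline_burden}")
    return 100.0 * saved / baseline_burden


def economic_benefit(
    total_dalys_saved: float,
    pcni: float,
    fertilizer_cost_per_ha: float = 900.0,
    area: float = 4.0e6,
) -> float:
    """Monetary benefit, RMB: DALYs saved x PCNI minus fertilizer cost.

    Cost is a flat per-hectare organic fertilizer price (labor is assumed
    comparable between fertilizer regimes) over the cultivated ``area``.
    The result may be negative.
    """
    if min(total_dalys_saved, pcni, fertilizer_cost_per_ha, area) < 0:
        raise HealthModelError("all economic inputs must be >= 0")
    return total_dalys_saved * pcni - fertilizer_cost_per_ha * area


def discounted_life_years(life_expectancy: float, discount_rate: float = 0.0) -> float:
    """Discounted remaining life years: L if r = 0, else (1 - e^(-rL)) / r."""
    if life_expectancy < 0 or discount_rate < 0:
        raise HealthModelError("life expectancy and discount rate must be >= 0")
    if discount_rate == 0:
        return life_expectancy
    return (1.0 - math.exp(-discount_rate * life_expectancy)) / discount_rate


def dalys_lost(
    population: float,
    mortality_fraction: float,
    life_expectancy: float,
    outcomes: Sequence[tuple[float, float, float]] = (),
    discount_rate: float = 0.0,
) -> float:
    """Current deficiency burden for one group, DALYs per year.

    YLL from the mortality fraction times (discounted) remaining life
    expectancy, plus YLD summed over morbidity outcomes given as
    (incidence, duration in years, disability weight) triples:

        population * (m * L_disc + sum_i I_i * D_i * w_i)
    """
    if population < 0 or mortality_fraction < 0 or life_expectancy < 0:
        raise HealthModelError("population, mortality and life expectancy must be >= 0")
    yll = mortality_fraction * discounted_life_years(life_expectancy, discount_rate)
    yld = 0.0
    for incidence, duration, weight in outcomes:
        if min(incidence, duration, weight) < 0:
            raise HealthModelError("outcome incidence, duration and weight must be >= 0")
        yld += incidence * duration * weight
    return population * (yll + yld)


# ---------------------------------------------------------------------------
# parameter containers

@dataclass(frozen=True)
class DemographicGroup:
    """Population segment with its intake status and deficiency burden.

    ``wheat_intake`` g day^-1 flour-equivalent; ``baseline_intake`` and
    ``rni`` mg day^-1 of the nutrient; ``baseline_burden`` DALYs lost per
    year attributable to the deficiency in this group.
    """

    name: str
    wheat_intake: float
    baseline_intake: float
    rni: float
    baseline_burden: float
    population: float | None = None

    def __post_init__(self) -> None:
        if min(self.wheat_intake, self.baseline_intake, self.baseline_burden) < 0:
            raise HealthModelError(f"group {self.name!r}: quantities must be >= 0")
        if self.rni <= 0:
            raise HealthModelError(f"group {self.name!r}: rni must be > 0")


@dataclass(frozen=True)
class Scenario:
    name: str
    coverage: float

    def __post_init__(self) -> None:
        if not 0 <= self.coverage <= 1:
            raise HealthModelError(f"coverage must be in [0, 1], got {self.coverage}")


@dataclass(frozen=True)
class Economics:
    pcni: float  # RMB per DALY
    fertilizer_cost_per_ha: float = 900.0  # RMB ha^-1
    area_ha: float = 4.0e6


@dataclass(frozen=True)
class NutrientParams:
    """Health-model parameters for one nutrient."""

    name: str
    recovery: float
    grain_content: Mapping[str, float]  # treatment -> mg kg^-1
    groups: tuple[DemographicGroup, ...]
    #: denominator for % burden reduction; defaults to the sum of group burdens
    total_baseline_burden: float | None = None

    @property
    def burden_denominator(self) -> float:
        if self.total_baseline_burden is not None:
            return self.total_baseline_burden
        return sum(g.baseline_burden for g in self.groups)


@dataclass(frozen=True)
class HealthParams:
    nutrients: Mapping[str, NutrientParams]
    scenarios: tuple[Scenario, ...]
    economics: Economics


def load_health_params(path: str | Path | None = None) -> HealthParams:
    """Load health-model parameters from YAML (packaged defaults if no path)."""
    if path is None:
        text = resources.files("ofswheat.data").joinpath("health_params.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        raw = yaml.safe_load(Path(path).read_text())
    try:
        nutrients = {}
        for name, np_ in raw["nutrients"].items():
            groups = tuple(
                DemographicGroup(
                    name=g["name"],
                    wheat_intake=float(g["wheat_intake"]),
                    baseline_intake=float(g["baseline_intake"]),
                    rni=float(g["rni"]),
                    baseline_burden=float(g["baseline_burden"]),
                    population=g.get("population"),
                )
                for g in np_["groups"]
            )
            nutrients[name] = NutrientParams(
                name=name,
                recovery=float(np_["recovery"]),
                grain_content={k: float(v) for k, v in np_["grain_content"].items()},
                groups=groups,
                total_baseline_burden=(
                    float(np_["total_baseline_burden"])
                    if np_.get("total_baseline_burden") is not None
                    else None
                ),
            )
        scenarios = tuple(
            Scenario(s["name"], float(s["coverage"])) for s in raw["scenarios"]
        )
        eco = raw["economics"]
        economics = Economics(
            pcni=float(eco["pcni"]),
            fertilizer_cost_per_ha=float(eco.get("fertilizer_cost_per_ha", 900.0)),
            area_ha=float(eco.get("area_ha", 4.0e6)),
        )
    except KeyError as exc:
        raise HealthModelError(f"health parameter file is missing field {exc}") from None
    return HealthParams(nutrients=nutrients, scenarios=scenarios, economics=economics)


# ---------------------------------------------------------------------------
# assembled assessment

@dataclass(frozen=True)
class GroupImpact:
    group: str
    additional_intake: float  # mg day^-1
    intake_with_ofs: float  # mg day^-1
    pct_rni: float  # percent of RNI reached with the improved grain
    gap_closure: float
    dalys_saved: float


@dataclass(frozen=True)
class ScenarioResult:
    nutrient: str
    treatment: str
    scenario: str
    coverage: float
    groups: tuple[GroupImpact, ...]
    total_dalys_saved: float
    pct_burden_reduction: float


@dataclass(frozen=True)
class EconomicSummary:
    treatment: str
    scenario: str
    total_dalys_saved: float  # summed over nutrients
    economic_benefit: float  # RMB


@dataclass(frozen=True)
class HealthAssessment:
    results: tuple[ScenarioResult, ...]
    economics: tuple[EconomicSummary, ...]


def run_health_assessment(
    params: HealthParams,
    reference: str = "OPT",
    treatments: Sequence[str] = ("OF15", "OF30"),
    contents: Mapping[str, Mapping[str, float]] | None = None,
) -> HealthAssessment:
    """Full chain: content difference -> intake -> gap closure -> DALYs saved
    -> burden reduction -> economic benefit.

    ``contents`` optionally overrides the grain contents in ``params``
    (nutrient -> treatment -> mg kg^-1), e.g. treatment means estimated
    from a plot table.  Content differences are taken against the
    ``reference`` treatment.  Economic benefit is reported per
    treatment x scenario with DALYs summed over nutrients (one fertilizer
    cost per scenario).
    """
    results: list[ScenarioResult] = []
    totals: dict[tuple[str, str], float] = {}
    for nutrient, np_ in params.nutrients.items():
        content_map = (contents or {}).get(nutrient, np_.grain_content)
        if reference not in content_map:
            raise HealthModelError(
                f"nutrient {nutrient!r}: no grain content for reference treatment {reference!r}"
            )
        ref_content = content_map[reference]
        for treatment in treatments:
            if treatment not in content_map:
                raise HealthModelError(
                    f"nutrient {nutrient!r}: no grain content for treatment {treatment!r}"
                )
            delta = content_map[treatment] - ref_content
            for scenario in params.scenarios:
                impacts = []
                for g in np_.groups:
                    add = additional_intake(delta, g.wheat_intake, np_.recovery)
                    intake = intake_with_ofs(g.baseline_intake, add)
                    closure = gap_closure(g.baseline_intake, add, g.rni)
                    saved = dalys_saved(g.baseline_burden, scenario.coverage, closure)
                    impacts.append(
                        GroupImpact(
                            group=g.name,
                            additional_intake=add,
                            intake_with_ofs=intake,
                            pct_rni=pct_rni(intake, g.rni),
                            gap_closure=closure,
                            dalys_saved=saved,
                        )
                    )
                total = sum(i.dalys_saved for i in impacts)
                results.append(
                    ScenarioResult(
                        nutrient=nutrient,
                        treatment=treatment,
                        scenario=scenario.name,
                        coverage=scenario.coverage,
                        groups=tuple(impacts),
                        total_dalys_saved=total,
                        pct_burden_reduction=pct_burden_reduction(total, np_.burden_denominator),
                    )
                )
                totals[(treatment, scenario.name)] = totals.get((treatment, scenario.name), 0.0) + total

    economics = tuple(
        EconomicSummary(
            treatment=t,
            scenario=s,
            total_dalys_saved=saved,
            economic_benefit=economic_benefit(
                saved,
                params.economics.pcni,
                params.economics.fertilizer_cost_per_ha,
                params.economics.area_ha,
            ),
        )
        for (t, s), saved in totals.items()
    )
    return HealthAssessment(results=tuple(results), economics=economics)
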