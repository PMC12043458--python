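"""Nutritional yield and phytate-based mineral bioavailability.

Nutritional yield (NY) expresses land-use efficiency in human-nutrition
terms: the number of adults whose annual reference intake of a nutrient is
met by one hectare's harvest,

    NY (adults ha^-1) = C * GY / DRI / 365

with C the grain nutrient content, GY the dry grain yield and DRI the adult
daily reference intake.  For dietary energy the grain energy density
(339 kcal per 100 g for wheat) replaces C, converted with the
thermochemical calorie (4.184 kJ kcal^-1).

Phytic acid (InsP6) chelates divalent minerals in the gut; the molar ratio
of phytic acid to a mineral is the standard proxy for that mineral's
bioavailability.  Absorption-friendly thresholds are ratio < 15 for Zn and
< 1 for Fe.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trial import (
    PHYTIC_ACID_MOLAR_MASS,
    PlotRecord,
    NutrientSpec,
    default_nutrient_specs,
    records_to_frame,
)

#: wheat grain energy density, kcal per 100 g
WHEAT_ENERGY_KCAL_PER_100G: float = 339.0
#: thermochemical calorie, kJ per kcal
KJ_PER_KCAL: float = 4.184

#: bioavailability thresholds on the phytate/mineral molar ratio
MOLAR_RATIO_THRESHOLDS: dict[str, float] = {"Zn": 15.0, "Fe": 1.0}

_MINERAL_COLUMN = {"Fe": "grain_fe", "Mn": "grain_mn", "Cu": "grain_cu", "Zn": "grain_zn"}


class NutritionError(ValueError):
    """Invalid input to a nutrition calculation."""


def nutritional_yield(content: float, grain_yield: float, dri: float) -> float:
    """Adults ha^-1 fed for a year by one hectare's nutrient output.

    Parameters: ``content`` mg kg^-1, ``grain_yield`` Mg ha^-1 (dry),
    ``dri`` mg day^-1.  1 Mg = 1000 kg, so mg of nutrient per hectare is
    ``content * grain_yield * 1000``.
    """
    if dri <= 0:
        raise NutritionError(f"dri must be > 0, got {dri}")
    if content < 0 or grain_yield < 0:
        raise NutritionError("content and grain_yield must be >= 0")
    return content * grain_yield * 1000.0 / dri / 365.0


def energy_nutritional_yield(
    grain_yield: float,
    energy_density: float = WHEAT_ENERGY_KCAL_PER_100G,
    dri_energy: float = 8.47,
) -> float:
    """Energy nutritional yield, adults ha^-1.

    ``energy_density`` in kcal per 100 g, ``dri_energy`` in MJ day^-1.
    kcal/100 g converts to MJ kg^-1 as ``density * 4.184 / 100`` (kJ g^-1
    equals MJ kg^-1).
    """
    if grain_yield <= 0 or energy_density <= 0 or dri_energy <= 0:
        raise NutritionError("all inputs must be > 0")
    mj_per_kg = energy_density * KJ_PER_KCAL / 100.0
    return mj_per_kg * grain_yield * 1000.0 / dri_energy / 365.0


def phytate_molar_ratio(
    phytic_acid: float,
    mineral_content: float,
    mineral: str,
    specs: Mapping[str, NutrientSpec] | None = None,
) -> float:
    """Molar ratio of phytic acid to a mineral in grain.

    ``phytic_acid`` g kg^-1, ``mineral_content`` mg kg^-1; both are reduced
    to mol kg^-1 with the phytic acid molar mass 660.04 g mol^-1 and the
    mineral's atomic mass.
    """
    specs = specs or default_nutrient_specs()
    spec = specs.get(mineral)
    if spec is None or spec.molar_mass is None:
        raise NutritionError(f"no molar mass known for mineral {mineral!r}")
    if phytic_acid <= 0:
        raise NutritionError(f"phytic_acid must be > 0, got {phytic_acid}")
    if mineral_content <= 0:
        raise NutritionError(f"mineral content must be > 0, got {mineral_content}")
    pa_mol = phytic_acid / PHYTIC_ACID_MOLAR_MASS
    mineral_mol = (mineral_content / 1000.0) / spec.molar_mass
    return pa_mol / mineral_mol


def bioavailability_flag(ratio: float, mineral: str) -> bool:
    """True when the phytate/mineral molar ratio is below the
    absorption-friendly threshold (< 15 for Zn, < 1 for Fe)."""
    if mineral not in MOLAR_RATIO_THRESHOLDS:
        raise NutritionError(f"no bioavailability threshold defined for {mineral!r}")
    return ratio < MOLAR_RATIO_THRESHOLDS[mineral]


def percent_change(reference: float, value: float) -> float:
    """100 * (value - reference) / reference."""
    if reference == 0:
        raise NutritionError("reference must be nonzero")
    return 100.0 * (value - reference) / reference


@dataclass(frozen=True)
class NutritionalYieldResult:
    nutrient: str
    treatment: str
    ny: float  # adults ha^-1
    sd: float | None = None
    n: int | None = None


def nutritional_yield_table(
    records: Sequence[PlotRecord],
    specs: Mapping[str, NutrientSpec] | None = None,
    mode: str = "per_plot",
) -> pd.DataFrame:
    """Treatment-level nutritional yields for Fe, Mn, Cu, Zn and energy.

    ``mode='per_plot'`` (default) computes NY per plot and averages within
    treatment (mean +/- SD, the presentation used for trial reports);
    ``mode='of_means'`` applies the NY formula to treatment-mean content
    and yield.  Returns a tidy frame with columns
    nutrient, treatment, ny, sd, n.
    """
    specs = specs or default_nutrient_specs()
    df = records_to_frame(records)
    nutrients = ["Fe", "Mn", "Cu", "Zn", "energy"]
    rows = []
    for nutrient in nutrients:
        if nutrient == "energy":
            per_plot = df["yield"].map(
                lambda gy: energy_nutritional_yield(gy, dri_energy=specs["energy"].dri)
            )
        else:
            col = _MINERAL_COLUMN[nutrient]
            dri = specs[nutrient].dri
            per_plot = df.apply(lambda r: nutritional_yield(r[col], r["yield"], dri), axis=1)
        tmp = df.assign(_ny=per_plot)
        for treatment, grp in tmp.groupby("treatment", sort=False):
            if mode == "per_plot":
                ny = float(grp["_ny"].mean())
                sd = float(grp["_ny"].std(ddof=1)) if len(grp) > 1 else float("nan")
            elif mode == "of_means":
                if nutrient == "energy":
                    ny = energy_nutritional_yield(
                        float(grp["yield"].mean()), dri_energy=specs["energy"].dri
                    )
                else:
                    ny = nutritional_yield(
                        float(grp[_MINERAL_COLUMN[nutrient]].mean()),
                        float(grp["yield"].mean()),
                        specs[nutrient].dri,
                    )
                sd = float("nan")
            else:
                raise NutritionError(f"unknown mode {mode!r}")
            rows.append(
                {"nutrient": nutrient, "treatment": treatment, "ny": ny, "sd": sd, "n": len(grp)}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MolarRatioResult:
    mineral: str
    treatment: str
    ratio: float
    sd: float | None = None
    bioavailable: bool | None = None  # only defined for Fe and Zn


def molar_ratio_table(
    records: Sequence[PlotRecord],
    minerals: Sequence[str] = ("Fe", "Mn", "Cu", "Zn"),
    specs: Mapping[str, NutrientSpec] | None = None,
) -> pd.DataFrame:
    """Treatment-mean phytate/mineral molar ratios (per-plot, then averaged).

    The bioavailable flag (Fe, Zn only) is evaluated on the treatment mean
    ratio; other minerals carry no threshold and get a null flag.
    """
    specs = specs or default_nutrient_specs()
    df = records_to_frame(records)
    rows = []
    for mineral in minerals:
        col = _MINERAL_COLUMN[mineral]
        per_plot = df.apply(
            lambda r: phytate_molar_ratio(r["phytic_acid"], r[col], mineral, specs), axis=1
        )
        tmp = df.assign(_ratio=per_plot)
        for treatment, grp in tmp.groupby("treatment", sort=False):
            mean_ratio = float(grp["_ratio"].mean())
            rows.append(
                {
                    "mineral": mineral,
                    "treatment": treatment,
                    "ratio": mean_ratio,
                    "sd": float(grp["_ratio"].std(ddof=1)) if len(grp) > 1 else float("nan"),
                    "n": len(grp),
                    "bioavailable": (
                        bioavailability_flag(mean_ratio, mineral)
                        if mineral in MOLAR_RATIO_THRESHOLDS
                        else None
                    ),
                }
            )
    return pd.DataFrame(rows)
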