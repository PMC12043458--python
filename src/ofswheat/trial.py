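"""Plot-level field-trial records, nutrient reference data, and CSV I/O.

The data model mirrors a multi-site wheat fertilization trial: five
treatments (unfertilized control CK, farmers' practice FP, optimized
fertilization OPT, and 15% / 30% organic substitution of chemical nitrogen,
OF15 / OF30) replicated within sites.  Each :class:`PlotRecord` holds one
plot's dry grain yield (Mg ha^-1), grain micronutrient concentrations
(mg kg^-1), phytic acid (g kg^-1) and optional soil covariates.

Units are fixed per column and never inferred; yields are dry grain mass.
An optional moisture fraction converts fresh weights at read time.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Canonical treatment codes in the order used throughout reports.
TREATMENTS: tuple[str, ...] = ("CK", "FP", "OPT", "OF15", "OF30")

#: Accepted spellings for treatment labels found in input files.
TREATMENT_ALIASES: dict[str, str] = {
    "CK": "CK",
    "FP": "FP",
    "OPT": "OPT",
    "OF15": "OF15",
    "OF30": "OF30",
    "15%OF": "OF15",
    "30%OF": "OF30",
    "15OF": "OF15",
    "30OF": "OF30",
}

#: Required plot-table columns (snake_case, fixed units).
REQUIRED_COLUMNS: tuple[str, ...] = (
    "site",
    "treatment",
    "replicate",
    "yield",
    "grain_fe",
    "grain_mn",
    "grain_cu",
    "grain_zn",
    "phytic_acid",
)

#: Optional descriptive soil covariates (pH unitless, others mg kg^-1 or g kg^-1).
SOIL_COLUMNS: tuple[str, ...] = (
    "soil_ph",
    "soil_om",
    "soil_tn",
    "soil_avail_p",
    "soil_avail_k",
    "soil_dtpa_fe",
    "soil_dtpa_mn",
    "soil_dtpa_cu",
    "soil_dtpa_zn",
)

ANALYTES: tuple[str, ...] = ("grain_fe", "grain_mn", "grain_cu", "grain_zn", "phytic_acid")


class SchemaError(ValueError):
    """A required column is missing or the header cannot be interpreted."""


class ValidationError(ValueError):
    """A row violates a record invariant (negative yield, bad treatment, ...)."""


class UniquenessError(ValueError):
    """Duplicate (site, treatment, replicate) keys within one dataset."""


def normalize_treatment(label: str) -> str:
    """Map a treatment label (e.g. ``15%OF``) to its canonical code."""
    key = str(label).strip()
    canon = TREATMENT_ALIASES.get(key) or TREATMENT_ALIASES.get(key.upper())
    if canon is None:
        raise ValidationError(
            f"unknown treatment {label!r}; expected one of {sorted(set(TREATMENT_ALIASES))}"
        )
    return canon


@dataclass(frozen=True)
class PlotRecord:
    """One field plot: yield, grain composition and optional soil covariates.

    Attributes
    ----------
    site : str
        Site identifier (county / station name).
    treatment : str
        One of :data:`TREATMENTS`.
    replicate : int
        Replicate (block) number, >= 1.
    grain_yield : float
        Dry grain yield, Mg ha^-1, > 0.
    grain_fe, grain_mn, grain_cu, grain_zn : float
        Grain mineral concentration, mg kg^-1 dry matter, >= 0.
    phytic_acid : float
        Grain phytic acid, g kg^-1 dry matter, >= 0.
    """

    site: str
    treatment: str
    replicate: int
    grain_yield: float
    grain_fe: float
    grain_mn: float
    grain_cu: float
    grain_zn: float
    phytic_acid: float
    soil_ph: float | None = None
    soil_om: float | None = None
    soil_tn: float | None = None
    soil_avail_p: float | None = None
    soil_avail_k: float | None = None
    soil_dtpa_fe: float | None = None
    soil_dtpa_mn: float | None = None
    soil_dtpa_cu: float | None = None
    soil_dtpa_zn: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatment", normalize_treatment(self.treatment))
        if not (isinstance(self.replicate, int) and self.replicate >= 1):
            raise ValidationError(f"replicate must be a positive integer, got {self.replicate!r}")
        if not (math.isfinite(self.grain_yield) and self.grain_yield > 0):
            raise ValidationError(f"yield must be > 0, got {self.grain_yield!r}")
        for name in ("grain_fe", "grain_mn", "grain_cu", "grain_zn", "phytic_acid"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValidationError(f"{name} must be >= 0, got {v!r}")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.site, self.treatment, self.replicate)


# column name in file -> attribute name ("yield" is a Python keyword)
_COL_TO_ATTR = {c: c for c in REQUIRED_COLUMNS + SOIL_COLUMNS}
_COL_TO_ATTR["yield"] = "grain_yield"
_ATTR_TO_COL = {v: k for k, v in _COL_TO_ATTR.items()}


def read_plot_table(
    path: str | Path,
    column_aliases: Mapping[str, str] | None = None,
    moisture_fraction: float = 0.0,
) -> list[PlotRecord]:
    """Read a plot-level CSV table into validated :class:`PlotRecord` objects.

    Parameters
    ----------
    path
        CSV file with a header row; ``#`` lines are treated as comments.
    column_aliases
        Optional mapping from file column names to canonical names, for
        files whose headers differ from the documented schema.
    moisture_fraction
        If the stored yields are fresh weight, the grain moisture fraction
        in [0, 1); yields are converted to dry mass as ``fresh * (1 - m)``.
        Default 0 (yields already dry).

    Raises
    ------
    SchemaError, ValidationError, UniquenessError
    """
    if not 0 <= moisture_fraction < 1:
        raise ValidationError(f"moisture_fraction must be in [0, 1), got {moisture_fraction}")
    df = pd.read_csv(
        path,
        comment="#",
        dtype={"site": str},
        skip_blank_lines=True,
        float_precision="round_trip",
    )
    if column_aliases:
        df = df.rename(columns=dict(column_aliases))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[PlotRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        data = dict(zip(df.columns, row))
        kwargs: dict[str, object] = {}
        for col in REQUIRED_COLUMNS + SOIL_COLUMNS:
            if col not in df.columns:
                continue
            raw = data[col]
            attr = _COL_TO_ATTR[col]
            if col == "site":
                kwargs[attr] = str(raw)
            elif col == "treatment":
                kwargs[attr] = raw
            elif col == "replicate":
                try:
                    kwargs[attr] = int(raw)
                except (TypeError, ValueError) as exc:
                    raise ValidationError(f"row {idx}: non-integer replicate {raw!r}") from exc
            else:
                if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                    if col in SOIL_COLUMNS:
                        kwargs[attr] = None
                        continue
                    raise ValidationError(f"row {idx}: missing value in column {col!r}")
                try:
                    kwargs[attr] = float(raw)
                except (TypeError, ValueError) as exc:
                    raise ValidationError(f"row {idx}: non-numeric value {raw!r} in column {col!r}") from exc
        if moisture_fraction:
            kwargs["grain_yield"] = float(kwargs["grain_yield"]) * (1.0 - moisture_fraction)
        try:
            records.append(PlotRecord(**kwargs))  # type: ignore[arg-type]
        except ValidationError as exc:
            raise ValidationError(f"row {idx}: {exc}") from None

    seen: dict[tuple[str, str, int], int] = {}
    for idx, rec in enumerate(records, start=1):
        if rec.key in seen:
            raise UniquenessError(
                f"duplicate (site, treatment, replicate) = {rec.key} at rows {seen[rec.key]} and {idx}"
            )
        seen[rec.key] = idx
    return records


def write_plot_table(records: Iterable[PlotRecord], path: str | Path) -> None:
    """Write records as CSV so that :func:`read_plot_table` round-trips exactly.

    Floats are written with shortest round-trip representation, so numeric
    fields are bit-equivalent after a read/write cycle.  An empty collection
    yields a header-only file.
    """
    cols = list(REQUIRED_COLUMNS + SOIL_COLUMNS)
    rows = []
    for rec in records:
        rows.append({col: getattr(rec, _COL_TO_ATTR[col]) for col in cols})
    df = pd.DataFrame(rows, columns=cols)
    # shortest round-trip float repr so read_plot_table restores exact bits
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def records_to_frame(records: Sequence[PlotRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of a record collection (column ``yield`` for grain yield)."""
    cols = list(REQUIRED_COLUMNS + SOIL_COLUMNS)
    return pd.DataFrame(
        [{col: getattr(r, _COL_TO_ATTR[col]) for col in cols} for r in records],
        columns=cols,
    )


@dataclass(frozen=True)
class NutrientSpec:
    """Reference data for one nutrient.

    ``dri`` is the adult daily reference intake used in the nutritional-yield
    denominator: mg day^-1 for minerals, MJ day^-1 for energy.  ``recovery``
    is the fraction retained in flour after milling (bran removal); it is
    only established for Zn (0.310) and Fe (0.217) and is None otherwise.
    """

    name: str
    dri: float
    molar_mass: float | None = None  # g mol^-1; None for energy
    recovery: float | None = None  # milling retention fraction in [0, 1]

    def __post_init__(self) -> None:
        if self.dri <= 0:
            raise ValidationError(f"dri must be > 0, got {self.dri}")
        if self.recovery is not None and not 0 <= self.recovery <= 1:
            raise ValidationError(f"recovery must be in [0, 1], got {self.recovery}")
        if self.molar_mass is not None and self.molar_mass <= 0:
            raise ValidationError(f"molar_mass must be > 0, got {self.molar_mass}")


#: Molar mass of phytic acid (C6H18O24P6), g mol^-1.
PHYTIC_ACID_MOLAR_MASS: float = 660.04


def default_nutrient_specs() -> dict[str, NutrientSpec]:
    """Default nutrient reference set for wheat-grain assessments.

    Adult DRIs: energy 8.47 MJ day^-1; Fe 13.00, Mn 2.05, Cu 0.90 and
    Zn 9.50 mg day^-1.  Milling recovery 31.0% for Zn and 21.7% for Fe
    (both concentrate in the bran removed during flour production).
    """
    specs = [
        NutrientSpec("Fe", dri=13.00, molar_mass=55.845, recovery=0.217),
        NutrientSpec("Mn", dri=2.05, molar_mass=54.938),
        NutrientSpec("Cu", dri=0.90, molar_mass=63.546),
        NutrientSpec("Zn", dri=9.50, molar_mass=65.38, recovery=0.310),
        NutrientSpec("energy", dri=8.47),
    ]
    return {s.name: s for s in specs}
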