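"""One-shot report bundle: plot table -> descriptive summary, treatment
comparisons with significance letters, molar ratios, and health impact.

All report files round to a configurable number of decimals (default 2,
matching conventional trial tables); every file starts with a comment line
declaring its units; reruns with identical inputs and config are
byte-identical (no timestamps are written).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .health import HealthAssessment, load_health_params, run_health_assessment
from .nutrition import molar_ratio_table, nutritional_yield_table
from .stats import describe, fisher_lsd_letters
from .synthetic import GeneratorConfig, default_config, generate_trial
from .trial import (
    ANALYTES,
    TREATMENTS,
    PlotRecord,
    read_plot_table,
    records_to_frame,
    write_plot_table,
)

_VARIABLES = ("yield",) + ANALYTES

_UNIT_LINES = {
    "summary": "# units: yield Mg ha-1; grain_fe/mn/cu/zn mg kg-1; phytic_acid g kg-1; cv percent",
    "treatment_summaries": "# units: yield Mg ha-1 and ny adults ha-1 rows as labelled; grain_* mg kg-1; phytic_acid g kg-1",
    "ratios": "# units: ratio mol/mol (phytic acid : mineral); bioavailable true when below threshold (Zn<15, Fe<1)",
    "plots": "# units: yield Mg ha-1 (dry); grain_* mg kg-1; phytic_acid g kg-1; soil columns as sampled",
}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    plots_path: str | None = None  # None -> simulate with `seed`
    params_path: str | None = None  # None -> packaged health parameters
    outdir: str = "ofswheat_out"
    seed: int = 0
    alpha: float = 0.05
    reference_treatment: str = "OPT"
    ofs_treatments: tuple[str, ...] = ("OF15", "OF30")
    precision: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.precision < 0:
            raise ValueError("precision must be >= 0")


def _round_df(df: pd.DataFrame, precision: int) -> pd.DataFrame:
    return df.round(precision)


def _write_csv(df: pd.DataFrame, path: Path, unit_line: str, precision: int) -> None:
    with open(path, "w") as fh:
        fh.write(unit_line + "\n")
        _round_df(df, precision).to_csv(fh, index=False)


def summary_table(records: Sequence[PlotRecord]) -> pd.DataFrame:
    """Descriptive statistics of yield and grain composition (all plots)."""
    df = records_to_frame(records)
    rows = []
    for var in _VARIABLES:
        d = describe(df[var])
        rows.append(
            {
                "variable": var,
                "n": d.n,
                "mean": d.mean,
                "sd": d.sd,
                "median": d.median,
                "min": d.min,
                "max": d.max,
                "cv_percent": d.cv_percent,
            }
        )
    return pd.DataFrame(rows)


def treatment_summary_table(
    records: Sequence[PlotRecord], alpha: float = 0.05
) -> tuple[pd.DataFrame, list[str]]:
    """Treatment means +/- SD with LSD letters for yield, composition and
    nutritional yields.  Returns (table, notes); with fewer than two
    treatments the letters column is 'n/a' and a note says so.
    """
    df = records_to_frame(records)
    notes: list[str] = []
    present = [t for t in TREATMENTS if t in set(df["treatment"])]
    present += [t for t in sorted(set(df["treatment"])) if t not in present]
    rows = []

    def letter_block(variable: str, values_by_treatment: Mapping[str, Sequence[float]]):
        if len(values_by_treatment) < 2 or any(
            len(v) < 2 for v in values_by_treatment.values()
        ):
            notes.append(f"{variable}: letters not applicable (needs >= 2 treatments with >= 2 plots)")
            for t, v in values_by_treatment.items():
                s = pd.Series(v, dtype=float)
                rows.append(
                    {"variable": variable, "treatment": t, "n": len(v),
                     "mean": float(s.mean()), "sd": float(s.std(ddof=1)), "letters": "not applicable"}
                )
            return
        for summ in fisher_lsd_letters(values_by_treatment, alpha=alpha, variable=variable):
            rows.append(dataclasses.asdict(summ))

    for var in _VARIABLES:
        groups = {t: df.loc[df["treatment"] == t, var].tolist() for t in present}
        letter_block(var, groups)

    # nutritional yields per plot, compared the same way
    plot_ny = _per_plot_ny_frame(records)
    for nutrient in ("Fe", "Mn", "Cu", "Zn", "energy"):
        groups = {
            t: plot_ny.loc[(plot_ny["treatment"] == t) & (plot_ny["nutrient"] == nutrient), "ny"].tolist()
            for t in present
        }
        letter_block(f"ny_{nutrient}", groups)
    return pd.DataFrame(rows, columns=["variable", "treatment", "n", "mean", "sd", "letters"]), notes


def _per_plot_ny_frame(records: Sequence[PlotRecord]) -> pd.DataFrame:
    from .nutrition import energy_nutritional_yield, nutritional_yield
    from .trial import default_nutrient_specs

    specs = default_nutrient_specs()
    df = records_to_frame(records)
    frames = []
    for nutrient, col in (("Fe", "grain_fe"), ("Mn", "grain_mn"), ("Cu", "grain_cu"), ("Zn", "grain_zn")):
        frames.append(
            pd.DataFrame(
                {
                    "treatment": df["treatment"],
                    "nutrient": nutrient,
                    "ny": [
                        nutritional_yield(c, gy, specs[nutrient].dri)
                        for c, gy in zip(df[col], df["yield"])
                    ],
                }
            )
        )
    frames.append(
        pd.DataFrame(
            {
                "treatment": df["treatment"],
                "nutrient": "energy",
                "ny": [energy_nutritional_yield(gy, dri_energy=specs["energy"].dri) for gy in df["yield"]],
            }
        )
    )
    return pd.concat(frames, ignore_index=True)


def grain_content_means(records: Sequence[PlotRecord]) -> dict[str, dict[str, float]]:
    """Treatment-mean grain Zn and Fe contents (mg kg^-1) from a plot table."""
    df = records_to_frame(records)
    out: dict[str, dict[str, float]] = {}
    for nutrient, col in (("Zn", "grain_zn"), ("Fe", "grain_fe")):
        out[nutrient] = {t: float(m) for t, m in df.groupby("treatment")[col].mean().items()}
    return out


def assessment_to_dict(assessment: HealthAssessment, precision: int = 2) -> dict:
    """JSON-serializable view of a health assessment (Table-3-like nesting)."""

    def r(x: float) -> float:
        return round(float(x), precision)

    nested: dict = {"units": {
        "intake": "mg day-1",
        "pct_rni": "percent",
        "dalys_saved": "DALYs year-1",
        "pct_burden_reduction": "percent",
        "economic_benefit": "RMB",
    }, "nutrients": {}}
    for res in assessment.results:
        node = (
            nested["nutrients"]
            .setdefault(res.nutrient, {})
            .setdefault(res.treatment, {})
            .setdefault(res.scenario, {})
        )
        node["coverage"] = res.coverage
        node["groups"] = {
            g.group: {
                "additional_intake": r(g.additional_intake),
                "intake_with_ofs": r(g.intake_with_ofs),
                "pct_rni": r(g.pct_rni),
                "dalys_saved": r(g.dalys_saved),
            }
            for g in res.groups
        }
        node["total_dalys_saved"] = r(res.total_dalys_saved)
        node["pct_burden_reduction"] = r(res.pct_burden_reduction)
    nested["economics"] = {
        f"{e.treatment}/{e.scenario}": {
            "total_dalys_saved": r(e.total_dalys_saved),
            "economic_benefit": r(e.economic_benefit),
        }
        for e in assessment.economics
    }
    return nested


def full_run(config: RunConfig) -> dict[str, Path]:
    """Run the whole pipeline and write the report bundle.

    Emits summary.csv, treatment_summaries.csv, ratios.csv, impact.json and
    run.log into ``config.outdir`` (plus plots.csv when simulating).
    Returns the mapping of artifact names to paths.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [
        f"ofswheat {__version__}",
        f"seed: {config.seed}",
    ]
    cfg_hash = hashlib.sha256(
        json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]
    log_lines.append(f"config_hash: {cfg_hash}")
    log_lines.append(f"config: {dataclasses.asdict(config)}")
    artifacts: dict[str, Path] = {}

    stage = "input"
    try:
        if config.plots_path is None:
            records = generate_trial(default_config(seed=config.seed))
            plots_path = outdir / "plots.csv"
            with open(plots_path, "w") as fh:
                fh.write(_UNIT_LINES["plots"] + "\n")
            # append data below the unit comment
            records_to_frame(records).to_csv(plots_path, mode="a", index=False)
            artifacts["plots"] = plots_path
            log_lines.append(f"input: simulated {len(records)} plots (seed {config.seed})")
        else:
            records = read_plot_table(config.plots_path)
            log_lines.append(f"input: {config.plots_path} ({len(records)} plots)")

        stage = "summary"
        sm = summary_table(records)
        artifacts["summary"] = outdir / "summary.csv"
        _write_csv(sm, artifacts["summary"], _UNIT_LINES["summary"], config.precision)
        log_lines.append("summary: ok")

        stage = "treatment_summaries"
        ts, notes = treatment_summary_table(records, alpha=config.alpha)
        artifacts["treatment_summaries"] = outdir / "treatment_summaries.csv"
        _write_csv(ts, artifacts["treatment_summaries"], _UNIT_LINES["treatment_summaries"], config.precision)
        for note in notes:
            log_lines.append(f"treatment_summaries: {note}")
        log_lines.append("treatment_summaries: ok")

        stage = "ratios"
        rt = molar_ratio_table(records)
        artifacts["ratios"] = outdir / "ratios.csv"
        _write_csv(rt, artifacts["ratios"], _UNIT_LINES["ratios"], config.precision)
        log_lines.append("ratios: ok")

        stage = "health"
        params = load_health_params(config.params_path)
        contents = grain_content_means(records)
        usable = {
            n: c
            for n, c in contents.items()
            if config.reference_treatment in c
            and all(t in c for t in config.ofs_treatments)
        }
        if len(usable) == len(contents):
            assessment = run_health_assessment(
                params,
                reference=config.reference_treatment,
                treatments=config.ofs_treatments,
                contents=usable,
            )
            log_lines.append("health: contents from plot treatment means")
        else:
            assessment = run_health_assessment(
                params,
                reference=config.reference_treatment,
                treatments=config.ofs_treatments,
            )
            log_lines.append(
                "health: plot table lacks reference/OFS treatments; using parameter-file contents"
            )
        artifacts["impact"] = outdir / "impact.json"
        with open(artifacts["impact"], "w") as fh:
            json.dump(assessment_to_dict(assessment, config.precision), fh, indent=2, sort_keys=True)
            fh.write("\n")
        log_lines.append("health: ok")
    except Exception as exc:
        log_lines.append(f"ERROR in stage {stage}: {exc}")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        raise

    artifacts["log"] = outdir / "run.log"
    artifacts["log"].write_text("\n".join(log_lines) + "\n")
    return artifacts
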