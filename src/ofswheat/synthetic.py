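"""Synthetic multi-site fertilization-trial generator.

Emulates a 5-site x 5-treatment x 3-replicate wheat trial so that every
downstream stage (summary statistics, ANOVA/LSD, nutritional yield, molar
ratios, health impact) can be exercised and calibrated without field data.

Model
-----
For plot (s, t, r):

    yield_str   = site_mean_s * f_t / mean(f) * eps_yield
    content_str = analyte_mean * g_{a,t} / mean(g_a) * eps_a

where f and g are multiplicative treatment effects (CK = 1 baseline) and
eps are mean-one noise terms — log-normal by default, truncated normal as
an alternative.  Treatment factors are normalized by their mean so that the
configured site means and analyte means are the expected marginal means.
Residual noise CVs are derived in closed form from the configured *total*
CVs by removing the structural (site, treatment) variance components, so
sample CVs recover the configured values.

A latent per-plot factor gives yield and grain-composition noise a negative
log-scale correlation (the agronomic "dilution" effect: high-yielding plots
carry lower mineral concentrations); its loading is
``yield_content_correlation``.

Each site draws from its own child PRNG stream spawned from the root seed,
so appending a site never perturbs earlier sites.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trial import ANALYTES, TREATMENTS, PlotRecord, ValidationError, records_to_frame

_ANALYTE_COLS = ANALYTES  # grain_fe, grain_mn, grain_cu, grain_zn, phytic_acid


def _as_tuple(x: Sequence[float]) -> tuple[float, ...]:
    return tuple(float(v) for v in x)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic trial generator.

    Treatment effects are multiplicative factors relative to the CK control;
    CVs are fractions (0.15 = 15%).  ``grain_cvs`` are *total* coefficients
    of variation across all plots, as reported by trial-level descriptive
    statistics.
    """

    n_sites: int = 5
    treatments: tuple[str, ...] = TREATMENTS
    n_reps: int = 3
    #: site mean yields, Mg ha^-1 (regional variation 7.07-9.85, grand mean 9.06)
    site_yield_means: tuple[float, ...] = (9.85, 9.60, 7.07, 9.45, 9.33)
    #: yield factors vs CK, calibrated to treatment means 8.00/8.95/9.30/9.58/9.47
    treatment_yield_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "CK": 1.0,
            "FP": 1.11875,
            "OPT": 1.1625,
            "OF15": 1.1975,
            "OF30": 1.18375,
        }
    )
    yield_cv: float = 0.1508  # total CV of yield across plots
    #: grand-mean grain composition (mg kg^-1; phytic_acid g kg^-1)
    grain_means: Mapping[str, float] = field(
        default_factory=lambda: {
            "grain_fe": 37.13,
            "grain_mn": 31.26,
            "grain_cu": 4.42,
            "grain_zn": 24.61,
            "phytic_acid": 8.5,
        }
    )
    #: total CVs of grain composition across plots
    grain_cvs: Mapping[str, float] = field(
        default_factory=lambda: {
            "grain_fe": 0.2756,
            "grain_mn": 0.1764,
            "grain_cu": 0.2360,
            "grain_zn": 0.1016,
            "phytic_acid": 0.12,
        }
    )
    #: content factors vs CK per analyte.  Fe/Zn: organic substitution raises
    #: Fe by ~24.69% and Zn by ~19.19% over CK (and ~10.59% / ~13.99% over FP);
    #: Mn/Cu essentially flat; phytic acid slightly depressed under OFS.
    treatment_content_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "grain_fe": {"CK": 1.0, "FP": 1.1275, "OPT": 1.13, "OF15": 1.2469, "OF30": 1.2469},
            "grain_zn": {"CK": 1.0, "FP": 1.0456, "OPT": 1.072, "OF15": 1.1919, "OF30": 1.1919},
            "grain_mn": {"CK": 1.0, "FP": 1.019, "OPT": 1.051, "OF15": 1.011, "OF30": 0.942},
            "grain_cu": {"CK": 1.0, "FP": 0.894, "OPT": 0.923, "OF15": 0.994, "OF30": 0.967},
            "phytic_acid": {"CK": 1.0, "FP": 0.990, "OPT": 0.962, "OF15": 0.923, "OF30": 0.933},
        }
    )
    #: log-scale correlation between yield noise and every content noise
    yield_content_correlation: float = -0.3
    noise_model: str = "lognormal"  # or "truncnorm"
    seed: int = 0
    #: explicit residual (plot-level) noise CVs.  When None (default) they
    #: are derived from the total CVs by removing the site/treatment
    #: structural variance; pinning them makes the per-plot noise scale
    #: independent of the site list, so appending a site cannot perturb
    #: earlier sites even through the calibration.
    yield_residual_cv: float | None = None
    grain_residual_cvs: Mapping[str, float] | None = None

    def validate(self) -> None:
        if self.n_sites < 1 or self.n_reps < 1:
            raise ValidationError("n_sites and n_reps must be >= 1")
        if len(self.site_yield_means) != self.n_sites:
            raise ValidationError("site_yield_means length must equal n_sites")
        if any(m <= 0 for m in self.site_yield_means):
            raise ValidationError("site yield means must be > 0")
        if self.noise_model not in ("lognormal", "truncnorm"):
            raise ValidationError(f"unknown noise_model {self.noise_model!r}")
        if not -1 <= self.yield_content_correlation <= 1:
            raise ValidationError("yield_content_correlation must be in [-1, 1]")
        if self.yield_cv < 0 or any(cv < 0 for cv in self.grain_cvs.values()):
            raise ValidationError("CVs must be >= 0")
        if any(m <= 0 for m in self.grain_means.values()):
            raise ValidationError("grain means must be > 0")
        for t in self.treatments:
            if self.treatment_yield_effects.get(t, 0) <= 0:
                raise ValidationError(f"missing/non-positive yield effect for {t!r}")
            for a in _ANALYTE_COLS:
                if self.treatment_content_effects.get(a, {}).get(t, 0) <= 0:
                    raise ValidationError(f"missing/non-positive {a} effect for {t!r}")


def default_config(seed: int = 0) -> GeneratorConfig:
    """Configuration calibrated to the reference five-county Shandong trial."""
    return GeneratorConfig(seed=seed)


def _normalized_effects(effects: Mapping[str, float], treatments: Sequence[str]) -> np.ndarray:
    f = np.array([effects[t] for t in treatments], dtype=float)
    return f / f.mean()


def _pop_cv(values: np.ndarray) -> float:
    """Population (N-denominator) CV of a fixed set of level means."""
    return float(np.std(values) / np.mean(values))


def _residual_cv(total_cv: float, *structural_cvs: float) -> float:
    """Residual noise CV so that structural x residual variation totals ``total_cv``.

    Multiplicative independent components: 1 + cv_tot^2 = prod(1 + cv_i^2).
    Clipped at 0 when the structure alone exceeds the target.
    """
    denom = math.prod(1 + c * c for c in structural_cvs)
    ratio = (1 + total_cv * total_cv) / denom
    return math.sqrt(ratio - 1) if ratio > 1 else 0.0


def resolved_residual_cvs(cfg: GeneratorConfig) -> tuple[float, dict[str, float]]:
    """Residual plot-level noise CVs actually used for a config.

    Explicit values take precedence; otherwise they are backed out of the
    configured total CVs given the site and treatment structure.
    """
    treatments = cfg.treatments
    f_yield = _normalized_effects(cfg.treatment_yield_effects, treatments)
    if cfg.yield_residual_cv is not None:
        cv_yield = cfg.yield_residual_cv
    else:
        site_cv = _pop_cv(np.asarray(cfg.site_yield_means))
        cv_yield = _residual_cv(cfg.yield_cv, site_cv, _pop_cv(f_yield))
    cvs: dict[str, float] = {}
    for a in _ANALYTE_COLS:
        if cfg.grain_residual_cvs is not None and a in cfg.grain_residual_cvs:
            cvs[a] = cfg.grain_residual_cvs[a]
        else:
            g = _normalized_effects(cfg.treatment_content_effects[a], treatments)
            cvs[a] = _residual_cv(cfg.grain_cvs[a], _pop_cv(g))
    return cv_yield, cvs


def generate_trial(config: GeneratorConfig | None = None) -> list[PlotRecord]:
    """Generate one synthetic trial (n_sites x treatments x n_reps plots).

    Deterministic for a fixed config (including seed): identical configs
    produce bit-identical records.
    """
    cfg = config or default_config()
    cfg.validate()

    treatments = cfg.treatments
    f_yield = _normalized_effects(cfg.treatment_yield_effects, treatments)
    g = {a: _normalized_effects(cfg.treatment_content_effects[a], treatments) for a in _ANALYTE_COLS}

    cv_resid_yield, cv_resid = resolved_residual_cvs(cfg)

    rho = cfg.yield_content_correlation
    root = np.random.SeedSequence(cfg.seed)
    site_seeds = root.spawn(cfg.n_sites)

    records: list[PlotRecord] = []
    for s in range(cfg.n_sites):
        rng = np.random.default_rng(site_seeds[s])
        site_name = f"site{s + 1:02d}"
        for ti, t in enumerate(treatments):
            for rep in range(1, cfg.n_reps + 1):
                # latent plot factor couples yield and composition noise
                w_yield = rng.standard_normal()
                u = rng.standard_normal(len(_ANALYTE_COLS))
                w = {
                    a: rho * w_yield + math.sqrt(max(0.0, 1 - rho * rho)) * u[i]
                    for i, a in enumerate(_ANALYTE_COLS)
                }

                y_mean = cfg.site_yield_means[s] * f_yield[ti]
                y = y_mean * _noise(w_yield, cv_resid_yield, cfg.noise_model)
                contents = {
                    a: cfg.grain_means[a] * g[a][ti] * _noise(w[a], cv_resid[a], cfg.noise_model)
                    for a in _ANALYTE_COLS
                }
                records.append(
                    PlotRecord(
                        site=site_name,
                        treatment=t,
                        replicate=rep,
                        grain_yield=float(y),
                        grain_fe=float(contents["grain_fe"]),
                        grain_mn=float(contents["grain_mn"]),
                        grain_cu=float(contents["grain_cu"]),
                        grain_zn=float(contents["grain_zn"]),
                        phytic_acid=float(contents["phytic_acid"]),
                    )
                )
    return records


def _noise(w: float, cv: float, model: str) -> float:
    """Mean-one positive noise from a standard-normal draw ``w``."""
    if cv == 0:
        return 1.0
    if model == "lognormal":
        sigma = math.sqrt(math.log1p(cv * cv))
        return math.exp(sigma * w - 0.5 * sigma * sigma)
    # truncated normal: reflect draws that would go non-positive; slight
    # positive mean bias at extreme CVs, documented alternative model
    v = 1.0 + cv * w
    return abs(v) if v != 0 else 1e-12


@dataclass(frozen=True)
class RecoveredParameters:
    """Sample estimates used to check generator calibration."""

    yield_mean: float
    yield_cv: float
    grain_means: dict[str, float]
    grain_cvs: dict[str, float]
    #: treatment mean / CK mean, per variable ("yield" plus analytes)
    treatment_effects: dict[str, dict[str, float]]
    #: within-cell residual correlation of yield with each analyte
    yield_content_correlations: dict[str, float]


def recover_parameters(records: Sequence[PlotRecord]) -> RecoveredParameters:
    """Estimate generator parameters from a plot table.

    Means and CVs are overall sample statistics; treatment effects are
    ratios of treatment means to the CK mean; dilution correlations are
    Pearson correlations of residuals within site x treatment cells
    (removing the design structure).
    """
    if not records:
        raise ValidationError("cannot recover parameters from an empty record set")
    df = records_to_frame(records)

    def cv(x: pd.Series) -> float:
        return float(x.std(ddof=1) / x.mean())

    effects: dict[str, dict[str, float]] = {}
    for var in ("yield",) + _ANALYTE_COLS:
        tmeans = df.groupby("treatment")[var].mean()
        ck = tmeans.get("CK")
        effects[var] = {t: float(m / ck) for t, m in tmeans.items()} if ck else {}

    cell = df.groupby(["site", "treatment"])
    resid = df[["yield", *list(_ANALYTE_COLS)]] - cell[["yield", *list(_ANALYTE_COLS)]].transform("mean")
    corrs = {}
    for a in _ANALYTE_COLS:
        sy, sa = resid["yield"].std(), resid[a].std()
        corrs[a] = float(resid["yield"].corr(resid[a])) if sy > 0 and sa > 0 else float("nan")

    return RecoveredParameters(
        yield_mean=float(df["yield"].mean()),
        yield_cv=cv(df["yield"]),
        grain_means={a: float(df[a].mean()) for a in _ANALYTE_COLS},
        grain_cvs={a: cv(df[a]) for a in _ANALYTE_COLS},
        treatment_effects=effects,
        yield_content_correlations=corrs,
    )
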