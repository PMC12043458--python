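"""Inferential machinery from closed forms: one-way ANOVA, Fisher's LSD
post hoc with compact letter display, descriptive statistics, and Pearson
correlation.

Sums of squares, F and t criteria are written out explicitly (textbook
forms); only distribution functions come from scipy.  The compact letter
display uses the standard insert-and-absorb procedure, so two groups share
a letter if and only if the LSD test does not declare them different.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    """Preconditions for a statistical routine are not met."""


@dataclass(frozen=True)
class DescriptiveStats:
    """Mean, SD (n-1), median, range and CV% of one variable."""

    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    cv_percent: float


def describe(values: Sequence[float]) -> DescriptiveStats:
    """Descriptive statistics with sample SD and CV% = 100 * sd / mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise StatsError(f"describe requires >= 2 values, got {x.size}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return DescriptiveStats(
        n=int(x.size),
        mean=mean,
        sd=sd,
        median=float(np.median(x)),
        min=float(x.min()),
        max=float(x.max()),
        cv_percent=100.0 * sd / mean if mean != 0 else math.inf,
    )


@dataclass(frozen=True)
class AnovaResult:
    """One-way fixed-effects ANOVA decomposition."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    ss_between: float
    ss_within: float
    ms_between: float
    ms_within: float


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA from textbook sums of squares.

    ``F = MS_between / MS_within`` with ``df = (k-1, N-k)``; the p-value is
    the upper tail of the F distribution.  With zero within-group variance,
    F is 0 (all means equal, p = 1) or +inf (means differ, p = 0).
    """
    if len(groups) < 2:
        raise StatsError("ANOVA requires >= 2 groups")
    arrays = {}
    for name, vals in groups.items():
        a = np.asarray(vals, dtype=float)
        if a.size < 2:
            raise StatsError(f"group {name!r} has {a.size} observation(s); >= 2 required")
        arrays[name] = a

    all_x = np.concatenate(list(arrays.values()))
    grand = all_x.mean()
    n_total = all_x.size
    k = len(arrays)

    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values()))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays.values()))
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w

    if ms_w == 0.0:
        f = 0.0 if ss_between == 0.0 else math.inf
        p = 1.0 if ss_between == 0.0 else 0.0
    else:
        f = ms_b / ms_w
        p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(f, df_b, df_w, p, ss_between, ss_within, ms_b, ms_w)


@dataclass(frozen=True)
class TreatmentSummary:
    """Per-group mean +/- SD with significance letters for one variable."""

    variable: str
    treatment: str
    n: int
    mean: float
    sd: float
    letters: str


def lsd_significant_pairs(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> tuple[AnovaResult, dict[tuple[str, str], bool]]:
    """Pairwise LSD decisions: (i, j) different iff
    ``|mean_i - mean_j| > t(1 - alpha/2, df_w) * sqrt(MS_w * (1/n_i + 1/n_j))``.

    Unprotected by default (decisions reported whatever the ANOVA p); pass
    the result through :func:`fisher_lsd_letters` for the letter display.
    """
    if not 0 < alpha < 1:
        raise StatsError(f"alpha must be in (0, 1), got {alpha}")
    anova = one_way_anova(groups)
    names = list(groups)
    means = {g: float(np.mean(np.asarray(groups[g], dtype=float))) for g in names}
    ns = {g: len(groups[g]) for g in names}
    tcrit = float(sps.t.ppf(1 - alpha / 2, anova.df_within))
    decisions: dict[tuple[str, str], bool] = {}
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            lsd = tcrit * math.sqrt(anova.ms_within * (1 / ns[gi] + 1 / ns[gj]))
            diff = abs(means[gi] - means[gj]) > lsd
            decisions[(gi, gj)] = decisions[(gj, gi)] = diff
    return anova, decisions


def letters_from_decisions(
    order: Sequence[str], decisions: Mapping[tuple[str, str], bool]
) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    ``order`` lists the groups by descending mean (ties pre-broken by the
    caller); letters start at 'a' for the column containing the top group.
    Two groups share a letter iff their pair is not flagged in ``decisions``.
    """
    idx = {g: i for i, g in enumerate(order)}
    columns: list[set[str]] = [set(order)]
    for i, gi in enumerate(order):
        for gj in order[i + 1 :]:
            if not decisions.get((gi, gj), False):
                continue
            new_cols: list[set[str]] = []
            for col in columns:
                if gi in col and gj in col:
                    new_cols.append(col - {gj})
                    new_cols.append(col - {gi})
                else:
                    new_cols.append(col)
            # absorb: deduplicate, then drop any column properly contained
            # in another
            unique: list[set[str]] = []
            for c in new_cols:
                if c and c not in unique:
                    unique.append(c)
            columns = [c for c in unique if not any(c < o for o in unique)]
    # order columns by their highest-ranked member, then assign letters
    columns.sort(key=lambda c: min(idx[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assigned: dict[str, list[str]] = {g: [] for g in order}
    for li, col in enumerate(columns):
        letter = alphabet[li % 26] * (1 + li // 26)
        for g in col:
            assigned[g].append(letter)
    return {g: "".join(sorted(set(ls))) for g, ls in assigned.items()}


def fisher_lsd_letters(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    variable: str = "",
    protected: bool = False,
) -> list[TreatmentSummary]:
    """LSD post hoc letters for each group, in the input group order.

    Groups are ranked by descending mean for letter assignment (ties broken
    by input order, e.g. the conventional CK, FP, OPT, OF15, OF30 ordering).
    With ``protected=True`` pairwise tests are only performed when the
    omnibus ANOVA is significant at ``alpha``; otherwise all groups share
    the letter 'a'.
    """
    anova, decisions = lsd_significant_pairs(groups, alpha)
    if protected and anova.p_value >= alpha:
        decisions = {k: False for k in decisions}
    names = list(groups)
    means = {g: float(np.mean(np.asarray(groups[g], dtype=float))) for g in names}
    order = sorted(names, key=lambda g: (-means[g], names.index(g)))
    letters = letters_from_decisions(order, decisions)
    return [
        TreatmentSummary(
            variable=variable,
            treatment=g,
            n=len(groups[g]),
            mean=means[g],
            sd=float(np.std(np.asarray(groups[g], dtype=float), ddof=1)),
            letters=letters[g],
        )
        for g in names
    ]


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with a two-tailed p-value from the t transform (n-2 df)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise StatsError("x and y must have equal length")
    n = xa.size
    if n < 3:
        raise StatsError("pearson requires >= 3 paired observations")
    sx = xa.std(ddof=1)
    sy = ya.std(ddof=1)
    if sx == 0 or sy == 0:
        raise StatsError("pearson undefined for zero-variance input")
    r = float(((xa - xa.mean()) * (ya - ya.mean())).sum() / ((n - 1) * sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = float(2 * sps.t.sf(abs(t), n - 2))
    return r, p
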