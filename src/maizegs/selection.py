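"""Advancement rules and stage-II cohort comparisons.

Stage-I advancement uses an "above average" truncation rule: phenotyped lines
advance on their BLUEs, unphenotyped lines on their GEBVs, each judged against
the arithmetic mean of its own cohort.  Stage-II comparisons operate on hybrid
(line x tester) BLUEs: top-fraction means, best hybrids, commercial checks and
the integer percent yield improvements between them, plus the share of each
cohort among the jointly selected top fraction (the advancement rate).

All integer rounding here is round-half-up (0.5 rounds towards +inf), for both
top-k counts and percent cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SelectionDecision",
    "round_half_up",
    "select_above_average",
    "top_fraction",
    "percent_improvement",
    "ComparisonTable",
    "comparison_table",
    "advancement_rates",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (2.5 -> 3).

    A tiny epsilon guards exact .5 ties computed in floating point
    (e.g. 100 * (11.7 / 7.2 - 1) evaluates just below 62.5).
    """
    return int(math.floor(x + 0.5 + 1e-9))


@dataclass(frozen=True)
class SelectionDecision:
    line: str
    cohort: str
    value: float
    selected: bool
    rule: str


def select_above_average(values: pd.Series, cohort: str = "GS",
                         rule: str = "above-cohort-mean") -> list[SelectionDecision]:
    """Advance every line whose criterion is strictly above the cohort mean.

    ``values`` is indexed by line ID (BLUEs or GEBVs, trait units).  With all
    values identical nothing exceeds the mean: the selection is empty and a
    warning is issued.
    """
    vals = values.dropna()
    if len(vals) == 0:
        raise ValueError("need at least one line with a finite criterion value")
    mean = float(vals.mean())
    decisions = [
        SelectionDecision(line=str(i), cohort=cohort, value=float(v),
                          selected=bool(v > mean), rule=rule)
        for i, v in vals.items()
    ]
    if not any(d.selected for d in decisions):
        warnings.warn("all criterion values identical: empty selection")
    return decisions


def top_fraction(scores: pd.Series, fraction: float = 0.15) -> list[str]:
    """IDs of the top round-half-up(f*N) scorers, ties broken by input order."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    scores = scores.dropna()
    n = len(scores)
    if n == 0:
        raise ValueError("no entries with finite scores")
    n_sel = min(n, round_half_up(fraction * n))
    # stable sort on the negated score keeps earlier entries ahead on ties
    order = np.argsort(-scores.to_numpy(), kind="stable")[:n_sel]
    return [str(i) for i in scores.index[order]]


def percent_improvement(candidate_mean: float, reference_mean: float) -> int:
    """Integer percent gain of candidate over reference (may be negative)."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be > 0")
    return round_half_up(100.0 * (candidate_mean / reference_mean - 1.0))


@dataclass
class ComparisonTable:
    """Stage-II cohort summary per management level, checks kept separate.

    ``means`` rows: (management, cohort) -> all-hybrid mean, top-fraction mean,
    best hybrid, checks mean, best check (trait units).  ``improvements`` holds
    the four integer percent contrasts per (management, cohort).
    """

    fraction: float
    means: pd.DataFrame
    improvements: pd.DataFrame

    def render(self) -> str:
        lines = [f"Stage-II cohort comparison (top fraction = {self.fraction:g})", ""]
        lines.append(self.means.round(2).to_string())
        lines.append("")
        lines.append("Yield improvement (%):")
        lines.append(self.improvements.to_string())
        return "\n".join(lines)


def comparison_table(stage2: pd.DataFrame, fraction: float = 0.15,
                     value_col: str = "value") -> ComparisonTable:
    """Build the cohort-vs-check comparison from hybrid BLUEs.

    ``stage2`` needs columns ``entry``, ``cohort`` (PS / GS / check),
    ``management`` and the value column.  Checks never enter cohort statistics;
    each management level must include at least one check.
    """
    required = {"entry", "cohort", "management", value_col}
    missing = required - set(stage2.columns)
    if missing:
        raise ValueError(f"stage2 table missing columns: {sorted(missing)}")
    df = stage2.dropna(subset=[value_col])
    mean_rows, imp_rows = [], []
    for mgmt, grp in df.groupby("management", sort=True):
        checks = grp[grp["cohort"] == "check"]
        if checks.empty:
            raise ValueError(f"management {mgmt!r} has no check entries")
        checks_mean = float(checks[value_col].mean())
        best_check = float(checks[value_col].max())
        for cohort, cgrp in grp[grp["cohort"] != "check"].groupby("cohort", sort=True):
            scores = cgrp.set_index("entry")[value_col]
            top_ids = top_fraction(scores, fraction)
            top_mean = float(scores.loc[top_ids].mean())
            all_mean = float(scores.mean())
            best = float(scores.max())
            mean_rows.append({
                "management": mgmt, "cohort": cohort,
                "all_hybrids_mean": all_mean, "top_fraction_mean": top_mean,
                "best_hybrid": best, "checks_mean": checks_mean,
                "best_check": best_check, "n_hybrids": len(scores),
                "n_top": len(top_ids),
            })
            imp_rows.append({
                "management": mgmt, "cohort": cohort,
                "top_over_checks_mean": percent_improvement(top_mean, checks_mean),
                "top_over_best_check": percent_improvement(top_mean, best_check),
                "best_over_checks_mean": percent_improvement(best, checks_mean),
                "best_over_best_check": percent_improvement(best, best_check),
            })
    means = pd.DataFrame(mean_rows).set_index(["management", "cohort"])
    improvements = pd.DataFrame(imp_rows).set_index(["management", "cohort"])
    return ComparisonTable(fraction=fraction, means=means,
                           improvements=improvements)


def advancement_rates(scores: pd.Series, cohorts: pd.Series,
                      fraction: float = 0.15) -> dict[str, int]:
    """Cohort shares (integer %) of the pooled top fraction.

    Both cohorts compete in one ranking; the share of cohort c is
    round-half-up(100 * n_c_selected / n_selected).
    """
    cohorts = cohorts.reindex(scores.index)
    if cohorts.isna().any():
        raise ValueError("every scored entry needs a cohort label")
    present = sorted(cohorts.unique())
    if len(present) < 2:
        raise ValueError("advancement rates need two or more cohorts")
    selected = top_fraction(scores, fraction)
    if not selected:
        raise ValueError("empty selection")
    sel_cohorts = cohorts.loc[selected]
    return {c: round_half_up(100.0 * (sel_cohorts == c).sum() / len(selected))
            for c in present}
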