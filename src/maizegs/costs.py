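"""Breeding-program cost accounting.

Spreadsheet-style budgeting for comparing a conventional phenotypic-selection
(PS) stage-I campaign against a genotype-all / phenotype-half genomic-selection
(GS) strategy.  Each activity row carries a per-entry cost and the design
multipliers (entries, replicates per site, rows per site, sites); the activity
total is their product, strategy totals are sums over rows, and the headline
statistic is the GS:PS cost ratio.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "CostActivity",
    "CostLedger",
    "activity_cost",
    "strategy_cost",
    "cost_ratio",
    "read_ledger",
    "write_ledger",
    "example_ledgers",
    "cost_report",
]

_LEDGER_COLUMNS = [
    "strategy",
    "label",
    "cost_per_entry",
    "n_entries",
    "reps_per_site",
    "rows_per_site",
    "n_sites",
]


@dataclass(frozen=True)
class CostActivity:
    """One budget row: an activity costed per entry times design multipliers."""

    label: str
    cost_per_entry: float
    n_entries: float
    reps_per_site: float = 1
    rows_per_site: float = 1
    n_sites: float = 1

    def __post_init__(self) -> None:
        for name in ("cost_per_entry", "n_entries", "reps_per_site",
                     "rows_per_site", "n_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def cost(self) -> float:
        return activity_cost(self)


@dataclass
class CostLedger:
    """A strategy's list of budget activities (labels unique)."""

    strategy: str
    activities: list[CostActivity] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [a.label for a in self.activities]
        if len(set(labels)) != len(labels):
            raise ValueError("activity labels must be unique within a ledger")

    @property
    def total(self) -> float:
        return strategy_cost(self)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "strategy": self.strategy,
                "label": a.label,
                "cost_per_entry": a.cost_per_entry,
                "n_entries": a.n_entries,
                "reps_per_site": a.reps_per_site,
                "rows_per_site": a.rows_per_site,
                "n_sites": a.n_sites,
                "total_cost": a.cost,
            }
            for a in self.activities
        ]
        return pd.DataFrame(rows)


def activity_cost(a: CostActivity) -> float:
    """cost/entry x entries x reps/site x rows/site x sites.

    Integer inputs give exact integer dollar totals (spreadsheet parity).
    """
    return (a.cost_per_entry * a.n_entries * a.reps_per_site
            * a.rows_per_site * a.n_sites)


def strategy_cost(ledger: CostLedger) -> float:
    """Sum of activity costs; an empty ledger costs 0."""
    return sum(a.cost for a in ledger.activities)


def cost_ratio(gs_total: float, ps_total: float) -> float:
    """GS:PS cost ratio rounded to 2 decimals. Requires a positive PS total."""
    if ps_total <= 0:
        raise ValueError("PS total must be > 0 to form a cost ratio")
    return round(gs_total / ps_total, 2)


def read_ledger(path: str | Path) -> list[CostLedger]:
    """Read a ledger CSV (one row per activity, grouped by strategy label)."""
    df = pd.read_csv(path)
    missing = [c for c in _LEDGER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ledger CSV missing columns: {missing}")
    ledgers = []
    for strategy, grp in df.groupby("strategy", sort=False):
        acts = [
            CostActivity(
                label=r["label"],
                cost_per_entry=r["cost_per_entry"],
                n_entries=r["n_entries"],
                reps_per_site=r["reps_per_site"],
                rows_per_site=r["rows_per_site"],
                n_sites=r["n_sites"],
            )
            for _, r in grp.iterrows()
        ]
        ledgers.append(CostLedger(strategy=str(strategy), activities=acts))
    return ledgers


def write_ledger(ledgers: list[CostLedger], path: str | Path) -> None:
    pd.concat([l.to_frame() for l in ledgers], ignore_index=True).drop(
        columns="total_cost"
    ).to_csv(path, index=False)


def example_ledgers() -> dict[str, CostLedger]:
    """The bundled PS vs GS stage-I budget for a 1492-line DH cohort.

    PS testcrosses and yield-trials all 1492 lines; GS testcrosses and
    phenotypes the 855-line training half and genotypes everything.
    """
    ref = importlib.resources.files("maizegs.data") / "stage1_cost_ledger.csv"
    with importlib.resources.as_file(ref) as p:
        ledgers = read_ledger(p)
    return {l.strategy: l for l in ledgers}


def cost_report(ledgers: dict[str, CostLedger]) -> pd.DataFrame:
    """Totals per strategy plus the GS:PS ratio when both are present."""
    rows = [{"quantity": f"total_cost_{k}", "value": v.total}
            for k, v in ledgers.items()]
    if "GS" in ledgers and "PS" in ledgers:
        rows.append({
            "quantity": "gs_ps_cost_ratio",
            "value": cost_ratio(ledgers["GS"].total, ledgers["PS"].total),
        })
    return pd.DataFrame(rows)
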