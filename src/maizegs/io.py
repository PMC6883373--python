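"""Readers and writers for the pipeline's flat-file formats.

One CSV dialect throughout: comma separator, UTF-8, "." decimal, "NA" for
missing values.  Genotype files are lines x markers with a leading ``line``
column; phenotype files are long-format plot records; every writer's output
is re-readable by the matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

__all__ = [
    "PipelineConfig",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_blues",
    "write_blues",
    "write_grm",
    "read_grm",
    "read_config",
]

_NA = "NA"
PHENO_REQUIRED = ["trial", "location", "management", "rep", "block",
                  "entry", "tester", "cohort"]
VALID_MANAGEMENT = {"WW", "WS"}
VALID_CODES = {0.0, 1.0, 2.0}


class PipelineConfig(BaseModel):
    """Validated end-to-end pipeline configuration (JSON on disk)."""

    seed: int
    outdir: str = "maizegs_out"
    trait: str = "GY"
    genotype_csv: str | None = None
    phenotype_csv: str | None = None
    ledger_csv: str | None = None
    simulate: dict = Field(default_factory=dict)   # SimConfig overrides
    stage2: dict = Field(default_factory=dict)
    cv_folds: int = 5
    cv_repeats: int = 10
    chain: dict = Field(default_factory=dict)      # GenomicModelSpec overrides
    selection_fraction: float = Field(default=0.15, gt=0, le=1)
    train_fraction: float = Field(default=0.5, gt=0, lt=1)


def read_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.model_validate(json.load(fh))


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Lines x markers codes in {0, 1, 2, NA}; duplicate IDs rejected."""
    df = pd.read_csv(path, na_values=[_NA], keep_default_na=True)
    first = df.columns[0]
    df = df.rename(columns={first: "line"}).set_index("line")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate line IDs: {dup}")
    if df.columns.duplicated().any():
        raise ValueError("duplicate marker IDs")
    X = df.apply(pd.to_numeric, errors="coerce")
    bad = X.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric marker code at line {df.index[r]!r}, "
            f"marker {df.columns[c]!r}: {df.iat[r, c]!r}")
    vals = set(np.unique(X.to_numpy()[~np.isnan(X.to_numpy())]))
    illegal = vals - VALID_CODES
    if illegal:
        loc = np.argwhere(np.isin(X.to_numpy(), list(illegal)))[0]
        raise ValueError(
            f"invalid marker code {X.iat[loc[0], loc[1]]!r} at line "
            f"{X.index[loc[0]]!r}, marker {X.columns[loc[1]]!r} "
            "(expected 0, 1, 2 or NA)")
    return X


def write_genotypes(markers: pd.DataFrame, path: str | Path) -> None:
    out = markers.copy()
    out.index.name = "line"
    out.to_csv(path, na_rep=_NA)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Long-format plot records; trait columns are auto-detected as the
    numeric columns beyond the design factors."""
    df = pd.read_csv(path, na_values=[_NA])
    missing = [c for c in PHENO_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype CSV missing required columns: {missing}")
    bad_mgmt = set(df["management"].dropna().astype(str)) - VALID_MANAGEMENT
    if bad_mgmt:
        raise ValueError(
            f"unknown management labels {sorted(bad_mgmt)}; expected "
            f"{sorted(VALID_MANAGEMENT)}")
    traits = [c for c in df.columns if c not in PHENO_REQUIRED]
    if not traits:
        raise ValueError("phenotype CSV has no trait columns")
    for c in ("trial", "location", "rep", "block", "entry", "tester",
              "cohort"):
        df[c] = df[c].astype(str)
    for t in traits:
        df[t] = pd.to_numeric(df[t], errors="raise")
    return df


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    cols = PHENO_REQUIRED + [c for c in pheno.columns
                             if c not in PHENO_REQUIRED]
    pheno[cols].to_csv(path, index=False, na_rep=_NA)


def read_blues(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[_NA])
    need = {"line", "environment", "value"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"BLUE CSV missing columns: {sorted(missing)}")
    df["line"] = df["line"].astype(str)
    return df


def write_blues(blues: pd.DataFrame, path: str | Path) -> None:
    blues.to_csv(path, index=False, na_rep=_NA)


def write_grm(grm, path: str | Path) -> None:
    grm.to_frame().rename_axis("line").to_csv(path, na_rep=_NA)


def read_grm(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if not df.index.equals(df.columns):
        raise ValueError("GRM CSV must have identical row and column IDs")
    return df
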