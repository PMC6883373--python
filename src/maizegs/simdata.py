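"""Synthetic doubled-haploid populations and multi-environment testcross trials.

The generator emulates a two-stage tropical maize testcross program: a set of
bi-parental DH families genotyped with dominant presence/absence sequence-tag
markers, testcrossed and evaluated in alpha-lattice yield trials across
well-watered (WW) locations plus one managed drought (WS) location.

Genetics: each DH line is one recombinant F1 gamete doubled to homozygosity;
crossovers follow the Haldane (no-interference) model, i.e. a Poisson process
at 1 event per Morgan along each chromosome.  Genetic values are additive over
a configurable number of QTL placed at marker positions, with effects rescaled
so the line-set variance hits the configured sigma2_G exactly per management.

Phenotypes: plot value = management mean + location + rep-within-location +
incomplete-block effect + genetic value + (WW only) line-by-location
interaction + residual, all Gaussian at the configured variances.  Commercial
checks are fixed-value entries replicated in every trial but absent from the
marker matrix, mirroring how checks carry phenotypes but no genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "SimConfig",
    "TruthSet",
    "default_stage1_config",
    "simulate_dh_population",
    "simulate_population_set",
    "simulate_trials",
    "simulate_stage2_trials",
    "TABLE1_FAMILY_SIZES",
]

# genotyped DH family sizes of the emulated 12-family stage-I cohort
TABLE1_FAMILY_SIZES = [34, 181, 185, 240, 162, 134, 180, 110, 40, 51, 75, 100]


class SimConfig(BaseModel):
    """Scenario description for one simulated stage of the program."""

    n_populations: int = Field(ge=1)
    lines_per_population: list[int]
    n_chromosomes: int = Field(default=10, ge=1)
    chrom_length_cM: float = Field(default=150.0, gt=0)
    markers_per_chromosome: int | list[int] = 466
    n_qtl: int = Field(default=100, ge=1)
    environments: list[tuple[str, Literal["WW", "WS"]]]
    n_reps: int = Field(default=2, ge=1)
    blocks_per_rep: int = Field(default=10, ge=1)
    n_trials: int = Field(default=1, ge=1)
    # per management: (sigma2_G, sigma2_GxE, sigma2_e) in trait units^2
    variance_targets: dict[str, tuple[float, float, float]]
    trait_means: dict[str, float]
    sigma2_location: float = Field(default=0.42, ge=0)
    sigma2_rep: float = Field(default=0.02, ge=0)
    sigma2_block: float = Field(default=0.05, ge=0)
    n_checks: int = Field(default=6, ge=0)
    marker_coding: Literal["dominant", "additive"] = "dominant"
    trait: str = "GY"
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if len(self.lines_per_population) != self.n_populations:
            raise ValueError("lines_per_population length must equal n_populations")
        if any(n < 1 for n in self.lines_per_population):
            raise ValueError("all population sizes must be >= 1")
        for mgmt, (vg, vge, ve) in self.variance_targets.items():
            if min(vg, vge, ve) < 0:
                raise ValueError(f"negative variance target for {mgmt!r}")
        for _, mgmt in self.environments:
            if mgmt not in self.variance_targets:
                raise ValueError(f"no variance targets for management {mgmt!r}")
        mpc = self.markers_per_chromosome
        if isinstance(mpc, list):
            if len(mpc) != self.n_chromosomes:
                raise ValueError("markers_per_chromosome list length must "
                                 "equal n_chromosomes")
            if any(m < 1 for m in mpc):
                raise ValueError("markers_per_chromosome must be >= 1")
        elif mpc < 1:
            raise ValueError("markers_per_chromosome must be >= 1")
        return self

    @property
    def n_lines(self) -> int:
        return sum(self.lines_per_population)

    @property
    def marker_counts(self) -> list[int]:
        mpc = self.markers_per_chromosome
        return list(mpc) if isinstance(mpc, list) else \
            [mpc] * self.n_chromosomes

    @property
    def n_markers(self) -> int:
        return sum(self.marker_counts)


def default_stage1_config(seed: int = 1, **overrides) -> SimConfig:
    """Stage-I-shaped scenario: 12 DH families totalling 1492 lines, 4657
    dominant markers, 3 WW + 1 WS environments, 2 reps, and grain-yield
    variance components in the magnitude range of the emulated program."""
    params = dict(
        n_populations=12,
        lines_per_population=list(TABLE1_FAMILY_SIZES),
        markers_per_chromosome=[466] * 7 + [465] * 3,
        environments=[("WW1", "WW"), ("WW2", "WW"), ("WW3", "WW"), ("WS1", "WS")],
        variance_targets={"WW": (0.19, 0.18, 1.41), "WS": (0.17, 0.0, 0.33)},
        trait_means={"WW": 6.03, "WS": 3.25},
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


@dataclass
class TruthSet:
    """Ground truth for recovery tests: per-line genetic values by management,
    per-environment interaction deviations, QTL positions/effects, and the
    plot-level heritability implied by the configured variances."""

    line_ids: list[str]
    g: pd.DataFrame                      # index line, columns managements
    ge: pd.DataFrame | None              # index line, columns WW env labels
    qtl_index: np.ndarray
    qtl_effects: pd.DataFrame            # index qtl marker, columns managements
    check_values: pd.DataFrame | None    # index check id, columns managements
    entry_mean_h2: dict[str, float]

    def env_value(self, env: str, mgmt: str) -> pd.Series:
        """True testcross genetic value per line in one environment."""
        v = self.g[mgmt].copy()
        if self.ge is not None and env in self.ge.columns:
            v = v + self.ge[env]
        return v

    def to_frame(self) -> pd.DataFrame:
        df = self.g.copy()
        df.index.name = "line"
        return df.reset_index()


def _genetic_map(config: SimConfig) -> list[np.ndarray]:
    """Equally spaced marker positions (cM) per chromosome."""
    return [np.linspace(0.0, config.chrom_length_cM, m)
            for m in config.marker_counts]


def _meiosis(positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Parental origin (0/1) at each position for one gamete under Haldane.

    Crossovers form a Poisson process with intensity 1/Morgan; the phase at
    a position flips with each crossover to its left.
    """
    length_m = positions[-1] / 100.0 if len(positions) else 0.0
    n_co = rng.poisson(length_m)
    start = rng.integers(0, 2)
    if n_co == 0:
        return np.full(len(positions), start, dtype=np.int8)
    xo = np.sort(rng.uniform(0.0, positions[-1], size=n_co))
    flips = np.searchsorted(xo, positions, side="left")
    return ((start + flips) % 2).astype(np.int8)


def simulate_dh_population(parent_a: np.ndarray, parent_b: np.ndarray,
                           n_lines: int, genetic_map: list[np.ndarray],
                           rng: np.random.Generator | int,
                           coding: str = "dominant") -> np.ndarray:
    """Derive ``n_lines`` DH lines from the cross parent_a x parent_b.

    Parents are haplotypes over the mapped markers (0/1 tag presence,
    concatenated over chromosomes).  Each line is a single recombinant gamete
    doubled to full homozygosity, so lines are homozygous everywhere and a
    family segregates 1:1 at each polymorphic marker.  Returns the marker-code
    matrix: tag presence 0/1 under ``dominant`` coding, or 0/2 allele dosage
    under ``additive`` coding (homozygous lines carry 0 or 2 copies).
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    parent_a = np.asarray(parent_a, dtype=np.int8)
    parent_b = np.asarray(parent_b, dtype=np.int8)
    p = sum(len(pos) for pos in genetic_map)
    if parent_a.shape != (p,) or parent_b.shape != (p,):
        raise ValueError("parent haplotype length must match the genetic map")
    if np.array_equal(parent_a, parent_b):
        raise ValueError("monomorphic cross: parents are identical at every marker")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    geno = np.empty((n_lines, p), dtype=np.int8)
    for i in range(n_lines):
        origin = np.concatenate([_meiosis(pos, rng) for pos in genetic_map])
        geno[i] = np.where(origin == 0, parent_a, parent_b)
    if coding == "additive":
        geno = geno * 2
    return geno


def simulate_population_set(config: SimConfig):
    """All DH families of a scenario: marker matrix, truth set, line metadata.

    Returns ``(genotypes, truth)`` where ``genotypes`` is a line x marker
    DataFrame of codes and ``truth`` the :class:`TruthSet`.  Fully
    deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    gmap = _genetic_map(config)
    p = config.n_markers
    blocks, line_ids = [], []
    for k, n in enumerate(config.lines_per_population, start=1):
        # parents drawn per family; redraw B until the cross segregates
        parent_a = rng.integers(0, 2, size=p, dtype=np.int8)
        parent_b = rng.integers(0, 2, size=p, dtype=np.int8)
        while np.array_equal(parent_a, parent_b):    # pragma: no cover
            parent_b = rng.integers(0, 2, size=p, dtype=np.int8)
        geno = simulate_dh_population(parent_a, parent_b, n, gmap, rng,
                                      coding=config.marker_coding)
        blocks.append(geno)
        line_ids += [f"P{k:02d}_L{j:03d}" for j in range(1, n + 1)]
    X = np.vstack(blocks).astype(float)
    marker_ids = [f"M{m:05d}" for m in range(1, p + 1)]
    genotypes = pd.DataFrame(X, index=pd.Index(line_ids, name="line"),
                             columns=marker_ids)

    managements = sorted({m for _, m in config.environments})
    qtl_index = np.sort(rng.choice(p, size=min(config.n_qtl, p), replace=False))
    Xq = X[:, qtl_index]
    Xq = Xq - Xq.mean(axis=0)
    g_cols, eff_cols = {}, {}
    for mgmt in managements:
        target_vg = config.variance_targets[mgmt][0]
        beta = rng.standard_normal(len(qtl_index))
        g = Xq @ beta
        sd = g.std()
        scale = np.sqrt(target_vg) / sd if sd > 0 and target_vg > 0 else 0.0
        g_cols[mgmt] = g * scale
        eff_cols[mgmt] = beta * scale
    g = pd.DataFrame(g_cols, index=genotypes.index)
    qtl_effects = pd.DataFrame(eff_cols,
                               index=[marker_ids[i] for i in qtl_index])

    ww_envs = [e for e, m in config.environments if m == "WW"]
    ge = None
    if ww_envs:
        vge = config.variance_targets["WW"][1]
        ge = pd.DataFrame(
            rng.normal(0.0, np.sqrt(vge), size=(len(line_ids), len(ww_envs))),
            index=genotypes.index, columns=ww_envs)

    check_values = None
    if config.n_checks > 0:
        cv = {m: rng.normal(0.0, np.sqrt(config.variance_targets[m][0]),
                            size=config.n_checks) for m in managements}
        check_values = pd.DataFrame(
            cv, index=[f"CHK{c:02d}" for c in range(1, config.n_checks + 1)])

    h2 = {}
    for mgmt in managements:
        vg_t, vge_t, ve_t = config.variance_targets[mgmt]
        l = sum(1 for _, m in config.environments if m == mgmt)
        r = config.n_reps
        denom = vg_t + (vge_t / l if l > 1 else 0.0) + ve_t / (l * r)
        h2[mgmt] = vg_t / denom if denom > 0 else np.nan

    truth = TruthSet(line_ids=line_ids, g=g, ge=ge, qtl_index=qtl_index,
                     qtl_effects=qtl_effects, check_values=check_values,
                     entry_mean_h2=h2)
    return genotypes, truth


def _layout(entries: list[str], n_blocks: int,
            rng: np.random.Generator) -> pd.DataFrame:
    """Randomize entries into ``n_blocks`` incomplete blocks of near-equal size."""
    order = rng.permutation(len(entries))
    splits = np.array_split(order, n_blocks)
    rows = [{"entry": entries[i], "block": f"B{b + 1:02d}"}
            for b, idx in enumerate(splits) for i in idx]
    return pd.DataFrame(rows)


def simulate_trials(truth: TruthSet, config: SimConfig) -> pd.DataFrame:
    """Plot-level phenotypes for every environment of the scenario.

    Entries (lines plus checks) are split over ``n_trials`` trials; checks are
    replicated in every trial so trials stay connected.  WW environments
    receive the line-by-location deviations from ``truth``; the WS environment
    follows the single-environment model with no interaction term.  Returns a
    long-format table with columns trial, location, management, rep, block,
    entry, tester, cohort and the trait.
    """
    rng = np.random.default_rng(config.seed + 104729)  # independent stream
    lines = list(truth.line_ids)
    checks = (list(truth.check_values.index)
              if truth.check_values is not None else [])
    trial_lines = [list(a) for a in np.array_split(np.array(lines), config.n_trials)]
    env_effects = {env: rng.normal(0.0, np.sqrt(config.sigma2_location))
                   for env, _ in config.environments}
    records = []
    for t, tlines in enumerate(trial_lines, start=1):
        entries = tlines + checks
        for env, mgmt in config.environments:
            _, _, ve = config.variance_targets[mgmt]
            mean = config.trait_means[mgmt]
            for rep in range(1, config.n_reps + 1):
                rep_eff = rng.normal(0.0, np.sqrt(config.sigma2_rep))
                n_blocks = min(config.blocks_per_rep, len(entries))
                lay = _layout(entries, n_blocks, rng)
                block_eff = {b: rng.normal(0.0, np.sqrt(config.sigma2_block))
                             for b in lay["block"].unique()}
                resid = rng.normal(0.0, np.sqrt(ve), size=len(lay))
                for (_, row), eps in zip(lay.iterrows(), resid):
                    entry = row["entry"]
                    if entry in truth.g.index:
                        gval = float(truth.env_value(env, mgmt).loc[entry])
                        cohort = "GS"
                    else:
                        gval = float(truth.check_values.loc[entry, mgmt])
                        cohort = "check"
                    records.append({
                        "trial": f"T{t:02d}", "location": env,
                        "management": mgmt, "rep": f"R{rep}",
                        "block": row["block"], "entry": entry,
                        "tester": "T1", "cohort": cohort,
                        config.trait: mean + env_effects[env] + rep_eff
                        + block_eff[row["block"]] + gval + eps,
                    })
    return pd.DataFrame(records)


def simulate_stage2_trials(line_values: pd.DataFrame, cohorts: pd.Series,
                           config: SimConfig,
                           testers: tuple[str, ...] = ("TA", "TB", "TC"),
                           sigma2_tester: float = 0.3,
                           sigma2_line_tester: float = 0.2,
                           drop_hybrids: int = 0) -> pd.DataFrame:
    """Stage-II trials: selected lines crossed to common testers.

    ``line_values`` gives true line values per management (index line);
    hybrid value = line value + tester effect + line x tester deviation.
    ``drop_hybrids`` removes that many random line x tester combinations,
    mimicking failed crosses.  Returns a plot-level table in which ``entry``
    is the hybrid (line/tester) and ``cohort`` carries the PS/GS label of the
    underlying line.
    """
    rng = np.random.default_rng(config.seed + 224737)
    managements = sorted({m for _, m in config.environments})
    hybrids = [(ln, ts) for ln in line_values.index for ts in testers]
    if drop_hybrids:
        keep = rng.choice(len(hybrids), size=len(hybrids) - drop_hybrids,
                          replace=False)
        hybrids = [hybrids[i] for i in sorted(keep)]
    tester_eff = {(ts, m): rng.normal(0.0, np.sqrt(sigma2_tester))
                  for ts in testers for m in managements}
    hyb_ids = [f"{ln}/{ts}" for ln, ts in hybrids]
    g_cols = {}
    for m in managements:
        lt = rng.normal(0.0, np.sqrt(sigma2_line_tester), size=len(hybrids))
        g_cols[m] = np.array([
            line_values.loc[ln, m] + tester_eff[(ts, m)] + d
            for (ln, ts), d in zip(hybrids, lt)
        ])
    g = pd.DataFrame(g_cols, index=hyb_ids)

    n_checks = config.n_checks
    check_values = pd.DataFrame(
        {m: rng.normal(0.0, np.sqrt(config.variance_targets[m][0]), n_checks)
         for m in managements},
        index=[f"CHK{c:02d}" for c in range(1, n_checks + 1)])
    ww_envs = [e for e, m in config.environments if m == "WW"]
    ge = None
    if ww_envs:
        vge = config.variance_targets["WW"][1]
        ge = pd.DataFrame(rng.normal(0.0, np.sqrt(vge),
                                     size=(len(hyb_ids), len(ww_envs))),
                          index=hyb_ids, columns=ww_envs)
    truth = TruthSet(line_ids=hyb_ids, g=g, ge=ge,
                     qtl_index=np.array([], dtype=int),
                     qtl_effects=pd.DataFrame(), check_values=check_values,
                     entry_mean_h2={})
    pheno = simulate_trials(truth, config)
    hyb_cohort = {f"{ln}/{ts}": cohorts.loc[ln] for ln, ts in hybrids}
    pheno["cohort"] = pheno["entry"].map(lambda e: hyb_cohort.get(e, "check"))
    pheno["tester"] = pheno["entry"].map(
        lambda e: e.split("/")[-1] if e in hyb_cohort else "check")
    return pheno
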