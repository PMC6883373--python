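"""End-to-end two-stage genomic-selection pipeline on simulated data.

Stage I: simulate DH families and testcross trials; phenotype a training
fraction of the lines; estimate per-environment BLUEs; build the GRM; fit the
genomic model per management level; predict GEBVs of the unphenotyped
holdout; advance lines with above-average BLUEs (PS cohort, from phenotyped
lines) or above-average GEBVs (GS cohort, from the holdout); optionally
cross-validate the training set.

Stage II: cross the advanced lines of both cohorts to common testers,
simulate multi-location trials of the hybrids alongside commercial checks,
estimate hybrid BLUEs per management, and produce the cohort comparison
table, the advancement-rate shares, and the PS-vs-GS cost report.

Every stochastic step derives its stream from the single config seed, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import costs as costs_mod
from . import io as mio
from .crossval import make_folds, run_cv
from .genomic import GenomicModelSpec, build_grm, fit_genomic, predict_gebv
from .pheno import fit_multi_location, fit_single_location
from .selection import (advancement_rates, comparison_table,
                        select_above_average, top_fraction)
from .simdata import (default_stage1_config, simulate_stage2_trials,
                      simulate_population_set, simulate_trials)

__all__ = ["run_pipeline", "stage1_blues_per_environment", "stage2_blues"]

logger = logging.getLogger(__name__)


def stage1_blues_per_environment(pheno: pd.DataFrame, trait: str,
                                 lines: set[str] | None = None) -> pd.DataFrame:
    """Per-location BLUEs (entry fixed) stacked into a line x environment
    table ready for the genomic model.  Check entries are dropped."""
    out = []
    for env, sub in pheno.groupby("location"):
        fit = fit_single_location(sub, trait, genotype_role="fixed")
        checks = set(sub.loc[sub["cohort"] == "check", "entry"])
        b = fit.blues[~fit.blues["entry"].isin(checks)]
        if lines is not None:
            b = b[b["entry"].isin(lines)]
        out.append(pd.DataFrame({"line": b["entry"], "environment": env,
                                 "value": b["blue"]}))
    return pd.concat(out, ignore_index=True)


def stage2_blues(pheno2: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Hybrid BLUEs per management level (entry = hybrid), checks included."""
    rows = []
    for mgmt, sub in pheno2.groupby("management"):
        if sub["location"].nunique() > 1:
            fit = fit_multi_location(sub, trait, genotype_role="fixed")
        else:
            fit = fit_single_location(sub, trait, genotype_role="fixed")
        cohort = sub.drop_duplicates("entry").set_index("entry")["cohort"]
        b = fit.blues.copy()
        b["management"] = mgmt
        b["cohort"] = b["entry"].map(cohort)
        rows.append(b)
    return pd.concat(rows, ignore_index=True)


def run_pipeline(config: mio.PipelineConfig, outdir: str | Path | None = None,
                 write: bool = True) -> dict:
    """Run both stages from one validated config; returns a result dict."""
    out = Path(outdir or config.outdir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    sim_overrides = dict(config.simulate)
    sim_cfg = default_stage1_config(seed=config.seed, **sim_overrides)
    genotypes, truth = simulate_population_set(sim_cfg)
    pheno = simulate_trials(truth, sim_cfg)
    logger.info("simulated %d lines, %d markers, %d plots",
                genotypes.shape[0], genotypes.shape[1], len(pheno))

    # phenotype a training fraction of each family; the rest is the holdout
    lines = pd.Index(truth.line_ids)
    fams = lines.str.split("_").str[0]
    train_lines: list[str] = []
    for fam in fams.unique():
        fam_lines = list(lines[fams == fam])
        n_train = max(1, int(round(config.train_fraction * len(fam_lines))))
        picked = rng.choice(fam_lines, size=n_train, replace=False)
        train_lines += [str(x) for x in picked]
    train_set = set(train_lines)
    holdout = [l for l in lines if l not in train_set]
    checks = set(pheno.loc[pheno["cohort"] == "check", "entry"])
    pheno_obs = pheno[pheno["entry"].isin(train_set | checks)]

    blues = stage1_blues_per_environment(pheno_obs, sim_cfg.trait)
    grm = build_grm(genotypes)

    ww_envs = [e for e, m in sim_cfg.environments if m == "WW"]
    ws_envs = [e for e, m in sim_cfg.environments if m == "WS"]
    chain = dict(config.chain)
    chain.setdefault("seed", config.seed + 1)

    fits, gebv_tables = {}, []
    if ww_envs:
        variant = "E+G+GE+e" if len(ww_envs) > 1 else "E+G+e"
        spec_ww = GenomicModelSpec(variant=chain.pop("variant_ww", variant),
                                   **chain)
        fits["WW"] = fit_genomic(blues[blues["environment"].isin(ww_envs)],
                                 grm, spec_ww)
        chain["variant_ww"] = spec_ww.variant
    if ws_envs:
        spec_ws = GenomicModelSpec(variant="G+e",
                                   **{k: v for k, v in chain.items()
                                    if k != "variant_ww"})
        fits["WS"] = fit_genomic(blues[blues["environment"].isin(ws_envs)],
                                 grm, spec_ws)
    for mgmt, fit in fits.items():
        t = predict_gebv(fit, holdout)
        t["management"] = mgmt
        gebv_tables.append(t)
    gebv = pd.concat(gebv_tables, ignore_index=True)

    cv_table = None
    if config.cv_repeats > 0 and ww_envs:
        plan = make_folds(sorted(train_set), k=config.cv_folds,
                          n_repeats=config.cv_repeats, seed=config.seed + 2)
        cv_spec = fits["WW"].spec if "WW" in fits else fits["WS"].spec
        cv_table = run_cv(blues[blues["environment"].isin(ww_envs)], grm,
                          cv_spec, plan)

    # advancement: PS on mean WW BLUE of phenotyped lines, GS on holdout GEBV
    sel_mgmt = "WW" if ww_envs else "WS"
    ps_crit = (blues[blues["environment"].isin(ww_envs or ws_envs)]
               .groupby("line")["value"].mean())
    gs_crit = (gebv[gebv["management"] == sel_mgmt]
               .set_index("line")["gebv"])
    ps_dec = select_above_average(ps_crit, cohort="PS")
    gs_dec = select_above_average(gs_crit, cohort="GS")
    ps_adv = [d.line for d in ps_dec if d.selected]
    gs_adv = [d.line for d in gs_dec if d.selected]
    cap = config.stage2.get("capacity_per_cohort")
    if cap:
        ps_adv = top_fraction(ps_crit.loc[ps_adv], min(1.0, cap / len(ps_adv)))
        gs_adv = top_fraction(gs_crit.loc[gs_adv], min(1.0, cap / len(gs_adv)))

    # stage II: advanced lines x common testers, plus checks
    cohorts = pd.Series("PS", index=ps_adv).combine_first(
        pd.Series("GS", index=gs_adv))
    adv = list(ps_adv) + list(gs_adv)
    st2_over = {k: v for k, v in config.stage2.items()
                if k != "capacity_per_cohort"}
    st2_over.setdefault("environments",
                        [["WW1", "WW"], ["WW2", "WW"], ["WS1", "WS"]])
    st2_over.setdefault("trait_means", {"WW": 7.59, "WS": 3.23})
    st2_cfg = default_stage1_config(seed=config.seed + 3, **{
        "lines_per_population": [len(adv)], "n_populations": 1, **st2_over})
    pheno2 = simulate_stage2_trials(truth.g.loc[adv], cohorts, st2_cfg,
                                    drop_hybrids=st2_over.get("drop_hybrids", 0))
    blues2 = stage2_blues(pheno2, st2_cfg.trait)
    comp = comparison_table(
        blues2.rename(columns={"blue": "value"}),
        fraction=config.selection_fraction)
    adv_rates = {}
    for mgmt, sub in blues2.groupby("management"):
        hy = sub[sub["cohort"] != "check"].set_index("entry")
        adv_rates[mgmt] = advancement_rates(hy["blue"], hy["cohort"],
                                            fraction=config.selection_fraction)

    if config.ledger_csv:
        ledgers = {l.strategy: l
                   for l in costs_mod.read_ledger(config.ledger_csv)}
    else:
        ledgers = costs_mod.example_ledgers()
    cost_rep = costs_mod.cost_report(ledgers)

    result = {
        "config": config, "sim_config": sim_cfg, "genotypes": genotypes,
        "truth": truth, "pheno": pheno, "blues": blues, "grm": grm,
        "gebv": gebv, "cv": cv_table, "fits": fits,
        "train_lines": sorted(train_set), "holdout_lines": holdout,
        "ps_advanced": ps_adv, "gs_advanced": gs_adv,
        "stage2_blues": blues2, "comparison": comp,
        "advancement_rates": adv_rates, "cost_report": cost_rep,
    }
    if write:
        mio.write_genotypes(genotypes, out / "genotypes.csv")
        mio.write_phenotypes(pheno, out / "phenotypes_stage1.csv")
        mio.write_blues(blues, out / "blues_stage1.csv")
        mio.write_grm(grm, out / "grm.csv")
        gebv.to_csv(out / "gebv_holdout.csv", index=False)
        if cv_table is not None:
            cv_table.to_csv(out / "cv_accuracy.csv", index=False)
        blues2.to_csv(out / "blues_stage2.csv", index=False)
        comp.means.to_csv(out / "comparison_means.csv")
        comp.improvements.to_csv(out / "comparison_improvements.csv")
        (out / "comparison_table.txt").write_text(comp.render() + "\n")
        cost_rep.to_csv(out / "cost_report.csv", index=False)
        summary = {
            "seed": config.seed,
            "n_lines": int(genotypes.shape[0]),
            "n_markers": int(genotypes.shape[1]),
            "n_train": len(train_set), "n_holdout": len(holdout),
            "n_ps_advanced": len(ps_adv), "n_gs_advanced": len(gs_adv),
            "advancement_rates": adv_rates,
            "cv": (cv_table.to_dict("records") if cv_table is not None
                   else None),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return result
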