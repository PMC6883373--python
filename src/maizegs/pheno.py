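"""Mixed-model analysis of multi-environment testcross trials.

Three model variants over plot records Y with design factors location (L),
replicate within location (R), incomplete block within replicate (B), and
entry (G):

* multi-location:  Y = mu + L + R(L) + B[R(L)] + G + GxL + e
* single-location: Y = mu + R + B(R) + G + e
* across-trials:   multi-location model plus a fixed trial effect, with
  trials connected through common check entries.

Location, replicate (and trial) are fixed; blocks are random.  With
``genotype_role="fixed"`` the fit returns BLUEs (adjusted entry means with
standard errors) and GxL stays random; with ``genotype_role="random"`` it
returns entry BLUPs plus the variance components sigma2_B(RL), sigma2_G,
sigma2_GxL and sigma2_e estimated by REML, from which the entry-mean
broad-sense heritability, LSD and CV% summaries derive:

    h2  = s2_G / (s2_G + s2_GxL / l + s2_e / (l r))
    LSD = t(1 - alpha/2, df_e) * sqrt(2 s2_e / (l r))
    CV% = 100 * sqrt(s2_e) / grand mean
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import fit_mixed_model, incidence_matrix

__all__ = [
    "ModelFit",
    "TraitSummary",
    "ModelRankError",
    "fit_multi_location",
    "fit_single_location",
    "fit_across_trials",
    "trait_summary",
    "entry_mean_h2",
]


class ModelRankError(RuntimeError):
    """The fixed design is rank-deficient or saturated for this layout."""


@dataclass
class ModelFit:
    model: str
    trait: str
    genotype_role: str
    n_locations: int
    n_reps: int
    varcomp: dict[str, float]
    blues: pd.DataFrame | None
    blups: pd.Series | None
    fixed_effects: pd.Series
    grand_mean: float
    loglik: float
    converged: bool
    df_residual: int
    n_obs: int
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TraitSummary:
    h2: float
    lsd: float
    cv_pct: float
    grand_mean: float


def _required(pheno: pd.DataFrame, cols: set[str], trait: str) -> pd.DataFrame:
    missing = (cols | {trait}) - set(pheno.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    df = pheno.dropna(subset=[trait]).copy()
    if df.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    return df


def _dummies(labels: pd.Series, drop_first: bool) -> tuple[np.ndarray, list[str]]:
    d = pd.get_dummies(labels.astype(str), drop_first=drop_first, dtype=float)
    return d.to_numpy(), list(d.columns)


def _fit(df: pd.DataFrame, trait: str, genotype_role: str, model: str,
         with_location: bool, with_trial: bool,
         metadata: dict | None = None) -> ModelFit:
    if genotype_role not in ("fixed", "random"):
        raise ValueError("genotype_role must be 'fixed' or 'random'")
    y = df[trait].to_numpy(dtype=float)
    entries = df["entry"].astype(str)
    entry_levels = sorted(entries.unique())
    locs = sorted(df["location"].astype(str).unique())
    n_loc = len(locs)
    n_rep = int(df.groupby("location")["rep"].nunique().max())

    cols: list[np.ndarray] = [np.ones((len(df), 1))]
    names: list[str] = ["intercept"]
    weights: list[float] = [1.0]        # averaging weights for adjusted means

    if with_trial:
        tr_mat, tr_names = _dummies(df["trial"], drop_first=True)
        n_trial = df["trial"].nunique()
        cols.append(tr_mat)
        names += [f"trial[{t}]" for t in tr_names]
        weights += [1.0 / n_trial] * len(tr_names)
    if with_location:
        loc_mat, loc_names = _dummies(df["location"], drop_first=True)
        cols.append(loc_mat)
        names += [f"location[{x}]" for x in loc_names]
        weights += [1.0 / n_loc] * len(loc_names)
    # replicate within location: drop the first rep of each location
    locrep = df["location"].astype(str) + ":" + df["rep"].astype(str)
    first_rep = {loc: sorted(df.loc[df["location"].astype(str) == loc, "rep"]
                             .astype(str).unique())[0] for loc in locs}
    rep_keep = [lv for lv in sorted(locrep.unique())
                if lv.split(":", 1)[1] != first_rep[lv.split(":", 1)[0]]]
    if rep_keep:
        rep_all = pd.get_dummies(locrep, dtype=float)
        cols.append(rep_all[rep_keep].to_numpy())
        names += [f"rep[{x}]" for x in rep_keep]
        weights += [1.0 / (n_loc * n_rep)] * len(rep_keep)

    n_fixed_base = sum(c.shape[1] for c in cols)
    if genotype_role == "fixed":
        ent_mat, ent_names = _dummies(entries, drop_first=True)
        cols.append(ent_mat)
        names += [f"entry[{e}]" for e in ent_names]
        weights += [0.0] * len(ent_names)
    X = np.hstack(cols)

    random_terms: dict = {}
    levels: dict = {}
    blk = (df["location"].astype(str) + ":" + df["rep"].astype(str)
           + ":" + df["block"].astype(str))
    if df.groupby(["location", "rep"])["block"].nunique().max() > 1:
        random_terms["block"], levels["block"] = incidence_matrix(blk)
    if genotype_role == "random":
        random_terms["genotype"], levels["genotype"] = incidence_matrix(entries)
    if with_location and n_loc > 1:
        gxl = entries + "@" + df["location"].astype(str)
        random_terms["gxl"], levels["gxl"] = incidence_matrix(gxl)

    try:
        res = fit_mixed_model(y, X, random_terms, fixed_names=names)
    except ValueError as exc:
        raise ModelRankError(str(exc)) from exc
    except np.linalg.LinAlgError as exc:
        raise ModelRankError(
            f"rank-deficient fixed design for model {model!r}: {exc}") from exc

    w = np.array(weights + [0.0] * (X.shape[1] - len(weights)))
    fixed = pd.Series(res.beta, index=names)

    blues = blups = None
    if genotype_role == "fixed":
        ent_cols = [i for i, nm in enumerate(names) if nm.startswith("entry[")]
        ent_of_col = {names[i][6:-1]: i for i in ent_cols}
        rows = []
        for e in entry_levels:
            c = w.copy()
            if e in ent_of_col:
                c[ent_of_col[e]] = 1.0
            rows.append({
                "entry": e,
                "blue": float(c @ res.beta),
                "se": float(np.sqrt(c @ res.beta_cov @ c)),
                "n_obs": int((entries == e).sum()),
            })
        blues = pd.DataFrame(rows)
        grand_mean = float(blues["blue"].mean())
    else:
        u = res.blup.get("genotype", np.zeros(len(entry_levels)))
        blups = pd.Series(u, index=levels["genotype"], name="blup")
        grand_mean = float(w @ res.beta)

    varcomp = dict(res.varcomp)
    return ModelFit(model=model, trait=trait,
                    genotype_role=genotype_role, n_locations=n_loc,
                    n_reps=n_rep, varcomp=varcomp, blues=blues, blups=blups,
                    fixed_effects=fixed, grand_mean=grand_mean,
                    loglik=res.loglik, converged=res.converged,
                    df_residual=res.df_residual, n_obs=len(df),
                    metadata=metadata or {})


def fit_multi_location(pheno: pd.DataFrame, trait: str,
                       genotype_role: str = "fixed") -> ModelFit:
    """Across-location fit; needs >= 2 locations (one management level)."""
    df = _required(pheno, {"location", "rep", "block", "entry"}, trait)
    if df["location"].nunique() < 2:
        raise ValueError("only one location present: use fit_single_location")
    return _fit(df, trait, genotype_role, "multi_location",
                with_location=True, with_trial=False)


def fit_single_location(pheno: pd.DataFrame, trait: str,
                        genotype_role: str = "fixed") -> ModelFit:
    """Single-site fit (the managed-drought model): no location or GxL terms."""
    df = _required(pheno, {"location", "rep", "block", "entry"}, trait)
    if df["location"].nunique() != 1:
        raise ValueError("fit_single_location requires exactly one location")
    return _fit(df, trait, genotype_role, "single_location",
                with_location=False, with_trial=False)


def _trial_connectivity(df: pd.DataFrame) -> bool:
    """True when every trial is linked to every other through shared entries."""
    trials = sorted(df["trial"].astype(str).unique())
    parent = {t: t for t in trials}

    def find(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for _, grp in df.groupby("entry"):
        ts = sorted(grp["trial"].astype(str).unique())
        for other in ts[1:]:
            parent[find(other)] = find(ts[0])
    return len({find(t) for t in trials}) == 1


def fit_across_trials(pheno: pd.DataFrame, trait: str,
                      genotype_role: str = "fixed") -> ModelFit:
    """Multi-trial fit with trial as an extra fixed effect.

    Entry means become comparable across trials through the shared checks; a
    connectivity warning is recorded in the fit metadata when some trials
    share no entries with the rest.
    """
    df = _required(pheno, {"trial", "location", "rep", "block", "entry"}, trait)
    if df["trial"].nunique() < 2:
        raise ValueError("fit_across_trials requires >= 2 trials")
    meta = {}
    if not _trial_connectivity(df):
        meta["connectivity_warning"] = (
            "trials are not all connected by shared entries; "
            "across-trial BLUEs are not mutually comparable")
        warnings.warn(meta["connectivity_warning"])
    with_location = df["location"].nunique() > 1
    return _fit(df, trait, genotype_role, "across_trials",
                with_location=with_location, with_trial=True, metadata=meta)


def entry_mean_h2(sigma2_g: float, sigma2_gxl: float, sigma2_e: float,
                  n_locations: int, n_reps: int) -> float:
    """Entry-mean broad-sense heritability for l locations and r reps."""
    denom = (sigma2_g + sigma2_gxl / n_locations
             + sigma2_e / (n_locations * n_reps))
    return sigma2_g / denom if denom > 0 else np.nan


def trait_summary(fit: ModelFit, alpha: float = 0.05) -> TraitSummary:
    """h2, LSD and CV% from a genotype-random fit."""
    if fit.genotype_role != "random":
        raise ValueError("trait_summary needs a fit with genotype_role='random'")
    l, r = fit.n_locations, fit.n_reps
    vg = fit.varcomp.get("genotype", 0.0)
    vgl = fit.varcomp.get("gxl", 0.0)
    ve = fit.varcomp["residual"]
    h2 = entry_mean_h2(vg, vgl if l > 1 else 0.0, ve, l, r)
    t = stats.t.ppf(1 - alpha / 2, fit.df_residual)
    lsd = float(t * np.sqrt(2.0 * ve / (l * r)))
    if fit.grand_mean == 0:
        raise ValueError("CV undefined: grand mean is zero")
    cv = float(100.0 * np.sqrt(ve) / abs(fit.grand_mean))
    return TraitSummary(h2=float(h2), lsd=lsd, cv_pct=cv,
                        grand_mean=fit.grand_mean)
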