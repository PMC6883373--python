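"""Genomic relationship matrix and Bayesian G-BLUP prediction.

The relationship matrix is G = Xs Xs' / p over the column-standardized marker
matrix (markers centered and scaled by their divisor-n standard deviation),
which pins mean(diag(G)) = 1 exactly.  Marker coding (0/1 dominant tags or
0/1/2 dosages) is immaterial after standardization.

Prediction models over line-by-environment means y_ij:

* G + e:          y_ij = mu + g_j + e_ij              (single environment)
* E + G + e:      y_ij = mu + E_i + g_j + e_ij
* E + G + GE + e: adds the reaction-norm interaction gE with covariance
                  (Z_g G Z_g') o (Z_E Z_E') sigma2_gE  (Hadamard product)

with g ~ N(0, G sigma2_g), e ~ N(0, I sigma2_e), flat priors on mu and E, and
scaled-inverse-chi-square priors on every variance component.  Inference is a
Gibbs sampler run in the eigenbasis of G restricted to phenotyped lines: when
every phenotyped line is observed in every environment the conditional
posterior of the eigen-coordinates is diagonal and one iteration costs O(n k);
unbalanced records fall back to a dense joint update (small problems only).
Posterior means are Rao-Blackwellized (averages of conditional means).

GEBVs of unphenotyped lines follow from the joint prior: conditional on the
phenotyped lines' values, E[g_miss | y] = G_mo G_oo^+ E[g_obs | y], so any
line in G can be predicted, and a line unrelated to all training lines gets
the prior mean 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "GRMatrix",
    "GenomicModelSpec",
    "GenomicFit",
    "build_grm",
    "fit_genomic",
    "predict_gebv",
]

_DENSE_LIMIT = 500


@dataclass
class GRMatrix:
    """Genomic relationship matrix with its standardization metadata."""

    values: np.ndarray
    line_ids: list[str]
    marker_means: np.ndarray
    marker_scales: np.ndarray
    n_markers: int

    def __post_init__(self) -> None:
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids,
                            columns=self.line_ids)

    def submatrix(self, rows: list[str], cols: list[str]) -> np.ndarray:
        pos = {l: i for i, l in enumerate(self.line_ids)}
        ri = [pos[l] for l in rows]
        ci = [pos[l] for l in cols]
        return self.values[np.ix_(ri, ci)]


def build_grm(markers: pd.DataFrame, missing_policy: str = "mean",
              scaling: str = "std") -> GRMatrix:
    """G = Xs Xs'/p from a lines x markers code matrix (0/1 or 0/1/2, NaN ok).

    Monomorphic markers are dropped; missing codes are mean-imputed per
    marker (``missing_policy="mean"``); columns are centered and, with
    ``scaling="std"``, divided by their divisor-n standard deviation.
    """
    if markers.index.duplicated().any():
        raise ValueError("duplicate line IDs in marker matrix")
    if markers.columns.duplicated().any():
        raise ValueError("duplicate marker IDs in marker matrix")
    X = markers.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 lines to build a relationship matrix")
    all_missing = np.isnan(X).all(axis=1)
    if all_missing.any():
        bad = [markers.index[i] for i in np.flatnonzero(all_missing)]
        raise ValueError(f"lines with all marker codes missing: {bad}")
    if missing_policy == "mean":
        mu = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = np.take(mu, idx[1])
    elif missing_policy == "error":
        if np.isnan(X).any():
            raise ValueError("missing marker codes present")
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    means = X.mean(axis=0)
    scales = X.std(axis=0)          # divisor n
    poly = scales > 0
    if not poly.any():
        raise ValueError("no polymorphic markers after filtering")
    Xs = X[:, poly] - means[poly]
    if scaling == "std":
        Xs = Xs / scales[poly]
    elif scaling != "center":
        raise ValueError(f"unknown scaling {scaling!r}")
    p = int(poly.sum())
    G = (Xs @ Xs.T) / p
    G = 0.5 * (G + G.T)
    return GRMatrix(values=G, line_ids=[str(i) for i in markers.index],
                    marker_means=means[poly], marker_scales=scales[poly],
                    n_markers=p)


class GenomicModelSpec(BaseModel):
    """Model variant, chain settings and prior hyperparameters."""

    variant: Literal["G+e", "E+G+e", "E+G+GE+e"] = "E+G+e"
    n_iter: int = Field(default=15000, ge=10)
    burn_in: int = Field(default=5000, ge=0)
    thin: int = Field(default=5, ge=1)
    seed: int
    df0: float = Field(default=5.0, gt=0)
    r2: float = Field(default=0.5, gt=0, lt=1)
    fix_variances: dict[str, float] | None = None

    @model_validator(mode="after")
    def _check(self) -> "GenomicModelSpec":
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        return self


@dataclass
class GenomicFit:
    """Posterior summaries of a fitted genomic model."""

    spec: GenomicModelSpec
    mu: float
    env_effects: pd.Series
    g: pd.Series                       # posterior mean per line (all G lines)
    g_sd: pd.Series
    ge: pd.DataFrame | None            # lines x environments, GxE models only
    var_g: float
    var_ge: float | None
    var_e: float
    var_samples: pd.DataFrame
    line_ids: list[str]
    environments: list[str]
    observed_lines: list[str]
    n_samples: int


def _eigen_basis(G_oo: np.ndarray):
    d, U = np.linalg.eigh(G_oo)
    if d.min() < -1e-8:
        raise ValueError(
            f"relationship matrix is not PSD: smallest eigenvalue {d.min():.3e}")
    keep = d > max(1e-12, 1e-12 * d.max())
    return d[keep], U[:, keep]


def fit_genomic(blues: pd.DataFrame, grm: GRMatrix,
                spec: GenomicModelSpec) -> GenomicFit:
    """Fit the genomic model to line-by-environment means.

    ``blues`` needs columns ``line``, ``environment`` and ``value``; every
    line must be present in ``grm``.  Fully reproducible given ``spec.seed``.
    """
    req = {"line", "environment", "value"}
    if not req <= set(blues.columns):
        raise ValueError(f"blues table needs columns {sorted(req)}")
    df = blues.dropna(subset=["value"]).copy()
    df["line"] = df["line"].astype(str)
    df["environment"] = df["environment"].astype(str)
    known = set(grm.line_ids)
    unknown = sorted(set(df["line"]) - known)
    if unknown:
        raise ValueError(f"lines absent from relationship matrix: {unknown}")
    envs = sorted(df["environment"].unique())
    if spec.variant == "G+e" and len(envs) != 1:
        raise ValueError("variant 'G+e' requires exactly one environment")
    if spec.variant == "E+G+GE+e" and len(envs) < 2:
        raise ValueError("variant 'E+G+GE+e' requires >= 2 environments")
    use_ge = spec.variant == "E+G+GE+e"

    obs_lines = sorted(df["line"].unique())
    n_o = len(obs_lines)
    line_pos = {l: i for i, l in enumerate(obs_lines)}
    df = df.sort_values(["environment", "line"], kind="stable")
    y = df["value"].to_numpy(dtype=float)
    n = len(y)
    env_codes = df["environment"].to_numpy()
    line_idx = df["line"].map(line_pos).to_numpy()
    env_slices = {e: np.flatnonzero(env_codes == e) for e in envs}
    counts = np.bincount(line_idx, minlength=n_o)

    balanced = (counts == counts[0]).all() and all(
        len(env_slices[e]) == n_o for e in envs)
    if not balanced and n_o > _DENSE_LIMIT:
        raise ValueError(
            "unbalanced line-by-environment records need the dense sampler, "
            f"which is limited to {_DENSE_LIMIT} phenotyped lines (got {n_o})")

    G_oo = grm.submatrix(obs_lines, obs_lines)
    d, U = _eigen_basis(G_oo)
    k = len(d)
    ZU = U[line_idx]                       # maps eigen-coordinates to records

    vy = float(np.var(y)) if n > 1 else 1.0
    n_terms = 2 if use_ge else 1
    s0_g = vy * spec.r2 / n_terms * (spec.df0 + 2) / spec.df0
    s0_ge = s0_g
    s0_e = vy * (1 - spec.r2) * (spec.df0 + 2) / spec.df0
    fixed = spec.fix_variances or {}
    var_g = fixed.get("g", vy * spec.r2 / n_terms)
    var_ge = fixed.get("ge", vy * spec.r2 / n_terms) if use_ge else None
    var_e = fixed.get("e", vy * (1 - spec.r2))

    rng = np.random.default_rng(spec.seed)
    beta = np.array([y[env_slices[e]].mean() for e in envs])
    beta_of_obs = {e: i for i, e in enumerate(envs)}
    env_col = np.array([beta_of_obs[e] for e in env_codes])
    alpha = np.zeros(k)
    alphaE = np.zeros((k, len(envs))) if use_ge else None

    keep_iters = range(spec.burn_in, spec.n_iter, spec.thin)
    n_keep = len(keep_iters)
    keep_set = set(keep_iters)
    sum_alpha = np.zeros(k)
    sum_beta = np.zeros(len(envs))
    sum_g = np.zeros(n_o)
    sum_g2 = np.zeros(n_o)
    sum_alphaE = np.zeros((k, len(envs))) if use_ge else None
    var_draws = {"var_g": [], "var_ge": [], "var_e": []}

    g_line = U @ alpha
    ge_line = (U @ alphaE) if use_ge else None      # lines x environments
    for it in range(spec.n_iter):
        ge_obs = ge_line[line_idx, env_col] if use_ge else 0.0
        # environment means (flat prior)
        r = y - g_line[line_idx] - ge_obs
        cond_beta = np.empty(len(envs))
        for i, e in enumerate(envs):
            sl = env_slices[e]
            cond_beta[i] = r[sl].mean()
            beta[i] = cond_beta[i] + rng.normal(0, np.sqrt(var_e / len(sl)))
        # main genomic effect in the eigenbasis
        r1 = y - beta[env_col] - ge_obs
        acc = np.bincount(line_idx, weights=r1, minlength=n_o)
        if balanced:
            t = U.T @ acc
            prec = counts[0] / var_e + 1.0 / (d * var_g)
            cmean = (t / var_e) / prec
            alpha = cmean + rng.standard_normal(k) / np.sqrt(prec)
        else:
            Q = (ZU.T @ ZU) / var_e + np.diag(1.0 / (d * var_g))
            L = np.linalg.cholesky(Q)
            rhs = (U.T @ acc) / var_e
            cmean = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
            alpha = cmean + np.linalg.solve(L.T, rng.standard_normal(k))
        g_line = U @ alpha
        g_rec = g_line[line_idx]
        # interaction deviations, one eigen-block per environment
        cmeanE = None
        if use_ge:
            cmeanE = np.empty_like(alphaE)
            r2v = y - beta[env_col] - g_rec
            for i, e in enumerate(envs):
                sl = env_slices[e]
                accE = np.bincount(line_idx[sl], weights=r2v[sl],
                                   minlength=n_o)
                if balanced:
                    tE = U.T @ accE
                    precE = 1.0 / var_e + 1.0 / (d * var_ge)
                    cmeanE[:, i] = (tE / var_e) / precE
                    alphaE[:, i] = (cmeanE[:, i]
                                    + rng.standard_normal(k) / np.sqrt(precE))
                else:
                    Ue = U[line_idx[sl]]
                    Q = (Ue.T @ Ue) / var_e + np.diag(1.0 / (d * var_ge))
                    L = np.linalg.cholesky(Q)
                    rhs = (U.T @ accE) / var_e
                    cmeanE[:, i] = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
                    alphaE[:, i] = cmeanE[:, i] + np.linalg.solve(
                        L.T, rng.standard_normal(k))
            ge_line = U @ alphaE
            ge_obs = ge_line[line_idx, env_col]
        # variance components: scaled-inverse-chi-square updates
        if "g" not in fixed:
            ssq = float(np.sum(alpha ** 2 / d))
            var_g = (ssq + spec.df0 * s0_g) / rng.chisquare(k + spec.df0)
        if use_ge and "ge" not in fixed:
            ssqE = float(np.sum(alphaE ** 2 / d[:, None]))
            var_ge = ((ssqE + spec.df0 * s0_ge)
                      / rng.chisquare(k * len(envs) + spec.df0))
        resid = y - beta[env_col] - g_rec - (ge_obs if use_ge else 0.0)
        if "e" not in fixed:
            var_e = ((float(resid @ resid) + spec.df0 * s0_e)
                     / rng.chisquare(n + spec.df0))
        if it in keep_set:
            sum_alpha += cmean
            sum_beta += cond_beta
            sum_g += g_line
            sum_g2 += g_line ** 2
            if use_ge:
                sum_alphaE += cmeanE
            var_draws["var_g"].append(var_g)
            var_draws["var_ge"].append(var_ge if use_ge else np.nan)
            var_draws["var_e"].append(var_e)

    # posterior summaries (Rao-Blackwellized means)
    g_obs_mean = U @ (sum_alpha / n_keep)
    g_obs_sd = np.sqrt(np.maximum(sum_g2 / n_keep
                                  - (sum_g / n_keep) ** 2, 0.0))
    beta_mean = sum_beta / n_keep
    mu = float(beta_mean.mean())
    env_eff = pd.Series(beta_mean - mu, index=envs, name="env_effect")

    # project to every line in G through the joint prior
    all_lines = grm.line_ids
    miss = [l for l in all_lines if l not in line_pos]
    g_all = pd.Series(0.0, index=all_lines, name="gebv")
    g_all.loc[obs_lines] = g_obs_mean
    sd_all = pd.Series(np.nan, index=all_lines, name="gebv_sd")
    sd_all.loc[obs_lines] = g_obs_sd
    ge_all = None
    proj = None
    if miss:
        G_mo = grm.submatrix(miss, obs_lines)
        proj = G_mo @ (U @ np.diag(1.0 / d) @ U.T)
        g_all.loc[miss] = proj @ g_obs_mean
    if use_ge:
        geo = U @ (sum_alphaE / n_keep)
        ge_all = pd.DataFrame(0.0, index=all_lines, columns=envs)
        ge_all.loc[obs_lines] = geo
        if miss:
            ge_all.loc[miss] = proj @ geo

    var_samples = pd.DataFrame(var_draws)
    return GenomicFit(
        spec=spec, mu=mu, env_effects=env_eff, g=g_all, g_sd=sd_all,
        ge=ge_all, var_g=float(var_samples["var_g"].mean()),
        var_ge=float(var_samples["var_ge"].mean()) if use_ge else None,
        var_e=float(var_samples["var_e"].mean()), var_samples=var_samples,
        line_ids=list(all_lines), environments=envs,
        observed_lines=obs_lines, n_samples=n_keep)


def predict_gebv(fit: GenomicFit, target_line_ids,
                 per_environment: bool = False) -> pd.DataFrame:
    """GEBVs for target lines (phenotyped or not) from a fitted model.

    With ``per_environment=True`` each row adds the environment effect and,
    when the interaction model was fitted, the line's gE deviation.
    """
    targets = [str(t) for t in target_line_ids]
    missing = sorted(set(targets) - set(fit.line_ids))
    if missing:
        raise KeyError(
            f"target lines absent from the relationship matrix: {missing}")
    if not per_environment:
        return pd.DataFrame({
            "line": targets,
            "gebv": fit.g.loc[targets].to_numpy(),
            "gebv_sd": fit.g_sd.loc[targets].to_numpy(),
        })
    rows = []
    for env in fit.environments:
        ge = (fit.ge.loc[targets, env].to_numpy()
              if fit.ge is not None else 0.0)
        rows.append(pd.DataFrame({
            "line": targets,
            "environment": env,
            "gebv": (fit.mu + fit.env_effects[env]
                     + fit.g.loc[targets].to_numpy() + ge),
        }))
    return pd.concat(rows, ignore_index=True)
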