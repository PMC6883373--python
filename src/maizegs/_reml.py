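"""Restricted maximum likelihood for Gaussian variance-component models.

Fits y = X b + sum_i Z_i u_i + e with u_i ~ N(0, I s2_i), e ~ N(0, I s2_e)
by average-information (AI) REML with EM-REML fallback steps.  All matrix
functionals of V = s2_e I + sum_i s2_i Z_i Z_i' are evaluated through the
Woodbury identity on the stacked sparse incidence matrix Z, so the dense work
scales with the number of random-effect levels q, not the number of plots n.

Conventions: the AI step is replaced by (damped) EM whenever it would leave
the parameter space or decrease the restricted likelihood; components are
kept nonnegative by projection onto a small floor relative to var(y), and a
component parked at the floor with a negative gradient is treated as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve

__all__ = ["REMLResult", "fit_mixed_model", "incidence_matrix"]


def incidence_matrix(labels) -> tuple[sp.csr_matrix, list]:
    """0/1 incidence matrix mapping observations to factor levels."""
    codes, levels = pd_factorize(labels)
    n = len(codes)
    Z = sp.csr_matrix((np.ones(n), (np.arange(n), codes)),
                      shape=(n, len(levels)))
    return Z, list(levels)


def pd_factorize(labels):
    import pandas as pd
    codes, levels = pd.factorize(np.asarray(labels), sort=True)
    if (codes < 0).any():
        raise ValueError("missing level in random-effect factor")
    return codes, levels


@dataclass
class REMLResult:
    varcomp: dict[str, float]            # per-term variances + "residual"
    beta: np.ndarray
    beta_cov: np.ndarray
    blup: dict[str, np.ndarray]
    loglik: float
    converged: bool
    n_iter: int
    df_residual: int
    fixed_names: list[str] = field(default_factory=list)


class _Woodbury:
    """V^-1 products for V = s2e I + Z D Z' at fixed variances."""

    def __init__(self, Z: sp.csr_matrix, T: np.ndarray, slices, sigma, s2e):
        self.Z, self.T, self.s2e = Z, T, s2e
        q = T.shape[0]
        dinv = np.empty(q)
        for sl, s2 in zip(slices, sigma):
            dinv[sl] = 1.0 / s2
        A = T / s2e + np.diag(dinv)
        self.chol = cho_factor(A, lower=True)
        self.logdet_A = 2.0 * np.sum(np.log(np.diag(self.chol[0])))
        self.M = cho_solve(self.chol, np.eye(q))

    def vinv(self, B: np.ndarray) -> np.ndarray:
        """V^-1 B for dense B (n x k) or (n,)."""
        ZtB = self.Z.T @ B
        return (B - self.Z @ (self.M @ ZtB) / self.s2e) / self.s2e


def _design_ok(X: np.ndarray) -> None:
    if X.ndim != 2:
        raise ValueError("X must be 2-D")


def fit_mixed_model(y, X, random_terms: dict[str, sp.csr_matrix],
                    max_iter: int = 200, tol: float = 1e-9,
                    init: dict[str, float] | None = None,
                    fixed_names: list[str] | None = None) -> REMLResult:
    """AI-REML fit; ``random_terms`` maps term name -> sparse incidence Z_i.

    Raises ``np.linalg.LinAlgError`` when X'V^-1 X is singular (rank-deficient
    fixed design) and ``ValueError`` on a saturated model (no residual df).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    _design_ok(X)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X row counts differ")
    names = list(random_terms)
    Zs = [sp.csr_matrix(random_terms[k]) for k in names]
    qs = [Z.shape[1] for Z in Zs]
    Z = sp.hstack(Zs, format="csr") if Zs else sp.csr_matrix((n, 0))
    offs = np.concatenate([[0], np.cumsum(qs)]).astype(int)
    slices = [slice(offs[i], offs[i + 1]) for i in range(len(names))]
    T = (Z.T @ Z).toarray() if Z.shape[1] else np.zeros((0, 0))

    vary = float(np.var(y)) if n > 1 else 1.0
    if vary == 0.0:
        vary = 1.0
    floor = 1e-8 * vary
    df_res = n - p
    if df_res <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")

    m = len(names)
    sigma = np.full(m, vary / (m + 1) if m else vary, dtype=float)
    s2e = vary / (m + 1)
    if init:
        for i, k in enumerate(names):
            if k in init:
                sigma[i] = max(init[k], floor)
        s2e = max(init.get("residual", s2e), floor)

    at_floor = np.zeros(m, dtype=bool)
    loglik = -np.inf
    converged = False
    it = 0

    def functionals(sigma, s2e):
        """Everything the scores/AI/loglik need at the current variances."""
        W = _Woodbury(Z, T, slices, sigma, s2e) if m else None
        if W is not None:
            VinvX = W.vinv(X)
            Vinvy = W.vinv(y)
        else:
            VinvX, Vinvy = X / s2e, y / s2e
        C = X.T @ VinvX
        Cc = cho_factor(C, lower=True)
        beta = cho_solve(Cc, X.T @ Vinvy)
        Py = Vinvy - VinvX @ beta
        # restricted loglik (constant terms dropped)
        if W is not None:
            logdet_V = (n * np.log(s2e)
                        + sum(q * np.log(s) for q, s in zip(qs, sigma))
                        + W.logdet_A)
        else:
            logdet_V = n * np.log(s2e)
        logdet_C = 2.0 * np.sum(np.log(np.diag(Cc[0])))
        ll = -0.5 * (logdet_V + logdet_C + float(y @ Py))
        # per-term traces and quadratic forms
        trs = np.empty(m)
        quads = np.empty(m)
        ZtPy = (Z.T @ Py) if m else np.zeros(0)
        if m:
            MT = W.M @ T
            ZtVinvX = Z.T @ VinvX            # q x p
            CinvZtX = cho_solve(Cc, ZtVinvX.T)   # p x q
        for i, sl in enumerate(slices):
            quads[i] = float(ZtPy[sl] @ ZtPy[sl])
            tr_vinv = (np.trace(T[sl, sl]) -
                       np.sum(T[:, sl] * MT[:, sl]) / s2e) / s2e
            tr_x = float(np.sum(ZtVinvX[sl].T * CinvZtX[:, sl]))
            trs[i] = tr_vinv - tr_x
        # residual term via tr(PV) = n - p
        trP = (df_res - float(sigma @ trs)) / s2e if m else df_res / s2e
        quad_e = float(Py @ Py)
        return dict(W=W, beta=beta, Cc=Cc, C=C, Py=Py, ll=ll, trs=trs,
                    quads=quads, trP=trP, quad_e=quad_e, ZtPy=ZtPy,
                    VinvX=VinvX)

    F = functionals(sigma, s2e)
    loglik = F["ll"]

    for it in range(1, max_iter + 1):
        # scores: dl/ds2_i = -0.5 (tr(P Zi Zi') - y'P Zi Zi'P y)
        score = 0.5 * np.concatenate([F["quads"] - F["trs"],
                                      [F["quad_e"] - F["trP"]]])
        theta = np.concatenate([sigma, [s2e]])

        # EM proposal (always valid, guaranteed uphill)
        em = theta.copy()
        for i in range(m):
            em[i] = theta[i] + theta[i] ** 2 * (F["quads"][i] - F["trs"][i]) / qs[i]
        em[m] = theta[m] + theta[m] ** 2 * (F["quad_e"] - F["trP"]) / df_res

        # AI proposal after the first iteration; step-halve on overshoot,
        # clamp boundary components to the floor, fall back to EM if the
        # restricted likelihood still will not improve
        proposals = []
        if it > 1:
            Wcols = []
            for i, sl in enumerate(slices):
                Wcols.append(Zs[i] @ F["ZtPy"][sl])
            Wcols.append(F["Py"].copy())
            Wmat = np.column_stack(Wcols)
            if F["W"] is not None:
                VinvW = F["W"].vinv(Wmat)
            else:
                VinvW = Wmat / s2e
            PW = VinvW - F["VinvX"] @ cho_solve(F["Cc"], X.T @ VinvW)
            AI = 0.5 * (Wmat.T @ PW)
            frozen = at_floor & (score[:m] < 0)
            free = np.concatenate([~frozen, [True]])
            try:
                step = np.zeros(m + 1)
                step[free] = np.linalg.solve(AI[np.ix_(free, free)],
                                             score[free])
                for halve in range(4):
                    proposals.append(theta + step / 2 ** halve)
            except np.linalg.LinAlgError:
                pass
        proposals.append(em)

        Fn = None
        for cand in proposals:
            new_sigma = np.maximum(cand[:m], floor)
            new_s2e = max(cand[m], floor)
            try:
                Fc = functionals(new_sigma, new_s2e)
            except np.linalg.LinAlgError:
                continue
            if Fc["ll"] >= F["ll"] - 1e-10 or cand is em:
                Fn = Fc
                break
        if Fn is None:       # pragma: no cover - EM is always evaluable
            break

        delta = np.max(np.abs(np.concatenate([new_sigma, [new_s2e]]) - theta))
        sigma, s2e, F = new_sigma, new_s2e, Fn
        at_floor = sigma <= floor * (1 + 1e-12)
        loglik = F["ll"]
        if delta < tol * vary:
            converged = True
            break

    beta = F["beta"]
    beta_cov = cho_solve(F["Cc"], np.eye(p))
    blup = {}
    for i, (k, sl) in enumerate(zip(names, slices)):
        blup[k] = sigma[i] * np.asarray(F["ZtPy"][sl]).ravel()
    varcomp = {k: (0.0 if at_floor[i] else float(sigma[i]))
               for i, k in enumerate(names)}
    varcomp["residual"] = float(s2e)
    return REMLResult(varcomp=varcomp, beta=beta, beta_cov=beta_cov,
                      blup=blup, loglik=float(loglik), converged=converged,
                      n_iter=it, df_residual=df_res,
                      fixed_names=fixed_names or [])
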