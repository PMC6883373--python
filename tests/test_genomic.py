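import numpy as np
import pandas as pd
import pytest

from maizegs._reml import incidence_matrix
from maizegs.genomic import (GenomicModelSpec, GRMatrix, build_grm,
                             fit_genomic, predict_gebv)


def _random_markers(n, p, seed=0, index=None):
    rng = np.random.default_rng(seed)
    idx = index or [f"L{i:03d}" for i in range(n)]
    return pd.DataFrame(rng.integers(0, 2, (n, p)).astype(float), index=idx,
                        columns=[f"M{j}" for j in range(p)])


def mme_gblup(y, G, s2g, s2e):
    """Dense mixed-model-equations oracle for [mu, g] with flat prior on mu."""
    n = len(y)
    Ginv = np.linalg.inv(G + 1e-10 * np.eye(n))
    A = np.zeros((n + 1, n + 1))
    A[0, 0] = n
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = np.eye(n) + (s2e / s2g) * Ginv
    sol = np.linalg.solve(A, np.concatenate([[y.sum()], y]))
    return sol[0], sol[1:]


class TestGRM:
    def test_mean_diagonal_exactly_one(self):
        g = build_grm(_random_markers(30, 100, seed=1))
        assert np.diag(g.values).mean() == pytest.approx(1.0, abs=1e-12)

    def test_brute_force_oracle_on_four_line_toy(self):
        X = pd.DataFrame([[0, 1], [1, 0], [1, 1], [0, 0]],
                         index=list("abcd"), columns=["m1", "m2"],
                         dtype=float)
        g = build_grm(X)
        Xn = X.to_numpy()
        Xs = (Xn - Xn.mean(0)) / Xn.std(0)
        assert np.allclose(g.values, Xs @ Xs.T / 2, atol=1e-12)

    def test_duplicate_marker_rows_duplicate_relationships(self):
        M = _random_markers(10, 50, seed=2)
        M.iloc[1] = M.iloc[0]
        g = build_grm(M)
        assert np.allclose(g.values[0], g.values[1], atol=1e-12)
        # duplicated lines make G rank-deficient
        assert np.linalg.matrix_rank(g.values, tol=1e-8) < g.n_lines

    def test_monomorphic_markers_dropped(self):
        M = _random_markers(12, 20, seed=3)
        M["mono"] = 1.0
        g = build_grm(M)
        assert g.n_markers == 20

    def test_all_monomorphic_rejected(self):
        M = pd.DataFrame(np.ones((5, 4)), index=list("abcde"))
        with pytest.raises(ValueError, match="polymorphic"):
            build_grm(M)

    def test_all_missing_line_named_in_error(self):
        M = _random_markers(6, 10, seed=4)
        M.iloc[2] = np.nan
        with pytest.raises(ValueError, match="L002"):
            build_grm(M)

    def test_missing_codes_mean_imputed(self):
        M = _random_markers(20, 40, seed=5)
        M.iloc[0, 0] = np.nan
        g = build_grm(M)
        assert np.isfinite(g.values).all()

    def test_duplicate_ids_rejected(self):
        M = _random_markers(4, 5, seed=6, index=["a", "a", "b", "c"])
        with pytest.raises(ValueError, match="duplicate line"):
            build_grm(M)


class TestFitGenomic:
    def test_posterior_mean_matches_dense_mme_at_fixed_variances(self):
        """With variance updates disabled the Gibbs posterior mean of g is
        the mixed-model-equations G-BLUP solution."""
        rng = np.random.default_rng(1)
        grm = build_grm(_random_markers(8, 30, seed=1))
        y = rng.normal(5, 1, 8)
        blues = pd.DataFrame({"line": grm.line_ids, "environment": "E1",
                              "value": y})
        s2g, s2e = 0.7, 0.5
        spec = GenomicModelSpec(variant="G+e", n_iter=30000, burn_in=3000,
                                thin=1, seed=11,
                                fix_variances={"g": s2g, "e": s2e})
        fit = fit_genomic(blues, grm, spec)
        mu, g = mme_gblup(y, grm.values, s2g, s2e)
        assert fit.mu == pytest.approx(mu, abs=1e-3)
        assert np.abs(fit.g.to_numpy() - g).max() < 1e-3

    def test_constant_phenotype_gives_null_gebvs(self):
        grm = build_grm(_random_markers(12, 40, seed=2))
        blues = pd.DataFrame({"line": grm.line_ids, "environment": "E1",
                              "value": 4.2})
        spec = GenomicModelSpec(variant="G+e", n_iter=2000, burn_in=500,
                                thin=2, seed=3)
        fit = fit_genomic(blues, grm, spec)
        assert fit.mu == pytest.approx(4.2, abs=0.05)
        assert np.abs(fit.g.to_numpy()).max() < 0.05

    def test_phenotype_shift_absorbed_by_mean(self):
        grm = build_grm(_random_markers(25, 60, seed=3))
        rng = np.random.default_rng(4)
        blues = pd.DataFrame({"line": grm.line_ids, "environment": "E1",
                              "value": rng.normal(0, 1, 25)})
        spec = GenomicModelSpec(variant="G+e", n_iter=1500, burn_in=500,
                                thin=2, seed=5)
        f0 = fit_genomic(blues, grm, spec)
        f1 = fit_genomic(blues.assign(value=blues["value"] + 50), grm, spec)
        assert np.abs(f1.g - f0.g).max() < 1e-10
        assert f1.mu - f0.mu == pytest.approx(50, abs=1e-8)

    def test_same_seed_bitwise_reproducible(self):
        grm = build_grm(_random_markers(15, 30, seed=6))
        rng = np.random.default_rng(7)
        blues = pd.DataFrame({"line": grm.line_ids, "environment": "E1",
                              "value": rng.normal(0, 1, 15)})
        spec = GenomicModelSpec(variant="G+e", n_iter=800, burn_in=200,
                                thin=2, seed=9)
        a = fit_genomic(blues, grm, spec)
        b = fit_genomic(blues, grm, spec)
        assert (a.g == b.g).all()
        assert a.var_samples.equals(b.var_samples)

    def test_ge_variance_near_zero_reduces_to_main_effects_model(self):
        rng = np.random.default_rng(8)
        n = 40
        grm = build_grm(_random_markers(n, 120, seed=8))
        L = np.linalg.cholesky(grm.values + 1e-6 * np.eye(n))
        g = L @ rng.standard_normal(n)
        rows = []
        for e in ("WW1", "WW2"):
            rows.append(pd.DataFrame({
                "line": grm.line_ids, "environment": e,
                "value": 3 + g + rng.normal(0, 0.5, n)}))
        blues = pd.concat(rows)
        base = GenomicModelSpec(variant="E+G+e", n_iter=6000, burn_in=1000,
                                thin=2, seed=10,
                                fix_variances={"g": 1.0, "e": 0.25})
        inter = GenomicModelSpec(variant="E+G+GE+e", n_iter=6000,
                                 burn_in=1000, thin=2, seed=10,
                                 fix_variances={"g": 1.0, "e": 0.25,
                                                "ge": 1e-8})
        f0 = fit_genomic(blues, grm, base)
        f1 = fit_genomic(blues, grm, inter)
        assert np.abs(f0.g - f1.g).max() < 0.02

    def test_heritability_recovery_single_environment(self):
        """Posterior variance ratio tracks the simulated h2 = 0.5 (compact
        version; the multi-seed average runs in the acceptance suite)."""
        n = 250
        grm = build_grm(_random_markers(n, 500, seed=12))
        L = np.linalg.cholesky(grm.values + 1e-6 * np.eye(n))
        ratios = []
        for seed in (0, 1):
            rng = np.random.default_rng(40 + seed)
            g = L @ rng.standard_normal(n)
            y = 5 + g + rng.normal(0, 1.0, n)
            blues = pd.DataFrame({"line": grm.line_ids,
                                  "environment": "E1", "value": y})
            spec = GenomicModelSpec(variant="G+e", n_iter=3000, burn_in=1000,
                                    thin=2, seed=seed)
            fit = fit_genomic(blues, grm, spec)
            ratios.append(fit.var_g / (fit.var_g + fit.var_e))
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.12)

    def test_non_psd_matrix_reports_smallest_eigenvalue(self):
        bad = np.array([[1.0, 0.999], [0.999, 1.0]])
        bad[0, 1] = bad[1, 0] = 1.2      # forces a negative eigenvalue
        grm = GRMatrix(values=bad, line_ids=["a", "b"],
                       marker_means=np.zeros(1), marker_scales=np.ones(1),
                       n_markers=1)
        blues = pd.DataFrame({"line": ["a", "b"], "environment": "E1",
                              "value": [1.0, 2.0]})
        spec = GenomicModelSpec(variant="G+e", n_iter=100, burn_in=10,
                                seed=1)
        with pytest.raises(ValueError, match="eigenvalue"):
            fit_genomic(blues, grm, spec)

    def test_chain_settings_validated(self):
        with pytest.raises(ValueError, match="burn_in"):
            GenomicModelSpec(variant="G+e", n_iter=100, burn_in=100, seed=1)

    def test_variant_environment_mismatch(self):
        grm = build_grm(_random_markers(6, 10, seed=13))
        two_env = pd.concat([
            pd.DataFrame({"line": grm.line_ids, "environment": e,
                          "value": 1.0}) for e in ("A", "B")])
        spec = GenomicModelSpec(variant="G+e", n_iter=100, burn_in=10,
                                seed=1)
        with pytest.raises(ValueError, match="exactly one environment"):
            fit_genomic(two_env, grm, spec)


class TestPredictGEBV:
    def _fit_with_holdout(self, n=60, n_train=40, seed=20, h2_noise=0.3):
        grm = build_grm(_random_markers(n, 200, seed=seed))
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(grm.values + 1e-6 * np.eye(n))
        g = L @ rng.standard_normal(n)
        train = grm.line_ids[:n_train]
        blues = pd.DataFrame({
            "line": train, "environment": "E1",
            "value": 5 + g[:n_train] + rng.normal(0, h2_noise, n_train)})
        spec = GenomicModelSpec(variant="G+e", n_iter=2500, burn_in=500,
                                thin=2, seed=seed)
        return grm, g, fit_genomic(blues, grm, spec)

    def test_unrelated_line_predicted_at_prior_mean(self):
        grm, _, fit = self._fit_with_holdout()
        zrow = grm.values.copy()
        zrow[-1, :] = zrow[:, -1] = 0.0
        zrow[-1, -1] = 1.0
        grm2 = GRMatrix(values=zrow, line_ids=grm.line_ids,
                        marker_means=grm.marker_means,
                        marker_scales=grm.marker_scales,
                        n_markers=grm.n_markers)
        blues = pd.DataFrame({
            "line": grm.line_ids[:40], "environment": "E1",
            "value": np.linspace(4, 6, 40)})
        spec = GenomicModelSpec(variant="G+e", n_iter=1500, burn_in=500,
                                thin=2, seed=1)
        fit2 = fit_genomic(blues, grm2, spec)
        target = grm.line_ids[-1]
        assert predict_gebv(fit2, [target])["gebv"].iloc[0] == \
            pytest.approx(0.0, abs=1e-10)

    def test_duplicate_of_training_line_gets_its_gebv(self):
        M = _random_markers(30, 80, seed=21)
        M.loc["COPY"] = M.iloc[5]
        grm = build_grm(M)
        rng = np.random.default_rng(22)
        blues = pd.DataFrame({
            "line": grm.line_ids[:30], "environment": "E1",
            "value": rng.normal(5, 1, 30)})
        spec = GenomicModelSpec(variant="G+e", n_iter=2000, burn_in=500,
                                thin=2, seed=23)
        fit = fit_genomic(blues, grm, spec)
        got = predict_gebv(fit, ["COPY"])["gebv"].iloc[0]
        assert got == pytest.approx(fit.g.loc[grm.line_ids[5]], abs=1e-6)

    def test_masked_lines_recovered_at_high_heritability(self):
        """100 training + 50 masked lines at high h2: correlation between
        GEBV and true genetic value of the masked lines exceeds 0.5."""
        n, n_train = 150, 100
        grm = build_grm(_random_markers(n, 300, seed=24))
        rng = np.random.default_rng(25)
        L = np.linalg.cholesky(grm.values + 1e-6 * np.eye(n))
        g = L @ rng.standard_normal(n)
        blues = pd.DataFrame({
            "line": grm.line_ids[:n_train], "environment": "E1",
            "value": 5 + g[:n_train] + rng.normal(0, 0.5, n_train)})
        spec = GenomicModelSpec(variant="G+e", n_iter=3000, burn_in=1000,
                                thin=2, seed=26)
        fit = fit_genomic(blues, grm, spec)
        masked = grm.line_ids[n_train:]
        pred = predict_gebv(fit, masked)
        r = np.corrcoef(pred["gebv"], g[n_train:])[0, 1]
        assert r > 0.5

    def test_unknown_target_listed_in_error(self):
        _, _, fit = self._fit_with_holdout()
        with pytest.raises(KeyError, match="NOPE"):
            predict_gebv(fit, ["NOPE"])


def test_hadamard_interaction_kernel_is_block_diagonal():
    """With disjoint environments the reaction-norm covariance
    (Zg G Zg') o (ZE ZE') has no cross-environment covariance."""
    G = build_grm(_random_markers(5, 30, seed=30)).values
    lines = np.array([0, 1, 2, 3, 4, 0, 1, 2, 3, 4])
    envs = np.array(["A"] * 5 + ["B"] * 5)
    Zg, _ = incidence_matrix(lines)
    Ze, _ = incidence_matrix(envs)
    K = np.asarray(Zg @ G @ Zg.T) * (Ze @ Ze.T).toarray()
    assert np.allclose(K[:5, 5:], 0.0)
    assert np.allclose(K[:5, :5], G)
    assert np.allclose(K[5:, 5:], G)
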