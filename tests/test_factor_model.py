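"""Factor-analysis internals checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest

import fiberfa as ff
from fiberfa.factor import (ConvergenceError, MappingError, kmo_from_corr,
                            quartimin_value, zscore)

R3 = np.array([[1.0, 0.6, 0.3],
               [0.6, 1.0, 0.2],
               [0.3, 0.2, 1.0]])


def partial_corr_oracle(R, i, j, k):
    """First-order partial correlation via the explicit regression formula."""
    return (R[i, j] - R[i, k] * R[j, k]) / np.sqrt(
        (1 - R[i, k] ** 2) * (1 - R[j, k] ** 2))


class TestKmo:
    def test_matches_regression_residual_oracle(self):
        # for 3 variables the anti-image partials are the first-order
        # partial correlations, computable without any matrix inverse
        q01 = partial_corr_oracle(R3, 0, 1, 2)
        q02 = partial_corr_oracle(R3, 0, 2, 1)
        q12 = partial_corr_oracle(R3, 1, 2, 0)
        r2 = 2 * (R3[0, 1] ** 2 + R3[0, 2] ** 2 + R3[1, 2] ** 2)
        q2 = 2 * (q01 ** 2 + q02 ** 2 + q12 ** 2)
        expected = r2 / (r2 + q2)
        overall, msa = kmo_from_corr(R3)
        assert abs(overall - expected) < 1e-10
        msa0 = (R3[0, 1] ** 2 + R3[0, 2] ** 2) / (
            R3[0, 1] ** 2 + R3[0, 2] ** 2 + q01 ** 2 + q02 ** 2)
        assert abs(msa[0] - msa0) < 1e-10

    def test_independent_variable_has_smallest_msa(self):
        R = np.array([[1.0, 0.999, 0.0],
                      [0.999, 1.0, 0.0],
                      [0.0, 0.0, 1.0]])
        _, msa = kmo_from_corr(R)
        assert np.argmin(msa) == 2

    def test_singular_matrix_without_ridge_errors(self):
        R = np.array([[1.0, 1.0, 0.0],
                      [1.0, 1.0, 0.0],
                      [0.0, 0.0, 1.0]])
        with pytest.raises(np.linalg.LinAlgError):
            kmo_from_corr(R)
        overall, _ = kmo_from_corr(R, ridge=1e-8)
        assert 0.0 <= overall <= 1.0

    def test_constant_variable_named(self):
        X = np.column_stack([np.ones(50), np.arange(50.0)])
        with pytest.raises(ValueError, match="constant"):
            ff.kmo(X)


class TestParallelAnalysis:
    def test_pure_noise_retains_zero(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((500, 7))
        m, table = ff.parallel_analysis(X, n_reps=100, quantile=0.95, seed=0)
        assert m == 0
        assert len(table) == 7

    def test_rank_one_structure_retains_one(self):
        rng = np.random.default_rng(1)
        f = rng.standard_normal(300)
        X = np.tile(f[:, None], (1, 6)) + 1e-9 * rng.standard_normal((300, 6))
        m, _ = ff.parallel_analysis(X, n_reps=50, seed=0)
        assert m == 1

    def test_two_program_data_retains_two(self, default_expr):
        expr, _ = default_expr
        panel = expr.subset_genes(["Myh1", "Myh2", "Myh4", "Myh7",
                                   "Myh7b", "Myh11", "Myh3"])
        m, _ = ff.parallel_analysis(panel, n_reps=100, seed=0)
        assert m == 2

    def test_invalid_reps_rejected(self):
        with pytest.raises(ValueError):
            ff.parallel_analysis(np.zeros((10, 3)), n_reps=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 5))
        m1, t1 = ff.parallel_analysis(X, seed=9)
        m2, t2 = ff.parallel_analysis(X, seed=9)
        assert m1 == m2
        pd.testing.assert_frame_equal(t1, t2)


def paf_oracle(R, m, iters=2000):
    """Independent principal-axis iteration, written from the definition."""
    h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    for _ in range(iters):
        Rr = R - np.diag(1.0 - h2)
        vals, vecs = np.linalg.eigh(Rr)
        L = vecs[:, ::-1][:, :m] * np.sqrt(np.clip(vals[::-1][:m], 0, None))
        h2 = np.clip((L ** 2).sum(axis=1), 0, 1)
    return L


def offdiag_ss(R, L):
    resid = R - L @ L.T
    np.fill_diagonal(resid, 0)
    return (resid ** 2).sum()


class TestExtraction:
    def test_noiseless_one_factor_unit_communalities(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal(200)
        X = np.outer(f, [1.0, -0.5, 2.0, 0.8])
        L, h2, u2 = ff.extract_factors(X, m=1)
        np.testing.assert_allclose(h2, 1.0, atol=1e-6)
        np.testing.assert_allclose(u2, 0.0, atol=1e-6)

    def test_minres_at_least_as_good_as_principal_axis(self):
        R = np.array([[1.00, 0.55, 0.45, 0.10],
                      [0.55, 1.00, 0.50, 0.15],
                      [0.45, 0.50, 1.00, 0.20],
                      [0.10, 0.15, 0.20, 1.00]])
        L_minres, _, _ = ff.extract_factors(R, m=1)
        L_paf = paf_oracle(R, m=1)
        assert offdiag_ss(R, L_minres) <= offdiag_ss(R, L_paf) + 1e-8

    @pytest.mark.parametrize("m", [0, 7, 10])
    def test_invalid_factor_count_rejected(self, m):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 7))
        with pytest.raises(ValueError):
            ff.extract_factors(X, m=m)


class TestQuartimin:
    def grid_oracle(self, A, step=1e-3):
        """Brute-force search over the two oblique rotation angles."""
        thetas = np.arange(0.0, np.pi, step)
        cos, sin = np.cos(thetas), np.sin(thetas)
        best = np.inf
        for i, t1 in enumerate(thetas):
            c1, s1 = cos[i], sin[i]
            # T columns: (c1,s1) and (cos t2, sin t2); skip near-singular T
            det = c1 * sin - s1 * cos
            ok = np.abs(det) > 1e-3
            inv00, inv01 = sin[ok] / det[ok], -cos[ok] / det[ok]
            inv10, inv11 = -s1 / det[ok], c1 / det[ok]
            # L = A @ inv(T).T ; build for all t2 at once
            L1 = A[:, 0][:, None] * inv00[None, :] + A[:, 1][:, None] * inv01[None, :]
            L2 = A[:, 0][:, None] * inv10[None, :] + A[:, 1][:, None] * inv11[None, :]
            q = ((L1 ** 2) * (L2 ** 2)).sum(axis=0) * 2.0
            best = min(best, q.min())
        return best

    def test_perfect_simple_structure_is_fixed_point(self):
        A = np.array([[0.8, 0.0], [0.7, 0.0], [0.0, 0.9], [0.0, 0.6]])
        L, Phi = ff.rotate_quartimin(A)
        assert quartimin_value(L) == pytest.approx(0.0, abs=1e-10)
        # unchanged up to column permutation/sign
        recovered = np.abs(L)[:, np.argsort(-np.abs(L).sum(axis=0))]
        target = np.abs(A)[:, np.argsort(-np.abs(A).sum(axis=0))]
        np.testing.assert_allclose(recovered, target, atol=1e-6)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((7, 2)) * 0.6
        L, Phi = ff.rotate_quartimin(A, seed=0)
        assert quartimin_value(L) <= self.grid_oracle(A) + 1e-4

    def test_model_fit_preserved(self):
        rng = np.random.default_rng(11)
        A = rng.standard_normal((7, 2)) * 0.6
        L, Phi = ff.rotate_quartimin(A)
        np.testing.assert_allclose(L @ Phi @ L.T, A @ A.T, atol=1e-8)
        # Phi symmetric, unit diagonal, positive definite
        np.testing.assert_allclose(Phi, Phi.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(Phi), 1.0, atol=1e-10)
        assert np.linalg.eigvalsh(Phi).min() > 0

    def test_single_factor_rejected(self):
        with pytest.raises(ValueError):
            ff.rotate_quartimin(np.ones((5, 1)))


class TestScores:
    def test_direct_formula_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((20, 7))
        L = rng.standard_normal((7, 2)) * 0.5
        Phi = np.array([[1.0, 0.3], [0.3, 1.0]])
        F = ff.score_factors(X, L, Phi)
        Z = zscore(X)
        R = np.corrcoef(Z.T)
        expected = Z @ np.linalg.inv(R) @ (L @ Phi)
        np.testing.assert_allclose(F, expected, atol=1e-10)

    def test_near_noiseless_two_factor_recovery(self):
        rng = np.random.default_rng(2)
        n = 500
        Ftrue = rng.standard_normal((n, 2))
        Lam = np.array([[0.9, 0.0], [0.8, 0.0], [0.85, 0.0],
                        [0.0, 0.9], [0.0, 0.8], [0.0, 0.85]])
        X = Ftrue @ Lam.T + 0.05 * rng.standard_normal((n, 6))
        L, h2, u2 = ff.extract_factors(X, m=2)
        Lr, Phi = ff.rotate_quartimin(L)
        F = ff.score_factors(X, Lr, Phi)
        # align estimated factors to the truth before correlating
        for k in range(2):
            corr = max(abs(np.corrcoef(F[:, j], Ftrue[:, k])[0, 1])
                       for j in range(2))
            assert corr > 0.99

    def test_bartlett_scores_available(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((100, 5))
        L, _, _ = ff.extract_factors(X, m=2)
        F = ff.score_factors(X, L, method="bartlett")
        assert F.shape == (100, 2)

    def test_constant_variable_rejected(self):
        X = np.column_stack([np.ones(30), np.arange(30.0)])
        with pytest.raises(ValueError):
            ff.score_factors(X, np.ones((2, 1)))


class TestFiberMapping:
    def test_default_fit_recovers_seed_pattern(self, default_fit):
        res, _ = default_fit
        fast_load = res.loadings.loc[["Myh1", "Myh2", "Myh4"]]
        assert fast_load["fast"].mean() > 0.6
        assert fast_load["slow"].abs().max() < 0.3
        slow_load = res.loadings.loc[["Myh7", "Myh7b"]]
        assert slow_load["slow"].mean() > 0.4
        assert slow_load["fast"].abs().max() < 0.3

    def test_column_permutation_invariant(self):
        L = pd.DataFrame({"f1": [0.8, 0.7, 0.0], "f2": [0.0, 0.1, 0.9]},
                         index=["Myh1", "Myh2", "Myh7"])
        m1 = ff.map_factors_to_fiber_types(L, ["Myh1", "Myh2"], ["Myh7"])
        m2 = ff.map_factors_to_fiber_types(L[["f2", "f1"]],
                                           ["Myh1", "Myh2"], ["Myh7"])
        assert m1 == {"fast": 0, "slow": 1}
        assert m2 == {"fast": 1, "slow": 0}

    def test_zero_slow_rows_ambiguous(self):
        L = pd.DataFrame({"f1": [0.8, 0.0], "f2": [0.0, 0.0]},
                         index=["Myh1", "Myh7"])
        with pytest.raises(MappingError):
            ff.map_factors_to_fiber_types(L, ["Myh1"], ["Myh7"])


class TestModelResults:
    def test_rotation_invariants_on_default_fit(self, default_fit):
        res, _ = default_fit
        L = res.loadings.to_numpy()
        Phi = res.phi.to_numpy()
        fit_rot = L @ Phi @ L.T
        L0, h2, u2 = ff.extract_factors(res.model.data.to_numpy(), m=2)
        np.testing.assert_allclose(fit_rot, L0 @ L0.T, atol=1e-8)
        np.testing.assert_allclose(res.communalities.to_numpy(), h2,
                                   atol=1e-8)
        np.testing.assert_allclose(res.communalities + res.uniquenesses, 1.0,
                                   atol=1e-12)
        assert 0.0 <= res.kmo <= 1.0
        assert ((res.communalities >= 0) & (res.communalities <= 1)).all()

    def test_summary_mentions_key_quantities(self, default_fit):
        res, _ = default_fit
        text = res.summary()
        for token in ("KMO", "Phi", "Parallel analysis", "Myh7b", "h2"):
            assert token in text

    def test_factor_order_fast_then_slow(self, default_fit):
        res, _ = default_fit
        assert res.factor_names[:2] == ["fast", "slow"]
        assert list(res.scores.columns[:2]) == ["F_fast", "F_slow"]
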