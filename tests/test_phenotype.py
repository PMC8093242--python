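import numpy as np
import pandas as pd
import pytest

from cvsem.datasets import CATEGORY_ORDER, ITEMS, DataValidationError
from cvsem.phenotype import (
    IpfConvergenceError,
    category_scores,
    covariance_selection,
    delta_scores,
    find_cliques_above,
    ggm_mle,
    item_pca,
    partial_correlation_matrix,
)
from cvsem.simulate import SimulationConfig, simulate_genotypes, simulate_phenotypes
from ._oracles import partial_corr_oracle


def _questionnaire_from_deltas(before: int, after: int) -> pd.DataFrame:
    data = {f"{q}_before": [before] for q in ITEMS}
    data.update({f"{q}_after": [after] for q in ITEMS})
    return pd.DataFrame(data, index=["s1"])


class TestDeltaScores:
    def test_simple_difference(self):
        from cvsem.datasets import QuestionnaireData

        q = QuestionnaireData(_questionnaire_from_deltas(2, 5))
        assert (delta_scores(q).iloc[0] == 3).all()

    def test_equal_conditions_zero(self):
        from cvsem.datasets import QuestionnaireData

        q = QuestionnaireData(_questionnaire_from_deltas(4, 4))
        assert (delta_scores(q).iloc[0] == 0).all()

    def test_mean_delta_is_difference_of_condition_means(self):
        # population with mean before ~2.05 and after ~4.70 -> mean delta 2.65
        cfg = SimulationConfig(n_samples=5000, n_variants=2, seed=21)
        geno = simulate_genotypes(cfg)
        q, _ = simulate_phenotypes(geno, cfg)
        deltas = delta_scores(q)
        before = q.responses[[f"{i}_before" for i in ITEMS]].to_numpy()
        after = q.responses[[f"{i}_after" for i in ITEMS]].to_numpy()
        assert deltas.to_numpy().mean() == pytest.approx(
            after.mean() - before.mean(), abs=1e-12
        )

    def test_out_of_range_value_names_subject_and_item(self):
        from cvsem.datasets import QuestionnaireData

        frame = _questionnaire_from_deltas(2, 5)
        frame.loc["s1", "q3_after"] = 9
        with pytest.raises(DataValidationError, match="q3_after"):
            delta_scores(QuestionnaireData(frame))


class TestCategoryScores:
    def test_arithmetic_means(self):
        deltas = pd.DataFrame(
            {q: [0.0] for q in ITEMS}, index=["s1"]
        )
        deltas.loc["s1", ["q1", "q2", "q3"]] = [2, 4, 6]
        deltas.loc["s1", ["q8", "q9"]] = [1, 5]
        cats = category_scores(deltas)
        assert cats.loc["s1", "asthenopic"] == 4.0
        assert cats.loc["s1", "visual"] == 3.0

    def test_constant_items_give_constant_categories(self):
        deltas = pd.DataFrame({q: [2.5, 2.5] for q in ITEMS})
        cats = category_scores(deltas)
        assert (cats.to_numpy() == 2.5).all()
        assert list(cats.columns) == CATEGORY_ORDER

    def test_missing_item_rejected(self):
        deltas = pd.DataFrame({q: [1.0] for q in ITEMS[:-1]})
        with pytest.raises(DataValidationError, match="q14"):
            category_scores(deltas)


def _data_with_exact_correlation(R: np.ndarray, n: int, rng) -> np.ndarray:
    """Sample matrix whose empirical correlation equals R exactly."""
    p = R.shape[0]
    Z = rng.standard_normal((n, p))
    Z -= Z.mean(axis=0)
    # whiten exactly, then colour by chol(R)
    cov = Z.T @ Z / (n - 1)
    Z = Z @ np.linalg.inv(np.linalg.cholesky(cov)).T
    return Z @ np.linalg.cholesky(R).T


class TestPartialCorrelations:
    def test_equicorrelation_third(self, rng):
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        X = _data_with_exact_correlation(R, 500, rng)
        net = partial_correlation_matrix(pd.DataFrame(X))
        off = net.partial_corr.to_numpy()[np.triu_indices(3, 1)]
        np.testing.assert_allclose(off, 1.0 / 3.0, atol=1e-10)

    def test_independent_variables_near_zero(self, rng):
        X = rng.standard_normal((4000, 6))
        net = partial_correlation_matrix(pd.DataFrame(X))
        off = net.partial_corr.to_numpy()[np.triu_indices(6, 1)]
        assert np.abs(off).max() < 0.07

    def test_matches_regression_residual_oracle(self, rng):
        X = rng.standard_normal((300, 5)) @ rng.standard_normal((5, 5))
        net = partial_correlation_matrix(pd.DataFrame(X))
        np.testing.assert_allclose(
            net.partial_corr.to_numpy(), partial_corr_oracle(X), atol=1e-10
        )

    def test_one_factor_items_all_positive(self):
        cfg = SimulationConfig(n_samples=3000, n_variants=2, seed=33)
        geno = simulate_genotypes(cfg)
        q, _ = simulate_phenotypes(geno, cfg)
        net = partial_correlation_matrix(delta_scores(q))
        # common latent factor induces non-negative partials throughout
        off = net.partial_corr.to_numpy()[np.triu_indices(14, 1)]
        assert off.min() > -0.05

    def test_more_variables_than_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            partial_correlation_matrix(pd.DataFrame(rng.standard_normal((5, 6))))


def _cov_from_precision(K: np.ndarray) -> np.ndarray:
    return np.linalg.inv(K)


class TestCovarianceSelection:
    def test_full_graph_reproduces_unconstrained_mle(self, rng):
        X = rng.standard_normal((200, 5))
        S = np.cov(X, rowvar=False)
        K, sigma = ggm_mle(S, ~np.eye(5, dtype=bool))
        np.testing.assert_allclose(K, np.linalg.inv(S), atol=1e-10)

    def test_constrained_fit_zeroes_precision_and_matches_edges(self, rng):
        X = rng.standard_normal((500, 4)) @ rng.standard_normal((4, 4))
        S = np.cov(X, rowvar=False)
        adj = np.zeros((4, 4), bool)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = True
        K, sigma = ggm_mle(S, adj)
        assert abs(K[0, 2]) < 1e-8 and abs(K[1, 3]) < 1e-8
        np.testing.assert_allclose(np.diag(sigma), np.diag(S), atol=1e-6)
        assert sigma[0, 1] == pytest.approx(S[0, 1], abs=1e-6)

    def test_saturated_truth_keeps_all_edges(self):
        K = np.eye(4) * 2.0
        K[K == 0] = -0.5  # all partials = 0.25, strongly supported
        S = _cov_from_precision(K)
        sel = covariance_selection(S * 1.0, n=100_000)
        assert len(sel.aic_trace) == 1  # first elimination raised AIC
        assert sel.adjacency.to_numpy().sum() == 12

    def test_aic_trace_monotone_decreasing(self, rng):
        X = rng.standard_normal((800, 6))
        sel = covariance_selection(np.cov(X, rowvar=False), n=800)
        assert all(np.diff(sel.aic_trace) < 0)

    def test_chain_truth_true_edges_always_kept(self):
        K = np.eye(5)
        for i in range(4):
            K[i, i + 1] = K[i + 1, i] = -0.3
        S_true = _cov_from_precision(K)
        rng = np.random.default_rng(99)
        kept = 0
        reps = 20
        for _ in range(reps):
            X = rng.multivariate_normal(np.zeros(5), S_true, 5000)
            sel = covariance_selection(np.cov(X, rowvar=False), n=5000)
            A = sel.adjacency.to_numpy().astype(bool)
            kept += all(A[i, i + 1] for i in range(4))
        assert kept == reps

    def test_diagonal_truth_empty_rate_matches_aic_theory(self):
        # each null edge survives w.p. P(chi2_1 > 2) ~ 0.157, so the exact
        # empty-graph rate is ~0.843**6 ~ 0.36 for 4 nodes, independent of n
        rng = np.random.default_rng(7)
        empty = 0
        reps = 60
        for _ in range(reps):
            X = rng.standard_normal((2000, 4))
            sel = covariance_selection(np.cov(X, rowvar=False), n=2000)
            empty += sel.adjacency.to_numpy().sum() == 0
        assert 0.15 <= empty / reps <= 0.60

    def test_non_positive_definite_rejected(self):
        with pytest.raises(ValueError):
            covariance_selection(np.ones((3, 3)), n=100)

    def test_clique_diagnostic(self, rng):
        K = np.eye(4) * 2.0
        K[K == 0] = -0.5  # all partial correlations 0.25, K still PD
        S = _cov_from_precision(K)
        sel = covariance_selection(S, n=50_000)
        cliques = find_cliques_above(sel, threshold=0.2)
        assert any(len(c) == 4 for c in cliques)


class TestItemPca:
    def test_identity_matrix_equal_shares(self):
        vals, coords, shares = item_pca(np.eye(14))
        np.testing.assert_allclose(shares, 1.0 / 14.0)

    def test_rank_one_matrix_full_first_share(self):
        v = np.arange(1.0, 6.0)
        vals, coords, shares = item_pca(np.outer(v, v))
        assert shares[0] == pytest.approx(1.0)

    def test_one_factor_items_share_sign_on_pc1(self):
        cfg = SimulationConfig(n_samples=3000, n_variants=2, seed=44)
        geno = simulate_genotypes(cfg)
        q, _ = simulate_phenotypes(geno, cfg)
        net = partial_correlation_matrix(delta_scores(q))
        vals, coords, shares = item_pca(net.partial_corr)
        pc1 = coords["pc1"].to_numpy()
        assert (pc1 > 0).all() or (pc1 < 0).all()

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            item_pca(np.arange(9.0).reshape(3, 3))
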