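import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fmica import (
    amari_index,
    center_whiten,
    estimate_order_laplace,
    fastica,
    icasso_select,
    match_components,
    mean_order,
)
from fmica.ica import _laplace_log_evidence

from oracles import brute_force_rotation_unmixing


def _two_uniform_mixture(rng, n=20000):
    S = rng.uniform(-np.sqrt(3), np.sqrt(3), size=(2, n))
    A = rng.standard_normal((2, 2)) + 2 * np.eye(2)
    return A @ S, A, S


class TestCenterWhiten:
    def test_round_trip_and_identity_covariance(self, rng):
        X = rng.standard_normal((6, 400)) * rng.uniform(0.5, 4, (6, 1))
        Z, wt = center_whiten(X, order=6)
        assert np.allclose(Z.mean(axis=1), 0, atol=1e-10)
        assert np.allclose(Z @ Z.T / Z.shape[1], np.eye(6), atol=1e-8)
        Xc = X - X.mean(axis=1, keepdims=True)
        assert np.allclose(wt.dewhiten(Z), X, atol=1e-8)
        assert np.allclose(wt.whiten(X), Z)
        del Xc

    def test_rank_deficient_reduces_with_warning(self, rng):
        basis = rng.standard_normal((2, 300))
        X = rng.standard_normal((5, 2)) @ basis
        with pytest.warns(RuntimeWarning, match="rank"):
            Z, wt = center_whiten(X, order=5)
        assert wt.order == 2 and Z.shape[0] == 2

    def test_bad_order_rejected(self, rng):
        with pytest.raises(ValueError):
            center_whiten(rng.standard_normal((4, 50)), order=0)
        with pytest.raises(ValueError):
            center_whiten(rng.standard_normal((4, 50)), order=9)


class TestFastICA:
    def test_separates_uniform_mixture_against_truth_and_oracle(self, rng):
        X, A, S = _two_uniform_mixture(rng)
        model = fastica(X, 2, seed=1)
        assert model.converged
        assert amari_index(model.unmixing @ A) < 0.05
        W_oracle = brute_force_rotation_unmixing(X)
        assert amari_index(model.unmixing @ np.linalg.inv(W_oracle)) < 0.02

    def test_sources_decorrelated_unit_variance(self, rng):
        X = rng.laplace(size=(4, 5000)) * [[1], [3], [0.5], [2]]
        X = rng.standard_normal((6, 4)) @ X
        model = fastica(X, 4, seed=0)
        C = model.sources @ model.sources.T / model.sources.shape[1]
        assert np.allclose(C, np.eye(4), atol=1e-6)

    def test_identity_mixing_recovers_inputs(self, rng):
        S = rng.laplace(size=(3, 8000))
        S = (S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True)
        model = fastica(S, 3, seed=2)
        res = match_components(model.sources, S)
        assert all(abs(r) > 0.98 for r in res.correlations.values())

    def test_gaussian_data_not_identifiable(self, rng):
        X = rng.standard_normal((3, 6000))
        model = fastica(X, 3, seed=0, max_iter=200)
        kurt = np.mean(model.sources ** 4, axis=1) - 3.0
        assert (not model.converged) or np.all(np.abs(kurt) < 0.2)

    def test_deterministic_given_seed(self, rng):
        X, _, _ = _two_uniform_mixture(rng, n=4000)
        m1 = fastica(X, 2, seed=7)
        m2 = fastica(X, 2, seed=7)
        assert np.array_equal(m1.sources, m2.sources)

    def test_row_permutation_equivariance(self, rng):
        X = rng.standard_normal((5, 5)) @ rng.laplace(size=(5, 6000))
        perm = [3, 0, 4, 1, 2]
        m1 = fastica(X, 3, seed=4)
        m2 = fastica(X[perm], 3, seed=4)
        res = match_components(m2.sources, m1.sources)
        assert all(abs(r) > 0.99 for r in res.correlations.values())

    def test_matches_sklearn_reference(self, rng):
        sklearn_ica = pytest.importorskip("sklearn.decomposition")
        X, A, S = _two_uniform_mixture(rng, n=10000)
        model = fastica(X, 2, seed=3)
        sk = sklearn_ica.FastICA(
            n_components=2, whiten="unit-variance", random_state=0, max_iter=1000
        )
        Y_sk = sk.fit_transform(X.T).T
        res = match_components(model.sources, Y_sk)
        assert all(abs(r) > 0.99 for r in res.correlations.values())


class TestLaplaceOrder:
    def test_matches_published_evidence_formula(self, rng):
        from sklearn.decomposition._pca import _assess_dimension

        X = rng.standard_normal((20, 1500))
        X[:4] *= 5
        Xc = X - X.mean(1, keepdims=True)
        spec = np.linalg.eigvalsh(Xc @ Xc.T / 1500)[::-1]
        for k in (1, 3, 7, 15):
            assert _laplace_log_evidence(spec, k, 1500) == pytest.approx(
                _assess_dimension(spec, k, 1500), rel=1e-9
            )

    def test_recovers_rank_of_strong_signal(self, rng):
        S = 5 * rng.standard_normal((5, 500))
        A = rng.standard_normal((40, 5))
        X = A @ S + rng.standard_normal((40, 500))
        assert estimate_order_laplace(X).chosen == 5

    def test_white_noise_prefers_smallest_order(self, rng):
        X = rng.standard_normal((20, 5000))
        assert estimate_order_laplace(X).chosen == 1

    def test_scores_align_with_candidates(self, rng):
        X = rng.standard_normal((10, 8)) @ rng.standard_normal((8, 2000))
        est = estimate_order_laplace(X, max_order=6)
        assert est.chosen in est.candidates
        assert len(est.scores) == len(est.candidates)


class TestMeanOrder:
    @pytest.mark.parametrize(
        "orders,expected",
        [([13, 13, 13], 13), ([10, 11], 11), ([20, 22, 25], 22), ([12], 12)],
    )
    def test_round_half_up(self, orders, expected):
        assert mean_order(orders) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_order([])

    @given(st.lists(st.integers(1, 60), min_size=1, max_size=20))
    def test_bounded_by_extremes(self, orders):
        assert min(orders) <= mean_order(orders) <= max(orders)


def _well_separated_maps(rng, k=5, V=3000):
    S = rng.exponential(1.0, size=(k, V)) * (rng.random((k, V)) < 0.12)
    S += 0.02 * rng.standard_normal((k, V))
    return S


class TestIcasso:
    def test_selects_true_order_with_high_stability(self, rng):
        # rank-5 mixture: decompositions beyond the true order split
        # components unstably across restarts, pulling their Iq down
        S = _well_separated_maps(rng, V=2000)
        A = rng.standard_normal((8, 5))
        X = A @ S
        with pytest.warns(RuntimeWarning):
            est = icasso_select(X, 3, 8, n_runs=8, seed=0)
        assert est.candidates == list(range(3, 9))
        assert est.chosen == 5
        detail = est.detail.set_index("order")
        assert detail.loc[5, "mean_iq"] > 0.9
        assert detail.loc[8, "mean_iq"] < detail.loc[5, "mean_iq"]

    def test_duplicate_runs_are_perfectly_stable(self, rng):
        S = _well_separated_maps(rng, k=3)
        X = rng.standard_normal((5, 3)) @ S
        est = icasso_select(X, 3, 3, n_runs=2, seed=0, run_seeds=[7, 7])
        assert est.detail["mean_iq"].iloc[0] > 0.95

    def test_bad_arguments_rejected(self, rng):
        X = rng.standard_normal((5, 200))
        with pytest.raises(ValueError):
            icasso_select(X, 4, 3)
        with pytest.raises(ValueError):
            icasso_select(X, 2, 3, n_runs=1)
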