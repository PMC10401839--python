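"""EM fitting: closed forms, fixed points, ascent, symmetry, and a brute-force oracle."""

import numpy as np
import pytest

from segmint import FitConfig, PlsaError, PlsaModel, em_step, fit_plsa, log_likelihood
from segmint.plsa import loglik_trace, saturated_loglik

from conftest import make_matrix

LN_QUARTER_X4 = 4 * np.log(0.25)  # -5.5452: independence model on the all-ones 2x2
LN_FIFTH_X5 = 5 * np.log(0.2)  # -8.0472: saturated bound of the 3x3 block matrix


def uniform_model(K, I, V):
    return PlsaModel(
        K=K,
        pz=np.full(K, 1.0 / K),
        pi_z=np.full((I, K), 1.0 / I),
        pv_z=np.full((V, K), 1.0 / V),
    )


def block_exact_model():
    """K=2 parameters reproducing the 3x3 block matrix's empirical cell distribution."""
    return PlsaModel(
        K=2,
        pz=np.array([0.8, 0.2]),
        pi_z=np.array([[0.5, 0.0], [0.5, 0.0], [0.0, 1.0]]),
        pv_z=np.array([[0.5, 0.0], [0.5, 0.0], [0.0, 1.0]]),
    )


class TestLogLikelihood:
    def test_uniform_k1_on_all_ones(self, ones_2x2):
        model = uniform_model(1, 2, 2)
        assert log_likelihood(model, ones_2x2) == pytest.approx(LN_QUARTER_X4, abs=1e-10)

    def test_all_zero_matrix_contributes_nothing(self):
        model = uniform_model(2, 3, 3)
        assert log_likelihood(model, make_matrix(np.zeros((3, 3)))) == 0.0

    def test_block_exact_attains_saturated_bound(self, block_matrix):
        assert log_likelihood(block_exact_model(), block_matrix) == pytest.approx(
            LN_FIFTH_X5, abs=1e-12
        )
        assert saturated_loglik(block_matrix) == pytest.approx(LN_FIFTH_X5, abs=1e-12)

    def test_dimension_mismatch_raises(self, block_matrix):
        with pytest.raises(PlsaError, match="dimensions"):
            log_likelihood(uniform_model(1, 2, 2), block_matrix)

    def test_zero_probability_on_observed_cell_raises(self, block_matrix):
        broken = PlsaModel(
            K=1,
            pz=np.array([1.0]),
            pi_z=np.array([[0.5], [0.5], [0.0]]),  # row 2 observed but zero mass
            pv_z=np.full((3, 1), 1 / 3),
        )
        with pytest.raises(PlsaError, match="zero modeled probability"):
            log_likelihood(broken, block_matrix)


class TestEmStep:
    def test_stationary_point_is_fixed(self, block_matrix):
        model = block_exact_model()
        after = em_step(model, block_matrix)
        assert np.allclose(after.pz, model.pz, atol=1e-12)
        assert np.allclose(after.pi_z, model.pi_z, atol=1e-12)
        assert np.allclose(after.pv_z, model.pv_z, atol=1e-12)

    def test_input_model_not_mutated(self, block_matrix):
        model = uniform_model(2, 3, 3)
        pz0 = model.pz.copy()
        em_step(model, block_matrix)
        assert (model.pz == pz0).all()

    @pytest.mark.parametrize("seed", range(8))
    def test_single_step_never_decreases_loglik(self, seed):
        rng = np.random.default_rng(seed)
        mat = make_matrix(rng.integers(0, 2, size=(6, 5)))
        if mat.n.sum() == 0:
            mat.n[0, 0] = 1
        model = PlsaModel(
            K=3,
            pz=rng.dirichlet(np.ones(3)),
            pi_z=rng.dirichlet(np.ones(6), size=3).T,
            pv_z=rng.dirichlet(np.ones(5), size=3).T,
        )
        before = log_likelihood(model, mat)
        after = em_step(model, mat)
        assert after.loglik >= before - 1e-10

    def test_uniform_start_stays_symmetric_and_collapses_to_independence(
        self, block_matrix
    ):
        """Exactly symmetric initializations are EM fixed points equal to K=1.

        This is why restarts draw random (asymmetric) initializations.
        """
        model = uniform_model(2, 3, 3)
        after = em_step(model, block_matrix)
        # clusters remain identical to each other
        assert np.allclose(after.pi_z[:, 0], after.pi_z[:, 1], atol=1e-14)
        assert np.allclose(after.pv_z[:, 0], after.pv_z[:, 1], atol=1e-14)
        # and the achieved loglik equals the K=1 independence optimum
        k1 = fit_plsa(block_matrix, 1, FitConfig(n_restarts=1, seed=0))
        steps = em_step(em_step(after, block_matrix), block_matrix)
        assert steps.loglik == pytest.approx(k1.loglik, abs=1e-10)


class TestFit:
    def test_k1_closed_form_on_all_ones(self, ones_2x2):
        model = fit_plsa(ones_2x2, 1, FitConfig(n_restarts=1, seed=0))
        assert model.loglik == pytest.approx(LN_QUARTER_X4, abs=1e-8)
        assert np.allclose(model.pi_z.ravel(), [0.5, 0.5], atol=1e-6)
        assert np.allclose(model.pv_z.ravel(), [0.5, 0.5], atol=1e-6)

    def test_k1_is_independence_model(self):
        rng = np.random.default_rng(3)
        mat = make_matrix(rng.integers(0, 2, size=(7, 5)))
        model = fit_plsa(mat, 1, FitConfig(n_restarts=1, seed=1))
        R = mat.n.sum()
        expected = mat.n.sum(axis=1) / R
        assert np.allclose(model.pi_z.ravel(), expected, atol=1e-8)

    def test_k2_block_matrix_reaches_saturated_bound(self, block_matrix):
        model = fit_plsa(block_matrix, 2, FitConfig(seed=0))
        assert model.loglik == pytest.approx(LN_FIFTH_X5, abs=1e-4)
        model.validate()

    def test_k_larger_than_dimensions_raises(self, block_matrix):
        with pytest.raises(PlsaError, match="exceeds"):
            fit_plsa(block_matrix, 4, FitConfig(seed=0))

    def test_nonconvergence_warns_but_returns(self, block_matrix):
        with pytest.warns(RuntimeWarning, match="did not converge"):
            model = fit_plsa(block_matrix, 2, FitConfig(max_iter=2, seed=0))
        assert model.converged is False

    def test_winning_seed_reproduces_fit(self, block_matrix):
        model = fit_plsa(block_matrix, 2, FitConfig(n_restarts=5, seed=10))
        refit = fit_plsa(
            block_matrix, 2, FitConfig(n_restarts=1, seed=model.seed)
        )
        assert refit.loglik == pytest.approx(model.loglik, abs=1e-12)
        assert np.allclose(refit.pv_z, model.pv_z, atol=1e-12)

    def test_model_json_round_trip(self, tmp_path, block_matrix):
        model = fit_plsa(block_matrix, 2, FitConfig(seed=0))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = PlsaModel.from_json(path)
        assert back.K == model.K
        assert back.loglik == model.loglik
        assert np.allclose(back.pv_z, model.pv_z)
        assert back.row_ids == [str(r) for r in model.row_ids]


class TestInvariants:
    @pytest.mark.parametrize("seed", range(50))
    def test_em_trace_monotone_on_random_small_matrices(self, seed):
        rng = np.random.default_rng(1000 + seed)
        I, V = rng.integers(3, 8, size=2)
        mat = make_matrix(rng.integers(0, 2, size=(I, V)))
        if mat.n.sum() == 0:
            mat.n[0, 0] = 1
        K = int(rng.integers(1, min(I, V) + 1))
        trace = loglik_trace(mat, K, seed=seed, n_iter=40)
        assert (np.diff(trace) >= -1e-10).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_final_loglik_below_saturated_bound(self, seed):
        rng = np.random.default_rng(2000 + seed)
        mat = make_matrix(rng.integers(0, 2, size=(6, 6)))
        if mat.n.sum() == 0:
            mat.n[0, 0] = 1
        model = fit_plsa(mat, 3, FitConfig(seed=seed))
        assert model.loglik <= saturated_loglik(mat) + 1e-9

    def test_normalization_invariants_hold_after_fit(self, block_matrix):
        model = fit_plsa(block_matrix, 2, FitConfig(seed=5))
        assert model.pz.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(model.pi_z.sum(axis=0), 1.0, atol=1e-10)
        assert np.allclose(model.pv_z.sum(axis=0), 1.0, atol=1e-10)

    def test_permutation_of_rows_and_columns_permutes_solution(self):
        rng = np.random.default_rng(7)
        n = rng.integers(0, 2, size=(6, 5))
        n[0, 0] = 1
        mat = make_matrix(n)
        model = fit_plsa(mat, 2, FitConfig(seed=3))
        rp = rng.permutation(6)
        cp = rng.permutation(5)
        permuted = make_matrix(n[np.ix_(rp, cp)])
        moved = PlsaModel(
            K=2, pz=model.pz, pi_z=model.pi_z[rp], pv_z=model.pv_z[cp]
        )
        assert log_likelihood(moved, permuted) == pytest.approx(model.loglik, abs=1e-10)
        # and the permuted model is still a fixed point of EM on the permuted data
        after = em_step(moved, permuted)
        assert after.loglik >= model.loglik - 1e-10

    def test_cluster_label_permutation_leaves_loglik_unchanged(self, block_matrix):
        model = fit_plsa(block_matrix, 2, FitConfig(seed=1))
        swapped = PlsaModel(
            K=2,
            pz=model.pz[::-1].copy(),
            pi_z=model.pi_z[:, ::-1].copy(),
            pv_z=model.pv_z[:, ::-1].copy(),
        )
        assert log_likelihood(swapped, block_matrix) == pytest.approx(
            model.loglik, abs=1e-12
        )

    def test_best_loglik_nondecreasing_in_k(self):
        rng = np.random.default_rng(11)
        mat = make_matrix(rng.integers(0, 2, size=(8, 6)))
        lls = [
            fit_plsa(mat, K, FitConfig(n_restarts=5, seed=4)).loglik for K in (1, 2, 3)
        ]
        assert lls[1] >= lls[0] - 1e-6
        assert lls[2] >= lls[1] - 1e-6


class TestBruteForceOracle:
    def test_em_matches_direct_numerical_maximization(self):
        """Best-of-restarts EM attains the likelihood a generic optimizer finds.

        The oracle maximizes the same objective by L-BFGS on a softmax
        parameterization from many random starts — it shares no code with
        the EM path.
        """
        from scipy.optimize import minimize
        from scipy.special import softmax

        rng = np.random.default_rng(42)
        n = rng.integers(0, 2, size=(4, 4)).astype(float)
        n[0, 0] = 1.0
        K, I, V = 2, 4, 4

        def neg_loglik(x):
            pz = softmax(x[:K])
            pi = softmax(x[K : K + K * I].reshape(I, K), axis=0)
            pv = softmax(x[K + K * I :].reshape(V, K), axis=0)
            P = np.einsum("k,ik,vk->iv", pz, pi, pv)
            return -np.sum(n * np.log(np.maximum(P, 1e-300)))

        best = np.inf
        for s in range(25):
            x0 = np.random.default_rng(s).normal(size=K + 2 * K * 4)
            res = minimize(neg_loglik, x0, method="L-BFGS-B")
            best = min(best, res.fun)
        oracle_ll = -best

        mat = make_matrix(n.astype(np.int8))
        model = fit_plsa(mat, 2, FitConfig(n_restarts=10, seed=0, tol=1e-12))
        assert model.loglik == pytest.approx(oracle_ll, abs=1e-4)
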