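"""The entropy-maximization fit and its supporting operations."""

import numpy as np
import pytest
from scipy.optimize import root

import ofcnet as oc
from ofcnet.exceptions import (
    ConstraintError,
    NormalizationError,
    SingularMatrixError,
)
from ofcnet.maxent import (
    ConstraintSet,
    InteractionMatrix,
    OptimizerSettings,
    constraint_residual,
)

from conftest import random_spd


class TestObjective:
    def test_scalar_case(self):
        # N=1: f = K*C - ln K = 2*0.5 - ln 2
        val = oc.objective(np.array([[2.0]]), np.array([[0.5]]))
        assert val == pytest.approx(1 - np.log(2))

    def test_stationary_point_value_and_gradient(self, rng):
        C = random_spd(rng, 5)
        K = np.linalg.inv(C)
        assert oc.objective(K, C) == pytest.approx(
            5 + np.log(np.linalg.det(C)))
        np.testing.assert_allclose(oc.gradient(K, C), 0.0, atol=1e-10)

    def test_matches_eigendecomposition_oracle(self, rng):
        K = random_spd(rng, 4)
        C = random_spd(rng, 4)
        lam = np.linalg.eigvalsh(K)
        oracle = float(np.sum(K * C)) - float(np.sum(np.log(lam)))
        assert oc.objective(K, C) == pytest.approx(oracle, rel=1e-12)

    def test_singular_K_raises_with_eigenvalue(self, rng):
        C = random_spd(rng, 3)
        K = np.diag([1.0, 1.0, -0.5])
        with pytest.raises(SingularMatrixError) as err:
            oc.objective(K, C)
        assert err.value.eigenvalue == pytest.approx(-0.5)


class TestGradient:
    def test_scalar_case(self):
        g = oc.gradient(np.array([[1.0]]), np.array([[2.0]]))
        assert g[0, 0] == pytest.approx(1.0)

    def test_finite_difference_oracle(self, rng):
        K = random_spd(rng, 5)
        C = random_spd(rng, 5)
        G = oc.gradient(K, C)
        h = 1e-6
        for i, j in [(0, 0), (1, 3), (4, 2)]:
            dK = np.zeros((5, 5))
            dK[i, j] = dK[j, i] = h  # symmetric perturbation
            fd = (oc.objective(K + dK, C) - oc.objective(K - dK, C)) / (2 * h)
            expected = G[i, j] * (1.0 if i == j else 2.0)
            assert fd == pytest.approx(expected, rel=1e-5, abs=1e-7)


class TestOptimizeK:
    def test_full_constraints_recover_inverse(self, rng):
        for n in (4, 9, 17):
            C = random_spd(rng, n)
            K = oc.optimize_K(C, ConstraintSet.all_pairs(n))
            Cinv = np.linalg.inv(C)
            err = np.linalg.norm(K.K - Cinv) / np.linalg.norm(Cinv)
            assert err <= 10 * 0.01
            assert K.converged

    def test_empty_pi_gives_independent_gaussians(self):
        C = np.diag([0.5, 2.0, 4.0])
        K = oc.optimize_K(C, ConstraintSet.from_pairs([]))
        np.testing.assert_allclose(K.K, np.diag([2.0, 0.5, 0.25]),
                                   rtol=0.02)
        assert np.all(K.K[~np.eye(3, dtype=bool)] == 0.0)

    def test_three_residue_chain_matches_root_solver_oracle(self, rng):
        C = random_spd(rng, 3, cond_lift=2.0)
        pi = ConstraintSet.from_pairs([(0, 1), (1, 2)])
        K = oc.optimize_K(C, pi, OptimizerSettings(tolerance=1e-4))

        # independent oracle: solve the stationarity system
        # (K^-1)_ab = C_ab on constrained entries with K_02 = 0
        def eqs(x):
            k = np.array([[x[0], x[3], 0.0],
                          [x[3], x[1], x[4]],
                          [0.0, x[4], x[2]]])
            kinv = np.linalg.inv(k)
            return [kinv[0, 0] - C[0, 0], kinv[1, 1] - C[1, 1],
                    kinv[2, 2] - C[2, 2], kinv[0, 1] - C[0, 1],
                    kinv[1, 2] - C[1, 2]]

        x0 = [1 / C[0, 0], 1 / C[1, 1], 1 / C[2, 2], 0.0, 0.0]
        sol = root(eqs, x0, tol=1e-12)
        assert sol.success
        K_oracle = np.array([[sol.x[0], sol.x[3], 0.0],
                             [sol.x[3], sol.x[1], sol.x[4]],
                             [0.0, sol.x[4], sol.x[2]]])
        np.testing.assert_allclose(K.K, K_oracle, rtol=5e-3, atol=1e-4)

    def test_constrained_entries_reproduced_within_tolerance(self, fitted_K30,
                                                             sampled_cov30,
                                                             network30):
        K_true, _ = network30
        mask = K_true.constraints.mask(30)
        res = constraint_residual(fitted_K30.K, sampled_cov30, mask)
        assert res <= 0.01

    def test_unconstrained_offdiagonal_exactly_zero(self, fitted_K30,
                                                    network30):
        K_true, _ = network30
        mask = K_true.constraints.mask(30) | np.eye(30, dtype=bool)
        assert np.all(fitted_K30.K[~mask] == 0.0)

    def test_converged_K_nonnegative_definite(self, fitted_K30):
        lam = np.linalg.eigvalsh(fitted_K30.K)
        assert lam[0] >= -1e-8 * np.trace(fitted_K30.K) / 30

    def test_scaling_covariance_relation(self, network30):
        K_true, _ = network30
        C = oc.true_covariance(K_true)
        mask = K_true.constraints.mask(30)
        K1 = oc.optimize_K(C, K_true.constraints)
        for c in (0.1, 10.0):
            Kc = oc.optimize_K(c * C, K_true.constraints)
            # (1/c)-scaled fit must satisfy the unscaled constraints to
            # the same tolerance
            assert constraint_residual(c * Kc.K, C, mask) <= 0.011

    def test_nonpositive_msf_rejected(self):
        C = np.diag([1.0, 0.0, 2.0])
        with pytest.raises(ConstraintError):
            oc.optimize_K(C, ConstraintSet.from_pairs([]))

    def test_singular_covariance_gets_ridge(self, rng):
        # rank-deficient C (m-1 < N regime)
        s = rng.standard_normal((4, 8))
        C = s.T @ s / 4
        C.flat[:: 9] += 1e-12  # keep diagonal positive
        pi = ConstraintSet.from_pairs([(0, 1), (2, 3)])
        K = oc.optimize_K(C, pi)
        assert "ridge" in K.meta
        assert K.converged


class TestForceConstantTable:
    def test_sign_convention_and_annotation_fields(self, helix_annotations):
        K = np.array([[3.0, -2.0, 0.0], [-2.0, 4.0, 1.0], [0.0, 1.0, 3.0]])
        im = InteractionMatrix(
            K=K, constraints=ConstraintSet.from_pairs([(0, 1), (1, 2)]),
            converged=True)
        mean = oc.MeanStructure(np.array([[0, 0, 0], [3.8, 0, 0],
                                          [7.6, 0, 0.0]]))
        t = oc.force_constant_table(im, mean)
        assert t.loc[(t.i == 1) & (t.j == 2), "gamma"].item() == 2.0
        assert t.loc[(t.i == 2) & (t.j == 3), "gamma"].item() == -1.0
        assert (t["k"] == 1).all()
        assert t["d"].tolist() == pytest.approx([3.8, 3.8])

    def test_helical_hbond_pair_has_order_four(self, helix_ensemble,
                                               helix_annotations):
        n = helix_ensemble.n_residues
        pairs = [(i, i + 4) for i in range(n - 4)]
        K = np.eye(n) * 2.0
        for i, j in pairs:
            K[i, j] = K[j, i] = -0.5
        im = InteractionMatrix(K=K,
                               constraints=ConstraintSet.from_pairs(pairs),
                               converged=True)
        mean = oc.MeanStructure(helix_ensemble.model_coords[0])
        t = oc.force_constant_table(im, mean, helix_annotations)
        interior = t[(t.i > 1) & (t.j < n)]
        assert (interior["k"] == 4).all()
        assert interior["hbond"].all()
        assert (interior["ss_i"] == "H").all()


class TestNormalization:
    def test_definition_and_idempotence(self):
        import pandas as pd
        t = pd.DataFrame({"i": [1, 2], "j": [2, 3], "d": [3.8, 3.8],
                          "k": [1, 1], "gamma": [2.0, -4.0],
                          "ss_i": "other", "ss_j": "other",
                          "hbond": False})
        out = oc.normalize_ofc(t)
        assert out["gamma"].tolist() == pytest.approx([2 / 3, -4 / 3])
        assert out["gamma"].abs().mean() == pytest.approx(1.0, abs=1e-12)
        again = oc.normalize_ofc(out)
        assert again["gamma"].tolist() == pytest.approx(out["gamma"].tolist())

    def test_all_zero_rejected(self):
        import pandas as pd
        t = pd.DataFrame({"gamma": [0.0, 0.0]})
        with pytest.raises(NormalizationError):
            oc.normalize_ofc(t)


class TestPhysicalUnits:
    def test_3kbt_conversion(self):
        im = InteractionMatrix(K=np.array([[1.0]]))
        out = oc.to_physical_units(im, 300.0)
        assert out.K[0, 0] == pytest.approx(1.7885, abs=2e-4)

    def test_linearity_and_zero(self):
        im = InteractionMatrix(K=np.array([[0.0, -2.0], [-2.0, 4.0]]))
        out1 = oc.to_physical_units(im, 310.0)
        im2 = InteractionMatrix(K=2 * im.K)
        out2 = oc.to_physical_units(im2, 310.0)
        np.testing.assert_allclose(out2.K, 2 * out1.K)
        assert out1.K[0, 0] == 0.0


class TestPruning:
    def test_zero_fraction_is_identity(self, fitted_K30):
        out = oc.prune_weak_interactions(fitted_K30, 0.0)
        np.testing.assert_array_equal(out.K, fitted_K30.K)

    def test_exact_count_and_weakest_edge(self):
        n = 6
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)][:10]
        K = np.eye(n) * 5.0
        for rank, (i, j) in enumerate(pairs):
            K[i, j] = K[j, i] = -(0.1 + 0.1 * rank)
        im = InteractionMatrix(K=K,
                               constraints=ConstraintSet.from_pairs(pairs),
                               converged=True)
        out = oc.prune_weak_interactions(im, 0.10)
        assert out.constraints.q == 9
        i0, j0 = pairs[0]  # smallest |gamma|
        assert out.K[i0, j0] == 0.0

    def test_pruning_degrades_covariance_agreement(self, fitted_K30,
                                                   sampled_cov30, network30):
        _, topo = network30
        def all_off_cc(K):
            C = oc.covariance_from_K(K.K).C
            sel = ~np.eye(30, dtype=bool)
            return np.corrcoef(C[sel], sampled_cov30[sel])[0, 1]
        full = all_off_cc(fitted_K30)
        pruned = all_off_cc(oc.prune_weak_interactions(fitted_K30, 0.10))
        assert pruned < full
        assert full > 0.9  # unconstrained pairs keep "all" below 1


class TestParameterRecovery:
    def test_springs_recovered_within_bootstrap_se(self):
        spec = oc.SyntheticNetworkSpec(n=12, seed=5)
        K_true, _ = oc.generate_network(spec)
        samples = oc.sample_scalar_displacements(K_true, 10_000, seed=6)
        C = oc.empirical_scalar_covariance(samples)
        K_fit = oc.optimize_K(C, K_true.constraints,
                              oc.OptimizerSettings(tolerance=0.005))

        rng = np.random.default_rng(99)
        boot = []
        for _ in range(30):
            idx = rng.integers(0, samples.shape[0], samples.shape[0])
            Cb = oc.empirical_scalar_covariance(samples[idx])
            Kb = oc.optimize_K(Cb, K_true.constraints,
                               oc.OptimizerSettings(tolerance=0.005))
            boot.append([Kb.K[i, j] for i, j in K_true.constraints.pairs])
        se = np.std(np.array(boot), axis=0)
        for (i, j), s in zip(K_true.constraints.pairs, se):
            assert abs(K_fit.K[i, j] - K_true.K[i, j]) <= 3 * s + 1e-9


def test_tolerance_halving_changes_springs_below_one_percent(sampled_cov30,
                                                             network30):
    K_true, _ = network30
    K_a = oc.optimize_K(sampled_cov30, K_true.constraints,
                        oc.OptimizerSettings(tolerance=0.01))
    K_b = oc.optimize_K(sampled_cov30, K_true.constraints,
                        oc.OptimizerSettings(tolerance=0.005))
    g_a = np.array([-K_a.K[i, j] for i, j in K_true.constraints.pairs])
    g_b = np.array([-K_b.K[i, j] for i, j in K_true.constraints.pairs])
    mean_rel = np.mean(np.abs(g_b - g_a) / np.abs(g_b))
    assert mean_rel < 0.01
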