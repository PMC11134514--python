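from itertools import permutations

import numpy as np
import pytest

from taskhard.featurizers import EmbeddedDataset
from taskhard.otdd import (
    GaussianLabelModel,
    OTDDConfig,
    fit_label_gaussians,
    ground_cost_matrix,
    otdd_distance,
    solve_exact_ot,
    solve_sinkhorn,
    wasserstein2_gaussians,
)

from conftest import make_dataset


def permutation_ot_cost(cost):
    """Brute-force optimal cost for uniform square marginals (Birkhoff oracle)."""
    n = cost.shape[0]
    best = np.inf
    for perm in permutations(range(n)):
        best = min(best, sum(cost[i, perm[i]] for i in range(n)) / n)
    return best


class TestFitLabelGaussians:
    def test_singleton_class_degenerate(self):
        ds = EmbeddedDataset("t", np.array([[2.0, 3.0]]), np.array([1]), "f")
        g = fit_label_gaussians(ds, shrinkage=0.0)[1]
        assert np.allclose(g.mean, [2.0, 3.0])
        # pre-shrinkage covariance is 0; only the absolute floor remains
        assert np.allclose(g.covariance, 1e-8 * np.eye(2))

    def test_two_sample_covariance_denominator_n(self):
        ds = EmbeddedDataset("t", np.array([[0.0, 0.0], [2.0, 0.0]]), np.array([0, 0]), "f")
        g = fit_label_gaussians(ds, shrinkage=0.0)[0]
        assert np.allclose(g.mean, [1.0, 0.0])
        assert np.allclose(g.covariance, [[1.0, 0.0], [0.0, 0.0]], atol=1e-7)

    def test_one_model_per_present_label(self, rng):
        ds = make_dataset(rng)
        models = fit_label_gaussians(ds)
        assert set(models) == {0, 1}

    def test_empty_dataset(self):
        ds = EmbeddedDataset("t", np.zeros((0, 2)), np.zeros(0, dtype=int), "f")
        with pytest.raises(ValueError, match="empty"):
            fit_label_gaussians(ds)


class TestWasserstein2:
    def g(self, mean, cov, label=0):
        mean = np.atleast_1d(np.asarray(mean, dtype=float))
        cov = np.atleast_2d(np.asarray(cov, dtype=float))
        return GaussianLabelModel(label, mean, cov, 10)

    def test_identical_gaussians_zero(self):
        g1 = self.g([1.0, 2.0], [[2.0, 0.5], [0.5, 1.0]])
        assert wasserstein2_gaussians(g1, g1) == pytest.approx(0.0, abs=1e-9)

    def test_1d_equal_variance_mean_shift(self):
        assert wasserstein2_gaussians(self.g(0.0, 1.0), self.g(3.0, 1.0)) == pytest.approx(3.0)

    def test_1d_equal_mean_sd_difference(self):
        # W2 between N(0,1) and N(0,9) is |sigma1 - sigma2| = 2
        assert wasserstein2_gaussians(self.g(0.0, 1.0), self.g(0.0, 9.0)) == pytest.approx(2.0)

    def test_2d_commuting_covariances(self):
        # Sigma1 = I, Sigma2 = diag(4,1): W2^2 = tr(I + diag(4,1) - 2 diag(2,1)) = 1
        g1 = self.g([0.0, 0.0], np.eye(2))
        g2 = self.g([0.0, 0.0], np.diag([4.0, 1.0]))
        assert wasserstein2_gaussians(g1, g2) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        for _ in range(10):
            a = rng.normal(size=(3, 3))
            b = rng.normal(size=(3, 3))
            g1 = self.g(rng.normal(size=3), a @ a.T)
            g2 = self.g(rng.normal(size=3), b @ b.T)
            assert wasserstein2_gaussians(g1, g2) == pytest.approx(
                wasserstein2_gaussians(g2, g1), rel=1e-8, abs=1e-10
            )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            wasserstein2_gaussians(self.g([0.0], [[1.0]]), self.g([0.0, 0.0], np.eye(2)))

    def test_matches_empirical_ot_between_samples(self, rng):
        """Closed form vs exact OT between 500-point samples (2-D, seeded)."""
        a = rng.normal(size=(2, 2))
        cov1 = a @ a.T + 0.5 * np.eye(2)
        b = rng.normal(size=(2, 2))
        cov2 = b @ b.T + 0.5 * np.eye(2)
        mu1, mu2 = np.array([0.0, 0.0]), np.array([2.0, -1.0])
        g1, g2 = self.g(mu1, cov1), self.g(mu2, cov2)
        n = 500
        x = rng.multivariate_normal(mu1, cov1, size=n)
        y = rng.multivariate_normal(mu2, cov2, size=n)
        cost = ((x[:, None, :] - y[None, :, :]) ** 2).sum(axis=2)
        plan = solve_exact_ot(cost, np.full(n, 1 / n), np.full(n, 1 / n))
        empirical = np.sqrt(plan.cost)
        closed = wasserstein2_gaussians(g1, g2)
        assert closed == pytest.approx(empirical, rel=0.1)


class TestGroundCost:
    def test_same_feature_same_label_zero(self):
        ds = EmbeddedDataset("a", np.array([[1.0]]), np.array([0]), "f")
        cost = ground_cost_matrix(ds, ds, {(0, 0): 0.0})
        assert cost[0, 0] == 0.0

    def test_hand_computed_entry(self):
        a = EmbeddedDataset("a", np.array([[0.0]]), np.array([0]), "f")
        b = EmbeddedDataset("b", np.array([[1.0]]), np.array([1]), "f")
        cost = ground_cost_matrix(a, b, {(0, 1): 1.0})
        assert cost[0, 0] == pytest.approx(2.0)  # 1^2 feature + 1^2 label

    def test_identical_features_cross_label_entries(self):
        x = np.ones((4, 2))
        a = EmbeddedDataset("a", x, np.array([0, 0, 1, 1]), "f")
        b = EmbeddedDataset("b", x, np.array([1, 1, 0, 0]), "f")
        w = 3.0
        table = {(0, 0): 0.0, (1, 1): 0.0, (0, 1): w, (1, 0): w}
        cost = ground_cost_matrix(a, b, table)
        cross = cost[np.ix_([0, 1], [0, 1])]  # labels 0 vs 1
        assert np.allclose(cross, w**2)

    def test_missing_pair_errors(self):
        a = EmbeddedDataset("a", np.zeros((1, 1)), np.array([0]), "f")
        b = EmbeddedDataset("b", np.zeros((1, 1)), np.array([1]), "f")
        with pytest.raises(KeyError):
            ground_cost_matrix(a, b, {(0, 0): 0.0})


class TestExactOT:
    def test_1x1(self):
        plan = solve_exact_ot(np.array([[5.0]]), np.array([1.0]), np.array([1.0]))
        assert plan.cost == pytest.approx(5.0)
        assert np.allclose(plan.plan, [[1.0]])

    def test_2x2_antidiagonal(self):
        cost = np.array([[0.0, 1.0], [1.0, 0.0]])
        plan = solve_exact_ot(cost, np.full(2, 0.5), np.full(2, 0.5))
        assert plan.cost == pytest.approx(0.0)
        assert np.allclose(plan.plan, np.diag([0.5, 0.5]))

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_matches_permutation_oracle(self, n, rng):
        for _ in range(10):
            cost = rng.random((n, n)) * 10
            plan = solve_exact_ot(cost, np.full(n, 1 / n), np.full(n, 1 / n))
            assert plan.cost == pytest.approx(permutation_ot_cost(cost), abs=1e-9)

    def test_lp_path_general_marginals(self, rng):
        # non-uniform marginals exercise the LP branch; check feasibility + optimality
        cost = rng.random((3, 4))
        a = np.array([0.5, 0.3, 0.2])
        b = np.array([0.25, 0.25, 0.25, 0.25])
        plan = solve_exact_ot(cost, a, b)
        assert np.allclose(plan.plan.sum(axis=1), a, atol=1e-8)
        assert np.allclose(plan.plan.sum(axis=0), b, atol=1e-8)
        # any feasible coupling costs at least as much
        outer = np.outer(a, b)
        assert plan.cost <= np.sum(outer * cost) + 1e-9

    def test_lp_branch_agrees_with_assignment_branch(self, rng):
        # near-uniform marginals route through the LP; its cost must sit
        # within a Lipschitz neighborhood of the assignment-branch optimum
        cost = rng.random((4, 4))
        uniform = np.full(4, 0.25)
        assignment_cost = solve_exact_ot(cost, uniform, uniform).cost
        eps = 1e-7
        a = np.array([0.25 + eps, 0.25 - eps, 0.25, 0.25])
        lp_cost = solve_exact_ot(cost, a, uniform).cost
        assert assignment_cost == pytest.approx(permutation_ot_cost(cost), abs=1e-9)
        assert lp_cost == pytest.approx(assignment_cost, abs=1e-5)

    def test_bad_marginals_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            solve_exact_ot(np.ones((2, 2)), np.array([0.6, 0.6]), np.full(2, 0.5))


class TestSinkhorn:
    def test_constant_cost(self):
        cost = np.full((3, 3), 4.0)
        plan = solve_sinkhorn(cost, np.full(3, 1 / 3), np.full(3, 1 / 3), epsilon=0.5)
        assert plan.cost == pytest.approx(4.0)

    def test_epsilon_sweep_converges_to_exact(self):
        cost = np.array([[0.0, 1.0], [1.0, 0.0]])
        a = b = np.full(2, 0.5)
        costs = [solve_sinkhorn(cost, a, b, eps).cost for eps in (1.0, 0.1, 0.01)]
        assert costs[0] >= costs[1] >= costs[2]
        assert costs[2] == pytest.approx(0.0, abs=0.01)

    def test_marginal_violation_below_tol(self, rng):
        cost = rng.random((6, 4))
        a = rng.dirichlet(np.ones(6))
        b = rng.dirichlet(np.ones(4))
        plan = solve_sinkhorn(cost, a, b, epsilon=0.1, tol=1e-8)
        assert plan.converged
        assert np.abs(plan.plan.sum(axis=1) - a).max() < 1e-8

    def test_sinkhorn_cost_upper_bounds_exact(self, rng):
        for _ in range(10):
            cost = rng.random((6, 6))
            a = b = np.full(6, 1 / 6)
            exact = solve_exact_ot(cost, a, b).cost
            entropic = solve_sinkhorn(cost, a, b, epsilon=0.05, tol=1e-10).cost
            assert entropic >= exact - 1e-9

    def test_nonpositive_epsilon_rejected(self):
        with pytest.raises(ValueError, match="epsilon"):
            solve_sinkhorn(np.ones((2, 2)), np.full(2, 0.5), np.full(2, 0.5), 0.0)


class TestOTDDDistance:
    def test_identity_of_indiscernibles(self, rng):
        ds = make_dataset(rng, n=30)
        assert otdd_distance(ds, ds) == pytest.approx(0.0, abs=1e-8)

    def test_two_singleton_worked_case(self):
        # A = {(x=0, y=0)}, B = {(x=1, y=0)}: label W2 = 1 between degenerate
        # Gaussians at 0 and 1... both singletons carry label 0 here with
        # means 0 and 1, so the label term equals the feature term:
        # cost = 1 + 1 = 2, distance sqrt(2)
        a = EmbeddedDataset("a", np.array([[0.0]]), np.array([0]), "f")
        b = EmbeddedDataset("b", np.array([[1.0]]), np.array([0]), "f")
        cfg = OTDDConfig(covariance_shrinkage=0.0)
        assert otdd_distance(a, b, cfg) == pytest.approx(np.sqrt(2.0), abs=1e-6)

    def test_symmetry(self, rng):
        for i in range(5):
            a = make_dataset(rng, f"a{i}", n=25)
            b = make_dataset(rng, f"b{i}", n=35, shift=rng.normal())
            assert otdd_distance(a, b) == pytest.approx(otdd_distance(b, a), rel=1e-8)

    def test_non_negativity(self, rng):
        for i in range(5):
            a = make_dataset(rng, n=20)
            b = make_dataset(rng, n=20, shift=2.0)
            assert otdd_distance(a, b) >= 0.0

    def test_scaling_homogeneity(self, rng):
        """Scaling all features by s scales the distance by s (shrinkage 0)."""
        a = make_dataset(rng, "a", n=20)
        b = make_dataset(rng, "b", n=24, shift=1.0)
        cfg = OTDDConfig(covariance_shrinkage=0.0, seed=3)
        base = otdd_distance(a, b, cfg)
        s = 3.5
        a2 = EmbeddedDataset("a", a.features * s, a.labels, a.featurizer_name)
        b2 = EmbeddedDataset("b", b.features * s, b.labels, b.featurizer_name)
        assert otdd_distance(a2, b2, cfg) == pytest.approx(s * base, rel=1e-5)

    def test_featurizer_mismatch_rejected(self, rng):
        a = make_dataset(rng, "a", featurizer="f1")
        b = make_dataset(rng, "b", featurizer="f2")
        with pytest.raises(ValueError, match="featurizer mismatch"):
            otdd_distance(a, b)

    def test_subsampling_cap_respected(self, rng):
        a = make_dataset(rng, "a", n=100)
        b = make_dataset(rng, "b", n=100, shift=1.0)
        capped = OTDDConfig(max_samples_per_task=30, seed=0)
        assert otdd_distance(a, b, capped) == pytest.approx(
            otdd_distance(a, b, capped)
        )  # deterministic under the same seed
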