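import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mimtl import (
    Bag,
    GeneratorConfig,
    MetricHyperparams,
    MIMLDataset,
    bag_distance,
    bag_mean,
    build_constraints,
    fit_metric,
    generate_shifted_miml,
    mahalanobis_sq,
    penalty_gradients,
    penalty_objective,
    train_per_class,
)

from conftest import make_dataset


def random_problem(rng, d=4, n_within=5, n_between=4):
    """Random constraint set + point for gradient checking."""
    from mimtl.metric_learning import ConstraintSet

    cs = ConstraintSet(
        within_index=[(i, 0) for i in range(n_within)],
        within_diffs=rng.normal(size=(n_within, d)),
        within_weights=np.abs(rng.normal(size=n_within)) + 0.1,
        between_index=[(i, i + 1) for i in range(n_between)],
        between_diffs=rng.normal(size=(n_between, d)),
        between_weights=np.abs(rng.normal(size=n_between)) + 0.1,
        delta_s=0.5,
        delta_d=2.0,
    )
    A = np.eye(d) + 0.2 * rng.normal(size=(d, d))
    xi = rng.normal(size=n_within)
    zeta = rng.normal(size=n_between)
    return cs, A, xi, zeta


def fd_gradients(A, xi, zeta, cs, hp, h=1e-5):
    """Central finite differences of penalty_objective."""
    gA = np.zeros_like(A)
    for p in range(A.shape[0]):
        for q in range(A.shape[1]):
            Ap, Am = A.copy(), A.copy()
            Ap[p, q] += h
            Am[p, q] -= h
            gA[p, q] = (
                penalty_objective(Ap, xi, zeta, cs, hp)
                - penalty_objective(Am, xi, zeta, cs, hp)
            ) / (2 * h)
    gx = np.zeros_like(xi)
    for m in range(len(xi)):
        xp, xm = xi.copy(), xi.copy()
        xp[m] += h
        xm[m] -= h
        gx[m] = (
            penalty_objective(A, xp, zeta, cs, hp)
            - penalty_objective(A, xm, zeta, cs, hp)
        ) / (2 * h)
    gz = np.zeros_like(zeta)
    for m in range(len(zeta)):
        zp, zm = zeta.copy(), zeta.copy()
        zp[m] += h
        zm[m] -= h
        gz[m] = (
            penalty_objective(A, xi, zp, cs, hp)
            - penalty_objective(A, xi, zm, cs, hp)
        ) / (2 * h)
    return gA, gx, gz


class TestMahalanobis:
    def test_identity_is_euclidean(self, rng):
        u, v = rng.normal(size=4), rng.normal(size=4)
        assert mahalanobis_sq(u, v, np.eye(4)) == pytest.approx(
            float(((u - v) ** 2).sum()), abs=1e-12
        )

    def test_zero_at_equal_points(self, rng):
        u = rng.normal(size=3)
        A = rng.normal(size=(3, 3))
        assert mahalanobis_sq(u, u, A) == 0.0

    def test_triple_product_oracle(self, rng):
        u, v = rng.normal(size=4), rng.normal(size=4)
        A = rng.normal(size=(4, 4))
        expected = float((u - v) @ A.T @ A @ (u - v))
        assert mahalanobis_sq(u, v, A) == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            mahalanobis_sq(np.zeros(3), np.zeros(4), np.eye(3))


class TestBagDistance:
    def test_identical_bags_zero(self, rng):
        bag = Bag("x", rng.normal(size=(3, 4)))
        assert bag_distance(bag, bag, np.eye(4)) == 0.0

    def test_single_instance_euclidean(self, rng):
        x, y = rng.normal(size=4), rng.normal(size=4)
        d = bag_distance(Bag("a", x[None]), Bag("b", y[None]), np.eye(4))
        assert d == pytest.approx(float(((x - y) ** 2).sum()), abs=1e-12)

    def test_symmetry(self, rng):
        a = Bag("a", rng.normal(size=(2, 3)))
        b = Bag("b", rng.normal(size=(4, 3)))
        A = rng.normal(size=(3, 3))
        assert bag_distance(a, b, A) == pytest.approx(bag_distance(b, a, A), abs=1e-12)


class TestBuildConstraints:
    def make_labeled(self, rng, n_pos, n_neg, d=3):
        bags = [Bag(f"b{i}", rng.normal(size=(2, d))) for i in range(n_pos + n_neg)]
        labels = np.zeros((n_pos + n_neg, 1), dtype=int)
        labels[:n_pos, 0] = 1
        return MIMLDataset(bags, labels, ["k"])

    def test_between_pair_count(self, rng):
        ds = self.make_labeled(rng, 2, 3)
        hp = MetricHyperparams()
        cs = build_constraints(ds, "k", np.ones(5), None, hp)
        assert cs.n_between == 6
        for i, j in cs.between_index:
            assert ds.labels[i, 0] == 1 and ds.labels[j, 0] == 0

    def test_unit_weights_give_unit_pair_weights(self, rng):
        ds = self.make_labeled(rng, 2, 2)
        cs = build_constraints(ds, "k", np.ones(4), None, MetricHyperparams())
        np.testing.assert_allclose(cs.between_weights, 1.0)
        np.testing.assert_allclose(cs.within_weights, 1.0)

    def test_within_enumerates_every_instance(self, rng):
        ds = self.make_labeled(rng, 1, 2)
        cs = build_constraints(ds, "k", np.array([2.0, 3.0, 4.0]), None, MetricHyperparams())
        assert cs.n_within == ds.n_all == 6
        # weight of each within constraint is its bag's omega
        for (i, _), w in zip(cs.within_index, cs.within_weights):
            assert w == [2.0, 3.0, 4.0][i]

    def test_pair_cap_sampling(self, rng):
        ds = self.make_labeled(rng, 5, 5)
        hp = MetricHyperparams(max_pairs=10, seed=3)
        cs1 = build_constraints(ds, "k", np.ones(10), None, hp)
        cs2 = build_constraints(ds, "k", np.ones(10), None, hp)
        assert cs1.n_between == 10
        assert len(set(cs1.between_index)) == 10
        assert cs1.between_index == cs2.between_index  # seed reproducibility
        all_pairs = {(i, j) for i in range(5) for j in range(5, 10)}
        assert set(cs1.between_index) <= all_pairs

    def test_td_bags_carry_weight_one(self, rng):
        ds = self.make_labeled(rng, 1, 1)
        td = self.make_labeled(rng, 1, 1)
        cs = build_constraints(ds, "k", np.array([5.0, 7.0]), td, MetricHyperparams())
        # TD bags are appended after SD bags with weight exactly 1
        for (i, _), w in zip(cs.within_index, cs.within_weights):
            expected = [5.0, 7.0, 1.0, 1.0][i]
            assert w == expected
        for (i, j), w in zip(cs.between_index, cs.between_weights):
            wi = [5.0, 7.0, 1.0, 1.0][i]
            wj = [5.0, 7.0, 1.0, 1.0][j]
            assert w == pytest.approx(wi * wj)

    def test_no_positive_raises(self, rng):
        ds = self.make_labeled(rng, 1, 1)
        ds.labels[:, 0] = 0
        with pytest.raises(ValueError, match="k"):
            build_constraints(ds, "k", np.ones(2), None, MetricHyperparams())

    def test_delta_defaults_ordered(self, rng):
        ds = self.make_labeled(rng, 2, 2)
        cs = build_constraints(ds, "k", np.ones(4), None, MetricHyperparams())
        assert cs.delta_s < cs.delta_d


class TestPenaltyObjective:
    def test_no_constraints_is_frobenius(self, rng):
        from mimtl.metric_learning import ConstraintSet

        cs = ConstraintSet([], np.zeros((0, 3)), np.zeros(0), [], np.zeros((0, 3)),
                           np.zeros(0), 0.5, 2.0)
        A = rng.normal(size=(3, 3))
        f = penalty_objective(A, np.zeros(0), np.zeros(0), cs, MetricHyperparams())
        assert f == pytest.approx(float((A**2).sum()), abs=1e-12)

    def test_satisfied_constraints_linear_only(self, rng):
        cs, A, _, _ = random_problem(rng)
        hp = MetricHyperparams(lam=2.0, beta=3.0)
        # choose slacks large enough that every constraint holds strictly
        from mimtl.metric_learning import _distances

        xi = _distances(A, cs.within_diffs) - cs.delta_s + 1.0
        zeta = cs.delta_d - _distances(A, cs.between_diffs) + 1.0
        xi = np.maximum(xi, 0.1)
        zeta = np.maximum(zeta, 0.1)
        f = penalty_objective(A, xi, zeta, cs, hp)
        expected = (
            float((A**2).sum())
            + 2.0 * float(cs.within_weights @ xi)
            + 3.0 * float(cs.between_weights @ zeta)
        )
        assert f == pytest.approx(expected, rel=1e-12)

    def test_term_by_term_loop_oracle(self, rng):
        cs, A, xi, zeta = random_problem(rng, d=3, n_within=4, n_between=3)
        hp = MetricHyperparams(lam=1.5, beta=0.7, sigma=4.0)
        f = penalty_objective(A, xi, zeta, cs, hp)
        expected = sum(a * a for row in A for a in row)
        for m in range(cs.n_within):
            u = cs.within_diffs[m]
            dist = float(u @ A.T @ A @ u)
            expected += 1.5 * cs.within_weights[m] * xi[m]
            expected += 4.0 * max(0.0, dist - cs.delta_s - xi[m]) ** 2
            expected += 4.0 * max(0.0, -xi[m]) ** 2
        for m in range(cs.n_between):
            v = cs.between_diffs[m]
            dist = float(v @ A.T @ A @ v)
            expected += 0.7 * cs.between_weights[m] * zeta[m]
            expected += 4.0 * max(0.0, cs.delta_d - zeta[m] - dist) ** 2
            expected += 4.0 * max(0.0, -zeta[m]) ** 2
        assert f == pytest.approx(expected, rel=1e-12)

    def test_size_mismatch(self, rng):
        cs, A, xi, zeta = random_problem(rng)
        with pytest.raises(ValueError):
            penalty_objective(A, xi[:-1], zeta, cs, MetricHyperparams())


class TestPenaltyGradients:
    @pytest.mark.parametrize("d", [4, 6, 8])
    def test_finite_difference_agreement(self, d):
        rng = np.random.default_rng(d)
        cs, A, xi, zeta = random_problem(rng, d=d)
        hp = MetricHyperparams(lam=1.2, beta=0.8, sigma=3.0)
        gA, gx, gz = penalty_gradients(A, xi, zeta, cs, hp)
        fA, fx, fz = fd_gradients(A, xi, zeta, cs, hp)
        for got, exp in ((gA, fA), (gx, fx), (gz, fz)):
            scale = max(1.0, np.abs(exp).max())
            assert np.abs(got - exp).max() / scale < 1e-5

    def test_interior_point_linear_gradient(self, rng):
        cs, A, _, _ = random_problem(rng)
        hp = MetricHyperparams(lam=2.5, beta=1.5)
        from mimtl.metric_learning import _distances

        xi = _distances(A, cs.within_diffs) - cs.delta_s + 1.0
        zeta = cs.delta_d - _distances(A, cs.between_diffs) + 1.0
        xi, zeta = np.maximum(xi, 0.5), np.maximum(zeta, 0.5)
        _, gx, gz = penalty_gradients(A, xi, zeta, cs, hp)
        np.testing.assert_allclose(gx, 2.5 * cs.within_weights, atol=1e-12)
        np.testing.assert_allclose(gz, 1.5 * cs.between_weights, atol=1e-12)

    def test_no_constraints_gradient_is_2A(self, rng):
        from mimtl.metric_learning import ConstraintSet

        cs = ConstraintSet([], np.zeros((0, 3)), np.zeros(0), [], np.zeros((0, 3)),
                           np.zeros(0), 0.5, 2.0)
        A = rng.normal(size=(3, 3))
        gA, _, _ = penalty_gradients(A, np.zeros(0), np.zeros(0), cs, MetricHyperparams())
        np.testing.assert_allclose(gA, 2 * A, atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_gradient_consistency_property(self, seed):
        rng = np.random.default_rng(seed)
        cs, A, xi, zeta = random_problem(rng, d=3, n_within=3, n_between=2)
        hp = MetricHyperparams(sigma=2.0)
        gA, gx, gz = penalty_gradients(A, xi, zeta, cs, hp)
        fA, fx, fz = fd_gradients(A, xi, zeta, cs, hp)
        for got, exp in ((gA, fA), (gx, fx), (gz, fz)):
            scale = max(1.0, np.abs(exp).max())
            assert np.abs(got - exp).max() / scale < 1e-4


class TestFitMetric:
    def test_trace_non_increasing(self, rng):
        ds = make_dataset(rng, n_bags=10, d=4)
        hp = MetricHyperparams(max_iter=50)
        cs = build_constraints(ds, ds.class_ids[0], np.ones(10), None, hp)
        model = fit_metric(cs, hp)
        trace = model.objective_trace
        assert all(a >= b - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_epsilon_termination(self, rng):
        ds = make_dataset(rng, n_bags=8, d=3)
        hp = MetricHyperparams(max_iter=10_000, epsilon=1.0)
        cs = build_constraints(ds, ds.class_ids[0], np.ones(8), None, hp)
        model = fit_metric(cs, hp)
        assert model.converged
        assert len(model.objective_trace) < 10_000

    def test_regularizer_shrinks_a(self, rng):
        # single satisfied within constraint, lam=beta=0: only r(A) drives A
        from mimtl.metric_learning import ConstraintSet

        cs = ConstraintSet([(0, 0)], np.array([[0.1, 0.0]]), np.array([1.0]),
                           [], np.zeros((0, 2)), np.zeros(0), 1.0, 2.0)
        hp = MetricHyperparams(lam=0.0, beta=0.0, sigma=100.0, max_iter=100)
        model = fit_metric(cs, hp)
        assert np.linalg.norm(model.A) <= np.linalg.norm(np.eye(2)) + 1e-9

    def test_m_is_psd(self, rng):
        ds = make_dataset(rng, n_bags=10, d=4)
        hp = MetricHyperparams(max_iter=30)
        cs = build_constraints(ds, ds.class_ids[0], np.ones(10), None, hp)
        model = fit_metric(cs, hp)
        eigs = np.linalg.eigvalsh(model.M)
        assert eigs.min() >= -1e-10

    def test_empty_constraints_rejected(self):
        from mimtl.metric_learning import ConstraintSet

        cs = ConstraintSet([], np.zeros((0, 2)), np.zeros(0), [], np.zeros((0, 2)),
                           np.zeros(0), 0.5, 2.0)
        with pytest.raises(ValueError):
            fit_metric(cs, MetricHyperparams())

    def test_separation_improves(self):
        # 2-class bags with concepts split along 2 coordinates: the learned
        # metric should not reduce the between-class / within-bag ratio
        wins = 0
        for seed in range(3):
            means = np.zeros((2, 6))
            means[0, :2] = [2.0, 0.0]
            means[1, :2] = [0.0, 2.0]
            cfg = GeneratorConfig(d=6, n_classes=2, n_source=30, n_target=30,
                                  concept_means=means, label_rate=0.5,
                                  background_spread=2.0, seed=seed)
            src, _, _ = generate_shifted_miml(cfg)
            hp = MetricHyperparams(seed=seed, max_iter=100)
            cs = build_constraints(src, src.class_ids[0], np.ones(30), None, hp)
            model = fit_metric(cs, hp)

            def sep_ratio(A):
                y = src.labels[:, 0]
                m = np.vstack([bag_mean(b) for b in src.bags]) @ A.T
                pos, neg = m[y == 1], m[y == 0]
                between = ((pos[:, None] - neg[None, :]) ** 2).sum(-1).mean()
                within = np.mean([
                    (((b.instances - b.instances.mean(0)) @ A.T) ** 2).sum(1).mean()
                    for b in src.bags
                ])
                return between / within

            if sep_ratio(model.A) >= sep_ratio(np.eye(6)):
                wins += 1
        assert wins >= 2


class TestTrainPerClass:
    def test_single_class(self, rng):
        ds = make_dataset(rng, n_bags=8, d=3, n_classes=1)
        models = train_per_class(ds, np.ones(8), None, MetricHyperparams(max_iter=5))
        assert set(models) == {ds.class_ids[0]}

    def test_classes_without_positives_skipped(self, rng, caplog):
        ds = make_dataset(rng, n_bags=6, d=3, n_classes=2)
        ds.labels[:, 1] = 0
        models = train_per_class(ds, np.ones(6), None, MetricHyperparams(max_iter=5))
        assert ds.class_ids[1] not in models
        assert ds.class_ids[0] in models

    def test_pair_partition_matches_label_matrix(self, rng):
        ds = make_dataset(rng, n_bags=8, d=3, n_classes=2)
        hp = MetricHyperparams(max_iter=1)
        for k, class_k in enumerate(ds.class_ids):
            cs = build_constraints(ds, class_k, np.ones(8), None, hp)
            y = ds.labels[:, k]
            expected = {(i, j) for i in np.flatnonzero(y == 1)
                        for j in np.flatnonzero(y == 0)}
            assert set(cs.between_index) == expected
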