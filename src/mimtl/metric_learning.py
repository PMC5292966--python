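"""Weighted per-class Mahalanobis metric learning over multi-instance bags.

For one class the metric ``M = A^T A`` is fit by minimizing a penalty-function
relaxation of the constrained problem

    min  ||A||_F^2 + lambda * sum_w omega_i * xi_w + beta * sum_b w_ij * zeta_b
    s.t. D(x, c_i)    <= delta_S + xi_w     for every instance x of bag i,
         D(X_i, X_j)  >= delta_D - zeta_b   for oppositely labelled pairs,
         xi >= 0, zeta >= 0,

where ``D`` is the squared Mahalanobis distance, ``c_i`` the bag's instance
mean, and ``omega_i`` bag importance weights mapping the source-domain
distribution onto the target domain (labelled target bags carry weight 1, and
pair weights factorize as ``omega_i * omega_j``).  Each constraint and each
slack-negativity condition contributes a quadratic one-sided penalty
``sigma * max(0, violation)^2``; the relaxed objective is minimized by
gradient descent with backtracking on ``(A, xi, zeta)`` jointly.
Parameterizing by ``A`` keeps ``M`` positive semidefinite at every iterate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .miml_data import Bag, MIMLDataset, bag_mean

__all__ = [
    "MetricHyperparams",
    "ConstraintSet",
    "MetricModel",
    "mahalanobis_sq",
    "bag_distance",
    "build_constraints",
    "penalty_objective",
    "penalty_gradients",
    "fit_metric",
    "train_per_class",
]

logger = logging.getLogger(__name__)


@dataclass
class MetricHyperparams:
    """Hyperparameters of the penalty-function metric fit.

    ``delta_s``/``delta_d`` default to data-driven medians at ``A = I`` when
    left as ``None`` (computed inside :func:`build_constraints`), with
    ``delta_s < delta_d`` enforced by clamping.
    """

    lam: float = 1.0
    beta: float = 1.0
    delta_s: float | None = None
    delta_d: float | None = None
    sigma: float = 10.0
    epsilon: float = 1e-6
    step_a: float = 1e-3
    step_slack: float = 1e-2
    max_iter: int = 200
    max_pairs: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam < 0 or self.beta < 0:
            raise ValueError("lam and beta must be non-negative")
        if self.sigma <= 0 or self.epsilon <= 0:
            raise ValueError("sigma and epsilon must be positive")
        if (
            self.delta_s is not None
            and self.delta_d is not None
            and not self.delta_s < self.delta_d
        ):
            raise ValueError("delta_s must be strictly less than delta_d")


@dataclass
class ConstraintSet:
    """Materialized constraint system for one class.

    ``within`` holds one row per (bag, instance): the centred difference
    ``x - c_i`` and weight ``omega_i``.  ``between`` holds one row per sampled
    oppositely-labelled bag pair: the bag-mean difference and weight
    ``omega_i * omega_j``.  Slack vectors are indexed positionally: one ``xi``
    per within row, one ``zeta`` per between row.
    """

    within_index: list[tuple[int, int]]  # (bag index, instance index)
    within_diffs: np.ndarray  # m x d
    within_weights: np.ndarray  # m
    between_index: list[tuple[int, int]]  # (bag i, bag j)
    between_diffs: np.ndarray  # q x d
    between_weights: np.ndarray  # q
    delta_s: float
    delta_d: float

    @property
    def n_within(self) -> int:
        return self.within_diffs.shape[0]

    @property
    def n_between(self) -> int:
        return self.between_diffs.shape[0]

    @property
    def d(self) -> int:
        return self.within_diffs.shape[1]


@dataclass
class MetricModel:
    """Learned linear map ``A`` (metric ``M = A^T A``) for one class."""

    A: np.ndarray
    class_id: str
    hyperparams: MetricHyperparams
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def M(self) -> np.ndarray:
        return self.A.T @ self.A


def mahalanobis_sq(u: np.ndarray, v: np.ndarray, A: np.ndarray) -> float:
    """Squared Mahalanobis distance ``||A (u - v)||^2``."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or A.shape[1] != u.shape[0]:
        raise ValueError("dimension mismatch")
    w = A @ (u - v)
    return float(w @ w)


def bag_distance(bag_x: Bag, bag_y: Bag, A: np.ndarray) -> float:
    """Squared Mahalanobis distance between bag means."""
    if bag_x.d != bag_y.d:
        raise ValueError("dimension mismatch")
    return mahalanobis_sq(bag_mean(bag_x), bag_mean(bag_y), A)


def build_constraints(
    train: MIMLDataset,
    class_k: str,
    omega: np.ndarray,
    td_labeled: MIMLDataset | None,
    hyperparams: MetricHyperparams,
) -> ConstraintSet:
    """Enumerate within-bag and between-class constraints for one class.

    Source bags carry their importance weight; labelled target-domain bags
    carry weight exactly 1.  Pair weights are products of the two bag weights.
    When the positive-by-negative pair count exceeds ``max_pairs`` the pairs
    are down-sampled uniformly without replacement under ``hyperparams.seed``.
    Passing ``td_labeled=None`` (or an empty dataset) gives the
    source-only mode.
    """
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (train.n_bags,):
        raise ValueError("omega must have one weight per training bag")
    if np.any(omega < 0):
        raise ValueError("omega must be non-negative")

    bags = list(train.bags)
    weights = list(omega)
    if class_k not in train.class_ids:
        raise KeyError(f"unknown class {class_k!r}")
    k = train.class_ids.index(class_k)
    y = list(train.labels[:, k])
    if td_labeled is not None and td_labeled.n_bags > 0:
        if class_k not in td_labeled.class_ids:
            raise KeyError(f"class {class_k!r} missing from td_labeled")
        k_td = td_labeled.class_ids.index(class_k)
        bags.extend(td_labeled.bags)
        weights.extend([1.0] * td_labeled.n_bags)  # TD labelled bags weigh 1
        y.extend(td_labeled.labels[:, k_td])
    weights = np.array(weights)
    y = np.array(y)

    if not np.any(y == 1):
        raise ValueError(f"class {class_k!r} has no positive bag in the training set")

    within_index: list[tuple[int, int]] = []
    within_rows: list[np.ndarray] = []
    within_w: list[float] = []
    centers = []
    for i, bag in enumerate(bags):
        c = bag_mean(bag)
        centers.append(c)
        for j in range(bag.n_instances):
            within_index.append((i, j))
            within_rows.append(bag.instances[j] - c)
            within_w.append(weights[i])
    centers = np.vstack(centers)

    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    pairs = [(int(i), int(j)) for i in pos for j in neg]
    if len(pairs) > hyperparams.max_pairs:
        rng = np.random.default_rng(hyperparams.seed)
        sel = rng.choice(len(pairs), size=hyperparams.max_pairs, replace=False)
        pairs = [pairs[s] for s in np.sort(sel)]
    between_diffs = (
        np.vstack([centers[i] - centers[j] for i, j in pairs])
        if pairs
        else np.zeros((0, train.d))
    )
    between_w = np.array([weights[i] * weights[j] for i, j in pairs])

    within_diffs = np.vstack(within_rows) if within_rows else np.zeros((0, train.d))
    within_weights = np.array(within_w)

    delta_s = hyperparams.delta_s
    delta_d = hyperparams.delta_d
    if delta_s is None:
        sq = (within_diffs**2).sum(axis=1)
        delta_s = float(np.median(sq)) if sq.size else 0.0
    if delta_d is None:
        sq = (between_diffs**2).sum(axis=1)
        delta_d = float(np.median(sq)) if sq.size else delta_s + 1.0
    if not delta_s < delta_d:  # clamp to preserve the margin ordering
        delta_d = delta_s + max(1e-6, abs(delta_s))

    return ConstraintSet(
        within_index=within_index,
        within_diffs=within_diffs,
        within_weights=within_weights,
        between_index=pairs,
        between_diffs=between_diffs,
        between_weights=between_w,
        delta_s=delta_s,
        delta_d=delta_d,
    )


def _distances(A: np.ndarray, diffs: np.ndarray) -> np.ndarray:
    if diffs.shape[0] == 0:
        return np.zeros(0)
    t = diffs @ A.T
    return (t**2).sum(axis=1)


def penalty_objective(
    A: np.ndarray,
    xi: np.ndarray,
    zeta: np.ndarray,
    constraints: ConstraintSet,
    hyperparams: MetricHyperparams,
) -> float:
    """Penalty-relaxed objective value (see module docstring)."""
    cs = constraints
    if xi.shape != (cs.n_within,) or zeta.shape != (cs.n_between,):
        raise ValueError("slack vector size mismatch")
    h = hyperparams
    d_within = _distances(A, cs.within_diffs)
    d_between = _distances(A, cs.between_diffs)
    viol_w = np.maximum(0.0, d_within - cs.delta_s - xi)
    viol_b = np.maximum(0.0, cs.delta_d - zeta - d_between)
    f = float((A**2).sum())
    f += h.lam * float(cs.within_weights @ xi)
    f += h.beta * float(cs.between_weights @ zeta)
    f += h.sigma * float(
        (viol_w**2).sum()
        + (viol_b**2).sum()
        + (np.maximum(0.0, -xi) ** 2).sum()
        + (np.maximum(0.0, -zeta) ** 2).sum()
    )
    return f


def penalty_gradients(
    A: np.ndarray,
    xi: np.ndarray,
    zeta: np.ndarray,
    constraints: ConstraintSet,
    hyperparams: MetricHyperparams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of :func:`penalty_objective` w.r.t. A, xi, zeta."""
    cs = constraints
    if xi.shape != (cs.n_within,) or zeta.shape != (cs.n_between,):
        raise ValueError("slack vector size mismatch")
    h = hyperparams
    d_within = _distances(A, cs.within_diffs)
    d_between = _distances(A, cs.between_diffs)
    viol_w = np.maximum(0.0, d_within - cs.delta_s - xi)
    viol_b = np.maximum(0.0, cs.delta_d - zeta - d_between)

    grad_a = 2.0 * A
    if cs.n_within:
        # sum_m 2 sigma viol_m * 2 A u_m u_m^T  ==  4 sigma A (U^T diag(viol) U)
        grad_a = grad_a + 4.0 * h.sigma * A @ (
            cs.within_diffs.T @ (viol_w[:, None] * cs.within_diffs)
        )
    if cs.n_between:
        grad_a = grad_a - 4.0 * h.sigma * A @ (
            cs.between_diffs.T @ (viol_b[:, None] * cs.between_diffs)
        )

    grad_xi = (
        h.lam * cs.within_weights
        - 2.0 * h.sigma * viol_w
        - 2.0 * h.sigma * np.maximum(0.0, -xi)
    )
    grad_zeta = (
        h.beta * cs.between_weights
        - 2.0 * h.sigma * viol_b
        - 2.0 * h.sigma * np.maximum(0.0, -zeta)
    )
    return grad_a, grad_xi, grad_zeta


def fit_metric(
    constraints: ConstraintSet,
    hyperparams: MetricHyperparams,
    class_id: str = "",
) -> MetricModel:
    """Fit ``A`` from ``A = I`` by joint gradient descent with backtracking.

    Each iteration proposes a simultaneous update of ``(A, xi, zeta)`` at the
    current step scale and halves the scale until the objective decreases;
    iteration stops when ``|f_t - f_{t-1}| < epsilon`` or ``max_iter``.
    """
    cs = constraints
    if cs.n_within == 0 and cs.n_between == 0:
        raise ValueError("constraint set is empty")
    h = hyperparams
    A = np.eye(cs.d)
    xi = np.zeros(cs.n_within)
    zeta = np.zeros(cs.n_between)
    f = penalty_objective(A, xi, zeta, cs, h)
    trace = [f]
    converged = False
    # per-block adaptive step scales: grow after acceptance, halve on rejection
    scales = {"A": 1.0, "xi": 1.0, "zeta": 1.0}

    def line_search(block: str) -> bool:
        nonlocal A, xi, zeta, f
        grad_a, grad_xi, grad_zeta = penalty_gradients(A, xi, zeta, cs, h)
        for _ in range(40):
            if block == "A":
                cand = (A - scales[block] * h.step_a * grad_a, xi, zeta)
            elif block == "xi":
                cand = (A, xi - scales[block] * h.step_slack * grad_xi, zeta)
            else:
                cand = (A, xi, zeta - scales[block] * h.step_slack * grad_zeta)
            f_new = penalty_objective(*cand, cs, h)
            if np.isfinite(f_new) and f_new <= f:
                A, xi, zeta = cand
                f = f_new
                scales[block] = min(scales[block] * 2.0, 1e8)
                return True
            scales[block] *= 0.5
        return False

    for it in range(h.max_iter):
        f_prev = f
        moved_a = line_search("A")
        moved_x = line_search("xi") if cs.n_within else False
        moved_z = line_search("zeta") if cs.n_between else False
        if not np.isfinite(f):
            raise FloatingPointError(f"non-finite objective at iteration {it}")
        trace.append(f)
        if not (moved_a or moved_x or moved_z):  # stationary at smallest steps
            converged = True
            break
        if f_prev - f < h.epsilon:
            converged = True
            break
    return MetricModel(
        A=A,
        class_id=class_id,
        hyperparams=h,
        objective_trace=trace,
        converged=converged,
    )


def train_per_class(
    train: MIMLDataset,
    omega: np.ndarray,
    td_labeled: MIMLDataset | None,
    hyperparams: MetricHyperparams,
    classes: list[str] | None = None,
) -> dict[str, MetricModel]:
    """Fit one metric per class (one-vs-rest); classes without a positive bag
    in the combined training set are skipped with a warning."""
    if classes is None:
        classes = list(train.class_ids)
    models: dict[str, MetricModel] = {}
    for class_k in classes:
        try:
            cs = build_constraints(train, class_k, omega, td_labeled, hyperparams)
        except ValueError as exc:
            if "no positive bag" in str(exc):
                logger.warning("skipping class %s: no positive training bag", class_k)
                continue
            raise
        models[class_k] = fit_metric(cs, hyperparams, class_id=class_k)
    return models
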