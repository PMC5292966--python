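"""Bag importance weights via least-squares density-ratio fitting.

The ratio ``omega(X) = P'(X)/P(X)`` between the target and source bag
distributions is approximated as a non-negative linear combination of set
kernels ``psi_j(X) = k(X, basis_j)`` anchored at target-domain bags.  The
coefficients minimize the quadratic least-squares surrogate

    (1/2) alpha^T B alpha - b^T alpha,    alpha >= 0,

with ``B`` the source-domain Gram average and ``b`` the target-domain kernel
mean, solved by projected gradient descent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .miml_data import Bag, MIMLDataset

__all__ = [
    "BasisConfig",
    "ImportanceModel",
    "mi_kernel",
    "mi_kernel_matrix",
    "build_weight_system",
    "fit_bag_weights",
    "estimate_weights",
    "median_heuristic_gamma",
]


@dataclass
class BasisConfig:
    basis_bags: list[Bag]
    gamma: float
    ridge: float = 1e-6

    def __post_init__(self) -> None:
        if len(self.basis_bags) < 1:
            raise ValueError("need at least one basis bag")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")


@dataclass
class ImportanceModel:
    """Fitted density-ratio model: omega(X) = sum_j alpha_j k(X, basis_j)."""

    alpha: np.ndarray
    basis: BasisConfig
    omega: np.ndarray  # weight per source bag, aligned with the source dataset

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if np.any(self.alpha < 0):
            raise ValueError("alpha must be non-negative")

    def weight(self, bag: Bag) -> float:
        """Evaluate omega at a new bag."""
        psi = np.array(
            [mi_kernel(bag, bj, self.basis.gamma) for bj in self.basis.basis_bags]
        )
        return float(self.alpha @ psi)


def _cross_rbf_sum(x: np.ndarray, y: np.ndarray, gamma: float) -> float:
    sq = ((x[:, None, :] - y[None, :, :]) ** 2).sum(axis=2)
    return float(np.exp(-gamma * sq).sum())


def mi_kernel(bag_x: Bag, bag_y: Bag, gamma: float, normalize: bool = True) -> float:
    """Set kernel between bags: summed RBF over all cross-bag instance pairs.

    With ``normalize=True`` (default) the kernel is
    ``S(X,Y) / sqrt(S(X,X) S(Y,Y))`` so that ``k(X,X) = 1`` and bag size does
    not inflate similarity.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if bag_x.d != bag_y.d:
        raise ValueError(f"dimension mismatch: {bag_x.d} vs {bag_y.d}")
    s_xy = _cross_rbf_sum(bag_x.instances, bag_y.instances, gamma)
    if not normalize:
        return s_xy
    s_xx = _cross_rbf_sum(bag_x.instances, bag_x.instances, gamma)
    s_yy = _cross_rbf_sum(bag_y.instances, bag_y.instances, gamma)
    return s_xy / np.sqrt(s_xx * s_yy)


def mi_kernel_matrix(
    bags: list[Bag], basis_bags: list[Bag], gamma: float, normalize: bool = True
) -> np.ndarray:
    """``len(bags) x len(basis_bags)`` matrix of set-kernel values."""
    stacked = np.vstack([b.instances for b in bags])
    basis_stacked = np.vstack([b.instances for b in basis_bags])
    sq = (
        (stacked**2).sum(axis=1)[:, None]
        - 2.0 * stacked @ basis_stacked.T
        + (basis_stacked**2).sum(axis=1)[None, :]
    )
    rbf = np.exp(-gamma * np.maximum(sq, 0.0))
    # block-sum the instance-level kernel into bag-level sums
    row_edges = np.concatenate([[0], np.cumsum([b.n_instances for b in bags])])
    col_edges = np.concatenate([[0], np.cumsum([b.n_instances for b in basis_bags])])
    out = np.add.reduceat(np.add.reduceat(rbf, row_edges[:-1], axis=0), col_edges[:-1], axis=1)
    if normalize:
        self_x = np.array([_cross_rbf_sum(b.instances, b.instances, gamma) for b in bags])
        self_y = np.array(
            [_cross_rbf_sum(b.instances, b.instances, gamma) for b in basis_bags]
        )
        out = out / np.sqrt(np.outer(self_x, self_y))
    return out


def median_heuristic_gamma(
    source: MIMLDataset, target: MIMLDataset, seed: int = 0, max_points: int = 500
) -> float:
    """Median heuristic ``gamma = 1 / (2 median^2)`` on instance distances.

    The median is taken over pairwise Euclidean distances between instances
    pooled from both domains (deterministically subsampled to ``max_points``
    under ``seed`` when larger).
    """
    X = np.vstack([source.all_instances(), target.all_instances()])
    if len(X) > max_points:
        rng = np.random.default_rng(seed)
        X = X[np.sort(rng.choice(len(X), size=max_points, replace=False))]
    sq = (
        (X**2).sum(axis=1)[:, None] - 2.0 * X @ X.T + (X**2).sum(axis=1)[None, :]
    )
    iu = np.triu_indices(len(X), k=1)
    med_sq = float(np.median(np.maximum(sq[iu], 0.0)))
    if med_sq <= 0:
        return 1.0
    return 1.0 / (2.0 * med_sq)


def build_weight_system(
    source_bags: list[Bag],
    target_bags: list[Bag],
    basis: BasisConfig,
    normalize_kernel: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the quadratic system (B, b) of the least-squares ratio fit.

    ``B = mean_SD psi psi^T + ridge I`` and ``b = mean_TD psi`` with
    ``psi_j(X) = k(X, basis_j)``.
    """
    if not source_bags or not target_bags:
        raise ValueError("both domains must be nonempty")
    psi_src = mi_kernel_matrix(source_bags, basis.basis_bags, basis.gamma, normalize_kernel)
    psi_tgt = mi_kernel_matrix(target_bags, basis.basis_bags, basis.gamma, normalize_kernel)
    p = len(basis.basis_bags)
    B = psi_src.T @ psi_src / len(source_bags) + basis.ridge * np.eye(p)
    b = psi_tgt.mean(axis=0)
    return B, b


def fit_bag_weights(
    B: np.ndarray,
    b: np.ndarray,
    max_iter: int = 5000,
    tol: float = 1e-10,
) -> np.ndarray:
    """Minimize ``(1/2) a^T B a - b^T a`` s.t. ``a >= 0`` by projected gradient.

    Deterministic (zero initialization); exits when the projected-gradient
    KKT residual drops below ``tol``.
    """
    B = np.asarray(B, dtype=float)
    b = np.asarray(b, dtype=float)
    eigmin = float(np.linalg.eigvalsh((B + B.T) / 2.0).min())
    if eigmin < -1e-8 * max(1.0, float(np.abs(B).max())):
        raise ValueError(f"B is not positive semidefinite (min eigenvalue {eigmin:.3e})")
    p = b.shape[0]
    alpha = np.zeros(p)
    lip = float(np.linalg.eigvalsh((B + B.T) / 2.0).max())
    step = 1.0 / lip if lip > 0 else 1.0

    def objective(a: np.ndarray) -> float:
        return 0.5 * a @ B @ a - b @ a

    f = objective(alpha)
    for _ in range(max_iter):
        grad = B @ alpha - b
        residual = np.abs(alpha - np.maximum(0.0, alpha - grad)).max()
        if residual <= tol:
            break
        t = step
        for _ in range(60):  # backtracking halving
            cand = np.maximum(0.0, alpha - t * grad)
            f_cand = objective(cand)
            if f_cand <= f + 1e-15:
                break
            t *= 0.5
        alpha, f = cand, f_cand
    return alpha


def estimate_weights(
    source: MIMLDataset,
    target: MIMLDataset,
    basis_size: int = 100,
    gamma: float | None = None,
    ridge: float = 1e-6,
    seed: int = 0,
    normalize_kernel: bool = True,
    renormalize: bool = False,
) -> ImportanceModel:
    """Fit bag importance weights for every source bag.

    Basis bags are ``min(basis_size, n_target)`` target bags sampled uniformly
    under ``seed``; ``gamma=None`` invokes the median heuristic on bag means.
    Optionally rescale so that ``mean(omega) = 1`` over the source domain.
    """
    if source.n_bags == 0 or target.n_bags == 0:
        raise ValueError("both datasets must be nonempty")
    if source.d != target.d:
        raise ValueError("source and target dimension mismatch")
    if gamma is None:
        gamma = median_heuristic_gamma(source, target, seed=seed)
    rng = np.random.default_rng(seed)
    p = min(basis_size, target.n_bags)
    basis_idx = np.sort(rng.choice(target.n_bags, size=p, replace=False))
    basis = BasisConfig(
        basis_bags=[target.bags[i] for i in basis_idx], gamma=gamma, ridge=ridge
    )
    B, b = build_weight_system(source.bags, target.bags, basis, normalize_kernel)
    alpha = fit_bag_weights(B, b)
    psi_src = mi_kernel_matrix(source.bags, basis.basis_bags, gamma, normalize_kernel)
    omega = psi_src @ alpha
    if renormalize:
        m = omega.mean()
        if m > 0:
            omega = omega / m
    return ImportanceModel(alpha=alpha, basis=basis, omega=omega)
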