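"""Covariate-shifted synthetic MIML data with an exactly known density ratio.

Generative family
-----------------
Instances are drawn i.i.d. within a bag from a spherical Gaussian mixture:
one "background" component centred at the origin plus one component per class
concept.  A bag is positive for class k iff at least one of its instances was
drawn from concept k.  The target domain uses the same mixture translated by
``shift_vector``; bag sizes follow a shifted Poisson law (``1 + Poisson``)
shared by both domains, so the bag-size factor cancels from the density ratio
and ``P'(X)/P(X)`` is available in closed form as a product of per-instance
mixture-density quotients.

When a shift is requested, generated concept means are projected orthogonal
to the shift direction.  With equal concept/background spreads this makes the
instance density factorize along the shift direction, so the per-instance
log-ratio is exactly linear in the shifted coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.vq import kmeans2

from .miml_data import Bag, MIMLDataset, bag_mean

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "DomainSplit",
    "generate_shifted_miml",
    "true_density_ratio",
    "split_by_feature_median",
    "split_random_clusters",
]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic covariate-shift MIML generator."""

    d: int = 8
    n_classes: int = 3
    n_source: int = 100
    n_target: int = 100
    bag_size_mean: float = 3.13
    bag_size_dispersion: float = 1.0  # 0 freezes every bag at round(mean)
    concept_means: np.ndarray | None = None  # K x d; auto-generated if None
    concept_scale: float = 2.0  # magnitude of auto-generated concept means
    concept_spread: float | np.ndarray = 1.0  # scalar or per-dimension vector
    background_spread: float | np.ndarray = 1.0
    label_rate: float = 0.3  # expected fraction of positive bags per class
    shift_vector: np.ndarray | None = None  # d-vector; zeros if None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 1 or self.n_classes < 1:
            raise ValueError("d and n_classes must be positive")
        if self.n_source < 1 or self.n_target < 1:
            raise ValueError("need at least one bag per domain")
        if not (0.0 < self.label_rate < 1.0):
            raise ValueError("label_rate must lie in (0, 1)")
        if self.bag_size_mean < 1.0:
            raise ValueError("bag_size_mean must be >= 1")
        if self.bag_size_dispersion < 0:
            raise ValueError("bag_size_dispersion must be non-negative")
        if np.any(np.asarray(self.concept_spread) <= 0) or np.any(
            np.asarray(self.background_spread) <= 0
        ):
            raise ValueError("spreads must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to evaluate P(X) and P'(X) of a bag in closed form."""

    concept_means: np.ndarray  # K x d (source frame)
    concept_spread: float | np.ndarray  # scalar or per-dimension
    background_spread: float | np.ndarray
    mix_weights: np.ndarray  # length K+1: background then concepts
    shift_vector: np.ndarray  # d-vector
    concept_assignments_source: list[np.ndarray] = field(repr=False, default=None)
    concept_assignments_target: list[np.ndarray] = field(repr=False, default=None)

    def _log_instance_density(self, x: np.ndarray, shift: bool) -> np.ndarray:
        """Log mixture density of instance rows ``x`` under source or target."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        d = self.concept_means.shape[1]
        if x.shape[1] != d:
            raise ValueError(f"instance dimension {x.shape[1]} != {d}")
        means = np.vstack([np.zeros(d), self.concept_means])
        if shift:
            means = means + self.shift_vector
        spreads = _spread_rows(
            self.background_spread, self.concept_spread, self.concept_means.shape[0], d
        )
        # log of sum_j w_j N(x; m_j, diag(s_j^2))
        z = (x[:, None, :] - means[None, :, :]) / spreads[None, :, :]
        sq = (z**2).sum(axis=2)
        log_comp = (
            np.log(self.mix_weights)[None, :]
            - 0.5 * sq
            - np.log(spreads).sum(axis=1)[None, :]
            - 0.5 * d * np.log(2.0 * np.pi)
        )
        m = log_comp.max(axis=1, keepdims=True)
        return (m + np.log(np.exp(log_comp - m).sum(axis=1, keepdims=True))).ravel()


@dataclass(frozen=True)
class DomainSplit:
    """Disjoint source/target index sets covering a dataset."""

    source_indices: np.ndarray
    target_indices: np.ndarray

    def __post_init__(self) -> None:
        src = np.asarray(self.source_indices, dtype=int)
        tgt = np.asarray(self.target_indices, dtype=int)
        if np.intersect1d(src, tgt).size:
            raise ValueError("source and target index sets overlap")
        object.__setattr__(self, "source_indices", src)
        object.__setattr__(self, "target_indices", tgt)


def _spread_rows(
    background_spread: float | np.ndarray,
    concept_spread: float | np.ndarray,
    n_concepts: int,
    d: int,
) -> np.ndarray:
    """(K+1) x d matrix of per-component per-dimension standard deviations."""
    bg = np.broadcast_to(np.asarray(background_spread, dtype=float), (d,))
    cs = np.broadcast_to(np.asarray(concept_spread, dtype=float), (d,))
    return np.vstack([bg] + [cs] * n_concepts)


def _project_off(vectors: np.ndarray, direction: np.ndarray) -> np.ndarray:
    norm2 = float(direction @ direction)
    if norm2 == 0.0:
        return vectors
    return vectors - np.outer(vectors @ direction / norm2, direction)


def _draw_domain(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    means: np.ndarray,
    mix: np.ndarray,
    shift: np.ndarray,
    n_bags: int,
    prefix: str,
) -> tuple[list[Bag], np.ndarray, list[np.ndarray]]:
    K = means.shape[0]
    spreads = _spread_rows(cfg.background_spread, cfg.concept_spread, K, cfg.d)
    comp_means = np.vstack([np.zeros(cfg.d), means]) + shift
    bags: list[Bag] = []
    labels = np.zeros((n_bags, K), dtype=int)
    assignments: list[np.ndarray] = []
    if cfg.bag_size_dispersion > 0:
        sizes = 1 + rng.poisson(cfg.bag_size_mean - 1.0, size=n_bags)
    else:
        sizes = np.full(n_bags, max(1, round(cfg.bag_size_mean)))
    for i in range(n_bags):
        comp = rng.choice(K + 1, size=sizes[i], p=mix)
        inst = comp_means[comp] + rng.normal(size=(sizes[i], cfg.d)) * spreads[comp]
        bags.append(Bag(f"{prefix}{i:04d}", inst))
        for k in range(K):
            if np.any(comp == k + 1):
                labels[i, k] = 1
        assignments.append(comp)
    return bags, labels, assignments


def generate_shifted_miml(
    config: GeneratorConfig,
) -> tuple[MIMLDataset, MIMLDataset, GroundTruth]:
    """Draw a source and a target MIML dataset plus the generative ground truth.

    Identical configs (including seed) reproduce identical datasets.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    shift = (
        np.zeros(cfg.d)
        if cfg.shift_vector is None
        else np.asarray(cfg.shift_vector, dtype=float)
    )
    if shift.shape != (cfg.d,):
        raise ValueError("shift_vector must have length d")

    if cfg.concept_means is not None:
        means = np.asarray(cfg.concept_means, dtype=float)
        if means.shape != (cfg.n_classes, cfg.d):
            raise ValueError("concept_means must be K x d")
    else:
        means = rng.normal(size=(cfg.n_classes, cfg.d))
        means *= cfg.concept_scale / np.maximum(
            np.linalg.norm(means, axis=1, keepdims=True), 1e-12
        )
        # keep the log density ratio linear along the shift direction
        means = _project_off(means, shift)

    # per-instance concept probability q chosen so that a bag of the mean size
    # is positive for a class with probability ~ label_rate
    q = 1.0 - (1.0 - cfg.label_rate) ** (1.0 / cfg.bag_size_mean)
    q = min(q, 0.9 / cfg.n_classes)
    mix = np.concatenate([[1.0 - cfg.n_classes * q], np.full(cfg.n_classes, q)])

    src_bags, src_labels, src_assign = _draw_domain(
        rng, cfg, means, mix, np.zeros(cfg.d), cfg.n_source, "s"
    )
    tgt_bags, tgt_labels, tgt_assign = _draw_domain(
        rng, cfg, means, mix, shift, cfg.n_target, "t"
    )
    class_ids = [f"c{k:03d}" for k in range(cfg.n_classes)]
    source = MIMLDataset(src_bags, src_labels, class_ids, domain="source")
    target = MIMLDataset(tgt_bags, tgt_labels, class_ids, domain="target")
    truth = GroundTruth(
        concept_means=means,
        concept_spread=cfg.concept_spread,
        background_spread=cfg.background_spread,
        mix_weights=mix,
        shift_vector=shift,
        concept_assignments_source=src_assign,
        concept_assignments_target=tgt_assign,
    )
    return source, target, truth


def true_density_ratio(truth: GroundTruth, bag: Bag) -> float:
    """Exact ``P'(X)/P(X)`` of a bag under the generative model.

    The bag-size law is shared by both domains, so the ratio reduces to the
    product over instances of the target/source mixture-density quotient.
    """
    log_p_tgt = truth._log_instance_density(bag.instances, shift=True)
    log_p_src = truth._log_instance_density(bag.instances, shift=False)
    return float(np.exp((log_p_tgt - log_p_src).sum()))


def split_by_feature_median(dataset: MIMLDataset) -> DomainSplit:
    """Deterministic median split on the per-bag mean feature value.

    Bags whose statistic is >= the median go to the source domain; sizes
    differ by at most one (ties resolved by stable index order).
    """
    n = dataset.n_bags
    if n < 2:
        raise ValueError("need at least two bags to split")
    stats = np.array([float(bag.instances.mean()) for bag in dataset.bags])
    # stable sort descending: larger statistic -> source
    order = np.argsort(-stats, kind="stable")
    n_src = (n + 1) // 2
    source = np.sort(order[:n_src])
    target = np.sort(order[n_src:])
    return DomainSplit(source_indices=source, target_indices=target)


def split_random_clusters(dataset: MIMLDataset, seed: int) -> DomainSplit:
    """2-means clustering of bag means; one cluster (seed-chosen) is source."""
    n = dataset.n_bags
    if n < 2:
        raise ValueError("need at least two bags to split")
    rng = np.random.default_rng(seed)
    centers = np.vstack([bag_mean(b) for b in dataset.bags])
    _, assign = kmeans2(centers, 2, minit="++", seed=rng, missing="warn")
    if len(np.unique(assign)) < 2:  # degenerate: all bags identical
        assign = (np.arange(n) >= (n + 1) // 2).astype(int)
    source_cluster = int(rng.integers(2))
    source = np.flatnonzero(assign == source_cluster)
    target = np.flatnonzero(assign != source_cluster)
    return DomainSplit(source_indices=source, target_indices=target)
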