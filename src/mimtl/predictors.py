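"""Prediction heads consuming a learned per-class bag metric.

Two heads are provided:

* :class:`KnnHead` — citation-kNN voting over the ``r`` nearest training bags
  (references) and the training bags that count the test bag among their own
  ``c`` nearest neighbours (citers);
* :class:`MedoidEmbeddingHead` — per class, cluster the training bags into
  k-medoids under the class metric, embed every bag as its vector of distances
  to the medoids, and fit a binary RBF max-margin classifier on the embedding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .metric_learning import MetricModel, bag_distance
from .miml_data import Bag, MIMLDataset, bag_mean

__all__ = [
    "KnnHead",
    "MedoidEmbeddingHead",
    "citation_knn_predict",
    "kmedoids_bags",
    "bag_embedding",
    "fit_knn_head",
    "fit_svm_head",
    "predict",
]

logger = logging.getLogger(__name__)


def _metric_A(metric_models: dict[str, MetricModel], class_k: str, d: int) -> np.ndarray:
    model = metric_models.get(class_k)
    return np.eye(d) if model is None else model.A


def _pairwise_bag_dists(means_x: np.ndarray, means_y: np.ndarray, A: np.ndarray) -> np.ndarray:
    tx = means_x @ A.T
    ty = means_y @ A.T
    sq = (
        (tx**2).sum(axis=1)[:, None]
        - 2.0 * tx @ ty.T
        + (ty**2).sum(axis=1)[None, :]
    )
    return np.maximum(sq, 0.0)


@dataclass
class KnnHead:
    """Citation-kNN head: votes from references and citers per class."""

    r: int
    c: int
    metric_models: dict[str, MetricModel]
    train: MIMLDataset

    def __post_init__(self) -> None:
        if self.r < 1 or self.c < 0:
            raise ValueError("need r >= 1 and c >= 0")
        if self.train.n_bags == 0:
            raise ValueError("empty training set")

    @property
    def class_ids(self) -> list[str]:
        return [c for c in self.train.class_ids if c in self.metric_models]


@dataclass
class MedoidEmbeddingHead:
    """k-medoid embedding + binary RBF SVM, one per class."""

    train: MIMLDataset
    metric_models: dict[str, MetricModel]
    medoid_indices: dict[str, np.ndarray]
    classifiers: dict[str, SVC | None]  # None marks a degenerate constant class
    constant_labels: dict[str, int]
    scalers: dict[str, tuple[np.ndarray, np.ndarray]]  # per-class (mean, std)
    cluster_ratio: float = 0.4

    @property
    def class_ids(self) -> list[str]:
        return list(self.medoid_indices.keys())


def citation_knn_predict(
    test_bag: Bag, head: KnnHead, class_k: str
) -> tuple[int, float]:
    """Vote class-k labels of references and citers of the test bag.

    References are the ``r`` training bags nearest to the test bag under the
    class metric.  A training bag B is a citer when the test bag ranks within
    B's ``c`` nearest neighbours among all other training bags plus the test
    bag (rank = 1 + number of strictly closer candidates).  Votes form a
    multiset; ties predict negative; confidence = positive votes / total.
    """
    train = head.train
    n = train.n_bags
    if n == 0:
        raise ValueError("empty training set")
    A = _metric_A(head.metric_models, class_k, train.d)
    k = train.class_ids.index(class_k)
    y = train.labels[:, k]

    train_means = np.vstack([bag_mean(b) for b in train.bags])
    test_mean = bag_mean(test_bag)[None, :]
    d_test = _pairwise_bag_dists(test_mean, train_means, A)[0]  # test -> each train
    d_train = _pairwise_bag_dists(train_means, train_means, A)

    order = np.argsort(d_test, kind="stable")
    references = order[: min(head.r, n)]

    citers = []
    for b in range(n):
        # candidates: all other training bags plus the test bag
        others = np.delete(d_train[b], b)
        rank = 1 + int((others < d_test[b]).sum())
        if rank <= head.c:
            citers.append(b)

    voters = list(references) + citers
    if not voters:
        return 0, 0.5
    pos = int(sum(y[v] for v in voters))
    total = len(voters)
    label = 1 if pos > total - pos else 0
    return label, pos / total


def kmedoids_bags(
    bags: list[Bag], A: np.ndarray, k: int, seed: int = 0, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating k-medoids on bag distances; medoids are input bags.

    Assignment ties break toward the lowest medoid index; the medoid update
    picks the cluster member minimizing the within-cluster distance sum (ties
    to the lowest index).  Deterministic given ``seed``.
    """
    n = len(bags)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} bags")
    means = np.vstack([bag_mean(b) for b in bags])
    dist = _pairwise_bag_dists(means, means, A)
    rng = np.random.default_rng(seed)
    medoids = np.sort(rng.choice(n, size=k, replace=False))
    for _ in range(max_iter):
        assign = np.argmin(dist[:, medoids], axis=1)  # ties -> lowest position
        new_medoids = medoids.copy()
        for ci in range(k):
            members = np.flatnonzero(assign == ci)
            if members.size == 0:
                continue
            costs = dist[np.ix_(members, members)].sum(axis=0)
            new_medoids[ci] = members[int(np.argmin(costs))]
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    assign = np.argmin(dist[:, medoids], axis=1)
    return medoids, assign


def bag_embedding(bag: Bag, medoid_bags: list[Bag], A: np.ndarray) -> np.ndarray:
    """Vector of squared metric distances from the bag to each medoid."""
    return np.array([bag_distance(bag, m, A) for m in medoid_bags])


def _embed_all(bags: list[Bag], medoid_bags: list[Bag], A: np.ndarray) -> np.ndarray:
    means = np.vstack([bag_mean(b) for b in bags])
    med_means = np.vstack([bag_mean(m) for m in medoid_bags])
    return _pairwise_bag_dists(means, med_means, A)


def fit_knn_head(
    train: MIMLDataset,
    metric_models: dict[str, MetricModel],
    r: int = 3,
    c: int = 5,
) -> KnnHead:
    return KnnHead(r=r, c=c, metric_models=metric_models, train=train)


def fit_svm_head(
    train: MIMLDataset,
    metric_models: dict[str, MetricModel],
    cluster_ratio: float = 0.4,
    svm_c: float = 1.0,
    svm_gamma: float = 0.2,
    seed: int = 0,
    classes: list[str] | None = None,
) -> MedoidEmbeddingHead:
    """Per class: k-medoid the training bags under the class metric, embed,
    and fit a binary RBF SVM (defaults cost 1, kernel coefficient 0.2).

    ``k = max(1, round(cluster_ratio * n_train_bags))``.  A class whose
    training labels are constant gets a constant predictor (logged).
    """
    if classes is None:
        classes = [c_ for c_ in train.class_ids if c_ in metric_models] or list(
            train.class_ids
        )
    n = train.n_bags
    k = max(1, round(cluster_ratio * n))
    medoid_indices: dict[str, np.ndarray] = {}
    classifiers: dict[str, SVC | None] = {}
    constant_labels: dict[str, int] = {}
    scalers: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for class_k in classes:
        A = _metric_A(metric_models, class_k, train.d)
        medoids, _ = kmedoids_bags(train.bags, A, k, seed=seed)
        medoid_indices[class_k] = medoids
        y = train.labels[:, train.class_ids.index(class_k)]
        if len(np.unique(y)) < 2:
            logger.warning(
                "class %s has constant training labels; using constant predictor",
                class_k,
            )
            classifiers[class_k] = None
            constant_labels[class_k] = int(y[0])
            continue
        Z = _embed_all(train.bags, [train.bags[m] for m in medoids], A)
        # standardize with training stats so the RBF width is scale-free
        mu = Z.mean(axis=0)
        sd = Z.std(axis=0)
        sd[sd == 0] = 1.0
        scalers[class_k] = (mu, sd)
        clf = SVC(C=svm_c, gamma=svm_gamma, kernel="rbf", random_state=seed)
        clf.fit((Z - mu) / sd, y)
        classifiers[class_k] = clf
    return MedoidEmbeddingHead(
        train=train,
        metric_models=metric_models,
        medoid_indices=medoid_indices,
        classifiers=classifiers,
        constant_labels=constant_labels,
        scalers=scalers,
        cluster_ratio=cluster_ratio,
    )


def predict(
    test: MIMLDataset, head: KnnHead | MedoidEmbeddingHead
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Predict labels and confidences for every test bag and trained class.

    Returns ``(labels, confidences, class_ids)`` with shape
    ``n_test x len(class_ids)``; label = 1 exactly when confidence > 0.5.
    """
    if test.n_bags and test.d != head.train.d:
        raise ValueError("test dimension does not match training dimension")
    class_ids = head.class_ids
    n = test.n_bags
    labels = np.zeros((n, len(class_ids)), dtype=int)
    confidences = np.zeros((n, len(class_ids)))
    if isinstance(head, KnnHead):
        for j, class_k in enumerate(class_ids):
            for i, bag in enumerate(test.bags):
                lab, conf = citation_knn_predict(bag, head, class_k)
                labels[i, j] = lab
                confidences[i, j] = conf
        return labels, confidences, class_ids
    for j, class_k in enumerate(class_ids):
        clf = head.classifiers[class_k]
        if clf is None:
            const = head.constant_labels[class_k]
            labels[:, j] = const
            confidences[:, j] = 1.0 if const == 1 else 0.0
            continue
        A = _metric_A(head.metric_models, class_k, head.train.d)
        medoid_bags = [head.train.bags[m] for m in head.medoid_indices[class_k]]
        Z = _embed_all(test.bags, medoid_bags, A)
        mu, sd = head.scalers[class_k]
        dec = clf.decision_function((Z - mu) / sd)
        # logistic squashing: ranking metrics are invariant to this monotone map
        confidences[:, j] = 1.0 / (1.0 + np.exp(-dec))
        labels[:, j] = (dec > 0).astype(int)
    return labels, confidences, class_ids
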