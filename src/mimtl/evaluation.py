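"""Multi-label ranking metrics, the repeated benchmark harness, and the
Friedman/Nemenyi average-rank comparison.

Tie conventions are the pessimistic ones: a tie between a relevant and an
irrelevant confidence counts as misordered in the ranking loss, and coverage
assigns every tied confidence the worst (largest) rank of its tie group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .importance_weights import estimate_weights
from .metric_learning import MetricHyperparams, train_per_class
from .miml_data import MIMLDataset, centralize, apply_centering
from .predictors import fit_knn_head, fit_svm_head, predict
from .synthetic_data import GeneratorConfig, generate_shifted_miml

__all__ = [
    "EvalReport",
    "RankTable",
    "ranking_loss",
    "coverage",
    "set_metrics",
    "score_predictions",
    "benchmark_run",
    "friedman_nemenyi",
    "METHODS",
]

#: headline metrics reported by the benchmark harness
HEADLINE_METRICS = ("ranking_loss", "coverage", "avg_recall", "avg_f1")


@dataclass
class EvalReport:
    """Per-run metric rows plus mean/std aggregation for one method."""

    method: str
    dataset: str
    per_run: list[dict[str, float]]
    seeds: list[int]

    @property
    def mean(self) -> dict[str, float]:
        keys = self.per_run[0].keys()
        return {k: float(np.mean([r[k] for r in self.per_run])) for k in keys}

    @property
    def std(self) -> dict[str, float]:
        keys = self.per_run[0].keys()
        return {k: float(np.std([r[k] for r in self.per_run])) for k in keys}


@dataclass
class RankTable:
    """Average-rank comparison of methods across datasets."""

    methods: list[str]
    scores: np.ndarray  # datasets x methods
    ranks: np.ndarray  # datasets x methods, ties averaged
    average_ranks: np.ndarray
    critical_distance: float
    alpha: float
    friedman_statistic: float
    friedman_pvalue: float
    significant_pairs: list[tuple[str, str]] = field(default_factory=list)


def ranking_loss(confidences: np.ndarray, Y: np.ndarray) -> float:
    """Average fraction of (relevant, irrelevant) label pairs that are
    misordered by the confidences; ties count as misordered.

    Bags with an empty or full relevant set are skipped; if every bag is
    skipped the metric is undefined and an error is raised.
    """
    confidences = np.asarray(confidences, dtype=float)
    Y = np.asarray(Y)
    if confidences.shape != Y.shape:
        raise ValueError("shape mismatch")
    losses = []
    for i in range(Y.shape[0]):
        rel = np.flatnonzero(Y[i] == 1)
        irr = np.flatnonzero(Y[i] == 0)
        if rel.size == 0 or irr.size == 0:
            continue
        # pair (y, y') misordered when h(y) <= h(y')
        bad = (confidences[i, rel][:, None] <= confidences[i, irr][None, :]).sum()
        losses.append(bad / (rel.size * irr.size))
    if not losses:
        raise ValueError("ranking loss undefined: no bag with a proper label subset")
    return float(np.mean(losses))


def coverage(confidences: np.ndarray, Y: np.ndarray) -> float:
    """Mean over bags of (worst rank of any relevant label) - 1.

    Rank 1 is the highest confidence; tied confidences all receive the worst
    rank of their tie group.  Bags with no relevant label contribute 0.
    """
    confidences = np.asarray(confidences, dtype=float)
    Y = np.asarray(Y)
    if confidences.shape != Y.shape:
        raise ValueError("shape mismatch")
    vals = []
    for i in range(Y.shape[0]):
        rel = np.flatnonzero(Y[i] == 1)
        if rel.size == 0:
            vals.append(0.0)
            continue
        ranks = stats.rankdata(-confidences[i], method="max")
        vals.append(float(ranks[rel].max()) - 1.0)
    return float(np.mean(vals))


def set_metrics(
    pred_labels: np.ndarray, Y: np.ndarray
) -> tuple[float, float, float]:
    """Set-based (avg_recall, avg_precision, avg_f1).

    Recall averages over bags with at least one relevant label, precision over
    bags with at least one predicted label; F1 is the harmonic mean of the two
    averages (0 when both are 0).
    """
    pred_labels = np.asarray(pred_labels)
    Y = np.asarray(Y)
    if pred_labels.shape != Y.shape:
        raise ValueError("shape mismatch")
    inter = ((pred_labels == 1) & (Y == 1)).sum(axis=1)
    n_rel = (Y == 1).sum(axis=1)
    n_pred = (pred_labels == 1).sum(axis=1)
    has_rel = n_rel > 0
    if not has_rel.any():
        raise ValueError("avg_recall undefined: no bag has a relevant label")
    recall = float((inter[has_rel] / n_rel[has_rel]).mean())
    has_pred = n_pred > 0
    precision = float((inter[has_pred] / n_pred[has_pred]).mean()) if has_pred.any() else 0.0
    f1 = 0.0 if precision + recall == 0 else 2.0 * precision * recall / (precision + recall)
    return recall, precision, f1


def score_predictions(
    labels: np.ndarray, confidences: np.ndarray, Y: np.ndarray
) -> dict[str, float]:
    """All five metrics in one dictionary."""
    recall, precision, f1 = set_metrics(labels, Y)
    return {
        "ranking_loss": ranking_loss(confidences, Y),
        "coverage": coverage(confidences, Y),
        "avg_recall": recall,
        "avg_precision": precision,
        "avg_f1": f1,
    }


def _run_method(
    method: str,
    source: MIMLDataset,
    target: MIMLDataset,
    seed: int,
    hyperparams: MetricHyperparams | None,
    knn_r: int,
    knn_c: int,
    cluster_ratio: float,
) -> dict[str, float]:
    hp = hyperparams if hyperparams is not None else MetricHyperparams(seed=seed)
    centered_source, transform = centralize(source)
    centered_target = apply_centering(target, transform)

    if method in ("mimtl_svm", "mimtl_knn"):
        omega = estimate_weights(source, target, seed=seed).omega
    else:  # unweighted variants
        omega = np.ones(source.n_bags)

    if method == "euclidean_svm_baseline":
        metric_models = {}  # A = I fallback per class
        classes = list(source.class_ids)
    else:
        metric_models = train_per_class(centered_source, omega, None, hp)
        classes = list(metric_models.keys())

    if method == "mimtl_knn":
        head = fit_knn_head(centered_source, metric_models, r=knn_r, c=knn_c)
    else:
        head = fit_svm_head(
            centered_source,
            metric_models,
            cluster_ratio=cluster_ratio,
            seed=seed,
            classes=classes,
        )
    labels, confidences, class_ids = predict(centered_target, head)
    cols = [target.class_ids.index(c) for c in class_ids]
    return score_predictions(labels, confidences, target.labels[:, cols])


METHODS = ("mimtl_svm", "mimtl_knn", "euclidean_svm_baseline", "unweighted_metric")


def benchmark_run(
    config: GeneratorConfig,
    methods: list[str],
    n_reps: int,
    seeds: list[int] | None = None,
    hyperparams: MetricHyperparams | None = None,
    knn_r: int = 3,
    knn_c: int = 5,
    cluster_ratio: float = 0.4,
    dataset_name: str = "synthetic",
) -> dict[str, EvalReport]:
    """Repeat generate/fit/predict/score ``n_reps`` times per method.

    Each repetition regenerates a source/target pair under its own seed;
    results are fully reproducible from the seed list.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
    if seeds is None:
        seeds = [config.seed + rep for rep in range(n_reps)]
    if len(seeds) != n_reps:
        raise ValueError("need one seed per repetition")
    per_method: dict[str, list[dict[str, float]]] = {m: [] for m in methods}
    for seed in seeds:
        cfg = GeneratorConfig(**{**config.__dict__, "seed": seed})
        source, target, _ = generate_shifted_miml(cfg)
        for m in methods:
            per_method[m].append(
                _run_method(
                    m, source, target, seed, hyperparams, knn_r, knn_c, cluster_ratio
                )
            )
    return {
        m: EvalReport(method=m, dataset=dataset_name, per_run=per_method[m], seeds=list(seeds))
        for m in methods
    }


# Nemenyi critical values q_alpha (already divided by sqrt(2)) indexed by the
# number of compared methods m = 2..10.
_NEMENYI_Q = {
    0.05: [1.960, 2.343, 2.569, 2.728, 2.850, 2.949, 3.031, 3.102, 3.164],
    0.10: [1.645, 2.052, 2.291, 2.459, 2.589, 2.693, 2.780, 2.855, 2.920],
}


def friedman_nemenyi(
    score_matrix: np.ndarray,
    methods: list[str],
    higher_is_better: bool = True,
    alpha: float = 0.05,
) -> RankTable:
    """Average ranks across datasets plus the Nemenyi critical distance.

    ``score_matrix`` is datasets x methods.  Per-dataset ranks average ties;
    rank 1 is the best method.  ``CD = q_alpha * sqrt(m (m + 1) / (6 N))``;
    method pairs whose average ranks differ by at least CD are flagged.
    """
    scores = np.asarray(score_matrix, dtype=float)
    if scores.ndim != 2:
        raise ValueError("score_matrix must be 2-D (datasets x methods)")
    n_datasets, m = scores.shape
    if m != len(methods):
        raise ValueError("method names do not match score columns")
    if m < 2 or n_datasets < 2:
        raise ValueError("need at least 2 methods and 2 datasets")
    if alpha not in _NEMENYI_Q:
        raise ValueError(f"alpha must be one of {sorted(_NEMENYI_Q)}")
    if m > len(_NEMENYI_Q[alpha]) + 1:
        raise ValueError("no tabulated critical value for this many methods")

    oriented = -scores if higher_is_better else scores
    ranks = np.vstack([stats.rankdata(row, method="average") for row in oriented])
    avg_ranks = ranks.mean(axis=0)

    # Friedman chi-square with tie-free formula (adequate for reporting)
    chi2 = (
        12.0 * n_datasets / (m * (m + 1)) * ((avg_ranks**2).sum() - m * (m + 1) ** 2 / 4.0)
    )
    pvalue = float(stats.chi2.sf(chi2, df=m - 1))

    q = _NEMENYI_Q[alpha][m - 2]
    cd = q * np.sqrt(m * (m + 1) / (6.0 * n_datasets))
    pairs = [
        (methods[i], methods[j])
        for i in range(m)
        for j in range(i + 1, m)
        if abs(avg_ranks[i] - avg_ranks[j]) >= cd
    ]
    return RankTable(
        methods=list(methods),
        scores=scores,
        ranks=ranks,
        average_ranks=avg_ranks,
        critical_distance=float(cd),
        alpha=alpha,
        friedman_statistic=float(chi2),
        friedman_pvalue=pvalue,
        significant_pairs=pairs,
    )
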