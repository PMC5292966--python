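# mimtl

Multi-instance metric transfer learning for multi-label bag classification
(e.g. genome-wide protein function annotation, where a protein is a bag of
domain feature vectors and the labels are function terms).

The pipeline has three stages:

1. **Bag importance weighting** (`mimtl.importance_weights`) — estimate
   `omega(X) = P'(X)/P(X)`, the density ratio between the target- and
   source-domain bag distributions, by non-negative least squares over a
   normalized summed-RBF set-kernel basis anchored at target bags.
2. **Per-class Mahalanobis metric learning** (`mimtl.metric_learning`) —
   for each class fit a linear map `A` (metric `M = AᵀA`) that compacts each
   bag around its center and pushes oppositely labelled bags at least a
   margin apart, with per-constraint slack and the constraints weighted by
   `omega` (labelled target bags weigh 1). The constrained problem is relaxed
   with quadratic one-sided penalties and minimized by block gradient descent
   with backtracking.
3. **Prediction heads** (`mimtl.predictors`) — citation-kNN voting
   (references + citers) or a k-medoid bag embedding followed by a binary RBF
   SVM, both consuming the learned per-class metric.

Supporting modules: `mimtl.miml_data` (bag/dataset model, TSV serialization,
centering), `mimtl.synthetic_data` (covariate-shifted generator with an
exactly known density ratio, plus median and random-cluster domain splits),
and `mimtl.evaluation` (ranking loss, coverage, average recall/precision/F1,
the repeated benchmark harness, and Friedman/Nemenyi average-rank tests).

## Data format

Bag table (TSV): header `bag_id<TAB>f1...fd`, one row per instance, instance
order within a bag is file order. Labels table (TSV): header
`bag_id<TAB>labels`, where `labels` is a comma-separated list of class ids
(empty allowed).

## CLI

All commands are deterministic given `--seed`; re-runs are byte-identical.

```sh
# generate a covariate-shifted synthetic dataset pair + true-ratio sidecar
mimtl simulate --d 8 --n-classes 3 --n-source 100 --n-target 100 \
    --shift 1,1,0,0,0,0,0,0 --seed 0 --out-prefix data/sim

# estimate source-bag importance weights
mimtl weights --source-bags data/sim.source.bags.tsv \
    --source-labels data/sim.source.labels.tsv \
    --target-bags data/sim.target.bags.tsv \
    --target-labels data/sim.target.labels.tsv \
    --gamma auto --seed 0 --out data/omega.tsv

# fit per-class metrics (JSON model archive)
mimtl train --train-bags data/sim.source.bags.tsv \
    --train-labels data/sim.source.labels.tsv \
    --weights data/omega.tsv --seed 0 --out data/model.json

# predict with either head
mimtl predict --model data/model.json \
    --train-bags data/sim.source.bags.tsv --train-labels data/sim.source.labels.tsv \
    --test-bags data/sim.target.bags.tsv --test-labels data/sim.target.labels.tsv \
    --head svm --out-confidence data/conf.tsv --out-labels data/pred.tsv

# score predictions
mimtl evaluate --confidence data/conf.tsv --pred-labels data/pred.tsv \
    --true-labels data/sim.target.labels.tsv --out data/report.json

# repeated benchmark + average-rank table
mimtl benchmark --config bench.json --out-report report.json --out-ranks ranks.tsv
```

`bench.json` holds generator fields plus `methods` (from `mimtl_svm`,
`mimtl_knn`, `euclidean_svm_baseline`, `unweighted_metric`), `n_reps` and
optional `seeds`.

## Acceptance

`tests/test_acceptance.py` holds the property-based acceptance suite
(gradient correctness against finite differences, optimizer descent
contract, brute-force oracles for the weight system / NNLS / metrics /
citation-kNN / k-medoids, density-ratio recovery, expected-loss consistency
under importance weighting, metric benefit, end-to-end shift benefit, CLI
determinism).

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs a fast end-to-end self-check and writes the target report. There are no
numeric headline targets: the published tables are measured on external
organism datasets that are not bundled here, so the report is an empty JSON
object by design.
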