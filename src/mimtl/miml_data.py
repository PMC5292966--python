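"""Core multi-instance multi-label (MIML) data model and plain-text serialization.

A :class:`Bag` is an ordered set of instance vectors representing one object
(e.g. a protein whose structural domains are the instances).  A
:class:`MIMLDataset` couples a list of bags with a binary bag-by-class label
matrix.  The on-disk format is two UTF-8 TSV files:

* bag table -- header ``bag_id<TAB>f1<TAB>...<TAB>fd``, one row per instance,
  instance order within a bag is file order;
* labels table -- header ``bag_id<TAB>labels`` where ``labels`` is a
  comma-separated list of class identifiers (may be empty).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Bag",
    "MIMLDataset",
    "CenteringTransform",
    "MIMLFormatError",
    "read_miml_table",
    "write_miml_table",
    "bag_mean",
    "centralize",
    "apply_centering",
]


class MIMLFormatError(ValueError):
    """Raised when a bag table or labels table violates the format contract."""


@dataclass(frozen=True)
class Bag:
    """One bag: an identifier plus an ``n_i x d`` matrix of instance vectors."""

    bag_id: str
    instances: np.ndarray

    def __post_init__(self) -> None:
        inst = np.asarray(self.instances, dtype=float)
        if inst.ndim != 2:
            raise ValueError(f"bag {self.bag_id!r}: instances must be 2-D")
        if inst.shape[0] < 1:
            raise ValueError(f"bag {self.bag_id!r}: need at least one instance")
        if not np.all(np.isfinite(inst)):
            raise ValueError(f"bag {self.bag_id!r}: non-finite instance values")
        object.__setattr__(self, "instances", inst)

    @property
    def n_instances(self) -> int:
        return self.instances.shape[0]

    @property
    def d(self) -> int:
        return self.instances.shape[1]


@dataclass
class MIMLDataset:
    """Bags plus an aligned binary label matrix.

    ``labels[i, k] == 1`` iff ``bags[i]`` is annotated with ``class_ids[k]``.
    ``domain`` tags the dataset as ``"source"``, ``"target"`` or ``"unsplit"``.
    """

    bags: list[Bag]
    labels: np.ndarray
    class_ids: list[str]
    domain: str = "unsplit"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D matrix")
        if self.labels.shape != (len(self.bags), len(self.class_ids)):
            raise ValueError(
                f"labels shape {self.labels.shape} does not match "
                f"({len(self.bags)} bags, {len(self.class_ids)} classes)"
            )
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        if self.domain not in ("source", "target", "unsplit"):
            raise ValueError(f"unknown domain tag {self.domain!r}")
        dims = {b.d for b in self.bags}
        if len(dims) > 1:
            raise ValueError(f"bags have inconsistent dimensions: {sorted(dims)}")

    @property
    def n_bags(self) -> int:
        return len(self.bags)

    @property
    def n_classes(self) -> int:
        return len(self.class_ids)

    @property
    def d(self) -> int:
        if not self.bags:
            raise ValueError("empty dataset has no dimension")
        return self.bags[0].d

    @property
    def n_all(self) -> int:
        """Total instance count over all bags."""
        return sum(b.n_instances for b in self.bags)

    def all_instances(self) -> np.ndarray:
        """Stack every instance of every bag into one ``n_all x d`` matrix."""
        return np.vstack([b.instances for b in self.bags])

    def subset(self, indices: Sequence[int], domain: str | None = None) -> "MIMLDataset":
        idx = list(indices)
        return MIMLDataset(
            bags=[self.bags[i] for i in idx],
            labels=self.labels[idx],
            class_ids=list(self.class_ids),
            domain=domain if domain is not None else self.domain,
        )


@dataclass(frozen=True)
class CenteringTransform:
    """Grand-mean shift fitted on training-visible instances.

    ``mean_vector`` is the mean over all ``n_all`` instances (instance-weighted,
    not bag-weighted).  Apply to held-out bags to map them into the same frame.
    """

    mean_vector: np.ndarray
    n_all: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_vector", np.asarray(self.mean_vector, dtype=float))


def bag_mean(bag: Bag) -> np.ndarray:
    """Arithmetic mean of the bag's instances (also used as the bag center)."""
    return bag.instances.mean(axis=0)


def centralize(dataset: MIMLDataset) -> tuple[MIMLDataset, CenteringTransform]:
    """Subtract the grand instance mean from every instance.

    The mean is taken over all instances of all bags (``n_all`` denominator).
    Returns the shifted dataset and the reusable transform.
    """
    if dataset.n_bags == 0:
        raise ValueError("cannot centralize an empty dataset")
    all_inst = dataset.all_instances()
    mean_vector = all_inst.mean(axis=0)
    transform = CenteringTransform(mean_vector=mean_vector, n_all=all_inst.shape[0])
    return apply_centering(dataset, transform), transform


def apply_centering(dataset: MIMLDataset, transform: CenteringTransform) -> MIMLDataset:
    """Shift every instance of ``dataset`` by a previously fitted transform."""
    bags = [Bag(b.bag_id, b.instances - transform.mean_vector) for b in dataset.bags]
    return MIMLDataset(
        bags=bags,
        labels=dataset.labels.copy(),
        class_ids=list(dataset.class_ids),
        domain=dataset.domain,
    )


def read_miml_table(path_bags: str, path_labels: str) -> MIMLDataset:
    """Read a bag table plus labels table into a :class:`MIMLDataset`.

    Bag order follows first appearance in the labels table; every labelled
    bag_id must have at least one instance row in the bag table.
    """
    instances_by_bag: dict[str, list[np.ndarray]] = {}
    with open(path_bags, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "bag_id":
            raise MIMLFormatError(f"{path_bags}: malformed header {header!r}")
        d = len(header) - 1
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != d + 1:
                raise MIMLFormatError(
                    f"{path_bags}:{lineno}: expected {d} features, got {len(parts) - 1}"
                )
            try:
                vec = np.array([float(x) for x in parts[1:]], dtype=float)
            except ValueError as exc:
                raise MIMLFormatError(f"{path_bags}:{lineno}: non-numeric feature") from exc
            instances_by_bag.setdefault(parts[0], []).append(vec)

    bag_order: list[str] = []
    label_sets: dict[str, list[str]] = {}
    with open(path_labels, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["bag_id", "labels"]:
            raise MIMLFormatError(f"{path_labels}: malformed header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            bag_id = parts[0]
            labels_field = parts[1] if len(parts) > 1 else ""
            if bag_id not in instances_by_bag:
                raise MIMLFormatError(
                    f"{path_labels}:{lineno}: bag {bag_id!r} has no instances in bag table"
                )
            bag_order.append(bag_id)
            label_sets[bag_id] = [t for t in labels_field.split(",") if t]

    class_ids = sorted({c for labs in label_sets.values() for c in labs})
    class_index = {c: k for k, c in enumerate(class_ids)}
    bags = [Bag(bid, np.vstack(instances_by_bag[bid])) for bid in bag_order]
    labels = np.zeros((len(bags), len(class_ids)), dtype=int)
    for i, bid in enumerate(bag_order):
        for c in label_sets[bid]:
            labels[i, class_index[c]] = 1
    return MIMLDataset(bags=bags, labels=labels, class_ids=class_ids)


def write_miml_table(dataset: MIMLDataset, path_bags: str, path_labels: str) -> None:
    """Write a dataset in the bag-table / labels-table TSV format.

    Floats use ``repr`` (shortest round-tripping decimal), so reading the files
    back reproduces the instance matrices exactly.
    """
    d = dataset.d
    with open(path_bags, "w", encoding="utf-8") as fh:
        fh.write("bag_id\t" + "\t".join(f"f{j + 1}" for j in range(d)) + "\n")
        for bag in dataset.bags:
            for row in bag.instances:
                fh.write(bag.bag_id + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")
    with open(path_labels, "w", encoding="utf-8") as fh:
        fh.write("bag_id\tlabels\n")
        for i, bag in enumerate(dataset.bags):
            labs = [dataset.class_ids[k] for k in np.flatnonzero(dataset.labels[i])]
            fh.write(bag.bag_id + "\t" + ",".join(labs) + "\n")
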