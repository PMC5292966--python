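import numpy as np
import pytest

from mimtl import Bag, MIMLDataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_bag(rng, bag_id="b", n=3, d=4, scale=1.0):
    return Bag(bag_id, scale * rng.normal(size=(n, d)))


def make_dataset(rng, n_bags=6, d=4, n_classes=2, max_inst=4, domain="unsplit"):
    bags = [
        make_bag(rng, f"bag{i}", n=int(rng.integers(1, max_inst + 1)), d=d)
        for i in range(n_bags)
    ]
    labels = rng.integers(0, 2, size=(n_bags, n_classes))
    # guarantee at least one positive and one negative per class
    for k in range(n_classes):
        labels[k % n_bags, k] = 1
        if (k + 1) % n_bags != k % n_bags:
            labels[(k + 1) % n_bags, k] = 0
    class_ids = [f"c{k:03d}" for k in range(n_classes)]
    return MIMLDataset(bags=bags, labels=labels, class_ids=class_ids, domain=domain)


@pytest.fixture
def small_dataset(rng):
    return make_dataset(rng)
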