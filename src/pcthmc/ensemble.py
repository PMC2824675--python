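"""Bagged ensembles of predictive clustering trees.

Bagging trains ``k`` trees on bootstrap replicates of the training set
(sampled with replacement until each replicate has the original size) and
predicts with the unweighted mean of the per-tree class vectors, after
which a threshold can be applied exactly as for a single tree.  Averaging
parent-monotone vectors preserves parent-monotonicity, so ensemble
predictions also respect the hierarchy constraint.

Out-of-bag (OOB) estimation aggregates, for each training instance, only
the trees whose bootstrap replicate excluded it, giving an honest
performance estimate without a set-aside test set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dataset_io import Dataset, PredictionMatrix
from .pct import PCTParams, PCTree, build_tree

__all__ = [
    "DEFAULT_N_TREES",
    "EnsembleModel",
    "bootstrap_sample",
    "fit_bagging",
    "predict_ensemble",
    "oob_predictions",
]

#: default ensemble size; larger ensembles bring little further gain
DEFAULT_N_TREES = 50


def bootstrap_sample(n: int, rng: np.random.Generator):
    """Draw one bootstrap replicate of ``0..n-1``.

    Returns ``(sample, out_of_bag)``: a length-``n`` index array drawn with
    replacement, and the sorted array of indices it never picked.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sample = rng.integers(0, n, size=n)
    in_bag = np.zeros(n, dtype=bool)
    in_bag[sample] = True
    return sample, np.flatnonzero(~in_bag)


@dataclass
class EnsembleModel:
    """k bootstrap-trained trees plus their bag memberships."""

    trees: list[PCTree]
    bag_membership: list[np.ndarray]
    params: PCTParams
    n_trees: int
    rng_seed: int
    n_training: int
    bootstrap: bool = True

    @property
    def hierarchy(self):
        return self.trees[0].hierarchy

    def predict(self, instance) -> np.ndarray:
        return np.mean([t.predict(instance) for t in self.trees], axis=0)

    def predict_dataset(self, d: Dataset) -> np.ndarray:
        out = np.zeros((d.n_instances, len(self.hierarchy.classes)))
        for t in self.trees:
            out += t.predict_dataset(d)
        return out / len(self.trees)

    def to_dict(self) -> dict:
        return {
            "format": "pcthmc-model",
            "version": 1,
            "kind": "ensemble",
            "n_trees": self.n_trees,
            "rng_seed": self.rng_seed,
            "n_training": self.n_training,
            "bootstrap": self.bootstrap,
            "bag_membership": [b.tolist() for b in self.bag_membership],
            "trees": [t.to_dict() for t in self.trees],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_dict(cls, obj: dict) -> "EnsembleModel":
        if obj.get("kind") != "ensemble":
            raise ValueError("not an ensemble model")
        trees = [PCTree.from_dict(t) for t in obj["trees"]]
        return cls(
            trees=trees,
            bag_membership=[np.asarray(b, dtype=int) for b in obj["bag_membership"]],
            params=trees[0].params,
            n_trees=obj["n_trees"],
            rng_seed=obj["rng_seed"],
            n_training=obj["n_training"],
            bootstrap=obj["bootstrap"],
        )

    @classmethod
    def from_json(cls, text: str) -> "EnsembleModel":
        return cls.from_dict(json.loads(text))


def _subset_dataset(d: Dataset, rows: np.ndarray) -> Dataset:
    X = d.X.iloc[rows].reset_index(drop=True)
    ids = [d.ids[i] for i in rows] if d.ids is not None else None
    return Dataset(list(d.attributes), X, d.labels[rows], d.hierarchy,
                   ids, d.label_column)


def fit_bagging(
    d: Dataset,
    k: int = DEFAULT_N_TREES,
    params: PCTParams | None = None,
    bootstrap: bool = True,
) -> EnsembleModel:
    """Train a bagged ensemble of k trees.

    Per-tree seeds are spawned by counter from ``params.rng_seed``, so
    growing ``k`` re-uses the earlier trees' replicates unchanged.  With
    ``bootstrap=False`` every tree sees the full training set (a degenerate
    ensemble of identical trees, useful for equivalence checks).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    params = params or PCTParams()
    trees: list[PCTree] = []
    bags: list[np.ndarray] = []
    n = d.n_instances
    for i in range(k):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=params.rng_seed, spawn_key=(i,)))
        if bootstrap:
            sample, _ = bootstrap_sample(n, rng)
        else:
            sample = np.arange(n)
        bags.append(sample)
        trees.append(build_tree(_subset_dataset(d, sample), params))
    return EnsembleModel(trees, bags, params, k, params.rng_seed, n, bootstrap)


def predict_ensemble(m: EnsembleModel, instance) -> np.ndarray:
    """Unweighted mean of the k per-tree class vectors for one instance."""
    return m.predict(instance)


def oob_predictions(m: EnsembleModel, d: Dataset):
    """Out-of-bag score matrix for the model's own training set.

    Returns ``(PredictionMatrix, covered)`` where row i averages the
    predictions of exactly those trees whose bag excludes instance i;
    ``covered[i]`` is False when every bag contains i (such rows carry a
    zero score vector and should be skipped in evaluation).
    """
    if d.n_instances != m.n_training:
        raise ValueError(
            f"dataset has {d.n_instances} rows but the model was trained "
            f"on {m.n_training}")
    n, c = d.n_instances, len(m.hierarchy.classes)
    total = np.zeros((n, c))
    counts = np.zeros(n, dtype=int)
    for tree, bag in zip(m.trees, m.bag_membership):
        in_bag = np.zeros(n, dtype=bool)
        in_bag[bag] = True
        oob_rows = np.flatnonzero(~in_bag)
        if len(oob_rows) == 0:
            continue
        scores = tree.predict_dataset(_subset_dataset(d, oob_rows))
        total[oob_rows] += scores
        counts[oob_rows] += 1
    covered = counts > 0
    out = np.zeros((n, c))
    out[covered] = total[covered] / counts[covered, None]
    ids = tuple(d.ids) if d.ids is not None else tuple(str(i) for i in range(n))
    return PredictionMatrix(ids, tuple(m.hierarchy.classes), out), covered
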