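"""Synthetic hierarchies and planted-rule datasets.

Every learning and evaluation component in this package can be exercised
without external downloads: this module grows random FunCat-like trees or
GO-like DAGs and plants simple axis-aligned decision rules
(``x_a > threshold -> class c``) that deterministically annotate
instances, followed by ancestor closure.  Thresholds grow with class
depth, so deeper classes are rarer — mimicking real function catalogues
where most specific functions annotate few genes.  Optional label noise
flips positive bits off (compensated by a random bit flipped on) and
re-closes ancestors, so emitted labels always satisfy the hierarchy
constraint; the configured rate is therefore an *effective* pre-closure
rate.

What this generator deliberately does not emulate: correlated genomic
feature distributions (homology e-values, expression profiles), missing
data patterns, or inter-class dependencies beyond the hierarchy itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset_io import Attribute, Dataset, BINARY, NUMERIC
from .hierarchy import ClassHierarchy, build_hierarchy, close_ancestors
from .pct import PCTree

__all__ = [
    "SyntheticConfig",
    "PlantedRule",
    "generate_hierarchy",
    "generate_dataset",
    "make_dataset",
    "planted_split_recovery",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the generator; defaults give a small FunCat-like problem."""

    n_classes: int = 10
    max_depth: int = 3
    dag_extra_parent_prob: float = 0.0
    n_instances: int = 500
    n_numeric_attrs: int = 6
    n_binary_attrs: int = 2
    rules_per_class: int = 1
    label_noise_rate: float = 0.0
    top_level_prob: float = 0.15
    distinct_rule_attributes: bool = False
    attr_step: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_classes, self.n_instances, self.rules_per_class) < 1:
            raise ValueError("counts must be positive")
        if self.n_numeric_attrs < 1:
            raise ValueError("at least one numeric attribute is required")
        for p in (self.dag_extra_parent_prob, self.label_noise_rate,
                  self.top_level_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedRule:
    """Ground truth: instances with ``attribute > threshold`` carry
    ``class_id`` (and its ancestors)."""

    class_id: str
    attribute: str
    threshold: float


def generate_hierarchy(cfg: SyntheticConfig, rng: np.random.Generator) -> ClassHierarchy:
    """Grow a random rooted forest class-by-class; with probability
    ``dag_extra_parent_prob`` a non-top class gains a second parent among
    earlier classes (acyclic by construction)."""
    names = [f"c{i:03d}" for i in range(cfg.n_classes)]
    edges: list[tuple[str, str]] = []
    depth = {names[0]: 0}
    for i in range(1, cfg.n_classes):
        child = names[i]
        if rng.random() < cfg.top_level_prob:
            depth[child] = 0
            continue
        eligible = [n for n in names[:i] if depth[n] < cfg.max_depth]
        if not eligible:
            depth[child] = 0
            continue
        parent = eligible[rng.integers(len(eligible))]
        edges.append((child, parent))
        depth[child] = depth[parent] + 1
        others = [n for n in names[:i] if n != parent]
        if others and rng.random() < cfg.dag_extra_parent_prob:
            extra = others[rng.integers(len(others))]
            edges.append((child, extra))
            depth[child] = min(depth[child], depth[extra] + 1)
    return build_hierarchy(edges, names)


def _rule_threshold(depth: int, rng: np.random.Generator) -> float:
    # deeper classes get higher thresholds, hence lower frequency
    base = 1.0 - 0.5 * (0.65 ** depth)
    return float(np.clip(base + rng.uniform(-0.05, 0.05), 0.05, 0.95))


def generate_dataset(
    h: ClassHierarchy,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[Dataset, list[PlantedRule]]:
    """Draw attributes, plant one-condition rules on childless classes,
    annotate, close ancestors, then apply label noise (re-closing after)."""
    n = cfg.n_instances
    num_names = [f"x{j:03d}" for j in range(cfg.n_numeric_attrs)]
    bin_names = [f"b{j:02d}" for j in range(cfg.n_binary_attrs)]
    X_num = rng.uniform(0.0, 1.0, size=(n, cfg.n_numeric_attrs))
    if cfg.attr_step > 0.0:
        # record features at finite measurement resolution; rule thresholds
        # stay continuous, so each planted boundary sits inside a value gap
        # that a midpoint split can land in exactly
        X_num = np.round(X_num / cfg.attr_step) * cfg.attr_step
    X_bin = rng.integers(0, 2, size=(n, cfg.n_binary_attrs)).astype(float)

    attributes = [Attribute(nm, NUMERIC) for nm in num_names] + \
                 [Attribute(nm, BINARY) for nm in bin_names]
    X = pd.DataFrame(
        np.hstack([X_num, X_bin]) if cfg.n_binary_attrs else X_num,
        columns=num_names + bin_names)

    has_child = {p for ps in h.parent_edges.values() for p in ps}
    rule_classes = [c for c in h.classes if c not in has_child]
    depths = h.depths
    rules: list[PlantedRule] = []
    labels = np.zeros((n, len(h.classes)), dtype=np.uint8)
    attr_pool: list[int] = []
    if cfg.distinct_rule_attributes:
        # one attribute per rule, sampled without replacement, so each
        # planted rule is identifiable from the data alone
        n_rules = len(rule_classes) * cfg.rules_per_class
        if n_rules > cfg.n_numeric_attrs:
            raise ValueError(
                f"distinct_rule_attributes needs >= {n_rules} numeric "
                f"attributes, have {cfg.n_numeric_attrs}")
        attr_pool = list(rng.permutation(cfg.n_numeric_attrs)[:n_rules])
    for cls in rule_classes:
        ci = h.class_index[cls]
        for _ in range(cfg.rules_per_class):
            attr_j = (int(attr_pool.pop()) if cfg.distinct_rule_attributes
                      else int(rng.integers(cfg.n_numeric_attrs)))
            thr = _rule_threshold(int(depths[ci]), rng)
            rules.append(PlantedRule(cls, num_names[attr_j], thr))
            labels[X_num[:, attr_j] > thr, ci] = 1
    labels = close_ancestors(h, labels)

    if cfg.label_noise_rate > 0.0:
        flip_off = (rng.random(labels.shape) < cfg.label_noise_rate) & (labels == 1)
        n_classes = labels.shape[1]
        for i in np.flatnonzero(flip_off.any(axis=1)):
            offs = np.flatnonzero(flip_off[i])
            labels[i, offs] = 0
            zeros = np.flatnonzero(labels[i] == 0)
            for _ in range(len(offs)):
                labels[i, zeros[rng.integers(len(zeros))]] = 1
        labels = close_ancestors(h, labels)

    ids = [f"g{i:05d}" for i in range(n)]
    return Dataset(attributes, X, labels, h, ids), rules


def make_dataset(cfg: SyntheticConfig) -> tuple[Dataset, list[PlantedRule]]:
    """Hierarchy + dataset from a config's own seed, in one call."""
    rng = np.random.default_rng(cfg.seed)
    h = generate_hierarchy(cfg, rng)
    return generate_dataset(h, cfg, rng)


def planted_split_recovery(
    tree: PCTree,
    d: Dataset,
    rules: list[PlantedRule],
) -> dict[PlantedRule, bool]:
    """Check which planted rules a fitted tree recovered.

    A rule ``x_a > theta -> c`` counts as recovered when some internal node
    splits on ``x_a`` with a threshold that partitions that node's own
    training rows exactly as ``theta`` does (i.e. the learned threshold
    lies inside the same empty gap of the node's observed values).
    """
    from .pct import _TrainingMatrix, _route_mask

    cols = {a.name: d.X[a.name].to_numpy(dtype=float)
            for a in d.attributes if a.kind == NUMERIC}
    found = {r: False for r in rules}
    tm = _TrainingMatrix(d)
    attr_pos = {a.name: i for i, a in enumerate(d.attributes)}

    def walk(node, rows: np.ndarray):
        if node.is_leaf or len(rows) == 0:
            return
        t = node.test
        if t.kind == "numeric_gt" and t.attribute in cols:
            x = cols[t.attribute][rows]
            for r in rules:
                if r.attribute == t.attribute and not found[r]:
                    if np.array_equal(x > t.threshold, x > r.threshold):
                        found[r] = True
        yes = _route_mask(tm, t, rows, node.missing_to_yes, attr_pos)
        walk(node.yes, rows[yes])
        walk(node.no, rows[~yes])

    walk(tree.root, np.arange(d.n_instances))
    return found
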