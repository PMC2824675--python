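"""Predictive clustering trees for hierarchical multi-label classification.

A predictive clustering tree (PCT) is a binary decision tree grown by
standard top-down induction, but scored on the *label side*: each split is
chosen to maximise the reduction in the variance of the examples' class
vectors, where variance is the mean squared weighted Euclidean distance to
the subset's mean vector,

    Var(S)   = (1/|S|) * sum_k d^2(v_k, mean(S)),
    d^2(a,b) = sum_i w(c_i) * (a_i - b_i)^2 .

The class weights decay with depth, ``w(c) = w0 * mean_j w(parent_j(c))``,
so similarity near the top of the function hierarchy dominates.  Growth
stops when no split passes a one-way F-test on the variance reduction, or
when a split would leave a child with fewer than ``min_leaf`` examples.
Each leaf stores the mean class vector of its training examples (the
*prototype*); component i is the fraction of the leaf's examples annotated
with class i.  Because training labels are ancestor-closed, prototypes are
parent-monotone, so thresholding with any ancestor-compatible threshold map
yields hierarchy-consistent predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .dataset_io import Attribute, Dataset, BINARY, NOMINAL, NUMERIC
from .hierarchy import ClassHierarchy, ClassWeights, build_hierarchy, compute_class_weights

__all__ = [
    "SplitTest",
    "PCTNode",
    "PCTParams",
    "PCTree",
    "Rule",
    "weighted_sq_distance",
    "variance",
    "enumerate_candidate_splits",
    "variance_reduction",
    "f_test_acceptable",
    "build_tree",
    "apply_thresholds",
    "extract_rules",
    "print_tree",
]

#: significance grid used when tuning the F-test stopping parameter
SIGNIFICANCE_GRID = (0.001, 0.005, 0.01, 0.05, 0.1, 0.125)

# relative slack when comparing candidate variance reductions: two splits
# whose scores agree to ~1e-12 are treated as tied and the earlier candidate
# (attribute declaration order, then ascending threshold) wins
_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class SplitTest:
    """A binary test on one attribute.

    kinds:
      * ``numeric_gt``        — yes iff value > threshold
      * ``binary_is_one``     — yes iff value == 1
      * ``nominal_in_subset`` — yes iff value in subset
    """

    attribute: str
    kind: str
    threshold: float | None = None
    subset: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.kind == "numeric_gt" and (
                self.threshold is None or not np.isfinite(self.threshold)):
            raise ValueError("numeric test needs a finite threshold")
        if self.kind == "nominal_in_subset" and not self.subset:
            raise ValueError("nominal test needs a non-empty subset")

    def describe(self, negate: bool = False) -> str:
        if self.kind == "numeric_gt":
            op = "<=" if negate else ">"
            return f"{self.attribute} {op} {self.threshold:g}"
        if self.kind == "binary_is_one":
            return f"{self.attribute} = {0 if negate else 1}"
        inner = ",".join(self.subset)
        return f"{self.attribute} {'not in' if negate else 'in'} {{{inner}}}"


@dataclass
class PCTNode:
    """Either an internal node (test + two children) or a prototype leaf."""

    n_examples: int
    test: SplitTest | None = None
    yes: "PCTNode | None" = None
    no: "PCTNode | None" = None
    missing_to_yes: bool = True
    prototype: np.ndarray | None = None

    @property
    def is_leaf(self) -> bool:
        return self.test is None


@dataclass(frozen=True)
class PCTParams:
    """Induction parameters.

    ``w0`` controls the depth decay of class weights, ``min_leaf`` lower
    bounds the number of training examples per leaf, and
    ``f_test_significance`` is the significance level of the F-test
    stopping criterion (tuned over :data:`SIGNIFICANCE_GRID` in the full
    protocol).
    """

    w0: float = 0.75
    min_leaf: int = 5
    f_test_significance: float = 0.125
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.w0 < 1.0):
            raise ValueError("w0 must lie in (0, 1)")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if not (0.0 < self.f_test_significance < 1.0):
            raise ValueError("f_test_significance must lie in (0, 1)")


# ---------------------------------------------------------------------------
# variance primitives


def _weight_vector(w: ClassWeights | np.ndarray) -> np.ndarray:
    return w.vector if isinstance(w, ClassWeights) else np.asarray(w, float)


def weighted_sq_distance(v1, v2, w: ClassWeights | np.ndarray) -> float:
    """Squared weighted Euclidean distance between two class vectors."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    wv = _weight_vector(w)
    if v1.shape != v2.shape or v1.shape != wv.shape:
        raise ValueError("vectors and weights must have equal length")
    diff = v1 - v2
    return float(np.dot(wv, diff * diff))


def variance(examples: np.ndarray, w: ClassWeights | np.ndarray) -> float:
    """Mean squared weighted distance of class vectors to their mean."""
    Y = np.asarray(examples, dtype=float)
    if Y.ndim != 2 or len(Y) == 0:
        raise ValueError("variance needs a non-empty (n, n_classes) matrix")
    wv = _weight_vector(w)
    mean = Y.mean(axis=0)
    diff = Y - mean
    return float(np.einsum("j,ij,ij->", wv, diff, diff) / len(Y))


def _node_ss(Y_sum: np.ndarray, Y_sqsum: np.ndarray, n: int, wv: np.ndarray) -> float:
    """Total squared weighted distance to the mean, from per-class sums."""
    if n == 0:
        return 0.0
    return float(np.dot(wv, Y_sqsum - Y_sum * Y_sum / n))


# ---------------------------------------------------------------------------
# candidate enumeration (reference path; induction uses the vectorised
# scorer below, which enumerates identically)


def _observed_levels(col, attr: Attribute, rows) -> list[str]:
    vals = col.iloc[list(rows)].dropna().unique().tolist()
    return [lv for lv in attr.levels if lv in set(vals)]


def enumerate_candidate_splits(d: Dataset, rows: Sequence[int]) -> list[SplitTest]:
    """All candidate tests for a node, in the canonical deterministic order:
    attribute declaration order, then ascending threshold / declared level
    order.  Attributes with fewer than two distinct observed (non-missing)
    values yield no candidates."""
    rows = list(rows)
    if not rows:
        raise ValueError("rows must be non-empty")
    out: list[SplitTest] = []
    for a in d.attributes:
        col = d.X[a.name]
        if a.kind == NUMERIC:
            vals = np.unique(col.iloc[rows].dropna().to_numpy(dtype=float))
            for lo, hi in zip(vals[:-1], vals[1:]):
                out.append(SplitTest(a.name, "numeric_gt", threshold=(lo + hi) / 2.0))
        elif a.kind == BINARY:
            vals = np.unique(col.iloc[rows].dropna().to_numpy(dtype=float))
            if len(vals) >= 2:
                out.append(SplitTest(a.name, "binary_is_one"))
        else:
            levels = _observed_levels(col, a, rows)
            if len(levels) >= 2:
                for lv in levels:
                    out.append(SplitTest(a.name, "nominal_in_subset", subset=(lv,)))
    return out


def _test_outcomes(d: Dataset, split: SplitTest, rows: Sequence[int]):
    """Per row: True (yes), False (no) or None (missing value)."""
    col = d.X[split.attribute]
    out = []
    for r in rows:
        v = col.iloc[r]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            out.append(None)
        elif split.kind == "numeric_gt":
            out.append(bool(float(v) > split.threshold))
        elif split.kind == "binary_is_one":
            out.append(bool(float(v) == 1.0))
        else:
            out.append(str(v) in split.subset)
    return out


def partition_rows(d: Dataset, split: SplitTest, rows: Sequence[int]):
    """Partition node rows into (yes, no, missing_to_yes).

    Rows with a missing value follow the branch holding more non-missing
    rows; on a tie they follow the yes branch.
    """
    rows = list(rows)
    outcomes = _test_outcomes(d, split, rows)
    yes = [r for r, o in zip(rows, outcomes) if o is True]
    no = [r for r, o in zip(rows, outcomes) if o is False]
    missing = [r for r, o in zip(rows, outcomes) if o is None]
    missing_to_yes = len(yes) >= len(no)
    if missing_to_yes:
        yes += missing
    else:
        no += missing
    return yes, no, missing_to_yes


def variance_reduction(
    split: SplitTest,
    d: Dataset,
    rows: Sequence[int],
    w: ClassWeights | np.ndarray,
    min_leaf: int = 5,
) -> float:
    """Variance reduction of a split on a node.

    Returns ``Var(S) - |S_yes|/|S| Var(S_yes) - |S_no|/|S| Var(S_no)``, or
    ``-inf`` when either side would fall below ``min_leaf`` rows.
    """
    rows = list(rows)
    yes, no, _ = partition_rows(d, split, rows)
    if len(yes) < min_leaf or len(no) < min_leaf:
        return -np.inf
    wv = _weight_vector(w)
    Y = d.labels.astype(float)
    n = len(rows)
    v_tot = variance(Y[rows], wv)
    v_yes = variance(Y[yes], wv)
    v_no = variance(Y[no], wv)
    return v_tot - (len(yes) / n) * v_yes - (len(no) / n) * v_no


def f_test_acceptable(
    var_total: float,
    var_within_weighted: float,
    n: int,
    significance: float,
) -> bool:
    """One-way ANOVA-style acceptance test for a binary split.

    ``var_within_weighted`` is ``sum_side (n_side/n) * Var(side)``.  With
    weighted sums of squares ``SS = n * Var`` the statistic is

        F = (SS_total - SS_within) / (SS_within / (n - 2))

    on (1, n-2) degrees of freedom; the split is acceptable iff F exceeds
    the upper critical value at ``significance``.  A perfect split
    (``SS_within == 0`` with ``SS_total > 0``) is always acceptable; a
    totally uninformative node (both zero) never is.
    """
    if n < 3:
        return False
    if var_within_weighted <= 0.0:
        return var_total > 0.0
    f_stat = (var_total - var_within_weighted) * (n - 2) / var_within_weighted
    crit = stats.f.isf(significance, 1, n - 2)
    return bool(f_stat > crit)


# ---------------------------------------------------------------------------
# fast split search


class _TrainingMatrix:
    """Column-wise numeric view of a dataset for fast split scoring.

    Nominal attributes are level-coded to floats (NaN = missing) so every
    column is a float array.
    """

    def __init__(self, d: Dataset):
        self.attributes = list(d.attributes)
        self.columns: list[np.ndarray] = []
        for a in d.attributes:
            col = d.X[a.name]
            if a.kind in (NUMERIC, BINARY):
                self.columns.append(col.to_numpy(dtype=float))
            else:
                codes = np.full(len(col), np.nan)
                lut = {lv: float(i) for i, lv in enumerate(a.levels)}
                for i, v in enumerate(col):
                    if v is not None and not (isinstance(v, float) and np.isnan(v)):
                        codes[i] = lut[str(v)]
                self.columns.append(codes)
        self.Y = d.labels.astype(float)


def _score_two_way(mask_yes, mask_no, n_miss, Y_rows, sum_miss, wv, min_leaf,
                   ss_total, n_node):
    """Score a single membership split (binary / nominal candidate)."""
    n_yes_nm = int(mask_yes.sum())
    n_no_nm = int(mask_no.sum())
    to_yes = n_yes_nm >= n_no_nm
    n_yes = n_yes_nm + (n_miss if to_yes else 0)
    n_no = n_no_nm + (0 if to_yes else n_miss)
    if n_yes < min_leaf or n_no < min_leaf:
        return None
    s_yes = Y_rows[mask_yes].sum(axis=0)
    s_no = Y_rows[mask_no].sum(axis=0)
    if to_yes:
        s_yes = s_yes + sum_miss
    else:
        s_no = s_no + sum_miss
    ss = (_node_ss(s_yes, s_yes, n_yes, wv)
          + _node_ss(s_no, s_no, n_no, wv))
    return (ss_total - ss) / n_node, to_yes


def _best_numeric_split(x, Y_rows, wv, min_leaf, ss_total, n_node):
    """Best midpoint threshold for one numeric attribute, vectorised.

    Returns (reduction, threshold, missing_to_yes) or None.  Candidates are
    scanned in ascending-threshold order with the earliest winning ties.
    """
    nm = ~np.isnan(x)
    n_miss = int((~nm).sum())
    xs = x[nm]
    if len(xs) < 2:
        return None
    order = np.argsort(xs, kind="stable")
    xs = xs[order]
    Ys = Y_rows[nm][order]
    # boundaries between distinct consecutive values
    bnd = np.flatnonzero(xs[:-1] < xs[1:])
    if len(bnd) == 0:
        return None
    thresholds = (xs[bnd] + xs[bnd + 1]) / 2.0
    csum = np.cumsum(Ys, axis=0)
    total_nm = csum[-1]
    sum_miss = Y_rows[~nm].sum(axis=0) if n_miss else np.zeros(Y_rows.shape[1])

    s_no_nm = csum[bnd]                      # value <= threshold -> no branch
    n_no_nm = bnd + 1
    s_yes_nm = total_nm[None, :] - s_no_nm   # value > threshold -> yes branch
    n_yes_nm = len(xs) - n_no_nm

    to_yes = n_yes_nm >= n_no_nm
    n_yes = n_yes_nm + np.where(to_yes, n_miss, 0)
    n_no = n_no_nm + np.where(to_yes, 0, n_miss)
    s_yes = s_yes_nm + np.where(to_yes[:, None], sum_miss[None, :], 0.0)
    s_no = s_no_nm + np.where(to_yes[:, None], 0.0, sum_miss[None, :])

    ok = (n_yes >= min_leaf) & (n_no >= min_leaf)
    if not ok.any():
        return None
    with np.errstate(invalid="ignore", divide="ignore"):
        ss_yes = (s_yes - s_yes * s_yes / n_yes[:, None]) @ wv
        ss_no = (s_no - s_no * s_no / n_no[:, None]) @ wv
    red = (ss_total - ss_yes - ss_no) / n_node
    red[~ok] = -np.inf
    # earliest (smallest-threshold) candidate wins numerical ties
    best = int(np.argmax(red > np.max(red) - _TIE_RTOL * max(1.0, abs(np.max(red)))))
    if not np.isfinite(red[best]):
        return None
    return float(red[best]), float(thresholds[best]), bool(to_yes[best])


def _is_better(new: float, best: float) -> bool:
    if not np.isfinite(new):
        return False
    if not np.isfinite(best):
        return True
    return new > best + _TIE_RTOL * max(1.0, abs(best))


def _find_best_split(tm: _TrainingMatrix, rows: np.ndarray, wv: np.ndarray,
                     min_leaf: int):
    """Scan all candidates in canonical order; return the best split as
    (reduction, SplitTest, missing_to_yes) or None."""
    Y_rows = tm.Y[rows]
    n_node = len(rows)
    s_all = Y_rows.sum(axis=0)
    ss_total = _node_ss(s_all, s_all, n_node, wv)

    best_red = -np.inf
    best = None
    for a, col in zip(tm.attributes, tm.columns):
        x = col[rows]
        if a.kind == NUMERIC:
            res = _best_numeric_split(x, Y_rows, wv, min_leaf, ss_total, n_node)
            if res is not None and _is_better(res[0], best_red):
                best_red = res[0]
                best = (SplitTest(a.name, "numeric_gt", threshold=res[1]), res[2])
        elif a.kind == BINARY:
            nm = ~np.isnan(x)
            vals = np.unique(x[nm])
            if len(vals) < 2:
                continue
            mask_yes = nm & (x == 1.0)
            mask_no = nm & (x == 0.0)
            sum_miss = Y_rows[~nm].sum(axis=0) if (~nm).any() else np.zeros(Y_rows.shape[1])
            res = _score_two_way(mask_yes, mask_no, int((~nm).sum()), Y_rows,
                                 sum_miss, wv, min_leaf, ss_total, n_node)
            if res is not None and _is_better(res[0], best_red):
                best_red = res[0]
                best = (SplitTest(a.name, "binary_is_one"), res[1])
        else:
            nm = ~np.isnan(x)
            observed = set(x[nm].tolist())
            levels = [(i, lv) for i, lv in enumerate(a.levels) if float(i) in observed]
            if len(levels) < 2:
                continue
            n_miss = int((~nm).sum())
            sum_miss = Y_rows[~nm].sum(axis=0) if n_miss else np.zeros(Y_rows.shape[1])
            for code, lv in levels:
                mask_yes = nm & (x == float(code))
                mask_no = nm & (x != float(code))
                res = _score_two_way(mask_yes, mask_no, n_miss, Y_rows,
                                     sum_miss, wv, min_leaf, ss_total, n_node)
                if res is not None and _is_better(res[0], best_red):
                    best_red = res[0]
                    best = (SplitTest(a.name, "nominal_in_subset", subset=(lv,)), res[1])
    if best is None:
        return None
    return best_red, best[0], best[1]


def _route_mask(tm: _TrainingMatrix, test: SplitTest, rows: np.ndarray,
                missing_to_yes: bool, attr_pos: Mapping[str, int]) -> np.ndarray:
    """Boolean yes-mask over ``rows`` for a fitted split."""
    x = tm.columns[attr_pos[test.attribute]][rows]
    nm = ~np.isnan(x)
    if test.kind == "numeric_gt":
        yes = nm & (x > test.threshold)
    elif test.kind == "binary_is_one":
        yes = nm & (x == 1.0)
    else:
        a = tm.attributes[attr_pos[test.attribute]]
        codes = {float(i) for i, lv in enumerate(a.levels) if lv in test.subset}
        yes = nm & np.isin(x, sorted(codes))
    if missing_to_yes:
        yes = yes | ~nm
    return yes


# ---------------------------------------------------------------------------
# the tree


@dataclass
class PCTree:
    """A fitted predictive clustering tree."""

    root: PCTNode
    hierarchy: ClassHierarchy
    weights: ClassWeights
    params: PCTParams
    attributes: list[Attribute] = field(default_factory=list)

    # -- prediction -------------------------------------------------------

    def predict(self, instance: Mapping) -> np.ndarray:
        """Score vector for a single instance (attribute name -> value;
        missing values may be NaN/None or absent)."""
        node = self.root
        while not node.is_leaf:
            o = _instance_outcome(node.test, instance, self.attributes)
            if o is None:
                o = node.missing_to_yes
            node = node.yes if o else node.no
        return node.prototype.copy()

    def predict_dataset(self, d: Dataset) -> np.ndarray:
        """Score matrix (n_instances, n_classes) for a dataset."""
        _check_attributes(self.attributes, d)
        tm = _TrainingMatrix(d)
        attr_pos = {a.name: i for i, a in enumerate(tm.attributes)}
        out = np.empty((d.n_instances, len(self.hierarchy.classes)))
        stack = [(self.root, np.arange(d.n_instances))]
        while stack:
            node, rows = stack.pop()
            if len(rows) == 0:
                continue
            if node.is_leaf:
                out[rows] = node.prototype
                continue
            yes = _route_mask(tm, node.test, rows, node.missing_to_yes, attr_pos)
            stack.append((node.yes, rows[yes]))
            stack.append((node.no, rows[~yes]))
        return out

    # -- introspection ----------------------------------------------------

    def leaves(self) -> list[PCTNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            else:
                stack.extend([n.no, n.yes])
        return out

    def n_nodes(self) -> int:
        cnt, stack = 0, [self.root]
        while stack:
            n = stack.pop()
            cnt += 1
            if not n.is_leaf:
                stack.extend([n.no, n.yes])
        return cnt

    def splits(self) -> list[SplitTest]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            if not n.is_leaf:
                out.append(n.test)
                stack.extend([n.no, n.yes])
        return out

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "pcthmc-model",
            "version": 1,
            "kind": "pct",
            "hierarchy": _hierarchy_to_dict(self.hierarchy),
            "params": {
                "w0": self.params.w0,
                "min_leaf": self.params.min_leaf,
                "f_test_significance": self.params.f_test_significance,
                "rng_seed": self.params.rng_seed,
            },
            "attributes": [
                {"name": a.name, "kind": a.kind,
                 "levels": list(a.levels) if a.levels else None}
                for a in self.attributes
            ],
            "tree": _node_to_dict(self.root),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_dict(cls, obj: dict) -> "PCTree":
        if obj.get("kind") != "pct":
            raise ValueError("not a single-tree model")
        h = _hierarchy_from_dict(obj["hierarchy"])
        params = PCTParams(**obj["params"])
        attrs = [
            Attribute(a["name"], a["kind"],
                      tuple(a["levels"]) if a["levels"] else None)
            for a in obj["attributes"]
        ]
        root = _node_from_dict(obj["tree"])
        return cls(root, h, compute_class_weights(h, params.w0), params, attrs)

    @classmethod
    def from_json(cls, text: str) -> "PCTree":
        return cls.from_dict(json.loads(text))


def _instance_outcome(test: SplitTest, instance: Mapping, attributes):
    v = instance.get(test.attribute) if hasattr(instance, "get") else instance[test.attribute]
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    if test.kind == "numeric_gt":
        return float(v) > test.threshold
    if test.kind == "binary_is_one":
        return float(v) == 1.0
    return str(v) in test.subset


def _check_attributes(attrs: list[Attribute], d: Dataset) -> None:
    have = {a.name for a in d.attributes}
    missing = [a.name for a in attrs if a.name not in have]
    if missing:
        raise ValueError(f"dataset lacks training attributes: {missing}")


def _hierarchy_to_dict(h: ClassHierarchy) -> dict:
    return {
        "classes": list(h.classes),
        "edges": [[c, p] for c in h.classes for p in h.parent_edges[c]],
    }


def _hierarchy_from_dict(obj: dict) -> ClassHierarchy:
    return build_hierarchy([(c, p) for c, p in obj["edges"]], obj["classes"])


def _node_to_dict(node: PCTNode) -> dict:
    if node.is_leaf:
        return {"n": node.n_examples, "prototype": [float(v) for v in node.prototype]}
    return {
        "n": node.n_examples,
        "test": {
            "attribute": node.test.attribute,
            "kind": node.test.kind,
            "threshold": node.test.threshold,
            "subset": list(node.test.subset) if node.test.subset else None,
        },
        "missing_to_yes": node.missing_to_yes,
        "yes": _node_to_dict(node.yes),
        "no": _node_to_dict(node.no),
    }


def _node_from_dict(obj: dict) -> PCTNode:
    if "prototype" in obj:
        return PCTNode(n_examples=obj["n"],
                       prototype=np.asarray(obj["prototype"], dtype=float))
    t = obj["test"]
    test = SplitTest(t["attribute"], t["kind"], t["threshold"],
                     tuple(t["subset"]) if t["subset"] else None)
    return PCTNode(
        n_examples=obj["n"], test=test,
        yes=_node_from_dict(obj["yes"]), no=_node_from_dict(obj["no"]),
        missing_to_yes=obj["missing_to_yes"],
    )


# ---------------------------------------------------------------------------
# induction


def build_tree(d: Dataset, params: PCTParams | None = None) -> PCTree:
    """Grow a predictive clustering tree on a dataset.

    Fully deterministic: the same dataset and parameters always produce a
    byte-identical serialized tree.
    """
    params = params or PCTParams()
    if d.n_instances < params.min_leaf:
        raise ValueError(
            f"need at least min_leaf={params.min_leaf} training instances")
    weights = compute_class_weights(d.hierarchy, params.w0)
    wv = weights.vector
    tm = _TrainingMatrix(d)
    attr_pos = {a.name: i for i, a in enumerate(tm.attributes)}

    def grow(rows: np.ndarray) -> PCTNode:
        n = len(rows)
        Y_rows = tm.Y[rows]
        if n >= 2 * params.min_leaf:
            found = _find_best_split(tm, rows, wv, params.min_leaf)
            if found is not None:
                red, test, to_yes = found
                s = Y_rows.sum(axis=0)
                var_total = _node_ss(s, s, n, wv) / n
                var_within = var_total - red
                if f_test_acceptable(var_total, var_within, n,
                                     params.f_test_significance):
                    yes_mask = _route_mask(tm, test, rows, to_yes, attr_pos)
                    return PCTNode(
                        n_examples=n, test=test, missing_to_yes=to_yes,
                        yes=grow(rows[yes_mask]), no=grow(rows[~yes_mask]),
                    )
        return PCTNode(n_examples=n, prototype=Y_rows.mean(axis=0))

    root = grow(np.arange(d.n_instances))
    return PCTree(root, d.hierarchy, weights, params, list(d.attributes))


# ---------------------------------------------------------------------------
# thresholded prediction and rules


def apply_thresholds(
    h: ClassHierarchy,
    scores: np.ndarray,
    thresholds: Mapping[str, float] | float,
) -> set[str]:
    """Classes whose score reaches their threshold.

    The threshold map must satisfy ``t_ancestor <= t_descendant`` for every
    hierarchy edge (checked eagerly); combined with parent-monotone scores
    this guarantees an ancestor-closed prediction.  A score exactly equal
    to the threshold counts as predicted.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(h.classes),):
        raise ValueError("score vector length does not match hierarchy")
    if isinstance(thresholds, Mapping):
        t = np.array([thresholds[c] for c in h.classes], dtype=float)
    else:
        t = np.full(len(h.classes), float(thresholds))
    for pi, ci in h.edge_index_pairs():
        if t[pi] > t[ci]:
            raise ValueError(
                f"threshold of {h.classes[pi]!r} exceeds that of its "
                f"descendant {h.classes[ci]!r}")
    return {h.classes[i] for i in np.flatnonzero(scores >= t)}


@dataclass(frozen=True)
class Rule:
    """An if-then rule read off a tree leaf for one class."""

    conditions: tuple[str, ...]
    class_id: str
    score: float
    n_examples: int

    def __str__(self) -> str:
        body = " and ".join(self.conditions) if self.conditions else "true"
        return (f"if {body} then {self.class_id} "
                f"(score {self.score:.3f}, n={self.n_examples})")


def extract_rules(tree: PCTree, class_id: str, min_score: float = 0.5) -> list[Rule]:
    """One rule per leaf whose prototype reaches ``min_score`` for a class.

    The antecedent is the conjunction of the tests along the path; the
    consequent is the class with the leaf's score for it.
    """
    if class_id not in tree.hierarchy.class_index:
        raise KeyError(f"unknown class {class_id!r}")
    ci = tree.hierarchy.class_index[class_id]
    rules: list[Rule] = []

    def walk(node: PCTNode, conds: tuple[str, ...]):
        if node.is_leaf:
            if node.prototype[ci] >= min_score:
                rules.append(Rule(conds, class_id,
                                  float(node.prototype[ci]), node.n_examples))
            return
        walk(node.yes, conds + (node.test.describe(),))
        walk(node.no, conds + (node.test.describe(negate=True),))

    walk(tree.root, ())
    return rules


def print_tree(tree: PCTree, max_classes: int = 6) -> str:
    """Human-readable indented rendering of a fitted tree."""
    lines: list[str] = []
    classes = tree.hierarchy.classes

    def fmt_leaf(node: PCTNode) -> str:
        order = np.argsort(-node.prototype, kind="stable")
        parts = [f"{classes[i]}:{node.prototype[i]:.2f}"
                 for i in order[:max_classes] if node.prototype[i] > 0]
        return f"leaf n={node.n_examples} [{', '.join(parts)}]"

    def walk(node: PCTNode, prefix: str):
        if node.is_leaf:
            lines.append(prefix + fmt_leaf(node))
            return
        lines.append(prefix + node.test.describe() + " ?")
        lines.append(prefix + "+-- yes:")
        walk(node.yes, prefix + "|     ")
        lines.append(prefix + "+-- no:")
        walk(node.no, prefix + "      ")

    walk(tree.root, "")
    return "\n".join(lines)
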