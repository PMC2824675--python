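"""Class hierarchies for hierarchical multi-label classification.

Gene function catalogues organise their classes either as a rooted tree
(FunCat, with slash-path names such as ``4/3/1``) or as a directed acyclic
graph (the Gene Ontology, where a term may have several parents).  This
module represents both as a :class:`ClassHierarchy`: an ordered set of class
identifiers plus a child-to-parents map.  On top of that it provides

* depth-decaying class weights ``w(c) = w0 * mean_j w(parent_j(c))`` used by
  the tree-induction heuristic,
* encoding of annotation sets as ancestor-closed binary vectors, and
* the hierarchy-consistency check for thresholded predictions (a class may
  only be predicted when all of its ancestors are predicted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "HierarchyStructureError",
    "ClassHierarchy",
    "ClassWeights",
    "build_hierarchy",
    "parse_funcat_labels",
    "compute_class_weights",
    "encode_label_set",
    "encode_label_sets",
    "close_ancestors",
    "check_hierarchy_consistent",
    "read_edge_file",
    "write_edge_file",
]


class HierarchyStructureError(ValueError):
    """Raised for structurally invalid hierarchies (cycles, bad references)."""


@dataclass(frozen=True)
class ClassHierarchy:
    """A rooted forest or DAG of function classes with a fixed vector order.

    Attributes
    ----------
    classes:
        Class identifiers in the fixed vector ordering.
    parent_edges:
        Mapping class -> tuple of parent classes (empty tuple = top-level).
    is_dag:
        True iff some class has two or more parents.
    class_index:
        Mapping class -> position in ``classes``.
    """

    classes: tuple[str, ...]
    parent_edges: Mapping[str, tuple[str, ...]]
    is_dag: bool
    class_index: Mapping[str, int] = field(repr=False)

    # --- derived structure, computed lazily and cached on the instance ---

    def __len__(self) -> int:
        return len(self.classes)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def parents_of(self, cls: str) -> tuple[str, ...]:
        return self.parent_edges[cls]

    @property
    def parent_index_lists(self) -> list[list[int]]:
        """Per class (in vector order), the indices of its parents."""
        try:
            return self._parent_idx_cache  # type: ignore[attr-defined]
        except AttributeError:
            idx = [
                [self.class_index[p] for p in self.parent_edges[c]]
                for c in self.classes
            ]
            object.__setattr__(self, "_parent_idx_cache", idx)
            return idx

    @property
    def ancestor_matrix(self) -> np.ndarray:
        """Boolean matrix A with ``A[i, j]`` true iff class j is a strict
        ancestor of class i."""
        try:
            return self._anc_cache  # type: ignore[attr-defined]
        except AttributeError:
            n = len(self.classes)
            anc = np.zeros((n, n), dtype=bool)
            for c in self.topological_order():
                i = self.class_index[c]
                for p in self.parent_edges[c]:
                    j = self.class_index[p]
                    anc[i, j] = True
                    anc[i] |= anc[j]
            object.__setattr__(self, "_anc_cache", anc)
            return anc

    @property
    def depths(self) -> np.ndarray:
        """Depth per class: length of a shortest path up to a top-level class
        (top-level classes have depth 0)."""
        try:
            return self._depth_cache  # type: ignore[attr-defined]
        except AttributeError:
            d = np.zeros(len(self.classes), dtype=int)
            for c in self.topological_order():
                i = self.class_index[c]
                parents = self.parent_edges[c]
                if parents:
                    d[i] = 1 + min(d[self.class_index[p]] for p in parents)
            object.__setattr__(self, "_depth_cache", d)
            return d

    def topological_order(self) -> list[str]:
        """Classes ordered so every parent precedes its children; ties broken
        by vector order so the result is deterministic."""
        try:
            return self._topo_cache  # type: ignore[attr-defined]
        except AttributeError:
            g = nx.DiGraph()
            g.add_nodes_from(self.classes)
            for c, parents in self.parent_edges.items():
                for p in parents:
                    g.add_edge(p, c)
            order = list(nx.lexicographical_topological_sort(
                g, key=lambda c: self.class_index[c]))
            object.__setattr__(self, "_topo_cache", order)
            return order

    def top_level_classes(self) -> tuple[str, ...]:
        return tuple(c for c in self.classes if not self.parent_edges[c])

    def edge_index_pairs(self) -> list[tuple[int, int]]:
        """All (parent_index, child_index) pairs."""
        return [
            (self.class_index[p], self.class_index[c])
            for c in self.classes
            for p in self.parent_edges[c]
        ]


@dataclass(frozen=True)
class ClassWeights:
    """Depth-decaying class weights for the weighted Euclidean distance.

    ``weights`` maps every class to a positive real; ``vector`` is the same
    information aligned to the hierarchy's vector ordering.
    """

    w0: float
    weights: Mapping[str, float]
    vector: np.ndarray


def build_hierarchy(
    edge_list: Iterable[tuple[str, str]],
    class_order: Sequence[str] | None = None,
) -> ClassHierarchy:
    """Build a validated hierarchy from (child, parent) pairs.

    Classes are the union of all identifiers in the edge list and
    ``class_order`` (when given).  The vector ordering is ``class_order``
    when supplied, otherwise lexicographic.  Cycles are rejected.
    """
    edges = [(str(c), str(p)) for c, p in edge_list]
    for c, p in edges:
        if not c or not p:
            raise HierarchyStructureError("empty class identifier in edge list")

    names: set[str] = set()
    for c, p in edges:
        names.add(c)
        names.add(p)

    if class_order is not None:
        order = [str(c) for c in class_order]
        if len(set(order)) != len(order):
            dup = next(c for c in order if order.count(c) > 1)
            raise HierarchyStructureError(f"duplicate class in class_order: {dup!r}")
        missing = names - set(order)
        if missing:
            raise HierarchyStructureError(
                f"edge list references classes absent from class_order: {sorted(missing)}")
        classes = tuple(order)
    else:
        classes = tuple(sorted(names))

    if not classes:
        raise HierarchyStructureError("hierarchy has no classes")

    g = nx.DiGraph()
    g.add_nodes_from(classes)
    g.add_edges_from((p, c) for c, p in edges)  # parent -> child
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise HierarchyStructureError(
            f"cycle detected in hierarchy involving class {cycle[0][0]!r}")

    parent_edges = {
        c: tuple(sorted(set(g.predecessors(c)))) for c in classes
    }
    is_dag = any(len(ps) > 1 for ps in parent_edges.values())
    class_index = {c: i for i, c in enumerate(classes)}
    return ClassHierarchy(classes, parent_edges, is_dag, class_index)


def parse_funcat_labels(
    label_strings: Iterable[str],
    class_order: Sequence[str] | None = None,
) -> ClassHierarchy:
    """Build a rooted-tree hierarchy implicit in FunCat slash-path labels.

    Every prefix of every path becomes a class; the parent of ``a/b/c`` is
    ``a/b``.  Single-token paths are top-level classes.
    """
    edges: list[tuple[str, str]] = []
    classes: set[str] = set()
    for label in label_strings:
        tokens = str(label).split("/")
        if any(not t for t in tokens):
            raise HierarchyStructureError(f"empty token in FunCat path {label!r}")
        for d in range(len(tokens)):
            cls = "/".join(tokens[: d + 1])
            classes.add(cls)
            if d > 0:
                edges.append((cls, "/".join(tokens[:d])))
    if class_order is None:
        class_order = sorted(classes)
    return build_hierarchy(edges, class_order)


def compute_class_weights(h: ClassHierarchy, w0: float) -> ClassWeights:
    """Evaluate the recursion ``w(c) = w0 * avg_j w(parent_j(c))``.

    Top-level classes have no parents; the average over the empty set is
    taken to be 1, so their weight is ``w0``.  In a rooted tree this gives
    ``w0 ** (depth + 1)``; in a DAG the average mixes parent weights.
    """
    if not (0.0 < w0 < 1.0):
        raise ValueError(f"w0 must lie strictly in (0, 1), got {w0}")
    vec = np.empty(len(h.classes), dtype=float)
    for c in h.topological_order():
        i = h.class_index[c]
        parents = h.parent_edges[c]
        if parents:
            vec[i] = w0 * float(
                np.mean([vec[h.class_index[p]] for p in parents]))
        else:
            vec[i] = w0
    return ClassWeights(w0=w0, weights={c: float(vec[h.class_index[c]]) for c in h.classes}, vector=vec)


def encode_label_set(h: ClassHierarchy, labels: Iterable[str]) -> np.ndarray:
    """Encode an annotation set as an ancestor-closed binary vector.

    The hierarchy constraint is always enforced: the bit of every ancestor
    of every given label is set, mirroring up-propagated annotations.
    """
    bits = np.zeros(len(h.classes), dtype=np.uint8)
    anc = h.ancestor_matrix
    for label in labels:
        label = str(label)
        if label not in h.class_index:
            raise KeyError(f"unknown class label {label!r}")
        i = h.class_index[label]
        bits[i] = 1
        bits[anc[i]] = 1
    return bits


def encode_label_sets(h: ClassHierarchy, label_sets: Iterable[Iterable[str]]) -> np.ndarray:
    """Encode many annotation sets into a (n, |classes|) uint8 matrix."""
    rows = [encode_label_set(h, labels) for labels in label_sets]
    if not rows:
        return np.zeros((0, len(h.classes)), dtype=np.uint8)
    return np.stack(rows)


def close_ancestors(h: ClassHierarchy, bits: np.ndarray) -> np.ndarray:
    """Return a copy of a binary label matrix with ancestors up-propagated."""
    out = np.asarray(bits, dtype=np.uint8).copy()
    single = out.ndim == 1
    if single:
        out = out[None, :]
    anc = h.ancestor_matrix
    # row has class i -> also set every ancestor of i
    closed = (out.astype(bool) | (out @ anc.astype(np.uint8) > 0)).astype(np.uint8)
    return closed[0] if single else closed


def check_hierarchy_consistent(
    h: ClassHierarchy,
    scores: np.ndarray,
    threshold_map: Mapping[str, float] | float,
) -> bool:
    """True iff the predicted set ``{c : score[c] >= t_c}`` is ancestor-closed."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(h.classes),):
        raise ValueError(
            f"score vector of length {scores.shape} does not match "
            f"{len(h.classes)} classes")
    if isinstance(threshold_map, Mapping):
        t = np.array([threshold_map[c] for c in h.classes], dtype=float)
    else:
        t = np.full(len(h.classes), float(threshold_map))
    predicted = scores >= t
    for pi, ci in h.edge_index_pairs():
        if predicted[ci] and not predicted[pi]:
            return False
    return True


def read_edge_file(path) -> ClassHierarchy:
    """Read a two-column tab-separated ``child<TAB>parent`` edge list.

    Lines starting with '#' are comments.  A line with a single column
    declares a top-level class with no parent.
    """
    edges: list[tuple[str, str]] = []
    extra: list[str] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                extra.append(parts[0])
            elif len(parts) == 2:
                edges.append((parts[0], parts[1]))
            else:
                raise HierarchyStructureError(
                    f"{path}:{lineno}: expected 1 or 2 tab-separated columns")
    names = sorted({c for e in edges for c in e} | set(extra))
    return build_hierarchy(edges, names)


def write_edge_file(h: ClassHierarchy, path) -> None:
    """Write the hierarchy as a child<TAB>parent edge list (top-level classes
    appear as single-column lines)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# child\tparent\n")
        for c in h.classes:
            parents = h.parent_edges[c]
            if not parents:
                fh.write(f"{c}\n")
            for p in parents:
                fh.write(f"{c}\t{p}\n")
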