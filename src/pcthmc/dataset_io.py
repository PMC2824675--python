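"""Reading and writing hierarchically labelled tabular datasets.

Two on-disk formats are supported for datasets:

* **delimited** — tab- or comma-separated text with a header row; attribute
  kinds are inferred (or declared via ``attribute_kinds``).
* **arff** — a plain ARFF subset where the multi-label class column is
  declared as a ``string`` attribute.

In both formats a label cell contains the instance's classes joined by
``'@'`` (e.g. ``"1@2/2"``); an empty cell means "no annotations".  ``'@'``
is used because FunCat class names already contain ``'/'``.  Missing
attribute values are written as ``'?'``.  Label vectors are always
ancestor-closed on load, matching up-propagated function annotations.

Prediction matrices (gene x class score tables, as published for the
MouseFunc challenge systems) are stored as tab-separated text with a class
header row and an instance-id first column.
"""

from __future__ import annotations

import csv
import io
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hierarchy import (
    ClassHierarchy,
    close_ancestors,
    encode_label_sets,
    parse_funcat_labels,
    read_edge_file,
)

__all__ = [
    "Attribute",
    "Dataset",
    "PredictionMatrix",
    "read_dataset",
    "write_dataset",
    "filter_sparse_attributes",
    "read_prediction_matrix",
    "write_prediction_matrix",
]

LABEL_SEP = "@"
MISSING = "?"

NUMERIC = "numeric"
BINARY = "binary"
NOMINAL = "nominal"


@dataclass(frozen=True)
class Attribute:
    """A dataset column: numeric, binary (0/1) or nominal with fixed levels."""

    name: str
    kind: str
    levels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.kind not in (NUMERIC, BINARY, NOMINAL):
            raise ValueError(f"unknown attribute kind {self.kind!r}")
        if self.kind == NOMINAL and not self.levels:
            raise ValueError(f"nominal attribute {self.name!r} needs levels")


@dataclass
class Dataset:
    """In-memory dataset: attribute table + ancestor-closed label matrix.

    ``X`` holds one column per attribute: float (NaN = missing) for numeric
    and binary attributes, object/str (None = missing) for nominal ones.
    ``labels`` is a (n_instances, n_classes) uint8 matrix aligned to
    ``hierarchy.class_index``.
    """

    attributes: list[Attribute]
    X: pd.DataFrame
    labels: np.ndarray
    hierarchy: ClassHierarchy
    ids: list[str] | None = None
    label_column: str = "class"

    def __post_init__(self):
        if len(self.X) != len(self.labels):
            raise ValueError("instance rows and label rows differ in count")
        if self.labels.shape[1] != len(self.hierarchy.classes):
            raise ValueError("label width does not match hierarchy size")

    @property
    def n_instances(self) -> int:
        return len(self.X)

    def label_sets(self) -> list[list[str]]:
        """Per instance, the annotated classes (including ancestors)."""
        classes = self.hierarchy.classes
        return [
            [classes[j] for j in np.flatnonzero(row)] for row in self.labels
        ]

    def minimal_label_sets(self) -> list[list[str]]:
        """Per instance, the most specific classes (ancestors implied)."""
        anc = self.hierarchy.ancestor_matrix
        out = []
        for row in self.labels:
            on = np.flatnonzero(row)
            keep = [j for j in on if not any(anc[k, j] for k in on if k != j)]
            out.append([self.hierarchy.classes[j] for j in keep])
        return out


@dataclass(frozen=True)
class PredictionMatrix:
    """Scores in [0, 1] for every (instance, class) pair."""

    ids: tuple[str, ...]
    classes: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (len(self.ids), len(self.classes)):
            raise ValueError("score matrix shape does not match ids x classes")
        if not np.all(np.isfinite(s)):
            raise ValueError("scores must be finite")
        object.__setattr__(self, "scores", s)


# ---------------------------------------------------------------------------
# dataset reading


def _parse_label_cell(cell: str, rownum: int) -> list[str]:
    cell = cell.strip()
    if not cell:
        return []
    parts = cell.split(LABEL_SEP)
    if any(not p.strip() for p in parts):
        raise ValueError(f"row {rownum}: malformed label cell {cell!r}")
    return [p.strip() for p in parts]


def _infer_kind(values: Sequence[str]) -> Attribute | None:
    """Infer an attribute kind from string cells (missing already removed)."""
    try:
        floats = [float(v) for v in values]
    except ValueError:
        levels = tuple(sorted(set(values)))
        return Attribute("", NOMINAL, levels)
    if floats and set(floats) <= {0.0, 1.0}:
        return Attribute("", BINARY)
    return Attribute("", NUMERIC)


def _coerce_column(name: str, kind: Attribute, cells: list[str], offset: int = 2):
    if kind.kind in (NUMERIC, BINARY):
        vals = np.empty(len(cells), dtype=float)
        for i, c in enumerate(cells):
            c = c.strip()
            if c == MISSING or c == "":
                vals[i] = np.nan
            else:
                try:
                    vals[i] = float(c)
                except ValueError:
                    raise ValueError(
                        f"row {i + offset}: cannot parse {c!r} as "
                        f"{kind.kind} attribute {name!r}") from None
        if kind.kind == BINARY:
            ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
            if not ok.all():
                bad = int(np.flatnonzero(~ok)[0])
                raise ValueError(
                    f"row {bad + offset}: binary attribute {name!r} has "
                    f"value {vals[bad]!r}")
        return vals
    # nominal
    out = []
    for i, c in enumerate(cells):
        c = c.strip()
        if c == MISSING or c == "":
            out.append(None)
        elif kind.levels is not None and c not in kind.levels:
            raise ValueError(
                f"row {i + offset}: level {c!r} not declared for nominal "
                f"attribute {name!r}")
        else:
            out.append(c)
    return pd.array(out, dtype=object)


def _resolve_hierarchy(
    hierarchy_source: str | ClassHierarchy,
    label_sets: list[list[str]],
) -> ClassHierarchy:
    if isinstance(hierarchy_source, ClassHierarchy):
        return hierarchy_source
    if hierarchy_source == "funcat_implicit":
        flat = [lab for labels in label_sets for lab in labels]
        if not flat:
            raise ValueError(
                "cannot infer a FunCat hierarchy: no labels in the file")
        return parse_funcat_labels(flat)
    # otherwise treat as a path to an edge file
    return read_edge_file(hierarchy_source)


def _encode_labels(h: ClassHierarchy, label_sets: list[list[str]]) -> np.ndarray:
    for rownum, labels in enumerate(label_sets, start=2):
        for lab in labels:
            if lab not in h.class_index:
                raise ValueError(
                    f"row {rownum}: label {lab!r} not in the hierarchy")
    return encode_label_sets(h, label_sets)


def read_dataset(
    path,
    format: str = "delimited",
    label_column: str = "class",
    hierarchy_source: str | ClassHierarchy = "funcat_implicit",
    sep: str | None = None,
    attribute_kinds: Mapping[str, Attribute] | None = None,
    id_column: str = "id",
) -> Dataset:
    """Read a dataset from delimited text or the ARFF dialect.

    Parameters
    ----------
    hierarchy_source:
        ``"funcat_implicit"`` to build the hierarchy from slash-path labels
        found in the file, a path to a child/parent edge file, or an
        existing :class:`ClassHierarchy`.
    attribute_kinds:
        Optional explicit kinds for delimited files (otherwise inferred:
        float-parseable -> numeric, {0,1}-valued -> binary, else nominal
        with levels taken from the data).
    """
    if format == "arff":
        return _read_arff(path, label_column, hierarchy_source)
    if format != "delimited":
        raise ValueError(f"unknown format {format!r}")

    with open(path, "rt", encoding="utf-8") as fh:
        text = fh.read()
    if sep is None:
        first = text.splitlines()[0] if text else ""
        sep = "\t" if "\t" in first else ","
    rows = [line.split(sep) for line in text.splitlines() if line != ""]
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    if label_column not in header:
        raise ValueError(f"{path}: label column {label_column!r} not found")
    body = rows[1:]
    for i, r in enumerate(body, start=2):
        if len(r) != len(header):
            raise ValueError(f"{path}: row {i} has {len(r)} fields, "
                             f"expected {len(header)}")

    cols = {name: [r[j] for r in body] for j, name in enumerate(header)}
    ids = [v.strip() for v in cols[id_column]] if id_column in header else None

    label_sets = [
        _parse_label_cell(c, i) for i, c in enumerate(cols[label_column], start=2)
    ]
    h = _resolve_hierarchy(hierarchy_source, label_sets)
    labels = _encode_labels(h, label_sets)

    attr_names = [n for n in header if n not in (label_column, id_column)]
    attributes: list[Attribute] = []
    data = {}
    for name in attr_names:
        cells = cols[name]
        if attribute_kinds and name in attribute_kinds:
            kind = attribute_kinds[name]
        else:
            non_missing = [c.strip() for c in cells
                           if c.strip() not in ("", MISSING)]
            kind = _infer_kind(non_missing) or Attribute("", NUMERIC)
        kind = replace(kind, name=name)
        attributes.append(kind)
        data[name] = _coerce_column(name, kind, cells)
    X = pd.DataFrame(data, columns=attr_names)
    return Dataset(attributes, X, labels, h, ids, label_column)


def write_dataset(d: Dataset, path, format: str = "delimited", sep: str = "\t") -> None:
    """Write a dataset so that :func:`read_dataset` round-trips it."""
    if format == "arff":
        _write_arff(d, path)
        return
    if format != "delimited":
        raise ValueError(f"unknown format {format!r}")
    label_cells = [LABEL_SEP.join(s) for s in d.minimal_label_sets()]
    with open(path, "wt", encoding="utf-8") as fh:
        header = []
        if d.ids is not None:
            header.append("id")
        header.extend(a.name for a in d.attributes)
        header.append(d.label_column)
        fh.write(sep.join(header) + "\n")
        for i in range(d.n_instances):
            row = []
            if d.ids is not None:
                row.append(d.ids[i])
            for a in d.attributes:
                v = d.X.iloc[i][a.name]
                row.append(_format_value(a, v))
            row.append(label_cells[i])
            fh.write(sep.join(row) + "\n")


def _format_value(a: Attribute, v) -> str:
    if a.kind in (NUMERIC, BINARY):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return MISSING
        if a.kind == BINARY or float(v).is_integer():
            return str(int(v))
        return repr(float(v))
    return MISSING if v is None else str(v)


# ---------------------------------------------------------------------------
# ARFF dialect

_ARFF_ATTR_RE = re.compile(r"@attribute\s+(\S+)\s+(.+)", re.IGNORECASE)


def _read_arff(path, label_column: str, hierarchy_source) -> Dataset:
    attributes: list[Attribute] = []
    names: list[str] = []
    data_lines: list[str] = []
    in_data = False
    with open(path, "rt", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            if in_data:
                data_lines.append(line)
                continue
            low = line.lower()
            if low.startswith("@relation"):
                continue
            if low.startswith("@data"):
                in_data = True
                continue
            m = _ARFF_ATTR_RE.match(line)
            if not m:
                raise ValueError(f"{path}: cannot parse ARFF line {line!r}")
            name, spec = m.group(1), m.group(2).strip()
            names.append(name)
            if name == label_column:
                if spec.lower() != "string":
                    raise ValueError(
                        f"{path}: label attribute {name!r} must be declared "
                        f"'string', got {spec!r}")
                attributes.append(None)  # placeholder, not a feature
            elif spec.lower() in ("numeric", "real", "integer"):
                attributes.append(Attribute(name, NUMERIC))
            elif spec.startswith("{"):
                levels = tuple(
                    t.strip().strip("'\"") for t in spec.strip("{}").split(","))
                if levels == ("0", "1"):
                    attributes.append(Attribute(name, BINARY))
                else:
                    attributes.append(Attribute(name, NOMINAL, levels))
            else:
                raise ValueError(f"{path}: unsupported ARFF type {spec!r}")
    if label_column not in names:
        raise ValueError(f"{path}: label attribute {label_column!r} missing")

    rows = []
    for i, line in enumerate(data_lines, start=1):
        cells = next(iter(csv.reader(
            io.StringIO(line), quotechar="'", skipinitialspace=True)))
        if len(cells) != len(names):
            raise ValueError(f"{path}: data line {i} has {len(cells)} fields, "
                             f"expected {len(names)}")
        rows.append(cells)

    label_j = names.index(label_column)
    label_sets = [
        _parse_label_cell(r[label_j], i) for i, r in enumerate(rows, start=2)
    ]
    h = _resolve_hierarchy(hierarchy_source, label_sets)
    labels = _encode_labels(h, label_sets)

    feat_attrs = [a for a in attributes if a is not None]
    data = {}
    for j, name in enumerate(names):
        if name == label_column:
            continue
        a = next(a for a in feat_attrs if a.name == name)
        data[name] = _coerce_column(name, a, [r[j] for r in rows])
    X = pd.DataFrame(data, columns=[a.name for a in feat_attrs])
    return Dataset(feat_attrs, X, labels, h, None, label_column)


def _write_arff(d: Dataset, path) -> None:
    label_cells = [LABEL_SEP.join(s) for s in d.minimal_label_sets()]
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("@relation pcthmc\n")
        for a in d.attributes:
            if a.kind == NUMERIC:
                fh.write(f"@attribute {a.name} numeric\n")
            elif a.kind == BINARY:
                fh.write(f"@attribute {a.name} {{0,1}}\n")
            else:
                fh.write(f"@attribute {a.name} "
                         f"{{{','.join(a.levels)}}}\n")
        fh.write(f"@attribute {d.label_column} string\n")
        fh.write("@data\n")
        for i in range(d.n_instances):
            row = [_format_value(a, d.X.iloc[i][a.name]) for a in d.attributes]
            row.append(f"'{label_cells[i]}'")
            fh.write(",".join(row) + "\n")


# ---------------------------------------------------------------------------
# sparse-attribute filter


def filter_sparse_attributes(d: Dataset, min_nonzero: int) -> Dataset:
    """Drop attributes with fewer than ``min_nonzero`` non-zero, non-missing
    values (the standard treatment of near-empty sparse feature columns).

    Nominal values count as non-zero whenever they are non-missing.
    Instance rows and labels are never changed; attribute order is kept.
    """
    if min_nonzero < 0:
        raise ValueError("min_nonzero must be >= 0")
    keep: list[Attribute] = []
    for a in d.attributes:
        col = d.X[a.name]
        if a.kind in (NUMERIC, BINARY):
            n_nonzero = int(((col != 0) & col.notna()).sum())
        else:
            n_nonzero = int(col.notna().sum())
        if n_nonzero >= min_nonzero:
            keep.append(a)
    if not keep:
        warnings.warn("filter_sparse_attributes removed every attribute")
    X = d.X[[a.name for a in keep]].copy()
    return Dataset(keep, X, d.labels.copy(), d.hierarchy,
                   list(d.ids) if d.ids is not None else None, d.label_column)


# ---------------------------------------------------------------------------
# prediction matrices


def write_prediction_matrix(m: PredictionMatrix, path) -> None:
    """Write a tab-separated gene x class score table (10 significant digits,
    so a read/write cycle is value-exact)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(m.classes) + "\n")
        for i, gid in enumerate(m.ids):
            cells = ("%.10g" % v for v in m.scores[i])
            fh.write(gid + "\t" + "\t".join(cells) + "\n")


def read_prediction_matrix(path) -> PredictionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    return PredictionMatrix(
        ids=tuple(str(i) for i in df.index),
        classes=tuple(str(c) for c in df.columns),
        scores=df.to_numpy(dtype=float),
    )
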