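"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive (explicit loops, two-pass formulas)
and shares no code with the package's fast paths.
"""

from __future__ import annotations

import numpy as np

# tie rule shared with the canonical candidate ordering: a later candidate
# must be strictly better (beyond ~1e-12 relative) to displace an earlier one
_TIE = 1e-12


def two_pass_variance(Y, w):
    """Mean squared weighted distance to the mean, computed literally."""
    Y = np.asarray(Y, dtype=float)
    mean = Y.mean(axis=0)
    total = 0.0
    for row in Y:
        total += sum(wi * (a - b) ** 2 for wi, a, b in zip(w, row, mean))
    return total / len(Y)


def enumerate_splits(d, rows):
    """(attr_name, kind, threshold_or_level) candidates in canonical order."""
    out = []
    for a in d.attributes:
        col = d.X[a.name]
        vals = [col.iloc[r] for r in rows]
        if a.kind == "numeric":
            xs = sorted({float(v) for v in vals if not _is_missing(v)})
            for lo, hi in zip(xs[:-1], xs[1:]):
                out.append((a.name, "numeric", (lo + hi) / 2.0))
        elif a.kind == "binary":
            xs = {float(v) for v in vals if not _is_missing(v)}
            if len(xs) >= 2:
                out.append((a.name, "binary", None))
        else:
            seen = {str(v) for v in vals if not _is_missing(v)}
            levels = [lv for lv in a.levels if lv in seen]
            if len(levels) >= 2:
                for lv in levels:
                    out.append((a.name, "nominal", lv))
    return out


def _is_missing(v):
    return v is None or (isinstance(v, float) and np.isnan(v))


def split_rows(d, rows, cand):
    """Partition rows; missing follows the larger non-missing side (tie: yes)."""
    name, kind, arg = cand
    col = d.X[name]
    yes, no, miss = [], [], []
    for r in rows:
        v = col.iloc[r]
        if _is_missing(v):
            miss.append(r)
        elif kind == "numeric":
            (yes if float(v) > arg else no).append(r)
        elif kind == "binary":
            (yes if float(v) == 1.0 else no).append(r)
        else:
            (yes if str(v) == arg else no).append(r)
    if len(yes) >= len(no):
        yes += miss
    else:
        no += miss
    return yes, no


def best_split(d, rows, w, min_leaf):
    """Exhaustive variance-reduction argmax; returns (candidate, reduction)
    or (None, None).  Earliest candidate wins ties."""
    rows = list(rows)
    Y = d.labels.astype(float)
    var_total = two_pass_variance(Y[rows], w)
    best, best_red = None, None
    for cand in enumerate_splits(d, rows):
        yes, no = split_rows(d, rows, cand)
        if len(yes) < min_leaf or len(no) < min_leaf:
            continue
        red = (var_total
               - len(yes) / len(rows) * two_pass_variance(Y[yes], w)
               - len(no) / len(rows) * two_pass_variance(Y[no], w))
        if best_red is None or red > best_red + _TIE * max(1.0, abs(best_red)):
            best, best_red = cand, red
    return best, best_red


def pr_points(scores, truth):
    """(threshold, recall, precision) per distinct score, by direct counting."""
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth).ravel().astype(bool)
    pts = []
    for t in sorted(set(scores), reverse=True):
        tp = fp = fn = 0
        for s, y in zip(scores, truth):
            if s >= t and y:
                tp += 1
            elif s >= t:
                fp += 1
            elif y:
                fn += 1
        pts.append((t, tp / (tp + fn), tp / (tp + fp)))
    return pts


def auprc_grid(scores, truth, n_grid=10_000):
    """AUPRC via a dense threshold grid + trapezoid, carrying the first
    precision back to recall 0."""
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth).ravel().astype(bool)
    n_pos = truth.sum()
    grid = np.linspace(scores.max(), scores.min(), n_grid)
    rs, ps = [0.0], [None]
    for t in grid:
        hit = scores >= t
        tp = int((hit & truth).sum())
        npred = int(hit.sum())
        if npred == 0:
            continue
        rs.append(tp / n_pos)
        ps.append(tp / npred)
    ps[0] = ps[1]
    return float(np.trapezoid(ps, rs))


def auroc_pairs(scores, truth):
    """Mann-Whitney by explicit pair counting (ties count half)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    pos = scores[truth]
    neg = scores[~truth]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_dataset(rng, n_rows=30, n_attrs=5, n_classes=6, missing_rate=0.05):
    """A small random dataset with a random tree hierarchy and random
    ancestor-closed labels (no planted structure)."""
    import pandas as pd

    from pcthmc.dataset_io import Attribute, Dataset
    from pcthmc.hierarchy import build_hierarchy, close_ancestors

    names = [f"k{i}" for i in range(n_classes)]
    edges = []
    for i in range(1, n_classes):
        if rng.random() < 0.8:
            edges.append((names[i], names[rng.integers(i)]))
    h = build_hierarchy(edges, names)

    attrs, data = [], {}
    kinds = rng.choice(["numeric", "binary", "nominal"], size=n_attrs,
                       p=[0.6, 0.25, 0.15])
    for j, kind in enumerate(kinds):
        nm = f"a{j}"
        if kind == "numeric":
            col = rng.normal(size=n_rows).round(3)
            col[rng.random(n_rows) < missing_rate] = np.nan
            attrs.append(Attribute(nm, "numeric"))
            data[nm] = col
        elif kind == "binary":
            col = rng.integers(0, 2, size=n_rows).astype(float)
            col[rng.random(n_rows) < missing_rate] = np.nan
            attrs.append(Attribute(nm, "binary"))
            data[nm] = col
        else:
            levels = ("lo", "mid", "hi")
            col = [levels[i] for i in rng.integers(0, 3, size=n_rows)]
            col = [None if rng.random() < missing_rate else v for v in col]
            attrs.append(Attribute(nm, "nominal", levels))
            data[nm] = pd.array(col, dtype=object)

    raw = (rng.random((n_rows, n_classes)) < 0.3).astype(np.uint8)
    labels = close_ancestors(h, raw)
    return Dataset(attrs, pd.DataFrame(data), labels, h,
                   [f"g{i}" for i in range(n_rows)])
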