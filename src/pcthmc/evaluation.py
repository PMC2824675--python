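"""Precision-recall based evaluation for hierarchical multi-label models.

Gene function classes are mostly rare, so negatives vastly outnumber
positives and ROC analysis paints an overly rosy picture; precision/recall
is the primary lens here.  Two curve types are produced by sweeping the
prediction threshold from 1 down to 0 over the score matrix:

* a **function-wise** curve per class i, from TP_i / FP_i / FN_i, and
* a **pooled** (micro-averaged) curve, from the sums of TP_i, FP_i, FN_i
  over all classes at a common threshold.

Correctly predicted negatives are ignored throughout.  Both curves are
functions of the score values only — permuting the instances never changes
a curve.  In particular a constant-score classifier yields, for any class,
the flat curve at precision = class frequency (and AUPRC = frequency); an
evaluation that depends on instance order is defective.

Scalar summaries: AU(pooled-PR), the area under the pooled curve (weights
frequent classes more), the unweighted mean of per-class AUPRCs, and the
mean per-class AUROC.  Classes without positive test instances are
excluded from the per-class means and counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .dataset_io import Dataset, PredictionMatrix
from .hierarchy import ClassHierarchy

__all__ = [
    "PRCurve",
    "EvaluationReport",
    "confusion_counts",
    "functionwise_pr_curve",
    "pooled_pr_curve",
    "auprc",
    "auroc",
    "evaluate",
    "stratify_by_specificity",
    "tune_significance",
    "TuneResult",
    "SPECIFICITY_RANGES",
]

#: specificity strata: number of training-set positives per class
SPECIFICITY_RANGES = ((3, 10), (11, 30), (31, 100), (101, 300))


@dataclass(frozen=True)
class PRCurve:
    """Ordered (recall, precision) points for one class or the pooled sweep.

    Points are ordered by decreasing threshold, hence non-decreasing
    recall.  The raw TP/FP counts per point are kept so that non-linear
    (hyperbolic) interpolation between points remains possible.
    """

    recall: np.ndarray
    precision: np.ndarray
    class_scope: str = "pooled"
    tp: np.ndarray | None = None
    fp: np.ndarray | None = None
    n_pos: int | None = None

    def __post_init__(self):
        r = np.asarray(self.recall, dtype=float)
        p = np.asarray(self.precision, dtype=float)
        if r.shape != p.shape or r.ndim != 1 or len(r) == 0:
            raise ValueError("curve needs matching non-empty point arrays")
        if np.any(np.diff(r) < 0):
            raise ValueError("recall must be non-decreasing along the curve")
        object.__setattr__(self, "recall", r)
        object.__setattr__(self, "precision", p)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.recall, self.precision])


def confusion_counts(
    pred: PredictionMatrix | np.ndarray,
    truth: np.ndarray,
    threshold: float,
):
    """Per-class (TP, FP, FN) at a single threshold (score >= t predicts).

    True negatives are deliberately not counted.
    """
    scores = pred.scores if isinstance(pred, PredictionMatrix) else np.asarray(pred, float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    hit = scores >= threshold
    pos = truth.astype(bool)
    tp = (hit & pos).sum(axis=0)
    fp = (hit & ~pos).sum(axis=0)
    fn = (~hit & pos).sum(axis=0)
    return tp, fp, fn


def _sweep(scores: np.ndarray, pos: np.ndarray):
    """TP and predicted-count per distinct threshold (descending).

    Returns (thresholds, tp, npred); depends only on the multiset of
    (score, label) pairs, never on instance order.
    """
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = pos[order]
    cum_tp = np.cumsum(y)
    cum_n = np.arange(1, len(s) + 1)
    last = np.flatnonzero(np.append(s[1:] < s[:-1], True))
    return s[last], cum_tp[last], cum_n[last]


def functionwise_pr_curve(scores: np.ndarray, truth: np.ndarray,
                          class_scope: str = "") -> PRCurve:
    """PR curve for a single class, one point per distinct score value."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(truth).astype(bool)
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError(
            f"class {class_scope!r} has no positive instances; excluded "
            f"from function-wise evaluation")
    _, tp, npred = _sweep(scores, pos)
    recall = tp / n_pos
    precision = tp / npred
    return PRCurve(recall, precision, class_scope or "class",
                   tp=tp, fp=npred - tp, n_pos=n_pos)


def pooled_pr_curve(pred: PredictionMatrix | np.ndarray, truth: np.ndarray) -> PRCurve:
    """Micro-averaged PR curve: one global threshold over all gene-class
    pairs; precision = sum TP_i / (sum TP_i + sum FP_i), likewise recall."""
    scores = pred.scores if isinstance(pred, PredictionMatrix) else np.asarray(pred, float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    flat_s = scores.ravel()
    flat_y = truth.ravel().astype(bool)
    n_pos = int(flat_y.sum())
    if n_pos == 0:
        raise ValueError("no positive gene-class pair to evaluate")
    _, tp, npred = _sweep(flat_s, flat_y)
    return PRCurve(tp / n_pos, tp / npred, "pooled",
                   tp=tp, fp=npred - tp, n_pos=n_pos)


def auprc(curve: PRCurve, interpolation: str = "trapezoid") -> float:
    """Area under a PR curve over the achieved recall range.

    ``"trapezoid"`` (default): linear interpolation between achieved
    points, with the curve anchored at recall 0 by carrying the first
    point's precision back.  ``"davis-goadrich"``: hyperbolic
    interpolation in TP/FP space between achieved points (requires the
    stored counts), same anchoring.
    """
    r, p = curve.recall, curve.precision
    if interpolation == "trapezoid":
        r_ext = np.concatenate([[0.0], r])
        p_ext = np.concatenate([[p[0]], p])
        return float(np.trapezoid(p_ext, r_ext))
    if interpolation != "davis-goadrich":
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if curve.tp is None or curve.fp is None or curve.n_pos is None:
        raise ValueError("davis-goadrich interpolation needs TP/FP counts")
    area = r[0] * p[0]  # anchor segment: precision carried back to recall 0
    for i in range(len(r) - 1):
        tp1, fp1 = int(curve.tp[i]), int(curve.fp[i])
        tp2, fp2 = int(curve.tp[i + 1]), int(curve.fp[i + 1])
        d_tp = tp2 - tp1
        if d_tp == 0:
            continue
        slope = (fp2 - fp1) / d_tp
        xs = np.arange(1, d_tp + 1, dtype=float)
        prec = (tp1 + xs) / (tp1 + xs + fp1 + slope * xs)
        prev = np.concatenate([[p[i]], prec[:-1]])
        area += float(np.sum((prec + prev) / 2.0) / curve.n_pos)
    return float(area)


def auroc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney statistic, ties half)."""
    truth = np.asarray(truth).astype(int)
    if truth.min() == truth.max():
        raise ValueError("AUROC needs at least one positive and one negative")
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


@dataclass
class EvaluationReport:
    """Scalar summaries plus the per-class table.

    ``per_class`` maps class -> (auprc, auroc-or-nan, n_pos) for every class
    with at least one positive test instance.
    """

    au_pooled_prc: float
    mean_auprc: float
    mean_auroc: float
    per_class: dict[str, tuple[float, float, int]]
    classes_evaluated: int
    classes_skipped: tuple[str, ...] = ()
    pooled_curve: PRCurve | None = field(default=None, repr=False)

    def summary_lines(self) -> list[str]:
        return [
            f"AU(pooled-PR)\t{self.au_pooled_prc:.4f}",
            f"mean per-class AUPRC\t{self.mean_auprc:.4f}",
            f"mean per-class AUROC\t{self.mean_auroc:.4f}",
            f"classes evaluated\t{self.classes_evaluated}",
            f"classes without test positives\t{len(self.classes_skipped)}",
        ]


def _align(pred: PredictionMatrix | np.ndarray, h: ClassHierarchy) -> np.ndarray:
    if not isinstance(pred, PredictionMatrix):
        return np.asarray(pred, dtype=float)
    if tuple(pred.classes) == tuple(h.classes):
        return pred.scores
    try:
        cols = [pred.classes.index(c) for c in h.classes]
    except ValueError as e:
        raise ValueError(f"prediction matrix lacks a hierarchy class: {e}") from None
    return pred.scores[:, cols]


def evaluate(
    pred: PredictionMatrix | np.ndarray,
    truth: np.ndarray,
    hierarchy: ClassHierarchy,
    interpolation: str = "trapezoid",
) -> EvaluationReport:
    """Full evaluation of a score matrix against ancestor-closed truth.

    Classes with no positive test instance are excluded from the per-class
    means (they admit no recall) and reported in ``classes_skipped``.
    """
    scores = _align(pred, hierarchy)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    per_class: dict[str, tuple[float, float, int]] = {}
    skipped: list[str] = []
    for j, cls in enumerate(hierarchy.classes):
        n_pos = int(truth[:, j].sum())
        if n_pos == 0:
            skipped.append(cls)
            continue
        curve = functionwise_pr_curve(scores[:, j], truth[:, j], cls)
        a_pr = auprc(curve, interpolation)
        a_roc = (auroc(scores[:, j], truth[:, j])
                 if n_pos < len(truth) else float("nan"))
        per_class[cls] = (a_pr, a_roc, n_pos)
    if not per_class:
        raise ValueError("no class has a positive test instance")
    pooled = pooled_pr_curve(scores, truth)
    rocs = [v[1] for v in per_class.values() if np.isfinite(v[1])]
    return EvaluationReport(
        au_pooled_prc=auprc(pooled, interpolation),
        mean_auprc=float(np.mean([v[0] for v in per_class.values()])),
        mean_auroc=float(np.mean(rocs)) if rocs else float("nan"),
        per_class=per_class,
        classes_evaluated=len(per_class),
        classes_skipped=tuple(skipped),
        pooled_curve=pooled,
    )


def stratify_by_specificity(
    report: EvaluationReport,
    train_positives: Mapping[str, int],
    ranges: Sequence[tuple[int, int]] = SPECIFICITY_RANGES,
) -> dict[str, tuple[float, float, int]]:
    """Group the per-class table by training-set specificity.

    Specificity of a class is the number of training genes annotated with
    it; each range maps to (mean AUPRC, mean AUROC, n classes).
    """
    out: dict[str, tuple[float, float, int]] = {}
    for lo, hi in ranges:
        rows = [
            v for cls, v in report.per_class.items()
            if lo <= train_positives.get(cls, 0) <= hi
        ]
        if not rows:
            continue
        rocs = [v[1] for v in rows if np.isfinite(v[1])]
        out[f"{lo}-{hi}"] = (
            float(np.mean([v[0] for v in rows])),
            float(np.mean(rocs)) if rocs else float("nan"),
            len(rows),
        )
    return out


# ---------------------------------------------------------------------------
# significance tuning


@dataclass
class TuneResult:
    significance: float
    model: object
    validation_scores: dict[float, float]


def _stratified_split(labels: np.ndarray, val_fraction: float,
                      rng: np.random.Generator):
    """2/3 build / 1/3 validation split, stratified by whether an instance
    carries any annotation at all."""
    n = len(labels)
    has_label = labels.sum(axis=1) > 0
    build, val = [], []
    for mask in (has_label, ~has_label):
        idx = np.flatnonzero(mask)
        idx = idx[rng.permutation(len(idx))]
        n_val = int(round(len(idx) * val_fraction))
        val.extend(idx[:n_val])
        build.extend(idx[n_val:])
    return np.sort(np.asarray(build, int)), np.sort(np.asarray(val, int))


def tune_significance(
    d: Dataset,
    params=None,
    candidates: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
    ensemble_k: int | None = None,
    val_fraction: float = 1.0 / 3.0,
) -> TuneResult:
    """Select the F-test significance level on an internal validation split.

    One third of the training data (stratified by any-label presence) is
    held out; for each candidate significance a model is trained on the
    rest and scored by AU(pooled-PR) on the hold-out.  The best candidate
    wins (ties go to the smaller, i.e. more stringent, value) and the final
    model is retrained on the full training set with it.  Set
    ``ensemble_k`` to tune a bagged ensemble instead of a single tree.
    """
    from dataclasses import replace

    from .ensemble import fit_bagging
    from .pct import SIGNIFICANCE_GRID, PCTParams, build_tree

    params = params or PCTParams()
    if candidates is None:
        candidates = SIGNIFICANCE_GRID
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    rng = rng or np.random.default_rng(params.rng_seed)

    build_idx, val_idx = _stratified_split(d.labels, val_fraction, rng)
    if len(build_idx) < 2 * params.min_leaf or len(val_idx) < 1:
        raise ValueError("dataset too small for a tuning split")

    from .ensemble import _subset_dataset
    d_build = _subset_dataset(d, build_idx)
    d_val = _subset_dataset(d, val_idx)

    def fit(train, p):
        if ensemble_k is None:
            return build_tree(train, p)
        return fit_bagging(train, ensemble_k, p)

    scores: dict[float, float] = {}
    best_sig, best_score = None, -np.inf
    for sig in sorted(candidates):
        p = replace(params, f_test_significance=sig)
        model = fit(d_build, p)
        pred = model.predict_dataset(d_val)
        score = auprc(pooled_pr_curve(pred, d_val.labels))
        scores[sig] = score
        if score > best_score:  # strict: ties keep the smaller significance
            best_sig, best_score = sig, score
    final = fit(d, replace(params, f_test_significance=best_sig))
    return TuneResult(best_sig, final, scores)
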