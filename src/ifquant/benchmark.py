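"""Instance-segmentation benchmarking against a reference mask.

Objects of a predicted label mask are matched one-to-one to reference
objects (maximum-cardinality matching over pairs whose IoU passes the
threshold, seeded by descending IoU for determinism). From the
TP/FP/FN counts at each IoU threshold of the 0..1 grid (step 0.05) the
four quality metrics are computed:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    jaccard   = TP / (TP + FP + FN)
    f-measure = 2 TP / (2 TP + FP + FN)

with the 0/0 cases defined as 0. An efficacy summary aggregates the
detected-object fraction and the four metrics at a fixed threshold into
their arithmetic mean, and percent evolutions between methods as
(b/a - 1) x 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import LabelMask

__all__ = [
    "MatchResult",
    "BenchmarkCurve",
    "iou_matrix",
    "match_at_threshold",
    "metrics",
    "curve",
    "percent_detected",
    "average_efficacy",
    "evolution_pct",
    "efficacy_summary",
    "IOU_GRID",
]

#: the 21-point IoU threshold grid
IOU_GRID = tuple(np.round(np.arange(21) * 0.05, 2))

EFFICACY_MEASURES = ("detected_fraction", "precision", "recall", "jaccard", "fmeasure")


@dataclass(frozen=True)
class MatchResult:
    threshold: float
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("tp/fp/fn must be >= 0")

    @property
    def n_reference(self) -> int:
        return self.tp + self.fn

    @property
    def n_predicted(self) -> int:
        return self.tp + self.fp


@dataclass
class BenchmarkCurve:
    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    jaccard: np.ndarray
    fmeasure: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "TP": self.tp, "FP": self.fp, "FN": self.fn,
            "precision": self.precision, "recall": self.recall,
            "jaccard": self.jaccard, "fmeasure": self.fmeasure,
        })

    def at(self, threshold: float) -> dict[str, float]:
        idx = int(np.argmin(np.abs(self.thresholds - threshold)))
        if abs(self.thresholds[idx] - threshold) > 1e-9:
            raise KeyError(f"threshold {threshold} not on the grid")
        return {
            "precision": float(self.precision[idx]),
            "recall": float(self.recall[idx]),
            "jaccard": float(self.jaccard[idx]),
            "fmeasure": float(self.fmeasure[idx]),
        }


def iou_matrix(reference: LabelMask, predicted: LabelMask) -> np.ndarray:
    """Pairwise IoU between reference objects (rows) and predictions (cols)."""
    if reference.shape != predicted.shape:
        raise ValueError(
            f"mask shapes differ: {reference.shape} vs {predicted.shape}"
        )
    n_ref, n_pred = reference.n_objects, predicted.n_objects
    if n_ref == 0 or n_pred == 0:
        return np.zeros((n_ref, n_pred))
    ref = reference.labels.ravel().astype(np.int64)
    pred = predicted.labels.ravel().astype(np.int64)
    joint = np.bincount(ref * (n_pred + 1) + pred,
                        minlength=(n_ref + 1) * (n_pred + 1))
    joint = joint.reshape(n_ref + 1, n_pred + 1).astype(np.float64)
    inter = joint[1:, 1:]
    ref_areas = joint[1:, :].sum(axis=1, keepdims=True)
    pred_areas = joint[:, 1:].sum(axis=0, keepdims=True)
    union = ref_areas + pred_areas - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def match_at_threshold(iou: np.ndarray, t: float) -> MatchResult:
    """Optimal one-to-one matching at threshold ``t``.

    A pair is admissible iff its IoU >= t and IoU > 0 (at t = 0 mere
    coexistence does not match). Matching is seeded greedily by
    descending IoU (ties: smaller reference label, then smaller
    predicted label) and then augmented to a maximum-cardinality
    matching, so the TP count is provably maximal — plain greedy
    matching can undercount on crossing overlap patterns. Unmatched
    predictions are FP, unmatched references FN.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    iou = np.asarray(iou, dtype=np.float64)
    n_ref, n_pred = iou.shape
    ri, pi = np.nonzero((iou >= t) & (iou > 0))
    vals = iou[ri, pi]
    order = np.lexsort((pi, ri, -vals))

    # greedy seed by descending IoU
    match_of_ref = np.full(n_ref, -1, dtype=np.int64)
    match_of_pred = np.full(n_pred, -1, dtype=np.int64)
    for k in order:
        r, p = ri[k], pi[k]
        if match_of_ref[r] < 0 and match_of_pred[p] < 0:
            match_of_ref[r] = p
            match_of_pred[p] = r

    # augmenting paths (Kuhn) to maximum cardinality
    neighbors: dict[int, list[int]] = {}
    for k in order:
        neighbors.setdefault(int(ri[k]), []).append(int(pi[k]))

    def try_augment(r: int, seen: set[int]) -> bool:
        for p in neighbors.get(r, ()):
            if p in seen:
                continue
            seen.add(p)
            if match_of_pred[p] < 0 or try_augment(int(match_of_pred[p]), seen):
                match_of_ref[r] = p
                match_of_pred[p] = r
                return True
        return False

    for r in range(n_ref):
        if match_of_ref[r] < 0:
            try_augment(r, set())

    tp = int((match_of_ref >= 0).sum())
    return MatchResult(t, tp, n_pred - tp, n_ref - tp)


def metrics(m: MatchResult) -> tuple[float, float, float, float]:
    """(precision, recall, jaccard, fmeasure); 0/0 defined as 0."""
    tp, fp, fn = m.tp, m.fp, m.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    jaccard = tp / (tp + fp + fn) if tp + fp + fn else 0.0
    fmeasure = 2 * tp / (2 * tp + fp + fn) if tp + fp + fn else 0.0
    return precision, recall, jaccard, fmeasure


def curve(
    reference: LabelMask, predicted: LabelMask, step: float = 0.05
) -> BenchmarkCurve:
    """Evaluate the four metrics over the IoU threshold grid."""
    n_points = int(round(1.0 / step)) + 1
    thresholds = np.round(np.arange(n_points) * step, 10)
    iou = iou_matrix(reference, predicted)
    rows = [match_at_threshold(iou, float(t)) for t in thresholds]
    mets = np.array([metrics(m) for m in rows])
    return BenchmarkCurve(
        thresholds=thresholds,
        tp=np.array([m.tp for m in rows]),
        fp=np.array([m.fp for m in rows]),
        fn=np.array([m.fn for m in rows]),
        precision=mets[:, 0], recall=mets[:, 1],
        jaccard=mets[:, 2], fmeasure=mets[:, 3],
    )


def percent_detected(
    reference: LabelMask, predicted: LabelMask, matched_only: bool = False
) -> float:
    """Predicted objects as a percentage of reference objects.

    The default counts every predicted object (the reference mask stands
    for 100%). With ``matched_only=True`` only predictions overlapping a
    reference object (IoU > 0, one-to-one) are counted.
    """
    if reference.n_objects == 0:
        raise ValueError("reference mask has no objects")
    if matched_only:
        n = match_at_threshold(iou_matrix(reference, predicted), 0.0).tp
    else:
        n = predicted.n_objects
    return 100.0 * n / reference.n_objects


def average_efficacy(values: dict[str, float] | list[float]) -> float:
    """Arithmetic mean of the five efficacy measurements."""
    if isinstance(values, dict):
        missing = set(EFFICACY_MEASURES) - set(values)
        if missing:
            raise ValueError(f"missing efficacy measurements: {sorted(missing)}")
        values = [values[k] for k in EFFICACY_MEASURES]
    if len(values) != 5:
        raise ValueError(f"expected 5 efficacy values, got {len(values)}")
    return float(np.mean(values))


def evolution_pct(a: float, b: float, decimals: int = 2) -> float:
    """Percent evolution from a to b: (b/a - 1) x 100, rounded."""
    if a == 0:
        raise ZeroDivisionError("undefined evolution: baseline efficacy is 0")
    return round((b / a - 1.0) * 100.0, decimals)


def efficacy_summary(
    per_method: dict[str, dict[str, float]],
    comparisons: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Tabulate per-method efficacies, their average, and evolutions.

    ``per_method`` maps method name -> the five efficacy measurements
    (fractions in [0, 1]; the detected fraction is percent/100).
    ``comparisons`` lists (baseline, method) pairs to report as percent
    evolutions of every row.
    """
    rows = []
    for measure in EFFICACY_MEASURES + ("average_efficacy",):
        row: dict[str, object] = {"measure": measure}
        for method, vals in per_method.items():
            row[method] = (average_efficacy(vals) if measure == "average_efficacy"
                           else vals[measure])
        for a, b in comparisons or []:
            try:
                row[f"evolution {a} -> {b} (%)"] = evolution_pct(
                    float(row[a]), float(row[b]))
            except ZeroDivisionError:
                row[f"evolution {a} -> {b} (%)"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
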