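"""Validation statistics for pixel segmentation and calcium measures.

Pixel-level quality is assessed per class by the ROC curve and its area
(probability scores against the binary ground truth), with the Youden
index picking an operating threshold, and by a 3x3 plaque confusion
matrix (calcium / lipid / fibrous) with per-class precision, recall and
F1 plus overall accuracy (trace over total).  Measurement-level
agreement between two readers or a reader and the model uses Pearson or
Spearman correlation, the intraclass correlation coefficient in its
two-way random-effects, absolute-agreement, single-measure form
(ICC(2,1)), and the 1D Dice coefficient over angular bins of two arcs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

from octcalc.phantom import CLASS_NAMES, PLAQUE_CLASSES


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # descending; classification is score >= threshold


def roc_auc(scores: Sequence[float], truth: Sequence[int]) -> Tuple[float, RocCurve]:
    """Trapezoidal ROC AUC; equals the Mann-Whitney rank statistic.

    Requires at least one positive and one negative item.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth).astype(bool)
    if truth.all() or not truth.any():
        raise ValueError("ROC requires at least one positive and one negative")
    fpr, tpr, thresholds = _sk_roc_curve(truth, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds)


def youden(roc: RocCurve) -> float:
    """Threshold maximizing sensitivity + specificity - 1.

    Ties are broken toward the lower threshold.  When the classes are
    perfectly separated (J = 1), the midpoint of the empty score gap is
    returned.
    """
    if roc.thresholds.size == 0:
        raise ValueError("empty ROC")
    j = roc.tpr - roc.fpr
    # sklearn's first threshold is +inf (classify nothing positive); a
    # real operating point never needs it unless it is the only one.
    valid = np.isfinite(roc.thresholds)
    if not valid.any():
        return float(roc.thresholds[0])
    j_v = np.where(valid, j, -np.inf)
    best = j_v.max()
    # thresholds descend, so the last argmax is the lowest threshold
    idx = int(np.nonzero(j_v == best)[0][-1])
    if best >= 1.0 - 1e-12 and idx + 1 < roc.thresholds.size:
        return float(0.5 * (roc.thresholds[idx] + roc.thresholds[idx + 1]))
    return float(roc.thresholds[idx])


def plaque_confusion(
    pred_labels: np.ndarray,
    true_labels: np.ndarray,
    plaque_classes: Sequence[int] = PLAQUE_CLASSES,
) -> Dict:
    """3x3 plaque confusion matrix restricted to ground-truth plaque pixels.

    Rows are ground truth, columns prediction, ordered as
    ``plaque_classes`` (calcium, lipid, fibrous by default).  Pixels
    whose prediction falls outside the plaque classes are excluded from
    the matrix and reported under ``n_excluded``.  Overall accuracy is
    trace over total; per-class precision is column-diagonal over
    column sum, recall row-diagonal over row sum, F1 their harmonic mean.
    """
    pred = np.asarray(pred_labels).ravel()
    true = np.asarray(true_labels).ravel()
    if pred.shape != true.shape:
        raise ValueError("prediction and truth must have the same shape")
    classes = list(plaque_classes)
    mask = np.isin(true, classes)
    if not mask.any():
        raise ValueError("ground truth contains no plaque pixels")
    pred, true = pred[mask], true[mask]
    in_plaque = np.isin(pred, classes)
    n_excluded = int((~in_plaque).sum())
    pred, true = pred[in_plaque], true[in_plaque]
    cm = _sk_confusion(true, pred, labels=classes)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total else float("nan")
    per_class = {}
    for i, c in enumerate(classes):
        col, row = cm[:, i].sum(), cm[i, :].sum()
        precision = float(cm[i, i] / col) if col else float("nan")
        recall = float(cm[i, i] / row) if row else float("nan")
        denom = precision + recall
        f1 = float(2 * precision * recall / denom) if denom else 0.0
        per_class[CLASS_NAMES[c] if c < len(CLASS_NAMES) else str(c)] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
        }
    return {
        "confusion": cm,
        "overall_accuracy": accuracy,
        "per_class": per_class,
        "n_excluded": n_excluded,
    }


def dice_1d(arc_a: np.ndarray, arc_b: np.ndarray) -> float:
    """Angular-overlap Dice coefficient ``2|A∩B| / (|A| + |B|)``.

    Arguments are boolean occupancy vectors over the same angular binning
    (1-degree bins by convention).  Two empty arcs agree perfectly: 1.0.
    """
    a = np.asarray(arc_a, dtype=bool)
    b = np.asarray(arc_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("arc bin vectors must share a binning")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _icc_2_1(x: np.ndarray, y: np.ndarray) -> Tuple[float, Tuple[float, float]]:
    """ICC(2,1) with F-based 95% CI via pingouin."""
    import pandas as pd
    import pingouin as pg

    n = x.size
    df = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["a", "b"], n),
            "score": np.concatenate([x, y]),
        }
    )
    icc_tab = pg.intraclass_corr(
        data=df, targets="target", raters="rater", ratings="score"
    )
    # The absolute-agreement single-measure row is labelled ICC2 (Shrout-
    # Fleiss) or ICC(A,1) (McGraw-Wong) depending on pingouin version.
    sel = icc_tab["Type"].isin(["ICC2", "ICC(A,1)"])
    row = icc_tab[sel].iloc[0]
    ci_col = "CI95%" if "CI95%" in icc_tab.columns else "CI95"
    lo, hi = row[ci_col]
    return float(row["ICC"]), (float(lo), float(hi))


def agreement(x: Sequence[float], y: Sequence[float]) -> Dict:
    """Correlation and agreement between two paired measurement series.

    Returns Pearson r (with Fisher-z 95% CI), Spearman rho, and ICC(2,1)
    (two-way random effects, absolute agreement, single measure) with its
    F-based 95% CI under ``ci_95``.  Requires n >= 3 and nonzero variance
    in both series.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D sequences")
    if x.size < 3:
        raise ValueError("agreement requires n >= 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("agreement requires finite values")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("agreement requires nonzero variance in both series")
    r = float(stats.pearsonr(x, y).statistic)
    rho = float(stats.spearmanr(x, y).statistic)
    if x.size > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(x.size - 3)
        r_ci = (float(np.tanh(z - 1.959963984540054 * se)),
                float(np.tanh(z + 1.959963984540054 * se)))
    else:
        r_ci = (float("nan"), float("nan"))
    icc, icc_ci = _icc_2_1(x, y)
    return {
        "pearson_r": r,
        "spearman_rho": rho,
        "pearson_ci_95": r_ci,
        "icc": icc,
        "ci_95": icc_ci,
    }


def majority_vote(label_maps: Sequence[np.ndarray]) -> np.ndarray:
    """Per-pixel majority label over several readers' label maps.

    Utility for multi-reader consensus; ties resolve to the smallest
    class index.
    """
    stack = np.stack([np.asarray(m) for m in label_maps])
    mode, _ = stats.mode(stack, axis=0, keepdims=False)
    return mode.astype(stack.dtype)


@dataclass
class EvalReport:
    """Per-class discrimination plus plaque-level segmentation quality."""

    per_class_auc: Dict[str, float] = field(default_factory=dict)
    youden_threshold: Dict[str, float] = field(default_factory=dict)
    confusion_3x3: Optional[np.ndarray] = None
    per_class_prf: Dict[str, Dict[str, float]] = field(default_factory=dict)
    overall_accuracy: float = float("nan")
    dice_1d: float = float("nan")
    agreement: Dict = field(default_factory=dict)
    n_excluded: int = 0

    def to_dict(self) -> Dict:
        return {
            "per_class_auc": self.per_class_auc,
            "youden_threshold": self.youden_threshold,
            "confusion_3x3": None
            if self.confusion_3x3 is None
            else np.asarray(self.confusion_3x3).tolist(),
            "per_class_prf": self.per_class_prf,
            "overall_accuracy": self.overall_accuracy,
            "dice_1d": self.dice_1d,
            "agreement": self.agreement,
            "n_excluded": self.n_excluded,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def evaluate_segmentation(
    proba: np.ndarray,
    pred_labels: np.ndarray,
    true_labels: np.ndarray,
    class_names: Sequence[str] = CLASS_NAMES,
    plaque_classes: Sequence[int] = PLAQUE_CLASSES,
    max_pixels: int = 200_000,
    seed: int = 0,
) -> EvalReport:
    """Full pixel-level report for a segmented pullback.

    ``proba`` is ``(n_frames, n_classes, H, W)`` class probabilities,
    ``pred_labels``/``true_labels`` are ``(n_frames, H, W)`` index maps.
    For the per-class ROC a random subsample of at most ``max_pixels``
    pixels keeps the rank statistics tractable; classes absent from the
    subsampled truth are skipped.
    """
    proba = np.asarray(proba)
    pred_labels = np.asarray(pred_labels)
    true_labels = np.asarray(true_labels)
    n_classes = proba.shape[1]
    flat_true = true_labels.ravel()
    flat_scores = proba.transpose(1, 0, 2, 3).reshape(n_classes, -1)
    rng = np.random.default_rng(seed)
    if flat_true.size > max_pixels:
        sel = rng.choice(flat_true.size, size=max_pixels, replace=False)
        flat_true = flat_true[sel]
        flat_scores = flat_scores[:, sel]

    report = EvalReport()
    for c in range(n_classes):
        name = class_names[c] if c < len(class_names) else str(c)
        truth_c = flat_true == c
        if truth_c.all() or not truth_c.any():
            continue
        auc, roc = roc_auc(flat_scores[c], truth_c)
        report.per_class_auc[name] = auc
        report.youden_threshold[name] = youden(roc)

    if np.isin(true_labels, list(plaque_classes)).any():
        conf = plaque_confusion(pred_labels, true_labels, plaque_classes)
        report.confusion_3x3 = conf["confusion"]
        report.per_class_prf = conf["per_class"]
        report.overall_accuracy = conf["overall_accuracy"]
        report.n_excluded = conf["n_excluded"]

    # Mean 1D Dice of the per-frame calcium arcs.
    from octcalc.quantify import frame_calcium_bins

    dices: List[float] = []
    for f in range(true_labels.shape[0]):
        a = frame_calcium_bins(pred_labels[f])
        b = frame_calcium_bins(true_labels[f])
        if a.any() or b.any():
            dices.append(dice_1d(a, b))
    report.dice_1d = float(np.mean(dices)) if dices else 1.0
    return report
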