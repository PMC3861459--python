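"""ROC machinery linking score maps to lesion ground truth.

Scores are oriented so that *higher means more lesion-like* (use −ΔAPA for
amplitude loss; cumulative-extrema maps are already positive).  Curves are
built over all distinct score thresholds with tied scores grouped, the AUC
is the trapezoid integral (exactly the Mann–Whitney pair-counting statistic
under that tie convention), the operating threshold maximizes Youden's
J = sensitivity + specificity − 1 with ties broken toward higher
specificity, and leave-one-out cross-validation across subjects quantifies
threshold/AUC stability.  Pixel non-independence is deliberately ignored in
curve construction; LOO across subjects is the unit of uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import LesionMask, ValidationError

__all__ = [
    "ScoredPixels",
    "ROCResult",
    "roc_curve",
    "optimal_threshold",
    "classify",
    "confusion_metrics",
    "loo_cv",
    "detection_timecourse",
    "band_classifier",
    "kruskal_wallis",
]


@dataclass
class ScoredPixels:
    """Flat per-pixel scores and lesion labels for one subject."""

    scores: np.ndarray
    labels: np.ndarray
    subject: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64).ravel()
        self.labels = np.asarray(self.labels, dtype=bool).ravel()
        if self.scores.shape != self.labels.shape:
            raise ValidationError("scores and labels must match")
        keep = np.isfinite(self.scores)
        self.scores = self.scores[keep]
        self.labels = self.labels[keep]

    @classmethod
    def from_maps(cls, score_map: np.ndarray, mask: LesionMask | np.ndarray,
                  subject: str = "") -> "ScoredPixels":
        m = mask.mask if isinstance(mask, LesionMask) else np.asarray(mask, dtype=bool)
        return cls(scores=np.asarray(score_map), labels=m, subject=subject)

    def both_classes(self) -> bool:
        return bool(self.labels.any() and (~self.labels).any())


@dataclass
class ROCResult:
    """ROC curve with AUC and the Youden operating point."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float


def _curve(scores: np.ndarray, labels: np.ndarray):
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # boundaries between distinct scores
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.r_[distinct, s.size - 1]
    tp = np.cumsum(y)[idx].astype(np.float64)
    fp = np.cumsum(~y)[idx].astype(np.float64)
    return np.r_[0.0, tp], np.r_[0.0, fp], s[idx]


def roc_curve(sp: ScoredPixels) -> ROCResult:
    """ROC curve over all distinct thresholds; trapezoid AUC; Youden point."""
    if not sp.both_classes():
        raise ValidationError("both classes required for a ROC curve")
    tp, fp, thr = _curve(sp.scores, sp.labels)
    P, N = tp[-1], fp[-1]
    # trapezoid in count units (exact integer arithmetic in floats)
    area = float(np.sum(np.diff(fp) * (tp[1:] + tp[:-1]) / 2.0))
    auc = area / (P * N)
    tpr = tp / P
    fpr = fp / N
    j = tpr - fpr
    best = int(np.argmax(j[1:])) + 1  # first max => smallest FPR => higher specificity
    # report the midpoint between the retained score and the next one below,
    # so "score >= threshold" reproduces the operating point
    s_k = thr[best - 1]
    lower = thr[best] if best < thr.size else None
    threshold = float(s_k if lower is None else 0.5 * (s_k + lower))
    sens = float(tpr[best])
    spec = float(1.0 - fpr[best])
    acc = float((tp[best] + (N - fp[best])) / (P + N))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(auc),
                     threshold=threshold, sensitivity=sens, specificity=spec,
                     accuracy=acc)


def optimal_threshold(r: ROCResult) -> float:
    """Youden-optimal threshold of a computed curve."""
    return r.threshold


def classify(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Predicted lesion labels: score >= threshold."""
    return np.asarray(scores) >= threshold


def confusion_metrics(scores: np.ndarray, labels: np.ndarray, threshold: float) -> dict:
    """Accuracy / sensitivity / specificity of ``score >= threshold``."""
    pred = classify(np.asarray(scores).ravel(), threshold)
    y = np.asarray(labels, dtype=bool).ravel()
    tp = float(np.sum(pred & y))
    tn = float(np.sum(~pred & ~y))
    p = float(y.sum())
    n = float((~y).sum())
    return {
        "accuracy": (tp + tn) / y.size,
        "sensitivity": tp / p if p else np.nan,
        "specificity": tn / n if n else np.nan,
    }


def loo_cv(subjects: Sequence[ScoredPixels]) -> dict:
    """Leave-one-subject-out validation of the ROC threshold.

    For each fold the Youden threshold is trained on the pooled remaining
    subjects and evaluated on the held-out one.  Subjects with single-class
    labels are skipped with a warning.  Returns pooled AUC plus mean ± sd of
    the per-fold training thresholds and held-out AUC/accuracy.
    """
    usable = []
    for sp in subjects:
        if sp.both_classes():
            usable.append(sp)
        else:
            warnings.warn(f"subject {sp.subject!r} has single-class labels; fold skipped")
    if len(usable) < 3:
        raise ValidationError("need >= 3 usable subjects for LOO")
    pooled = ScoredPixels(np.concatenate([s.scores for s in usable]),
                          np.concatenate([s.labels for s in usable]))
    pooled_roc = roc_curve(pooled)
    thr, auc_out, acc_out, auc_train = [], [], [], []
    for i, held in enumerate(usable):
        rest = ScoredPixels(
            np.concatenate([s.scores for j, s in enumerate(usable) if j != i]),
            np.concatenate([s.labels for j, s in enumerate(usable) if j != i]))
        r = roc_curve(rest)
        thr.append(r.threshold)
        auc_train.append(r.auc)
        held_roc = roc_curve(held)
        auc_out.append(held_roc.auc)
        acc_out.append(confusion_metrics(held.scores, held.labels, r.threshold)["accuracy"])
    return {
        "n_folds": len(usable),
        "pooled_auc": pooled_roc.auc,
        "pooled_threshold": pooled_roc.threshold,
        "threshold_mean": float(np.mean(thr)),
        "threshold_sd": float(np.std(thr)),
        "train_auc_mean": float(np.mean(auc_train)),
        "train_auc_sd": float(np.std(auc_train)),
        "heldout_auc_mean": float(np.mean(auc_out)),
        "heldout_auc_sd": float(np.std(auc_out)),
        "heldout_accuracy_mean": float(np.mean(acc_out)),
        "heldout_accuracy_sd": float(np.std(acc_out)),
    }


def detection_timecourse(score_frames: np.ndarray, truth: LesionMask | np.ndarray,
                         threshold: Optional[float] = None) -> pd.DataFrame:
    """Frame-by-frame detection metrics of a score-map sequence.

    Per frame: ROC AUC against the fixed truth mask and, when a trained
    ``threshold`` is given, accuracy/sensitivity/specificity of
    ``score >= threshold``.  With cumulative-extrema scores and a fixed
    threshold the predicted-positive pixel set is non-shrinking over frames.
    """
    frames = np.asarray(score_frames, dtype=np.float64)
    mask = truth.mask if isinstance(truth, LesionMask) else np.asarray(truth, dtype=bool)
    if not mask.any():
        raise ValidationError("empty truth mask")
    rows = []
    for t in range(frames.shape[0]):
        sp = ScoredPixels.from_maps(frames[t], mask)
        row = {"frame": t}
        row["auc"] = roc_curve(sp).auc if sp.both_classes() else np.nan
        if threshold is not None:
            row.update(confusion_metrics(sp.scores, sp.labels, threshold))
        rows.append(row)
    return pd.DataFrame(rows)


def band_classifier(dapa_map: np.ndarray,
                    bounds: tuple[float, float] = (-0.43, -0.19)) -> np.ndarray:
    """Three-band ΔAPA classification map.

    Band 2 = lesion (ΔAPA < bounds[0]), band 1 = detectable non-lesion
    change (bounds[0] ≤ ΔAPA < bounds[1]), band 0 = unchanged.  Default
    bounds are the lesion threshold −0.43 and the detectability bound −0.19.
    """
    lo, hi = bounds
    if not lo < hi:
        raise ValidationError("bounds must be ordered (lesion_bound < change_bound)")
    x = np.asarray(dapa_map, dtype=np.float64)
    out = np.zeros(x.shape, dtype=np.int8)
    out[x < hi] = 1
    out[x < lo] = 2
    return out


def kruskal_wallis(*groups: np.ndarray) -> tuple[float, float]:
    """Kruskal–Wallis H and p-value from the rank statistic formula.

    H is computed from pooled mid-ranks with the standard tie correction;
    the p-value uses the χ² approximation with k−1 degrees of freedom.
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    data = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    pooled = np.concatenate(data)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for g in data:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if tie > 0:
        h /= tie
    p = float(stats.chi2.sf(h, df=len(groups) - 1))
    return float(h), p
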