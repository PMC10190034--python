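"""Precision-recall machinery and threshold calibration.

The consensus score is calibrated on labelled validation variants: the
default reporting threshold is the F1-optimal point of the precision-recall
sweep, a second high-specificity threshold serves confirmatory settings,
and cross-tool comparisons fix each tool's threshold at the point reaching
a target precision (tools that never reach it are excluded). Evaluation is
also stratified by splice region (donor / acceptor / exon / intron), since
predictor performance is strongly region-dependent.

auPRC uses step-wise (rectangular) integration over recall; the precision
at recall 0 is anchored at the precision of the top-ranked point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class PRCurve:
    """One point per distinct score, swept with descending threshold."""

    thresholds: np.ndarray  # strictly decreasing
    precision: np.ndarray
    recall: np.ndarray  # non-decreasing along the sweep
    tp: np.ndarray
    fp: np.ndarray
    n_pos: int
    n_neg: int
    auprc: float = field(init=False)

    def __post_init__(self) -> None:
        self.auprc = float(
            np.sum(np.diff(np.concatenate([[0.0], self.recall])) * self.precision)
        )

    @property
    def fn(self) -> np.ndarray:
        return self.n_pos - self.tp

    @property
    def tn(self) -> np.ndarray:
        return self.n_neg - self.fp

    @property
    def specificity(self) -> np.ndarray:
        return self.tn / self.n_neg

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "precision": self.precision,
                "recall": self.recall,
                "specificity": self.specificity,
                "tp": self.tp,
                "fp": self.fp,
                "fn": self.fn,
                "tn": self.tn,
            }
        )


@dataclass
class CalibrationReport:
    f1_optimal_threshold: float
    f1: float
    sensitivity: float
    specificity: float
    high_specificity_threshold: float | None
    high_specificity_sensitivity: float | None
    precision95_threshold: float | None
    auprc: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def pr_curve(scores: Sequence[float], labels: Sequence[bool]) -> PRCurve:
    """Precision-recall sweep over every distinct score as a threshold.

    A prediction is positive when score >= threshold (inclusive), so tied
    scores share a threshold/point. Requires at least one positive and one
    negative label.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("pr_curve needs both classes present")

    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    cum_tp = np.cumsum(y_sorted)
    cum_fp = np.cumsum(~y_sorted)
    # last index of each tied block of scores
    last = np.nonzero(np.diff(s_sorted, append=np.nan))[0]
    thr = s_sorted[last]
    tp = cum_tp[last].astype(int)
    fp = cum_fp[last].astype(int)
    precision = tp / (tp + fp)
    recall = tp / n_pos
    return PRCurve(thr, precision, recall, tp, fp, n_pos, n_neg)


def f1_optimal_threshold(curve: PRCurve) -> tuple[float, float, float]:
    """Threshold maximizing F1; returns (threshold, sensitivity, specificity).

    Ties break toward the higher threshold (higher specificity).
    """
    with np.errstate(invalid="ignore"):
        f1 = 2 * curve.precision * curve.recall / (curve.precision + curve.recall)
    f1 = np.nan_to_num(f1, nan=0.0)  # tp == 0 at the top of the sweep
    best = int(np.argmax(f1 > np.max(f1) - 1e-12))  # first index = highest threshold
    return (
        float(curve.thresholds[best]),
        float(curve.recall[best]),
        float(curve.specificity[best]),
    )


def threshold_at_precision(curve: PRCurve, target: float = 0.95) -> float | None:
    """Lowest threshold whose precision >= target, or None if unattainable."""
    if not 0.0 < target <= 1.0:
        raise ValueError("target precision must be in (0, 1]")
    ok = np.nonzero(curve.precision >= target)[0]
    if ok.size == 0:
        return None
    return float(curve.thresholds[ok[-1]])  # thresholds descend along the sweep


def threshold_at_specificity(
    curve: PRCurve, target: float
) -> tuple[float, float]:
    """Lowest threshold with specificity >= target, plus its sensitivity.

    When no threshold attains the target, the highest (most specific)
    threshold is returned.
    """
    ok = np.nonzero(curve.specificity >= target)[0]
    idx = int(ok[-1]) if ok.size else 0
    return float(curve.thresholds[idx]), float(curve.recall[idx])


def threshold_at_sensitivity(
    curve: PRCurve, target: float
) -> tuple[float, float]:
    """Highest threshold with sensitivity >= target, plus its specificity.

    The complementary search direction to :func:`threshold_at_specificity`
    (useful when a sensitivity floor, not a specificity floor, is given).
    """
    ok = np.nonzero(curve.recall >= target)[0]
    idx = int(ok[0]) if ok.size else len(curve.thresholds) - 1
    return float(curve.thresholds[idx]), float(curve.specificity[idx])


def calibrate(
    scores: Sequence[float],
    labels: Sequence[bool],
    specificity_target: float = 0.975,
    precision_target: float = 0.95,
) -> CalibrationReport:
    """Full calibration: F1 point, high-specificity point, precision bar."""
    curve = pr_curve(scores, labels)
    thr, sens, spec = f1_optimal_threshold(curve)
    f1 = 2 * sens * (curve.precision[curve.thresholds == thr][0]) / (
        sens + curve.precision[curve.thresholds == thr][0]
    )
    hs_thr, hs_sens = threshold_at_specificity(curve, specificity_target)
    return CalibrationReport(
        f1_optimal_threshold=thr,
        f1=float(f1),
        sensitivity=sens,
        specificity=spec,
        high_specificity_threshold=hs_thr,
        high_specificity_sensitivity=hs_sens,
        precision95_threshold=threshold_at_precision(curve, precision_target),
        auprc=curve.auprc,
        n_pos=curve.n_pos,
        n_neg=curve.n_neg,
    )


def stratified_recall(
    scores: Sequence[float],
    labels: Sequence[bool],
    regions: Sequence[str],
    threshold: float,
) -> dict[str, dict]:
    """Recall per splice-region stratum at one threshold.

    Strata with no positive variants report recall None (undefined), never
    0. Counts are included for audit.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    r = np.asarray(regions)
    out: dict[str, dict] = {}
    for region in pd.unique(r):
        mask = r == region
        pos = y & mask
        n_pos = int(pos.sum())
        called = int((pos & (s >= threshold)).sum())
        out[str(region)] = {
            "recall": (called / n_pos) if n_pos else None,
            "n_pos": n_pos,
            "n_called": called,
        }
    return out


def concordance(
    scores_a: Mapping[str, float] | pd.Series,
    scores_b: Mapping[str, float] | pd.Series,
    labels: Mapping[str, bool] | pd.Series,
    threshold_a: float,
    threshold_b: float,
) -> dict:
    """Agreement of two tools' calls at their respective thresholds.

    Returns the concordant fraction, the discordant variants with both
    scores, and each tool's false-positive count among the discordant and
    overall. Requires identical variant keys in both score sets.
    """
    a = pd.Series(scores_a, dtype=float)
    b = pd.Series(scores_b, dtype=float)
    y = pd.Series(labels).astype(bool)
    if not (a.index.sort_values().equals(b.index.sort_values())):
        raise ValueError("score sets have mismatched variant keys")
    b = b.reindex(a.index)
    y = y.reindex(a.index)
    if y.isna().any():
        raise ValueError("labels missing for some variants")
    calls_a = a >= threshold_a
    calls_b = b >= threshold_b
    agree = calls_a == calls_b
    discordant = [
        {"key": k, "score_a": float(a[k]), "score_b": float(b[k]),
         "call_a": bool(calls_a[k]), "call_b": bool(calls_b[k]), "label": bool(y[k])}
        for k in a.index[~agree]
    ]
    return {
        "concordant_fraction": float(agree.mean()),
        "n": int(len(a)),
        "discordant": discordant,
        "false_positives_a": int((calls_a & ~y).sum()),
        "false_positives_b": int((calls_b & ~y).sum()),
    }
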