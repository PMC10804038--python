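"""Evaluation protocol: Likert mapping, metric battery, uncertainty analyses.

Likert grades are binarised as 1-2 good / 3-5 poor.  POOR quality is the
positive class throughout: detecting unusable images is the operational
target, so precision/recall/F1 refer to poor-quality detection.  Per
category we report accuracy, precision, recall, F1, AUC-ROC and AUC-PRC,
plus an unweighted cross-category average row.

The uncertainty analyses compare the Monte-Carlo variance of correct
versus incorrect predictions, trace accuracy while excluding the most
uncertain images (a selective-prediction curve), and correlate the
uncertainty with the extremity of the probability (|p - 0.5|): confident
predictions near 0 or 1 should carry low uncertainty, yielding a negative
correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    roc_auc_score,
)

from .categories import GOOD, POOR, categories_for

#: marker for metrics that are undefined on the given data (e.g. no
#: positive examples); deliberately not 0
NOT_AVAILABLE = float("nan")


def map_likert_to_binary(likert: int) -> str:
    """Binarise a Likert grade: 1-2 good image quality, 3-5 poor."""
    if likert not in (1, 2, 3, 4, 5):
        raise ValueError(f"Likert grade must be an integer in 1..5, got {likert!r}")
    return GOOD if likert <= 2 else POOR


def _as_binary(values) -> np.ndarray:
    """Coerce good/poor strings, bools or 0/1 ints to a 0/1 int array."""
    arr = np.asarray(values)
    if arr.dtype.kind in "USO":
        return np.asarray([1 if v == POOR else 0 for v in arr])
    return arr.astype(int)


# ---------------------------------------------------------------------------
# metric battery
# ---------------------------------------------------------------------------


@dataclass
class CategoryMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc_roc: float
    auc_prc: float
    n: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc_roc": self.auc_roc,
            "auc_prc": self.auc_prc,
            "n": self.n,
        }


def compute_metrics(y_true, y_pred, probabilities=None) -> CategoryMetrics:
    """Contingency metrics plus ranking AUCs for one category.

    Poor is the positive class.  With no positive ground-truth examples
    the precision/recall/F1 and AUCs are undefined and reported as NaN
    (never as 0); accuracy is always defined.
    """
    y = _as_binary(y_true)
    pred = _as_binary(y_pred)
    if len(y) != len(pred) or len(y) < 2:
        raise ValueError("need >= 2 samples with matching lengths")
    acc = accuracy_score(y, pred)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    has_pos = y.sum() > 0
    has_neg = y.sum() < len(y)
    precision = tp / (tp + fp) if (tp + fp) > 0 and has_pos else NOT_AVAILABLE
    recall = tp / (tp + fn) if has_pos else NOT_AVAILABLE
    if math.isfinite(precision) and math.isfinite(recall) and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    elif has_pos and (tp + fp) > 0:
        f1 = 0.0
    else:
        f1 = NOT_AVAILABLE
    if probabilities is not None and has_pos and has_neg:
        p = np.asarray(probabilities, dtype=float)
        auc_roc = float(roc_auc_score(y, p))
        auc_prc = float(average_precision_score(y, p))  # step-wise integral
    else:
        auc_roc = NOT_AVAILABLE
        auc_prc = NOT_AVAILABLE
    return CategoryMetrics(float(acc), precision, recall, f1, auc_roc, auc_prc, len(y))


@dataclass
class MetricsReport:
    """Per-category metrics plus the unweighted cross-category average."""

    per_category: dict[str, CategoryMetrics] = field(default_factory=dict)

    @property
    def average(self) -> dict:
        keys = ("accuracy", "precision", "recall", "f1", "auc_roc", "auc_prc")
        rows = [m.as_dict() for m in self.per_category.values()]
        with np.errstate(invalid="ignore"):
            return {k: float(np.nanmean([r[k] for r in rows])) for k in keys}

    def as_frame(self) -> pd.DataFrame:
        rows = {cat: m.as_dict() for cat, m in self.per_category.items()}
        rows["average"] = {**self.average, "n": sum(m.n for m in self.per_category.values())}
        return pd.DataFrame(rows).T

    def as_dict(self) -> dict:
        return {
            "per_category": {c: m.as_dict() for c, m in self.per_category.items()},
            "average": self.average,
        }


def evaluate_predictions(predictions: pd.DataFrame, modality: str) -> MetricsReport:
    """Metric battery from a prediction frame that still carries Likert labels."""
    report = MetricsReport()
    for cat in categories_for(modality):
        col = predictions[f"likert_{cat}"]
        sel = col.notna().to_numpy()
        if sel.sum() < 2:
            continue
        y_true = (col[sel].to_numpy(dtype=float) >= 3).astype(int)
        y_pred = predictions.loc[sel, f"decision_{cat}"]
        probs = predictions.loc[sel, f"p_{cat}"].to_numpy(dtype=float)
        report.per_category[cat] = compute_metrics(y_true, y_pred, probs)
    return report


# ---------------------------------------------------------------------------
# uncertainty analyses
# ---------------------------------------------------------------------------


def _correct_pairs(predictions: pd.DataFrame, modality: str):
    """Pooled (image, category) correctness, uncertainty and label mask."""
    cats = categories_for(modality)
    correct, unc, mask = [], [], []
    for cat in cats:
        col = predictions[f"likert_{cat}"]
        present = col.notna().to_numpy()
        y_true = (col.fillna(1).to_numpy(dtype=float) >= 3).astype(int)
        y_pred = _as_binary(predictions[f"decision_{cat}"])
        correct.append(y_true == y_pred)
        unc.append(predictions[f"u_{cat}"].to_numpy(dtype=float))
        mask.append(present)
    return np.stack(correct, 1), np.stack(unc, 1), np.stack(mask, 1)


def uncertainty_error_summary(predictions: pd.DataFrame, modality: str) -> dict:
    """Mean/median uncertainty of correct vs incorrect predictions.

    Pools all labelled (image, category) pairs across categories.  An
    empty side is reported as NaN.
    """
    correct, unc, mask = _correct_pairs(predictions, modality)
    flat_c = correct[mask]
    flat_u = unc[mask]
    right = flat_u[flat_c]
    wrong = flat_u[~flat_c]

    def _summ(v):
        if len(v) == 0:
            return {"mean": NOT_AVAILABLE, "median": NOT_AVAILABLE, "n": 0}
        return {"mean": float(np.mean(v)), "median": float(np.median(v)), "n": int(len(v))}

    return {"correct": _summ(right), "incorrect": _summ(wrong)}


def image_uncertainty(predictions: pd.DataFrame, modality: str) -> np.ndarray:
    """Scalar per-image uncertainty: mean of the per-category variances."""
    cats = categories_for(modality)
    u = np.stack([predictions[f"u_{c}"].to_numpy(dtype=float) for c in cats], axis=1)
    return u.mean(axis=1)


def exclusion_curve(
    predictions: pd.DataFrame,
    modality: str,
    fractions=(0.1, 0.2, 0.3),
    scalar_uncertainty: np.ndarray | None = None,
) -> dict[float, float]:
    """Total accuracy after excluding the most-uncertain fraction of images.

    For each fraction q the ceil(q*n) images with the largest scalar
    uncertainty are removed (ties resolved stably by manifest order) and
    the pooled accuracy over all labelled (image, category) pairs of the
    remainder is recomputed.  Fraction 0 reproduces the baseline.
    """
    fractions = sorted(fractions)
    if any(q < 0 or q >= 1 for q in fractions):
        raise ValueError("exclusion fractions must lie in [0, 1)")
    correct, _, mask = _correct_pairs(predictions, modality)
    u = (
        scalar_uncertainty
        if scalar_uncertainty is not None
        else image_uncertainty(predictions, modality)
    )
    n = len(predictions)
    # most-uncertain first; stable in the original row order on ties
    order = np.lexsort((np.arange(n), -u))
    out = {}
    for q in fractions:
        k = math.ceil(q * n)
        keep = np.ones(n, dtype=bool)
        keep[order[:k]] = False
        m = mask & keep[:, None]
        out[q] = float(correct[m].mean()) if m.any() else NOT_AVAILABLE
    return out


def uncertainty_probability_correlation(p_hat, u) -> float:
    """Pearson r between uncertainty and probability extremity |p - 0.5|.

    Confident predictions near 0 or 1 carry low Monte-Carlo variance, so a
    well-behaved model yields a clearly negative r.  Returns NaN when
    either series has zero variance or fewer than 3 points are given.
    """
    p = np.asarray(p_hat, dtype=float)
    v = np.asarray(u, dtype=float)
    if len(p) < 3:
        raise ValueError("need at least 3 points")
    extremity = np.abs(p - 0.5)
    if np.ptp(extremity) == 0 or np.ptp(v) == 0:
        return NOT_AVAILABLE
    return float(stats.pearsonr(v, extremity).statistic)


# ---------------------------------------------------------------------------
# McNemar's test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class McNemarResult:
    statistic: float | None  # chi-square statistic; None on the exact branch
    p_value: float
    b: int  # A correct, B incorrect
    c: int  # A incorrect, B correct
    method: str  # "chi2", "exact" or "degenerate"
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def mcnemar_test(decisions_a, decisions_b, y_true, alpha: float = 0.05) -> McNemarResult:
    """Paired comparison of two classifiers on the same samples.

    Counts the discordant pairs (b: only A correct, c: only B correct) and
    tests b = c.  With b + c >= 25 the chi-square statistic
    (b - c)^2 / (b + c) with 1 df is used (no continuity correction);
    otherwise the exact two-sided binomial p-value
    min(1, 2 * P[Bin(b+c, 1/2) <= min(b, c)]).  b + c = 0 is degenerate
    and reported as p = 1.
    """
    a = _as_binary(decisions_a)
    bb = _as_binary(decisions_b)
    y = _as_binary(y_true)
    if not (len(a) == len(bb) == len(y)):
        raise ValueError("decision and label vectors must share a length")
    a_ok = a == y
    b_ok = bb == y
    b = int((a_ok & ~b_ok).sum())
    c = int((~a_ok & b_ok).sum())
    n_disc = b + c
    if n_disc == 0:
        return McNemarResult(None, 1.0, b, c, "degenerate", alpha)
    if n_disc >= 25:
        stat = (b - c) ** 2 / n_disc
        p = float(stats.chi2.sf(stat, df=1))
        return McNemarResult(float(stat), p, b, c, "chi2", alpha)
    p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n_disc, 0.5)))
    return McNemarResult(None, p, b, c, "exact", alpha)
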