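"""Monte-Carlo-Dropout inference and visit-level aggregation.

Prediction runs ``T`` stochastic forward passes with the dropout layers
kept active (default T=16); the mean of the per-pass probabilities is the
final probability of poor quality and their population variance is the
uncertainty score.  The uncertainty says how much the probability can be
trusted — it is not itself a probability of poor quality.

A visit (all images of one eye at one appointment) is scored by averaging
the binary overall-quality decisions of its images, giving a poor-image
fraction in [0, 1] that is thresholded into a visit decision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .categories import GOOD, POOR

DEFAULT_T = 16
DEFAULT_TAU = 0.5
DEFAULT_VISIT_THRESHOLD = 0.5


@dataclass(frozen=True)
class PredictionResult:
    """Per-category MC-Dropout prediction for one image."""

    probability: dict[str, float]  # mean over T passes, probability of poor
    uncertainty: dict[str, float]  # variance over the passes
    decision: dict[str, str]
    tau: float
    T: int


def mc_predict(
    network,
    images: np.ndarray,
    T: int = DEFAULT_T,
    seed: int = 0,
    batch_size: int = 64,
    return_passes: bool = False,
):
    """Probabilities and uncertainties from ``T`` stochastic forward passes.

    Parameters
    ----------
    images : ndarray, shape (N, C, H, W)
    T : int
        Number of passes with dropout active.  With ``T=1`` or a dropout
        rate of 0 the uncertainty is exactly 0.
    seed : int
        Seeds the dropout masks; fixed weights + seed give bit-identical
        results.  Masks are resampled independently on every pass.

    Returns
    -------
    (p_hat, u) or (p_hat, u, passes)
        ``p_hat`` is the per-category mean probability of poor quality,
        ``u`` the population variance over the passes (shape ``(N, K)``;
        ``passes`` has shape ``(T, N, K)``).
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    rng = np.random.default_rng(seed)

    def _one_pass(mode):
        chunks = []
        for i in range(0, len(images), batch_size):
            chunks.append(expit(network.forward(images[i : i + batch_size], mode, rng)))
        return np.concatenate(chunks)

    if network.dropout_rate == 0:
        # every pass is the deterministic forward pass: u is exactly 0
        single = _one_pass("eval")
        passes = np.broadcast_to(single, (T,) + single.shape).copy()
        p_hat = single
        u = np.zeros_like(single)
    else:
        passes = np.stack([_one_pass("mc") for _ in range(T)])
        p_hat = passes.mean(axis=0)
        u = passes.var(axis=0)  # population variance: T=1 stays defined (u=0)
    if return_passes:
        return p_hat, u, passes
    return p_hat, u


def predict_image(network, image: np.ndarray, categories,
                  T: int = DEFAULT_T, seed: int = 0,
                  tau: float = DEFAULT_TAU) -> PredictionResult:
    """Single-image convenience wrapper around :func:`mc_predict`."""
    p, u = mc_predict(network, image[None] if image.ndim == 3 else image, T=T, seed=seed)
    return PredictionResult(
        probability={c: float(p[0, j]) for j, c in enumerate(categories)},
        uncertainty={c: float(u[0, j]) for j, c in enumerate(categories)},
        decision={c: decide(float(p[0, j]), tau) for j, c in enumerate(categories)},
        tau=tau,
        T=T,
    )


def decide(p_hat: float, tau: float = DEFAULT_TAU) -> str:
    """Binary decision: poor iff the probability reaches the threshold."""
    if not (0.0 < tau < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {tau}")
    if not (0.0 <= p_hat <= 1.0):
        raise ValueError(f"probability must be in [0, 1], got {p_hat}")
    return POOR if p_hat >= tau else GOOD


#: spec-facing alias: binarize a probability at a threshold
binarize = decide


def select_threshold(probabilities, labels) -> float:
    """Threshold maximising F1 for the poor class on held-out scores.

    Candidates are the midpoints between adjacent sorted unique
    probabilities plus 0.5; ties in F1 are broken toward 0.5 (and toward
    the smaller threshold if still tied).  ``labels`` may be 0/1 or
    good/poor strings; both classes must be present.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray([1 if lab in (1, POOR, True) else 0 for lab in np.asarray(labels).ravel()])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to select a threshold")
    uniq = np.unique(p)
    candidates = list((uniq[:-1] + uniq[1:]) / 2.0) + [0.5]
    candidates = sorted(set(c for c in candidates if 0.0 < c < 1.0))

    def f1_at(tau: float) -> float:
        pred = (p >= tau).astype(int)
        tp = int(((pred == 1) & (y == 1)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        if 2 * tp + fp + fn == 0:
            return 0.0
        return 2 * tp / (2 * tp + fp + fn)

    return min(candidates, key=lambda c: (-f1_at(c), abs(c - 0.5), c))


@dataclass(frozen=True)
class VisitPrediction:
    visit_id: str
    score: float  # fraction of images judged poor
    decision: str
    n_images: int


def predict_visit(
    decisions,
    visit_id: str = "",
    threshold: float = DEFAULT_VISIT_THRESHOLD,
) -> VisitPrediction:
    """Aggregate a visit's overall-quality decisions into a visit score.

    The score is the mean of the binary image decisions (good=0, poor=1);
    the visit is judged poor when the score reaches the threshold, so a
    tie counts as poor (conservative toward re-acquisition).
    """
    decisions = list(decisions)
    if not decisions:
        raise ValueError("a visit must contain at least one image")
    coded = [1 if d in (1, POOR, True) else 0 for d in decisions]
    score = float(np.mean(coded))
    return VisitPrediction(
        visit_id=visit_id,
        score=score,
        decision=POOR if score >= threshold else GOOD,
        n_images=len(coded),
    )


def predict_visits(
    predictions: pd.DataFrame, threshold: float = DEFAULT_VISIT_THRESHOLD
) -> list[VisitPrediction]:
    """Visit predictions for a prediction frame carrying ``decision_overall``."""
    out = []
    for visit_id, group in predictions.groupby("visit_id", sort=True):
        out.append(predict_visit(group["decision_overall"], str(visit_id), threshold))
    return out


# ---------------------------------------------------------------------------
# JSON round-trip for prediction artefacts
# ---------------------------------------------------------------------------


def predictions_to_json(predictions: pd.DataFrame, categories, path: str | Path) -> None:
    """One record per image: per-category {p, u, decision} plus T and tau."""
    records = []
    for _, row in predictions.iterrows():
        rec = {
            "image_path": row["image_path"],
            "visit_id": row["visit_id"],
            "patient_id": row["patient_id"],
            "categories": {
                cat: {
                    "p": float(row[f"p_{cat}"]),
                    "u": float(row[f"u_{cat}"]),
                    "decision": row[f"decision_{cat}"],
                }
                for cat in categories
            },
            "T": int(predictions.attrs.get("T", DEFAULT_T)),
            "tau": float(predictions.attrs.get("tau", DEFAULT_TAU)),
        }
        records.append(rec)
    Path(path).write_text(json.dumps(records, indent=1, sort_keys=True) + "\n")


def predictions_from_json(path: str | Path) -> pd.DataFrame:
    records = json.loads(Path(path).read_text())
    rows = []
    for rec in records:
        row = {
            "image_path": rec["image_path"],
            "visit_id": rec["visit_id"],
            "patient_id": rec["patient_id"],
        }
        for cat, vals in rec["categories"].items():
            row[f"p_{cat}"] = vals["p"]
            row[f"u_{cat}"] = vals["u"]
            row[f"decision_{cat}"] = vals["decision"]
        rows.append(row)
    frame = pd.DataFrame(rows)
    if records:
        frame.attrs["T"] = records[0]["T"]
        frame.attrs["tau"] = records[0]["tau"]
    return frame


def visits_to_json(visits: list[VisitPrediction], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            [
                {
                    "visit_id": v.visit_id,
                    "score": v.score,
                    "decision": v.decision,
                    "n_images": v.n_images,
                }
                for v in visits
            ],
            indent=1,
            sort_keys=True,
        )
        + "\n"
    )
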