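"""Likelihood scoring of candidate pairs, argmax selection, accuracy and ROC.

The combined score of a candidate pair is the product of the Gaussian density
of its warp-corrected time shift and the Gamma density of 1 - AR; the
candidate with the highest likelihood is reported as the corresponding
feature. Single-statistic modes (AT only / AR only) rank candidates by the
corresponding density alone, for diagnostics and baseline comparison.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

from .ground_truth import GroundTruthEntry
from .preprocess import PeakInterval
from .stat_models import (
    ARModel,
    ATModel,
    CorrespondencePair,
    ar_density,
    at_density,
    compute_ar,
    compute_at,
)
from .warp import WarpModel

logger = logging.getLogger(__name__)

SCORE_MODES = ("combined", "at", "ar")


def score_pair(at: float, ar: float, at_model: ATModel, ar_model: ARModel | None) -> float:
    """Combined likelihood density P(AT) * P(AR) of a candidate pair.

    With ``ar_model=None`` (degenerate shape model, e.g. all training shapes
    identical) the AR factor is the constant 1 and the score reduces to the
    time-shift density.
    """
    s = at_density(at_model, at)
    if ar_model is not None:
        s *= ar_density(ar_model, ar)
    return float(s)


def identify_corresponding(
    q1_feature: PeakInterval,
    candidates: Sequence[PeakInterval],
    warp: WarpModel,
    at_model: ATModel,
    ar_model: ARModel | None,
    *,
    mode: str = "combined",
    n_grid: int = 50,
    landmark: str = "apex",
    sequence: str = "",
    charge: int = 0,
    q1_run: str = "",
    q2_run: str = "",
) -> CorrespondencePair | None:
    """Score every candidate and return the maximum-likelihood pair.

    Returns ``None`` when there are no candidates (an unmatched peptide, which
    is distinct from a matched pair with a low score). Ties are broken by the
    smaller absolute time shift, then the earlier apex.
    """
    if mode not in SCORE_MODES:
        raise ValueError(f"unknown scoring mode {mode!r}")
    if not candidates:
        return None
    best = None
    best_key = None
    for cand in candidates:
        at = compute_at(q1_feature, cand, warp, landmark=landmark)
        ar = compute_ar(q1_feature, cand, n_grid=n_grid)
        score = score_pair(at, ar, at_model, ar_model)
        if mode == "at":
            rank = at_density(at_model, at)
        elif mode == "ar":
            rank = ar_density(ar_model, ar) if ar_model is not None else 1.0
        else:
            rank = score
        key = (-rank, abs(at), cand.apex_time)
        if best_key is None or key < best_key:
            best_key = key
            best = (cand, at, ar, score)
    cand, at, ar, score = best
    return CorrespondencePair(
        sequence=sequence,
        charge=charge,
        q1_run=q1_run,
        q2_run=q2_run,
        q1_feature=q1_feature,
        q2_feature=cand,
        at=at,
        ar=ar,
        score=score,
        n_candidates=len(candidates),
    )


def evaluate_accuracy(
    predictions: Sequence[CorrespondencePair | None],
    truth: Sequence[GroundTruthEntry],
) -> float:
    """Fraction of testing peptides whose chosen target-run interval contains
    the ground-truth retention time.

    ``predictions`` is aligned with ``truth`` (one attempt per testing entry);
    an unmatched peptide (``None``) counts as incorrect, keeping the
    denominator equal to the full testing set.
    """
    if len(truth) == 0:
        raise ValueError("empty testing set")
    if len(predictions) != len(truth):
        raise ValueError("one prediction attempt required per testing entry")
    correct = 0
    for pred, entry in zip(predictions, truth):
        if pred is not None and pred.q2_feature.contains(entry.rt_q2):
            correct += 1
    return correct / len(truth)


def roc_table(scores_pos: Iterable[float], scores_neg: Iterable[float]) -> tuple[pd.DataFrame, float]:
    """(FPR, TPR) sweep and trapezoidal AUC for one score statistic."""
    pos = np.asarray(list(scores_pos), dtype=float)
    neg = np.asarray(list(scores_neg), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    if pos.size < 10 or neg.size < 10:
        logger.warning("fewer than 10 scores on one side; ROC curve unreliable")
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    fpr, tpr, thr = _roc_curve(labels, np.concatenate([pos, neg]))
    df = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}).sort_values("fpr", kind="stable")
    return df.reset_index(drop=True), float(_auc(fpr, tpr))


def roc_curves(
    at_corr: Sequence[float],
    ar_corr: Sequence[float],
    at_noncorr: Sequence[float],
    ar_noncorr: Sequence[float],
    at_model: ATModel,
    ar_model: ARModel | None,
) -> dict[str, tuple[pd.DataFrame, float]]:
    """ROC curves of the AT density, the AR density and the combined score.

    Inputs are the raw AT/AR statistics of corresponding and non-corresponding
    training pairs; each statistic is converted to its model density (the
    likelihood-analogue ranking) before the threshold sweep.
    """
    at_c = np.asarray(at_corr, dtype=float)
    at_n = np.asarray(at_noncorr, dtype=float)
    ar_c = np.asarray(ar_corr, dtype=float)
    ar_n = np.asarray(ar_noncorr, dtype=float)
    d_at_c = at_density(at_model, at_c)
    d_at_n = at_density(at_model, at_n)
    if ar_model is not None:
        d_ar_c = ar_density(ar_model, ar_c)
        d_ar_n = ar_density(ar_model, ar_n)
    else:
        d_ar_c = np.ones_like(ar_c)
        d_ar_n = np.ones_like(ar_n)
    out = {
        "at": roc_table(d_at_c, d_at_n),
        "ar": roc_table(d_ar_c, d_ar_n),
        "combined": roc_table(d_at_c * d_ar_c, d_at_n * d_ar_n),
    }
    return out
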