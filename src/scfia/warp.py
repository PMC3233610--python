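"""Ground-truth-based warping: a polynomial map of source-run elution times to
the target run, fitted by least squares on identified time pairs.

This corrects the *mean* inter-run time shift; the residual shifts stay random
and are modelled separately (see :mod:`scfia.stat_models`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import PeakInterval

logger = logging.getLogger(__name__)


@dataclass
class WarpModel:
    """Polynomial warp, coefficients highest degree first (numpy convention)."""

    coefficients: np.ndarray
    degree: int
    domain: tuple[float, float]  # [min, max] of the training source times


def fit_gwarp(t_q1, t_q2, degree: int = 3) -> WarpModel:
    """Least-squares polynomial regressing target-run times on source-run times.

    Falls back to a lower degree when the data cannot support the requested one
    (fewer distinct abscissae, or a rank-deficient design).
    """
    t1 = np.asarray(t_q1, dtype=float)
    t2 = np.asarray(t_q2, dtype=float)
    if t1.size != t2.size or t1.size < 2:
        raise ValueError("need at least 2 time pairs")
    n_distinct = np.unique(t1).size
    eff = min(degree, n_distinct - 1)
    if eff < degree:
        logger.warning("reducing warp degree from %d to %d (%d distinct times)",
                       degree, eff, n_distinct)
    with warnings.catch_warnings():
        warnings.simplefilter("error", np.exceptions.RankWarning)
        while eff > 0:
            try:
                coeffs = np.polyfit(t1, t2, eff)
                break
            except np.exceptions.RankWarning:
                logger.warning("rank-deficient warp fit at degree %d; reducing", eff)
                eff -= 1
        else:
            coeffs = np.polyfit(t1, t2, 0)
            eff = 0
    return WarpModel(coefficients=np.asarray(coeffs, dtype=float), degree=int(eff),
                     domain=(float(t1.min()), float(t1.max())))


def apply_warp(model: WarpModel, t_q1):
    """Evaluate the warp at source-run time(s); extrapolation is permitted."""
    t = np.asarray(t_q1, dtype=float)
    if t.ndim == 0:
        tt = float(t)
        if tt < model.domain[0] or tt > model.domain[1]:
            logger.debug("warp extrapolation at t=%.1f outside %s", tt, model.domain)
        return float(np.polyval(model.coefficients, tt))
    return np.polyval(model.coefficients, t)


def identity_warp(domain: tuple[float, float] = (0.0, 1e9)) -> WarpModel:
    return WarpModel(coefficients=np.array([1.0, 0.0]), degree=1, domain=domain)


def gwarp_nearest_match(
    q1_feature: PeakInterval,
    candidates: list[PeakInterval],
    model: WarpModel,
) -> PeakInterval | None:
    """Warping-only baseline: the candidate whose apex is nearest the mapped
    source-run apex time. Ties go to the earlier apex."""
    if not candidates:
        return None
    mapped = apply_warp(model, q1_feature.apex_time)
    return min(candidates, key=lambda iv: (abs(iv.apex_time - mapped), iv.apex_time))
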