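"""Per-pair statistics and their distributions.

Two statistics describe a candidate feature pair:

* **AT** — the residual elution-time shift after warping correction,
  ``t_q2_apex - warp(t_q1_apex)``; across corresponding pairs AT is modelled
  as Gaussian, ``AT ~ N(mu, sigma^2)``.
* **AR** — the alignment R^2: each peak trace is resampled onto a common
  number of grid points spanning its own interval, and the target-run vector
  is regressed on the source-run vector; R^2 = 1 means identical shapes.
  ``X = 1 - AR`` across corresponding pairs is modelled as
  ``X ~ Gamma(k, theta)`` (shape/scale), whose density is
  ``f(x) = x^(k-1) exp(-x/theta) / (theta^k Gamma(k))``.

The combined likelihood of a pair is the product of the two densities,
``P(y) = P(AT) * P(AR)``; the two statistics are treated as independent
(time shifts come from run-to-run chromatographic variation, peak shape from
the peptide's physicochemistry).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import yaml
from scipy import stats

from .preprocess import PeakInterval
from .warp import WarpModel, apply_warp

logger = logging.getLogger(__name__)


class DegenerateModelError(ValueError):
    """Raised when a sample has no dispersion, making the fitted density degenerate."""


@dataclass
class ATModel:
    """Gaussian model of warp-corrected elution-time shifts (seconds)."""

    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass
class ARModel:
    """Gamma model (shape k, scale theta) of X = 1 - AR."""

    k: float
    theta: float
    x_floor: float = 1e-6

    def __post_init__(self):
        if self.k <= 0 or self.theta <= 0:
            raise ValueError("k and theta must be > 0")
        if not (0 < self.x_floor < 1):
            raise ValueError("x_floor must be in (0, 1)")


@dataclass
class CorrespondencePair:
    """A source-run feature matched to a target-run candidate."""

    sequence: str
    charge: int
    q1_run: str
    q2_run: str
    q1_feature: PeakInterval
    q2_feature: PeakInterval
    at: float
    ar: float
    score: float
    n_candidates: int = 1


def _landmark(feature: PeakInterval, which: str) -> float:
    if which == "apex":
        return feature.apex_time
    if which == "midpoint":
        return 0.5 * (feature.start_time + feature.end_time)
    raise ValueError(f"unknown landmark {which!r}")


def compute_at(
    q1_feature: PeakInterval,
    q2_feature: PeakInterval,
    warp: WarpModel,
    landmark: str = "apex",
) -> float:
    """Warp-corrected elution-time shift of a candidate pair, seconds."""
    t1 = _landmark(q1_feature, landmark)
    t2 = _landmark(q2_feature, landmark)
    return t2 - apply_warp(warp, t1)


def _resample(feature: PeakInterval, n_grid: int) -> np.ndarray:
    grid = np.linspace(feature.start_time, feature.end_time, n_grid)
    return np.interp(grid, feature.times, feature.intensities)


def compute_ar(q1_feature: PeakInterval, q2_feature: PeakInterval, n_grid: int = 50) -> float:
    """Alignment R^2 between two peak traces.

    Each trace is linearly interpolated onto ``n_grid`` points spanning its own
    interval (boundary to boundary, so the comparison sees shape only, not
    position or scale), and the target vector is regressed on the source vector
    with an intercept. Returns R^2 clamped to [0, 1]; a zero-variance target
    trace has no defined R^2 and yields 0.
    """
    if n_grid < 5:
        raise ValueError("n_grid must be >= 5")
    y1 = _resample(q1_feature, n_grid)
    y2 = _resample(q2_feature, n_grid)
    x = y1 - y1.mean()
    y = y2 - y2.mean()
    sxx = float(x @ x)
    syy = float(y @ y)
    if syy <= 0.0:
        logger.warning("zero-variance target trace; AR undefined, returning 0")
        return 0.0
    if sxx <= 0.0:
        return 0.0
    sxy = float(x @ y)
    r2 = (sxy * sxy) / (sxx * syy)
    return float(min(max(r2, 0.0), 1.0))


def fit_at_model(shifts) -> ATModel:
    """Gaussian fit of residual shifts: sample mean and unbiased (n-1) std."""
    a = np.asarray(shifts, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 shifts")
    sigma = float(a.std(ddof=1))
    if sigma == 0.0:
        raise DegenerateModelError("all shifts identical; Gaussian fit degenerate")
    return ATModel(mu=float(a.mean()), sigma=sigma)


def fit_ar_model(ars, x_floor: float = 1e-6) -> ARModel:
    """Maximum-likelihood Gamma fit of X = 1 - AR (clamped below at x_floor)."""
    a = np.asarray(ars, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 AR values")
    x = np.clip(1.0 - a, x_floor, None)
    if np.unique(x).size < 2:
        raise DegenerateModelError("fewer than 2 distinct 1-AR values; Gamma fit degenerate")
    k, _, theta = stats.gamma.fit(x, floc=0.0)
    return ARModel(k=float(k), theta=float(theta), x_floor=x_floor)


def at_density(model: ATModel, at) -> float | np.ndarray:
    """Normal pdf of the residual time shift."""
    at = np.asarray(at, dtype=float)
    z = (at - model.mu) / model.sigma
    out = np.exp(-0.5 * z * z) / (model.sigma * np.sqrt(2.0 * np.pi))
    return float(out) if out.ndim == 0 else out


def ar_density(model: ARModel, ar) -> float | np.ndarray:
    """Gamma pdf evaluated at x = max(1 - AR, x_floor)."""
    x = np.clip(1.0 - np.asarray(ar, dtype=float), model.x_floor, None)
    out = stats.gamma.pdf(x, a=model.k, scale=model.theta)
    return float(out) if out.ndim == 0 else out


@dataclass
class ScfiaModels:
    """The full trained parameter set for one ordered run pair."""

    warp: WarpModel
    at_model: ATModel
    ar_model: ARModel | None  # None => AR factor degenerate/disabled (constant 1)


def save_models(models: ScfiaModels, path) -> None:
    """Serialize trained models to a human-readable YAML file at full precision."""
    doc = {
        "warp": {
            "coefficients": [float(c) for c in models.warp.coefficients],
            "degree": int(models.warp.degree),
            "domain": [float(models.warp.domain[0]), float(models.warp.domain[1])],
        },
        "at_model": {"mu": float(models.at_model.mu), "sigma": float(models.at_model.sigma)},
        "ar_model": None
        if models.ar_model is None
        else {
            "k": float(models.ar_model.k),
            "theta": float(models.ar_model.theta),
            "x_floor": float(models.ar_model.x_floor),
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_models(path) -> ScfiaModels:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    w = doc["warp"]
    ar = doc.get("ar_model")
    return ScfiaModels(
        warp=WarpModel(
            coefficients=np.asarray(w["coefficients"], dtype=float),
            degree=int(w["degree"]),
            domain=(float(w["domain"][0]), float(w["domain"][1])),
        ),
        at_model=ATModel(mu=float(doc["at_model"]["mu"]), sigma=float(doc["at_model"]["sigma"])),
        ar_model=None if ar is None else ARModel(k=float(ar["k"]), theta=float(ar["theta"]),
                                                 x_floor=float(ar["x_floor"])),
    )
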