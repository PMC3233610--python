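"""XIC extraction, background-noise estimation and elution-peak detection.

A peptide feature is represented by a contiguous high-intensity interval of an
extracted-ion chromatogram (XIC). Candidate intervals are the maximal runs of
points above ``median noise level + 3 * noise standard deviation``; in the run
where the peptide carries a Tandem-MS identity the true interval is the one
containing the recorded retention time, while in the other run every detected
interval is a correspondence candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

from .io_formats import RunData

logger = logging.getLogger(__name__)

#: C13 - C12 mass difference in Daltons.
ISOTOPE_SPACING = 1.0033548

# MAD->sigma constant consistent for Gaussian noise when the MAD median is
# taken over the sub-90th-percentile points only: solves 2*Phi(c)-1 = 0.45.
_MAD_SCALE_TRUNC90 = 1.0 / ndtri(0.725)


class FeatureNotFoundError(ValueError):
    """No detected interval matches a peptide's recorded retention time."""

    def __init__(self, message: str, key=None):
        super().__init__(message)
        self.key = key


@dataclass
class XIC:
    """Extracted-ion chromatogram: per-MS1-scan summed intensity in a ppm window."""

    run_id: str
    target_mz: float
    ppm_window: float
    times: np.ndarray
    intensities: np.ndarray


@dataclass
class PeakInterval:
    """A contiguous above-threshold region of an XIC — one candidate feature."""

    start_time: float
    end_time: float
    apex_time: float
    apex_intensity: float
    times: np.ndarray
    intensities: np.ndarray

    def contains(self, t: float) -> bool:
        return self.start_time <= t <= self.end_time


@dataclass
class NoiseEstimate:
    level: float  # median noise level, counts
    sigma: float  # noise standard deviation, counts

    @property
    def threshold(self) -> float:
        """Detection threshold: 3 noise standard deviations above the median level."""
        return self.level + 3.0 * self.sigma


def extract_xic(run: RunData, target_mz: float, ppm_window: float = 10.0) -> XIC:
    """Sum centroid intensities within ``target_mz * (1 +- ppm_window*1e-6)`` per scan."""
    if target_mz <= 0 or ppm_window <= 0:
        raise ValueError("target_mz and ppm_window must be positive")
    half = target_mz * ppm_window * 1e-6
    lo, hi = target_mz - half, target_mz + half
    n = run.n_scans
    times = np.empty(n)
    intensities = np.zeros(n)
    for i, scan in enumerate(run.scans):
        times[i] = scan.time
        a = np.searchsorted(scan.mz, lo, side="left")
        b = np.searchsorted(scan.mz, hi, side="right")
        if b > a:
            intensities[i] = scan.intensity[a:b].sum()
    return XIC(run_id=run.run_id, target_mz=target_mz, ppm_window=ppm_window,
               times=times, intensities=intensities)


def first_isotope_mz(mz_mono: float, charge: int) -> float:
    """m/z of the first (mono+1) isotope peak in the given charge state."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return mz_mono + ISOTOPE_SPACING / charge


def estimate_noise(xic: XIC) -> NoiseEstimate:
    """Robust background-noise estimate of an XIC.

    Level is the median intensity. Sigma is a MAD-type estimate over the
    sub-90th-percentile points (so the elution peaks themselves do not inflate
    it), scaled to be consistent for Gaussian noise under that truncation.
    """
    inten = np.asarray(xic.intensities, dtype=float)
    if inten.size == 0:
        raise ValueError("empty XIC")
    level = float(np.median(inten))
    q90 = np.percentile(inten, 90)
    sub = inten[inten <= q90]
    sigma = float(_MAD_SCALE_TRUNC90 * np.median(np.abs(sub - level)))
    return NoiseEstimate(level=level, sigma=sigma)


def detect_peak_intervals(
    xic: XIC,
    noise: NoiseEstimate,
    max_n: int = 20,
    min_points: int = 3,
) -> list[PeakInterval]:
    """Detect up to ``max_n`` candidate elution-peak intervals of an XIC.

    Maximal runs of consecutive points strictly above the noise threshold
    become intervals; runs shorter than ``min_points`` are discarded; if more
    than ``max_n`` remain, the ``max_n`` with highest apex intensity are kept.
    Returned sorted by start time.
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    thr = noise.threshold
    mask = xic.intensities > thr
    if not mask.any():
        return []
    padded = np.concatenate(([0], mask.astype(np.int8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    starts, ends = edges[0::2], edges[1::2]
    intervals: list[PeakInterval] = []
    for a, b in zip(starts, ends):
        if b - a < min_points:
            continue
        seg_t = xic.times[a:b]
        seg_i = xic.intensities[a:b]
        k = int(np.argmax(seg_i))
        intervals.append(
            PeakInterval(
                start_time=float(seg_t[0]),
                end_time=float(seg_t[-1]),
                apex_time=float(seg_t[k]),
                apex_intensity=float(seg_i[k]),
                times=seg_t.copy(),
                intensities=seg_i.copy(),
            )
        )
    if len(intervals) > max_n:
        intervals = sorted(intervals, key=lambda iv: -iv.apex_intensity)[:max_n]
    return sorted(intervals, key=lambda iv: iv.start_time)


def build_q1_feature(
    intervals: list[PeakInterval],
    rt_sec: float,
    rt_tolerance: float = 60.0,
    key=None,
) -> PeakInterval:
    """Select the detected interval of an identified peptide.

    The interval containing ``rt_sec`` wins; failing that, the interval whose
    apex is nearest to ``rt_sec`` within ``rt_tolerance`` seconds. If neither
    exists the peptide has no usable feature in this run.
    """
    for iv in intervals:
        if iv.contains(rt_sec):
            return iv
    if intervals:
        best = min(intervals, key=lambda iv: abs(iv.apex_time - rt_sec))
        if abs(best.apex_time - rt_sec) <= rt_tolerance:
            return best
    raise FeatureNotFoundError(
        f"no peak interval within {rt_tolerance} s of rt={rt_sec:.1f} s", key=key
    )


def build_q2_candidates(
    xic: XIC,
    noise: NoiseEstimate,
    max_n: int = 20,
    min_points: int = 3,
) -> list[PeakInterval]:
    """All detected intervals of the target-run XIC are correspondence candidates."""
    return detect_peak_intervals(xic, noise, max_n=max_n, min_points=min_points)
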