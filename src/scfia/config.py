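"""Analysis configuration: every tunable of the matching pipeline in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class ScfiaConfig:
    """Pipeline parameters.

    ppm_window          half-width of the XIC mass window, parts per million
    max_candidates      max detected intervals kept per XIC
    min_peak_points     minimum scans per interval (suppresses single-scan spikes)
    rt_tolerance_sec    fallback tolerance when a recorded RT falls outside
                        every detected interval
    detection_trace     which XIC drives detection and shape comparison:
                        'iso1' (first isotope), 'mono', or 'sum'
    prob_threshold      identification-probability cutoff for the ground truth
    train_fraction      top-intensity fraction of the ground truth used for training
    min_training_size   below this common-identification count a run pair is
                        considered untrainable (multi-run propagation skips it)
    warp_degree         polynomial degree of the warping function
    ar_grid_points      resampling grid size for the alignment R^2
    x_floor             lower clamp on 1 - AR before the Gamma fit
    at_landmark         time landmark of a feature: 'apex' or 'midpoint'
    rng_seed            seed for decoy sampling (model fitting is deterministic)
    """

    ppm_window: float = 10.0
    max_candidates: int = 20
    min_peak_points: int = 3
    rt_tolerance_sec: float = 60.0
    detection_trace: str = "iso1"
    prob_threshold: float = 0.95
    train_fraction: float = 0.20
    min_training_size: int = 50
    warp_degree: int = 3
    ar_grid_points: int = 50
    x_floor: float = 1e-6
    at_landmark: str = "apex"
    rng_seed: int = 0

    def __post_init__(self):
        if self.detection_trace not in ("iso1", "mono", "sum"):
            raise ValueError("detection_trace must be 'iso1', 'mono' or 'sum'")
        if self.at_landmark not in ("apex", "midpoint"):
            raise ValueError("at_landmark must be 'apex' or 'midpoint'")
        if not 0 <= self.prob_threshold <= 1:
            raise ValueError("prob_threshold must be in [0, 1]")
        if not 0 < self.train_fraction <= 1:
            raise ValueError("train_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "ScfiaConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        doc.update(overrides)
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
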