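"""Ground-truth list construction from two runs' identification tables.

Peptides identified in both runs above a probability threshold form the ground
truth. The top-intensity fraction trains the statistical models; the rest
evaluates matching accuracy. Non-corresponding (decoy) training pairs are made
by swapping the true target-run interval for a random other interval of the
same XIC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import PeptideID
from .preprocess import PeakInterval

logger = logging.getLogger(__name__)


@dataclass
class GroundTruthEntry:
    sequence: str
    charge: int
    mz_mono: float
    rt_q1: float
    rt_q2: float
    probability: float  # min of the two runs' probabilities
    apex_intensity_q1: float | None = None

    @property
    def key(self) -> tuple[str, int]:
        return (self.sequence, self.charge)


@dataclass
class TrainTestSplit:
    training: list[GroundTruthEntry] = field(default_factory=list)
    testing: list[GroundTruthEntry] = field(default_factory=list)


def dedupe_identifications(ids: list[PeptideID]) -> list[PeptideID]:
    """One identification per (sequence, charge): the highest probability wins,
    probability ties broken by the earlier retention time."""
    best: dict[tuple[str, int], PeptideID] = {}
    for p in ids:
        cur = best.get(p.key)
        if cur is None or (p.probability, -p.rt_sec) > (cur.probability, -cur.rt_sec):
            best[p.key] = p
    return sorted(best.values(), key=lambda p: p.key)


def build_ground_truth(
    ids_q1: list[PeptideID],
    ids_q2: list[PeptideID],
    prob_threshold: float = 0.95,
) -> list[GroundTruthEntry]:
    """Intersect two deduped identification lists above a probability threshold."""
    m2 = {p.key: p for p in ids_q2}
    entries: list[GroundTruthEntry] = []
    for p1 in ids_q1:
        p2 = m2.get(p1.key)
        if p2 is None:
            continue
        if p1.probability < prob_threshold or p2.probability < prob_threshold:
            continue
        entries.append(
            GroundTruthEntry(
                sequence=p1.sequence,
                charge=p1.charge,
                mz_mono=p1.mz_mono,
                rt_q1=p1.rt_sec,
                rt_q2=p2.rt_sec,
                probability=min(p1.probability, p2.probability),
            )
        )
    if not entries:
        logger.warning("empty ground-truth intersection")
    return sorted(entries, key=lambda e: e.key)


def split_train_test(
    entries: list[GroundTruthEntry],
    train_fraction: float = 0.20,
    min_training_size: int = 50,
) -> TrainTestSplit:
    """Top-intensity fraction trains; the remainder tests.

    Training entries are the ``ceil(train_fraction * N)`` with highest Q1 apex
    intensity (higher-intensity features are least corrupted by noise);
    intensity ties are broken lexicographically for determinism.
    """
    if any(e.apex_intensity_q1 is None for e in entries):
        raise ValueError("apex_intensity_q1 must be filled before splitting")
    n = len(entries)
    n_train = math.ceil(train_fraction * n)
    if n_train < min_training_size:
        logger.warning(
            "training set has %d entries; around 200 common identifications "
            "are preferable for stable model estimates", n_train,
        )
    ranked = sorted(entries, key=lambda e: (-e.apex_intensity_q1, e.sequence, e.charge))
    return TrainTestSplit(
        training=sorted(ranked[:n_train], key=lambda e: e.key),
        testing=sorted(ranked[n_train:], key=lambda e: e.key),
    )


def build_noncorresponding_pairs(
    training_items: list[tuple[GroundTruthEntry, PeakInterval, list[PeakInterval], PeakInterval]],
    rng: np.random.Generator,
) -> list[tuple[GroundTruthEntry, PeakInterval, PeakInterval]]:
    """Decoy pairs: replace the true target-run interval with a random other
    interval of the same XIC.

    ``training_items`` carries, per entry: the source-run feature, the
    target-run candidate intervals, and the true target-run interval. Entries
    whose only detected interval is the true one are skipped.
    """
    out = []
    for entry, q1_feature, q2_intervals, q2_true in training_items:
        others = [iv for iv in q2_intervals if iv is not q2_true]
        if not others:
            continue
        decoy = others[rng.integers(len(others))]
        out.append((entry, q1_feature, decoy))
    return out
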