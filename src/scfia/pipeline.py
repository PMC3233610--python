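"""End-to-end pairwise pipeline: features -> ground truth -> models -> matches.

This module glues the pieces together for one ordered run pair (Q1 source,
Q2 target): it caches XICs and detected intervals per run, builds the ground
truth from the two identification tables, fits the warp and the AT/AR models
on the top-intensity training subset, and matches testing (or arbitrary)
peptides by maximum likelihood. The synthetic benchmark driver used by the
diagnostics lives here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import ScfiaConfig
from .ground_truth import (
    GroundTruthEntry,
    TrainTestSplit,
    build_ground_truth,
    build_noncorresponding_pairs,
    dedupe_identifications,
    split_train_test,
)
from .io_formats import PeptideID, RunData
from .preprocess import (
    FeatureNotFoundError,
    NoiseEstimate,
    PeakInterval,
    XIC,
    build_q1_feature,
    detect_peak_intervals,
    estimate_noise,
    extract_xic,
    first_isotope_mz,
)
from .scoring import evaluate_accuracy, identify_corresponding
from .stat_models import (
    ARModel,
    ATModel,
    DegenerateModelError,
    ScfiaModels,
    compute_ar,
    compute_at,
    fit_ar_model,
    fit_at_model,
)
from .warp import fit_gwarp, gwarp_nearest_match

logger = logging.getLogger(__name__)

# sigma substituted when training residuals are numerically identical
# (noiseless simulations); keeps the Gaussian density finite and the argmax
# meaningful without affecting any realistic fit
_SIGMA_FALLBACK = 1e-6


class FeatureIndex:
    """Per-run cache of detection-trace XICs and their detected intervals."""

    def __init__(self, run: RunData, config: ScfiaConfig):
        self.run = run
        self.config = config
        self._cache: dict[tuple[str, int, float], tuple[XIC, NoiseEstimate, list[PeakInterval]]] = {}

    def _detection_xic(self, mz_mono: float, charge: int) -> XIC:
        cfg = self.config
        if cfg.detection_trace == "mono":
            return extract_xic(self.run, mz_mono, cfg.ppm_window)
        iso = extract_xic(self.run, first_isotope_mz(mz_mono, charge), cfg.ppm_window)
        if cfg.detection_trace == "iso1":
            return iso
        mono = extract_xic(self.run, mz_mono, cfg.ppm_window)
        return XIC(run_id=iso.run_id, target_mz=mz_mono, ppm_window=cfg.ppm_window,
                   times=iso.times, intensities=iso.intensities + mono.intensities)

    def intervals(self, sequence: str, charge: int, mz_mono: float):
        """(XIC, noise estimate, candidate intervals) for one peptide channel."""
        key = (sequence, charge, round(mz_mono, 6))
        if key not in self._cache:
            cfg = self.config
            xic = self._detection_xic(mz_mono, charge)
            noise = estimate_noise(xic)
            ivs = detect_peak_intervals(xic, noise, max_n=cfg.max_candidates,
                                        min_points=cfg.min_peak_points)
            self._cache[key] = (xic, noise, ivs)
        return self._cache[key]


@dataclass
class EntryFeatures:
    """Resolved features of one ground-truth entry."""

    entry: GroundTruthEntry
    q1_feature: PeakInterval
    q2_candidates: list[PeakInterval]
    q2_true: PeakInterval | None  # interval containing rt_q2, when locatable


@dataclass
class PreparedPair:
    """Ground truth of an ordered run pair with features resolved."""

    q1_id: str
    q2_id: str
    idx_q1: FeatureIndex
    idx_q2: FeatureIndex
    features: list[EntryFeatures]
    excluded: list[GroundTruthEntry] = field(default_factory=list)

    @property
    def entries(self) -> list[GroundTruthEntry]:
        return [f.entry for f in self.features]


@dataclass
class TrainedPair:
    """Everything fitted on the training subset of one ordered pair."""

    models: ScfiaModels
    split: TrainTestSplit
    at_corr: np.ndarray
    ar_corr: np.ndarray
    at_noncorr: np.ndarray
    ar_noncorr: np.ndarray
    ar_degenerate: bool = False


def prepare_pair(
    idx_q1: FeatureIndex,
    idx_q2: FeatureIndex,
    ids_q1: list[PeptideID],
    ids_q2: list[PeptideID],
    config: ScfiaConfig,
) -> PreparedPair:
    """Build the ground truth of a run pair and resolve its features.

    Entries whose source-run feature cannot be located within the RT tolerance
    are excluded from training and testing (logged); entries with no target-run
    candidates stay (they count as unmatched at evaluation).
    """
    gt = build_ground_truth(
        dedupe_identifications(ids_q1),
        dedupe_identifications(ids_q2),
        prob_threshold=config.prob_threshold,
    )
    features: list[EntryFeatures] = []
    excluded: list[GroundTruthEntry] = []
    for entry in gt:
        _, _, ivs1 = idx_q1.intervals(entry.sequence, entry.charge, entry.mz_mono)
        try:
            q1f = build_q1_feature(ivs1, entry.rt_q1, config.rt_tolerance_sec, key=entry.key)
        except FeatureNotFoundError:
            logger.warning("excluding %s/%d: no source-run feature near rt=%.0f s",
                           entry.sequence, entry.charge, entry.rt_q1)
            excluded.append(entry)
            continue
        entry.apex_intensity_q1 = q1f.apex_intensity
        _, _, ivs2 = idx_q2.intervals(entry.sequence, entry.charge, entry.mz_mono)
        q2_true = next((iv for iv in ivs2 if iv.contains(entry.rt_q2)), None)
        features.append(EntryFeatures(entry=entry, q1_feature=q1f,
                                      q2_candidates=list(ivs2), q2_true=q2_true))
    return PreparedPair(q1_id=idx_q1.run.run_id, q2_id=idx_q2.run.run_id,
                        idx_q1=idx_q1, idx_q2=idx_q2, features=features, excluded=excluded)


def train_pair(
    prepared: PreparedPair,
    config: ScfiaConfig,
    rng: np.random.Generator | None = None,
    train_fraction: float | None = None,
) -> TrainedPair:
    """Fit warp + AT + AR models on the training subset of a prepared pair.

    Degenerate fits (zero-variance residuals or all-identical shapes, which
    arise in noiseless simulations) fall back to a tiny-sigma Gaussian and a
    disabled (constant) AR factor respectively; both are logged.
    """
    rng = rng or np.random.default_rng(config.rng_seed)
    frac = config.train_fraction if train_fraction is None else train_fraction
    split = split_train_test([f.entry for f in prepared.features], frac,
                             min_training_size=config.min_training_size)
    by_key = {f.entry.key: f for f in prepared.features}
    trainable = [by_key[e.key] for e in split.training
                 if by_key[e.key].q2_true is not None]
    if len(trainable) < len(split.training):
        logger.warning("%d training entries lack a locatable target-run true interval",
                       len(split.training) - len(trainable))
    if len(trainable) < 2:
        raise ValueError("fewer than 2 trainable ground-truth entries")

    t1 = [f.q1_feature.apex_time for f in trainable]
    t2 = [f.q2_true.apex_time for f in trainable]
    warp = fit_gwarp(t1, t2, degree=config.warp_degree)

    at_corr = np.array([
        compute_at(f.q1_feature, f.q2_true, warp, landmark=config.at_landmark)
        for f in trainable
    ])
    ar_corr = np.array([
        compute_ar(f.q1_feature, f.q2_true, n_grid=config.ar_grid_points)
        for f in trainable
    ])
    try:
        at_model = fit_at_model(at_corr)
    except DegenerateModelError:
        logger.warning("degenerate AT residuals; substituting sigma=%g s", _SIGMA_FALLBACK)
        at_model = ATModel(mu=float(np.mean(at_corr)), sigma=_SIGMA_FALLBACK)
    ar_degenerate = False
    try:
        ar_model: ARModel | None = fit_ar_model(ar_corr, x_floor=config.x_floor)
    except DegenerateModelError:
        logger.warning("degenerate AR sample (all shapes identical); AR factor disabled")
        ar_model = None
        ar_degenerate = True

    decoys = build_noncorresponding_pairs(
        [(f.entry, f.q1_feature, f.q2_candidates, f.q2_true) for f in trainable], rng
    )
    at_non = np.array([
        compute_at(q1f, d, warp, landmark=config.at_landmark) for _, q1f, d in decoys
    ])
    ar_non = np.array([
        compute_ar(q1f, d, n_grid=config.ar_grid_points) for _, q1f, d in decoys
    ])
    return TrainedPair(
        models=ScfiaModels(warp=warp, at_model=at_model, ar_model=ar_model),
        split=split,
        at_corr=at_corr,
        ar_corr=ar_corr,
        at_noncorr=at_non,
        ar_noncorr=ar_non,
        ar_degenerate=ar_degenerate,
    )


def match_entries(
    prepared: PreparedPair,
    models: ScfiaModels,
    entries: list[GroundTruthEntry],
    config: ScfiaConfig,
    mode: str = "combined",
):
    """One maximum-likelihood prediction attempt per entry (None = unmatched)."""
    by_key = {f.entry.key: f for f in prepared.features}
    preds = []
    for entry in entries:
        f = by_key[entry.key]
        preds.append(
            identify_corresponding(
                f.q1_feature, f.q2_candidates, models.warp, models.at_model,
                models.ar_model, mode=mode, n_grid=config.ar_grid_points,
                landmark=config.at_landmark, sequence=entry.sequence,
                charge=entry.charge, q1_run=prepared.q1_id, q2_run=prepared.q2_id,
            )
        )
    return preds


def match_nearest(prepared: PreparedPair, models: ScfiaModels,
                  entries: list[GroundTruthEntry]):
    """Warping-only baseline predictions (nearest candidate to the mapped time)."""
    from .stat_models import CorrespondencePair

    by_key = {f.entry.key: f for f in prepared.features}
    preds = []
    for entry in entries:
        f = by_key[entry.key]
        cand = gwarp_nearest_match(f.q1_feature, f.q2_candidates, models.warp)
        if cand is None:
            preds.append(None)
            continue
        at = compute_at(f.q1_feature, cand, models.warp)
        preds.append(CorrespondencePair(
            sequence=entry.sequence, charge=entry.charge, q1_run=prepared.q1_id,
            q2_run=prepared.q2_id, q1_feature=f.q1_feature, q2_feature=cand,
            at=at, ar=float("nan"), score=float("nan"),
            n_candidates=len(f.q2_candidates)))
    return preds


@dataclass
class ExperimentResult:
    """Outcome of one simulated pairwise benchmark."""

    accuracies: dict[str, float]  # mode -> accuracy on the testing set
    trained: TrainedPair
    prepared: PreparedPair
    n_testing: int
    mean_candidates: float
    predictions: dict[str, list]


def run_pairwise_experiment(
    sim_cfg,
    config: ScfiaConfig,
    modes: tuple[str, ...] = ("combined", "at", "gwarp"),
) -> ExperimentResult:
    """Simulate a two-run experiment and evaluate matching accuracy per mode.

    Modes are the likelihood variants plus ``'gwarp'``, the warping-only
    nearest-feature baseline. Accuracy follows the ground-truth convention: a
    prediction is correct iff its chosen interval contains the recorded
    target-run retention time.
    """
    from .synthetic import generate_runs

    runs, truth = generate_runs(sim_cfg)
    if len(runs) < 2:
        raise ValueError("need at least two runs")
    idx1 = FeatureIndex(runs[0], config)
    idx2 = FeatureIndex(runs[1], config)
    prepared = prepare_pair(idx1, idx2, truth.id_tables[runs[0].run_id],
                            truth.id_tables[runs[1].run_id], config)
    rng = np.random.default_rng(config.rng_seed)
    trained = train_pair(prepared, config, rng=rng)
    testing = trained.split.testing
    accuracies: dict[str, float] = {}
    predictions: dict[str, list] = {}
    n_cands = []
    for mode in modes:
        if mode == "gwarp":
            preds = match_nearest(prepared, trained.models, testing)
        else:
            preds = match_entries(prepared, trained.models, testing, config, mode=mode)
        accuracies[mode] = evaluate_accuracy(preds, testing)
        predictions[mode] = preds
    by_key = {f.entry.key: f for f in prepared.features}
    for e in testing:
        n_cands.append(len(by_key[e.key].q2_candidates))
    return ExperimentResult(
        accuracies=accuracies,
        trained=trained,
        prepared=prepared,
        n_testing=len(testing),
        mean_candidates=float(np.mean(n_cands)) if n_cands else 0.0,
        predictions=predictions,
    )
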