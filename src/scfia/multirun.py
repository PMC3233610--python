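"""Complete identification across three or more runs.

A peptide identified by Tandem MS in at least one run can have its elution
interval located in every other run by pairwise likelihood matching; when an
interval exists in every run the peptide is *completely identified* and can be
quantified everywhere. Because the per-run identified sets overlap little,
propagation grows the completely-quantifiable set from the small intersection
toward the much larger union.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .config import ScfiaConfig
from .io_formats import PeptideID, RunData
from .ground_truth import dedupe_identifications
from .pipeline import FeatureIndex, prepare_pair, train_pair
from .preprocess import FeatureNotFoundError, build_q1_feature
from .scoring import identify_corresponding
from .stat_models import CorrespondencePair

logger = logging.getLogger(__name__)


@dataclass
class CoverageReport:
    """Union/intersection accounting of a multi-run propagation.

    Two denominators are reported for the coverage fraction: the
    union-minus-intersection count (peptides that were not already complete
    from Tandem MS alone) and the full union.
    """

    per_run_identified: dict[str, int]
    union_size: int
    intersection_size: int
    completely_identified: int  # analyzed peptides that gained intervals in all runs
    partially_identified: int  # analyzed peptides with intervals in >=2 but not all runs
    analyzed: int  # union - intersection
    coverage_analyzed: float
    coverage_union: float
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_run_identified": self.per_run_identified,
            "union_size": self.union_size,
            "intersection_size": self.intersection_size,
            "completely_identified": self.completely_identified,
            "partially_identified": self.partially_identified,
            "analyzed": self.analyzed,
            "coverage_analyzed": self.coverage_analyzed,
            "coverage_union": self.coverage_union,
            "skipped_pairs": [list(p) for p in self.skipped_pairs],
        }


def venn_counts(id_tables: dict[str, list[PeptideID]]) -> dict:
    """Set cardinalities of per-run identified (sequence, charge) keys."""
    keysets = {rid: {p.key for p in ids} for rid, ids in id_tables.items()}
    rids = list(keysets)
    union = set().union(*keysets.values()) if keysets else set()
    inter = set.intersection(*keysets.values()) if keysets else set()
    pairwise = {
        (a, b): len(keysets[a] & keysets[b])
        for a, b in itertools.combinations(rids, 2)
    }
    return {
        "per_run": {rid: len(s) for rid, s in keysets.items()},
        "union": len(union),
        "intersection": len(inter),
        "pairwise": pairwise,
    }


def complete_identification(
    runs: list[RunData],
    id_tables: list[list[PeptideID]],
    config: ScfiaConfig,
) -> tuple[list[CorrespondencePair], CoverageReport]:
    """Propagate identities until every union peptide is located everywhere possible.

    For every (peptide, run) lacking a Tandem-MS identity, matching is
    attempted from a run where the peptide's interval is known, preferring
    sources with the highest identification probability (native identities
    before propagated ones, conflicts resolved by that same order and logged).
    Pairwise models are trained once per unordered run pair on all of the
    pair's common identifications; pairs with fewer common identifications
    than ``config.min_training_size`` are skipped and their peptides may stay
    partial.
    """
    if len(runs) < 2 or len(runs) != len(id_tables):
        raise ValueError("need >= 2 runs with one identification table each")
    rids = [r.run_id for r in runs]
    deduped = {
        rid: [p for p in dedupe_identifications(ids) if p.probability >= config.prob_threshold]
        for rid, ids in zip(rids, id_tables)
    }
    venn = venn_counts(deduped)
    indices = {r.run_id: FeatureIndex(r, config) for r in runs}

    # train pairwise models on each unordered pair's shared identifications
    pair_models: dict[tuple[str, str], tuple] = {}  # ordered (src, dst) -> (prepared, trained)
    skipped: list[tuple[str, str]] = []
    rng = np.random.default_rng(config.rng_seed)
    for a, b in itertools.combinations(rids, 2):
        common = {p.key for p in deduped[a]} & {p.key for p in deduped[b]}
        if len(common) < config.min_training_size:
            logger.warning("pair (%s, %s): only %d common identifications; skipping",
                           a, b, len(common))
            skipped.append((a, b))
            continue
        for src, dst in ((a, b), (b, a)):
            prepared = prepare_pair(indices[src], indices[dst],
                                    deduped[src], deduped[dst], config)
            trained = train_pair(prepared, config, rng=rng, train_fraction=1.0)
            pair_models[(src, dst)] = (prepared, trained)

    # located[key][rid] = (interval, source_tag, preference)
    id_by_run = {rid: {p.key: p for p in deduped[rid]} for rid in rids}
    union_keys = sorted(set().union(*({p.key for p in deduped[rid]} for rid in rids)))
    meta = {}
    for rid in rids:
        for p in deduped[rid]:
            meta[p.key] = p
    located: dict[tuple, dict[str, object]] = {k: {} for k in union_keys}
    for key in union_keys:
        for rid in rids:
            pid = id_by_run[rid].get(key)
            if pid is None:
                continue
            _, _, ivs = indices[rid].intervals(pid.sequence, pid.charge, pid.mz_mono)
            try:
                feat = build_q1_feature(ivs, pid.rt_sec, config.rt_tolerance_sec, key=key)
            except FeatureNotFoundError:
                logger.warning("%s/%d: identity in %s has no locatable feature",
                               key[0], key[1], rid)
                continue
            located[key][rid] = (feat, "native", pid.probability)

    correspondences: list[CorrespondencePair] = []
    changed = True
    while changed:
        changed = False
        for key in union_keys:
            pep = meta[key]
            have = located[key]
            for rid in rids:
                if rid in have:
                    continue
                # source preference: native identities by probability, then
                # propagated intervals, then run order
                sources = sorted(
                    have.items(),
                    key=lambda kv: (kv[1][1] != "native", -kv[1][2], rids.index(kv[0])),
                )
                for src, (src_feat, _, _) in sources:
                    pt = pair_models.get((src, rid))
                    if pt is None:
                        continue
                    prepared, trained = pt
                    _, _, cands = indices[rid].intervals(pep.sequence, pep.charge, pep.mz_mono)
                    pred = identify_corresponding(
                        src_feat, cands, trained.models.warp, trained.models.at_model,
                        trained.models.ar_model, n_grid=config.ar_grid_points,
                        landmark=config.at_landmark, sequence=pep.sequence,
                        charge=pep.charge, q1_run=src, q2_run=rid,
                    )
                    if pred is None:
                        continue
                    located[key][rid] = (pred.q2_feature, "matched", -1.0)
                    correspondences.append(pred)
                    changed = True
                    break

    n_runs = len(rids)
    inter_keys = set.intersection(*({p.key for p in deduped[rid]} for rid in rids))
    complete = 0
    partial = 0
    for key in union_keys:
        if key in inter_keys:
            continue
        n_located = len(located[key])
        if n_located == n_runs:
            complete += 1
        elif n_located >= 2:
            partial += 1
    analyzed = venn["union"] - venn["intersection"]
    report = CoverageReport(
        per_run_identified=venn["per_run"],
        union_size=venn["union"],
        intersection_size=venn["intersection"],
        completely_identified=complete,
        partially_identified=partial,
        analyzed=analyzed,
        coverage_analyzed=complete / analyzed if analyzed else 1.0,
        coverage_union=(complete + len(inter_keys)) / venn["union"] if venn["union"] else 1.0,
        skipped_pairs=skipped,
    )
    return correspondences, report
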