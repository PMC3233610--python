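"""Synthetic multi-run LC-MS data with known ground truth.

The generator emulates the data regime the matcher is built for: runs sharing
peptides whose elution peaks have reproducible shapes, related by a smooth
non-linear warp with Gaussian residual time jitter, crowded by decoy
(interfering) peaks in the same mass channel, carrying large (up to ~50x)
intensity fold changes across runs, on top of baseline noise. Per-run
identification tables are emitted by sampling a fraction of peptides, with an
optional rate of planted false identifications whose recorded retention time
points at a decoy peak.

Each peptide occupies its own pair of mass channels (monoisotopic and first
isotope); channels are laid on a grid spaced widely enough that ppm windows
never overlap, matching the high-resolution assumption that XICs contain very
few overlapping peaks from unrelated species.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import exponnorm

from .io_formats import PeptideID, RunData, Scan, write_peptide_table
from .preprocess import first_isotope_mz

logger = logging.getLogger(__name__)

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# channel spacing (Th) > max isotope offset (+1.0034) + window slack
_MIN_CHANNEL_SPACING = 2.2


class SimConfigError(ValueError):
    """Infeasible simulation geometry or parameters."""


def default_warp_coefficients(run_index: int) -> list[float]:
    """Mild, monotone, non-linear truth warps (run 0 is the identity)."""
    presets = [
        [1.0, 0.0],
        [2.0e-5, 0.96, 5.0],
        [-1.2e-5, 1.03, -4.0],
        [1.5e-5, 0.98, 8.0],
        [-0.8e-5, 1.02, -6.0],
    ]
    return presets[run_index % len(presets)]


@dataclass
class SimConfig:
    """Study conditions of the simulated experiment.

    Defaults describe the pairwise benchmark: 150 shared peptides (the
    ground-truth intersection after per-run identification sampling lands near
    135, a desk-scale stand-in for thousands), 9 s residual time jitter, two
    decoy peaks per peptide placed 20-26 s from the true peak (inside three
    jitter standard deviations, i.e. a crowded chromatogram), exponentially
    modified Gaussian peak shapes 0.9-1.5 s wide, fold changes up to 50, and
    baseline noise N(30, 10^2) counts.
    """

    n_peptides: int = 150
    n_runs: int = 2
    mz_range: tuple[float, float] = (400.0, 900.0)
    run_length: float = 900.0  # seconds
    scan_interval: float = 1.0  # seconds
    warp_coefficients: list[list[float]] | None = None  # per run, highest first
    at_sigma: float = 9.0  # per-run residual elution-time jitter, seconds
    shape_family: str = "emg"  # 'emg' or 'gaussian'
    shape_sigma_range: tuple[float, float] = (0.9, 1.5)  # peak width, seconds
    shape_tau_range: tuple[float, float] = (0.2, 0.6)  # EMG tail constant, seconds
    shape_noise: float = 0.05  # relative width/tail + multiplicative point noise
    shape_reproducible: bool = True  # False => independent shapes per run
    decoys_per_peptide: int = 2
    decoy_offset_range: tuple[float, float] = (20.0, 26.0)  # |offset| from true apex, s
    fold_change_range: tuple[float, float] = (1.0, 50.0)  # max intensity ratio across runs
    base_intensity_range: tuple[float, float] = (5e3, 2e4)  # counts
    noise_level: float = 30.0  # baseline counts
    noise_sigma: float = 10.0
    identified_fraction: float = 0.95  # per-run Tandem-MS sampling
    id_false_positive_rate: float = 0.0  # per-peptide mis-assignment rate
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("identified_fraction", "id_false_positive_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1]")
        if self.scan_interval <= 0:
            raise SimConfigError("scan_interval must be > 0")
        if self.at_sigma < 0:
            raise SimConfigError("at_sigma must be >= 0")
        if self.shape_family not in ("emg", "gaussian"):
            raise SimConfigError("shape_family must be 'emg' or 'gaussian'")
        span = self.mz_range[1] - self.mz_range[0]
        if span / max(self.n_peptides, 1) < _MIN_CHANNEL_SPACING:
            raise SimConfigError(
                f"{self.n_peptides} peptides do not fit in {span:.0f} Th at "
                f">= {_MIN_CHANNEL_SPACING} Th channel spacing"
            )
        if self.decoys_per_peptide and self.decoy_offset_range[1] >= self.run_length:
            raise SimConfigError("decoy offsets exceed run length")

    def truth_warp(self, run_index: int) -> np.ndarray:
        if self.warp_coefficients is not None:
            return np.asarray(self.warp_coefficients[run_index], dtype=float)
        return np.asarray(default_warp_coefficients(run_index), dtype=float)


@dataclass
class RunPeptideTruth:
    """Where one peptide's true peak lies in one run."""

    apex_time: float
    interval: tuple[float, float]
    apex_intensity: float
    jitter: float  # the drawn residual time shift, seconds
    identified: bool = False
    recorded_rt: float | None = None
    false_positive: bool = False
    decoy_apexes: list[float] = field(default_factory=list)


@dataclass
class PeptideTruth:
    sequence: str
    charge: int
    mz_mono: float
    base_time: float
    is_false_id: bool
    runs: dict[str, RunPeptideTruth] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int]:
        return (self.sequence, self.charge)


@dataclass
class SimTruth:
    peptides: list[PeptideTruth]
    id_tables: dict[str, list[PeptideID]]

    def by_key(self) -> dict[tuple[str, int], PeptideTruth]:
        return {p.key: p for p in self.peptides}

    def to_json(self, path: str | Path) -> None:
        doc = {
            "peptides": [
                {
                    **{k: v for k, v in asdict(p).items() if k != "runs"},
                    "runs": {rid: asdict(rt) for rid, rt in p.runs.items()},
                }
                for p in self.peptides
            ]
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, default=float)


def _random_sequence(rng: np.random.Generator) -> str:
    n = int(rng.integers(7, 16))
    body = "".join(_AMINO_ACIDS[i] for i in rng.integers(0, len(_AMINO_ACIDS), n))
    return body + ("K" if rng.random() < 0.5 else "R")


@dataclass
class _PeakShape:
    """A peptide's characteristic elution profile: a main component plus an
    optional shoulder at a fixed relative offset — the reproducible 'fingerprint'
    that makes peak-shape correlation informative, as with real peptides."""

    sigma: float  # main width, s
    tau: float  # EMG tail constant, s
    shoulder_offset: float  # s relative to the main apex
    shoulder_weight: float  # relative height of the shoulder component
    shoulder_sigma: float

    def perturbed(self, rng: np.random.Generator, rel: float) -> "_PeakShape":
        f = lambda: 1.0 + rel * rng.normal()
        return _PeakShape(
            sigma=max(self.sigma * f(), 0.3),
            tau=max(self.tau * f(), 0.05),
            shoulder_offset=self.shoulder_offset * f(),
            shoulder_weight=min(max(self.shoulder_weight * f(), 0.0), 0.9),
            shoulder_sigma=max(self.shoulder_sigma * f(), 0.3),
        )


def _component(grid: np.ndarray, center: float, sigma: float, tau: float,
               family: str) -> np.ndarray:
    if family == "gaussian" or tau < 0.05 * sigma:
        return np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    k = max(tau / sigma, 0.05)
    prof = exponnorm.pdf(grid, K=k, loc=center, scale=sigma)
    m = prof.max()
    return prof / m if m > 0 else np.zeros_like(grid)


def _peak_profile(grid: np.ndarray, apex_target: float, height: float,
                  shape: _PeakShape, family: str) -> np.ndarray:
    """Elution profile on the scan grid, apex height ``height`` near ``apex_target``."""
    prof = _component(grid, apex_target, shape.sigma, shape.tau, family)
    if shape.shoulder_weight > 0:
        prof = prof + shape.shoulder_weight * _component(
            grid, apex_target + shape.shoulder_offset, shape.shoulder_sigma,
            shape.tau, family)
    m = prof.max()
    if m <= 0:
        return np.zeros_like(grid)
    return height * prof / m


def _draw_shape(rng: np.random.Generator, cfg: SimConfig, widen: float = 1.0) -> _PeakShape:
    lo, hi = cfg.shape_sigma_range
    tlo, thi = cfg.shape_tau_range
    return _PeakShape(
        sigma=rng.uniform(lo, hi * widen),
        tau=rng.uniform(tlo, thi * widen),
        shoulder_offset=rng.uniform(1.2, 3.0) * rng.choice([-1.0, 1.0]),
        shoulder_weight=rng.uniform(0.1, 0.4),
        shoulder_sigma=rng.uniform(lo, hi * widen),
    )


def generate_runs(cfg: SimConfig) -> tuple[list[RunData], SimTruth]:
    """Generate ``cfg.n_runs`` centroided MS1 runs plus the planted truth.

    Two independent random streams are derived from ``cfg.rng_seed``: one for
    the signal (peaks, shapes, jitter, decoys, noise) and one for the
    identification sampling, so identification settings can vary without
    changing the underlying chromatograms.
    """
    ss = np.random.SeedSequence(cfg.rng_seed)
    rng_sig, rng_ids = [np.random.default_rng(s) for s in ss.spawn(2)]

    n = cfg.n_peptides
    grid = np.arange(0.0, cfg.run_length, cfg.scan_interval)
    n_scans = grid.size
    run_ids = [f"Q{r + 1}" for r in range(cfg.n_runs)]

    # --- peptide catalogue ------------------------------------------------
    spacing = (cfg.mz_range[1] - cfg.mz_range[0]) / n
    seqs: set[str] = set()
    peptides: list[PeptideTruth] = []
    base_shapes = []
    base_heights = []
    iso_ratios = []
    t_lo, t_hi = 0.08 * cfg.run_length, 0.85 * cfg.run_length
    for i in range(n):
        while True:
            seq = _random_sequence(rng_sig)
            if seq not in seqs:
                seqs.add(seq)
                break
        charge = int(rng_sig.choice([1, 2, 3], p=[0.2, 0.6, 0.2]))
        mz = cfg.mz_range[0] + i * spacing + rng_sig.uniform(0, 0.2)
        base_time = rng_sig.uniform(t_lo, t_hi)
        peptides.append(PeptideTruth(sequence=seq, charge=charge, mz_mono=mz,
                                     base_time=base_time, is_false_id=False))
        base_shapes.append(_draw_shape(rng_sig, cfg))
        lo, hi = cfg.base_intensity_range
        base_heights.append(np.exp(rng_sig.uniform(np.log(lo), np.log(hi))))
        iso_ratios.append(rng_sig.uniform(0.4, 0.9))

    # geometry feasibility: every planted peak (and its decoys) must fit the run
    margin = 4 * cfg.at_sigma + 8 * cfg.shape_sigma_range[1]
    if cfg.decoys_per_peptide:
        margin += cfg.decoy_offset_range[1]
    for r in range(cfg.n_runs):
        coeffs = cfg.truth_warp(r)
        w_hi = float(np.polyval(coeffs, t_hi))
        w_lo = float(np.polyval(coeffs, t_lo))
        if w_hi + margin > cfg.run_length or w_lo - margin < -0.1 * cfg.run_length:
            raise SimConfigError(
                f"run {r}: warped peak span [{w_lo - margin:.0f}, {w_hi + margin:.0f}] s "
                f"exceeds the {cfg.run_length:.0f} s run"
            )

    log_half_fold = 0.5 * np.log(cfg.fold_change_range[1] / cfg.fold_change_range[0])

    # --- per-run signal ---------------------------------------------------
    runs: list[RunData] = []
    for r, rid in enumerate(run_ids):
        coeffs = cfg.truth_warp(r)
        mono = np.zeros((n, n_scans))
        iso = np.zeros((n, n_scans))
        for i, pep in enumerate(peptides):
            jitter = rng_sig.normal(0.0, cfg.at_sigma) if cfg.at_sigma > 0 else 0.0
            target = float(np.polyval(coeffs, pep.base_time)) + jitter
            if cfg.shape_reproducible:
                shape = base_shapes[i].perturbed(rng_sig, cfg.shape_noise)
            else:
                shape = _draw_shape(rng_sig, cfg)
            height = base_heights[i] * np.exp(rng_sig.uniform(-log_half_fold, log_half_fold))
            prof = _peak_profile(grid, target, height, shape, cfg.shape_family)
            if cfg.shape_noise > 0:
                prof = prof * np.clip(1.0 + cfg.shape_noise * rng_sig.normal(size=n_scans), 0.2, None)
            clean_iso = prof * iso_ratios[i]
            # truth bookkeeping on the clean first-isotope trace
            apex_idx = int(np.argmax(clean_iso))
            thr = cfg.noise_level + 3.0 * cfg.noise_sigma
            above = clean_iso > thr
            a = apex_idx
            while a > 0 and above[a - 1]:
                a -= 1
            b = apex_idx
            while b < n_scans - 1 and above[b + 1]:
                b += 1
            rt = RunPeptideTruth(
                apex_time=float(grid[apex_idx]),
                interval=(float(grid[a]), float(grid[b])),
                apex_intensity=float(clean_iso[apex_idx]),
                jitter=float(jitter),
            )
            mono[i] += prof
            iso[i] += clean_iso
            # decoy (interfering) peaks: independent species per run
            for _ in range(cfg.decoys_per_peptide):
                off = rng_sig.uniform(*cfg.decoy_offset_range) * rng_sig.choice([-1.0, 1.0])
                d_shape = _draw_shape(rng_sig, cfg, widen=1.25)
                d_height = height * np.exp(rng_sig.uniform(np.log(0.5), np.log(2.0)))
                d_prof = _peak_profile(grid, target + off, d_height, d_shape,
                                       cfg.shape_family)
                if cfg.shape_noise > 0:
                    d_prof = d_prof * np.clip(
                        1.0 + cfg.shape_noise * rng_sig.normal(size=n_scans), 0.2, None)
                rt.decoy_apexes.append(float(grid[int(np.argmax(d_prof))]))
                mono[i] += d_prof
                iso[i] += d_prof * rng_sig.uniform(0.4, 0.9)
            pep.runs[rid] = rt
        # baseline noise per channel point
        if cfg.noise_sigma > 0 or cfg.noise_level > 0:
            mono += np.clip(rng_sig.normal(cfg.noise_level, cfg.noise_sigma, mono.shape), 0, None)
            iso += np.clip(rng_sig.normal(cfg.noise_level, cfg.noise_sigma, iso.shape), 0, None)
        # assemble centroided scans: fixed channel set, sorted by m/z
        mz_channels = np.empty(2 * n)
        inten = np.empty((2 * n, n_scans))
        for i, pep in enumerate(peptides):
            mz_channels[2 * i] = pep.mz_mono
            mz_channels[2 * i + 1] = first_isotope_mz(pep.mz_mono, pep.charge)
            inten[2 * i] = mono[i]
            inten[2 * i + 1] = iso[i]
        order = np.argsort(mz_channels)
        mz_sorted = mz_channels[order]
        inten_sorted = inten[order]
        scans = [Scan(time=float(grid[s]), mz=mz_sorted.copy(),
                      intensity=inten_sorted[:, s].copy()) for s in range(n_scans)]
        runs.append(RunData(run_id=rid, scans=scans))

    # --- identification tables -------------------------------------------
    for pep in peptides:
        pep.is_false_id = bool(rng_ids.random() < cfg.id_false_positive_rate)
    id_tables: dict[str, list[PeptideID]] = {}
    for rid in run_ids:
        table: list[PeptideID] = []
        for pep in peptides:
            rt = pep.runs[rid]
            if rng_ids.random() >= cfg.identified_fraction:
                continue
            rt.identified = True
            if pep.is_false_id:
                rt.false_positive = True
                if rt.decoy_apexes:
                    recorded = rt.decoy_apexes[rng_ids.integers(len(rt.decoy_apexes))]
                else:
                    recorded = rng_ids.uniform(t_lo, t_hi)
                prob = float(rng_ids.beta(4.0, 2.0))
            else:
                recorded = rt.apex_time + rng_ids.normal(0.0, 1.0)
                prob = float(rng_ids.beta(200.0, 3.0))
            rt.recorded_rt = float(recorded)
            table.append(PeptideID(sequence=pep.sequence, charge=pep.charge,
                                   mz_mono=pep.mz_mono, rt_sec=float(recorded),
                                   probability=prob, run_id=rid))
        id_tables[rid] = table

    return runs, SimTruth(peptides=peptides, id_tables=id_tables)


# ---------------------------------------------------------------------------
# minimal mzML writer (centroided MS1 only)

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _b64(arr: np.ndarray) -> str:
    import base64

    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


def write_mzml(run: RunData, path: str | Path, time_unit: str = "second") -> None:
    """Write a run as centroided-MS1 mzML readable by :func:`scfia.io_formats.read_mzml`.

    ``time_unit`` controls the unit the scan start times are recorded in
    ('second' or 'minute'); the stored values are converted accordingly.
    """
    if run.n_scans == 0:
        raise ValueError("cannot write an empty run")
    if time_unit == "second":
        unit_acc, unit_name, factor = "UO:0000010", "second", 1.0
    elif time_unit == "minute":
        unit_acc, unit_name, factor = "UO:0000031", "minute", 1.0 / 60.0
    else:
        raise ValueError("time_unit must be 'second' or 'minute'")
    parts = [_MZML_HEADER.format(run_id=run.run_id, count=run.n_scans)]
    for i, scan in enumerate(run.scans):
        t = scan.time * factor
        mz64 = _b64(scan.mz)
        in64 = _b64(scan.intensity)
        parts.append(
            f"""      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{scan.mz.size}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{t:.9g}" unitCvRef="UO" unitAccession="{unit_acc}" unitName="{unit_name}"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(in64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{in64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
""")
    parts.append(_MZML_FOOTER)
    Path(path).write_text("".join(parts))


def write_fixture(cfg: SimConfig, out_dir: str | Path) -> tuple[list[Path], list[Path], Path]:
    """Simulate and persist a full fixture: mzML runs, ID tables, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runs, truth = generate_runs(cfg)
    run_paths, table_paths = [], []
    for run in runs:
        rp = out / f"{run.run_id}.mzML"
        write_mzml(run, rp)
        run_paths.append(rp)
        tp = out / f"{run.run_id}_ids.tsv"
        write_peptide_table(truth.id_tables[run.run_id], tp)
        table_paths.append(tp)
    truth_path = out / "truth.json"
    truth.to_json(truth_path)
    return run_paths, table_paths, truth_path
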