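"""Reading LC-MS runs (mzML) and peptide-identification tables, writing results.

All retention times are seconds internally; mzML scan start times recorded in
minutes are converted on read. Identification tables are plain TSV with the
columns ``sequence, charge, mz, rt_sec, probability`` — the minimal subset of a
search-engine/PeptideProphet report that the matcher consumes.

The mzML reader is a small self-contained parser for centroided MS1 spectra
(plain or indexed mzML; 32/64-bit float arrays, zlib or uncompressed). It
reads only what the matcher needs: scan times, m/z arrays, intensity arrays
and the MS level.
"""

from __future__ import annotations

import base64
import logging
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PEPTIDE_TABLE_COLUMNS = ("sequence", "charge", "mz", "rt_sec", "probability")

CORRESPONDENCE_COLUMNS = (
    "sequence",
    "charge",
    "q1_run",
    "q1_rt_apex",
    "q2_run",
    "q2_rt_apex",
    "q2_interval_start",
    "q2_interval_end",
    "AT",
    "AR",
    "score",
    "n_candidates",
)


class EmptyRunError(ValueError):
    """Raised when an mzML file contains no MS1 spectra."""


class SchemaError(ValueError):
    """Raised when an identification table is missing a required column."""


@dataclass
class Scan:
    """One centroided MS1 scan."""

    time: float  # seconds
    mz: np.ndarray  # Th, ascending
    intensity: np.ndarray  # counts >= 0


@dataclass
class RunData:
    """A single LC-MS run: time-ordered MS1 scans."""

    run_id: str
    scans: list[Scan] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.scans])

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    def total_ion_current(self) -> float:
        return float(sum(s.intensity.sum() for s in self.scans))


@dataclass(frozen=True)
class PeptideID:
    """One peptide identification from a Tandem-MS search of a single run.

    ``probability`` plays the PeptideProphet-probability role: the confidence
    that the sequence assignment is a true positive.
    """

    sequence: str
    charge: int
    mz_mono: float
    rt_sec: float
    probability: float
    run_id: str = ""

    @property
    def key(self) -> tuple[str, int]:
        return (self.sequence, self.charge)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem) -> dict[str, tuple[str, dict]]:
    """accession -> (value, attributes) for the direct cvParam children."""
    out = {}
    for child in elem:
        if _local(child.tag) == "cvParam":
            out[child.get("accession", "")] = (child.get("value", ""), child.attrib)
    return out


def _decode_binary_array(bda) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (role accession, values)."""
    params = _cv_params(bda)
    dtype = "<f8" if "MS:1000523" in params else "<f4" if "MS:1000521" in params else "<f8"
    compressed = "MS:1000574" in params  # zlib
    role = next((a for a in ("MS:1000514", "MS:1000515") if a in params), None)
    binary = next((c for c in bda if _local(c.tag) == "binary"), None)
    text = (binary.text or "") if binary is not None else ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    itemsize = np.dtype(dtype).itemsize
    n = len(raw) // itemsize
    return role, np.frombuffer(raw, dtype=dtype, count=n).astype(float)


def _parse_spectrum(elem) -> Scan | None:
    """One <spectrum> element -> Scan, or None for non-MS1 spectra."""
    params = _cv_params(elem)
    ms_level = params.get("MS:1000511", (None,))[0]
    if ms_level is not None and int(ms_level) != 1:
        return None
    time_sec = None
    mz = inten = None
    for child in elem.iter():
        tag = _local(child.tag)
        if tag == "scan":
            sp = _cv_params(child)
            if "MS:1000016" in sp:
                value, attrs = sp["MS:1000016"]
                unit = attrs.get("unitName", "minute")
                if unit in ("second", "seconds"):
                    time_sec = float(value)
                elif unit in ("minute", "minutes"):
                    time_sec = float(value) * 60.0
                else:
                    raise ValueError(f"unsupported scan time unit: {unit!r}")
        elif tag == "binaryDataArray":
            role, values = _decode_binary_array(child)
            if role == "MS:1000514":
                mz = values
            elif role == "MS:1000515":
                inten = values
    if ms_level is None and (mz is None or inten is None):
        return None
    if time_sec is None:
        raise ValueError("spectrum without a scan start time")
    if mz is None or inten is None:
        mz = mz if mz is not None else np.empty(0)
        inten = inten if inten is not None else np.empty(0)
    if mz.size != inten.size:
        raise ValueError("m/z and intensity arrays differ in length")
    return Scan(time=time_sec, mz=mz, intensity=inten)


def read_mzml(path: str | Path, run_id: str | None = None) -> RunData:
    """Read the MS1 scans of an mzML file into a :class:`RunData`.

    MS2+ spectra are dropped; scan times are converted to seconds whatever
    unit the file records (minutes are the common converter convention);
    scans are returned sorted by time (a warning is logged if the file was not
    time-ordered).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    scans: list[Scan] = []
    for _, elem in ET.iterparse(str(path)):
        if _local(elem.tag) == "spectrum":
            scan = _parse_spectrum(elem)
            if scan is not None:
                scans.append(scan)
            elem.clear()
    if not scans:
        raise EmptyRunError(f"no MS1 spectra in {path}")
    times = np.array([s.time for s in scans])
    if np.any(np.diff(times) < 0):
        logger.warning("scan times in %s not monotone; sorting", path)
        scans.sort(key=lambda s: s.time)
    return RunData(run_id=run_id or path.stem, scans=scans)


def read_peptide_table(path: str | Path, run_id: str | None = None) -> list[PeptideID]:
    """Read a TSV identification table into a list of :class:`PeptideID`.

    Rows whose probability falls outside [0, 1] are rejected with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in PEPTIDE_TABLE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"identification table {path} missing column {col!r}")
    if df.empty:
        logger.warning("identification table %s is empty", path)
        return []
    bad = (df["probability"] < 0) | (df["probability"] > 1)
    if bad.any():
        logger.warning("rejecting %d rows of %s with probability outside [0,1]", int(bad.sum()), path)
        df = df[~bad]
    rid = run_id or path.stem
    return [
        PeptideID(
            sequence=str(r.sequence),
            charge=int(r.charge),
            mz_mono=float(r.mz),
            rt_sec=float(r.rt_sec),
            probability=float(r.probability),
            run_id=rid,
        )
        for r in df.itertuples(index=False)
    ]


def write_peptide_table(ids: Iterable[PeptideID], path: str | Path) -> None:
    """Write identifications as a TSV readable by :func:`read_peptide_table`."""
    rows = [
        {
            "sequence": p.sequence,
            "charge": p.charge,
            "mz": p.mz_mono,
            "rt_sec": p.rt_sec,
            "probability": p.probability,
        }
        for p in ids
    ]
    df = pd.DataFrame(rows, columns=list(PEPTIDE_TABLE_COLUMNS))
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_correspondences(pairs: Sequence, path: str | Path) -> None:
    """Write matched pairs as a deterministic TSV (sorted by sequence, charge).

    ``pairs`` are :class:`scfia.stat_models.CorrespondencePair` objects. Floats
    are written with 12 significant digits so a read-back round trip preserves
    AT/AR/score beyond 10 significant digits.
    """
    rows = []
    for p in sorted(pairs, key=lambda p: (p.sequence, p.charge)):
        rows.append(
            {
                "sequence": p.sequence,
                "charge": p.charge,
                "q1_run": p.q1_run,
                "q1_rt_apex": p.q1_feature.apex_time,
                "q2_run": p.q2_run,
                "q2_rt_apex": p.q2_feature.apex_time,
                "q2_interval_start": p.q2_feature.start_time,
                "q2_interval_end": p.q2_feature.end_time,
                "AT": p.at,
                "AR": p.ar,
                "score": p.score,
                "n_candidates": p.n_candidates,
            }
        )
    df = pd.DataFrame(rows, columns=list(CORRESPONDENCE_COLUMNS))
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_correspondences(path: str | Path) -> pd.DataFrame:
    """Read a correspondence TSV back into a DataFrame."""
    return pd.read_csv(path, sep="\t")
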