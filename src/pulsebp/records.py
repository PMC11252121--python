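"""Waveform record containers and persistence.

A :class:`PhysioRecord` holds one subject's synchronized photoplethysmogram
(PPG), electrocardiogram (ECG, limb lead I/II/III) and invasive arterial
blood pressure (ABP) channels on a common time base.  The on-disk format is
one CSV per record (one column per channel) plus a small JSON sidecar
carrying the subject id, sampling rate and ECG lead label — a desk-scale
stand-in for hospital-monitor record/header pairs.

Beat-level training samples (:class:`BeatSegment`) are persisted as a
:class:`SegmentStore`: a single CSV with one row per segment plus a JSON
manifest recording provenance and the schema version.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

#: canonical channel-name dialects (upper-cased before lookup)
PPG_ALIASES = {"PLETH", "PPG"}
ABP_ALIASES = {"ABP", "ART"}
ECG_LEADS = {"I", "II", "III"}

DEFAULT_FS = 125.0
SEGMENT_SCHEMA_VERSION = 1


class IneligibleRecordError(ValueError):
    """A record lacks a required channel or an acceptable ECG lead.

    Distinct from plain I/O failure so callers can skip ineligible records
    while still surfacing broken files.
    """


class SegmentStoreError(ValueError):
    """A segment store file failed validation; message names the field."""


@dataclass
class PhysioRecord:
    """One subject's synchronized PPG/ECG/ABP sample arrays."""

    subject_id: str
    sampling_rate: float
    ppg: np.ndarray
    ecg: np.ndarray
    ecg_lead: str
    abp: np.ndarray

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        if not (len(self.ppg) == len(self.ecg) == len(self.abp)):
            raise ValueError(
                "channel length mismatch: "
                f"ppg={len(self.ppg)} ecg={len(self.ecg)} abp={len(self.abp)}"
            )
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")

    def __len__(self) -> int:
        return len(self.ppg)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sampling_rate


@dataclass
class BeatSegment:
    """One training sample: a two-beat span of PPG and ECG plus labels.

    ``ppg200``/``ecg200`` are the 200-point resampled waveforms; ``rr1`` and
    ``rr2`` the two R-R intervals (seconds); ``sbp``/``dbp``/``pp`` the
    systolic, diastolic and pulse pressure (mmHg) read off the raw ABP.
    """

    ppg200: np.ndarray
    ecg200: np.ndarray
    rr1: float
    rr2: float
    sbp: float
    dbp: float
    pp: float
    subject_id: str

    def __post_init__(self) -> None:
        self.ppg200 = np.asarray(self.ppg200, dtype=float)
        self.ecg200 = np.asarray(self.ecg200, dtype=float)
        if self.ppg200.shape != (200,) or self.ecg200.shape != (200,):
            raise ValueError(
                f"segments must be 200-point: ppg={self.ppg200.shape} ecg={self.ecg200.shape}"
            )
        if self.rr1 <= 0 or self.rr2 <= 0:
            raise ValueError(f"R-R intervals must be positive: {self.rr1}, {self.rr2}")


@dataclass
class SegmentStore:
    """An ordered collection of segments with per-segment provenance."""

    segments: list[BeatSegment] = field(default_factory=list)
    #: segment index -> (subject_id, start sample offset in the source record)
    provenance: dict[int, tuple[str, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.segments)

    def append(self, segment: BeatSegment, offset: int = -1) -> None:
        self.provenance[len(self.segments)] = (segment.subject_id, int(offset))
        self.segments.append(segment)

    def extend(self, segments: Iterable[tuple[BeatSegment, int]]) -> None:
        for seg, off in segments:
            self.append(seg, off)


# ---------------------------------------------------------------------------
# record reading


def _classify_channel(name: str) -> tuple[str, str] | None:
    """Map a raw channel name to ('ppg'|'abp'|'ecg', canonical label)."""
    label = name.strip().upper()
    if label in PPG_ALIASES:
        return "ppg", label
    if label in ABP_ALIASES:
        return "abp", label
    lead = label.removeprefix("ECG ").strip()
    if lead in ECG_LEADS:
        return "ecg", lead
    return None


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_record(
    path: str | Path,
    required_channels: Sequence[str] = ("ppg", "ecg", "abp"),
    fs: float = DEFAULT_FS,
) -> PhysioRecord:
    """Read one record from the CSV + JSON-header container.

    The CSV holds one column per channel (monitor-style names; see
    :data:`PPG_ALIASES` etc.), the JSON sidecar ``subject_id``, ``fs`` and
    optionally ``lead``.  Records not sampled at ``fs`` are polyphase-resampled
    to it, because every downstream constant (8-s windows of 1000 samples,
    200-point segments) presumes 125 Hz.

    Raises
    ------
    IneligibleRecordError
        if a required channel (or an I/II/III ECG lead) is absent.
    IOError
        for unreadable files or a missing sampling rate.
    """
    path = Path(path)
    if path.suffix in {".hea", ".dat"}:
        raise IOError(
            f"{path}: raw WFDB record/header pairs are not supported by this reader; "
            "convert to the CSV + JSON container first"
        )
    if not path.exists():
        raise IOError(f"record file not found: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise IOError(f"record header not found: {sidecar}")
    header = json.loads(sidecar.read_text())
    if "fs" not in header:
        raise IOError(f"{sidecar}: sampling rate 'fs' absent from header")
    src_fs = float(header["fs"])
    table = pd.read_csv(path)

    found: dict[str, np.ndarray] = {}
    lead = str(header.get("lead", "")).upper() or None
    for col in table.columns:
        kind_label = _classify_channel(col)
        if kind_label is None:
            continue
        kind, label = kind_label
        if kind in found:
            continue  # first matching column wins
        found[kind] = table[col].to_numpy(dtype=float)
        if kind == "ecg":
            lead = label
    missing = [ch for ch in required_channels if ch not in found]
    if missing:
        raise IneligibleRecordError(f"{path}: missing required channel(s) {missing}")

    record = PhysioRecord(
        subject_id=str(header.get("subject_id", path.stem)),
        sampling_rate=src_fs,
        ppg=found.get("ppg", np.array([])),
        ecg=found.get("ecg", np.array([])),
        ecg_lead=lead or "II",
        abp=found.get("abp", np.array([])),
    )
    if src_fs != fs:
        record = resample_record(record, fs)
    return record


def resample_record(record: PhysioRecord, fs: float) -> PhysioRecord:
    """Polyphase-resample all channels of a record to ``fs`` Hz."""
    from fractions import Fraction

    frac = Fraction(fs / record.sampling_rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    return PhysioRecord(
        subject_id=record.subject_id,
        sampling_rate=fs,
        ppg=resample_poly(record.ppg, up, down),
        ecg=resample_poly(record.ecg, up, down),
        ecg_lead=record.ecg_lead,
        abp=resample_poly(record.abp, up, down),
    )


def write_record(record: PhysioRecord, path: str | Path) -> None:
    """Write a record in the CSV + JSON-header container (inverse of read)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"PLETH": record.ppg, record.ecg_lead: record.ecg, "ABP": record.abp}
    ).to_csv(path, index=False)
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "subject_id": record.subject_id,
                "fs": record.sampling_rate,
                "lead": record.ecg_lead,
            }
        )
    )


def select_eligible_records(paths: Sequence[str | Path]) -> list[PhysioRecord]:
    """Load records keeping only those with PPG, ABP and a lead-I/II/III ECG.

    Input order is preserved.  Unreadable files are logged and skipped —
    eligibility filtering must not abort a batch.
    """
    out: list[PhysioRecord] = []
    for p in paths:
        try:
            out.append(read_record(p))
        except IneligibleRecordError as exc:
            logger.info("skipping ineligible record: %s", exc)
        except (IOError, ValueError) as exc:
            logger.warning("skipping unreadable record %s: %s", p, exc)
    return out


# ---------------------------------------------------------------------------
# segment persistence

_SCALAR_COLS = ["subject_id", "offset", "rr1", "rr2", "sbp", "dbp", "pp"]


def write_segments(store: SegmentStore, path: str | Path) -> None:
    """Persist a segment store as CSV plus a JSON manifest.

    Full float precision (repr round-trip) is kept so read(write(x)) == x.
    """
    if len(store) == 0:
        raise SegmentStoreError("refusing to write an empty segment store")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = {}
    for i, seg in enumerate(store.segments):
        subj, off = store.provenance.get(i, (seg.subject_id, -1))
        rows[i] = [subj, off, seg.rr1, seg.rr2, seg.sbp, seg.dbp, seg.pp]
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=_SCALAR_COLS)
    ppg = pd.DataFrame(
        np.stack([s.ppg200 for s in store.segments]),
        columns=[f"ppg{j:03d}" for j in range(200)],
    )
    ecg = pd.DataFrame(
        np.stack([s.ecg200 for s in store.segments]),
        columns=[f"ecg{j:03d}" for j in range(200)],
    )
    # default float formatting is shortest-round-trip, so reals survive exactly
    pd.concat([frame.reset_index(drop=True), ppg, ecg], axis=1).to_csv(path, index=False)
    manifest = {
        "schema_version": SEGMENT_SCHEMA_VERSION,
        "n_segments": len(store),
        "columns": _SCALAR_COLS + ["ppg000..ppg199", "ecg000..ecg199"],
    }
    path.with_suffix(path.suffix + ".manifest.json").write_text(json.dumps(manifest, indent=2))


def read_segments(path: str | Path) -> SegmentStore:
    """Reload a segment store written by :func:`write_segments`."""
    path = Path(path)
    table = pd.read_csv(path, float_precision="round_trip")
    for col in _SCALAR_COLS:
        if col not in table.columns:
            raise SegmentStoreError(f"{path}: missing column '{col}'")
    ppg_cols = [f"ppg{j:03d}" for j in range(200)]
    ecg_cols = [f"ecg{j:03d}" for j in range(200)]
    for col in (ppg_cols[0], ppg_cols[-1], ecg_cols[0], ecg_cols[-1]):
        if col not in table.columns:
            raise SegmentStoreError(f"{path}: missing waveform column '{col}'")
    store = SegmentStore()
    ppg = table[ppg_cols].to_numpy(dtype=float)
    ecg = table[ecg_cols].to_numpy(dtype=float)
    for i, row in table.iterrows():
        seg = BeatSegment(
            ppg200=ppg[i],
            ecg200=ecg[i],
            rr1=float(row["rr1"]),
            rr2=float(row["rr2"]),
            sbp=float(row["sbp"]),
            dbp=float(row["dbp"]),
            pp=float(row["pp"]),
            subject_id=str(row["subject_id"]),
        )
        store.append(seg, int(row["offset"]))
    return store
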