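"""Reading, writing and assembling 12-lead ECG records and drug-trial cohorts.

Records are 10-second, 12-lead, 500-Hz signal matrices in microvolts, carrying
subject / timepoint / replicate identity.  Three on-disk dialects are
supported:

``wfdb``
    A WFDB-compatible pair ``<base>.hea`` + ``<base>.dat`` (format 16,
    little-endian int16, gain 400 ADU/mV so one digital unit is 2.5 uV —
    the amplitude resolution of the source recordings).  Writing in this
    dialect quantizes amplitudes to the 2.5 uV grid, so a round trip agrees
    with the original within half a quantization step.
``csv``
    One CSV per record: ``#``-prefixed metadata lines followed by a header
    row of lead names and one row per sample, in microvolts.  Lossless to
    the printed precision.
``bundle``
    The per-record file format used inside cohort bundle directories;
    identical to ``csv``.

A cohort bundle is a directory with ``annotation.csv`` (one row per blood
draw: subject, sex, arm, protocol, timepoint, plasma concentration in pg/ml,
and three replicate record paths), a ``records/`` subdirectory, and a JSON
provenance manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DuplicateDrawError,
    IncompleteTriplicateError,
    MalformedRecordError,
    RateMismatchError,
)

#: Standard 12-lead order; readers map leads by name, never by position.
STANDARD_LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

SAMPLING_RATE_HZ = 500.0
RECORD_SAMPLES = 5000  # 10 s at 500 Hz
AMPLITUDE_RESOLUTION_UV = 2.5

#: Blood-draw time grids (hours relative to the first dose) of the two
#: source protocols.  Protocol A: predose plus 15 post-dose draws after a
#: single morning dose.  Protocol B: one predose draw at -0.5 h plus 13
#: post-dose draws around three administrations during the day.
PROTOCOL_GRIDS: dict[str, tuple[float, ...]] = {
    "A": (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0, 7.0, 8.0,
          12.0, 14.0, 24.0),
    "B": (-0.5, 1.5, 2.0, 2.5, 3.0, 6.5, 7.0, 7.5, 8.0, 12.0, 12.5, 13.0,
          13.5, 24.0),
}

ANNOTATION_COLUMNS = (
    "subject_id", "sex", "arm", "protocol", "timepoint_h",
    "concentration_pg_ml", "record_1", "record_2", "record_3",
)


@dataclass
class ECGRecord:
    """One 10-s, 12-lead ECG with acquisition identity.

    ``signal`` is a float array of shape (12, 5000) in microvolts, rows in
    :data:`STANDARD_LEADS` order.
    """

    signal: np.ndarray
    subject_id: str = ""
    timepoint_h: float = 0.0
    replicate_index: int = 1
    sampling_rate_hz: float = SAMPLING_RATE_HZ
    amplitude_resolution_uv: float = AMPLITUDE_RESOLUTION_UV
    lead_names: tuple[str, ...] = STANDARD_LEADS

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float32)
        self.lead_names = tuple(self.lead_names)
        self.validate()

    def validate(self) -> None:
        if self.signal.ndim != 2 or self.signal.shape[0] != 12:
            raise MalformedRecordError(
                f"expected a 12-lead signal matrix, got shape {self.signal.shape}"
            )
        if len(self.lead_names) != 12 or len(set(self.lead_names)) != 12:
            raise MalformedRecordError(
                f"need 12 distinct lead names, got {self.lead_names}"
            )
        expected = int(round(10.0 * self.sampling_rate_hz))
        if self.signal.shape[1] != expected:
            raise MalformedRecordError(
                f"expected {expected} samples per lead for a 10-s record at "
                f"{self.sampling_rate_hz} Hz, got {self.signal.shape[1]}"
            )
        if not np.all(np.isfinite(self.signal)):
            raise MalformedRecordError("signal contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def quantized(self) -> "ECGRecord":
        """Snap amplitudes to the 2.5 uV acquisition grid (explicit step)."""
        q = self.amplitude_resolution_uv
        return replace(self, signal=np.rint(self.signal / q) * q)

    def lead(self, name: str) -> np.ndarray:
        try:
            return self.signal[self.lead_names.index(name)]
        except ValueError:
            raise MalformedRecordError(f"malformed record: missing lead {name!r}")


@dataclass
class CohortSample:
    """One blood draw: three replicate ECGs plus the measured plasma level."""

    subject_id: str
    sex: str
    arm: str
    protocol: str
    timepoint_h: float
    replicates: list[ECGRecord]
    concentration_pg_ml: float

    def __post_init__(self) -> None:
        if len(self.replicates) != 3:
            raise IncompleteTriplicateError(
                f"incomplete triplicate for {self.subject_id} @ "
                f"{self.timepoint_h} h: {len(self.replicates)} replicates"
            )
        for r in self.replicates:
            if r.subject_id != self.subject_id or r.timepoint_h != self.timepoint_h:
                raise MalformedRecordError(
                    f"replicate identity mismatch for {self.subject_id} @ "
                    f"{self.timepoint_h} h"
                )
        if self.concentration_pg_ml < 0:
            raise ValueError("concentration_pg_ml must be non-negative")
        if self.arm not in ("dofetilide", "placebo"):
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"unknown sex {self.sex!r}")


@dataclass
class Cohort:
    """A collection of blood-draw samples plus a subject table and provenance."""

    samples: list[CohortSample]
    subjects: pd.DataFrame  # columns: subject_id, sex, arm, protocol
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.subjects["subject_id"])
        seen: set[tuple[str, float]] = set()
        for s in self.samples:
            if s.subject_id not in known:
                raise MalformedRecordError(
                    f"sample subject {s.subject_id!r} missing from subject table"
                )
            key = (s.subject_id, s.timepoint_h)
            if key in seen:
                raise DuplicateDrawError(f"duplicate draw {key}")
            seen.add(key)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects["subject_id"])

    def samples_for(self, subject_id: str) -> list[CohortSample]:
        return [s for s in self.samples if s.subject_id == subject_id]

    def subset(self, subject_ids) -> "Cohort":
        keep = set(subject_ids)
        return Cohort(
            samples=[s for s in self.samples if s.subject_id in keep],
            subjects=self.subjects[self.subjects["subject_id"].isin(keep)]
            .reset_index(drop=True),
            provenance=dict(self.provenance, subset=sorted(keep)),
        )


# ---------------------------------------------------------------------------
# single-record I/O


def _infer_dialect(path: Path) -> str:
    if path.suffix == ".csv":
        return "csv"
    return "wfdb"


def write_record(record: ECGRecord, path, dialect: str = "csv") -> Path:
    """Write ``record`` to ``path``; returns the path of the primary file.

    For the ``wfdb`` dialect ``path`` is the record base name (without
    extension); a ``.hea``/``.dat`` pair is produced and the header path is
    returned.
    """
    record.validate()
    path = Path(path)
    if dialect in ("csv", "bundle"):
        return _write_csv(record, path)
    if dialect == "wfdb":
        return _write_wfdb(record, path)
    raise ValueError(f"unknown dialect {dialect!r}")


def read_record(path, dialect: str | None = None, resample: bool = False) -> ECGRecord:
    """Read an ECG record, mapping leads by name into standard order.

    Raises :class:`MalformedRecordError` when a lead is missing and
    :class:`RateMismatchError` when the stored sampling rate differs from
    500 Hz and ``resample`` is False.
    """
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect in ("csv", "bundle"):
        return _read_csv(path, resample=resample)
    if dialect == "wfdb":
        return _read_wfdb(path, resample=resample)
    raise ValueError(f"unknown dialect {dialect!r}")


def _meta_lines(record: ECGRecord, comment: str) -> list[str]:
    return [
        f"{comment} subject_id: {record.subject_id}",
        f"{comment} timepoint_h: {record.timepoint_h!r}",
        f"{comment} replicate_index: {record.replicate_index}",
        f"{comment} sampling_rate_hz: {record.sampling_rate_hz!r}",
        f"{comment} amplitude_resolution_uv: {record.amplitude_resolution_uv!r}",
    ]


def _write_csv(record: ECGRecord, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = _meta_lines(record, "#")
    lines.append(",".join(record.lead_names))
    sig = record.signal.T  # (samples, leads)
    for row in sig:
        lines.append(",".join(f"{v:.4f}" for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def _parse_meta(lines: list[str]) -> dict:
    meta = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if ":" in body:
            key, val = body.split(":", 1)
            meta[key.strip()] = val.strip()
    return meta


def _read_csv(path: Path, resample: bool) -> ECGRecord:
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text().splitlines()
    meta_lines = [ln for ln in text if ln.startswith("#")]
    body = [ln for ln in text if ln and not ln.startswith("#")]
    meta = _parse_meta(meta_lines)
    header = [h.strip() for h in body[0].split(",")]
    data = np.array([[float(v) for v in ln.split(",")] for ln in body[1:]],
                    dtype=np.float32)
    return _finish_read(
        data.T, header, meta, resample,
        fs=float(meta.get("sampling_rate_hz", SAMPLING_RATE_HZ)),
    )


def _finish_read(signal: np.ndarray, lead_names: list[str], meta: dict,
                 resample: bool, fs: float) -> ECGRecord:
    by_name = {nm: signal[i] for i, nm in enumerate(lead_names)}
    missing = [nm for nm in STANDARD_LEADS if nm not in by_name]
    if missing:
        raise MalformedRecordError(f"malformed record: missing lead {missing[0]!r}")
    ordered = np.stack([by_name[nm] for nm in STANDARD_LEADS])
    if fs != SAMPLING_RATE_HZ:
        if not resample:
            raise RateMismatchError(
                f"rate mismatch: file at {fs} Hz, expected {SAMPLING_RATE_HZ} Hz "
                "(pass resample=True to convert)"
            )
        from scipy.signal import resample_poly
        from fractions import Fraction

        frac = Fraction(SAMPLING_RATE_HZ / fs).limit_denominator(1000)
        ordered = resample_poly(ordered, frac.numerator, frac.denominator, axis=1)
        ordered = ordered[:, :RECORD_SAMPLES].astype(np.float32)
    return ECGRecord(
        signal=ordered,
        subject_id=str(meta.get("subject_id", "")),
        timepoint_h=float(meta.get("timepoint_h", 0.0)),
        replicate_index=int(meta.get("replicate_index", 1)),
        amplitude_resolution_uv=float(
            meta.get("amplitude_resolution_uv", AMPLITUDE_RESOLUTION_UV)
        ),
    )


# WFDB format 16: little-endian int16, samples interleaved across signals.
_WFDB_GAIN = 400.0  # ADU per mV -> 2.5 uV per digital unit


def _write_wfdb(record: ECGRecord, base: Path) -> Path:
    base.parent.mkdir(parents=True, exist_ok=True)
    name = base.name
    digital = np.rint(record.signal / record.amplitude_resolution_uv)
    digital = np.clip(digital, -32768, 32767).astype("<i2")
    interleaved = digital.T.reshape(-1)  # sample-major
    (base.with_suffix(".dat")).write_bytes(interleaved.tobytes())

    fs = record.sampling_rate_hz
    lines = [f"{name} 12 {fs:g} {record.n_samples}"]
    for i, lead in enumerate(record.lead_names):
        first = int(digital[i, 0])
        checksum = int(np.sum(digital[i], dtype=np.int64) % 65536)
        lines.append(
            f"{name}.dat 16 {_WFDB_GAIN:g}(0)/mV 16 0 {first} {checksum} 0 {lead}"
        )
    lines += _meta_lines(record, "#")
    hea = base.with_suffix(".hea")
    hea.write_text("\n".join(lines) + "\n")
    return hea


def _read_wfdb(path: Path, resample: bool) -> ECGRecord:
    base = Path(path)
    if base.suffix == ".hea":
        base = base.with_suffix("")
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = hea.read_text().splitlines()
    meta = _parse_meta([ln for ln in lines if ln.startswith("#")])
    head = lines[0].split()
    n_sig, fs, n_samples = int(head[1]), float(head[2]), int(head[3])
    if n_sig != 12:
        raise MalformedRecordError(f"malformed record: {n_sig} signals, expected 12")
    lead_names, gains = [], []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        gain_spec = parts[2].split("/")[0]
        gains.append(float(gain_spec.split("(")[0]))
        lead_names.append(parts[-1])
    raw = np.frombuffer(base.with_suffix(".dat").read_bytes(), dtype="<i2")
    sig = raw.reshape(n_samples, n_sig).T.astype(np.float32)
    uv = sig * (1000.0 / np.asarray(gains, dtype=np.float32))[:, None]
    return _finish_read(uv, lead_names, meta, resample, fs=fs)


# ---------------------------------------------------------------------------
# cohort assembly and bundle I/O


def assemble_cohort(annotation_csv, records_root=None, check_grid: bool = True,
                    dialect: str | None = None) -> Cohort:
    """Build a :class:`Cohort` from an annotation table plus record files.

    The table needs one row per blood draw with columns
    ``subject_id, sex, arm, protocol, timepoint_h, concentration_pg_ml``
    and three replicate record paths ``record_1..record_3`` (relative to
    ``records_root``, which defaults to the table's directory).
    """
    annotation_csv = Path(annotation_csv)
    root = Path(records_root) if records_root is not None else annotation_csv.parent
    table = pd.read_csv(annotation_csv, comment="#")
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing_cols:
        raise MalformedRecordError(
            f"annotation table missing columns {missing_cols}"
        )
    dup = table.duplicated(subset=["subject_id", "timepoint_h"])
    if dup.any():
        row = table[dup].iloc[0]
        raise DuplicateDrawError(
            f"duplicate draw ({row.subject_id!r}, {row.timepoint_h})"
        )
    samples = []
    for _, row in table.iterrows():
        paths = [row[f"record_{k}"] for k in (1, 2, 3)]
        if any(pd.isna(p) or str(p).strip() == "" for p in paths):
            raise IncompleteTriplicateError(
                f"incomplete triplicate for {row.subject_id!r} @ {row.timepoint_h} h"
            )
        reps = [read_record(root / str(p), dialect=dialect) for p in paths]
        samples.append(CohortSample(
            subject_id=str(row.subject_id), sex=str(row.sex), arm=str(row.arm),
            protocol=str(row.protocol), timepoint_h=float(row.timepoint_h),
            replicates=reps, concentration_pg_ml=float(row.concentration_pg_ml),
        ))
    subjects = (table[["subject_id", "sex", "arm", "protocol"]]
                .astype({"subject_id": str})
                .drop_duplicates("subject_id").reset_index(drop=True))
    cohort = Cohort(samples=samples, subjects=subjects,
                    provenance={"source": str(annotation_csv)})
    if check_grid:
        _check_protocol_grid(cohort)
    return cohort


def _check_protocol_grid(cohort: Cohort) -> None:
    for _, subj in cohort.subjects.iterrows():
        grid = PROTOCOL_GRIDS.get(str(subj.protocol))
        if grid is None:
            raise ValueError(f"unknown protocol {subj.protocol!r}")
        tps = sorted(s.timepoint_h for s in cohort.samples_for(subj.subject_id))
        if tps != sorted(grid):
            raise MalformedRecordError(
                f"subject {subj.subject_id!r} timepoints {tps} do not match "
                f"protocol {subj.protocol} grid"
            )


def annotation_frame(cohort: Cohort, record_paths: dict | None = None) -> pd.DataFrame:
    """Annotation table for ``cohort``; record paths optional placeholders."""
    rows = []
    for i, s in enumerate(cohort.samples):
        paths = (record_paths or {}).get(
            (s.subject_id, s.timepoint_h),
            [f"records/{s.subject_id}_d{i:03d}_r{k}.csv" for k in (1, 2, 3)],
        )
        rows.append({
            "subject_id": s.subject_id, "sex": s.sex, "arm": s.arm,
            "protocol": s.protocol, "timepoint_h": s.timepoint_h,
            "concentration_pg_ml": s.concentration_pg_ml,
            "record_1": paths[0], "record_2": paths[1], "record_3": paths[2],
        })
    return pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))


def write_cohort_bundle(cohort: Cohort, dirpath, ground_truth: pd.DataFrame | None = None) -> Path:
    """Write a cohort as a diffable directory bundle (manifest + CSV records)."""
    dirpath = Path(dirpath)
    (dirpath / "records").mkdir(parents=True, exist_ok=True)
    paths: dict[tuple[str, float], list[str]] = {}
    for i, s in enumerate(cohort.samples):
        rels = []
        for rec in s.replicates:
            rel = f"records/{s.subject_id}_d{i:03d}_r{rec.replicate_index}.csv"
            write_record(rec, dirpath / rel, dialect="bundle")
            rels.append(rel)
        paths[(s.subject_id, s.timepoint_h)] = rels
    annotation_frame(cohort, paths).to_csv(dirpath / "annotation.csv", index=False)
    cohort.subjects.to_csv(dirpath / "subjects.csv", index=False)
    (dirpath / "provenance.json").write_text(
        json.dumps(cohort.provenance, indent=2, default=str) + "\n"
    )
    if ground_truth is not None:
        ground_truth.to_csv(dirpath / "ground_truth.csv", index=False)
    return dirpath


def read_cohort_bundle(dirpath, check_grid: bool = True) -> Cohort:
    dirpath = Path(dirpath)
    cohort = assemble_cohort(dirpath / "annotation.csv", dirpath,
                             check_grid=check_grid)
    prov_path = dirpath / "provenance.json"
    if prov_path.exists():
        cohort.provenance = json.loads(prov_path.read_text())
    return cohort


def read_ground_truth(dirpath) -> pd.DataFrame | None:
    p = Path(dirpath) / "ground_truth.csv"
    return pd.read_csv(p) if p.exists() else None
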