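"""Reading and writing single-lead ECG records in the CinC-2017 WFDB dialect.

Each record is a pair of files sharing a base name: ``<id>.mat`` holding one
sample vector (MATLAB v5, variable ``val``) and a plain-text ``<id>.hea``
header whose first line declares record id, signal count, sampling rate and
sample count.  Reference labels live in a two-column ``REFERENCE.csv``
(record_id,label).  Amplitudes are converted to millivolts when the header
declares a gain (ADC units per mV); without a gain the raw stored unit is
kept and a warning is logged.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import loadmat, savemat

logger = logging.getLogger(__name__)

#: Rhythm classes: normal sinus rhythm, atrial fibrillation, other, noisy.
CLASS_LABELS = ("N", "A", "O", "~")
UNLABELED = "unlabeled"


class RecordError(Exception):
    """Base class for record-parsing failures."""


class MissingRecordFileError(RecordError):
    """The .mat or .hea file of a record does not exist."""


class HeaderParseError(RecordError):
    """The .hea header is malformed."""


class LengthMismatchError(RecordError):
    """Header-declared sample count differs from the .mat payload length."""


@dataclass
class ECGRecord:
    """One single-lead ECG signal.

    Parameters
    ----------
    record_id : str
        Identifier, also the file base name on disk.
    fs : float
        Sampling rate in Hz (300 for CinC 2017).
    samples : numpy.ndarray
        1-D array of amplitudes (mV when a gain was available).
    label : str
        One of ``N``, ``A``, ``O``, ``~`` or ``"unlabeled"``.
    meta : dict
        Free-form provenance (generator seed, realized SNR, ...).
    """

    record_id: str
    fs: float
    samples: np.ndarray
    label: str = UNLABELED
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.label not in CLASS_LABELS and self.label != UNLABELED:
            raise ValueError(f"unknown label {self.label!r}")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class DatasetManifest:
    """Per-record bookkeeping: id, length in samples, label."""

    entries: pd.DataFrame  # columns: record_id, length, label

    COLUMNS = ("record_id", "length", "label")

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, int, str]]) -> "DatasetManifest":
        df = pd.DataFrame(list(rows), columns=list(cls.COLUMNS))
        return cls(df.astype({"length": int}))

    @property
    def class_counts(self) -> dict[str, int]:
        counts = self.entries["label"].value_counts().to_dict()
        return {str(k): int(v) for k, v in counts.items()}

    def __len__(self) -> int:
        return len(self.entries)

    def to_csv(self, path: str | Path) -> None:
        self.entries.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DatasetManifest":
        df = pd.read_csv(path, dtype={"record_id": str, "label": str})
        return cls(df[list(cls.COLUMNS)].astype({"length": int}))


def write_record(record: ECGRecord, directory: str | Path) -> Path:
    """Write ``record`` as a CinC-dialect .mat/.hea pair; returns the base path.

    Generator output is stored as float64 mV with unit gain so that a
    write/read round-trip is bit-exact.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = directory / record.record_id
    savemat(str(base) + ".mat", {"val": record.samples[np.newaxis, :]})
    n = record.samples.size
    header = (
        f"{record.record_id} 1 {record.fs:g} {n}\n"
        f"{record.record_id}.mat 16+24 1/mV 16 0 0 0 0 ECG\n"
    )
    (base.with_suffix(".hea")).write_text(header)
    return base


def _parse_header(hea_path: Path) -> tuple[str, float, int, float | None]:
    """Return (record_id, fs, n_samples, gain-or-None) from a .hea file."""
    lines = [ln for ln in hea_path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise HeaderParseError(f"{hea_path}: empty header")
    head = lines[0].split()
    if len(head) < 4:
        raise HeaderParseError(f"{hea_path}: record line has {len(head)} fields, need 4")
    try:
        record_id = head[0]
        fs = float(head[2])
        n_samples = int(head[3])
    except ValueError as exc:
        raise HeaderParseError(f"{hea_path}: {exc}") from exc
    gain: float | None = None
    if len(lines) > 1:
        sig = lines[1].split()
        if len(sig) >= 3:
            gain_field = sig[2].split("(")[0].split("/")[0]
            try:
                gain = float(gain_field)
            except ValueError:
                gain = None
    return record_id, fs, n_samples, gain


def read_record(base_path: str | Path, label: str = UNLABELED) -> ECGRecord:
    """Read a .mat/.hea pair given the shared base path (extension ignored).

    Raises
    ------
    MissingRecordFileError, HeaderParseError, LengthMismatchError
    """
    base = Path(base_path)
    if base.suffix in (".mat", ".hea"):
        base = base.with_suffix("")
    hea, mat = base.with_suffix(".hea"), base.with_suffix(".mat")
    for p in (hea, mat):
        if not p.exists():
            raise MissingRecordFileError(str(p))
    record_id, fs, n_samples, gain = _parse_header(hea)
    payload = loadmat(str(mat))
    arrays = [v for k, v in payload.items() if not k.startswith("__")]
    if not arrays:
        raise HeaderParseError(f"{mat}: no sample variable found")
    samples = np.asarray(arrays[0]).squeeze()
    if samples.ndim != 1:
        raise HeaderParseError(f"{mat}: expected a single sample vector")
    if samples.size != n_samples:
        raise LengthMismatchError(
            f"{base}: header declares {n_samples} samples, file has {samples.size}"
        )
    if gain is not None and gain > 0:
        if gain != 1.0:
            samples = samples.astype(np.float64) / gain
    else:
        logger.warning("%s: no gain in header; keeping raw amplitude units", record_id)
    return ECGRecord(record_id=record_id, fs=fs, samples=samples, label=label)


def read_reference(path: str | Path) -> dict[str, str]:
    """Read a challenge-style REFERENCE.csv into {record_id: label}."""
    df = pd.read_csv(path, header=None, names=["record_id", "label"], dtype=str)
    return dict(zip(df["record_id"], df["label"]))


def read_dataset(directory: str | Path, reference: str | Path | None = None) -> list[ECGRecord]:
    """Read every .mat/.hea pair under ``directory``; labels from REFERENCE.csv
    if present (or given explicitly)."""
    directory = Path(directory)
    if reference is None:
        candidate = directory / "REFERENCE.csv"
        reference = candidate if candidate.exists() else None
    labels = read_reference(reference) if reference else {}
    records = []
    for hea in sorted(directory.glob("*.hea")):
        base = hea.with_suffix("")
        records.append(read_record(base, label=labels.get(base.name, UNLABELED)))
    return records


def build_manifest(records: Sequence[ECGRecord]) -> DatasetManifest:
    """One manifest entry per record; class counts derive from labels."""
    return DatasetManifest.from_rows(
        (r.record_id, len(r), r.label) for r in records
    )


def filter_records(manifest: DatasetManifest, min_length: int = 9000) -> DatasetManifest:
    """Keep entries with length >= ``min_length`` (inclusive), order preserved.

    The default drops recordings shorter than 9000 samples (30 s at 300 Hz),
    the length floor applied before training.
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    kept = manifest.entries[manifest.entries["length"] >= min_length]
    return DatasetManifest(kept.reset_index(drop=True))
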