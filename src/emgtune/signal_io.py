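"""Reading and writing signals, dataset manifests and feature tables.

Signals are delimited numeric text, one row per sample and one column per
channel (comma- or whitespace-delimited, auto-detected, no header by
default).  Manifests are YAML files listing (path, gesture, subject,
session) per recording; feature tables are CSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, SignalParseError

__all__ = [
    "SignalRecord",
    "ManifestEntry",
    "DatasetManifest",
    "read_signal",
    "write_signal",
    "load_manifest",
    "save_manifest",
    "load_dataset",
    "write_feature_table",
    "read_feature_table",
]

#: reserved label columns appended after the feature columns in CSV tables
LABEL_COLUMNS = ("gesture", "subject", "session")


@dataclass
class SignalRecord:
    """A multi-channel sEMG recording with its acquisition metadata.

    Parameters
    ----------
    samples : ndarray of shape (n_samples, n_channels)
        Raw amplitudes.  Units are treated as opaque; all thresholds
        downstream are configurable in the same units.
    fs : float
        Sampling rate in Hz (2000 Hz for the emulated acquisition).
    channel_names : list of str
    gesture, subject, session : str
        Categorical labels carried through windowing into the feature matrix.
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    gesture: str = ""
    subject: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.ndim != 2 or self.samples.shape[0] < 1 or self.samples.shape[1] < 1:
            raise ValueError("samples must be a non-empty 2-D array [n_samples x n_channels]")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples contain non-finite values")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(self.samples.shape[1])]
        if len(self.channel_names) != self.samples.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[1]} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class ManifestEntry:
    path: str
    gesture: str
    subject: str
    session: str


@dataclass
class DatasetManifest:
    """Ordered list of recordings sharing a sampling rate and channel layout.

    Order is load-bearing: the temporal train/test split downstream respects
    the order in which records (and hence windows) appear.
    """

    entries: list[ManifestEntry]
    fs: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        paths = [e.path for e in self.entries]
        if len(set(paths)) != len(paths):
            raise SchemaError("manifest paths are not unique")


def read_signal(
    path: str | os.PathLike,
    fs: float,
    channel_names: Sequence[str] | None = None,
    *,
    gesture: str = "",
    subject: str = "",
    session: str = "",
    header: bool = False,
) -> SignalRecord:
    """Parse a delimited-text signal file into a :class:`SignalRecord`.

    The delimiter (comma vs. whitespace) is auto-detected per file.  Parse
    failures name the offending 1-based line number.
    """
    path = Path(path)
    if not path.is_file():
        raise SignalParseError(f"signal file not found: {path}")
    rows: list[list[float]] = []
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.strip()
            if not line:
                continue
            parts = line.split(",") if "," in line else line.split()
            try:
                row = [float(p) for p in parts]
            except ValueError:
                raise SignalParseError(
                    f"{path}: non-numeric value on line {lineno}"
                ) from None
            if n_cols is None:
                n_cols = len(row)
            elif len(row) != n_cols:
                raise SignalParseError(
                    f"{path}: ragged row on line {lineno} "
                    f"(expected {n_cols} columns, got {len(row)})"
                )
            rows.append(row)
    if not rows:
        raise SignalParseError(f"{path}: file contains no samples")
    samples = np.asarray(rows, dtype=float)
    if not np.isfinite(samples).all():
        bad = int(np.argwhere(~np.isfinite(samples).all(axis=1))[0, 0]) + 1
        raise SignalParseError(f"{path}: non-finite value on line {bad}")
    if channel_names is not None and len(channel_names) != samples.shape[1]:
        raise SignalParseError(
            f"{path}: {samples.shape[1]} columns but "
            f"{len(channel_names)} channel names declared"
        )
    return SignalRecord(
        samples=samples,
        fs=fs,
        channel_names=list(channel_names) if channel_names is not None else [],
        gesture=gesture,
        subject=subject,
        session=session,
    )


def write_signal(record: SignalRecord, path: str | os.PathLike, fmt: str = "%.6f") -> None:
    """Write a record's samples as comma-delimited text (no header)."""
    np.savetxt(path, record.samples, fmt=fmt, delimiter=",")


def save_manifest(manifest: DatasetManifest, path: str | os.PathLike) -> None:
    doc = {
        "fs": float(manifest.fs),
        "channel_names": list(manifest.channel_names),
        "entries": [
            {"path": e.path, "gesture": e.gesture, "subject": e.subject, "session": e.session}
            for e in manifest.entries
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_manifest(path: str | os.PathLike) -> DatasetManifest:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    for key in ("fs", "channel_names", "entries"):
        if key not in doc:
            raise SchemaError(f"manifest {path} missing required key '{key}'")
    entries = [
        ManifestEntry(
            path=str(e["path"]),
            gesture=str(e["gesture"]),
            subject=str(e.get("subject", "")),
            session=str(e.get("session", "")),
        )
        for e in doc["entries"]
    ]
    return DatasetManifest(entries=entries, fs=float(doc["fs"]), channel_names=list(doc["channel_names"]))


def load_dataset(
    manifest: DatasetManifest, base_dir: str | os.PathLike | None = None
) -> list[SignalRecord]:
    """Load every manifest entry, preserving manifest order."""
    records = []
    for entry in manifest.entries:
        p = Path(entry.path)
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        if not p.is_file():
            raise SignalParseError(f"manifest entry not readable: {p}")
        records.append(
            read_signal(
                p,
                fs=manifest.fs,
                channel_names=manifest.channel_names,
                gesture=entry.gesture,
                subject=entry.subject,
                session=entry.session,
            )
        )
    return records


def write_feature_table(matrix, path: str | os.PathLike) -> None:
    """Serialize a FeatureMatrix to CSV (feature columns, then labels).

    Values are written at full ``repr`` precision so that
    ``read_feature_table(write_feature_table(m))`` reproduces the float64
    payload bit-for-bit.
    """
    df = matrix.to_frame()
    if df.columns.duplicated().any():
        raise SchemaError("feature matrix column names are not unique")
    df.to_csv(path, index=False)


def read_feature_table(path: str | os.PathLike):
    from .features import FeatureMatrix

    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table {path} missing label column(s): {missing}")
    return FeatureMatrix.from_frame(df)
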