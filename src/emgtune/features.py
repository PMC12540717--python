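"""Overlapping-window segmentation and the 17 per-window sEMG features.

Each preprocessed channel is segmented into 256 ms windows overlapping by
25 % of the window length.  Per window, 11 time-domain features (MAV, RMS,
VAR, AAC, DASDV, ZC, WL, WAMP, iEMG, MYOP, LOG) and 6 frequency-domain
features (TP, PKF, FR, MNF, MDF, MNP) are computed from the samples
x_p, p = 1..N and the one-sided periodogram P_k at frequencies f_k.

Feature definitions (x = window samples, d = first differences):

====== =====================================================================
MAV    mean |x_p|
RMS    sqrt(mean x_p^2)
VAR    sum x_p^2 / (N - 1)            (power about zero, not about the mean)
AAC    sum |d_p| / N
DASDV  sqrt(sum d_p^2 / (N - 1))
ZC     count of strict sign changes (x_p * x_{p+1} < 0)
WL     sum |d_p|                       (conventional waveform length; an
                                        ``as_printed`` mode reproduces the
                                        VAR-identical variant)
WAMP   count of |d_p| >= wamp_threshold
iEMG   sum |x_p|
MYOP   fraction of |x_p| >= myop_threshold
LOG    exp(mean log(|x_p| + log_epsilon))
TP     sum P_k
PKF    f_k at argmax P_k               (``as_printed`` mode: TP / 2)
FR     band power [LLC, ULC] / band power [LHC, UHC]
MNF    sum f_k P_k / sum P_k
MDF    first f_k with cumulative power >= TP / 2 (no interpolation)
MNP    TP / M
====== =====================================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import FeatureError, SegmentationError
from .signal_io import LABEL_COLUMNS, SignalRecord

__all__ = [
    "WindowSpec",
    "Window",
    "PowerSpectrum",
    "FeatureConfig",
    "FeatureMatrix",
    "TIME_FEATURE_NAMES",
    "FREQ_FEATURE_NAMES",
    "FEATURE_NAMES",
    "segment",
    "time_features",
    "power_spectrum",
    "freq_features",
    "window_features",
    "extract_feature_matrix",
]

TIME_FEATURE_NAMES = (
    "MAV", "RMS", "VAR", "AAC", "DASDV", "ZC", "WL", "WAMP", "iEMG", "MYOP", "LOG",
)
FREQ_FEATURE_NAMES = ("TP", "PKF", "FR", "MNF", "MDF", "MNP")
FEATURE_NAMES = TIME_FEATURE_NAMES + FREQ_FEATURE_NAMES


@dataclass
class WindowSpec:
    """Sliding-window geometry: window length (ms) and fractional overlap."""

    window_ms: float = 256.0
    overlap_frac: float = 0.25

    def __post_init__(self) -> None:
        if not self.window_ms > 0:
            raise SegmentationError("window_ms must be positive")
        if not 0 <= self.overlap_frac < 1:
            raise SegmentationError("overlap_frac must lie in [0, 1)")

    def window_samples(self, fs: float) -> int:
        w = int(round(self.window_ms * fs / 1000.0))
        if w < 2:
            raise SegmentationError(f"window of {self.window_ms} ms at {fs} Hz is < 2 samples")
        return w

    def step_samples(self, fs: float) -> int:
        w = self.window_samples(fs)
        return w - int(round(self.overlap_frac * w))


@dataclass
class Window:
    """One fixed-length view x_p, p = 1..N of a single channel."""

    values: np.ndarray
    fs: float
    gesture: str = ""
    subject: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 2:
            raise FeatureError("window must contain at least 2 samples")
        if not np.isfinite(self.values).all():
            raise FeatureError("window contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class PowerSpectrum:
    """One-sided power spectrum: power P_k >= 0 at frequencies f_k (Hz)."""

    power: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.power.shape != self.freqs.shape:
            raise FeatureError("power and freqs must have equal length")
        if np.any(self.power < 0):
            raise FeatureError("spectral power must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise FeatureError("frequencies must be strictly increasing")

    @property
    def m(self) -> int:
        return self.power.size


@dataclass
class FeatureConfig:
    """Thresholds, band edges and conventions for the 17 features.

    ``wamp_threshold`` / ``myop_threshold`` are in signal units (default
    0.01).  The frequency-ratio bands default to 10-250 Hz over 250-500 Hz,
    splitting the analysis passband at its midpoint.
    """

    wamp_threshold: float = 0.01
    myop_threshold: float = 0.01
    fr_low_band: tuple[float, float] = (10.0, 250.0)
    fr_high_band: tuple[float, float] = (250.0, 500.0)
    wl_convention: str = "conventional"   # or "as_printed"
    pkf_convention: str = "conventional"  # or "as_printed"
    log_epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.wamp_threshold < 0 or self.myop_threshold < 0:
            raise FeatureError("thresholds must be non-negative")
        llc, ulc = self.fr_low_band
        lhc, uhc = self.fr_high_band
        if not (llc < ulc <= lhc < uhc):
            raise FeatureError("frequency-ratio bands must satisfy LLC < ULC <= LHC < UHC")
        if not self.log_epsilon > 0:
            raise FeatureError("log_epsilon must be positive")
        if self.wl_convention not in ("conventional", "as_printed"):
            raise FeatureError(f"unknown wl_convention {self.wl_convention!r}")
        if self.pkf_convention not in ("conventional", "as_printed"):
            raise FeatureError(f"unknown pkf_convention {self.pkf_convention!r}")


def segment(record: SignalRecord, spec: WindowSpec) -> list[list[Window]]:
    """Cut a record into aligned per-channel windows.

    Returns a list over window positions; each element is the list of
    per-channel :class:`Window` objects sharing that start index.  Window
    length W = round(window_ms * fs / 1000), step = W - round(overlap * W);
    a trailing remainder shorter than W is discarded.
    """
    w = spec.window_samples(record.fs)
    step = spec.step_samples(record.fs)
    n = record.n_samples
    if n < w:
        raise SegmentationError(
            f"record of {n} samples is shorter than one {w}-sample window"
        )
    out: list[list[Window]] = []
    for start in range(0, n - w + 1, step):
        out.append(
            [
                Window(
                    values=record.samples[start : start + w, c],
                    fs=record.fs,
                    gesture=record.gesture,
                    subject=record.subject,
                    session=record.session,
                )
                for c in range(record.n_channels)
            ]
        )
    return out


def time_features(w: Window, cfg: FeatureConfig | None = None) -> dict[str, float]:
    """The 11 time-domain features of one window."""
    cfg = cfg or FeatureConfig()
    x = w.values
    n = x.size
    absx = np.abs(x)
    d = np.diff(x)
    absd = np.abs(d)

    feats = {
        "MAV": absx.mean(),
        "RMS": float(np.sqrt(np.mean(x * x))),
        "VAR": float(np.sum(x * x) / (n - 1)),
        "AAC": float(absd.sum() / n),
        "DASDV": float(np.sqrt(np.sum(d * d) / (n - 1))),
        "ZC": float(np.count_nonzero(x[:-1] * x[1:] < 0)),
        "WAMP": float(np.count_nonzero(absd >= cfg.wamp_threshold)),
        "iEMG": float(absx.sum()),
        "MYOP": float(np.count_nonzero(absx >= cfg.myop_threshold) / n),
        "LOG": float(np.exp(np.mean(np.log(absx + cfg.log_epsilon)))),
    }
    if cfg.wl_convention == "conventional":
        feats["WL"] = float(absd.sum())
    else:  # as printed: identical to VAR
        feats["WL"] = feats["VAR"]
    feats["MAV"] = float(feats["MAV"])
    return {name: feats[name] for name in TIME_FEATURE_NAMES}


def power_spectrum(w: Window) -> PowerSpectrum:
    """One-sided periodogram (rectangular taper, mean-detrended).

    Scaling is such that sum(P_k) equals the mean square of the detrended
    window (Parseval consistency).
    """
    freqs, p = sps.periodogram(
        w.values, fs=w.fs, window="boxcar", detrend="constant", scaling="spectrum"
    )
    return PowerSpectrum(power=p, freqs=freqs)


def freq_features(s: PowerSpectrum, cfg: FeatureConfig | None = None) -> dict[str, float]:
    """The 6 frequency-domain features of one power spectrum.

    An all-zero spectrum makes MNF/MDF/FR undefined; they are reported as
    NaN sentinels with a warning.  A nonzero spectrum whose high FR band
    holds zero power raises :class:`FeatureError`.
    """
    cfg = cfg or FeatureConfig()
    p = s.power
    f = s.freqs
    tp = float(p.sum())
    m = s.m
    feats: dict[str, float] = {"TP": tp, "MNP": tp / m}

    if cfg.pkf_convention == "conventional":
        feats["PKF"] = float(f[int(np.argmax(p))])
    else:  # as printed: (1/2) sum P_k
        feats["PKF"] = tp / 2.0

    if tp == 0.0:
        warnings.warn("all-zero spectrum: MNF/MDF/FR undefined, reporting NaN")
        feats.update({"FR": np.nan, "MNF": np.nan, "MDF": np.nan})
        return {name: feats[name] for name in FREQ_FEATURE_NAMES}

    feats["MNF"] = float((f * p).sum() / tp)
    cum = np.cumsum(p)
    feats["MDF"] = float(f[int(np.searchsorted(cum, tp / 2.0))])

    llc, ulc = cfg.fr_low_band
    lhc, uhc = cfg.fr_high_band
    low = float(p[(f >= llc) & (f <= ulc)].sum())
    high = float(p[(f >= lhc) & (f <= uhc)].sum())
    if high == 0.0:
        raise FeatureError("zero power in FR high band; frequency ratio undefined")
    feats["FR"] = low / high
    return {name: feats[name] for name in FREQ_FEATURE_NAMES}


def window_features(w: Window, cfg: FeatureConfig | None = None) -> dict[str, float]:
    """All 17 features of one window, in canonical order."""
    cfg = cfg or FeatureConfig()
    out = time_features(w, cfg)
    out.update(freq_features(power_spectrum(w), cfg))
    return out


@dataclass
class FeatureMatrix:
    """Windows x features table with per-row gesture/subject/session labels."""

    values: np.ndarray
    columns: list[str]
    gesture: np.ndarray
    subject: np.ndarray
    session: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gesture = np.asarray(self.gesture, dtype=object)
        self.subject = np.asarray(self.subject, dtype=object)
        self.session = np.asarray(self.session, dtype=object)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError("values shape inconsistent with column names")
        n = self.values.shape[0]
        if not (len(self.gesture) == len(self.subject) == len(self.session) == n):
            raise ValueError("label arrays must match row count")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.gesture.tolist()))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df["gesture"] = self.gesture
        df["subject"] = self.subject
        df["session"] = self.session
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        feature_cols = [c for c in df.columns if c not in LABEL_COLUMNS]
        return cls(
            values=df[feature_cols].to_numpy(dtype=float),
            columns=feature_cols,
            gesture=df["gesture"].astype(str).to_numpy(dtype=object),
            subject=df["subject"].astype(str).to_numpy(dtype=object),
            session=df["session"].astype(str).to_numpy(dtype=object),
        )

    def take(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[idx],
            columns=list(self.columns),
            gesture=self.gesture[idx],
            subject=self.subject[idx],
            session=self.session[idx],
        )


def extract_feature_matrix(
    records: list[SignalRecord],
    wspec: WindowSpec | None = None,
    fcfg: FeatureConfig | None = None,
) -> FeatureMatrix:
    """Segment every record and compute the full windows x features table.

    Rows are ordered by (record order, window start); columns are
    channel-major (all 17 features of channel 1, then channel 2, ...),
    named ``<feature>_<channel>``.
    """
    wspec = wspec or WindowSpec()
    fcfg = fcfg or FeatureConfig()
    if not records:
        raise ValueError("no records given")
    n_ch = records[0].n_channels
    ch_names = records[0].channel_names
    for r in records:
        if r.n_channels != n_ch:
            raise ValueError("records have inconsistent channel counts")
        if r.fs != records[0].fs:
            raise ValueError("records have inconsistent sampling rates")

    columns = [f"{feat}_{ch}" for ch in ch_names for feat in FEATURE_NAMES]
    rows, gestures, subjects, sessions = [], [], [], []
    for rec in records:
        for chans in segment(rec, wspec):
            row: list[float] = []
            for w in chans:
                row.extend(window_features(w, fcfg).values())
            rows.append(row)
            gestures.append(rec.gesture)
            subjects.append(rec.subject)
            sessions.append(rec.session)
    return FeatureMatrix(
        values=np.asarray(rows, dtype=float),
        columns=columns,
        gesture=np.asarray(gestures, dtype=object),
        subject=np.asarray(subjects, dtype=object),
        session=np.asarray(sessions, dtype=object),
    )
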