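"""Multi-channel sEMG records: containers, preprocessing, windowing, and disk I/O.

A :class:`SignalRecord` holds one labelled segment of a multi-channel surface-EMG
recording (channels x time).  Preprocessing follows the usual myoelectric-control
chain: band-pass filtering, per-channel standardization, 3-sigma outlier removal,
and fixed-width windowing (sliding windows, the middle third of a contraction, or
the whole segment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy import signal as sps

from .exceptions import (
    DegenerateChannelError,
    InvalidBandError,
    SchemaError,
    TooShortError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SignalRecord",
    "WindowSpec",
    "bandpass_filter",
    "standardize_channels",
    "standardize_dataset",
    "remove_outliers_3sigma",
    "segment_windows",
    "middle_third",
    "save_record",
    "load_record",
    "load_ninapro_mat",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SignalRecord:
    """One labelled multi-channel sEMG segment.

    Parameters
    ----------
    samples
        ``(n_channels, n_samples)`` array, or a list of per-channel 1-D arrays
        of unequal length (only produced by :func:`remove_outliers_3sigma`).
    fs
        Sampling rate in Hz.
    label
        Movement class id; 0 denotes rest.
    repetition
        1-based repetition index.
    subject
        Subject identifier.
    meta
        Free-form annotations.
    """

    samples: np.ndarray | list[np.ndarray]
    fs: float
    label: int = 0
    repetition: int = 1
    subject: str = "s1"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if isinstance(self.samples, np.ndarray):
            self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        else:
            self.samples = [np.asarray(ch, dtype=float).ravel() for ch in self.samples]

    @property
    def ragged(self) -> bool:
        return not isinstance(self.samples, np.ndarray)

    @property
    def n_channels(self) -> int:
        return len(self.samples)

    @property
    def n_samples(self) -> int:
        if self.ragged:
            raise SchemaError("ragged record has per-channel lengths")
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, i: int) -> np.ndarray:
        return self.samples[i]


@dataclass(frozen=True)
class WindowSpec:
    """Windowing specification.

    ``mode`` is one of ``sliding`` (fixed width/step), ``middle_third``
    (central third of the segment) or ``whole`` (the full segment).
    """

    width_ms: float = 400.0
    step_ms: float = 300.0
    mode: str = "sliding"

    def __post_init__(self) -> None:
        if self.mode not in ("sliding", "middle_third", "whole"):
            raise ValueError(f"unknown window mode {self.mode!r}")
        if self.width_ms <= 0 or self.step_ms <= 0:
            raise ValueError("window width and step must be positive")
        if self.mode == "sliding" and self.step_ms > self.width_ms + 1e-9:
            # overlapping or abutting windows only
            raise ValueError("step_ms must not exceed width_ms in sliding mode")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def bandpass_filter(
    record: SignalRecord, low_hz: float, high_hz: float, order: int = 4
) -> SignalRecord:
    """Zero-phase Butterworth band-pass filter.

    ``order`` is the analogue prototype order (an even number); the filter is
    applied forward-backward (``sosfiltfilt``) so the output has no group
    delay, at the cost of doubling the effective attenuation.
    """
    nyq = record.fs / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise InvalidBandError(
            f"band ({low_hz}, {high_hz}) Hz outside (0, {nyq}) Hz"
        )
    if order < 2 or order % 2:
        raise ValueError("order must be even and >= 2")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=record.fs, output="sos")
    # sosfiltfilt needs a minimum signal length for its edge padding
    padlen = 3 * (2 * sos.shape[0] + 1)
    if record.n_samples <= padlen:
        raise TooShortError(
            f"signal of {record.n_samples} samples shorter than filter warm-up ({padlen})"
        )
    filtered = sps.sosfiltfilt(sos, record.samples, axis=1)
    return replace(record, samples=np.ascontiguousarray(filtered))


def standardize_channels(record: SignalRecord, ddof: int = 1) -> SignalRecord:
    """Standardize each channel to zero mean and unit (sample) standard deviation."""
    x = record.samples
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    if np.any(sd <= 0):
        bad = np.where(sd.ravel() <= 0)[0].tolist()
        raise DegenerateChannelError(f"zero-variance channel(s) {bad}")
    return replace(record, samples=(x - mean) / sd)


def standardize_dataset(
    records: Sequence[SignalRecord], ddof: int = 1
) -> list[SignalRecord]:
    """Standardize channels with statistics pooled over all records of a subject.

    Mirrors standardizing the continuous recording before it is cut into
    movement segments: relative amplitude differences between movements are
    preserved, which per-segment standardization would erase.
    """
    if not records:
        return []
    n_ch = records[0].n_channels
    if any(r.n_channels != n_ch for r in records):
        raise SchemaError("records disagree on channel count")
    pooled = np.concatenate([r.samples for r in records], axis=1)
    mean = pooled.mean(axis=1, keepdims=True)
    sd = pooled.std(axis=1, ddof=ddof, keepdims=True)
    if np.any(sd <= 0):
        raise DegenerateChannelError("zero-variance channel in pooled recording")
    return [replace(r, samples=(r.samples - mean) / sd) for r in records]


def remove_outliers_3sigma(record: SignalRecord, ddof: int = 1) -> SignalRecord:
    """Drop samples beyond 3 channel standard deviations (single pass).

    The record should already be standardized.  Removal is per channel, so the
    returned record carries ragged per-channel streams (``record.ragged``).
    More than half of a channel flagged raises a warning log, not an error.
    """
    kept: list[np.ndarray] = []
    for i in range(record.n_channels):
        ch = record.channel(i)
        sd = ch.std(ddof=ddof)
        mask = np.abs(ch) <= 3.0 * sd if sd > 0 else np.ones(ch.shape, bool)
        frac = 1.0 - mask.mean()
        if frac > 0.5:
            logger.warning(
                "suspicious signal: %.0f%% of channel %d flagged by the 3-sigma rule",
                100 * frac, i,
            )
        kept.append(ch[mask])
    out = replace(record, samples=kept)
    out.meta = {**record.meta, "outliers_removed": True}
    return out


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def segment_windows(record: SignalRecord, spec: WindowSpec) -> list[SignalRecord]:
    """Cut a record into windows according to ``spec``.

    Sliding mode: windows of ``width_ms`` starting at multiples of ``step_ms``;
    the count is ``floor((T - W) / S) + 1`` for T >= W.
    """
    if record.ragged:
        raise SchemaError("cannot window a ragged record; remove outliers per window")
    if spec.mode == "whole":
        return [record]
    if spec.mode == "middle_third":
        return [middle_third(record)]
    width = int(round(spec.width_ms * record.fs / 1000.0))
    step = int(round(spec.step_ms * record.fs / 1000.0))
    n = record.n_samples
    if n < width:
        raise TooShortError(f"record of {n} samples shorter than window of {width}")
    starts = range(0, n - width + 1, step)
    out = []
    for k, s in enumerate(starts):
        win = replace(record, samples=record.samples[:, s : s + width].copy())
        win.meta = {**record.meta, "window_index": k, "window_start": s}
        out.append(win)
    return out


def middle_third(record: SignalRecord) -> SignalRecord:
    """Return the central third of a record.

    Uses 1-based sample indices ``floor(n/3)+1 .. floor(2n/3)``, i.e. the
    0-based slice ``[n//3 : (2*n)//3]``; the length is always ``floor(n/3)``
    or ``floor(n/3)+1``.
    """
    if record.ragged:
        raise SchemaError("middle_third requires a rectangular record")
    n = record.n_samples
    if n < 3:
        raise TooShortError(f"record of {n} samples cannot be split into thirds")
    lo, hi = n // 3, (2 * n) // 3
    out = replace(record, samples=record.samples[:, lo:hi].copy())
    out.meta = {**record.meta, "window": "middle_third"}
    return out


# ---------------------------------------------------------------------------
# disk I/O: CSV + YAML sidecar, and the Ninapro MAT adapter
# ---------------------------------------------------------------------------

def save_record(record: SignalRecord, path: str | Path) -> Path:
    """Write a record as CSV (rows = samples, columns = channels) + YAML sidecar."""
    path = Path(path).with_suffix(".csv")
    if record.ragged:
        raise SchemaError("cannot save a ragged record as CSV")
    np.savetxt(path, record.samples.T, delimiter=",")
    meta = {
        "fs": float(record.fs),
        "label": int(record.label),
        "repetition": int(record.repetition),
        "subject": str(record.subject),
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))
    return path


def load_record(path: str | Path) -> SignalRecord:
    """Read a record written by :func:`save_record`."""
    path = Path(path).with_suffix(".csv")
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    return SignalRecord(
        samples=data.T,
        fs=float(meta["fs"]),
        label=int(meta["label"]),
        repetition=int(meta["repetition"]),
        subject=str(meta["subject"]),
    )


def load_ninapro_mat(
    path: str | Path,
    subject: str = "s1",
    use_relabelled: bool = True,
) -> list[SignalRecord]:
    """Split a Ninapro-style MAT file into per-movement-repetition records.

    Expects the variables ``emg`` (samples x channels), ``stimulus`` /
    ``restimulus`` (movement label per sample) and ``repetition`` /
    ``rerepetition``.  Contiguous runs with a constant non-zero label become
    one record each; rest runs are skipped.
    """
    from scipy.io import loadmat

    mat = loadmat(str(path), squeeze_me=True)
    emg = np.asarray(mat["emg"], dtype=float)
    stim_key = "restimulus" if use_relabelled and "restimulus" in mat else "stimulus"
    rep_key = "rerepetition" if use_relabelled and "rerepetition" in mat else "repetition"
    stim = np.asarray(mat[stim_key]).ravel().astype(int)
    rep = np.asarray(mat[rep_key]).ravel().astype(int)
    fs = float(np.asarray(mat.get("frequency", 2000.0)).ravel()[0])
    records = []
    boundaries = np.flatnonzero(np.diff(stim) != 0) + 1
    for start, stop in zip(np.r_[0, boundaries], np.r_[boundaries, len(stim)]):
        label = int(stim[start])
        if label == 0:
            continue
        records.append(
            SignalRecord(
                samples=emg[start:stop].T,
                fs=fs,
                label=label,
                repetition=int(rep[start]) if rep[start] > 0 else 1,
                subject=subject,
            )
        )
    return records
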