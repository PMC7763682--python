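"""R-peak acquisition: two-moving-average QRS detection or supplied annotations.

The detector follows the Elgendi two-moving-average scheme: the signal is
band-passed to the QRS band (8-20 Hz), squared, and smoothed with a short
(QRS-scale, 97.5 ms) and a long (beat-scale, 611 ms) moving average.
Regions where the short average exceeds the long average plus an offset
proportional to the mean squared amplitude are QRS candidate blocks; each
sufficiently wide block yields one peak, snapped to the local absolute
extremum of the input signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import AnnotationSeries, EcgRecord

__all__ = ["RPeakSeries", "detect_rpeaks", "load_rpeaks"]

# Elgendi-style published defaults
_W_QRS_S = 0.0975    # short moving-average window (s)
_W_BEAT_S = 0.611    # long moving-average window (s)
_BETA = 0.08         # offset fraction of the mean squared amplitude
_SNAP_S = 0.040      # peak snapping half-window (s)
_REFRACTORY_S = 0.25


@dataclass(frozen=True)
class RPeakSeries:
    """Strictly increasing R-peak sample indices at sampling rate ``fs``."""

    indices: np.ndarray
    fs: float

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.ndim != 1:
            raise ValueError("indices must be 1-D")
        if idx.size and (np.diff(idx) <= 0).any():
            raise ValueError("R-peak indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)

    @property
    def n(self) -> int:
        return len(self.indices)

    def rr_intervals(self) -> np.ndarray:
        """Successive RR intervals in samples (length n - 1)."""
        return np.diff(self.indices)

    def cycle_rr(self) -> np.ndarray:
        """Per-cycle RR in samples: forward interval; the last cycle
        falls back to its backward interval (length n)."""
        rr = self.rr_intervals()
        if rr.size == 0:
            raise ValueError("need at least 2 R peaks for RR intervals")
        return np.r_[rr, rr[-1]]

    def rr_flags(self) -> np.ndarray:
        """True where an RR interval is physiologically implausible
        (< 0.2 s or > 3 s)."""
        rr_s = self.rr_intervals() / self.fs
        return (rr_s < 0.2) | (rr_s > 3.0)


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    kernel = np.full(w, 1.0 / w)
    return np.convolve(x, kernel, mode="same")


def detect_rpeaks(rec: EcgRecord, channel: int = 0) -> RPeakSeries:
    """Detect R peaks on one channel of a preprocessed record."""
    if rec.duration_s < 5.0:
        raise ValueError(
            f"record of {rec.duration_s:.1f}s is too short for QRS detection (< 5 s)"
        )
    z = rec.samples[:, channel]
    fs = rec.fs

    sos = signal.butter(3, (8.0, 20.0), btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, z)
    y2 = y * y

    w_qrs = max(1, int(round(_W_QRS_S * fs)))
    w_beat = max(w_qrs + 1, int(round(_W_BEAT_S * fs)))
    ma_qrs = _moving_average(y2, w_qrs)
    ma_beat = _moving_average(y2, w_beat)
    thr = ma_beat + _BETA * y2.mean()

    active = ma_qrs > thr
    if not active.any():
        return RPeakSeries(np.empty(0, dtype=np.int64), fs)

    edges = np.diff(active.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if active[0]:
        starts = np.r_[0, starts]
    if active[-1]:
        ends = np.r_[ends, len(active)]

    snap = int(round(_SNAP_S * fs))
    peaks = []
    for a, b in zip(starts, ends):
        if b - a < w_qrs:
            continue
        cand = a + int(np.argmax(y2[a:b]))
        lo, hi = max(0, cand - snap), min(len(z), cand + snap + 1)
        peaks.append(lo + int(np.argmax(np.abs(z[lo:hi]))))

    if not peaks:
        return RPeakSeries(np.empty(0, dtype=np.int64), fs)

    # enforce refractory period, keeping the larger-amplitude peak
    refractory = int(round(_REFRACTORY_S * fs))
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < refractory:
            if abs(z[p]) > abs(z[kept[-1]]):
                kept[-1] = p
        else:
            kept.append(p)
    return RPeakSeries(np.asarray(kept, dtype=np.int64), fs)


def load_rpeaks(ann: AnnotationSeries, rec: EcgRecord) -> RPeakSeries:
    """Convert a provided R-peak annotation series to the record's rate."""
    if ann.kind != "rpeak":
        raise ValueError(f"annotation kind {ann.kind!r} is not 'rpeak'")
    if len(ann) == 0:
        raise ValueError("no R peaks in annotation series")
    idx = np.rint(ann.indices * (rec.fs / ann.fs)).astype(np.int64)
    if (np.diff(idx) <= 0).any():
        raise ValueError("non-monotone R-peak series after rescaling")
    if idx[0] < 0 or idx[-1] >= rec.n_samples:
        raise ValueError("R-peak index out of record bounds")
    return RPeakSeries(idx, rec.fs)
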