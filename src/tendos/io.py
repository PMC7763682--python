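"""Reading, writing and resampling of ECG records and annotations.

Two on-disk dialects are supported for signals:

* **WFDB** (PhysioNet ``.hea``/``.dat``): a minimal reader/writer for
  format-16 (little-endian 16-bit two's complement) single ``.dat``
  records, which covers QT-database style data.
* **CSV**: one header line ``fs=<Hz>``, then one row per sample with
  comma-separated channels.

Annotations travel either as WFDB MIT-format binary annotation files or
as a small CSV dialect.  All sample indices are 0-based throughout.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

__all__ = [
    "EcgRecord",
    "AnnotationSeries",
    "MalformedRecordError",
    "EmptySignalError",
    "read_record",
    "write_record",
    "resample_record",
    "read_annotations",
    "write_annotations",
]


class MalformedRecordError(ValueError):
    """Header or data do not parse under the named standard."""


class EmptySignalError(ValueError):
    """The stored signal has zero length."""


#: longest run of non-finite samples repaired by linear interpolation
MAX_NAN_RUN = 5

# MIT annotation type codes used by this toolkit
_ANN_RPEAK = 1   # NORMAL beat
_ANN_TEND = 40   # ')' waveform offset
_ANN_SKIP = 59
_ANN_CODE = {"rpeak": _ANN_RPEAK, "tend": _ANN_TEND}
_ANN_KIND = {v: k for k, v in _ANN_CODE.items()}


def _repair_nonfinite(x: np.ndarray) -> np.ndarray:
    """Linearly interpolate runs of <= MAX_NAN_RUN non-finite samples."""
    x = np.asarray(x, dtype=float)
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    # run-length check
    idx = np.flatnonzero(bad)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in splits:
        if len(run) > MAX_NAN_RUN:
            raise MalformedRecordError(
                f"non-finite run of {len(run)} samples exceeds "
                f"the repairable maximum of {MAX_NAN_RUN}"
            )
        if run[0] == 0 or run[-1] == len(x) - 1:
            raise MalformedRecordError("non-finite samples at record boundary")
    good = np.flatnonzero(~bad)
    x[bad] = np.interp(np.flatnonzero(bad), good, x[good])
    return x


@dataclass(frozen=True)
class EcgRecord:
    """Uniformly sampled ECG trace.

    Parameters
    ----------
    samples : ndarray, shape (N, n_channels)
        Amplitudes in millivolts.
    fs : float
        Sampling rate in Hz.
    channel_names : tuple of str
    record_id : str
    """

    samples: np.ndarray
    fs: float
    channel_names: tuple = ()
    record_id: str = "record"

    def __post_init__(self):
        s = np.atleast_1d(np.asarray(self.samples, dtype=float))
        if s.ndim == 1:
            s = s[:, None]
        if s.ndim != 2:
            raise ValueError("samples must be 1-D or 2-D (N, n_channels)")
        if s.shape[0] < 1:
            raise EmptySignalError("record has zero samples")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        cols = []
        for c in range(s.shape[1]):
            cols.append(_repair_nonfinite(s[:, c]))
        s = np.column_stack(cols)
        object.__setattr__(self, "samples", s)
        names = tuple(self.channel_names) or tuple(
            f"ch{i + 1}" for i in range(s.shape[1])
        )
        if len(names) != s.shape[1]:
            raise ValueError("channel_names length does not match channel count")
        object.__setattr__(self, "channel_names", names)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, i: int = 0) -> "EcgRecord":
        """Single-channel view of channel ``i`` as a new record."""
        return EcgRecord(
            self.samples[:, i],
            self.fs,
            (self.channel_names[i],),
            self.record_id,
        )

    def with_samples(self, samples: np.ndarray, fs: float | None = None) -> "EcgRecord":
        return EcgRecord(
            samples, self.fs if fs is None else fs, self.channel_names, self.record_id
        )


@dataclass(frozen=True)
class AnnotationSeries:
    """Ordered sample-index annotations (R peaks or T ends), 0-based."""

    kind: str
    indices: np.ndarray
    fs: float
    source: str = "manual"

    def __post_init__(self):
        if self.kind not in ("rpeak", "tend"):
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.ndim != 1:
            raise ValueError("indices must be 1-D")
        if idx.size and (np.diff(idx) <= 0).any():
            raise ValueError("annotation indices must be strictly increasing")
        if idx.size and idx[0] < 0:
            raise ValueError("annotation indices must be non-negative")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AnnotationSeries)
            and self.kind == other.kind
            and self.fs == other.fs
            and np.array_equal(self.indices, other.indices)
        )


# ---------------------------------------------------------------------------
# CSV record dialect: header "fs=<Hz>", comma-separated channels per row
# ---------------------------------------------------------------------------

def _read_csv_record(path: Path) -> EcgRecord:
    with open(path) as fh:
        header = fh.readline().strip()
        m = re.fullmatch(r"fs=([0-9]*\.?[0-9]+)", header)
        if not m:
            raise MalformedRecordError(
                f"CSV record must start with 'fs=<Hz>', got {header!r}"
            )
        fs = float(m.group(1))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # empty payload handled below
                data = np.loadtxt(fh, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise MalformedRecordError(f"bad CSV sample data: {exc}") from exc
    if data.size == 0:
        raise EmptySignalError(f"{path}: zero-length signal")
    return EcgRecord(data, fs, record_id=path.stem)


def _write_csv_record(rec: EcgRecord, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"fs={rec.fs:g}\n")
        np.savetxt(fh, rec.samples, delimiter=",", fmt="%.9g")


# ---------------------------------------------------------------------------
# WFDB format-16 .hea/.dat
# ---------------------------------------------------------------------------

_GAIN_RE = re.compile(
    r"(?P<gain>-?[0-9.]+)(?:\((?P<baseline>-?[0-9]+)\))?(?:/(?P<units>\S+))?"
)


def _read_wfdb_record(path: Path) -> EcgRecord:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise MalformedRecordError(f"{hea}: empty header")
    head = lines[0].split()
    if len(head) < 4:
        raise MalformedRecordError(f"{hea}: record line needs name/nsig/fs/nsamp")
    record_id = head[0]
    try:
        n_sig = int(head[1])
        fs = float(head[2].split("/")[0])
        n_samp = int(head[3])
    except ValueError as exc:
        raise MalformedRecordError(f"{hea}: bad record line: {exc}") from exc
    if n_sig < 1 or len(lines) < 1 + n_sig:
        raise MalformedRecordError(f"{hea}: expected {n_sig} signal lines")
    if n_samp < 1:
        raise EmptySignalError(f"{hea}: zero-length signal")

    dat_names, gains, baselines, names = [], [], [], []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        if len(tok) < 3:
            raise MalformedRecordError(f"{hea}: short signal line {ln!r}")
        dat_names.append(tok[0])
        if tok[1] != "16":
            raise MalformedRecordError(
                f"{hea}: unsupported WFDB signal format {tok[1]!r} (only 16)"
            )
        m = _GAIN_RE.fullmatch(tok[2])
        if not m:
            raise MalformedRecordError(f"{hea}: bad gain spec {tok[2]!r}")
        gains.append(float(m.group("gain")) or 200.0)
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        baselines.append(
            int(m.group("baseline")) if m.group("baseline") is not None else adc_zero
        )
        names.append(tok[8] if len(tok) > 8 else f"ch{len(names) + 1}")
    if len(set(dat_names)) != 1:
        raise MalformedRecordError(f"{hea}: multi-.dat records not supported")

    dat = hea.parent / dat_names[0]
    if not dat.exists():
        raise FileNotFoundError(dat)
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size < n_samp * n_sig:
        raise MalformedRecordError(
            f"{dat}: expected {n_samp * n_sig} samples, found {raw.size}"
        )
    raw = raw[: n_samp * n_sig].reshape(n_samp, n_sig).astype(float)
    phys = (raw - np.asarray(baselines)) / np.asarray(gains)
    return EcgRecord(phys, fs, tuple(names), record_id)


def _write_wfdb_record(rec: EcgRecord, path: Path, gain: float = 1000.0) -> None:
    base = path.with_suffix("")
    hea, dat = base.with_suffix(".hea"), base.with_suffix(".dat")
    adc = np.rint(rec.samples * gain)
    if np.abs(adc).max(initial=0) > 32767:
        raise ValueError("signal amplitude exceeds the 16-bit range at this gain")
    adc = adc.astype("<i2")
    lines = [f"{base.name} {rec.n_channels} {rec.fs:g} {rec.n_samples}"]
    for c, name in enumerate(rec.channel_names):
        first = int(adc[0, c])
        lines.append(
            f"{dat.name} 16 {gain:g}(0)/mV 16 0 {first} 0 0 {name}"
        )
    hea.write_text("\n".join(lines) + "\n")
    adc.reshape(-1).tofile(dat)


# ---------------------------------------------------------------------------
# public record API
# ---------------------------------------------------------------------------

def read_record(path, format: str | None = None) -> EcgRecord:
    """Read an ECG record from ``path``.

    ``format`` is ``"wfdb"`` or ``"csv"``; if omitted it is inferred from
    the file suffix (``.hea``/``.dat`` -> wfdb, ``.csv`` -> csv).
    """
    path = Path(path)
    if format is None:
        format = "wfdb" if path.suffix in (".hea", ".dat", "") else "csv"
    if format == "csv":
        if not path.exists():
            raise FileNotFoundError(path)
        return _read_csv_record(path)
    if format == "wfdb":
        return _read_wfdb_record(path)
    raise ValueError(f"unknown record format {format!r}")


def write_record(rec: EcgRecord, path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix == ".csv" else "wfdb"
    if format == "csv":
        _write_csv_record(rec, path)
    elif format == "wfdb":
        _write_wfdb_record(rec, path)
    else:
        raise ValueError(f"unknown record format {format!r}")


def resample_record(rec: EcgRecord, target_fs: float) -> EcgRecord:
    """Rational-factor polyphase resampling to ``target_fs`` Hz.

    The up/down factors come from the exact (or best rational) ratio
    ``target_fs / fs``, so e.g. 200 -> 250 Hz is the exact 5:4 conversion.
    """
    if not target_fs > 0:
        raise ValueError("target_fs must be positive")
    if target_fs == rec.fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = np.column_stack(
        [resample_poly(rec.samples[:, c], up, down) for c in range(rec.n_channels)]
    )
    return EcgRecord(out, target_fs, rec.channel_names, rec.record_id)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def write_annotations(ann: AnnotationSeries, path, format: str = "csv") -> None:
    """Write an annotation series; ``format`` is ``"csv"`` or ``"wfdb_ann"``."""
    path = Path(path)
    if format == "csv":
        with open(path, "w") as fh:
            fh.write(f"kind={ann.kind},fs={ann.fs:g},source={ann.source}\n")
            for i in ann.indices:
                fh.write(f"{int(i)}\n")
    elif format == "wfdb_ann":
        _write_mit_annotations(ann, path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")


def read_annotations(path, format: str = "csv", fs: float | None = None,
                     shift_one_based: bool = False) -> AnnotationSeries:
    """Read annotations; ``fs`` is required for the WFDB binary format
    (the MIT annotation file does not store a sampling rate).

    ``shift_one_based`` subtracts 1 from every index on import, for
    external files using 1-based sample numbering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        ann = _read_csv_annotations(path)
    elif format == "wfdb_ann":
        if fs is None:
            raise ValueError("fs is required to read WFDB annotation files")
        ann = _read_mit_annotations(path, fs)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if shift_one_based:
        ann = replace(ann, indices=ann.indices - 1)
    return ann


def _read_csv_annotations(path: Path) -> AnnotationSeries:
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(kv.split("=", 1) for kv in header.split(",") if "=" in kv)
        if "kind" not in meta or "fs" not in meta:
            raise MalformedRecordError(
                f"{path}: annotation header must carry kind= and fs="
            )
        idx = [int(ln) for ln in fh if ln.strip()]
    return AnnotationSeries(
        meta["kind"], np.asarray(idx, dtype=np.int64), float(meta["fs"]),
        meta.get("source", "manual"),
    )


def _write_mit_annotations(ann: AnnotationSeries, path: Path) -> None:
    code = _ANN_CODE[ann.kind]
    words = []
    prev = 0
    for i in ann.indices:
        delta = int(i) - prev
        prev = int(i)
        if delta > 1023:
            # SKIP escape: 4-byte interval, high 16 bits first
            words.append(_ANN_SKIP << 10)
            words.append((delta >> 16) & 0xFFFF)
            words.append(delta & 0xFFFF)
            delta = 0
        words.append((code << 10) | delta)
    words.append(0)  # end of file
    np.asarray(words, dtype="<u2").tofile(path)


def _read_mit_annotations(path: Path, fs: float) -> AnnotationSeries:
    words = np.fromfile(path, dtype="<u2")
    idx, kinds = [], set()
    t = 0
    i = 0
    pending_skip = 0
    while i < len(words):
        w = int(words[i])
        code, delta = w >> 10, w & 0x3FF
        if w == 0:
            break
        if code == _ANN_SKIP:
            if i + 2 >= len(words):
                raise MalformedRecordError(f"{path}: truncated SKIP annotation")
            pending_skip = (int(words[i + 1]) << 16) | int(words[i + 2])
            i += 3
            continue
        t += delta + pending_skip
        pending_skip = 0
        if code in _ANN_KIND:
            idx.append(t)
            kinds.add(_ANN_KIND[code])
        i += 1
    if len(kinds) > 1:
        raise MalformedRecordError(f"{path}: mixed annotation kinds")
    kind = kinds.pop() if kinds else "rpeak"
    return AnnotationSeries(kind, np.asarray(idx, dtype=np.int64), fs, "wfdb_ann")
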