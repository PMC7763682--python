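"""T-end signal quality index (tSQI) and R-peak agreement (bSQI).

The tSQI of a segment compares the T-end sequences of two delineators:
with A cycles where both algorithms produced an estimate and B of those
agreeing within a grace period gamma (strictly ``|dt| < gamma``),

    tSQI = B / (2A - B),

which is 1 for perfectly matched sequences and 0 when nothing matches
(defined as 0 when A = 0: no detections is the worst quality state).
The per-cycle tSQI evaluates this on a window of +-``window_before/after``
samples around each R peak; the decision to denoise cycle i is
``tSQI_i < q``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .delineate import TendAnnotation
from .io import EcgRecord
from .rpeaks import RPeakSeries

__all__ = [
    "QualityConfig",
    "TsqiResult",
    "match_tends",
    "compute_tsqi",
    "cycle_tsqi",
    "record_cycle_tsqi",
    "compute_bsqi",
]


@dataclass(frozen=True)
class QualityConfig:
    gamma_ms: float = 50.0    # grace period
    q: float = 0.9            # tSQI threshold below which a cycle is denoised
    window_before: int = 1250  # samples before R for the per-cycle segment
    window_after: int = 1250   # samples after R

    def __post_init__(self):
        if not 0 <= self.q <= 1:
            raise ValueError("q must lie in [0, 1]")
        if not self.gamma_ms > 0:
            raise ValueError("gamma_ms must be positive")


@dataclass(frozen=True)
class TsqiResult:
    A: int
    B: int
    gamma_ms: float
    value: float
    flagged: bool = False  # True when the window held < 2 R peaks


def compute_tsqi(A: int, B: int) -> float:
    """tSQI = B / (2A - B); 0 when A = 0."""
    if B > A or B < 0:
        raise ValueError(f"need 0 <= B <= A, got A={A}, B={B}")
    if A == 0:
        return 0.0
    return B / (2 * A - B)


def match_tends(t1: TendAnnotation, t2: TendAnnotation,
                gamma_ms: float) -> tuple[int, int]:
    """Per-cycle counts (A, B) for two aligned T-end sequences.

    A counts cycles where both detectors produced an estimate; B counts
    those whose estimates differ by strictly less than ``gamma_ms``.
    Pairing is per cycle, never across cycles.
    """
    if len(t1) != len(t2) or not np.array_equal(t1.r_indices, t2.r_indices):
        raise ValueError("annotations are not aligned to the same R-peak series")
    if t1.fs != t2.fs:
        raise ValueError("annotations have different sampling rates")
    both = t1.present & t2.present
    a = int(both.sum())
    dt_ms = np.abs(t1.tend_indices - t2.tend_indices) * 1000.0 / t1.fs
    b = int((both & (dt_ms < gamma_ms)).sum())
    return a, b


def cycle_tsqi(rec: EcgRecord, rp: RPeakSeries, i: int, det1, det2,
               cfg: QualityConfig = QualityConfig()) -> TsqiResult:
    """tSQI of the i-th cycle, evaluated on the segment R(i) +- window.

    ``det1``/``det2`` are callables ``f(rec, rp) -> TendAnnotation``.
    Windows at the record boundary are clipped to the available span; a
    window holding fewer than 2 R peaks yields tSQI 0, flagged.
    """
    r = int(rp.indices[i])
    lo = max(0, r - cfg.window_before)
    hi = min(rec.n_samples, r + cfg.window_after + 1)
    inside = (rp.indices >= lo) & (rp.indices < hi)
    if inside.sum() < 2:
        return TsqiResult(0, 0, cfg.gamma_ms, 0.0, flagged=True)
    seg = rec.with_samples(rec.samples[lo:hi])
    seg_rp = RPeakSeries(rp.indices[inside] - lo, rp.fs)
    a, b = match_tends(det1(seg, seg_rp), det2(seg, seg_rp), cfg.gamma_ms)
    return TsqiResult(a, b, cfg.gamma_ms, compute_tsqi(a, b))


def record_cycle_tsqi(t1: TendAnnotation, t2: TendAnnotation, rp: RPeakSeries,
                      cfg: QualityConfig = QualityConfig(),
                      n_samples: int | None = None) -> list[TsqiResult]:
    """Per-cycle tSQI for every cycle from two full-record annotations.

    Equivalent to calling :func:`cycle_tsqi` per cycle — every detector
    estimate depends only on samples inside its own cycle's search
    window — but runs the delineators once instead of once per window.
    """
    if len(t1) != len(t2) or not np.array_equal(t1.r_indices, t2.r_indices):
        raise ValueError("annotations are not aligned to the same R-peak series")
    r = rp.indices
    n = n_samples if n_samples is not None else (int(r[-1]) + cfg.window_after + 1)
    both = t1.present & t2.present
    dt_ms = np.abs(t1.tend_indices - t2.tend_indices) * 1000.0 / t1.fs
    matched = both & (dt_ms < cfg.gamma_ms)
    out = []
    for i in range(rp.n):
        lo = max(0, int(r[i]) - cfg.window_before)
        hi = min(n, int(r[i]) + cfg.window_after + 1)
        j0, j1 = np.searchsorted(r, lo), np.searchsorted(r, hi)
        if j1 - j0 < 2:
            out.append(TsqiResult(0, 0, cfg.gamma_ms, 0.0, flagged=True))
            continue
        a = int(both[j0:j1].sum())
        b = int(matched[j0:j1].sum())
        out.append(TsqiResult(a, b, cfg.gamma_ms, compute_tsqi(a, b)))
    return out


def compute_bsqi(r1: RPeakSeries, r2: RPeakSeries, gamma_ms: float = 50.0) -> float:
    """bSQI: greedy one-to-one nearest matching of two R-peak series.

    A = max(n1, n2); B = matched pairs within the grace period (strict);
    returns B / (2A - B), 0 when both series are empty.
    """
    if r1.fs != r2.fs:
        raise ValueError("R-peak series have different sampling rates")
    a = max(r1.n, r2.n)
    if a == 0:
        return 0.0
    gamma = gamma_ms * r1.fs / 1000.0
    x, y = r1.indices, r2.indices
    pairs = []
    for i, xi in enumerate(x):
        j0 = np.searchsorted(y, xi - gamma)
        j1 = np.searchsorted(y, xi + gamma, side="right")
        for j in range(j0, j1):
            d = abs(int(xi) - int(y[j]))
            if d < gamma:
                pairs.append((d, i, j))
    pairs.sort()
    used_i: set[int] = set()
    used_j: set[int] = set()
    b = 0
    for _, i, j in pairs:
        if i not in used_i and j not in used_j:
            used_i.add(i)
            used_j.add(j)
            b += 1
    return compute_tsqi(a, b)
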