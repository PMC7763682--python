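"""Per-cycle template library and optimal singular-value shrinkage.

Each cardiac cycle is cut into a fixed-length segment around its R peak
(window from the 95% RR-interval quantile), forming a template library.
For a low-quality cycle, its xi nearest neighbours (by RR-interval
difference or l2 distance) are stacked into a p x (xi+1) data matrix
S = X + N, where X is low-rank (the shared PQRST morphology) and N is
i.i.d. noise.  Under this spike model the operator-norm optimal shrinker

    eta*(y) = sqrt((y^2 - beta - 1 + sqrt((y^2 - beta - 1)^2 - 4 beta)) / 2)
              for y >= 1 + sqrt(beta),  else 0

applied to the noise-normalized singular values y = lambda / (sigma sqrt(m))
(m the larger matrix dimension, beta = smaller/larger) recovers X
optimally in the large-matrix limit; the first column of the shrunk
matrix is the denoised cycle.

The noise level sigma is estimated once per record from the deviation of
every library segment from the per-coordinate median template.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import EcgRecord
from .rpeaks import RPeakSeries

__all__ = [
    "TemplateLibrary",
    "ShrinkageConfig",
    "ShrinkOutcome",
    "build_library",
    "cycle_distance",
    "select_neighbors",
    "estimate_sigma",
    "eta_star",
    "shrink_matrix",
    "denoise_cycle",
    "denoise_library",
]


@dataclass(frozen=True)
class ShrinkageConfig:
    xi: int = 19          # neighbour count
    metric: str = "rri"   # {"rri", "l2"}

    def __post_init__(self):
        if self.xi < 1:
            raise ValueError("xi must be >= 1")
        if self.metric not in ("rri", "l2"):
            raise ValueError(f"metric must be 'rri' or 'l2', got {self.metric!r}")


@dataclass(frozen=True)
class TemplateLibrary:
    """Fixed-length per-cycle segments.

    ``segments`` has shape (n_lib, p); ``cycle_index_map[j]`` is the
    cardiac-cycle number of library row j (cycles whose window exceeds
    the record bounds are excluded).  ``rr`` carries each included
    cycle's RR interval in samples (forward; backward for the last).
    """

    segments: np.ndarray
    w: int
    Lw: int
    Rw: int
    cycle_index_map: np.ndarray
    rr: np.ndarray
    fs: float

    @property
    def p(self) -> int:
        return self.segments.shape[1]

    @property
    def n(self) -> int:
        return self.segments.shape[0]


@dataclass(frozen=True)
class ShrinkOutcome:
    denoised_segment: np.ndarray
    sigma_hat: float
    beta: float
    kept_rank: int


def build_library(rec: EcgRecord, rp: RPeakSeries, channel: int = 0) -> TemplateLibrary:
    """Cut one segment per cycle: z[R(i)-Lw .. R(i)+Rw], Lw = Rw = ceil(w/2),
    w = round(95th percentile of RR intervals in samples)."""
    if rp.n < 2:
        raise ValueError("need at least 2 R peaks to build a template library")
    z = rec.samples[:, channel]
    rr_all = rp.cycle_rr()
    w = int(round(float(np.percentile(rp.rr_intervals(), 95))))
    lw = rw = int(np.ceil(w / 2))
    p = lw + rw + 1
    if p < 3:
        raise ValueError("template window degenerate (p < 3)")
    segs, keep = [], []
    for i, r in enumerate(rp.indices):
        a, b = int(r) - lw, int(r) + rw + 1
        if a < 0 or b > len(z):
            continue
        segs.append(z[a:b])
        keep.append(i)
    if len(segs) < 2:
        raise ValueError("fewer than 2 cycles fit inside the record bounds")
    keep = np.asarray(keep, dtype=np.int64)
    return TemplateLibrary(
        np.asarray(segs), w, lw, rw, keep, rr_all[keep], rec.fs
    )


def cycle_distance(lib: TemplateLibrary, a: int, b: int, metric: str = "rri") -> float:
    """Distance between library cycles a and b (library row positions)."""
    if metric == "rri":
        return float(abs(int(lib.rr[a]) - int(lib.rr[b])))
    if metric == "l2":
        return float(np.linalg.norm(lib.segments[a] - lib.segments[b]))
    raise ValueError(f"unknown metric {metric!r}")


def _distances(lib: TemplateLibrary, i: int, metric: str) -> np.ndarray:
    if metric == "rri":
        return np.abs(lib.rr - lib.rr[i]).astype(float)
    diff = lib.segments - lib.segments[i]
    return np.sqrt((diff * diff).sum(axis=1))


def neighbor_order(lib: TemplateLibrary, i: int,
                   cfg: ShrinkageConfig = ShrinkageConfig()) -> np.ndarray:
    """Library rows ordered by distance to row i (ties by cycle index),
    excluding i itself."""
    d = _distances(lib, i, cfg.metric)
    order = np.lexsort((lib.cycle_index_map, d))
    return order[order != i]


def select_neighbors(lib: TemplateLibrary, i: int,
                     cfg: ShrinkageConfig = ShrinkageConfig()) -> np.ndarray:
    """Data matrix S of shape (p, xi+1): column 1 is s_i, the rest the
    xi nearest neighbours."""
    if lib.n < cfg.xi + 1:
        raise ValueError(
            f"library holds {lib.n} cycles; neighbour selection needs "
            f">= {cfg.xi + 1}"
        )
    nbrs = neighbor_order(lib, i, cfg)[: cfg.xi]
    return np.column_stack([lib.segments[i], lib.segments[nbrs].T])


def estimate_sigma(lib: TemplateLibrary) -> float:
    """Noise level: RMS deviation of all segments from the per-coordinate
    median template,
    sigma = sqrt( (1/(n p)) sum_i sum_k (s_i(k) - median_k)^2 )."""
    med = np.median(lib.segments, axis=0)
    dev = lib.segments - med
    return float(np.sqrt((dev * dev).mean()))


def eta_star(y, beta: float):
    """Operator-norm optimal shrinker for noise-normalized singular values.

    Zero below the detection threshold 1 + sqrt(beta) (the noise bulk
    edge); above it, the debiased signal singular value.
    """
    if not 0 < beta <= 1:
        raise ValueError(f"beta must lie in (0, 1], got {beta}")
    y = np.asarray(y, dtype=float)
    if (y < 0).any():
        raise ValueError("singular values must be non-negative")
    out = np.zeros_like(y)
    above = y >= 1 + np.sqrt(beta)
    t = y[above] ** 2 - beta - 1
    out[above] = np.sqrt((t + np.sqrt(t * t - 4 * beta)) / 2)
    return out if out.ndim else float(out)


def shrink_matrix(S: np.ndarray, sigma: float) -> tuple[np.ndarray, int]:
    """Optimal-shrinkage denoising of a data matrix.

    Orients the matrix so rows <= columns, normalizes singular values by
    sigma * sqrt(m) (m the larger dimension), applies eta*, and rebuilds.
    sigma = 0 is a no-op (clean signal).  Returns (S_tilde, kept_rank).
    """
    S = np.asarray(S, dtype=float)
    if not np.isfinite(S).all():
        raise ValueError("data matrix contains non-finite entries")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return S.copy(), min(S.shape)
    transposed = S.shape[0] > S.shape[1]
    X = S.T if transposed else S
    m = X.shape[1]               # larger dimension
    beta = X.shape[0] / X.shape[1]
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    y = s / (sigma * np.sqrt(m))
    eta = eta_star(y, beta)
    out = (u * (sigma * np.sqrt(m) * eta)) @ vt
    kept = int((eta > 0).sum())
    return (out.T if transposed else out), kept


def denoise_cycle(lib: TemplateLibrary, i: int, sigma: float,
                  cfg: ShrinkageConfig = ShrinkageConfig()) -> ShrinkOutcome:
    """Denoise library row i; the first column of the shrunk neighbour
    matrix is the estimate of s_i."""
    S = select_neighbors(lib, i, cfg)
    beta = min(S.shape) / max(S.shape)
    out, kept = shrink_matrix(S, sigma)
    return ShrinkOutcome(out[:, 0], sigma, beta, kept)


def denoise_library(lib: TemplateLibrary, rp: RPeakSeries, flags: np.ndarray,
                    cfg: ShrinkageConfig = ShrinkageConfig()) -> TemplateLibrary:
    """Replace the segments of cycles flagged low-quality by their
    optimal-shrinkage estimates; sigma is estimated once from the full
    library.  ``flags`` is boolean, one entry per cardiac cycle."""
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != (rp.n,):
        raise ValueError("flags must align to the R-peak series")
    sigma = estimate_sigma(lib)
    segs = lib.segments.copy()
    for row, cyc in enumerate(lib.cycle_index_map):
        if flags[cyc]:
            segs[row] = denoise_cycle(lib, row, sigma, cfg).denoised_segment
    return replace(lib, segments=segs)
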