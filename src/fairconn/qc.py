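"""Motion-based frame censoring and Fisher-z functional connectivity.

Implements the frame-level quality control used before computing resting
state functional connectivity (RSFC): frames exceeding a framewise
displacement (FD) or DVARS threshold are censored together with a dilation
window around them, surviving uncensored segments shorter than a minimum
length are censored as well, and runs with more than a maximum fraction of
censored frames are discarded. RSFC is the Pearson correlation of ROI time
series over uncensored frames only, Fisher z-transformed and averaged across
usable runs.

DVARS here is the root mean square of the frame-differenced signal,
``DVARS_i = sqrt(mean_x [I_i(x) - I_{i-1}(x)]^2)``; frame 0 has no
differenced value and is assigned 0 so it never triggers censoring by
itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RunTimeseries",
    "CensorPolicy",
    "HCP_POLICY",
    "ABCD_POLICY",
    "compute_dvars",
    "censor_frames",
    "run_usable",
    "compute_rsfc",
    "vectorize_rsfc",
    "devectorize_rsfc",
    "edge_indices",
]

# atanh is applied after clipping |r| at 1 - this margin; degenerate r = ±1
# otherwise maps to ±inf and poisons run averaging.
_R_CLIP = 1e-7


@dataclass
class RunTimeseries:
    """One fMRI run: frames × ROI signal with per-frame FD/DVARS traces."""

    signal: np.ndarray
    fd: np.ndarray
    dvars: np.ndarray
    mask: np.ndarray | None = None  # True = censored

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, float)
        self.fd = np.asarray(self.fd, float)
        self.dvars = np.asarray(self.dvars, float)
        n = self.signal.shape[0]
        if self.fd.shape != (n,) or self.dvars.shape != (n,):
            raise ValueError("fd and dvars must match the frame count")
        if (self.fd < 0).any() or (self.dvars < 0).any():
            raise ValueError("fd and dvars must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.signal.shape[0]


@dataclass(frozen=True)
class CensorPolicy:
    """Thresholds and dilation/segment rules for frame censoring."""

    fd_threshold: float
    dvars_threshold: float
    n_before: int = 1
    n_after: int = 2
    min_segment: int = 5
    max_censored_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.fd_threshold <= 0 or self.dvars_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.n_before < 0 or self.n_after < 0:
            raise ValueError("dilation counts must be >= 0")
        if self.min_segment < 1:
            raise ValueError("min_segment must be >= 1")
        if not 0 < self.max_censored_fraction <= 1:
            raise ValueError("max_censored_fraction must be in (0, 1]")


HCP_POLICY = CensorPolicy(fd_threshold=0.2, dvars_threshold=75.0)
ABCD_POLICY = CensorPolicy(fd_threshold=0.3, dvars_threshold=50.0)


def compute_dvars(signal: np.ndarray) -> np.ndarray:
    """Per-frame DVARS of a frames × ROI signal matrix."""
    signal = np.asarray(signal, float)
    if signal.ndim != 2 or signal.shape[0] < 2:
        raise ValueError("signal must be a frames x ROI matrix with >= 2 frames")
    diff = np.diff(signal, axis=0)
    dvars = np.sqrt(np.mean(diff**2, axis=1))
    return np.concatenate([[0.0], dvars])


def censor_frames(
    fd: np.ndarray, dvars: np.ndarray, policy: CensorPolicy
) -> np.ndarray:
    """Boolean censoring mask (True = censored).

    Frames with FD or DVARS above threshold are flagged; the flag is dilated
    ``n_before`` frames back and ``n_after`` forward; any surviving
    uncensored segment shorter than ``min_segment`` contiguous frames is then
    censored too. Deterministic function of the traces, hence idempotent.
    """
    fd = np.asarray(fd, float)
    dvars = np.asarray(dvars, float)
    if fd.shape != dvars.shape or fd.ndim != 1:
        raise ValueError("fd and dvars must be equal-length 1-d traces")
    n = fd.size
    base = (fd > policy.fd_threshold) | (dvars > policy.dvars_threshold)
    mask = base.copy()
    for i in np.flatnonzero(base):
        lo = max(0, i - policy.n_before)
        hi = min(n, i + policy.n_after + 1)
        mask[lo:hi] = True
    return _censor_short_segments(mask, policy.min_segment)


def _censor_short_segments(mask: np.ndarray, min_segment: int) -> np.ndarray:
    mask = mask.copy()
    n = mask.size
    i = 0
    while i < n:
        if not mask[i]:
            j = i
            while j < n and not mask[j]:
                j += 1
            if j - i < min_segment:
                mask[i:j] = True
            i = j
        else:
            i += 1
    return mask


def run_usable(mask: np.ndarray, policy: CensorPolicy) -> bool:
    """A run is discarded only when *more than* ``max_censored_fraction`` of
    its frames are censored (exactly half censored under the 0.5 default is
    still usable)."""
    mask = np.asarray(mask, bool)
    if mask.size == 0:
        return True
    return not (mask.mean() > policy.max_censored_fraction)


def _masked_correlation(signal: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    keep = signal if mask is None else signal[~np.asarray(mask, bool)]
    if keep.shape[0] < 3:
        raise ValueError("fewer than 3 uncensored frames in run")
    sd = keep.std(axis=0)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance ROI(s) in uncensored frames: {bad.tolist()}")
    return np.corrcoef(keep, rowvar=False)


def compute_rsfc(
    runs: list[RunTimeseries], policy: CensorPolicy | None = None
) -> np.ndarray:
    """ROI × ROI Fisher-z RSFC averaged over usable runs.

    When ``policy`` is given, each run without a precomputed mask is censored
    by it and runs failing :func:`run_usable` are dropped. Censored frames are
    ignored in the correlation; correlations are clipped to ±(1 - 1e-7)
    before atanh; the diagonal is set to 0.
    """
    if not runs:
        raise ValueError("no runs supplied")
    zs = []
    for run in runs:
        mask = run.mask
        if mask is None and policy is not None:
            mask = censor_frames(run.fd, run.dvars, policy)
        if policy is not None and mask is not None and not run_usable(mask, policy):
            continue
        r = _masked_correlation(run.signal, mask)
        r = np.clip(r, -1 + _R_CLIP, 1 - _R_CLIP)
        zs.append(np.arctanh(r))
    if not zs:
        raise ValueError("no usable runs after censoring")
    z = np.mean(zs, axis=0)
    z = (z + z.T) / 2
    np.fill_diagonal(z, 0.0)
    return z


def edge_indices(n_roi: int) -> tuple[np.ndarray, np.ndarray]:
    """(row, col) indices of the strict lower triangle in column-major order
    — the fixed edge ordering used by every FC vector in this package."""
    rows, cols = np.tril_indices(n_roi, k=-1)
    order = np.lexsort((rows, cols))
    return rows[order], cols[order]


def vectorize_rsfc(matrix: np.ndarray) -> np.ndarray:
    """Strict lower-triangular entries of a square symmetric matrix, in
    column-major order; length p(p-1)/2."""
    matrix = np.asarray(matrix, float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    rows, cols = edge_indices(matrix.shape[0])
    return matrix[rows, cols]


def devectorize_rsfc(vector: np.ndarray, diagonal: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_rsfc` (symmetric, given diagonal)."""
    vector = np.asarray(vector, float)
    p_float = (1 + np.sqrt(1 + 8 * vector.size)) / 2
    p = int(round(p_float))
    if p * (p - 1) // 2 != vector.size:
        raise ValueError(f"vector length {vector.size} is not p(p-1)/2 for integer p")
    out = np.full((p, p), 0.0)
    rows, cols = edge_indices(p)
    out[rows, cols] = vector
    out = out + out.T
    np.fill_diagonal(out, diagonal)
    return out
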