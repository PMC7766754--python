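"""Signal labeling: map a raw signal onto its expected signal with DTW.

Preparing supervised training pairs requires knowing, for every raw sample,
which expected 6-mer level it measures.  Classical dynamic time warping with
local cost |a_i - b_j| and steps {(1,0), (0,1), (1,1)} provides that mapping
exactly at desk scale; an optional band around the resampled diagonal bounds
the search for long reads.  Both signals are z-scored before warping so the
alignment is scale-free.

Ties in the dynamic program are broken deterministically: diagonal first,
then the step that consumes the first (raw) signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import BandError, ValidationError
from .pore_model import ExpectedSignal
from .synthesis import zscore_normalize
from .training import TrainingPair

_INF = np.inf


@njit(cache=True)
def _dtw_fill(a, b, radius):  # pragma: no cover - exercised via dtw_path
    n, m = len(a), len(b)
    D = np.full((n, m), _INF)
    slope = (m - 1) / (n - 1) if n > 1 else 0.0
    for i in range(n):
        if radius < 0:
            j_lo, j_hi = 0, m - 1
        else:
            center = i * slope
            j_lo = max(0, int(np.ceil(center - radius)))
            j_hi = min(m - 1, int(np.floor(center + radius)))
        for j in range(j_lo, j_hi + 1):
            cost = abs(a[i] - b[j])
            if i == 0 and j == 0:
                D[i, j] = cost
            elif i == 0:
                D[i, j] = cost + D[i, j - 1]
            elif j == 0:
                D[i, j] = cost + D[i - 1, j]
            else:
                best = D[i - 1, j - 1]
                if D[i - 1, j] < best:
                    best = D[i - 1, j]
                if D[i, j - 1] < best:
                    best = D[i, j - 1]
                D[i, j] = cost + best
    return D


@njit(cache=True)
def _dtw_backtrack(D):  # pragma: no cover - exercised via dtw_path
    n, m = D.shape
    # path length is at most n + m - 1
    path = np.empty((n + m - 1, 2), dtype=np.int64)
    k = path.shape[0]
    i, j = n - 1, m - 1
    while True:
        k -= 1
        path[k, 0] = i
        path[k, 1] = j
        if i == 0 and j == 0:
            break
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag = D[i - 1, j - 1]
            up = D[i - 1, j]      # consumes a
            left = D[i, j - 1]    # consumes b
            best = min(diag, up, left)
            if diag == best:      # prefer diagonal, then the a-consuming step
                i -= 1
                j -= 1
            elif up == best:
                i -= 1
            else:
                j -= 1
    return path[k:]


@dataclass(frozen=True)
class WarpPath:
    """Monotone, continuous alignment path between two signals (0-based)."""

    steps: np.ndarray  # (L, 2) int indices into (a, b)
    total_cost: float

    def __post_init__(self) -> None:
        steps = np.asarray(self.steps, dtype=int)
        object.__setattr__(self, "steps", steps)
        if steps.ndim != 2 or steps.shape[1] != 2 or steps.shape[0] < 1:
            raise ValidationError("steps must be a non-empty (L, 2) index array")
        if self.total_cost < 0:
            raise ValidationError("total_cost must be >= 0")
        if tuple(steps[0]) != (0, 0):
            raise ValidationError("path must start at (0, 0)")
        d = np.diff(steps, axis=0)
        if np.any(d < 0) or np.any(d > 1) or np.any(d.sum(axis=1) < 1):
            raise ValidationError("path steps must increment i, j or both by 1")

    def __len__(self) -> int:
        return len(self.steps)


# above this many raw samples a band keeps the dynamic program affordable
DEFAULT_BAND_THRESHOLD = 50_000
DEFAULT_BAND_RADIUS = 1000


def dtw_path(a, b, band_radius: int | None = None) -> WarpPath:
    """Minimum-cost monotone warp between ``a`` and ``b``.

    Local cost |a_i - b_j|; with ``band_radius`` the search is restricted to
    cells within that many columns of the length-rescaled diagonal (the band
    always contains both corners; a radius < 1 cannot connect them).
    """
    a = np.ascontiguousarray(a, dtype=float)
    b = np.ascontiguousarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValidationError("both signals must be non-empty")
    if band_radius is None and max(a.size, b.size) > DEFAULT_BAND_THRESHOLD:
        band_radius = DEFAULT_BAND_RADIUS
    if band_radius is not None and band_radius < 1:
        raise BandError(f"band radius {band_radius} cannot connect the grid corners")
    radius = -1 if band_radius is None else int(band_radius)
    D = _dtw_fill(a, b, radius)
    total = D[-1, -1]
    if not np.isfinite(total):
        raise BandError("band too narrow: the grid corners are not connected")
    steps = _dtw_backtrack(D)
    return WarpPath(steps=steps, total_cost=float(total))


def _first_match_assignment(path: WarpPath, n_raw: int) -> np.ndarray:
    """First expected index DTW matched to each raw index (many-to-one rule)."""
    assign = np.full(n_raw, -1, dtype=int)
    for i, j in path.steps:
        if assign[i] < 0:
            assign[i] = j
    return assign


def warp_raw_to_expected(
    raw,
    expected: ExpectedSignal,
    band_radius: int | None = None,
    scale_refinements: int = 1,
) -> np.ndarray:
    """Expected-signal index assigned to each raw sample by DTW.

    Both signals are z-scored before warping.  Because the raw read's moments
    are dwell-weighted while the expected signal's are not, the two z-scales
    disagree slightly, which can push a whole dwell block onto a neighbouring
    6-mer of nearly equal level.  Each refinement pass therefore re-fits a
    linear map from the matched expected values onto the raw scale (least
    squares over the current assignment) and re-runs the warp; one pass is
    enough in practice.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size < 1:
        raise ValidationError("raw signal must be non-empty")
    raw_n, _ = zscore_normalize(raw)
    exp_n, _ = zscore_normalize(expected.values)
    scaled = exp_n
    assign = None
    for _ in range(scale_refinements + 1):
        path = dtw_path(raw_n, scaled, band_radius=band_radius)
        assign = _first_match_assignment(path, raw.size)
        matched = exp_n[assign]
        design = np.stack([matched, np.ones_like(matched)], axis=1)
        coef, *_ = np.linalg.lstsq(design, raw_n, rcond=None)
        scaled = coef[0] * exp_n + coef[1]
    return assign


def label_read(
    raw,
    expected: ExpectedSignal,
    band_radius: int | None = None,
) -> TrainingPair:
    """Build a supervised pair by warping a raw signal onto its expected signal.

    Each raw position takes the level of the expected index DTW assigns to it
    (see :func:`warp_raw_to_expected`), giving a ground-truth signal with the
    length of the raw read.  Returns TrainingPair(I = z-scored ground truth,
    R = z-scored raw).
    """
    raw = np.asarray(raw, dtype=float)
    assign = warp_raw_to_expected(raw, expected, band_radius=band_radius)
    ground_truth = expected.values[assign]
    I, _ = zscore_normalize(ground_truth)
    R, _ = zscore_normalize(raw)
    return TrainingPair(input=I, target=R, provenance="label_read")
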