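"""Windowed dynamic time warping.

Implements the textbook dynamic program for DTW with a Sakoe–Chiba band:
a local cost matrix (absolute or squared pointwise differences), a banded
cumulative ("global") cost matrix built with the unweighted three-predecessor
recursion

    D(i, j) = c(i, j) + min(D(i-1, j), D(i, j-1), D(i-1, j-1)),

the optimal alignment path recovered by backtracking, and a brute-force
path-enumeration oracle used in tests. The warping window is specified in
seconds and converted to a band half-width in samples by flooring, so a
100 s window at a 2 s sampling interval constrains alignments to
|i - j| <= 50.

Out-of-band cells of the cumulative matrix carry +inf sentinels, which keeps
the recursion branch-free. Distances are exact sums of local costs along the
optimal path; no step weighting or endpoint relaxation is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "DTWConfig",
    "DTWResult",
    "InfeasiblePathError",
    "seconds_to_samples",
    "local_cost_matrix",
    "accumulate_cost",
    "backtrack_path",
    "dtw_distance",
    "brute_force_dtw",
]

_LOCAL_COSTS = ("absolute", "squared")
_STEP_PATTERNS = ("symmetric_min3",)


class InfeasiblePathError(ValueError):
    """No monotone alignment path connects the matrix corners inside the band."""


@dataclass(frozen=True)
class DTWConfig:
    """Configuration of the warping computation.

    Parameters
    ----------
    window_seconds : float or None
        Half-width of the Sakoe–Chiba band in seconds; ``None`` removes the
        band entirely. Default 100 s, the window recommended for BOLD series.
    local_cost : {"absolute", "squared"}
        Pointwise cost between aligned samples. Absolute differences are the
        default.
    step_pattern : {"symmetric_min3"}
        The unweighted three-predecessor recursion. Exposed for future
        variants; only one pattern is implemented.
    """

    window_seconds: float | None = 100.0
    local_cost: str = "absolute"
    step_pattern: str = "symmetric_min3"

    def __post_init__(self) -> None:
        if self.window_seconds is not None and not self.window_seconds >= 0:
            raise ValueError("window_seconds must be >= 0 or None (unbounded)")
        if self.local_cost not in _LOCAL_COSTS:
            raise ValueError(f"local_cost must be one of {_LOCAL_COSTS}")
        if self.step_pattern not in _STEP_PATTERNS:
            raise ValueError(f"step_pattern must be one of {_STEP_PATTERNS}")

    def band(self, dt: float) -> int | None:
        """Band half-width in samples for sampling interval ``dt``."""
        if self.window_seconds is None:
            return None
        return seconds_to_samples(self.window_seconds, dt)


@dataclass(frozen=True)
class DTWResult:
    """Distance (sum of local costs along the optimal path) and, optionally,
    the 0-based alignment path from (0, 0) to (n-1, m-1)."""

    distance: float
    path: tuple[tuple[int, int], ...] | None = field(default=None)


def seconds_to_samples(window_seconds: float, dt: float) -> int:
    """Convert a warping window in seconds to a band half-width in samples.

    The conversion floors, so the band never admits alignments beyond the
    requested window: ``|i - j| <= floor(window_seconds / dt)``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if window_seconds < 0:
        raise ValueError("window_seconds must be >= 0")
    return int(math.floor(window_seconds / dt))


def _as_series(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if arr.size == 0:
        raise ValueError(f"{name} must not be empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must contain only finite values")
    return arr


def local_cost_matrix(a, b, cost: str = "absolute") -> np.ndarray:
    """Pairwise local cost grid: entry (i, j) compares a[i] with b[j]."""
    a = _as_series(a, "a")
    b = _as_series(b, "b")
    if cost not in _LOCAL_COSTS:
        raise ValueError(f"cost must be one of {_LOCAL_COSTS}")
    diff = a[:, None] - b[None, :]
    return np.abs(diff) if cost == "absolute" else diff**2


@njit(cache=False)
def _accumulate_kernel(local, band):  # pragma: no cover - exercised via wrapper
    n, m = local.shape
    D = np.full((n, m), np.inf)
    for i in range(n):
        lo = 0 if band < 0 else max(0, i - band)
        hi = m if band < 0 else min(m, i + band + 1)
        for j in range(lo, hi):
            if i == 0 and j == 0:
                D[0, 0] = local[0, 0]
                continue
            best = np.inf
            if i > 0 and D[i - 1, j] < best:
                best = D[i - 1, j]
            if j > 0 and D[i, j - 1] < best:
                best = D[i, j - 1]
            if i > 0 and j > 0 and D[i - 1, j - 1] < best:
                best = D[i - 1, j - 1]
            if best < np.inf:
                D[i, j] = local[i, j] + best
    return D


def accumulate_cost(local: np.ndarray, band: int | None = None) -> np.ndarray:
    """Banded cumulative cost matrix from a local cost matrix.

    Cells outside the band |i - j| <= band keep a +inf sentinel. Raises
    :class:`InfeasiblePathError` when no path reaches the bottom-right corner,
    which can only happen for unequal lengths with ``|n - m| > band``.
    """
    local = np.ascontiguousarray(local, dtype=np.float64)
    if local.ndim != 2 or local.size == 0:
        raise ValueError("local must be a nonempty 2-D matrix")
    if np.any(local < 0):
        raise ValueError("local costs must be nonnegative")
    if band is not None and band < 0:
        raise ValueError("band must be >= 0 or None")
    D = _accumulate_kernel(local, -1 if band is None else int(band))
    if not np.isfinite(D[-1, -1]):
        raise InfeasiblePathError(
            f"no alignment path for shape {local.shape} within band {band}"
        )
    return D


def backtrack_path(D: np.ndarray) -> tuple[tuple[int, int], ...]:
    """Recover one optimal alignment path from a cumulative cost matrix.

    Ties between predecessors are broken deterministically: diagonal first,
    then vertical (i-1, j), then horizontal (i, j-1). The distance itself is
    unaffected by this rule.
    """
    n, m = D.shape
    i, j = n - 1, m - 1
    path = [(i, j)]
    while (i, j) != (0, 0):
        candidates = []
        if i > 0 and j > 0:
            candidates.append((D[i - 1, j - 1], (i - 1, j - 1)))
        if i > 0:
            candidates.append((D[i - 1, j], (i - 1, j)))
        if j > 0:
            candidates.append((D[i, j - 1], (i, j - 1)))
        # stable min: the first candidate in preference order wins ties
        best_cost = min(c for c, _ in candidates)
        i, j = next(pos for c, pos in candidates if c == best_cost)
        path.append((i, j))
    path.reverse()
    return tuple(path)


def dtw_distance(
    a,
    b,
    config: DTWConfig | None = None,
    dt: float = 2.0,
    return_path: bool = False,
) -> DTWResult:
    """Banded DTW distance between two series sampled at interval ``dt``.

    Parameters
    ----------
    a, b : array-like
        One-dimensional series of length >= 2 with finite values.
    config : DTWConfig
        Warping window, local cost and step pattern; defaults to a 100 s
        window with absolute costs.
    dt : float
        Sampling interval in seconds, used to convert the window to samples.
    return_path : bool
        Also recover the optimal alignment path by backtracking.
    """
    config = config or DTWConfig()
    a = _as_series(a, "a")
    b = _as_series(b, "b")
    if a.size < 2 or b.size < 2:
        raise ValueError("series must have length >= 2")
    band = config.band(dt)
    local = local_cost_matrix(a, b, config.local_cost)
    D = accumulate_cost(local, band)
    path = backtrack_path(D) if return_path else None
    return DTWResult(distance=float(D[-1, -1]), path=path)


def brute_force_dtw(
    a,
    b,
    config: DTWConfig | None = None,
    dt: float = 2.0,
    max_cells: int = 64,
) -> DTWResult:
    """Exact DTW by explicit enumeration of every monotone, band-respecting
    alignment path. Exponential in the series lengths; refuses inputs with
    more than ``max_cells`` grid cells. Intended as an independent oracle for
    the dynamic program, never as the production path.
    """
    config = config or DTWConfig()
    a = _as_series(a, "a")
    b = _as_series(b, "b")
    if a.size < 2 or b.size < 2:
        raise ValueError("series must have length >= 2")
    if a.size * b.size > max_cells:
        raise ValueError(
            f"refusing enumeration for {a.size}x{b.size} > {max_cells} cells"
        )
    band = config.band(dt)
    local = local_cost_matrix(a, b, config.local_cost)
    n, m = local.shape

    def in_band(i: int, j: int) -> bool:
        return band is None or abs(i - j) <= band

    if not in_band(0, 0) or not in_band(n - 1, m - 1):
        raise InfeasiblePathError("corners outside band")

    best = math.inf
    stack = [((0, 0), float(local[0, 0]))]
    while stack:
        (i, j), c = stack.pop()
        if c >= best:
            continue
        if (i, j) == (n - 1, m - 1):
            best = c
            continue
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m and in_band(ni, nj):
                stack.append(((ni, nj), c + float(local[ni, nj])))
    if not math.isfinite(best):
        raise InfeasiblePathError(
            f"no alignment path for shape {(n, m)} within band {band}"
        )
    return DTWResult(distance=best)
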