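"""Robustness matrices, robust ranges, margins, and global ranges.

A feature that fails the robust criteria over the full parameter grid may
still be robust over a *sub-range*. Every start-end pair (i, j), i < j, of
an n-value grid is one *tile*: the robustness metrics recomputed over all
grid values from i to j inclusive. An n-value grid has C(n, 2) tiles —
435 for the 30-value bin-width grid, 496 for the 32-value bin-number grid,
378 for each 28-value voxel-size grid. Tiles meeting the robust criteria
are *robust tiles*; a feature with at least one robust tile is
*conditionally robust*, otherwise *non-robust*.

Two nested intervals summarise a matrix:

* the **robust range**: the largest closed square region of the matrix in
  which *every* contained off-diagonal tile is robust (a contiguity
  requirement that excludes tiles robust only by spurious metric values);
* the **robustness margin**: the outermost grid values touched by at least
  one robust tile anywhere in the matrix.

A **global robustness range** for a scenario aggregates the margins of its
conditionally robust features into a per-grid-value histogram and takes the
longest contiguous run of values whose count reaches at least half of those
features.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from math import comb, ceil
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import ParameterGrid, RobustCriteria
from .io import FeatureTable
from .metrics import RobustnessMetrics, is_robust, metrics_from_matrix

__all__ = [
    "ConditionalCategory",
    "RobustnessMatrix",
    "RobustnessRange",
    "GlobalRangeResult",
    "n_range_tiles",
    "compute_robustness_matrix",
    "derive_robust_range",
    "derive_margin",
    "classify_conditional",
    "aggregate_global_range",
    "matrix_to_frame",
]

logger = logging.getLogger("radrobust")


class ConditionalCategory(str, enum.Enum):
    CONDITIONALLY_ROBUST = "conditionally_robust"
    NON_ROBUST = "non_robust"


def n_range_tiles(n_parameters: int) -> int:
    """Number of distinct start-end ranges on an n-value grid: C(n, 2)."""
    if n_parameters < 2:
        raise ValueError("need at least 2 parameters to form a range")
    return comb(n_parameters, 2)


@dataclass
class RobustnessMatrix:
    """Upper-triangular tile metrics and robust mask for one feature."""

    feature_name: str
    grid: ParameterGrid
    tiles: dict[tuple[int, int], RobustnessMetrics]
    robust_mask: dict[tuple[int, int], bool]

    def robust_tiles(self) -> list[tuple[int, int]]:
        return sorted(k for k, v in self.robust_mask.items() if v)


@dataclass
class RobustnessRange:
    """Robust range nested inside a robustness margin, in grid indices.

    ``robust_range`` and ``margin`` are inclusive index intervals
    ``(a, b)`` with a < b, or None when no robust tile exists. Parameter
    units are available through :meth:`in_units`.
    """

    feature_name: str
    grid: ParameterGrid
    robust_range: tuple[int, int] | None
    margin: tuple[int, int] | None
    category: ConditionalCategory

    def __post_init__(self) -> None:
        if self.robust_range is not None:
            a, b = self.robust_range
            c, d = self.margin
            if not (c <= a < b <= d):
                raise ValueError("robust range must nest inside the margin")

    def in_units(
        self, which: str = "robust_range"
    ) -> tuple[float, float] | None:
        interval = getattr(self, which)
        if interval is None:
            return None
        a, b = interval
        return self.grid.values[a], self.grid.values[b]


@dataclass
class GlobalRangeResult:
    """Scenario-level parameter range recovering >= half the conditionally
    robust features."""

    grid: ParameterGrid
    n_conditionally_robust: int
    cutoff: int
    histogram_margin: np.ndarray
    histogram_robust_range: np.ndarray
    global_range: tuple[int, int]
    argmax_values_margin: list[float]
    argmax_values_robust_range: list[float]

    def in_units(self) -> tuple[float, float]:
        a, b = self.global_range
        return self.grid.values[a], self.grid.values[b]


def compute_robustness_matrix(
    table: FeatureTable,
    feature: str,
    grid: ParameterGrid,
    criteria: RobustCriteria = RobustCriteria(),
) -> RobustnessMatrix:
    """Metrics for every inclusive sub-range (i, j), i < j, of the grid.

    Each tile's CV_mean and r_rm are recomputed over *all* grid values k
    with i <= k <= j, per subject, not just the two endpoints. Requires a
    complete scenario (errors list the missing cells).
    """
    values = table.wide(feature, grid).to_numpy()  # raises on missing cells
    xs = np.asarray(grid.values)
    n = grid.n
    tiles: dict[tuple[int, int], RobustnessMetrics] = {}
    mask: dict[tuple[int, int], bool] = {}
    for i in range(n - 1):
        for j in range(i + 1, n):
            m = metrics_from_matrix(values, xs, i, j)
            tiles[(i, j)] = m
            mask[(i, j)] = is_robust(m, criteria)
    logger.info(
        "matrix %s/%s: %d/%d robust tiles",
        feature,
        grid.name,
        sum(mask.values()),
        len(mask),
    )
    return RobustnessMatrix(feature, grid, tiles, mask)


def derive_robust_range(
    matrix: RobustnessMatrix,
) -> tuple[int, int] | None:
    """Largest index interval [a, b] whose every contained tile is robust.

    Equivalent to run-length encoding the robust mask along rows and
    columns and extracting the largest closed square touching the diagonal.
    Ties between equal-length intervals break toward larger parameter
    values. None when no interval of at least two grid values exists.
    """
    n = matrix.grid.n
    mask = matrix.robust_mask
    # ok[a][b]: every tile within [a, b] robust; dynamic programme over
    # interval length — ok(a,b) = ok(a,b-1) & ok(a+1,b) & mask(a,b)
    ok = np.zeros((n, n), dtype=bool)
    for length in range(1, n):
        for a in range(0, n - length):
            b = a + length
            if length == 1:
                ok[a, b] = mask[(a, b)]
            else:
                ok[a, b] = ok[a, b - 1] and ok[a + 1, b] and mask[(a, b)]
    good = np.argwhere(ok)
    if good.size == 0:
        return None
    lengths = good[:, 1] - good[:, 0]
    longest = good[lengths == lengths.max()]
    # equal lengths: the interval with the larger end (hence start) wins
    a, b = max(map(tuple, longest), key=lambda ab: ab[1])
    return int(a), int(b)


def derive_margin(matrix: RobustnessMatrix) -> tuple[int, int] | None:
    """Outermost grid indices touched by any robust off-diagonal tile."""
    robust = matrix.robust_tiles()
    if not robust:
        return None
    return min(i for i, _ in robust), max(j for _, j in robust)


def classify_conditional(matrix: RobustnessMatrix) -> RobustnessRange:
    """Bundle robust range + margin; non_robust when no robust tile."""
    margin = derive_margin(matrix)
    if margin is None:
        return RobustnessRange(
            matrix.feature_name,
            matrix.grid,
            None,
            None,
            ConditionalCategory.NON_ROBUST,
        )
    return RobustnessRange(
        matrix.feature_name,
        matrix.grid,
        derive_robust_range(matrix),
        margin,
        ConditionalCategory.CONDITIONALLY_ROBUST,
    )


def _interval_histogram(
    intervals: list[tuple[int, int] | None], n: int
) -> np.ndarray:
    hist = np.zeros(n, dtype=int)
    for iv in intervals:
        if iv is not None:
            hist[iv[0] : iv[1] + 1] += 1
    return hist


def _longest_run(meets: np.ndarray, hist: np.ndarray) -> tuple[int, int]:
    """Longest contiguous True run; ties -> run containing the histogram
    maximum, then the run at larger parameter values."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, m in enumerate(meets):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(meets) - 1))
    if not runs:
        raise ValueError("no grid value meets the cutoff")
    max_len = max(b - a for a, b in runs)
    longest = [r for r in runs if r[1] - r[0] == max_len]
    if len(longest) > 1:
        # prefer the run holding the highest histogram count
        peaks = [int(hist[a : b + 1].max()) for a, b in longest]
        longest = [r for r, p in zip(longest, peaks) if p == max(peaks)]
    return longest[-1]  # larger parameter values win remaining ties


def aggregate_global_range(
    ranges: list[RobustnessRange], grid: ParameterGrid
) -> GlobalRangeResult:
    """Global robustness range for one scenario.

    Counts, per grid value, the conditionally robust features whose margin
    contains that value; the cutoff is ceil(n/2) ("at least half"); the
    global range is the longest contiguous run of grid values meeting the
    cutoff. The same histogram built from robust ranges is also reported,
    along with the argmax grid values of both variants.
    """
    cond = [
        r
        for r in ranges
        if r.category is ConditionalCategory.CONDITIONALLY_ROBUST
    ]
    if not cond:
        raise ValueError("no conditionally robust features to aggregate")
    n = grid.n
    hist_margin = _interval_histogram([r.margin for r in cond], n)
    hist_rr = _interval_histogram([r.robust_range for r in cond], n)
    cutoff = ceil(len(cond) / 2)
    run = _longest_run(hist_margin >= cutoff, hist_margin)
    argmax_m = [
        grid.values[i] for i in np.flatnonzero(hist_margin == hist_margin.max())
    ]
    argmax_r = (
        [grid.values[i] for i in np.flatnonzero(hist_rr == hist_rr.max())]
        if hist_rr.max() > 0
        else []
    )
    logger.info(
        "global range %s: %d conditionally robust, cutoff %d, range %s",
        grid.name,
        len(cond),
        cutoff,
        (grid.values[run[0]], grid.values[run[1]]),
    )
    return GlobalRangeResult(
        grid=grid,
        n_conditionally_robust=len(cond),
        cutoff=cutoff,
        histogram_margin=hist_margin,
        histogram_robust_range=hist_rr,
        global_range=run,
        argmax_values_margin=argmax_m,
        argmax_values_robust_range=argmax_r,
    )


def matrix_to_frame(matrix: RobustnessMatrix) -> pd.DataFrame:
    """Tidy CSV-ready view: one row per tile."""
    rows = []
    for (i, j), m in sorted(matrix.tiles.items()):
        rows.append(
            {
                "feature_name": matrix.feature_name,
                "start_value": matrix.grid.values[i],
                "end_value": matrix.grid.values[j],
                "cv_mean": m.cv_mean,
                "rrm": m.rrm,
                "rrm_abs": m.rrm_abs,
                "robust": matrix.robust_mask[(i, j)],
            }
        )
    return pd.DataFrame(rows)
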