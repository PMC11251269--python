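"""Parameter grids and robustness criteria.

A *scenario* is one image-processing scheme (intensity discretisation or
voxel interpolation) combined with one algorithm (fixed bin width, fixed
bin number, or one of four interpolators), swept over an ordered grid of
parameter values:

* fixed bin width (FBW): bin widths 0.05–1.50 SUV in 0.05 SUV steps (30 values)
* fixed bin number (FBN): 8–256 bins in steps of 8 (32 values)
* interpolation (linear / nearest-neighbour / B-spline / Gaussian):
  isotropic voxel sizes 0.8–3.5 mm in 0.1 mm steps (28 values each)

for a grand total of 30 + 32 + 4x28 = 174 parameter settings.

Grid values are constructed from integer step counts and then scaled
(e.g. FBW value k is 5k/100 SUV) so that tile indexing by parameter value
is exact: no accumulated binary floating-point step error.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Scheme",
    "Algorithm",
    "ParameterGrid",
    "RobustCriteria",
    "build_parameter_grid",
    "enumerate_default_scenarios",
]


class Scheme(str, enum.Enum):
    DISCRETISATION = "discretisation"
    INTERPOLATION = "interpolation"


class Algorithm(str, enum.Enum):
    FBW = "FBW"
    FBN = "FBN"
    LINEAR = "linear"
    NEAREST_NEIGHBOUR = "nearest_neighbour"
    B_SPLINE = "b_spline"
    GAUSSIAN = "gaussian"


#: algorithms valid under each scheme
_SCHEME_ALGORITHMS = {
    Scheme.DISCRETISATION: (Algorithm.FBW, Algorithm.FBN),
    Scheme.INTERPOLATION: (
        Algorithm.LINEAR,
        Algorithm.NEAREST_NEIGHBOUR,
        Algorithm.B_SPLINE,
        Algorithm.GAUSSIAN,
    ),
}

#: decimal places used for canonical rounding of parameter values per algorithm
GRID_DECIMALS = {
    Algorithm.FBW: 2,  # SUV, 0.05 steps
    Algorithm.FBN: 0,  # integer bin counts
    Algorithm.LINEAR: 1,  # mm, 0.1 steps
    Algorithm.NEAREST_NEIGHBOUR: 1,
    Algorithm.B_SPLINE: 1,
    Algorithm.GAUSSIAN: 1,
}

#: physical unit of the swept parameter per algorithm
GRID_UNITS = {
    Algorithm.FBW: "SUV",
    Algorithm.FBN: "bins",
    Algorithm.LINEAR: "mm",
    Algorithm.NEAREST_NEIGHBOUR: "mm",
    Algorithm.B_SPLINE: "mm",
    Algorithm.GAUSSIAN: "mm",
}


@dataclass(frozen=True)
class ParameterGrid:
    """An ordered sweep of one image-processing parameter.

    ``values`` are strictly increasing; units are implicit per algorithm
    (SUV for FBW bin widths, a count for FBN bins, mm for voxel sizes) and
    exposed via :attr:`unit`.
    """

    scheme: Scheme
    algorithm: Algorithm
    values: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if self.algorithm is Algorithm.FBN and any(
            float(v) <= 0 or float(v) != int(v) for v in self.values
        ):
            raise ValueError("FBN grid values must be positive integers")
        # canonical rounding at construction: 0.05*3 and 0.15 must be the
        # same grid value
        dec = GRID_DECIMALS[self.algorithm]
        vals = tuple(float(np.round(float(v), dec)) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) < 2:
            raise ValueError("a parameter grid needs at least 2 values")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("grid values must be strictly increasing")
        if self.algorithm not in _SCHEME_ALGORITHMS[self.scheme]:
            raise ValueError(
                f"algorithm {self.algorithm.value!r} is not valid under "
                f"scheme {self.scheme.value!r}"
            )

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def unit(self) -> str:
        return GRID_UNITS[self.algorithm]

    @property
    def decimals(self) -> int:
        return GRID_DECIMALS[self.algorithm]

    @property
    def name(self) -> str:
        return self.label or self.algorithm.value

    def canonicalise(self, value: float | np.ndarray) -> float | np.ndarray:
        """Round a parameter value to this grid's decimal precision."""
        return np.round(value, self.decimals)

    def index_of(self, value: float) -> int:
        """Exact index of a parameter value after canonical rounding."""
        v = float(self.canonicalise(value))
        try:
            return self.values.index(v)
        except ValueError:
            raise KeyError(
                f"{value!r} is not a value of the {self.name} grid"
            ) from None


@dataclass(frozen=True)
class RobustCriteria:
    """Thresholds defining a robust feature.

    A feature is robust over a parameter range when the mean within-subject
    percentage coefficient of variation stays below ``cv_threshold`` (percent)
    and the magnitude of the repeated-measures correlation stays below
    ``rrm_threshold``, both as strict inequalities.
    """

    cv_threshold: float = 10.0
    rrm_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.cv_threshold <= 0 or self.rrm_threshold <= 0:
            raise ValueError("robustness thresholds must be strictly positive")


def _integer_grid(first_step: int, last_step: int, scale: float) -> tuple[float, ...]:
    # integer multiples scaled once: exact to 1e-12 against start + k*step
    return tuple(k * scale for k in range(first_step, last_step + 1))


def build_parameter_grid(
    scheme: Scheme | str, algorithm: Algorithm | str, label: str = ""
) -> ParameterGrid:
    """Return the default grid for a scheme/algorithm combination.

    Raises ``ValueError`` for an invalid pairing (e.g. FBW under
    interpolation).
    """
    scheme = Scheme(scheme)
    algorithm = Algorithm(algorithm)
    if algorithm not in _SCHEME_ALGORITHMS[scheme]:
        raise ValueError(
            f"algorithm {algorithm.value!r} is not valid under scheme "
            f"{scheme.value!r}"
        )
    if algorithm is Algorithm.FBW:
        values = _integer_grid(1, 30, 0.05)  # 0.05 .. 1.50 SUV
    elif algorithm is Algorithm.FBN:
        values = _integer_grid(1, 32, 8.0)  # 8 .. 256 bins
    else:
        values = _integer_grid(8, 35, 0.1)  # 0.8 .. 3.5 mm
    return ParameterGrid(scheme, algorithm, values, label=label or algorithm.value)


def enumerate_default_scenarios() -> list[ParameterGrid]:
    """All six default scenarios: FBW, FBN and the four interpolators.

    Their value counts sum to 174.
    """
    grids = [
        build_parameter_grid(Scheme.DISCRETISATION, Algorithm.FBW),
        build_parameter_grid(Scheme.DISCRETISATION, Algorithm.FBN),
    ]
    for alg in _SCHEME_ALGORITHMS[Scheme.INTERPOLATION]:
        grids.append(build_parameter_grid(Scheme.INTERPOLATION, alg))
    return grids


def subgrid(grid: ParameterGrid, start: int, end: int) -> Sequence[float]:
    """Inclusive slice of grid values from index ``start`` to ``end``."""
    if not (0 <= start < end < grid.n):
        raise IndexError(f"invalid sub-range [{start}, {end}] for n={grid.n}")
    return grid.values[start : end + 1]
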