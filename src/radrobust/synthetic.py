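"""Seeded synthetic cohorts with the statistical structure the analysis
assumes.

Real feature-response curves are not reproducible without the source
images, so cohorts are generated directly at the feature level: each
subject i's value at parameter x follows

    value_i(x) = (alpha + a_i) * g(x) + (beta + b_i) + eps

with cohort-level dependency g drawn from the eight invertible forms the
correction stage models, subject-level random slope a_i ~ N(0, slope_sd *
|alpha|) and intercept b_i ~ N(0, intercept_sd) perturbations, and
(optionally heteroscedastic) Gaussian noise eps ~ N(0, noise_sd(x)).
Three profile shapes cover the downstream categories:

* ``flat`` — alpha = 0: robust by construction under low noise;
* ``dependency`` — a pure invertible dependence: correctable;
* ``plateau`` — the dependency below a breakpoint, continuous and flat
  above it: conditionally robust, with the margin expected to cover the
  plateau.

Identical spec + seed gives bit-identical output. Subject effects are
drawn before noise from a single named generator, so refining the grid
preserves each subject's random effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .correction import FunctionId, _G_FUNCS, _LOG_FAMILY
from .grids import ParameterGrid
from .io import FeatureTable

__all__ = [
    "FlatProfile",
    "DependencyProfile",
    "PlateauProfile",
    "SyntheticCohortSpec",
    "generate_cohort",
    "fbw_discretise",
    "fbn_discretise",
    "first_order_entropy",
    "first_order_uniformity",
]


@dataclass(frozen=True)
class FlatProfile:
    """Parameter-independent feature: robust by construction."""

    beta: float = 10.0


@dataclass(frozen=True)
class DependencyProfile:
    """Pure invertible dependence f(x) = alpha * g(x) + beta."""

    function_id: FunctionId
    alpha: float
    beta: float
    scale_s: float = 1.0

    def g(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if FunctionId(self.function_id) in _LOG_FAMILY:
            x = self.scale_s * x
        return _G_FUNCS[FunctionId(self.function_id)](x)

    def mean_curve(self, x: np.ndarray) -> np.ndarray:
        return self.alpha * self.g(x) + self.beta


@dataclass(frozen=True)
class PlateauProfile:
    """Dependency below the breakpoint, flat (continuous) above it."""

    breakpoint: float
    below: DependencyProfile

    def mean_curve(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = self.below.mean_curve(x)
        plateau = self.below.mean_curve(np.asarray([self.breakpoint]))[0]
        return np.where(x >= self.breakpoint, plateau, y)


Profile = Union[FlatProfile, DependencyProfile, PlateauProfile]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Recipe for one seeded synthetic cohort on one parameter grid.

    ``noise_sd`` may be a scalar (homoscedastic) or a per-grid-value
    sequence (heteroscedastic), in feature units. ``slope_sd`` is a
    fraction of each profile's alpha; ``intercept_sd`` is in feature
    units.
    """

    n_subjects: int
    grid: ParameterGrid
    features: tuple[tuple[str, Profile], ...]
    intercept_sd: float = 0.0
    slope_sd: float = 0.0
    noise_sd: float | tuple[float, ...] = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        noise = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))
        if (noise < 0).any():
            raise ValueError("noise_sd must be non-negative")
        if noise.size not in (1, self.grid.n):
            raise ValueError(
                "noise_sd must be scalar or one value per grid point"
            )
        for name, prof in self.features:
            if isinstance(prof, PlateauProfile):
                if not (
                    self.grid.values[0]
                    <= prof.breakpoint
                    <= self.grid.values[-1]
                ):
                    raise ValueError(
                        f"{name}: breakpoint {prof.breakpoint} outside grid"
                    )

    def noise_per_value(self) -> np.ndarray:
        noise = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))
        return np.broadcast_to(noise, (self.grid.n,)) if noise.size == 1 else noise


def _profile_alpha_beta(profile: Profile) -> tuple[float, float]:
    if isinstance(profile, FlatProfile):
        return 0.0, profile.beta
    if isinstance(profile, DependencyProfile):
        return profile.alpha, profile.beta
    return profile.below.alpha, profile.below.beta


def generate_cohort(spec: SyntheticCohortSpec) -> FeatureTable:
    """Simulate a long-format feature table from a cohort spec."""
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    x = np.asarray(grid.values)
    noise_sd = spec.noise_per_value()
    rows: list[pd.DataFrame] = []
    subjects = [f"S{i:03d}" for i in range(spec.n_subjects)]
    for name, profile in spec.features:
        if isinstance(profile, DependencyProfile):
            FunctionId(profile.function_id)  # raises on invalid id
        alpha, _ = _profile_alpha_beta(profile)
        # subject effects first, then noise: grid refinement keeps effects
        a = rng.normal(0.0, spec.slope_sd * abs(alpha), spec.n_subjects)
        b = rng.normal(0.0, spec.intercept_sd, spec.n_subjects)
        eps = rng.normal(0.0, 1.0, (spec.n_subjects, grid.n)) * noise_sd
        if isinstance(profile, FlatProfile):
            base = np.full(grid.n, profile.beta)
            gx = np.zeros(grid.n)
        elif isinstance(profile, DependencyProfile):
            base = profile.mean_curve(x)
            gx = profile.g(x)
        else:
            base = profile.mean_curve(x)
            # per-subject slope perturbation follows the same plateau shape
            gx_raw = profile.below.g(x)
            g_bp = profile.below.g(np.asarray([profile.breakpoint]))[0]
            gx = np.where(x >= profile.breakpoint, g_bp, gx_raw)
        values = base[None, :] + a[:, None] * gx[None, :] + b[:, None] + eps
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(subjects, grid.n),
                    "feature_name": name,
                    "scheme": grid.scheme.value,
                    "algorithm": grid.algorithm.value,
                    "parameter_value": np.tile(x, spec.n_subjects),
                    "value": values.ravel(),
                }
            )
        )
    return FeatureTable(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# Intensity discretisation and the two first-order fixture features
# ---------------------------------------------------------------------------


def fbw_discretise(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width discretisation anchored at the mask minimum.

    index = floor((v - v_min) / w) + 1, the IBSI fixed-bin-size convention.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty mask: nothing to discretise")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    return np.floor((v - v.min()) / bin_width).astype(int) + 1


def fbn_discretise(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Fixed-bin-number discretisation over the mask intensity range.

    index = min(n, floor(n * (v - v_min) / (v_max - v_min)) + 1); a
    constant input maps every voxel to bin 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty mask: nothing to discretise")
    if n_bins < 1:
        raise ValueError("need at least one bin")
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        return np.ones(v.shape, dtype=int)
    idx = np.floor(n_bins * (v - vmin) / (vmax - vmin)).astype(int) + 1
    return np.minimum(idx, n_bins)


def _bin_probabilities(indices: np.ndarray) -> np.ndarray:
    idx = np.asarray(indices).ravel()
    if idx.size == 0:
        raise ValueError("no bin indices")
    _, counts = np.unique(idx, return_counts=True)
    return counts / idx.size


def first_order_entropy(indices: np.ndarray) -> float:
    """Shannon entropy (bits) of the occupied-bin probabilities."""
    p = _bin_probabilities(indices)
    return float(-np.sum(p * np.log2(p))) + 0.0  # avoid -0.0


def first_order_uniformity(indices: np.ndarray) -> float:
    """Sum of squared occupied-bin probabilities (a.k.a. energy)."""
    p = _bin_probabilities(indices)
    return float(np.sum(p**2))
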