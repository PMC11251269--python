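import numpy as np
import pytest

import radrobust as rr


@pytest.fixture
def small_fbw_grid():
    """Ten-value bin-width grid (0.05..0.50 SUV) for fast matrix tests."""
    return rr.ParameterGrid(
        rr.Scheme.DISCRETISATION,
        rr.Algorithm.FBW,
        tuple(0.05 * k for k in range(1, 11)),
    )


@pytest.fixture
def designed_cohort(small_fbw_grid):
    """Cohort whose features are built to land in known categories.

    Two flat (robust), two plateau (conditionally robust above 0.30 SUV),
    two pure inverse dependencies (correctable), and one feature drowned
    in noise (non-robust and not correctable).
    """
    inv = rr.FunctionId.INV
    spec = rr.SyntheticCohortSpec(
        n_subjects=20,
        grid=small_fbw_grid,
        features=(
            ("flat_a", rr.FlatProfile(beta=10.0)),
            ("flat_b", rr.FlatProfile(beta=3.0)),
            ("plateau_a", rr.PlateauProfile(0.30, rr.DependencyProfile(inv, 1.0, 2.0))),
            ("plateau_b", rr.PlateauProfile(0.30, rr.DependencyProfile(inv, 2.0, 8.0))),
            ("dep_a", rr.DependencyProfile(inv, 2.0, 5.0)),
            # log-family dependence: g stays O(1) on the grid, so the
            # inverse correction does not amplify subject-level dispersion
            ("dep_b", rr.DependencyProfile(rr.FunctionId.LOG, 2.0, 1.0, 100.0)),
        ),
        intercept_sd=0.05,
        slope_sd=0.01,
        noise_sd=0.02,
        seed=20260925,
    )
    table = rr.generate_cohort(spec)
    # the pathological feature: mean 1, noise of the same magnitude
    noisy = rr.generate_cohort(
        rr.SyntheticCohortSpec(
            n_subjects=20,
            grid=small_fbw_grid,
            features=(("pathological", rr.FlatProfile(beta=1.0)),),
            noise_sd=1.0,
            seed=20260926,
        )
    )
    import pandas as pd

    return rr.FeatureTable(pd.concat([table.data, noisy.data], ignore_index=True))


def mask_matrix(grid, robust_pairs):
    """RobustnessMatrix stub carrying only a robust mask (1-based pairs)."""
    n = grid.n
    mask = {
        (i, j): (i + 1, j + 1) in set(robust_pairs)
        for i in range(n - 1)
        for j in range(i + 1, n)
    }
    return rr.RobustnessMatrix("stub", grid, {}, mask)


def brute_force_robust_range(grid, mask):
    """Exhaustive interval search: largest [a, b] with all tiles robust."""
    n = grid.n
    best = None
    for a in range(n - 1):
        for b in range(a + 1, n):
            if all(
                mask[(i, j)] for i in range(a, b) for j in range(i + 1, b + 1)
            ):
                if (
                    best is None
                    or b - a > best[1] - best[0]
                    or (b - a == best[1] - best[0] and b > best[1])
                ):
                    best = (a, b)
    return best


def brute_force_margin(mask):
    robust = [k for k, v in mask.items() if v]
    if not robust:
        return None
    return min(i for i, _ in robust), max(j for _, j in robust)
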