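import itertools

import numpy as np
import pytest

import radrobust as rr
from radrobust.ranges import (
    ConditionalCategory,
    aggregate_global_range,
    classify_conditional,
    derive_margin,
    derive_robust_range,
    n_range_tiles,
)

from conftest import brute_force_margin, brute_force_robust_range, mask_matrix


def _grid(n):
    return rr.ParameterGrid(
        rr.Scheme.DISCRETISATION,
        rr.Algorithm.FBW,
        tuple(0.05 * k for k in range(1, n + 1)),
    )


@pytest.mark.parametrize(
    "n, expected", [(28, 378), (30, 435), (32, 496), (2, 1), (4, 6)]
)
def test_tile_counts(n, expected):
    assert n_range_tiles(n) == expected


def test_tile_count_needs_two_parameters():
    with pytest.raises(ValueError):
        n_range_tiles(1)


class TestRobustRangeDerivation:
    def test_all_tiles_robust_full_grid(self):
        grid = _grid(5)
        pairs = [(i, j) for i in range(1, 6) for j in range(i + 1, 6)]
        m = mask_matrix(grid, pairs)
        assert derive_robust_range(m) == (0, 4)

    def test_documented_example_mask(self):
        # robust tiles {(1,2), (1,3), (2,3), (4,5)} -> range [1,3], margin [1,5]
        grid = _grid(5)
        m = mask_matrix(grid, [(1, 2), (1, 3), (2, 3), (4, 5)])
        assert derive_robust_range(m) == (0, 2)
        assert derive_margin(m) == (0, 4)

    def test_single_tile_defines_margin(self):
        # one robust tile spanning values 2..4 fixes both margin extremes,
        # but no interval has *all* its tiles robust, so no robust range
        m = mask_matrix(_grid(5), [(2, 4)])
        assert derive_margin(m) == (1, 3)
        assert derive_robust_range(m) is None

    def test_no_robust_tiles_gives_none_and_non_robust(self):
        m = mask_matrix(_grid(5), [])
        assert derive_robust_range(m) is None
        assert derive_margin(m) is None
        assert classify_conditional(m).category is ConditionalCategory.NON_ROBUST

    def test_tie_breaks_toward_larger_parameter_values(self):
        # two disjoint maximal intervals [1,2] and [4,5]
        m = mask_matrix(_grid(5), [(1, 2), (4, 5)])
        assert derive_robust_range(m) == (3, 4)

    def test_exhaustive_oracle_n5_all_masks(self):
        grid = _grid(5)
        pairs = [(i, j) for i in range(1, 6) for j in range(i + 1, 6)]
        for bits in itertools.product([False, True], repeat=len(pairs)):
            chosen = [p for p, b in zip(pairs, bits) if b]
            m = mask_matrix(grid, chosen)
            assert derive_robust_range(m) == brute_force_robust_range(
                grid, m.robust_mask
            )
            assert derive_margin(m) == brute_force_margin(m.robust_mask)

    def test_random_masks_n8_match_oracle(self):
        grid = _grid(8)
        rng = np.random.default_rng(2)
        keys = [(i, j) for i in range(8) for j in range(i + 1, 8)]
        for _ in range(200):
            mask = {k: bool(rng.integers(0, 2)) for k in keys}
            m = rr.RobustnessMatrix("stub", grid, {}, mask)
            assert derive_robust_range(m) == brute_force_robust_range(grid, mask)
            assert derive_margin(m) == brute_force_margin(mask)

    def test_removing_a_robust_tile_never_widens(self):
        grid = _grid(6)
        rng = np.random.default_rng(4)
        keys = [(i, j) for i in range(6) for j in range(i + 1, 6)]
        for _ in range(50):
            mask = {k: bool(rng.integers(0, 2)) for k in keys}
            robust = [k for k, v in mask.items() if v]
            if not robust:
                continue
            m = rr.RobustnessMatrix("stub", grid, {}, mask)
            before_rr = derive_robust_range(m)
            before_mg = derive_margin(m)
            drop = robust[rng.integers(len(robust))]
            smaller = dict(mask)
            smaller[drop] = False
            m2 = rr.RobustnessMatrix("stub", grid, {}, smaller)
            after_rr = derive_robust_range(m2)
            after_mg = derive_margin(m2)

            def width(iv):
                return -1 if iv is None else iv[1] - iv[0]

            assert width(after_rr) <= width(before_rr)
            assert width(after_mg) <= width(before_mg)


class TestComputeRobustnessMatrix:
    def test_constant_feature_all_tiles_robust(self):
        grid = _grid(4)
        spec = rr.SyntheticCohortSpec(
            n_subjects=4, grid=grid, features=(("c", rr.FlatProfile(9.0)),), seed=0
        )
        m = rr.compute_robustness_matrix(rr.generate_cohort(spec), "c", grid)
        assert len(m.tiles) == 6  # C(4,2)
        assert all(m.robust_mask.values())

    def test_tiles_match_direct_recomputation(self, small_fbw_grid):
        spec = rr.SyntheticCohortSpec(
            n_subjects=8,
            grid=small_fbw_grid,
            features=(("d", rr.DependencyProfile(rr.FunctionId.LIN, 3.0, 1.0)),),
            noise_sd=0.05,
            seed=9,
        )
        table = rr.generate_cohort(spec)
        m = rr.compute_robustness_matrix(table, "d", small_fbw_grid)
        for (i, j) in [(0, 1), (0, 9), (3, 7)]:
            direct = rr.compute_metrics(table, "d", small_fbw_grid, i, j)
            assert m.tiles[(i, j)].cv_mean == pytest.approx(direct.cv_mean)
            assert m.tiles[(i, j)].rrm == pytest.approx(direct.rrm)
            assert m.robust_mask[(i, j)] == rr.is_robust(
                direct, rr.RobustCriteria()
            )

    def test_strong_linear_dependence_wide_tiles_not_robust(self, small_fbw_grid):
        spec = rr.SyntheticCohortSpec(
            n_subjects=8,
            grid=small_fbw_grid,
            features=(("d", rr.DependencyProfile(rr.FunctionId.LIN, 50.0, 1.0)),),
            noise_sd=0.01,
            seed=9,
        )
        m = rr.compute_robustness_matrix(
            rr.generate_cohort(spec), "d", small_fbw_grid
        )
        assert not m.robust_mask[(0, small_fbw_grid.n - 1)]


class TestGlobalRange:
    def _ranges(self, grid, margins):
        out = []
        for k, mg in enumerate(margins):
            out.append(
                rr.RobustnessRange(
                    f"f{k}",
                    grid,
                    None,
                    mg,
                    ConditionalCategory.CONDITIONALLY_ROBUST
                    if mg
                    else ConditionalCategory.NON_ROBUST,
                )
            )
        return out

    def test_documented_three_margin_example(self):
        grid = rr.build_parameter_grid("discretisation", "FBW")
        i = grid.index_of
        margins = [
            (i(0.50), i(1.50)),
            (i(0.75), i(1.50)),
            (i(1.00), i(1.50)),
        ]
        res = aggregate_global_range(self._ranges(grid, margins), grid)
        assert res.cutoff == 2
        assert res.in_units() == (0.75, 1.50)

    def test_single_feature_global_range_is_its_margin(self):
        grid = _grid(6)
        res = aggregate_global_range(self._ranges(grid, [(1, 4)]), grid)
        assert res.cutoff == 1
        assert res.global_range == (1, 4)

    def test_disjoint_margins_tie_breaks_on_peak_then_larger_values(self):
        grid = _grid(6)
        # two features, disjoint equal-length margins; cutoff 1; runs tie
        res = aggregate_global_range(
            self._ranges(grid, [(0, 1), (4, 5)]), grid
        )
        assert res.global_range == (4, 5)

    def test_every_value_in_range_meets_cutoff(self):
        grid = _grid(8)
        rng = np.random.default_rng(6)
        for _ in range(30):
            margins = []
            for _ in range(rng.integers(1, 6)):
                a = int(rng.integers(0, 7))
                b = int(rng.integers(a + 1, 8))
                margins.append((a, b))
            res = aggregate_global_range(self._ranges(grid, margins), grid)
            a, b = res.global_range
            assert (res.histogram_margin[a : b + 1] >= res.cutoff).all()
            # the chosen run is maximal: neighbours fail the cutoff
            if a > 0:
                assert res.histogram_margin[a - 1] < res.cutoff
            if b < grid.n - 1:
                assert res.histogram_margin[b + 1] < res.cutoff

    def test_cutoff_is_ceiling_of_half(self):
        grid = _grid(6)
        res = aggregate_global_range(
            self._ranges(grid, [(0, 5), (0, 5), (2, 4)]), grid
        )
        assert res.n_conditionally_robust == 3
        assert res.cutoff == 2

    def test_empty_input_errors(self):
        grid = _grid(5)
        with pytest.raises(ValueError):
            aggregate_global_range(self._ranges(grid, [None]), grid)
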