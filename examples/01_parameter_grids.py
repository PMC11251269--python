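"""The six default image-processing sweeps and their combinatorics.

Two discretisation schemes (fixed bin width in SUV, fixed bin number) and
four interpolators (voxel size in mm) define 174 parameter settings in
total; every start-end pair of grid values is one candidate robustness
range (tile).
"""

import radrobust as rr

for grid in rr.enumerate_default_scenarios():
    print(
        f"{grid.name:>18}: {grid.n:2d} values "
        f"[{grid.values[0]:g} .. {grid.values[-1]:g}] {grid.unit:<4} "
        f"-> {rr.n_range_tiles(grid.n)} range tiles"
    )
total = sum(g.n for g in rr.enumerate_default_scenarios())
print(f"\ntotal parameter settings: {total}")
print(f"feature values for a 485-patient, 107-feature study: {485*107*total:,}")
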