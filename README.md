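# radrobust

Robustness analysis and dependency correction of PET radiomic features
under intensity-discretisation and voxel-interpolation variation.

## The problem

Radiomic features extracted from [18F]-FDG-PET images are sensitive to two
image-processing choices that vary freely between studies: how tumour
intensities are discretised (a fixed bin width in SUV, or a fixed number
of bins) and the isotropic voxel size onto which images are interpolated.
A texture feature extracted at 0.1 SUV bin width is not the same number at
1.0 SUV, which undermines any model built on it. `radrobust` implements a
complete pipeline for quantifying that sensitivity and for mitigating it,
for anyone who works with feature tables swept over processing parameters
(radiomics researchers, imaging-biomarker validation groups).

## The method

For each feature and each parameter sweep (bin widths 0.05–1.50 SUV in
0.05 steps; bin numbers 8–256 in steps of 8; voxel sizes 0.8–3.5 mm in 0.1
steps for four interpolators — 174 settings in total), two metrics are
computed over the cohort:

* **CV_mean** — the within-subject percentage coefficient of variation
  100·s/|m| over the sweep, averaged across subjects (agreement);
* **|r_rm|** — the magnitude of the repeated-measures correlation between
  feature value and parameter, estimated by ANCOVA with a common slope and
  subject-specific intercepts (reliability), with df = N − n_subjects − 1
  and a Fisher-z 95% CI.

A feature is **robust** when CV_mean < 10% and |r_rm| < 0.5. Non-robust
features get two parallel mitigations:

1. **Range conditions.** Both metrics are recomputed for every start–end
   sub-range of the grid (C(n,2) tiles: 435 for FBW, 496 for FBN, 378 per
   interpolator). The largest square region of all-robust tiles gives the
   feature's *robust range*; the outermost values touched by any robust
   tile give its *robustness margin*. A feature with at least one robust
   tile is *conditionally robust*. Margins aggregate into a per-scenario
   histogram whose longest run of grid values covering ≥ half of the
   conditionally robust features is the *global robustness range*.
2. **Dependency correction.** The cohort mean curve is fitted with eight
   invertible forms f(x) = α·g(x) + β, g ∈ {x, x², x³, 1/x, 1/x², 1/x³,
   log(s·x), 1/log(s·x)} (s = 100 for bin widths, 10 for voxel sizes), by
   iteratively reweighted least squares (Huber loss) with intrinsic
   weights 1/Var across subjects; the AIC-best form is inverted per
   subject, f_corr(x) = (f(x) − β)/g(x). The correction is *correctable*
   when per-subject CVs drop significantly (two-sided Wilcoxon signed-rank
   p < 0.05), the 95% CIs of |r_rm| before/after do not overlap, both
   metrics decrease, and the corrected feature meets the robust criteria;
   *moderately correctable* when significant but still above threshold;
   *not correctable* otherwise.

Because real multi-hundred-patient PET datasets cannot ship with a
library, the package includes a first-class synthetic-cohort generator
(flat, plateauing and dependency profiles with subject-level random
effects and configurable noise) and a miniature phantom fixture
(sphere-in-noise volume, IBSI-style FBW/FBN discretisation, first-order
entropy/uniformity, nearest-neighbour/linear resampling) so the whole
pipeline runs end to end from nothing.

## Worked example

```python
import radrobust as rr

grid = rr.build_parameter_grid("discretisation", "FBW")
spec = rr.SyntheticCohortSpec(
    n_subjects=25, grid=grid,
    features=(("glcm_like", rr.DependencyProfile(rr.FunctionId.INV, 2.0, 5.0)),),
    intercept_sd=0.03, slope_sd=0.01, noise_sd=0.02, seed=3,
)
table = rr.generate_cohort(spec)
result = rr.correct_feature(table, "glcm_like", grid)
```

Running `python examples/04_dependency_correction.py` (the same analysis)
prints:

```
AIC per candidate form (lower is better):
      lin:     198.0
     quad:     205.0
      cub:     208.7
      inv:    -140.6 <- selected
     ...
fitted f(x) = 1.998 * g(x) + 5.005
CV_mean :  74.71 % ->   1.00 %
|r_rm|  :  0.648  ->  0.031
Wilcoxon p = 5.96e-08, CI overlap = False
category: correctable
```

The simulated feature varies as 2/x + 5 with bin width x; AIC picks the
inverse form out of eight candidates and recovers α ≈ 2, β ≈ 5. Inverting
it collapses the within-subject variation from 75% to 1% and the
parameter correlation from 0.65 to 0.03, so the corrected feature meets
the robust criteria: correctable. The other scripts in `examples/` walk
through grids, metrics, robust ranges, the phantom, and the full scenario
report one capability at a time.

A thin CLI wraps the same stages
(`radrobust simulate|metrics|ranges|correct|run|report`); CSVs are the
canonical outputs.

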