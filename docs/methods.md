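# Methods

This note records the statistical model behind `radrobust`, the numerical
choices made where the procedure was genuinely open, what the synthetic
generator does and does not emulate, and the known limitations.

## Data model

The universal input is a long-format feature table: one value per
(subject, feature, scheme, algorithm, parameter value). A *scenario* is
one algorithm swept over an ordered parameter grid. Default grids are
built from integer step counts and scaled once (bin width k ↦ 5k/100 SUV;
bin number k ↦ 8k; voxel size k ↦ k/10 mm), then canonically rounded to
the grid's decimal precision (2 d.p. SUV, integer bins, 1 d.p. mm). Table
parameter values are matched to grid values by exact equality after the
same rounding — never nearest-match — so tile indexing is exact and a
typo'd parameter surfaces as an error. Scenarios must be complete (every
subject at every grid value); gaps are reported cell by cell and never
imputed, since silent imputation would bias both metrics toward stability.
Feature-table CSVs are written with 17-significant-digit floats and read
with the round-trip parser, so I/O is bit-lossless.

## Robustness metrics

**Within-subject CV.** For one subject's values across a parameter range,
CV = 100·s/|m| with the sample (n−1) standard deviation — the standard
within-subject CV convention. Constant input gives exactly 0. Subjects
whose |mean| falls below 1e-8 (in feature units; features such as
skewness can cross zero) are flagged degenerate and excluded from the
cross-subject average with a logged count; a strict mode errors instead.
CV_mean is the arithmetic mean over the remaining subjects.

**Repeated-measures correlation.** r_rm is the common within-subject
association between feature value and parameter from the ANCOVA model
y = subject intercepts + common slope·x: r_rm = sign(slope)·
√(SS_x/(SS_x+SS_err)). The implementation centres x and y within
subjects and computes the Pearson form of that quantity, which is
algebraically identical and O(N) per evaluation — important because a
30-value grid requires 435 tile evaluations per feature. Equality with an
explicit design-matrix least-squares solve is enforced to 1e-10 in tests,
and against `pingouin.rm_corr` as an independent reference. Degrees of
freedom are N_obs − n_subjects − 1; the 95% CI uses the Fisher
z-transform with standard error 1/√(df−1) (the convention of the
reference implementations). The CI reported for |r_rm| maps the signed
interval to magnitudes: [0, max(|lo|,|hi|)] when the signed CI straddles
zero, [min(|lo|,|hi|), max(|lo|,|hi|)] otherwise — this is the interval
the correction stage tests for overlap. A feature with zero within-subject
variance everywhere (shape features under discretisation) gets CV = 0 and
r_rm = 0 and is robust; zero within-subject variance of x is an error
because the common slope is undefined.

**Robust criteria.** CV_mean < 10% and |r_rm| < 0.5, both strict, both
configurable. Boundary values fail.

## Range analysis

Every tile (i, j), i < j, of an n-value grid holds the metrics recomputed
over the full inclusive sub-range i..j (not just the two endpoints):
a "range" means every grid value inside it, and the metrics must reflect
everything a study using that range would encounter. The *robust range*
is the largest interval whose every contained off-diagonal tile is
robust, found by a dynamic programme over interval length
(ok(a,b) = ok(a,b−1) ∧ ok(a+1,b) ∧ robust(a,b)), equivalent to
run-length encoding of the mask and verified exhaustively against brute
force for every 5-value mask and random 8-value masks. Where several
largest intervals tie, the one at larger parameter values wins — coarser
discretisation and larger voxels are where robustness empirically
accumulates, so this orientation is the consistent one; it is
deterministic and configurable in the brute-force sense (callers can
inspect the full mask). The *margin* spans the outermost grid values
touched by any robust tile. A single robust tile therefore defines a
margin but, unless it is an adjacent pair, no robust range.

The *global range* uses the margin-based histogram (features per grid
value whose margin contains it), cutoff ⌈n/2⌉ — a literal "at least
half" for odd counts — and takes the longest contiguous run of values
meeting the cutoff; ties prefer the run with the higher peak count, then
larger parameter values. The robust-range-based histogram and both
argmax value lists are also emitted, since either variant can be the
quantity of interest.

## Dependency correction

The fit target is the cohort mean curve — one point per grid value —
with intrinsic weights 1/Var across subjects at that value (variance
floored at 1e-12, floor events logged); per-subject fits are out of
scope. Robust regression is IRLS with a Huber loss (c = 1.345, the
95%-efficiency default), whose weights multiply the intrinsic ones; the
scale is re-estimated each iteration from the residual MAD/0.6745;
convergence at coefficient change < 1e-8 or 50 iterations. With all
residuals inside the Huber threshold the fit coincides with weighted
least squares to 1e-8 (tested against the closed-form solve). AIC is
n·ln(weighted RSS/n) + 2k with k = 3 (α, β, scale); additive constants
shared by all eight candidates are dropped, so only relative values
matter. Ties break by the fixed candidate order (x, x², x³, 1/x, 1/x²,
1/x³, log, 1/log). A design where g(x) is constant on the grid is
non-converged and excluded; if nothing converges the feature is
not-correctable with that reason.

For the log-family forms the argument is pre-scaled: ×100 for bin widths,
×10 for voxel sizes, ×1 for bin numbers (which start at 8). This keeps
log(s·x) away from zero on the default grids — at 0.05 SUV the argument
is 5, never 1. The code additionally validates |g(x)| > 1e-12 at every
grid value rather than trusting the rule, so custom grids that defeat
the scaling fail loudly.

The correction is f_corr(x) = (f(x) − β)/g(x) with the cohort-level β
applied to every subject. Corrected tables carry a `corrected` flag and
re-correction is refused, because the rearranged form is not idempotent.
The evaluation pairs per-subject CVs before/after in a two-sided Wilcoxon
signed-rank test; significance requires p < 0.05 *and* non-overlapping
95% CIs of |r_rm| *and* decreases in both metrics — the directional check
is added because a two-sided p-value alone would also flag a significant
worsening. Sidedness is configurable in principle but the default is
fixed; no multiplicity adjustment is applied across features, and the
report says so. Categories: *correctable* (significant and robust
afterwards), *moderately correctable* (significant, not robust),
*not correctable* (otherwise, including an undefined test when all paired
differences are zero).

One structural caveat the designed scenarios expose: the inverse form
divides by g(x), so for forms whose g is small somewhere on the grid
(x², x³ at small bin widths) the correction *amplifies* subject-level
intercept dispersion and residual noise there. A cohort-level β cannot
remove per-subject intercept deviations; such features end up moderately
correctable rather than correctable. This is a property of the
rearranged-form correction itself, not an implementation artefact.

## Synthetic data

The generator emulates exactly the structure the analysis assumes:
value_i(x) = (α+a_i)·g(x) + (β+b_i) + ε with a_i ~ N(0, slope_sd·|α|),
b_i ~ N(0, intercept_sd), ε ~ N(0, noise_sd(x)) (scalar or per-grid-value
noise). Flat profiles fix α = 0; plateau profiles follow the dependency
below a breakpoint and stay constant above it, continuous there per
subject, producing genuinely conditionally robust features. Subject
effects are drawn before noise from a single seeded generator, so grid
refinement preserves subject identities; identical spec + seed is
bit-identical.

Defaults used by the designed scenarios: 20–30 subjects, noise at ~2% of
the curve range, intercept_sd a few percent of the feature scale. These
are chosen as plausible for well-normalised PET feature curves, but the
generator makes no claim about real noise structure: real features have
discretisation-induced step artefacts, heteroscedasticity tied to tumour
volume, and inter-feature correlation, none of which are modelled. A
passing designed-scenario test shows the pipeline's logic is faithful to
its definitions, not that real cohorts are this clean.

The phantom fixture (spheres on optionally noisy background, voxel-centre
membership, IBSI fixed-bin-size binning anchored at the mask minimum,
FBN binning over the mask range, first-order entropy/uniformity,
centre-aligned nearest-neighbour/linear resampling via SimpleITK) exists
to smoke-test the image→table path. It implements two features and two
interpolators only; B-spline and Gaussian interpolation are accepted as
grid labels but have no image-level implementation here. Entropy grows
with bin number on a noisy phantom, but single steps can dip by a few
hundredths of a bit when bin edges shift — the tests assert the trend,
not strict monotonicity.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
10-value grids (45 tiles) for matrix-heavy paths, full 30/32/28-value
grids where only per-grid fits are involved, 20–30 subjects, 20 seeds per
dependency form, 1024 + 200 masks for the range oracle, 20³–24³-voxel
phantoms. Cohort-level results from multi-hundred-patient studies are
outside what synthetic data can certify and are not claimed.

## Known limitations

* Real-image feature extraction (the 107-feature IBSI set) is consumed,
  not produced; only the two-feature phantom path extracts from voxels.
* The Wilcoxon/CI significance machinery treats features independently.
* β is cohort-level; per-patient dependency corrections are out of scope.
* Mixed-effects comparisons of categorisation rates across scenarios or
  cohorts are out of scope.
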