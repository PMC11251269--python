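"""Robustness metrics: within-subject CV and repeated-measures correlation.

Two complementary metrics quantify how a feature responds when one image
processing parameter is swept over a range:

*Agreement* — the within-subject percentage coefficient of variation,
100 * s / |m| with the sample (n-1) standard deviation s and mean m of one
subject's values over the range, averaged across subjects to a per-feature
``CV_mean``.

*Reliability* — the repeated-measures correlation r_rm: the common
within-subject correlation between feature value and parameter, estimated
by ANCOVA with a shared slope and subject-specific intercepts. It handles
the non-independence of values measured repeatedly on the same subject,
which an ordinary Pearson correlation over the pooled data would not.
Algebraically r_rm equals the Pearson correlation of the within-subject
centred x and y, with degrees of freedom N_obs - n_subjects - 1; the
confidence interval uses the Fisher z-transform with that df.

A feature is *robust* over the range when CV_mean < 10% and |r_rm| < 0.5
(strict inequalities; both thresholds configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .grids import ParameterGrid, RobustCriteria
from .io import FeatureTable

__all__ = [
    "RobustnessMetrics",
    "within_subject_cv",
    "cv_mean",
    "rmcorr",
    "magnitude_ci",
    "is_robust",
    "compute_metrics",
]

logger = logging.getLogger("radrobust")

#: |mean| below this (in feature units) flags a subject's CV as degenerate
CV_MEAN_EPSILON = 1e-8

#: within-subject variance below this treats the feature as constant
ZERO_VARIANCE_EPSILON = 1e-24


@dataclass
class RobustnessMetrics:
    """Bundle of the two robustness metrics over one parameter range.

    ``rrm_ci_low``/``rrm_ci_high`` bound the magnitude ``|r_rm|`` (these are
    what the correction stage compares for overlap); the signed Fisher CI
    on ``r_rm`` itself is kept alongside.
    """

    cv_mean: float
    cv_per_subject: list[float]
    rrm: float
    rrm_ci_low: float
    rrm_ci_high: float
    rrm_ci_signed: tuple[float, float]
    df: int
    n_subjects: int
    n_parameters: int
    degenerate_flags: set[str] = field(default_factory=set)
    n_degenerate_subjects: int = 0

    @property
    def rrm_abs(self) -> float:
        return abs(self.rrm)


def within_subject_cv(values: np.ndarray) -> float:
    """Percentage CV of one subject's values across >= 2 parameters.

    Returns 0 for constant input. Raises for fewer than 2 values or a mean
    whose magnitude is below :data:`CV_MEAN_EPSILON` (callers flag such
    subjects as degenerate rather than silently computing a huge CV).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("within-subject CV needs at least 2 values")
    if not np.isfinite(v).all():
        raise ValueError("within-subject CV requires finite values")
    s = v.std(ddof=1)
    if s == 0.0:
        return 0.0
    m = v.mean()
    if abs(m) < CV_MEAN_EPSILON:
        raise ValueError(
            f"|mean| = {abs(m):.3g} below epsilon {CV_MEAN_EPSILON}; "
            "degenerate subject"
        )
    return 100.0 * s / abs(m)


def cv_mean(
    values: np.ndarray, strict: bool = False
) -> tuple[float, list[float], int]:
    """Mean within-subject percentage CV over a subjects x parameters matrix.

    Degenerate subjects (|mean| < epsilon with nonzero spread) are excluded
    from the average and counted; with ``strict=True`` they raise instead.

    Returns ``(cv_mean, per-subject CVs, n_degenerate)``.
    """
    mat = np.asarray(values, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("cv_mean needs a 2-D matrix with >= 2 parameters")
    cvs: list[float] = []
    n_degenerate = 0
    for row in mat:
        try:
            cvs.append(within_subject_cv(row))
        except ValueError as exc:
            if "degenerate" not in str(exc):
                raise
            if strict:
                raise
            n_degenerate += 1
    if not cvs:
        raise ValueError("no non-degenerate subjects for CV averaging")
    if n_degenerate:
        logger.info("cv_mean: excluded %d degenerate subject(s)", n_degenerate)
    return float(np.mean(cvs)), cvs, n_degenerate


def _fisher_ci(r: float, df: int, alpha: float = 0.05) -> tuple[float, float]:
    # Fisher z with se = 1/sqrt(df - 1); matches the rmcorr-R / pingouin
    # convention where the effective sample size is df + 2
    if df <= 1:
        return -1.0, 1.0
    r = float(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15))
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(df - 1)
    crit = stats.norm.ppf(1 - alpha / 2)
    return float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se))


def magnitude_ci(ci_low: float, ci_high: float) -> tuple[float, float]:
    """Map a signed correlation CI to a CI on the magnitude |r|."""
    if ci_low <= 0.0 <= ci_high:
        lo = 0.0
    else:
        lo = min(abs(ci_low), abs(ci_high))
    return lo, max(abs(ci_low), abs(ci_high))


def rmcorr(
    x: np.ndarray, y: np.ndarray, subjects: np.ndarray
) -> tuple[float, float, float, int]:
    """Repeated-measures correlation of y on x with subject grouping.

    Returns ``(r_rm, ci_low, ci_high, df)`` where the CI is on the signed
    coefficient. Implemented through within-subject centring, which is
    algebraically identical to the ANCOVA sums-of-squares definition
    (r_rm = sign(slope) * sqrt(SS_x / (SS_x + SS_err))).

    Zero within-subject variance of y returns r_rm = 0 (constant feature);
    zero within-subject variance of x (parameter constant in every subject)
    is an error since the common slope is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subjects = np.asarray(subjects)
    if not (x.shape == y.shape == subjects.shape) or x.ndim != 1:
        raise ValueError("x, y, subjects must be 1-D of equal length")
    uniq, inv, counts = np.unique(
        subjects, return_inverse=True, return_counts=True
    )
    if uniq.size < 2:
        raise ValueError("rmcorr needs at least 2 subjects")
    if (counts < 2).any():
        raise ValueError("every subject needs at least 2 observations")
    n_obs, n_subj = x.size, uniq.size
    df = n_obs - n_subj - 1
    if df < 1:
        raise ValueError(f"non-positive degrees of freedom (df={df})")

    # centre within subject
    xc = x - np.bincount(inv, weights=x)[inv] / counts[inv]
    yc = y - np.bincount(inv, weights=y)[inv] / counts[inv]
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx <= ZERO_VARIANCE_EPSILON * max(1.0, float(x @ x)):
        raise ValueError("x constant within all subjects: slope undefined")
    if syy <= ZERO_VARIANCE_EPSILON * max(1.0, float(y @ y)):
        return 0.0, *_fisher_ci(0.0, df), df
    r = float(xc @ yc / np.sqrt(sxx * syy))
    r = float(np.clip(r, -1.0, 1.0))
    lo, hi = _fisher_ci(r, df)
    return r, lo, hi, df


def is_robust(metrics: RobustnessMetrics, criteria: RobustCriteria) -> bool:
    """Strict-inequality robust test on CV_mean and |r_rm|."""
    return (
        metrics.cv_mean < criteria.cv_threshold
        and metrics.rrm_abs < criteria.rrm_threshold
    )


def compute_metrics(
    table: FeatureTable,
    feature: str,
    grid: ParameterGrid,
    start: int = 0,
    end: int | None = None,
    strict_degenerate: bool = False,
) -> RobustnessMetrics:
    """Both robustness metrics for one feature over an inclusive sub-range.

    ``start``/``end`` are grid indices; the default covers the full grid.
    The slice must be complete (every subject at every grid value).
    """
    if end is None:
        end = grid.n - 1
    if not (0 <= start < end <= grid.n - 1):
        raise ValueError(f"invalid sub-range [{start}, {end}] for n={grid.n}")
    values = table.wide(feature, grid).to_numpy()
    return metrics_from_matrix(
        values,
        np.asarray(grid.values),
        start,
        end,
        strict_degenerate=strict_degenerate,
    )


def metrics_from_matrix(
    matrix: np.ndarray,
    xs: np.ndarray,
    start: int,
    end: int,
    strict_degenerate: bool = False,
) -> RobustnessMetrics:
    """Metrics over columns ``start..end`` of a subjects x parameters array."""
    values = np.asarray(matrix, dtype=float)[:, start : end + 1]
    flags: set[str] = set()

    const = np.ptp(values, axis=1) == 0
    if const.all():
        # e.g. shape features under discretisation: unaffected by the sweep
        flags.add("zero_variance_feature")
        n_subj, n_par = values.shape
        df = n_subj * n_par - n_subj - 1
        lo, hi = _fisher_ci(0.0, df)
        mlo, mhi = magnitude_ci(lo, hi)
        return RobustnessMetrics(
            cv_mean=0.0,
            cv_per_subject=[0.0] * n_subj,
            rrm=0.0,
            rrm_ci_low=mlo,
            rrm_ci_high=mhi,
            rrm_ci_signed=(lo, hi),
            df=df,
            n_subjects=n_subj,
            n_parameters=n_par,
            degenerate_flags=flags,
        )

    cvm, cvs, n_deg = cv_mean(values, strict=strict_degenerate)
    if n_deg:
        flags.add("zero_mean_subjects")
    xs = np.tile(np.asarray(xs, dtype=float)[start : end + 1], values.shape[0])
    ys = values.ravel()
    subj = np.repeat(np.arange(values.shape[0]), values.shape[1])
    r, lo, hi, df = rmcorr(xs, ys, subj)
    mlo, mhi = magnitude_ci(lo, hi)
    return RobustnessMetrics(
        cv_mean=cvm,
        cv_per_subject=cvs,
        rrm=r,
        rrm_ci_low=mlo,
        rrm_ci_high=mhi,
        rrm_ci_signed=(lo, hi),
        df=df,
        n_subjects=values.shape[0],
        n_parameters=values.shape[1],
        degenerate_flags=flags,
        n_degenerate_subjects=n_deg,
    )
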