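"""Dependency modelling and invertible correction of non-robust features.

Many radiomic features depend systematically on the discretisation or
interpolation parameter x. That dependence is modelled at the cohort level
by one of eight two-parameter invertible functions

    f(x) = a*g(x) + b,   g in {x, x^2, x^3, 1/x, 1/x^2, 1/x^3,
                               log(s*x), 1/log(s*x)}

fitted to the per-grid-value cohort mean curve by iteratively reweighted
least squares with a Huber loss, multiplied by intrinsic weights equal to
the reciprocal of the cross-subject feature variance at each grid value.
The best function is selected by the Akaike information criterion, and the
correction applies its rearranged (inverse) form per subject:

    f_corrected(x) = (f(x) - b) / g(x)

which is constant in x when the model holds exactly. For log-family
functions the argument is pre-multiplied by s = 100 for bin widths (SUV)
and s = 10 for voxel sizes (mm) so that log never vanishes on the default
grids; bin numbers (>= 8) need no scaling.

A correction is *statistically significant* when the two-sided Wilcoxon
signed-rank test on per-subject CVs gives p < 0.05, the 95% confidence
intervals of |r_rm| before and after do not overlap, and both metrics
decrease. A significantly corrected feature is *correctable* when it meets
the robust criteria afterwards, *moderately correctable* when it does not,
and *not correctable* otherwise.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .grids import Algorithm, ParameterGrid, RobustCriteria, Scheme
from .io import FeatureTable
from .metrics import RobustnessMetrics, compute_metrics, is_robust

__all__ = [
    "FunctionId",
    "DependencyModel",
    "CorrectabilityCategory",
    "CorrectionResult",
    "default_log_scale",
    "fit_dependency",
    "fit_all",
    "select_best_model",
    "apply_correction",
    "evaluate_correction",
    "correct_feature",
]

logger = logging.getLogger("radrobust")

HUBER_C = 1.345
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 50
VARIANCE_FLOOR = 1e-12
G_EPSILON = 1e-12
AIC_K = 3  # alpha, beta, noise scale


class FunctionId(str, enum.Enum):
    """The eight candidate dependency forms, in canonical order."""

    LIN = "lin"
    QUAD = "quad"
    CUB = "cub"
    INV = "inv"
    INV2 = "inv2"
    INV3 = "inv3"
    LOG = "log"
    INVLOG = "invlog"


_G_FUNCS: dict[FunctionId, Callable[[np.ndarray], np.ndarray]] = {
    FunctionId.LIN: lambda x: x,
    FunctionId.QUAD: lambda x: x**2,
    FunctionId.CUB: lambda x: x**3,
    FunctionId.INV: lambda x: 1.0 / x,
    FunctionId.INV2: lambda x: 1.0 / x**2,
    FunctionId.INV3: lambda x: 1.0 / x**3,
    FunctionId.LOG: lambda x: np.log(x),
    FunctionId.INVLOG: lambda x: 1.0 / np.log(x),
}

_LOG_FAMILY = (FunctionId.LOG, FunctionId.INVLOG)


class CorrectabilityCategory(str, enum.Enum):
    CORRECTABLE = "correctable"
    MODERATELY_CORRECTABLE = "moderately_correctable"
    NOT_CORRECTABLE = "not_correctable"


@dataclass
class DependencyModel:
    """One fitted dependency form f(x) = alpha * g(x) + beta."""

    function_id: FunctionId
    alpha: float
    beta: float
    scale_s: float
    aic: float
    n_points: int
    converged: bool
    n_iterations: int = 0

    def g(self, x: np.ndarray) -> np.ndarray:
        """The x-dependent factor, with the log-argument scale applied."""
        x = np.asarray(x, dtype=float)
        if self.function_id in _LOG_FAMILY:
            x = self.scale_s * x
        g = _G_FUNCS[self.function_id](x)
        if np.any(np.abs(g) < G_EPSILON) or not np.all(np.isfinite(g)):
            raise ValueError(
                f"g(x) vanishes or diverges on the grid for "
                f"{self.function_id.value} (scale {self.scale_s})"
            )
        return g

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.alpha * self.g(x) + self.beta


@dataclass
class CorrectionResult:
    """Full record of one feature's correction attempt."""

    feature_name: str
    scenario: str
    best_model: DependencyModel | None
    all_aics: dict[str, float]
    corrected_table: FeatureTable | None
    metrics_before: RobustnessMetrics
    metrics_after: RobustnessMetrics | None
    wilcoxon_p: float
    ci_overlap: bool
    delta_cv: float
    delta_rrm: float
    category: CorrectabilityCategory
    reason: str = ""


def default_log_scale(grid: ParameterGrid) -> float:
    """Log-argument multiplier: 100 for bin widths, 10 for voxel sizes.

    Keeps log(s*x) away from zero on the default grids (x = 1 would make
    g = log(x) vanish and 1/log(x) diverge). Bin numbers start at 8, so no
    scaling is needed there.
    """
    if grid.algorithm is Algorithm.FBW:
        return 100.0
    if grid.scheme is Scheme.INTERPOLATION:
        return 10.0
    return 1.0


def _wls(A: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
    return coef


def fit_dependency(
    mean_curve: np.ndarray,
    weights: np.ndarray,
    x: np.ndarray,
    function_id: FunctionId | str,
    scale_s: float = 1.0,
) -> DependencyModel:
    """Fit one dependency form to a cohort mean curve.

    ``mean_curve`` holds the cross-subject mean feature value at each grid
    value; ``weights`` are the intrinsic weights, the reciprocal of the
    cross-subject variance at each grid value (variances are floored at
    1e-12 before inversion by the caller). The Huber loss (c = 1.345)
    enters as multiplicative IRLS weights on top of the intrinsic ones.
    AIC uses the weighted Gaussian log-likelihood up to constants shared by
    all candidates: n*ln(weighted RSS / n) + 2k with k = 3.

    A singular design (g effectively constant over the grid) returns a
    non-converged model with infinite AIC, excluded from selection.
    """
    function_id = FunctionId(function_id)
    y = np.asarray(mean_curve, dtype=float)
    w_in = np.asarray(weights, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 grid points to fit a dependency")
    if not (np.all(np.isfinite(w_in)) and np.all(w_in > 0)):
        raise ValueError("intrinsic weights must be finite and positive")

    probe = DependencyModel(function_id, 1.0, 0.0, scale_s, np.inf, n, False)
    try:
        g = probe.g(x)
    except ValueError:
        return probe
    if np.ptp(g) < G_EPSILON * max(1.0, np.abs(g).max()):
        return probe  # g constant: alpha unidentifiable

    A = np.column_stack([g, np.ones(n)])
    coef = _wls(A, y, w_in)
    n_iter = 0
    for n_iter in range(1, IRLS_MAX_ITER + 1):
        r = y - A @ coef
        mad = np.median(np.abs(r - np.median(r)))
        sigma = mad / 0.6745
        if sigma < 1e-14:
            break  # (near-)perfect fit: Huber weights are all 1
        u = np.abs(r) / sigma
        w_h = np.minimum(1.0, HUBER_C / np.maximum(u, 1e-300))
        new = _wls(A, y, w_in * w_h)
        if np.max(np.abs(new - coef)) < IRLS_TOL:
            coef = new
            break
        coef = new
    r = y - A @ coef
    rss_w = float(np.sum(w_in * r**2))
    aic = n * np.log(max(rss_w, 1e-300) / n) + 2 * AIC_K
    return DependencyModel(
        function_id=function_id,
        alpha=float(coef[0]),
        beta=float(coef[1]),
        scale_s=scale_s,
        aic=float(aic),
        n_points=n,
        converged=True,
        n_iterations=n_iter,
    )


def cohort_mean_and_weights(
    table: FeatureTable, feature: str, grid: ParameterGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-subject mean curve and intrinsic (1/variance) weights."""
    mat = table.wide(feature, grid).to_numpy()
    mean = mat.mean(axis=0)
    var = mat.var(axis=0, ddof=1)
    n_floored = int(np.sum(var < VARIANCE_FLOOR))
    if n_floored:
        logger.info(
            "%s/%s: %d grid value(s) with cross-subject variance below "
            "floor %.0e",
            feature,
            grid.name,
            n_floored,
            VARIANCE_FLOOR,
        )
    return mean, 1.0 / np.maximum(var, VARIANCE_FLOOR)


def fit_all(
    table: FeatureTable,
    feature: str,
    grid: ParameterGrid,
    scale_s: float | None = None,
) -> list[DependencyModel]:
    """Fit all eight dependency forms to one feature's mean curve."""
    if scale_s is None:
        scale_s = default_log_scale(grid)
    mean, weights = cohort_mean_and_weights(table, feature, grid)
    x = np.asarray(grid.values)
    return [
        fit_dependency(
            mean, weights, x, fid, scale_s if fid in _LOG_FAMILY else 1.0
        )
        for fid in FunctionId
    ]


def select_best_model(fits: list[DependencyModel]) -> DependencyModel | None:
    """Minimum-AIC converged fit; ties break by canonical function order.

    Returns None when no fit converged (feature then reported
    not-correctable with a reason).
    """
    order = {fid: i for i, fid in enumerate(FunctionId)}
    converged = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not converged:
        return None
    return min(converged, key=lambda f: (f.aic, order[f.function_id]))


def apply_correction(
    table: FeatureTable,
    feature: str,
    grid: ParameterGrid,
    model: DependencyModel,
) -> FeatureTable:
    """Rearranged-inverse correction per subject and grid value.

    corrected(x) = (f(x) - beta) / g(x), with the cohort-level beta used
    for every subject. The output table is tagged ``corrected``;
    re-correcting a corrected table is refused.
    """
    if table.corrected:
        raise ValueError("table is already corrected; refusing to re-correct")
    if not model.converged:
        raise ValueError("cannot apply a non-converged model")
    sub = table.scenario(grid).feature_slice(feature).copy()
    if sub.empty:
        raise ValueError(f"no rows for feature {feature!r} on {grid.name}")
    g = model.g(sub["parameter_value"].to_numpy())
    sub["value"] = (sub["value"].to_numpy() - model.beta) / g
    return FeatureTable(sub, corrected=True)


def _per_subject_cvs(
    table: FeatureTable, feature: str, grid: ParameterGrid
) -> np.ndarray:
    mat = table.wide(feature, grid).to_numpy()
    sd = mat.std(axis=1, ddof=1)
    mean = np.abs(mat.mean(axis=1))
    out = np.zeros(len(sd))
    nz = sd > 0
    out[nz] = 100.0 * sd[nz] / np.maximum(mean[nz], 1e-300)
    return out


def evaluate_correction(
    before: FeatureTable,
    after: FeatureTable,
    feature: str,
    grid: ParameterGrid,
    criteria: RobustCriteria = RobustCriteria(),
    best_model: DependencyModel | None = None,
    all_aics: dict[str, float] | None = None,
) -> CorrectionResult:
    """Categorise a correction as (moderately) correctable or not.

    Pairs per-subject CVs before/after in a two-sided Wilcoxon signed-rank
    test and checks the 95% CIs of |r_rm| for overlap; both metrics must
    additionally *decrease*. No multiplicity adjustment is applied across
    features.
    """
    m_before = compute_metrics(before, feature, grid)
    m_after = compute_metrics(after, feature, grid)
    cv_b = _per_subject_cvs(before, feature, grid)
    cv_a = _per_subject_cvs(after, feature, grid)

    reason = ""
    if np.allclose(cv_b, cv_a):
        p = np.nan
        reason = "per-subject CVs unchanged; signed-rank test undefined"
    else:
        p = float(stats.wilcoxon(cv_b, cv_a, alternative="two-sided").pvalue)

    overlap = not (
        m_before.rrm_ci_low > m_after.rrm_ci_high
        or m_after.rrm_ci_low > m_before.rrm_ci_high
    )
    delta_cv = m_after.cv_mean - m_before.cv_mean
    delta_rrm = m_after.rrm_abs - m_before.rrm_abs
    significant = (
        np.isfinite(p)
        and p < 0.05
        and not overlap
        and delta_cv < 0
        and delta_rrm < 0
    )
    if significant:
        category = (
            CorrectabilityCategory.CORRECTABLE
            if is_robust(m_after, criteria)
            else CorrectabilityCategory.MODERATELY_CORRECTABLE
        )
    else:
        category = CorrectabilityCategory.NOT_CORRECTABLE
        if not reason:
            parts = []
            if not (np.isfinite(p) and p < 0.05):
                parts.append(f"Wilcoxon p={p:.3g}")
            if overlap:
                parts.append("|r_rm| CIs overlap")
            if delta_cv >= 0:
                parts.append("CV did not decrease")
            if delta_rrm >= 0:
                parts.append("|r_rm| did not decrease")
            reason = "; ".join(parts)
    return CorrectionResult(
        feature_name=feature,
        scenario=grid.name,
        best_model=best_model,
        all_aics=all_aics or {},
        corrected_table=after,
        metrics_before=m_before,
        metrics_after=m_after,
        wilcoxon_p=p,
        ci_overlap=overlap,
        delta_cv=delta_cv,
        delta_rrm=delta_rrm,
        category=category,
        reason=reason,
    )


def correct_feature(
    table: FeatureTable,
    feature: str,
    grid: ParameterGrid,
    criteria: RobustCriteria = RobustCriteria(),
) -> CorrectionResult:
    """Fit, select, correct and categorise one feature on one scenario."""
    fits = fit_all(table, feature, grid)
    aics = {f.function_id.value: f.aic for f in fits}
    best = select_best_model(fits)
    if best is None:
        m_before = compute_metrics(table, feature, grid)
        return CorrectionResult(
            feature_name=feature,
            scenario=grid.name,
            best_model=None,
            all_aics=aics,
            corrected_table=None,
            metrics_before=m_before,
            metrics_after=None,
            wilcoxon_p=np.nan,
            ci_overlap=True,
            delta_cv=np.nan,
            delta_rrm=np.nan,
            category=CorrectabilityCategory.NOT_CORRECTABLE,
            reason="no dependency model converged",
        )
    after = apply_correction(table, feature, grid, best)
    result = evaluate_correction(
        table, after, feature, grid, criteria, best_model=best, all_aics=aics
    )
    logger.info(
        "correction %s/%s: best=%s category=%s",
        feature,
        grid.name,
        best.function_id.value,
        result.category.value,
    )
    return result
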