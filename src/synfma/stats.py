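"""Statistical evaluation: severity classes, robust regression screening,
group comparisons, and the task-subset / duration-reduction arithmetic.

The merging-rate-versus-severity relationship is fitted by robust linear
regression with Tukey bisquare weighting (IRLS, tuning constant 4.685,
MAD-based scale).  Residuals are checked for homoskedasticity
(Breusch-Pagan), independence (Durbin-Watson, normal approximation) and
normality (Anderson-Darling); when an assumption fails, the outlying
subject whose removal restores the assumptions is removed and the fit
repeated, at most twice.  Items whose screened regression is
non-significant are candidates
for removal from the assessment, and the time saved is the duration share
of the removed items.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import het_breuschpagan, normal_ad
from statsmodels.stats.stattools import durbin_watson

from .types import ValidationError, FMA_MAX, N_TASK_ITEMS

BISQUARE_TUNING = 4.685
SEVERE_FMA_CUTOFF = 30


def severity_class(fma_score: int) -> str:
    """Severity class from the FMA total: severe below 30, mild otherwise."""
    if fma_score is None or not 0 <= fma_score <= FMA_MAX:
        raise ValidationError(f"FMA score {fma_score!r} outside 0..{FMA_MAX}")
    return "severe" if fma_score < SEVERE_FMA_CUTOFF else "mild"


# ---------------------------------------------------------------------------
# robust regression


@dataclass
class RobustFit:
    slope: float
    intercept: float
    p_incline: float
    se_slope: float
    weights: np.ndarray
    residuals: np.ndarray
    residuals_adjusted: np.ndarray   # leverage-adjusted, r / sqrt(1 - h)
    scale: float
    n_iter: int
    converged: bool


def _mad_scale(r: np.ndarray, n_params: int = 0) -> float:
    """Normal-consistent MAD scale, excluding the ``n_params`` smallest
    absolute residuals (they are pinned near zero by the fit itself)."""
    a = np.sort(np.abs(r))[n_params:]
    s = np.median(a) / 0.6745 if a.size else 0.0
    if s <= 0:
        # degenerate spread; fall back to a tiny positive scale so weights
        # stay defined (all residuals essentially zero)
        s = max(np.abs(r).max(), 1e-12)
    return float(s)


def _bisquare_weights(u: np.ndarray) -> np.ndarray:
    w = np.zeros_like(u)
    inside = np.abs(u) < 1
    w[inside] = (1 - u[inside] ** 2) ** 2
    return w


def robust_regression(x: Sequence[float], y: Sequence[float],
                      tol: float = 1e-8, max_iter: int = 100) -> RobustFit:
    """Robust line fit by IRLS with Tukey bisquare weights.

    The scale is re-estimated from the residual MAD at each iteration;
    convergence is a relative coefficient change below ``tol``.  The slope
    P-value comes from the asymptotic M-estimator covariance (Huber
    small-sample correction) referred to a t distribution with n-2 degrees
    of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValidationError("robust regression needs at least 4 points")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant; slope undefined")
    X = np.column_stack([np.ones(n), x])
    # leverage adjustment: residuals at high-leverage points are shrunk by
    # the fit, so they are inflated back before weighting
    hat = np.einsum("ij,jk,ik->i", X, np.linalg.inv(X.T @ X), X)
    adj = 1.0 / np.sqrt(np.clip(1.0 - hat, 1e-8, None))

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    converged = False
    it = 0
    w = np.ones(n)
    for it in range(1, max_iter + 1):
        r = (y - X @ beta) * adj
        s = _mad_scale(r, n_params=2)
        u = r / (BISQUARE_TUNING * s)
        w = _bisquare_weights(u)
        if w.sum() == 0:   # pathological: everything downweighted to zero
            w = np.ones(n)
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ y)
        delta = np.max(np.abs(beta_new - beta)) / max(np.max(np.abs(beta_new)), 1e-12)
        beta = beta_new
        if delta < tol:
            converged = True
            break

    r = y - X @ beta
    radj = r * adj
    s = _mad_scale(radj, n_params=2)
    u = radj / (BISQUARE_TUNING * s)
    # asymptotic covariance of the bisquare M-estimator, with Huber's
    # small-sample correction factor for the psi-derivative variability
    psi = np.where(np.abs(u) < 1, u * (1 - u**2) ** 2, 0.0)
    dpsi = np.where(np.abs(u) < 1, (1 - u**2) * (1 - 5 * u**2), 0.0)
    p_dim = 2
    mean_dpsi = max(dpsi.mean(), 1e-12)
    K = 1.0 + p_dim / n * np.var(dpsi) / mean_dpsi**2
    sigma2 = (
        K**2
        * (BISQUARE_TUNING * s) ** 2
        * np.sum(psi**2) / (n - p_dim)
        / mean_dpsi**2
    )
    XtX_inv = np.linalg.inv(X.T @ X)
    se_slope = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    tstat = beta[1] / se_slope if se_slope > 0 else np.inf
    p = 2 * sps.t.sf(abs(tstat), n - p_dim)
    return RobustFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        p_incline=float(p),
        se_slope=se_slope,
        weights=w,
        residuals=r,
        residuals_adjusted=radj,
        scale=s,
        n_iter=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# residual diagnostics


class DiagnosticsError(ValueError):
    pass


def regression_diagnostics(residuals: Sequence[float], x: Sequence[float]
                           ) -> dict[str, float]:
    """Breusch-Pagan, Durbin-Watson (normal approximation) and
    Anderson-Darling P-values for a set of regression residuals."""
    r = np.asarray(residuals, dtype=float)
    x = np.asarray(x, dtype=float)
    if r.size < 5:
        raise ValidationError("diagnostics need at least 5 residuals")
    if np.ptp(r) == 0:
        raise DiagnosticsError("residuals are all equal; diagnostics undefined")
    exog = np.column_stack([np.ones_like(x), x])
    _, bp_p, _, _ = het_breuschpagan(r, exog)
    d = durbin_watson(r)
    # under the null d ~ N(2, 4/n) to first order
    z = (d - 2.0) / np.sqrt(4.0 / r.size)
    dw_p = 2 * sps.norm.sf(abs(z))
    _, ad_p = normal_ad(r)
    return {
        "breusch_pagan_p": float(bp_p),
        "durbin_watson_p": float(dw_p),
        "anderson_darling_p": float(ad_p),
    }


# ---------------------------------------------------------------------------
# outlier-screened regression


@dataclass
class ScreenEntry:
    """One task item's screened merging-rate-versus-FMA regression."""

    slope: float
    intercept: float
    p_incline: float
    diagnostics: dict[str, float]
    removed_subjects: list[str]
    n_used: int
    assumptions_met: bool
    converged: bool = True


def outlier_screened_regression(x: Sequence[float], y: Sequence[float],
                                subject_ids: Optional[Sequence[str]] = None,
                                max_removals: int = 2,
                                alpha: float = 0.05) -> ScreenEntry:
    """Robust regression with assumption-driven removal of up to two subjects.

    After each fit the three residual diagnostics are checked.  If any
    P-value is at or below ``alpha``, the removal targets the outlier whose
    deletion actually repairs the fit: among subjects whose removal leaves
    all diagnostics above ``alpha``, the one with the largest absolute
    (leverage-adjusted) residual is dropped; if no single removal restores
    the assumptions, the largest-residual subject is dropped regardless.
    The fit then repeats, at most ``max_removals`` times; if the
    assumptions still fail the last fit is kept with
    ``assumptions_met=False``.

    Tying the removal to assumption restoration keeps the screen close to
    its nominal level under the null: unconditionally truncating the
    largest residual shrinks the scale estimate round after round and
    inflates the type-I error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if subject_ids is None:
        subject_ids = [str(i) for i in range(x.size)]
    subject_ids = list(subject_ids)
    if x.size < 6:
        raise ValidationError("screened regression needs at least 6 points")

    keep = np.ones(x.size, dtype=bool)
    removed: list[str] = []
    while True:
        fit = robust_regression(x[keep], y[keep])
        diags = regression_diagnostics(fit.residuals_adjusted, x[keep])
        ok = all(p > alpha for p in diags.values())
        # stop removing when another removal would leave too few points for
        # the diagnostics themselves
        if ok or len(removed) >= max_removals or keep.sum() <= 6:
            return ScreenEntry(
                slope=fit.slope,
                intercept=fit.intercept,
                p_incline=fit.p_incline,
                diagnostics=diags,
                removed_subjects=removed,
                n_used=int(keep.sum()),
                assumptions_met=ok,
                converged=fit.converged,
            )
        idx_kept = list(np.flatnonzero(keep))
        restoring = []
        for j in idx_kept:
            trial_keep = keep.copy()
            trial_keep[j] = False
            f2 = robust_regression(x[trial_keep], y[trial_keep])
            d2 = regression_diagnostics(f2.residuals_adjusted, x[trial_keep])
            if all(p > alpha for p in d2.values()):
                restoring.append(j)
        pool = restoring if restoring else idx_kept
        worst = max(pool,
                    key=lambda j: abs(fit.residuals_adjusted[idx_kept.index(j)]))
        worst_subject = subject_ids[worst]
        removed.append(worst_subject)
        for i, sid in enumerate(subject_ids):
            if sid == worst_subject:
                keep[i] = False


# ---------------------------------------------------------------------------
# group tests


@dataclass
class GroupTestReport:
    anova_f: float
    anova_p: float
    tukey_p: dict[tuple[str, str], float]
    ttest: dict[tuple[str, str], tuple[float, float]]   # (t, p)


def group_tests(values_by_group: dict[str, Sequence[float]],
                equal_var: bool = True) -> GroupTestReport:
    """One-way ANOVA, Tukey-Kramer pairwise comparisons, and pairwise t-tests.

    The Tukey-Kramer procedure honours unequal group sizes.  ``equal_var``
    toggles Student (default) versus Welch t-tests.
    """
    names = list(values_by_group)
    groups = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValidationError("need >= 2 groups with >= 2 values each")
    f, p = sps.f_oneway(*groups)
    hsd = sps.tukey_hsd(*groups)
    tukey = {}
    ttest = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            tukey[(names[i], names[j])] = float(hsd.pvalue[i, j])
            t, tp = sps.ttest_ind(groups[i], groups[j], equal_var=equal_var)
            ttest[(names[i], names[j])] = (float(t), float(tp))
    return GroupTestReport(anova_f=float(f), anova_p=float(p),
                           tukey_p=tukey, ttest=ttest)


def two_way_anova(values: Sequence[float], factor_a: Sequence[str],
                  factor_b: Sequence[str]) -> dict[str, tuple[float, float]]:
    """Additive two-way ANOVA; returns per-factor (F, P)."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "a": list(factor_a), "b": list(factor_b)})
    model = smf.ols("value ~ C(a) + C(b)", data=df).fit()
    table = anova_lm(model, typ=2)
    return {
        "factor_a": (float(table.loc["C(a)", "F"]), float(table.loc["C(a)", "PR(>F)"])),
        "factor_b": (float(table.loc["C(b)", "F"]), float(table.loc["C(b)", "PR(>F)"])),
    }


# ---------------------------------------------------------------------------
# task-subset selection and duration arithmetic


@dataclass
class TaskSubset:
    retained: list[int]
    removed: list[int]
    missing: list[int]


def select_task_subset(p_values: Sequence[float], alpha: float = 0.05
                       ) -> TaskSubset:
    """Split the 37 items into retained (P < alpha) and removal candidates.

    Items with a missing P-value (NaN) are flagged separately and not
    counted as retained.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size != N_TASK_ITEMS:
        raise ValidationError(f"expected {N_TASK_ITEMS} P-values, got {p.size}")
    retained, removed, missing = [], [], []
    for i, pv in enumerate(p, start=1):
        if np.isnan(pv):
            missing.append(i)
        elif pv < alpha:
            retained.append(i)
        else:
            removed.append(i)
    return TaskSubset(retained=retained, removed=removed, missing=missing)


def duration_reduction(item_durations: Sequence[float],
                       removed_items: Sequence[int]) -> float:
    """Percent of total assessment time saved by dropping the removed items."""
    d = np.asarray(item_durations, dtype=float)
    if d.size != N_TASK_ITEMS:
        raise ValidationError(f"expected {N_TASK_ITEMS} durations, got {d.size}")
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise ValidationError("item durations must be positive and finite")
    removed = set(removed_items)
    if not removed <= set(range(1, N_TASK_ITEMS + 1)):
        raise ValidationError("removed item ids must be in 1..37")
    total = d.sum()
    removed_time = sum(d[i - 1] for i in removed)
    return float(100.0 * removed_time / total)
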