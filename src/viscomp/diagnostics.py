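"""Regression outlier diagnostics for purging extreme stimuli.

After a model of the ratings has been trained, a linear fit of the rating
on the selected features is screened for samples that distort it:

* **leverage** ``h_i`` — diagonal of the hat (projection) matrix;
* **externally studentized residuals** ``t_i`` — residual divided by a
  deletion-based standard error, t-distributed with n - p - 1 df under the
  model;
* **Cook's distance** ``D_i = r_i^2 / p * h_i / (1 - h_i)`` with ``r_i`` the
  internally studentized residual — the scaled shift of the coefficient
  vector when sample i is deleted;
* **Bonferroni outlier test** — n * (two-sided tail of the largest |t_i|);
* **Tukey non-additivity test** — t-test on the squared fitted values added
  as a regressor, probing lack of fit of the additive model.

The flagging rule is explicit and configurable: a sample is flagged when
(D_i > d_thresh AND |t_i| > t_thresh) OR its Bonferroni-adjusted p-value
falls below alpha; defaults are the conventional cutoffs 4/n, 3 and 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "LinearFitContext",
    "OutlierReport",
    "FlagConfig",
    "fit_context",
    "hat_values",
    "studentized_residuals",
    "internally_studentized_residuals",
    "cooks_distance",
    "bonferroni_outlier_test",
    "tukey_nonadditivity",
    "flag_outliers",
    "outlier_report",
]

#: Sentinel reported for a studentized residual at an exact-leverage point.
LEVERAGE_SENTINEL = np.inf


@dataclass
class LinearFitContext:
    """An OLS fit of the rating on selected features, with influence state."""

    design: np.ndarray        # n x p, includes the intercept column
    response: np.ndarray
    ids: list
    results: object           # statsmodels RegressionResults
    influence: object         # statsmodels OLSInfluence

    @property
    def n(self) -> int:
        return self.response.size

    @property
    def p(self) -> int:
        return self.design.shape[1]

    @property
    def df(self) -> int:
        return self.n - self.p

    @property
    def fitted(self) -> np.ndarray:
        return np.asarray(self.results.fittedvalues)

    @property
    def residuals(self) -> np.ndarray:
        return np.asarray(self.results.resid)


def fit_context(X: np.ndarray, y: np.ndarray, ids=None,
                add_intercept: bool = True) -> LinearFitContext:
    """Fit the diagnostic OLS model y ~ X (with intercept by default)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(y).size == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float)
    A = sm.add_constant(X, has_constant="add") if add_intercept else X
    if np.linalg.matrix_rank(A) < A.shape[1]:
        warnings.warn("rank-deficient diagnostic design; leverages computed "
                      "with the pseudo-inverse", stacklevel=2)
    res = sm.OLS(y, A).fit()
    infl = res.get_influence()
    if ids is None:
        ids = list(range(y.size))
    return LinearFitContext(design=A, response=y, ids=list(ids),
                            results=res, influence=infl)


def hat_values(context: LinearFitContext) -> np.ndarray:
    """Leverages: diagonal of the projection onto the design column space."""
    return np.asarray(context.influence.hat_matrix_diag)


def internally_studentized_residuals(context: LinearFitContext) -> np.ndarray:
    """Residuals scaled by the full-sample error estimate: e_i / (s sqrt(1-h_i))."""
    return np.asarray(context.influence.resid_studentized_internal)


def studentized_residuals(context: LinearFitContext) -> np.ndarray:
    """Externally studentized residuals e_i / (s_(-i) sqrt(1 - h_i)).

    Points with h_i = 1 are fit exactly and have no deletion residual; they
    are reported as an infinite sentinel with a warning.
    """
    if context.df < 2:
        raise ValueError("need residual df >= 2 to studentize")
    h = hat_values(context)
    # exact fit: all residuals are numerically zero and the 0/0 studentized
    # ratios would be floating-point noise
    scale = max(1.0, float(np.std(context.response)))
    if np.sqrt(context.results.mse_resid) <= 1e-10 * scale:
        return np.zeros(context.n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.asarray(context.influence.resid_studentized_external)
    exact = h >= 1.0 - 1e-12
    if np.any(exact):
        warnings.warn(f"{exact.sum()} leverage-one point(s): studentized "
                      "residual undefined, reported as inf", stacklevel=2)
        t = np.where(exact, LEVERAGE_SENTINEL, t)
    return t


def cooks_distance(context: LinearFitContext) -> np.ndarray:
    """Cook's distance D_i = (r_i^2 / p) * h_i / (1 - h_i)."""
    scale = max(1.0, float(np.std(context.response)))
    if np.sqrt(context.results.mse_resid) <= 1e-10 * scale:
        return np.zeros(context.n)  # exact fit: no deletion influence
    return np.asarray(context.influence.cooks_distance[0])


def bonferroni_outlier_test(context: LinearFitContext):
    """Bonferroni-corrected outlier test on the largest |t_i|.

    Returns (sample id, adjusted p) where p = min(1, n * 2 * P(T_df-1 > |t|))
    with df the residual degrees of freedom of the diagnostic fit.
    """
    if context.df < 3:
        raise ValueError("need residual df >= 3 for the outlier test")
    t = studentized_residuals(context)
    finite = np.isfinite(t)
    t_eff = np.where(finite, np.abs(t), np.inf)
    worst = int(np.argmax(t_eff))
    raw = 2.0 * stats.t.sf(abs(t[worst]), context.df - 1) if finite[worst] else 0.0
    p_adj = min(1.0, context.n * raw)
    return context.ids[worst], float(p_adj)


def bonferroni_adjusted_p(context: LinearFitContext) -> np.ndarray:
    """Per-sample Bonferroni-adjusted two-sided outlier p-values."""
    t = studentized_residuals(context)
    raw = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), context.df - 1),
                   0.0)
    return np.minimum(1.0, context.n * raw)


def tukey_nonadditivity(context: LinearFitContext) -> float:
    """Tukey's one-degree-of-freedom test for non-additivity.

    The squared fitted values are added to the design and the added
    coefficient is t-tested; small p indicates curvature the additive model
    misses.  Degenerate cases (constant response, collinear augmentation)
    return p = 1 with a warning.
    """
    yhat = context.fitted
    if np.ptp(context.response) <= 1e-12:
        warnings.warn("constant response: non-additivity test degenerate",
                      stacklevel=2)
        return 1.0
    aug = np.column_stack([context.design, yhat ** 2])
    if np.linalg.matrix_rank(aug) <= np.linalg.matrix_rank(context.design):
        warnings.warn("squared fitted values are collinear with the design; "
                      "returning p = 1", stacklevel=2)
        return 1.0
    res = sm.OLS(context.response, aug).fit()
    return float(res.pvalues[-1])


@dataclass(frozen=True)
class FlagConfig:
    """Thresholds of the combined outlier-flagging rule."""

    cooks_factor: float = 4.0     # D_i > cooks_factor / n
    t_threshold: float = 3.0      # AND |t_i| above this ...
    bonferroni_alpha: float = 0.05  # ... OR Bonferroni-significant


@dataclass
class OutlierReport:
    """Per-sample influence measures and the flag decision."""

    ids: list
    leverage: np.ndarray
    studentized: np.ndarray
    cooks: np.ndarray
    bonferroni_p: np.ndarray
    flagged: list
    tukey_p: float
    max_residual_p: float
    config: FlagConfig = field(default_factory=FlagConfig)


def flag_outliers(context: LinearFitContext,
                  config: FlagConfig | None = None) -> list:
    """Apply the combined flagging rule; returns flagged sample ids.

    Deterministic and monotone in each threshold: loosening any threshold
    can only unflag, tightening can only add flags.
    """
    if config is None:
        config = FlagConfig()
    h = hat_values(context)
    t = studentized_residuals(context)
    d = cooks_distance(context)
    p_adj = bonferroni_adjusted_p(context)
    rule = ((d > config.cooks_factor / context.n)
            & (np.abs(t) > config.t_threshold)) \
        | (p_adj < config.bonferroni_alpha)
    return [context.ids[i] for i in np.nonzero(rule)[0]]


def outlier_report(X: np.ndarray, y: np.ndarray, ids=None,
                   config: FlagConfig | None = None) -> OutlierReport:
    """One-call diagnostics: fit, influence measures, tests and flags."""
    if config is None:
        config = FlagConfig()
    ctx = fit_context(X, y, ids=ids)
    worst_id, p_worst = bonferroni_outlier_test(ctx)
    return OutlierReport(
        ids=ctx.ids,
        leverage=hat_values(ctx),
        studentized=studentized_residuals(ctx),
        cooks=cooks_distance(ctx),
        bonferroni_p=bonferroni_adjusted_p(ctx),
        flagged=flag_outliers(ctx, config),
        tukey_p=tukey_nonadditivity(ctx),
        max_residual_p=p_worst,
        config=config,
    )
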