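"""Comparison regressors for the visual-complexity benchmark.

Five standard methods, each with the hyperparameters conventionally used on
this problem:

* **LM** — multiple linear regression on all features, no selection.
* **GLM (stepwise)** — Gaussian GLM with bidirectional stepwise feature
  selection minimizing AIC.
* **Lasso** — L1-constrained regression parameterized by ``fraction``: the
  coefficient L1 norm is budgeted at ``fraction`` times the L1 norm of the
  unpenalized least-squares solution (default 0.1), resolved exactly along
  the LARS path.
* **ENET** — elastic net with mixing parameter ``alpha`` (default 0.8) and
  penalty magnitude chosen by internal 10-fold cross-validation.
* **SVM-RFE** — recursive feature elimination around an epsilon-insensitive
  SVR, ranking features by the squared-weight criterion w^2 (for nonlinear
  kernels, the drop in 1/2 a'Ka when the feature leaves the kernel), halving
  the feature set per iteration down to ``bestsubsetsize`` (default 256;
  sigma = 2^-6, C = 10, epsilon = 0.01).

Every fit standardizes features with training statistics; predictions apply
the stored statistics, so the fitted objects are safe to use inside
cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from sklearn.linear_model import ElasticNetCV, Ridge, lars_path
from sklearn.svm import SVR

__all__ = [
    "BaselineSpec",
    "FittedBaseline",
    "fit_lm",
    "fit_glm_stepwise",
    "fit_lasso",
    "fit_enet",
    "svm_rfe",
    "fit_baseline",
    "predict_baseline",
]

METHODS = ("LM", "GLM_stepwise", "Lasso", "ENET", "SVM_RFE")

_DEFAULT_PARAMS = {
    "LM": {},
    "GLM_stepwise": {},
    "Lasso": {"fraction": 0.1},
    "ENET": {"alpha": 0.8},
    "SVM_RFE": {"bestsubsetsize": 256, "sigma": 2.0 ** -6, "C": 10.0,
                "epsilon": 0.01},
}


@dataclass(frozen=True)
class BaselineSpec:
    """A baseline method plus its hyperparameters."""

    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; "
                             f"choose from {METHODS}")
        merged = dict(_DEFAULT_PARAMS[self.method])
        unknown = set(self.params) - set(merged)
        if unknown:
            raise ValueError(f"{self.method} does not take parameters "
                             f"{sorted(unknown)}")
        merged.update(self.params)
        object.__setattr__(self, "params", merged)


@dataclass
class FittedBaseline:
    """A fitted baseline: linear coefficients or an SVR dual model."""

    method: str
    mean: np.ndarray
    std: np.ndarray
    selected: list                      # surviving feature indices
    coef: np.ndarray | None = None      # linear methods (on standardized X)
    intercept: float = 0.0
    svr: object | None = None           # SVM_RFE final model

    def predict(self, Xnew: np.ndarray) -> np.ndarray:
        return predict_baseline(self, Xnew)

    @property
    def selected_features_(self) -> list:
        return self.selected


def _standardize(X: np.ndarray):
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return (X - mean) / std, mean, std


# --------------------------------------------------------------------------
# LM
# --------------------------------------------------------------------------

def fit_lm(X: np.ndarray, y: np.ndarray) -> FittedBaseline:
    """Ordinary least squares on all features (minimum-norm on rank-deficient
    designs, with a warning)."""
    Xs, mean, std = _standardize(X)
    y = np.asarray(y, dtype=float)
    A = np.column_stack([np.ones(Xs.shape[0]), Xs])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        import warnings
        warnings.warn("rank-deficient design: using the minimum-norm "
                      "least-squares solution", stacklevel=2)
    return FittedBaseline(method="LM", mean=mean, std=std,
                          selected=list(range(X.shape[1])),
                          coef=coef[1:], intercept=float(coef[0]))


# --------------------------------------------------------------------------
# stepwise-AIC GLM
# --------------------------------------------------------------------------

def _ols_aic(y: np.ndarray, cols: list, Xs: np.ndarray) -> float:
    A = np.column_stack([np.ones(y.size)] + [Xs[:, j] for j in cols])
    return sm.OLS(y, A).fit().aic


def fit_glm_stepwise(X: np.ndarray, y: np.ndarray,
                     max_steps: int = 1000) -> FittedBaseline:
    """Bidirectional stepwise selection from the intercept-only model,
    minimizing AIC at each step; stops when no single add/drop improves it.
    An empty (intercept-only) model is a legal outcome."""
    Xs, mean, std = _standardize(X)
    y = np.asarray(y, dtype=float)
    p = Xs.shape[1]
    current: list = []
    best_aic = _ols_aic(y, current, Xs)
    for _ in range(max_steps):
        moves = []
        for j in range(p):
            if j in current:
                moves.append(([c for c in current if c != j], ("drop", j)))
            else:
                moves.append((sorted(current + [j]), ("add", j)))
        aics = [(_ols_aic(y, cols, Xs), cols) for cols, _ in moves]
        aic_new, cols_new = min(aics, key=lambda t: t[0])
        if aic_new >= best_aic - 1e-10:
            break
        best_aic, current = aic_new, cols_new
    A = np.column_stack([np.ones(y.size)] + [Xs[:, j] for j in current])
    fit = sm.OLS(y, A).fit()
    coef = np.zeros(p)
    for i, j in enumerate(current):
        coef[j] = fit.params[i + 1]
    return FittedBaseline(method="GLM_stepwise", mean=mean, std=std,
                          selected=sorted(current), coef=coef,
                          intercept=float(fit.params[0]))


# --------------------------------------------------------------------------
# Lasso (fraction parameterization) and Elastic Net
# --------------------------------------------------------------------------

def fit_lasso(X: np.ndarray, y: np.ndarray, fraction: float = 0.1) -> FittedBaseline:
    """Lasso at an L1 budget of ``fraction`` x ||beta_OLS||_1.

    The LARS path is piecewise linear in the coefficients, so the solution at
    the exact budget is obtained by interpolating between the two bracketing
    path knots; fraction = 1 recovers the least-squares solution.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    Xs, mean, std = _standardize(X)
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    _, _, coefs = lars_path(Xs, yc, method="lasso")
    l1 = np.abs(coefs).sum(axis=0)
    budget = fraction * l1[-1]
    if l1[-1] == 0:
        beta = coefs[:, -1]
    elif budget >= l1[-1]:
        beta = coefs[:, -1]
    else:
        hi = int(np.searchsorted(l1, budget))
        lo = hi - 1
        span = l1[hi] - l1[lo]
        w = (budget - l1[lo]) / span if span > 0 else 0.0
        beta = (1 - w) * coefs[:, lo] + w * coefs[:, hi]
    selected = [int(j) for j in np.nonzero(np.abs(beta) > 1e-12)[0]]
    return FittedBaseline(method="Lasso", mean=mean, std=std,
                          selected=selected, coef=beta,
                          intercept=float(y.mean()))


def fit_enet(X: np.ndarray, y: np.ndarray, alpha: float = 0.8,
             n_alphas: int = 50, cv: int = 10,
             random_state: int = 0) -> FittedBaseline:
    """Elastic net with L1 ratio ``alpha``; penalty magnitude picked by
    internal cross-validation on a 50-point log-spaced grid.

    alpha = 1 is the Lasso limit; alpha = 0 is ridge (handled separately
    since the coordinate-descent grid degenerates there).
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    Xs, mean, std = _standardize(X)
    y = np.asarray(y, dtype=float)
    if alpha == 0.0:
        model = Ridge(alpha=1.0).fit(Xs, y)
        coef, intercept = model.coef_, float(model.intercept_)
    else:
        model = ElasticNetCV(l1_ratio=alpha, alphas=n_alphas, cv=cv,
                             random_state=random_state, max_iter=50_000)
        model.fit(Xs, y)
        coef, intercept = model.coef_, float(model.intercept_)
    selected = [int(j) for j in np.nonzero(np.abs(coef) > 1e-12)[0]]
    return FittedBaseline(method="ENET", mean=mean, std=std,
                          selected=selected, coef=coef, intercept=intercept)


# --------------------------------------------------------------------------
# SVM-RFE
# --------------------------------------------------------------------------

def _rbf_gram(XA: np.ndarray, XB: np.ndarray, sigma: float) -> np.ndarray:
    # kernlab rbfdot convention: exp(-sigma * ||x - x'||^2), which is the
    # scale on which the conventional sigma = 2^-6 default is expressed
    d2 = (np.sum(XA * XA, axis=1)[:, None] + np.sum(XB * XB, axis=1)[None, :]
          - 2.0 * XA @ XB.T)
    np.clip(d2, 0.0, None, out=d2)
    return np.exp(-sigma * d2)


def _rfe_criterion(Xs: np.ndarray, alpha: np.ndarray, features: list,
                   sigma: float) -> np.ndarray:
    """w^2 importance per surviving feature.

    For the Gaussian kernel the criterion is the decrease of 1/2 a'Ka when a
    feature is dropped from the kernel (alpha held fixed); for a linear
    kernel this reduces to the classical squared weight w_f^2.
    """
    sv = np.nonzero(alpha)[0]
    a = alpha[sv]
    Xsv = Xs[sv][:, features]
    K = _rbf_gram(Xsv, Xsv, sigma)
    base = 0.5 * a @ K @ a
    crit = np.empty(len(features))
    d2_full = (np.sum(Xsv * Xsv, axis=1)[:, None]
               + np.sum(Xsv * Xsv, axis=1)[None, :] - 2.0 * Xsv @ Xsv.T)
    np.clip(d2_full, 0.0, None, out=d2_full)
    for i in range(len(features)):
        col = Xsv[:, i]
        d2_f = (col[:, None] - col[None, :]) ** 2
        K_minus = np.exp(-sigma * (d2_full - d2_f))
        crit[i] = abs(base - 0.5 * a @ K_minus @ a)
    return crit


def svm_rfe(X: np.ndarray, y: np.ndarray, bestsubsetsize: int = 256,
            sigma: float = 2.0 ** -6, C: float = 10.0,
            epsilon: float = 0.01) -> FittedBaseline:
    """Recursive feature elimination around a Gaussian-kernel SVR.

    Each round fits the SVR on the survivors, scores every feature by the
    w^2 criterion and removes the lowest-scoring half (never dropping below
    ``bestsubsetsize``); ties are broken by column order.  The final model is
    refit on the survivors.
    """
    p = np.asarray(X).shape[1]
    if bestsubsetsize > p:
        raise ValueError(f"bestsubsetsize={bestsubsetsize} exceeds the "
                         f"{p} available features")
    Xs, mean, std = _standardize(X)
    y = np.asarray(y, dtype=float)
    features = list(range(p))
    while len(features) > bestsubsetsize:
        K = _rbf_gram(Xs[:, features], Xs[:, features], sigma)
        svr = SVR(kernel="precomputed", C=C, epsilon=epsilon).fit(K, y)
        alpha = np.zeros(y.size)
        alpha[svr.support_] = svr.dual_coef_[0]
        crit = _rfe_criterion(Xs, alpha, features, sigma)
        keep = max(bestsubsetsize, len(features) // 2)
        # stable sort keeps earlier columns on ties
        order = np.argsort(-crit, kind="stable")[:keep]
        features = sorted(features[i] for i in order)
    K = _rbf_gram(Xs[:, features], Xs[:, features], sigma)
    svr = SVR(kernel="precomputed", C=C, epsilon=epsilon).fit(K, y)
    fitted = FittedBaseline(method="SVM_RFE", mean=mean, std=std,
                            selected=list(features), svr=svr)
    fitted._sigma = sigma
    fitted._X_train = Xs[:, features]
    return fitted


# --------------------------------------------------------------------------
# dispatch
# --------------------------------------------------------------------------

def fit_baseline(spec: BaselineSpec, X: np.ndarray, y: np.ndarray) -> FittedBaseline:
    """Fit any baseline from its spec."""
    p = spec.params
    if spec.method == "LM":
        return fit_lm(X, y)
    if spec.method == "GLM_stepwise":
        return fit_glm_stepwise(X, y)
    if spec.method == "Lasso":
        return fit_lasso(X, y, fraction=p["fraction"])
    if spec.method == "ENET":
        return fit_enet(X, y, alpha=p["alpha"])
    return svm_rfe(X, y, bestsubsetsize=p["bestsubsetsize"],
                   sigma=p["sigma"], C=p["C"], epsilon=p["epsilon"])


def predict_baseline(model: FittedBaseline, Xnew: np.ndarray) -> np.ndarray:
    """Predict with training standardization; errors on column mismatch."""
    Xnew = np.asarray(Xnew, dtype=float)
    if Xnew.shape[1] != model.mean.size:
        raise ValueError(f"expected {model.mean.size} features, "
                         f"got {Xnew.shape[1]}")
    Xs = (Xnew - model.mean) / model.std
    if model.method == "SVM_RFE":
        K = _rbf_gram(Xs[:, model.selected], model._X_train, model._sigma)
        alpha = np.zeros(model._X_train.shape[0])
        alpha[model.svr.support_] = model.svr.dual_coef_[0]
        return K @ alpha + float(model.svr.intercept_[0])
    return Xs @ model.coef + model.intercept
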