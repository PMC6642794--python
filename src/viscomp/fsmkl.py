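"""Feature-Selection Multiple Kernel Learning (FSMKL) for regression.

The model predicts a real-valued rating from a high-dimensional, highly
redundant feature table by learning a convex combination of base kernels,

    K(d) = sum_m d_m K_m,   d on the probability simplex,

jointly with an epsilon-insensitive support vector regression (SVR) on
K(d).  What makes the approach a *feature selection* method is how the
kernel bank is built:

1. features are ranked by a filter criterion (|Pearson correlation| with
   the rating);
2. features are partitioned into groups of mutually correlated columns
   (complete-linkage clustering on 1 - |corr|);
3. within each group of size n, the top-k ranked members for k = 2..n form
   nested subsets, and every subset is crossed with every kernel
   specification in the bank (Gaussian with a range of bandwidths,
   polynomial with a range of degrees).

Because each candidate kernel sees only a feature subset, the learned
simplex weights double as a feature-importance signal: the accumulated
weight of a feature is the total weight of the active kernels whose subset
contains it.

The simplex weights are optimized SimpleMKL-style: the objective
J(d) = optimal SVR dual value on K(d) is minimized by projected gradient
with a monotone (backtracking) line search, the gradient being
dJ/dd_m = -1/2 alpha' K_m alpha at the current dual solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import complete, fcluster
from scipy.spatial.distance import squareform
from sklearn.svm import SVR

__all__ = [
    "KernelSpec",
    "CandidateKernel",
    "MKLSolution",
    "FSMKLConfig",
    "FSMKLModel",
    "DEFAULT_KERNEL_BANK",
    "filter_rank",
    "group_features",
    "enumerate_subset_kernels",
    "compute_gram",
    "svr_dual_solve",
    "fit_simplemkl",
    "predict",
    "feature_importance",
    "fsmkl_select",
]


# --------------------------------------------------------------------------
# kernel specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelSpec:
    """One base-kernel specification.

    Gaussian kernels use ``exp(-||x - x'||^2 / (2 sigma^2))``; polynomial
    kernels use ``(x . x' + 1)^degree``.
    """

    kind: str               # "gaussian" | "polynomial"
    sigma: float = 1.0      # gaussian bandwidth
    degree: int = 1         # polynomial degree

    def __post_init__(self):
        if self.kind not in ("gaussian", "polynomial"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "gaussian" and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.kind == "polynomial" and self.degree < 1:
            raise ValueError("degree must be a positive integer")

    def __str__(self) -> str:
        return (f"gaussian(sigma={self.sigma:g})" if self.kind == "gaussian"
                else f"polynomial(degree={self.degree})")


#: The standard bank: Gaussian bandwidths 0.1-2 plus polynomial degrees 1-4.
DEFAULT_KERNEL_BANK = tuple(
    [KernelSpec("gaussian", sigma=s) for s in (0.1, 0.2, 0.3, 0.4, 0.5, 1.0, 2.0)]
    + [KernelSpec("polynomial", degree=d) for d in (1, 2, 3, 4)]
)


@dataclass
class CandidateKernel:
    """A ranked feature subset paired with a kernel specification."""

    subset: tuple           # ordered feature indices (global column numbers)
    spec: KernelSpec
    gram: np.ndarray | None = None
    diag_mean: float = 1.0  # training diagonal mean used for normalization

    def __post_init__(self):
        if len(self.subset) < 2:
            raise ValueError("candidate kernels need subsets of size >= 2")


@dataclass
class MKLSolution:
    """Fitted MKL state: simplex weights, SVR duals, bias and trace."""

    weights: np.ndarray         # d, on the simplex
    alpha: np.ndarray           # signed dual coefficients, one per sample
    bias: float
    C: float
    epsilon: float
    trace: list = field(default_factory=list)   # objective per iteration
    converged: bool = True
    weight_floor: float = 1e-6

    @property
    def active_kernels(self) -> np.ndarray:
        return np.nonzero(self.weights > self.weight_floor)[0]


# --------------------------------------------------------------------------
# ranking and grouping
# --------------------------------------------------------------------------

def filter_rank(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Rank features by descending |Pearson correlation| with the target.

    Constant features score 0.  Ties are broken by original column order
    (stable sort), so the ranking is deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to rank features")
    yc = y - y.mean()
    sy = np.sqrt((yc * yc).sum())
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc * Xc).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    score = np.abs(np.where((sx > 0) & (sy > 0), r, 0.0))
    return np.argsort(-score, kind="stable")


def group_features(X: np.ndarray, rho: float = 0.8) -> list:
    """Partition features into groups of mutually correlated columns.

    Complete-linkage hierarchical clustering on the distance 1 - |corr|,
    cut at height 1 - rho: within a group every pair of features satisfies
    |corr| >= rho.  Groups are returned ordered by their smallest column
    index; singleton groups are allowed.
    """
    if not (0.0 < rho < 1.0):
        raise ValueError("rho must lie in (0, 1)")
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if p == 1:
        return [[0]]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = np.clip(1.0 - np.abs(corr), 0.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    Z = complete(squareform(dist, checks=False))
    labels = fcluster(Z, t=1.0 - rho, criterion="distance")
    groups: dict[int, list] = {}
    for j, lab in enumerate(labels):
        groups.setdefault(lab, []).append(j)
    return sorted(groups.values(), key=lambda g: min(g))


def enumerate_subset_kernels(groups: list, ranking: np.ndarray,
                             specs=DEFAULT_KERNEL_BANK) -> list:
    """Build the candidate list: nested ranked subsets x kernel specs.

    Each group is reordered by the global ranking; a group of size n
    contributes its top-k members for every k = 2..n, so the total candidate
    count is sum over groups of max(n - 1, 0) times len(specs).
    """
    specs = list(specs)
    if not specs:
        raise ValueError("kernel spec list must not be empty")
    pos = {f: i for i, f in enumerate(ranking)}
    candidates = []
    for group in groups:
        ordered = sorted(group, key=lambda f: pos[f])
        for k in range(2, len(ordered) + 1):
            subset = tuple(ordered[:k])
            for spec in specs:
                candidates.append(CandidateKernel(subset=subset, spec=spec))
    return candidates


# --------------------------------------------------------------------------
# gram computation
# --------------------------------------------------------------------------

def _raw_gram(XA: np.ndarray, XB: np.ndarray, spec: KernelSpec) -> np.ndarray:
    if spec.kind == "gaussian":
        d2 = (
            np.sum(XA * XA, axis=1)[:, None]
            + np.sum(XB * XB, axis=1)[None, :]
            - 2.0 * XA @ XB.T
        )
        np.clip(d2, 0.0, None, out=d2)
        return np.exp(-d2 / (2.0 * spec.sigma ** 2))
    return (XA @ XB.T + 1.0) ** spec.degree


def compute_gram(X: np.ndarray, subset, spec: KernelSpec) -> tuple[np.ndarray, float]:
    """Training Gram matrix on a feature subset, trace-normalized.

    Returns (gram, diag_mean) where ``gram`` has unit mean diagonal and
    ``diag_mean`` is the raw diagonal mean needed to normalize test-time
    cross-kernels consistently.  X is expected to be standardized already.
    """
    Xs = np.asarray(X, dtype=float)[:, list(subset)]
    K = _raw_gram(Xs, Xs, spec)
    if not np.all(np.isfinite(K)):
        bad = [f for f, col in zip(subset, Xs.T) if not np.all(np.isfinite(col))]
        raise ValueError(f"non-finite kernel entries (features {bad or list(subset)})")
    dm = float(np.mean(np.diag(K)))
    if dm <= 0:
        dm = 1.0
    return K / dm, dm


def _bank_grams(XA: np.ndarray, XB: np.ndarray, candidates: list,
                dtype=np.float64, diag_means: np.ndarray | None = None):
    """Grams for every candidate, computed incrementally over nested subsets.

    Candidates from :func:`enumerate_subset_kernels` share subset prefixes
    within a group, so squared distances and inner products are accumulated
    one feature at a time instead of being recomputed per candidate.  When
    ``diag_means`` is given (test time) it is used for normalization;
    otherwise training diagonal means are computed and returned.
    """
    nA, nB = XA.shape[0], XB.shape[0]
    M = len(candidates)
    grams = np.empty((M, nA, nB), dtype=dtype)
    out_dm = np.empty(M) if diag_means is None else np.asarray(diag_means, float)

    # group candidates by identical subset (prefix chains share work)
    order = sorted(range(M), key=lambda m: (candidates[m].subset, m))
    d2 = np.zeros((nA, nB))
    ip = np.zeros((nA, nB))
    prev: tuple = ()
    for m in order:
        cand = candidates[m]
        sub = cand.subset
        if sub[: len(prev)] != prev or len(sub) < len(prev):
            d2 = np.zeros((nA, nB))
            ip = np.zeros((nA, nB))
            prev = ()
        for f in sub[len(prev):]:
            a = XA[:, f][:, None]
            b = XB[:, f][None, :]
            diff = a - b
            d2 += diff * diff
            ip += a * b
        prev = sub
        if cand.spec.kind == "gaussian":
            K = np.exp(-d2 / (2.0 * cand.spec.sigma ** 2))
        else:
            K = (ip + 1.0) ** cand.spec.degree
        if diag_means is None:
            dm = float(np.trace(K)) / nA if nA == nB else 1.0
            dm = dm if dm > 0 else 1.0
            out_dm[m] = dm
        grams[m] = K / out_dm[m]
    return grams, out_dm


# --------------------------------------------------------------------------
# SVR inner solver
# --------------------------------------------------------------------------

def svr_dual_solve(K: np.ndarray, y: np.ndarray, C: float, epsilon: float,
                   tol: float = 1e-6) -> tuple[np.ndarray, float]:
    """Solve the epsilon-insensitive SVR dual on a precomputed kernel.

    Returns the signed dual coefficients alpha (|alpha_i| <= C,
    sum alpha_i = 0) and the bias b.  Backed by the libsvm SMO solver; the
    surrounding MKL machinery only needs (alpha, b) and the dual objective.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    y = np.asarray(y, dtype=float)
    svr = SVR(kernel="precomputed", C=C, epsilon=epsilon, tol=tol,
              max_iter=2_000_000)
    svr.fit(np.asarray(K, dtype=np.float64), y)
    if svr.fit_status_ != 0:
        raise RuntimeError(
            f"SVR solver did not converge (max_iter={svr.max_iter})")
    alpha = np.zeros(y.size)
    alpha[svr.support_] = svr.dual_coef_[0]
    return alpha, float(svr.intercept_[0])


def _dual_objective(K: np.ndarray, y: np.ndarray, alpha: np.ndarray,
                    epsilon: float) -> float:
    """SVR dual value -1/2 a'Ka - eps*sum|a| + y'a at a feasible alpha."""
    return float(-0.5 * alpha @ (K @ alpha) - epsilon * np.abs(alpha).sum()
                 + y @ alpha)


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    idx = np.arange(1, v.size + 1)
    cond = u - css / idx > 0
    r = idx[cond][-1]
    theta = css[cond][-1] / r
    return np.maximum(v - theta, 0.0)


def _weighted_gram(grams: np.ndarray, d: np.ndarray) -> np.ndarray:
    # keep everything in the gram dtype: mixed-dtype products would silently
    # upcast (i.e. copy) the whole stack, which matters at GiB scale
    nz = np.nonzero(d > 0)[0]
    dt = grams.dtype
    if nz.size > grams.shape[0] // 2:
        K = np.einsum("m,mij->ij", d.astype(dt), grams, optimize=True)
    else:
        K = np.zeros(grams.shape[1:], dtype=dt)
        for m in nz:
            K += dt.type(d[m]) * grams[m]
    return np.asarray(K, dtype=np.float64)


def _kernel_quadratic(grams: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """alpha' K_m alpha for every kernel, without upcasting the stack."""
    a = alpha.astype(grams.dtype)
    return np.einsum("mij,i,j->m", grams, a, a, optimize=True).astype(np.float64)


def fit_simplemkl(kernels: list, y: np.ndarray, C: float = 10.0,
                  epsilon: float = 0.01, tol: float = 1e-4,
                  max_iter: int = 200, weight_floor: float = 1e-6,
                  grams: np.ndarray | None = None) -> MKLSolution:
    """Fit the simplex-weighted kernel combination by projected gradient.

    Alternates (i) an SVR solve on the weighted kernel sum and (ii) a
    projected-gradient step on the weights with backtracking so the recorded
    objective trace is non-increasing.  Stops when the relative objective
    change falls below `tol`, the line search stalls, or `max_iter` is
    reached (the latter sets ``converged=False`` rather than raising).
    """
    if not kernels:
        raise ValueError("need at least one candidate kernel")
    y = np.asarray(y, dtype=float)
    if grams is None:
        grams = np.stack([k.gram for k in kernels])
    M = grams.shape[0]
    d = np.full(M, 1.0 / M)

    def solve(dvec):
        K = _weighted_gram(grams, dvec)
        alpha, b = svr_dual_solve(K, y, C, epsilon)
        return alpha, b, _dual_objective(K, y, alpha, epsilon)

    alpha, b, obj = solve(d)
    trace = [obj]
    converged = False
    step = 1.0
    for _ in range(max_iter):
        if M == 1:
            converged = True
            break
        grad = -0.5 * _kernel_quadratic(grams, alpha)
        gnorm = np.max(np.abs(grad))
        if gnorm <= 0:
            converged = True
            break
        improved = False
        trial = step / gnorm
        for _ in range(15):
            d_new = _project_simplex(d - trial * grad)
            if np.max(np.abs(d_new - d)) < 1e-14:
                break
            alpha_new, b_new, obj_new = solve(d_new)
            if obj_new <= obj + 1e-12:
                improved = True
                break
            trial *= 0.5
        if not improved:
            converged = True
            break
        rel = abs(obj - obj_new) / max(abs(obj), 1e-12)
        d, alpha, b, obj = d_new, alpha_new, b_new, obj_new
        trace.append(obj)
        step = min(trial * gnorm * 2.0, 1e6)
        if rel < tol:
            converged = True
            break
    return MKLSolution(weights=d, alpha=alpha, bias=b, C=C, epsilon=epsilon,
                       trace=trace, converged=converged,
                       weight_floor=weight_floor)


def predict(solution: MKLSolution, test_grams) -> np.ndarray:
    """Predict with a fitted solution.

    ``test_grams`` is the list/array of cross-kernels K_m(test, train),
    aligned with the training candidates (one per kernel, normalized by the
    training diagonal means).
    """
    test_grams = np.asarray(test_grams) if not isinstance(test_grams, np.ndarray) \
        else test_grams
    if test_grams.shape[0] != solution.weights.size:
        raise ValueError(
            f"got {test_grams.shape[0]} test kernels for "
            f"{solution.weights.size} training kernels")
    K = _weighted_gram(test_grams, solution.weights)
    return K @ solution.alpha + solution.bias


def feature_importance(solution: MKLSolution, kernels: list,
                       n_features: int | None = None) -> "pd.DataFrame":
    """Per-feature accumulated kernel weight and kernel count.

    A feature's accumulated weight is the sum of d_m over the active kernels
    (d_m above the weight floor) whose subset contains it; the kernel count
    is the number of such kernels.  Sorted by descending weight.
    """
    import pandas as pd

    if n_features is None:
        n_features = 1 + max(max(k.subset) for k in kernels)
    weight = np.zeros(n_features)
    count = np.zeros(n_features, dtype=int)
    for m in solution.active_kernels:
        for f in kernels[m].subset:
            weight[f] += solution.weights[m]
            count[f] += 1
    table = pd.DataFrame({
        "feature": np.arange(n_features),
        "accumulated_weight": weight,
        "kernel_count": count,
    })
    return table.sort_values("accumulated_weight", ascending=False,
                             kind="stable").reset_index(drop=True)


# --------------------------------------------------------------------------
# end-to-end estimator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FSMKLConfig:
    """Hyperparameters of the end-to-end FSMKL estimator."""

    rho: float = 0.8
    kernel_bank: tuple = DEFAULT_KERNEL_BANK
    C: float = 10.0
    epsilon: float = 0.01
    weight_floor: float = 1e-6
    tol: float = 1e-4
    max_iter: int = 200
    #: "auto" picks float32 when the stacked grams would exceed ~1 GiB.
    gram_dtype: str = "auto"


class FSMKLModel:
    """Fitted FSMKL regressor (returned by :func:`fsmkl_select`)."""

    def __init__(self, config: FSMKLConfig, mean, std, ranking, groups,
                 kernels, solution, importance, selected, X_train):
        self.config = config
        self.mean_ = mean
        self.std_ = std
        self.ranking_ = ranking
        self.groups_ = groups
        self.kernels_ = kernels
        self.solution_ = solution
        self.importance_ = importance
        self.selected_features_ = selected
        self._X_train = X_train  # standardized training matrix

    def predict(self, Xnew: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(Xnew, dtype=float) - self.mean_) / self.std_
        dm = np.array([k.diag_mean for k in self.kernels_])
        sol = self.solution_
        active = sol.active_kernels
        cands = [self.kernels_[m] for m in active]
        grams, _ = _bank_grams(Xs, self._X_train, cands,
                               diag_means=dm[active])
        K = np.tensordot(sol.weights[active], grams, axes=1)
        return np.asarray(K, dtype=float) @ sol.alpha + sol.bias


def fsmkl_select(X: np.ndarray, y: np.ndarray,
                 config: FSMKLConfig | None = None) -> FSMKLModel:
    """Rank, group, enumerate, fit and score features end to end.

    Features are standardized with training statistics, ranked by the filter
    criterion, grouped by correlation, expanded into the nested-subset
    kernel bank and fused by the SimpleMKL loop.  The returned model carries
    the solution, the importance table and the selected feature indices
    (features appearing in at least one active kernel).
    """
    if config is None:
        config = FSMKLConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Xs = (X - mean) / std

    ranking = filter_rank(Xs, y)
    groups = group_features(Xs, rho=config.rho)
    kernels = enumerate_subset_kernels(groups, ranking, config.kernel_bank)
    if not kernels:
        raise ValueError("no candidate kernels: every feature group is a "
                         "singleton at the configured rho")

    n = Xs.shape[0]
    nbytes = len(kernels) * n * n * 8
    dtype = np.float64
    if config.gram_dtype == "float32" or (config.gram_dtype == "auto"
                                          and nbytes > 2 ** 30):
        dtype = np.float32
    grams, diag_means = _bank_grams(Xs, Xs, kernels, dtype=dtype)
    for k, dm in zip(kernels, diag_means):
        k.diag_mean = float(dm)

    solution = fit_simplemkl(kernels, y, C=config.C, epsilon=config.epsilon,
                             tol=config.tol, max_iter=config.max_iter,
                             weight_floor=config.weight_floor, grams=grams)
    importance = feature_importance(solution, kernels, n_features=X.shape[1])
    selected = sorted(importance.loc[importance.kernel_count > 0, "feature"]
                      .astype(int).tolist())
    return FSMKLModel(config, mean, std, ranking, groups, kernels, solution,
                      importance, selected, Xs)
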