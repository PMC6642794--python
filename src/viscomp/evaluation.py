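"""Repeated cross-validation benchmarking and model-comparison statistics.

The benchmark protocol is `runs` repetitions (default 50) of k-fold
cross-validation (default 10 folds) with a fresh seeded fold partition per
run.  All preprocessing — standardization, ranking, grouping, feature
selection — happens inside each training fold; the test fold only ever
passes through stored training statistics, so scores are free of selection
bias.

Scores per run:

* **R²** — squared Pearson correlation between the pooled out-of-fold
  predictions and the observed ratings (a per-fold-averaged variant is
  available via ``pooled=False``);
* **RMSE** — root mean squared error of the pooled predictions;
* the **feature set** — union of the per-fold selections, whose signature
  (sorted names) feeds the stability accounting.

Model comparison uses the conventional non-parametric battery: paired
Wilcoxon signed-rank tests, the Friedman test with the Iman–Davenport F
correction, and a median-based contrast-estimation matrix.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CVConfig",
    "CVReport",
    "repeated_cv",
    "wilcoxon_paired",
    "friedman_iman_davenport",
    "median_contrast",
    "stability_report",
]


@dataclass(frozen=True)
class CVConfig:
    """Repeated cross-validation settings."""

    runs: int = 50
    folds: int = 10
    base_seed: int = 0
    pooled: bool = True   # pooled out-of-fold R2 vs mean of per-fold R2

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


@dataclass
class CVReport:
    """Per-run scores and feature sets from :func:`repeated_cv`."""

    r2: np.ndarray
    rmse: np.ndarray
    feature_sets: list              # one sorted tuple per run
    seeds: list
    degenerate_runs: list = field(default_factory=list)

    @property
    def median_r2(self) -> float:
        return float(np.median(self.r2))

    @property
    def median_rmse(self) -> float:
        return float(np.median(self.rmse))

    @property
    def stability(self) -> Counter:
        return Counter(self.feature_sets)


def _fold_partition(n: int, folds: int, seed: int) -> list:
    """Disjoint, covering fold index arrays, reproducible from the seed."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, folds)]


def _pearson_r2(pred: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Squared Pearson correlation; constant predictions score 0 (flagged)."""
    if np.std(pred) <= 1e-12 or np.std(y) <= 1e-12:
        return 0.0, True
    r = np.corrcoef(pred, y)[0, 1]
    return float(r * r), False


def repeated_cv(fit, X: np.ndarray, y: np.ndarray,
                config: CVConfig | None = None) -> CVReport:
    """Run the repeated-CV benchmark for one model.

    Parameters
    ----------
    fit:
        Callable ``fit(X_train, y_train) -> model`` where the model exposes
        ``predict(X_test)`` and, optionally, ``selected_features_``.
        Everything the model learns (standardization included) must come
        from the training split it is given.
    """
    if config is None:
        config = CVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n // config.folds < 3 or n - (n + config.folds - 1) // config.folds < 3:
        raise ValueError("fold size leaves fewer than 3 training samples")

    r2s, rmses, fsets, seeds, degenerate = [], [], [], [], []
    for run in range(config.runs):
        seed = config.base_seed + run
        seeds.append(seed)
        folds = _fold_partition(n, config.folds, seed)
        pred = np.empty(n)
        selected: set = set()
        fold_r2 = []
        for test_idx in folds:
            mask = np.ones(n, dtype=bool)
            mask[test_idx] = False
            model = fit(X[mask], y[mask])
            pred[test_idx] = model.predict(X[test_idx])
            selected.update(getattr(model, "selected_features_", []))
            if not config.pooled:
                fold_r2.append(_pearson_r2(pred[test_idx], y[test_idx])[0])
        if config.pooled:
            r2, flag = _pearson_r2(pred, y)
        else:
            r2, flag = float(np.mean(fold_r2)), False
        if flag:
            degenerate.append(run)
        r2s.append(r2)
        rmses.append(float(np.sqrt(np.mean((pred - y) ** 2))))
        fsets.append(tuple(sorted(selected)))
    return CVReport(r2=np.asarray(r2s), rmse=np.asarray(rmses),
                    feature_sets=fsets, seeds=seeds,
                    degenerate_runs=degenerate)


# --------------------------------------------------------------------------
# model-comparison statistics
# --------------------------------------------------------------------------

def wilcoxon_paired(scores_a, scores_b) -> float:
    """Two-sided Wilcoxon signed-rank p for paired score vectors.

    Exact distribution for n <= 25 (no ties/zeros), normal approximation
    with continuity correction otherwise.  Identical vectors give p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    diff = a - b
    if np.all(diff == 0):
        return 1.0
    # method="auto": exact distribution for n <= 25 without ties, normal
    # approximation (with continuity correction) otherwise
    res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True,
                         method="auto")
    return float(res.pvalue)


def friedman_iman_davenport(scores: np.ndarray):
    """Friedman rank test with the Iman–Davenport F correction.

    ``scores`` is runs x methods (higher = better; only ranks matter).
    Within-run midranks give the Friedman chi-square

        chi2 = 12N/(k(k+1)) * sum_j (Rbar_j - (k+1)/2)^2,

    transformed to F = (N-1) chi2 / (N(k-1) - chi2) against the
    F(k-1, (k-1)(N-1)) reference distribution.

    Returns (F statistic, p-value, mean ranks per method).  Identical
    methods give statistic 0, p = 1.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[0] < 2 or S.shape[1] < 2:
        raise ValueError("need a runs x methods matrix with >= 2 of each")
    N, k = S.shape
    # rank within each run, midranks for ties, rank 1 = best (highest score)
    ranks = np.vstack([stats.rankdata(-row) for row in S])
    mean_ranks = ranks.mean(axis=0)
    chi2 = 12.0 * N / (k * (k + 1)) * np.sum((mean_ranks - (k + 1) / 2) ** 2)
    denom = N * (k - 1) - chi2
    if denom <= 0:           # chi-square at its maximum: perfect ordering
        return float("inf"), 0.0, mean_ranks
    F = (N - 1) * chi2 / denom
    p = float(stats.f.sf(F, k - 1, (k - 1) * (N - 1)))
    return float(F), p, mean_ranks


def friedman_chi_square(scores: np.ndarray) -> float:
    """Uncorrected Friedman chi-square (midranks), exposed for cross-checks."""
    S = np.asarray(scores, dtype=float)
    N, k = S.shape
    ranks = np.vstack([stats.rankdata(-row) for row in S])
    mean_ranks = ranks.mean(axis=0)
    return float(12.0 * N / (k * (k + 1))
                 * np.sum((mean_ranks - (k + 1) / 2) ** 2))


def median_contrast(scores: np.ndarray) -> np.ndarray:
    """Median-based contrast estimation between methods.

    Entry (i, j) is the median over runs of score_i - score_j; the matrix is
    antisymmetric and ready for heatmap display.
    """
    S = np.asarray(scores, dtype=float)
    k = S.shape[1]
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            m = float(np.median(S[:, i] - S[:, j]))
            out[i, j] = m
            out[j, i] = -m
    return out


def stability_report(report: CVReport):
    """Modal feature set across runs, its count, and per-feature frequency."""
    counts = report.stability
    modal_set, modal_count = counts.most_common(1)[0]
    freq: Counter = Counter()
    for fs in report.feature_sets:
        freq.update(fs)
    n_runs = len(report.feature_sets)
    frequency = {f: c / n_runs for f, c in sorted(freq.items())}
    return modal_set, modal_count, frequency
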