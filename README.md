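# viscomp

Computational modelling of **perceived visual complexity**: how intricate a
human judges an image to be, on a 1–5 rating scale. The package is aimed at
researchers in visual psychophysics and computational aesthetics who want to
(a) describe raster stimuli by interpretable complexity features, (b) learn a
regression model of mean human ratings from those features, and (c) audit that
model with the standard benchmarking and outlier-diagnostic machinery.

## What is inside

**Complexity features** (`viscomp.image_features`). Each stimulus is split
into its Hue/Saturation/Value channels; each channel, raw or after an edge
filter (Canny or Sobel, full or single-axis), is summarized by

* JPEG compression error at three quality levels — RMS loss of a lossy
  round trip; complex images compress badly;
* fractal (quadtree PIFS) compression error at three fidelity levels;
* Canny edge density — the fraction of pixels on edges;
* Zipf statistics — slope *M* and fit quality *R²* of a log–log line through
  the rank-frequency ("Rank") or value-frequency ("Size") distribution of
  quantized intensities;
* mean and standard deviation.

Features are named in the conventional dialect, e.g. `JPEG(Canny(S),High)` or
`Rank(NoFilter(S),R2)`.

**FSMKL regression** (`viscomp.fsmkl`). Feature-Selection Multiple Kernel
Learning: features are ranked by |Pearson *r*| with the rating, grouped by
correlation (complete linkage on 1 − |corr|, cut at ρ = 0.8), and each group
of size *n* spawns nested top-*k* subsets for *k* = 2…*n*. Every subset is
crossed with a kernel bank (Gaussian, σ ∈ {0.1, 0.2, 0.3, 0.4, 0.5, 1, 2};
polynomial, degree ∈ {1, 2, 3, 4}). The model learns a simplex-constrained
combination K(d) = Σₘ dₘ Kₘ jointly with an ε-insensitive SVR (C = 10,
ε = 0.01), SimpleMKL-style: projected gradient on d with a monotone line
search, gradient −½ αᵀKₘα. Because kernels see feature subsets, the weights
double as feature importances: a feature's accumulated weight is Σ dₘ over
active kernels containing it.

**Baselines** (`viscomp.baselines`): multiple linear regression, stepwise-AIC
GLM, Lasso (L1 budget as a *fraction* of the least-squares norm, default 0.1),
Elastic Net (mixing α = 0.8, penalty by internal 10-fold CV), and SVM-RFE
(Gaussian-kernel SVR, w² pruning criterion, halving schedule down to
`bestsubsetsize` = 256, σ = 2⁻⁶, C = 10, ε = 0.01).

**Benchmark harness** (`viscomp.evaluation`): repeated k-fold CV (default
50 × 10-fold) with per-run R² (squared Pearson correlation of pooled
out-of-fold predictions) and RMSE, feature-set stability counts, paired
Wilcoxon tests, the Friedman test with Iman–Davenport correction, and
median-based contrast estimation.

**Outlier diagnostics** (`viscomp.diagnostics`): leverage, externally
studentized residuals, Cook's distance, the Bonferroni outlier test, Tukey's
non-additivity test, and an explicit combined flagging rule
(Dᵢ > 4/n ∧ |tᵢ| > 3, or Bonferroni-significant).

**Synthetic data** (`viscomp.synthetic`): seeded stimuli with analytically
known feature behavior, and latent-factor feature tables emulating the
structure of real complexity data — 48 correlated feature groups of
7.8 ± 2.5 features, with rating noise calibrated so two independent rater
panels agree at R² ≈ 0.85.

## Worked example

```python
import numpy as np
from viscomp import FSMKLConfig, fsmkl_select
from viscomp.synthetic import TableRecipe, make_feature_table

X, y, truth = make_feature_table(
    TableRecipe(n_samples=200, n_groups=12, informative_groups=3, seed=7))
model = fsmkl_select(X, y, FSMKLConfig())

sel = set(model.selected_features_)
planted = set(truth.informative_features)
print(f"groups found: {len(model.groups_)}")
print(f"planted-feature recall: {len(sel & planted) / len(planted):.2f}")
pred = model.predict(X)
print(f"training R2: {np.corrcoef(pred, y)[0, 1] ** 2:.3f}")
print(model.importance_.head(3))
```

prints

```
groups found: 12
planted-feature recall: 1.00
training R2: 1.000
   feature  accumulated_weight  kernel_count
0        9             0.14769            23
1       10             0.14769            23
2       16             0.14769            23
```

The 12 planted correlated groups are recovered exactly by the grouping stage;
every informative feature appears in at least one active kernel (recall 1.0);
and the highest accumulated kernel weights fall on features from the
informative groups. (Training R² of 1.0 reflects the memorization capacity of
the small-bandwidth Gaussian kernels — out-of-sample performance is what the
evaluation harness measures.)

The same pipeline is available from the shell:

```bash
viscomp simulate --kind table --seed 1 --out sim/
viscomp fit --model fsmkl --features sim/features.csv --ratings sim/ratings.csv --out model.json
viscomp evaluate --models lm,enet --features sim/features.csv --ratings sim/ratings.csv --runs 5 --out eval.json
viscomp diagnose --features sim/features.csv --ratings sim/ratings.csv --out diag.csv
viscomp extract-features --images stimuli/ --out features.csv
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline experiment from scratch: it generates the
48-group calibrated feature table, fits FSMKL and measures planted-feature
recovery, benchmarks an Elastic Net by repeated cross-validation against the
generative R² ceiling, and runs the outlier diagnostics on a bench with
planted 6-sd outliers, writing the JSON manifest to `--out` and a progress
summary to stderr.

See `docs/methods.md` for the model details, the synthetic-data design and
the numerical choices.
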