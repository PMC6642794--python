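# Methods

This note documents the models and procedures implemented in `viscomp`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data tests do and do not establish.

## 1. Complexity features

### Channel decomposition

Stimuli are 8-bit RGB images converted to HSV; every descriptor operates on
one channel plane scaled to [0, 1]. Hue is treated as an ordinary linear
channel — no circular statistics — which matches naive channel extraction
but makes Hue descriptors sensitive to the arbitrary red cut point; this is
a known limitation, and Hue features are empirically the least informative
for complexity anyway. The composite channel `H+CS` is implemented as the
mean of Hue and contrast-stretched Saturation; the historical definition of
this channel is not recoverable, so this is an explicit, documented guess
exposed through the registry rather than hidden in code.

### Edge filters

* `canny_all`: standard Canny, Gaussian σ = 1.0, hysteresis thresholds at
  the 70th/90th percentiles of the gradient magnitude. Quantile thresholds
  make the detector parameter-free across stimuli of very different
  contrast — a fixed absolute threshold would saturate on low-contrast art.
* `canny_h` / `canny_v`: no standard detector exposes a single-axis mode, so
  the smoothing / non-maximum-suppression / hysteresis chain is implemented
  directly on one gradient component. `_h` responds to horizontal edges
  (vertical derivative), matching the usual Sobel-kernel naming.
* `sobel_*`: gradient magnitude rescaled to [0, 1] by its maximum; constant
  planes return all-zero planes rather than erroring.

Edge density is defined only for binary (Canny) planes: the fraction of
nonzero pixels.

### Compression errors

*JPEG*: the plane is quantized to 8 bits, round-tripped through the JPEG
codec at quality 25/50/75 for fidelity level Low/Medium/High (evenly spaced
standard qualities), and scored by RMS pixel difference on the [0, 1] scale.
Deterministic for a fixed codec.

*Fractal*: a quadtree PIFS coder. Range blocks shrink from 16 px to 4 px;
domain blocks are twice the range size on a grid with step equal to the
range size, contracted by 2×2 averaging; each range block gets the affine
map s·D + o minimizing squared error, with s clamped to [−0.9, 0.9] so the
decoder is contractive by construction. A block splits while its best RMS
exceeds the level tolerance (0.15 / 0.08 / 0.02 for Low / Medium / High),
and a split is kept only when it lowers the summed squared error, which
makes the reported error monotone non-increasing as the tolerance tightens.
The reported quantity is the collage RMS — the standard deterministic proxy
for decode error (the collage theorem bounds the true reconstruction error
by a multiple of it). On planes with no exploitable self-similarity at any
scale (i.i.d. noise) all three levels split to the bottom and coincide;
level separation appears exactly when the image has structure, which is the
behavior the fidelity schedule is meant to probe.

### Zipf statistics

Intensities are quantized to 256 bins (native 8-bit depth). The *Rank*
family fits log(count) against log(rank) over the occupied bins sorted by
descending count; the *Size* family fits log(count) against log(bin index +
1). Natural logarithms; the fit is ordinary least squares, and *M* (slope)
and *R²* are reported. Fewer than three occupied bins makes the fit
meaningless: the pair (0, 0) is returned with a logged warning, never an
exception — so binary (Canny-filtered) planes yield constant sentinel
features by construction.

### Registry

The historical 329-feature composition is not recoverable from available
sources, so the feature grid is configuration: the default registry crosses
JPEG/Fractal (3 levels) and Size/Rank (M, R²) with all seven filters and
H/S/V, adds the unfiltered `H+CS` composite for Size/Rank, EdgeDensity for
the three Canny filters, and Mean/StdDev for all filters — 265 names. The
registry records its own length and any grid can be substituted.

## 2. FSMKL

The regression target is the mean rating y ∈ [1, 5]. The model learns

    f(x) = Σ_i α_i Σ_m d_m K_m(x_i, x) + b,    d ≥ 0, Σ_m d_m = 1

with an ε-insensitive SVR on the combined kernel. Candidate kernels come
from the feature-selection construction: rank features by |Pearson r| with
y (constant features score 0; ties break by column order), group features
by complete-linkage clustering on 1 − |corr| cut at 1 − ρ (default ρ = 0.8:
every within-group pair has |corr| ≥ ρ), and for each group of size n take
the nested top-k ranked subsets, k = 2…n, crossed with the kernel bank.
Gaussian kernels use exp(−‖x−x′‖²/2σ²); polynomial kernels (x·x′+1)^d; each
Gram matrix is normalized to unit mean diagonal (standard MKL scale
equalization — polynomial kernels would otherwise dominate by raw scale).
Features are standardized with training-fold statistics only.

The weights are optimized by minimizing J(d) = the optimal SVR dual value
on K(d), a convex function of d whose gradient at the dual solution α is
∂J/∂d_m = −½ αᵀK_mα. Each iteration takes a projected-gradient step
(Euclidean projection onto the simplex) with a backtracking line search
that only accepts objective decreases, so the recorded trace is monotone
non-increasing; the step doubles after success. Convergence: relative
objective change < 10⁻⁴ or a stalled line search; hitting `max_iter` = 200
flags the solution as unconverged rather than raising. The inner SVR is the
libsvm SMO solver on the precomputed kernel; C = 10 and ε = 0.01 (the
conventional settings for this problem family).

A kernel is *active* when d_m > 10⁻⁶. A feature's accumulated weight is
Σ d_m over active kernels whose subset contains it, and its kernel count the
number of such kernels; the selected set is every feature with kernel count
≥ 1. The importance table satisfies the conservation identity
Σ_f weight_f = Σ_m d_m·|subset_m| exactly. Accumulation is per fitted
model; summing across CV repetitions is a caller-side option (the published
weight tables are ambiguous between the two readings, and this package
asserts neither).

Memory note: the stacked Gram tensor is M×n×n. Above ~1 GiB it is stored in
float32, and all weighted sums and quadratic forms are computed in the
storage dtype — a mixed-dtype product would silently upcast (copy) the whole
stack. At n = 300 and the default bank on the 48-group table this is
~1.3 GiB and a fit takes ~3 minutes on one core.

## 3. Baselines

* **LM** — OLS on all standardized features; minimum-norm solution with a
  warning when rank-deficient.
* **GLM (stepwise)** — Gaussian family; bidirectional stepwise from the
  intercept-only model, minimizing AIC; an empty model is a legal outcome.
  Note the selection statistics: AIC admits a noise feature with
  probability P(χ²₁ > 2) ≈ 0.157, so on pure noise the empty-model rate is
  ≈ (1 − 0.157)^p, about 50% at p = 4 — chance-level behavior, not a defect.
* **Lasso** — parameterized by `fraction`: the coefficient L1 norm is
  budgeted at `fraction` × ‖β_OLS‖₁. The LARS path is piecewise linear in
  the coefficients, so the solution at the exact budget is interpolated
  between bracketing knots; fraction = 1 reproduces least squares,
  fraction → 0 the null model.
* **ENET** — mixing parameter α (L1 share), penalty magnitude by internal
  10-fold CV over a 50-point log-spaced grid (grid size and folds are
  conventional choices). α = 0 falls back to ridge since the
  coordinate-descent grid degenerates there.
* **SVM-RFE** — Gaussian-kernel SVR; the per-feature criterion is the
  change in ½ αᵀKα when the feature is removed from the kernel with α held
  fixed, which reduces to the classical squared weight w_f² for a linear
  kernel. Each round removes the lower-scoring half of the survivors (ties
  break by column order), never dropping below `bestsubsetsize`; survivor
  sets are nested by construction. The kernel is exp(−σ‖x−x′‖²) — the
  convention under which the standard default σ = 2⁻⁶ is expressed (the
  bandwidth convention used in the MKL bank would make that value
  degenerate).

## 4. Evaluation protocol

`runs` × k-fold CV (defaults 50 × 10) with a fresh seeded partition per run
(seed = base_seed + run index, recorded in the report). All fitting,
scaling and selection happens inside training folds — verified by a leak
canary test. Per run: R² = squared Pearson correlation between pooled
out-of-fold predictions and y (per-fold averaging available via
`pooled=False`; pooled is the default because the run-level score should
reflect one prediction per sample), RMSE on the pooled predictions, and the
union of per-fold selected features as the run's feature-set signature.
Constant predictions have no defined correlation; such runs score R² = 0
and are flagged. Medians over runs are the headline summaries.

Comparisons: two-sided Wilcoxon signed-rank (exact for n ≤ 25 without
ties, normal approximation with continuity correction otherwise; all-zero
differences give p = 1); Friedman midrank χ² transformed to the
Iman–Davenport F = (N−1)χ²/(N(k−1)−χ²) against F(k−1, (k−1)(N−1)) — at a
perfect ordering χ² attains N(k−1), the transform diverges and p = 0 is
returned; and the median-based contrast matrix, entry (i, j) = median over
runs of score_i − score_j.

## 5. Outlier diagnostics

The diagnostic model is an OLS fit of the rating on a chosen feature subset
(typically the model-selected features) plus intercept. Reported per
sample: leverage h_i (hat-matrix diagonal; Σh_i = p exactly), externally
studentized residual t_i = e_i/(s₍₋ᵢ₎√(1−h_i)) (t-distributed with
n−p−1 df under the model), and Cook's distance D_i = (r_i²/p)·h_i/(1−h_i)
with r_i internally studentized — both studentizations are exposed.
Exact-leverage points (h_i = 1) report an infinite sentinel with a warning;
numerically exact fits report all-zero residual diagnostics rather than
0/0 noise.

The Bonferroni outlier test takes the largest |t_i| and reports
min(1, n · 2 · P(T_{n−p−1} > |t|)). Tukey's one-degree-of-freedom
non-additivity test augments the design with ŷ² and t-tests the added
coefficient; degenerate cases (constant response, collinear augmentation)
return p = 1 with a warning.

The combined flagging rule is deliberately explicit because published
analyses typically report which diagnostics were run but not the numeric
decision rule: flag when (D_i > 4/n AND |t_i| > 3) OR the per-sample
Bonferroni-adjusted p < 0.05. All three thresholds are configurable, and
flagging is monotone in each.

## 6. Synthetic data

`make_image` renders flat fields, linear gradients, checkerboards, uniform
noise and blended textures — deterministic given the recipe, with edge
density and moments analytically known (checkerboard edges sit on the cell
grid; a flat field has zero variance and compresses losslessly).

`make_feature_table` draws a latent-factor table: 48 groups (sizes from a
rounded normal 7.8 ± 2.5 truncated at 2, matching the reported moments of
real complexity-feature groups), each feature loading √ρ on its group
latent so the within-group correlation is exactly ρ. Default ρ = 0.9 —
strictly above the 0.8 grouping threshold, because at ρ equal to the cut
the empirical partition is noise-driven and "the planted groups" are not
well-defined objects for a recovery experiment. The latent-factor
construction is used instead of explicit covariance matrices because it is
PSD-safe at any group size. The rating is a unit-variance combination of
the first k group latents plus Gaussian noise, mapped affinely to mean 3,
sd 0.6 and clipped to [1, 5]. The default noise sd is calibrated so that
two independent noisy replicates of the signal (two "rater panels") agree
at R² ≈ 0.85, the inter-group agreement real complexity ratings exhibit:
with replicate correlation r = 1/(1+sd²) and split-half R² = r², sd =
√(1/√0.85…) − 1) ≈ 0.29. The generative ceiling returned with each table is
the realized squared correlation between the noiseless signal and the
observed rating (≈ 0.92 at the default noise).

What the generator does *not* emulate: the real between-group correlation
structure (exposed as a parameter, zero by default), the five semantic
stimulus categories, nonlinear feature–rating relationships, and rater
idiosyncrasies beyond exchangeable noise. A green recovery test therefore
establishes that the pipeline recovers planted linear group structure at a
realistic noise level — not that it reproduces results on any particular
real corpus.

`make_outlier_bench` shifts k ratings by `magnitude` × the residual sd of
the clean rating regression (alternating sign). Detection power depends on
the diagnostic design: with p/n large, the residual-sd estimate deflates by
√(1−p/n) and leverage absorbs part of the shift, so a 6-sd outlier is
reliably detectable (≥95%) in well-posed designs (p/n ≲ 0.2) and
progressively masked beyond that; the acceptance fixture uses n = 200 with
~30 features accordingly, which mirrors the intended use — diagnostics on
the *selected* feature subset, not the full grid.

## 7. Scale of the shipped experiments

The recovery experiment runs the stated structure (48 groups, 7.8 ± 2.5
sizes, 3 informative groups, calibrated noise; ~375 features, ~3 700
candidate kernels) at n = 300 samples: the full n = 800 world would need a
~9 GiB kernel stack. Recall of planted features was 1.0 at both n = 300 and
n = 400 in development runs. The cross-validated ceiling check uses the
Elastic Net (3 runs × 10 folds) because a well-specified regularized linear
model attains the generative ceiling on this linear world at a fraction of
the cost of cross-validating the kernel model; the FSMKL out-of-sample
behavior is covered separately at smaller scale.

## 8. Known limitations

* The fractal coder searches a step-grid domain pool, not all translations,
  and omits the eight dihedral block symmetries; errors are therefore upper
  bounds relative to an exhaustive PIFS — consistently so across images, which
  is what a complexity *ranking* needs.
* Hue circularity, above.
* The SimpleMKL loop uses projected gradient with an Armijo-style monotone
  line search rather than the original reduced-gradient descent; both
  minimize the same convex objective, and the small-instance oracle test
  pins the solutions to a simplex grid search.
* Stepwise AIC is greedy; it is bounded below by the exhaustive-search AIC
  (asserted in tests) but may not attain it.
* R² conventions differ across the literature (pooled vs fold-averaged,
  correlation² vs 1 − SSE/SST); both pooled and fold-averaged squared
  correlations are implemented, pooled by default, and results should name
  the convention.
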