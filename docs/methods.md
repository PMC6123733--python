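# Methods

## Growth-curve modeling

Trait series from imaging platforms (digital volume, projected area,
height, in arbitrary positive units over days) are fitted with six
mechanistic families by *linearization*: each curve is transformed to a
straight line y\* = a + b·x\* and estimated by ordinary least squares.

| model | curve | transform (response, predictor) |
|---|---|---|
| linear | y = a + b t | (y, t) |
| exponential | y = a·e^{bt} | (ln y, t) |
| monomolecular | y = K(1 − a·e^{−rt}) | (ln(1 − y/K), t) |
| logistic | y = K/(1 + e^{−r(t−t₀)}) | (ln(K/y − 1), t) |
| Gompertz | y = K·e^{−a·e^{−rt}} | (ln ln(K/y), t) |
| Weibull | y = K(1 − e^{−(t/λ)^k}) | (ln(−ln(1 − y/K)), ln t) |

Observations outside a transform's domain (y ≤ 0 under a logarithm,
y ≥ K under a saturating transform, t ≤ 0 for Weibull) are masked with a
recorded count rather than rejected — early-time zeros are routine in
imaging pipelines — and a fit needs at least three valid points.
Both the linearized R² and the original-scale R² of the back-transformed
predictions are reported, together with the regression F-test p-value;
model ranking uses the original-scale R² (linearized R² values live on
incomparable scales), ties broken by smaller p-value, then a fixed model
order. A perfect fit reports the p-value floored at the smallest
positive float so the (0, 1] contract holds.

**Asymptote search.** K enters the transforms nonlinearly, so it is
chosen by a scan over max(y)·{1.001, 1.01, …, 2.0} followed by bounded
scalar refinement around the best grid point (allowed to descend below
the first grid point to just above max(y), which matters for
near-saturated series). The refinement objective is the
*original-scale* R². Under noise, maximizing the linearized R² instead
systematically inflates K — a larger asymptote damps the transform's
noise amplification near saturation — and that bias propagates into the
rate estimate; the original-scale criterion is free of the artifact and
still attains R² = 1 at the true K on noise-free data. (Measured on the
noisy-recovery condition below, linearized-R² refinement gives a median
relative error of ≈18% on r; original-scale gives ≈5%.)

**Derived parameters.** Logistic: R = r, IP = t₀, K_max = K. Gompertz:
IP = ln(a)/r (where the second derivative vanishes). Weibull with shape
k > 1: IP = λ((k−1)/k)^{1/k}; R is taken as k/λ, the characteristic
rate. Curves without an inflection (linear, exponential, monomolecular)
return IP as absent with an explanatory note; their K_max is the fitted
value at the last observed day. An IP far outside the observed time
range triggers a warning, not an error.

**Stress and recovery.** Growth under a stress episode is fitted in two
phases. Phase 1 fits four candidates reducible to quadratic OLS: ln y
quadratic in t (Gaussian bell), ln y quadratic in ln t (log-time bell),
√y quadratic in t, and y quadratic in t. A candidate whose quadratic
coefficient is not clearly negative (tolerance 1e-10 relative to the
other coefficients, so exactly-linear transformed data does not pass on
rounding noise) has no peak and is flagged invalid. The best valid
candidate by original-scale R² supplies peak time and value from its
vertex. Phase 2 is an OLS line in the recovery window; its slope is the
speed of re-growth R_rec.

**Group-level fits** pool all replicate (t, y) pairs of a group;
duplicate time points are averaged to keep times strictly increasing.

## Cross-validated prediction evaluation

Each of N randomizations (default 10) partitions the n samples into k
folds — stratified by class for classification — trains on (k−1)/k and
predicts the held-out 1/k, yielding one out-of-fold prediction per
sample per run. Metrics are computed on the pooled out-of-fold
predictions *within* each run, then summarized as mean ± sd across runs.
One master seed generates the N run seeds, and the same partition
schedule is reused across models and across greedy steps, so every
comparison is paired.

RMSRE and μ are relative-error metrics, undefined at y = 0; a zero
observed value is a hard error (silent exclusion would change the sample
size and bias both metrics). μ > 0 means overestimation, μ < 0
underestimation. Multiclass AUC is macro-averaged one-vs-rest.

Learners are scikit-learn estimators behind a registry (OLS/logistic,
ridge, lasso, elastic net, PLS, k-NN, decision tree, random forest,
gradient boosting, linear/RBF SVM, MLP, naive Bayes, LDA, plus a
feature-blind majority baseline); scale-sensitive families are wrapped
in a pipeline that standardizes using training-fold statistics only.
New models register through `register_model`.

**Importance** uses a family's built-in measure where one exists
(impurity importance for trees/ensembles, |standardized coefficient| for
linear models) and otherwise a univariate filter: |Pearson r| against a
numeric target, or the best direction-free one-vs-rest AUC
(max of AUC and 1−AUC over classes) for labels. Raw scores are min–max
scaled to [0, 100]; if all raw scores are equal the scale is undefined
and every feature gets 100 (positive scores) or 0. Zero-variance
features warn and score 0 raw.

**Predictive power** is the mean cross-validated R² of each feature used
alone. **Greedy backward elimination** (classification) scores, at each
step, every subset formed by dropping one remaining feature with the
shared k×N schedule, removes the feature whose absence gives the highest
mean accuracy, breaking ties in favor of the earliest input column, and
iterates down to a single feature; the full accuracy-vs-size trajectory
(k·N per-fold accuracies per size) is returned so users can pick a knee
point.

## Embedding, clustering, filtering

PCA is the SVD of the column-centered (optionally unit-scaled) matrix
with a deterministic sign convention; biplot loadings are the Pearson
correlations between each original column and each score column, with
raw eigenvectors also exported, and variance shares are reported over
all min(n−1, p) components (they sum to 1). t-SNE delegates to
scikit-learn under a seeded determinism contract and enforces
perplexity < (n−1)/3. MDS is classical (Torgerson) scaling — exact for
euclidean input of true dimension ≤ d — on euclidean or correlation
distances. The SOM is a batch self-organizing map: codebook initialized
on the first two principal components with a seeded jitter, Gaussian
neighborhood shrinking linearly over 30 epochs (floor 0.4 grid units),
best-matching-unit assignment by euclidean distance. k-means is Lloyd's
algorithm with k-means++ starts (10 restarts, best within-cluster sum of
squares kept) exposing a per-iteration WSS trace; hierarchical
clustering wraps scipy linkage (complete/average/ward) and returns the
merge tree and leaf order for heatmap reordering.

The ANOVA/fold-change filter runs a one-way F-test per feature across
observation groups and computes the fold change as (max group mean)/(min
group mean) on linear-scale values or 2^(max−min) for log2 input;
features pass with p below and FC above their thresholds, and an
optional Benjamini–Hochberg flag thresholds q-values instead (raw
p-values are the default). The matrix convention is n observations ×
p features with group labels on observations; expression matrices with
genes in rows should be transposed on ingestion. A multi-factor
(e.g. space × time) ANOVA is out of scope; with such designs the one-way
filter treats each factor combination as a group.

## Synthetic data: what it does and does not emulate

Generators are pure functions of (parameters, seed) and echo their truth
records. Default study conditions:

- *Growth*: y = f(t; θ) + ε with additive Gaussian ε (option:
  multiplicative lognormal, since the error structure of imaging traits
  varies by pipeline); values are floored at 1e-6 of the curve maximum
  (clip count recorded) to keep log transforms usable. The noisy
  recovery experiment uses the logistic curve (K=100, r=0.2/day,
  t₀=25 d), 30 time points over days 1–50, 5% multiplicative noise,
  100 seeds.
- *Stress*: Gaussian bell (height 50, peak day 20, width 5) meeting a
  linear recovery (slope 3/day) continuously at day 30, over days 1–45.
- *Supervised*: X ~ N(0,1); regression y = Xβ + ε with var(ε) set to a
  requested noise fraction of var(y) (calibration experiment: n=500,
  3 informative + 2 noise features, fraction 0.25); classification
  shifts class-conditional means by `class_sep` along informative
  dimensions only (elimination experiment: n=300, 2 informative +
  8 noise features, separation 2 sd, naive Bayes with k=5, N=2 — a fast
  deterministic combination sized so the 100-seed retention experiment
  completes in about a minute).
- *Clustered matrix*: log-scale block design, 3 groups × 30
  observations, 30 features of which 5 per group are shifted by
  10·within-sd. At these sizes the joint null probability of a noise
  feature passing p<0.05 *and* FC>2 is ≈2·10⁻⁴, so exact planted-feature
  recovery is the expected outcome.

These generators reproduce the *statistical shape* the engines assume —
monotone or bell trait curves, linear signal with controllable noise,
block-structured group effects. They do not emulate temporal error
autocorrelation, heteroscedastic imaging artifacts, feature–feature
correlation structure, or count-distributed expression; a pass on
synthetic data therefore demonstrates correctness of the estimation
machinery, not robustness to every property of real data.

## Reproducibility and interfaces

All randomness flows from explicit integer seeds (internally reduced
mod 2³¹); per-run and per-worker seeds are derived deterministically, so
serial and parallel execution produce identical bytes. The CLI writes
tidy CSVs, optional PNG/SVG/PDF plots and a `manifest.json` with package
version, configuration, seeds and SHA-256 input checksums — enough to
regenerate any result file bit-identically. The library surface follows
the model/results convention where a model is actually fitted
(`GrowthCurveModel(...).fit()` → `GrowthCurveResults` with `summary()`);
the evaluation and embedding engines are plain functions returning
result objects, which matches their one-shot semantics.

## Known limitations

- Linearized OLS weights errors on the transformed scale; for strongly
  heteroscedastic traits a nonlinear least-squares refinement would
  differ. The asymptote refinement objective (original-scale R²) limits
  but does not remove this.
- The bell/quadratic stress candidates share one quadratic-OLS engine;
  asymmetric stress responses are approximated, not modeled.
- Greedy elimination is O(p²) cross-validations; for large p use
  importance or predictive power first.
- t-SNE determinism is guaranteed per installed scikit-learn version,
  not across versions.
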