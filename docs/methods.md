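# Methods

## Problem setting

`genesig` identifies small gene signatures that discriminate the four
breast-cancer intrinsic subtypes (Basal, Her2, LumA, LumB) from bulk
RNA-seq expression — with explicit support for long-non-coding genes —
and evaluates those signatures both as classifiers (repeated
cross-validated accuracy, per-subtype ROC, t-SNE visualization,
IHC-marker concordance) and as prognostic predictors (supervised
principal-components risk scores, mixture-based risk grouping,
Kaplan–Meier / log-rank and Cox models).

## Preprocessing

Long-non-coding candidates are the six GENCODE biotypes `lincRNA`,
`antisense`, `sense_intronic`, `sense_overlapping`,
`processed_transcript` and `processed_pseudogene` (pseudogene classes
deliberately grouped with lncRNAs), restricted to an annotated length of
at least 200 bp — the conventional lncRNA size threshold. Length is the
gene-feature span (`end − start + 1`, 1-based inclusive GTF coordinates);
annotations rarely expose per-transcript lengths at the gene level, so the
feature span is used and the choice is exposed through
`BiotypeFilterSpec`. The common misspelling `processed_transcripted` is
aliased to `processed_transcript`.

Each gene is divided by its own maximum, mapping every row into [0, 1].
This per-gene scaling equalizes the dynamic range of low-expressed
lncRNAs and high-expressed coding genes and speeds up margin-based
training; it deliberately does **not** correct library size. Zero-variance
genes are dropped first (they carry no signal and make the scaling
undefined). Normalization is computed once on the full matrix, before any
cross-validation split — the same order a practitioner uses when the
signature is selected on the complete cohort. This leaks per-gene scale
across folds; the effect is a per-feature constant and does not carry
label information, but fold-internal normalization can be requested by
normalizing fold data externally. When a second feature block (e.g. a
microarray panel) is pooled with RNA-seq features, each block is
max-normalized independently and feature IDs are prefixed by block tags
so the namespaces cannot collide.

## The sparse subtype classifier

The core machine minimizes, over weights `w` and an unpenalized
intercept `b`,

    C · Σ_i max(0, 1 − y_i (wᵀ x_i + b))² + (1 − C) · ‖w‖₁ ,   0 < C < 1.

`C` is a convex-combination tradeoff between the squared-hinge loss and
the lasso penalty (a conventional penalty weight would be
λ = (1 − C)/C). Small `C` drives `w` to exactly zero; `C` near 1
reproduces a hard-margin-like fit. Because the penalty is the 1-norm, the
minimizer is sparse and the surviving nonzero-weight genes form the
signature. Multiclass problems use one-vs-rest: one sparse machine per
subtype, prediction by the argmax of decision values, with ties broken
toward the earliest class in the fixed order Basal < Her2 < LumA < LumB.
A gene is *attributed* to every subtype whose one-vs-rest machine gave it
nonzero weight.

**Solver.** Splitting `w = w⁺ − w⁻` with `w⁺, w⁻ ≥ 0` turns the problem
into a smooth bound-constrained convex program (the squared hinge is
continuously differentiable), solved with L-BFGS-B, followed by an exact
cyclic coordinate-descent polish restricted to KKT-violating or active
coordinates (each 1-D subproblem has a closed-form soft-threshold
solution). The polish snaps near-zero weights to exact zeros and brings
the objective to ~1e−12 relative accuracy. A deliberately independent
FISTA reference solver (cold start, exact Lipschitz step, adaptive
restart) lives in `genesig._reference` and is used only for
verification; the test suite checks objective agreement to 1e−6 relative
on random instances. Numerical "nonzero" is |w_k| > eps_w · max(1,
‖w‖_∞) with eps_w = 1e−6 by default, configurable because exact zeroness
is tolerance-dependent in floating point.

## Two-iteration recursive selection

The tradeoff grid is log-spaced from 0.99 down to 1e−3 (30 points by
default). Training accuracy (one-vs-rest argmax on the full training set)
decays as `C` decreases.

* **Iteration 1** sweeps the grid downward with warm starts and stops at
  `C*`, the smallest grid value whose training accuracy still meets the
  threshold θ (default 0.9). The union of nonzero genes over the
  one-vs-rest machines at `C*` is the gene pool. The sweep halts a few
  grid points after accuracy first falls below θ (accuracy is monotone
  along the path up to solver noise); `sweep_c` exposes full-grid curves
  with optional per-point CV accuracy for plotting.
* **Iteration 2** repeats the sweep on the pooled genes only and keeps
  the largest `C` whose pooled nonzero count is at most the requested
  signature size `target_n` (closest from below; if every grid point
  exceeds the target, the count closest to it is used). This mirrors the
  practice of reporting slightly fewer genes than targeted rather than
  forcing exact counts. The final signature is therefore always nested in
  the iteration-1 pool.

An optional post-hoc step re-applies the biotype/length filter to the
selected genes (default) or to the pool before shrinking, reproducing the
exclusion of small/uncertain transcripts from a selected list; both
orders are exposed because the original procedure is ambiguous on this
point.

**A note on redundant markers.** When many planted markers per class
carry the same strong shift (e.g. 10 exchangeable genes per class at 2 SD),
the lasso path maintains ≥ 0.9 training accuracy down to a handful of
active genes, so the `C*` pool keeps only a subset of each redundant
group: recall of the full planted set is structurally limited even though
the selected genes are almost exclusively true markers (precision ≈ 1).
With sparse ground truth (2–3 markers per class) the pool recovers nearly
all of them. This is a property of ℓ₁ selection, not of the solver.

## Evaluating a signature

Classification accuracy uses a standard 2-norm squared-hinge linear SVM
(liblinear, deterministic) under stratified k-fold CV repeated with
distinct fold seeds (defaults k = 10, 10 repeats). The interval reported
is mean ± t₀.₉₇₅,r−1 · SD/√r over the r repeat-level means — the
convention is stated because accuracy intervals are often left
undefined. Selecting genes on the full cohort and then cross-validating
on the same cohort inherits feature-selection bias (the held-out labels
participated in selection); under permuted labels this inflates
"chance" accuracy to ≈ 0.5 for 4 balanced classes. The chance-level
experiment therefore evaluates the null-selected signature on an
independently generated cohort, where accuracy sits at 1/K as it should.

Per-subtype ROC curves use the one-vs-rest linear decision values (not
calibrated probabilities). t-SNE (perplexity 30, PCA initialization,
fixed seed) embeds samples into 2-D; the API takes no labels — subtype
information is only ever used to color points. IHC concordance
cross-tabulates predicted subtypes against the three clinical marker
categories ER−/PR−/HER2−, ER−/PR−/HER2+ and ER+/PR+ (HER2 unrestricted
in the third, reproducing the conventional grouping); column percentages
sum to 100.

## Prognostic evaluation (superPC)

Genes are standardized and screened by the Wald z of a univariate Cox
proportional-hazards fit (Efron tie correction). The screening threshold
τ is chosen from 20 quantiles of |z| (always including 0) by stratified
10-fold CV: per fold, scores and the first principal component of the
retained standardized genes are computed on the training portion,
out-of-fold risk scores are pooled, and the τ maximizing the pooled Cox
likelihood-ratio statistic wins. The final model keeps genes with
|z| > τ, projects standardized expression on unit-norm PC1 loadings, and
orients the score so its training Cox coefficient is non-negative
(higher score = higher hazard). One component is used; with τ = 0 the
model reduces exactly to plain PC1-Cox. Single-covariate Cox fits use an
in-package vectorized Newton solver (suffix-sum risk-set aggregation,
Efron weights, step-halving); it is validated against lifelines to ~1e−4
and exists because threshold CV needs thousands of such fits.

Risk scores are split into high/low groups by a two-component univariate
Gaussian mixture (EM, k-means initialization, 10 restarts, fixed seed);
the cutoff is the point between the component means where the component
posteriors are equal. A fit whose smaller component carries less than two
samples' weight, or with no posterior crossing between the means, falls
back to a median split with a warning. Groups are compared by
Kaplan–Meier curves and the two-sided log-rank test, and by univariate /
multivariate Cox models (lifelines; Efron ties; complete-case rows with
dropped counts logged; categorical covariates dummy-coded against
configurable reference levels — White, Untreated-or-other, T1,
Infiltrating Ductal Carcinoma by default). Explained variation is
reported as R² = 1 − exp(−LR/n), the likelihood-ratio explained-variation
statistic; the definition is printed with the value since several R²
variants exist for censored outcomes. The multivariate model uses the
high/low group indicator by default (continuous risk score optional).
Top prognostic genes are those whose univariate |coefficient| exceeds a
threshold, ranked by |z| descending.

## Synthetic cohorts

The generator emulates the statistical shape of a subtyped tumor RNA-seq
study rather than any particular dataset:

* **Expression**: log-normal background (log-mean ~ N(1, 0.5), log-SD
  0.5), kept non-negative so max-normalization is well defined.
  Informative genes receive a class-specific shift of `effect_size`
  log-SDs (default 2) in their subtype. Defaults: 200 samples, 500
  genes, 4 equal-proportion subtypes, 10 informative genes per class.
* **lncRNA-like genes**: a 30% fraction down-scaled multiplicatively
  (×0.2) — mimicking the lower expression of non-coding transcripts —
  and annotated with the six lncRNA biotypes plus a few `miRNA` records
  and lengths spanning the 200 bp boundary (199/200/201 included), so
  the filter's edge cases are always exercised. Down-scaling (rather
  than re-distributing) keeps the scale-invariance of per-gene
  max-normalization testable: selection should not care about the factor.
* **Survival**: exponential times with log-hazard Σ β_g · z_g over 5
  planted prognostic genes (β ~ U[0.5, 1]), a shared log-normal frailty
  (SD 0.5) coupling OS and RFS (RFS baseline hazard ×1.5), and
  independent uniform censoring whose cap is tuned by bisection to the
  target censoring rate (default 30%, expected within ±0.05). Baseline
  hazard 1/1500 events/day puts median survival in a realistic few-year
  range.
* **IHC markers**: drawn per sample from P(category | subtype); by
  default Basal is triple-negative with probability 0.9, Her2 is
  hormone-negative/HER2+ with 0.7, and luminal subtypes are ER+/PR+ with
  0.95/0.85 — matching the clinical expectation that ~90% of Basal-like
  tumors are TNBC.
* Clinical covariates (age, race, treatment, stage, histology) are drawn
  from plausible marginals and are independent of survival, so
  multivariate adjustments can be exercised without confounding.

Everything derives from one seed; two calls with the same spec are
bit-identical.

What the generator does **not** emulate: batch effects, library-size
variation, count noise (negative binomial), gene–gene correlation beyond
the planted structure, informative censoring, or real identifiers.
Passing tests therefore demonstrate correctness of the algorithms under
their stated assumptions, not performance on real tumor cohorts.

## Numerical choices and degenerate inputs

* Solver tolerances: L-BFGS-B ftol 1e−15 / gtol 1e−10, polish to 1e−14
  coordinate stability; oracle agreement asserted at 1e−6 relative.
* Strictly `0 < C < 1`; single-class targets, non-finite inputs,
  all-zero genes, duplicate IDs, empty grids and non-decreasing grids
  are hard errors with the offending item named.
* Ties: argmax prediction breaks toward the earliest class in sorted
  order; Cox ties use the Efron approximation throughout.
* The mixture cutoff is the posterior-equality root between the two
  means only; a second crossing outside that interval (possible with
  unequal variances) is intentionally ignored.
* Problem sizes in the verification experiments (20 selection
  replicates, 200 null replicates, n = 1000 for bias checks) were chosen
  as the smallest sizes at which the statistical assertions are stable.

## Known limitations

* Selection-then-CV on the same cohort overstates accuracy (see above);
  the package measures and documents this rather than hiding it.
* The 1-norm path under-counts redundant marker groups by design.
* R² values for censored data are definition-dependent; only the
  likelihood-ratio form is implemented.
* The PAM50 classifier itself is not reimplemented; an external feature
  block can be pooled, which is the only integration supported.
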