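# genesig

Sparse-SVM gene-signature selection for tumor subtypes, with
cross-validated evaluation and supervised principal-components (superPC)
prognostic modeling.

## What problem this solves

Bulk RNA-seq of breast tumors measures tens of thousands of coding and
long-non-coding genes, but clinical subtype classification (Basal, Her2,
LumA, LumB) should rest on a signature small enough to assay cheaply.
`genesig` is for computational biologists who want to

1. filter candidate genes by GENCODE biotype and the 200 bp lncRNA length
   rule,
2. select a compact subtype signature with an ℓ₁-penalized SVM,
3. quantify how well that signature classifies (repeated cross-validated
   accuracy, per-subtype ROC, t-SNE maps, concordance with ER/PR/HER2
   immunohistochemistry), and
4. ask whether the signature also stratifies survival (superPC risk
   scores, Gaussian-mixture high/low risk groups, Kaplan–Meier / log-rank,
   Cox models).

A synthetic-cohort generator with planted subtype markers, lncRNA-like
low-expression genes, and survival driven by a known prognostic gene set
makes every stage testable without any data download.

## The model

Gene selection minimizes, for each subtype versus the rest,

    min_{w,b}  C · Σᵢ max(0, 1 − yᵢ(wᵀxᵢ + b))²  +  (1 − C) · ‖w‖₁

with C ∈ (0, 1) trading the squared-hinge loss against the lasso penalty
(intercept unpenalized). The 1-norm drives most weights to exactly zero;
the surviving nonzero-weight genes are the signature, each attributed to
the subtype(s) whose one-vs-rest machine used it. Selection is recursive:
a first sweep lowers C until training accuracy falls to θ = 0.9 and pools
the genes active at that C*; a second sweep over the pool shrinks the
signature to a target size (default 50). Prognosis uses superPC: screen
genes by univariate Cox Wald score, take the first principal component of
the survivors (threshold chosen by 10-fold cross-validation) as a risk
score, and split patients at the equal-posterior point of a two-component
Gaussian mixture fitted to the scores.

See `docs/methods.md` for assumptions, parameter defaults, and numerical
details.

## Worked example

Simulate a 200-sample, 500-gene four-subtype cohort and select a
signature from the shell:

```console
$ genesig simulate --seed 17 --out-dir demo/
wrote cohort to demo
$ genesig select --expr demo/expr.tsv --labels demo/labels.tsv \
      --theta 0.9 --target-n 50 --seed 17 --out-dir demo/sel
C*=0.02794 pool=10 signature=10 cv_accuracy=0.990
```

The sweep kept 90%+ training accuracy down to C* = 0.028, pooled 10
genes there, and the 10-gene signature classifies held-out samples at
99.0% accuracy (10-fold CV) — the planted markers are strong, so few
genes suffice. The same pipeline through the Python API, with prognosis:

```python
>>> from genesig.experiments import full_pipeline_demo
>>> full_pipeline_demo(seed=1)
{'n_signature_genes': 16,
 'signature_cv_accuracy': 0.995,
 'cv_ci_low': 0.9926, 'cv_ci_high': 0.9974,
 'C_star': 0.0354, 'n_pool_genes': 16,
 'risk_score_hazard_ratio': 1.407, 'risk_score_p': 6.43e-05,
 'n_high_risk': 55, 'n': 200}
```

A 16-gene signature reaches 99.5% repeated-CV accuracy
(t-interval [99.3%, 99.7%] over 10 repeats), and its superPC risk score
is strongly associated with overall survival (hazard ratio 1.41 per SD,
p = 6×10⁻⁵), flagging 55 of 200 patients as high-risk.

The estimators follow scikit-learn conventions
(`L1NormSVC`, `OneVsRestL1SVM`, `RecursiveSignatureSelector`,
`SuperPC`, `GaussianRiskSplit`: `fit` / `predict` / `transform`,
`get_params`, fitted attributes with trailing underscores), so they
compose with sklearn pipelines and model selection.

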