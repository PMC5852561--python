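"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a subtyped tumor expression study: a large
log-normal null background, a handful of genes shifted per subtype (the
planted signature), lncRNA-like features expressed at a fraction of the
coding level with annotated biotypes and lengths spanning the 200 bp filter
boundary, exponential survival driven by a small planted prognostic gene
set with uniform censoring, and IHC marker status drawn from a
subtype-conditional concordance matrix.  Everything is reproducible from a
single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    SUBTYPES,
    UNLABELED,
    ClinicalTable,
    ExpressionMatrix,
    GeneAnnotationSet,
    SubtypeLabels,
)
from .preprocess import LNC_BIOTYPES

IHC_CATEGORIES = ("ER-/PR-/HER2-", "ER-/PR-/HER2+", "ER+/PR+/HER2")

#: Default P(IHC category | subtype): Basal is mostly triple-negative,
#: Her2 mostly hormone-negative/HER2-positive, luminal subtypes ER+/PR+.
DEFAULT_IHC_CONCORDANCE = {
    "Basal": (0.90, 0.07, 0.03),
    "Her2": (0.15, 0.70, 0.15),
    "LumA": (0.02, 0.03, 0.95),
    "LumB": (0.05, 0.10, 0.85),
}


@dataclass
class SimSpec:
    """Parameters of the synthetic cohort.

    ``effect_size`` is the class-specific mean shift of informative genes
    in units of the log-expression SD; ``lnc_expression_scale`` down-scales
    lncRNA-like genes multiplicatively; ``hazard_betas`` is either a
    (low, high) range sampled uniformly or an explicit per-gene sequence of
    log-hazard coefficients for the planted prognostic genes.
    """

    n_samples: int = 200
    n_genes: int = 500
    n_classes: int = 4
    class_proportions: tuple | None = None
    n_informative_per_class: int = 10
    effect_size: float = 2.0
    lnc_fraction: float = 0.3
    lnc_expression_scale: float = 0.2
    n_prognostic: int = 5
    hazard_betas: tuple = (0.5, 1.0)
    baseline_hazard: float = 1.0 / 1500.0  # events per day
    rfs_rate_ratio: float = 1.5
    frailty_sd: float = 0.5
    censoring_rate: float = 0.3
    unlabeled_fraction: float = 0.0
    ihc_concordance: dict = field(default_factory=lambda: dict(DEFAULT_IHC_CONCORDANCE))
    log_mean: float = 1.0
    log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_proportions is None:
            self.class_proportions = tuple([1.0 / self.n_classes] * self.n_classes)
        if abs(sum(self.class_proportions) - 1.0) > 1e-8:
            raise ValueError("class_proportions must sum to 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.lnc_expression_scale <= 0:
            raise ValueError("lnc_expression_scale must be > 0")
        if self.n_informative_per_class * self.n_classes > self.n_genes:
            raise ValueError("more informative genes requested than genes exist")

    def class_names(self) -> list[str]:
        if self.n_classes <= len(SUBTYPES):
            return list(SUBTYPES[: self.n_classes])
        return [f"Class{k}" for k in range(self.n_classes)]


@dataclass
class SimTruth:
    """Ground truth of a generated cohort."""

    informative: dict  # class -> list of gene_ids
    prognostic_betas: dict  # gene_id -> true log-hazard coefficient
    subtype: pd.Series  # sample -> generating class (before unlabeling)

    def informative_genes(self) -> set:
        out: set = set()
        for genes in self.informative.values():
            out |= set(genes)
        return out


def _lnc_lengths(rng, n: int) -> np.ndarray:
    """Lengths spanning the 200 bp rule: boundary values plus a mix of
    short (filtered) and long (kept) transcripts."""
    lengths = rng.integers(80, 3000, size=n)
    boundary = np.array([199, 200, 201])
    lengths[: min(n, 3)] = boundary[: min(n, 3)]
    return lengths


def gen_expression(spec: SimSpec):
    """Generate (ExpressionMatrix, SubtypeLabels, GeneAnnotationSet, SimTruth)."""
    rng = np.random.default_rng(spec.seed)
    p, n = spec.n_genes, spec.n_samples
    classes = spec.class_names()

    gene_ids = [f"G{i:05d}" for i in range(p)]
    sample_ids = [f"S{i:04d}" for i in range(n)]
    y = rng.choice(len(classes), size=n, p=list(spec.class_proportions))

    mu = rng.normal(spec.log_mean, 0.5, size=p)
    log_expr = mu[:, None] + rng.normal(0.0, spec.log_sd, size=(p, n))

    perm = rng.permutation(p)
    n_inf = spec.n_informative_per_class
    informative: dict = {}
    for k, cls in enumerate(classes):
        genes = perm[k * n_inf : (k + 1) * n_inf]
        informative[cls] = [gene_ids[g] for g in genes]
        shift = spec.effect_size * spec.log_sd
        log_expr[np.ix_(genes, np.flatnonzero(y == k))] += shift
    expr = np.exp(log_expr)

    # lncRNA-like block: down-scaled expression, non-coding biotypes
    n_lnc = int(round(spec.lnc_fraction * p))
    lnc_idx = rng.choice(p, size=n_lnc, replace=False)
    expr[lnc_idx] *= spec.lnc_expression_scale

    biotypes = np.array(["protein_coding"] * p, dtype=object)
    lnc_pool = sorted(LNC_BIOTYPES) + ["miRNA"]  # miRNA exercises the biotype exclusion
    biotypes[lnc_idx] = [lnc_pool[i % len(lnc_pool)] for i in range(n_lnc)]
    lengths = rng.integers(500, 100_000, size=p)
    lengths[lnc_idx] = _lnc_lengths(rng, n_lnc)
    starts = rng.integers(1, 10_000_000, size=p)
    ann = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "biotype": biotypes,
            "chrom": [f"chr{1 + i % 22}" for i in range(p)],
            "start": starts,
            "end": starts + lengths - 1,
            "length_bp": lengths,
            "is_coding": biotypes == "protein_coding",
        }
    )

    # planted prognostic genes (drawn over the whole universe)
    prog_idx = rng.choice(p, size=spec.n_prognostic, replace=False)
    betas = np.asarray(spec.hazard_betas, dtype=float)
    if betas.shape == (2,) and spec.n_prognostic != 2:
        beta_vals = rng.uniform(betas[0], betas[1], size=spec.n_prognostic)
    elif betas.size == spec.n_prognostic:
        beta_vals = betas
    else:
        beta_vals = rng.uniform(betas.min(), betas.max(), size=spec.n_prognostic)
    prognostic = {gene_ids[g]: float(b) for g, b in zip(prog_idx, beta_vals)}

    labels = pd.Series([classes[k] for k in y], index=sample_ids, name="subtype")
    truth = SimTruth(informative=informative, prognostic_betas=prognostic, subtype=labels.copy())
    if spec.unlabeled_fraction > 0:
        n_unlab = int(round(spec.unlabeled_fraction * n))
        unlab = rng.choice(n, size=n_unlab, replace=False)
        labels.iloc[unlab] = UNLABELED

    matrix = ExpressionMatrix(pd.DataFrame(expr, index=gene_ids, columns=sample_ids))
    return (
        matrix,
        SubtypeLabels(labels, vocabulary=tuple(classes)),
        GeneAnnotationSet(ann),
        truth,
    )


def _tune_censoring_cap(times: np.ndarray, rate: float) -> float:
    """Bisection on the uniform-censoring cap so the expected censored
    fraction matches ``rate``: P(censored | T) = min(T / cap, 1)."""

    def frac(cap):
        return float(np.minimum(times / cap, 1.0).mean())

    lo, hi = times.min() * 1e-3 + 1e-9, times.max() * 1e3
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) > rate:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def gen_survival(matrix: ExpressionMatrix, truth: SimTruth, spec: SimSpec) -> ClinicalTable:
    """Exponential survival driven by the planted prognostic genes.

    The log-hazard is ``sum_g beta_g * z_g`` over z-scored expression, plus
    a shared log-normal frailty that couples the OS and RFS endpoints.
    Censoring is independent uniform, tuned to the requested rate.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n = matrix.n_samples
    lp = np.zeros(n)
    for gene, beta in truth.prognostic_betas.items():
        if gene not in matrix.data.index:
            raise KeyError(f"prognostic gene {gene} missing from matrix")
        row = matrix.data.loc[gene].to_numpy(dtype=float)
        sd = row.std()
        if sd > 0:
            lp += beta * (row - row.mean()) / sd
    if np.abs(lp).max() > 50:
        raise ValueError("hazard overflow: extreme prognostic betas")

    frailty = rng.lognormal(0.0, spec.frailty_sd, size=n) if spec.frailty_sd > 0 else np.ones(n)

    data = {}
    for prefix, ratio in (("os", 1.0), ("rfs", spec.rfs_rate_ratio)):
        rates = spec.baseline_hazard * ratio * np.exp(lp) * frailty
        T = rng.exponential(1.0 / rates)
        if spec.censoring_rate == 0:
            time, event = T, np.ones(n, dtype=int)
        else:
            cap = _tune_censoring_cap(T, spec.censoring_rate)
            Cens = rng.uniform(0.0, cap, size=n)
            time = np.minimum(T, Cens)
            event = (T <= Cens).astype(int)
        data[f"{prefix}_time"] = np.round(time, 2)
        data[f"{prefix}_event"] = event

    df = pd.DataFrame(data, index=matrix.sample_ids)
    df["age"] = np.round(rng.normal(58.0, 12.0, size=n).clip(25, 90), 1)
    df["race"] = rng.choice(["White", "Black", "Asian"], size=n, p=[0.75, 0.18, 0.07])
    df["treatment"] = rng.choice(
        ["Untreated or other", "Chemotherapy", "Radiation therapy", "Hormone therapy"],
        size=n,
        p=[0.4, 0.3, 0.2, 0.1],
    )
    df["stage"] = rng.choice(["T1", "T2", "T3", "T4"], size=n, p=[0.3, 0.45, 0.18, 0.07])
    df["histology"] = rng.choice(
        ["Infiltrating Ductal Carcinoma", "Infiltrating Lobular Carcinoma", "Mucinous Carcinoma"],
        size=n,
        p=[0.78, 0.18, 0.04],
    )
    return ClinicalTable(df)


def gen_ihc(labels: SubtypeLabels, spec: SimSpec) -> pd.DataFrame:
    """Draw ER/PR/HER2 status per sample from P(IHC category | subtype)."""
    rng = np.random.default_rng(spec.seed + 2)
    conc = spec.ihc_concordance
    for cls, probs in conc.items():
        if abs(sum(probs) - 1.0) > 1e-8:
            raise ValueError(f"IHC concordance row for {cls} must sum to 1")
    rows = []
    for sample, lab in labels.labels.items():
        truth_lab = lab
        if truth_lab == UNLABELED or truth_lab not in conc:
            rows.append({"er": "", "pr": "", "her2": ""})
            continue
        cat = IHC_CATEGORIES[rng.choice(3, p=list(conc[truth_lab]))]
        if cat == "ER-/PR-/HER2-":
            er, pr, her2 = "-", "-", "-"
        elif cat == "ER-/PR-/HER2+":
            er, pr, her2 = "-", "-", "+"
        else:  # ER+/PR+ with HER2 unrestricted
            er, pr, her2 = "+", "+", rng.choice(["+", "-"])
        rows.append({"er": er, "pr": pr, "her2": her2})
    return pd.DataFrame(rows, index=labels.labels.index)


def simulate_cohort(spec: SimSpec):
    """Full cohort: expression, labels, annotation, clinical (+IHC), truth."""
    matrix, labels, annotation, truth = gen_expression(spec)
    clinical = gen_survival(matrix, truth, spec)
    ihc = gen_ihc(labels, spec)
    clinical = ClinicalTable(clinical.data.join(ihc))
    return {
        "expression": matrix,
        "labels": labels,
        "annotation": annotation,
        "clinical": clinical,
        "truth": truth,
    }
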