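"""Signature evaluation: repeated cross-validated accuracy, per-subtype
ROC, unsupervised 2-D embedding, prediction of unlabeled samples, and
IHC-marker concordance."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import TSNE
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold

from .containers import ClinicalTable
from .svm import L2NormSVC

logger = logging.getLogger(__name__)

IHC_COLUMNS = ("ER-/PR-/HER2-", "ER-/PR-/HER2+", "ER+/PR+/HER2")


@dataclass
class CVReport:
    """Repeated stratified k-fold accuracy with a t-interval over repeats."""

    mean_accuracy: float
    ci_low: float
    ci_high: float
    per_fold: list
    k: int
    repeats: int
    seed: int | None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean_accuracy <= self.ci_high):
            raise ValueError("confidence interval must bracket the mean")


def cv_accuracy(
    X,
    y,
    k: int = 10,
    repeats: int = 10,
    seed: int | None = 0,
    estimator=None,
) -> CVReport:
    """Repeated stratified k-fold CV accuracy of a 2-norm SVM.

    Each repeat reshuffles folds with its own derived seed; the interval is
    mean +/- t_{0.975, repeats-1} * SD / sqrt(repeats) over the repeat-level
    mean accuracies (for a single repeat the interval collapses to the mean).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} samples < k={k}; use a smaller k"
        )
    base = estimator if estimator is not None else L2NormSVC()
    per_fold = []
    repeat_means = []
    for r in range(repeats):
        fold_seed = None if seed is None else seed + r
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
        accs = []
        for train, test in skf.split(X, y):
            from sklearn.base import clone

            model = clone(base).fit(X[train], y[train])
            accs.append(float((model.predict(X[test]) == y[test]).mean()))
        per_fold.extend(accs)
        repeat_means.append(float(np.mean(accs)))
    mean = float(np.mean(repeat_means))
    if repeats > 1:
        sd = float(np.std(repeat_means, ddof=1))
        half = stats.t.ppf(0.975, repeats - 1) * sd / np.sqrt(repeats)
    else:
        half = 0.0
    return CVReport(
        mean_accuracy=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        per_fold=per_fold,
        k=k,
        repeats=repeats,
        seed=seed,
    )


def roc_per_subtype(decision_values, labels, classes=None) -> dict:
    """One-vs-rest ROC per class from OVR decision values.

    ``decision_values`` is samples x classes (column order = ``classes``);
    returns class -> dict(fpr, tpr, auc).  Classes absent from the labels
    are skipped with a warning.
    """
    scores = np.asarray(decision_values, dtype=float)
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    if len(np.unique(labels)) < 2:
        logger.warning("single-class labels: no ROC computed")
        return {}
    out = {}
    for j, cls in enumerate(classes):
        positives = labels == cls
        if not positives.any():
            logger.warning("class %r absent from labels; skipped", cls)
            continue
        fpr, tpr, _ = roc_curve(positives.astype(int), scores[:, j])
        out[cls] = {"fpr": fpr, "tpr": tpr, "auc": float(auc(fpr, tpr))}
    return out


def tsne_embed(X, perplexity: float = 30.0, seed: int | None = 0) -> np.ndarray:
    """Unsupervised t-SNE to 2-D (labels play no part; they are only ever
    used downstream to color points)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large for {n} samples (need n > 3*perplexity)"
        )
    emb = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
    ).fit_transform(X)
    if not np.isfinite(emb).all():
        raise RuntimeError("t-SNE produced non-finite coordinates")
    return emb


def predict_unlabeled(classifier, X_unlabeled) -> np.ndarray:
    """Predict subtype labels for samples the classifier never saw."""
    X_unlabeled = np.asarray(X_unlabeled, dtype=float)
    if X_unlabeled.shape[1] != classifier.n_features_in_:
        raise ValueError(
            f"feature mismatch: classifier expects {classifier.n_features_in_}, "
            f"got {X_unlabeled.shape[1]}"
        )
    return classifier.predict(X_unlabeled)


def agreement(labels_a, labels_b) -> float:
    """Fraction of samples assigned the same label by two predictors."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    return float((a == b).mean())


def ihc_category(er: str, pr: str, her2: str) -> str | None:
    """Collapse marker status to the three clinical categories (the third,
    ER+/PR+, leaves HER2 unrestricted); None when not classifiable."""
    if er == "-" and pr == "-" and her2 == "-":
        return IHC_COLUMNS[0]
    if er == "-" and pr == "-" and her2 == "+":
        return IHC_COLUMNS[1]
    if er == "+" and pr == "+":
        return IHC_COLUMNS[2]
    return None


def ihc_concordance(predicted, clinical: ClinicalTable, sample_ids=None) -> pd.DataFrame:
    """Cross-tab of predicted subtype x IHC category with column percentages.

    Returns a DataFrame with a MultiIndex column per category: ('count',
    cat) and ('percent', cat); percentages are column-wise and sum to 100.
    Samples without classifiable marker status are excluded (count logged).
    """
    predicted = np.asarray(predicted)
    if sample_ids is None:
        sample_ids = clinical.data.index[: len(predicted)]
    rows = []
    skipped = 0
    for sample, label in zip(sample_ids, predicted):
        if sample not in clinical.data.index:
            skipped += 1
            continue
        rec = clinical.data.loc[sample]
        cat = ihc_category(str(rec.get("er", "")), str(rec.get("pr", "")), str(rec.get("her2", "")))
        if cat is None:
            skipped += 1
            continue
        rows.append({"subtype": label, "category": cat})
    if skipped:
        logger.warning("excluded %d sample(s) without classifiable IHC status", skipped)
    if not rows:
        logger.warning("no samples with IHC status; empty concordance table")
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    counts = pd.crosstab(df["subtype"], df["category"]).reindex(columns=list(IHC_COLUMNS), fill_value=0)
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    percent = counts.div(counts.sum(axis=0), axis=1) * 100.0
    return pd.concat({"count": counts, "percent": percent}, axis=1)
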