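"""Two-iteration recursive gene selection with a sparse one-vs-rest SVM.

The tradeoff ``C`` is swept downward from near 1: training accuracy starts
near 1 and decays as the lasso penalty dominates and weights vanish.
Iteration 1 stops at ``C*``, the smallest grid value whose training
accuracy still meets the threshold ``theta``, and pools every gene with a
nonzero weight in any one-vs-rest submodel there.  Iteration 2 repeats the
sweep on the pooled genes only and keeps the largest ``C`` whose pooled
nonzero count does not exceed the requested signature size, so the final
signature is always nested inside the iteration-1 pool.  Each selected gene
is attributed to the subtype(s) whose submodel gave it nonzero weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.utils.validation import check_is_fitted

from .preprocess import BiotypeFilterSpec, filter_noncoding
from .svm import L2NormSVC, OneVsRestL1SVM

logger = logging.getLogger(__name__)

CURVE_COLUMNS = ["C", "train_accuracy", "cv_accuracy", "n_nonzero"]


def default_c_grid(n_points: int = 30, c_max: float = 0.99, c_min: float = 1e-3) -> np.ndarray:
    """Log-spaced tradeoff grid, strictly decreasing from c_max to c_min."""
    return np.geomspace(c_max, c_min, n_points)


@dataclass
class SelectionResult:
    """Outcome of the two-iteration selection."""

    iteration1_genes: set
    iteration2_genes: set
    C_star: float
    theta: float
    target_n: int
    subtype_attribution: dict = field(default_factory=dict)  # gene -> {subtype}
    weight_magnitudes: dict = field(default_factory=dict)  # gene -> max |w|
    curve_iteration1: pd.DataFrame | None = None
    curve_iteration2: pd.DataFrame | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.iteration2_genes <= self.iteration1_genes:
            raise ValueError("iteration-2 genes must nest inside the iteration-1 pool")
        if not (0.0 < self.C_star < 1.0):
            raise ValueError("C_star must lie in (0, 1)")


def _validate_grid(c_grid) -> np.ndarray:
    grid = np.asarray(c_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("C grid is empty")
    if (grid <= 0).any() or (grid >= 1).any():
        raise ValueError("C grid values must lie strictly in (0, 1)")
    if grid.size > 1 and not (np.diff(grid) < 0).all():
        raise ValueError("C grid must be strictly decreasing")
    return grid


def _sweep(
    X,
    y,
    c_grid,
    eps_w: float = 1e-6,
    cv: int = 0,
    seed: int | None = None,
    stop_below: float | None = None,
    patience: int = 3,
):
    """Fit the OVR machine along the grid with warm starts.

    Returns (curve DataFrame, list of fitted models aligned with rows).
    When ``stop_below`` is given, the sweep halts after training accuracy
    has stayed below it for ``patience`` consecutive grid points (accuracy
    is monotone-decreasing in C apart from solver-level noise).
    """
    grid = _validate_grid(c_grid)
    y = np.asarray(y)
    rows, models = [], []
    coef_init = None
    below = 0
    for C in grid:
        model = OneVsRestL1SVM(C=float(C)).fit(X, y, coef_init=coef_init)
        coef_init = model.coef_matrix()
        train_acc = float((model.predict(X) == y).mean())
        n_nonzero = len(model.nonzero_union(eps_w=eps_w))
        cv_acc = np.nan
        if cv and cv >= 2:
            skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
            cv_acc = float(
                cross_val_score(OneVsRestL1SVM(C=float(C)), X, y, cv=skf).mean()
            )
        rows.append({"C": float(C), "train_accuracy": train_acc, "cv_accuracy": cv_acc, "n_nonzero": n_nonzero})
        models.append(model)
        if stop_below is not None:
            below = below + 1 if train_acc < stop_below else 0
            if below >= patience:
                break
    return pd.DataFrame(rows, columns=CURVE_COLUMNS), models


def sweep_c(X, y, c_grid, eps_w: float = 1e-6, cv: int = 0, seed: int | None = None) -> pd.DataFrame:
    """Selection curve along a decreasing C grid: training accuracy,
    optional k-fold CV accuracy, and the pooled nonzero gene count."""
    curve, _ = _sweep(X, y, c_grid, eps_w=eps_w, cv=cv, seed=seed)
    return curve


def select_iteration1(
    X,
    y,
    c_grid,
    theta: float = 0.9,
    feature_names=None,
    eps_w: float = 1e-6,
    patience: int = 3,
):
    """Sweep C downward and pool nonzero genes at C*.

    C* is the smallest grid value whose training accuracy is still >=
    ``theta``.  Raises if no grid point reaches the threshold.
    """
    if not (0.0 < theta <= 1.0) and theta != 0.0:
        raise ValueError("theta must lie in [0, 1]")
    stop = theta if theta > 0 else None
    curve, models = _sweep(X, y, c_grid, eps_w=eps_w, stop_below=stop, patience=patience)
    ok = curve.index[curve["train_accuracy"] >= theta]
    if len(ok) == 0:
        raise ValueError(
            f"no grid point reached training accuracy {theta}; "
            "use a denser grid or one extending closer to C=1"
        )
    star = ok[-1]  # grid is decreasing, last qualifying row has smallest C
    model = models[star]
    if feature_names is None:
        feature_names = np.arange(np.asarray(X).shape[1])
    pool = model.nonzero_union(eps_w=eps_w, feature_names=list(feature_names))
    return float(curve.loc[star, "C"]), pool, curve, model


def select_iteration2(
    X_pool,
    y,
    target_n: int,
    c_grid,
    feature_names=None,
    eps_w: float = 1e-6,
):
    """Shrink the pooled genes to at most ``target_n``.

    Chooses the largest grid C whose pooled nonzero count is <= target_n
    (closest to the target from below); if every grid point exceeds the
    target, falls back to the C minimizing |count - target_n|.  Returns
    (genes, attribution, weight magnitudes, curve, model).
    """
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    X_pool = np.asarray(X_pool, dtype=float)
    if X_pool.shape[1] == 0:
        raise ValueError("iteration-1 gene pool is empty")
    if feature_names is None:
        feature_names = np.arange(X_pool.shape[1])
    feature_names = list(feature_names)

    curve, models = _sweep(X_pool, y, c_grid, eps_w=eps_w)
    counts = curve["n_nonzero"].to_numpy()
    eligible = np.flatnonzero((counts <= target_n) & (counts > 0))
    if eligible.size:
        pick = int(eligible[0])  # grid decreasing -> first row is largest C
    else:
        pick = int(np.argmin(np.abs(counts - target_n)))
        logger.warning(
            "no grid C gave a nonzero count <= %d; using closest count %d",
            target_n,
            int(counts[pick]),
        )
    model = models[pick]
    by_class = model.nonzero_by_class(eps_w=eps_w, feature_names=feature_names)
    attribution: dict = {}
    weights: dict = {}
    for cls, genes in by_class.items():
        for gene, mag in genes.items():
            attribution.setdefault(gene, set()).add(cls)
            weights[gene] = max(weights.get(gene, 0.0), mag)
    selected = set(attribution)
    if not selected:
        raise ValueError("iteration 2 selected no genes; extend the grid toward C=1")
    return selected, attribution, weights, curve, model


def recursive_select(
    X,
    y,
    feature_names=None,
    theta: float = 0.9,
    target_n: int = 50,
    c_grid=None,
    eps_w: float = 1e-6,
    seed: int | None = None,
    annotation=None,
    biotype_spec: BiotypeFilterSpec | None = None,
    filter_stage: str = "after",
) -> SelectionResult:
    """Run both selection iterations and return a :class:`SelectionResult`.

    When an annotation (and optionally a biotype spec) is supplied, the
    biotype/length filter is re-applied to the signature, either to the
    iteration-1 pool before shrinking (``filter_stage='before'``) or to
    the final gene set (``'after'``, default) — the post-hoc exclusion of
    small/uncertain transcripts from a selected list.
    """
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = np.arange(X.shape[1])
    feature_names = list(feature_names)
    grid = default_c_grid() if c_grid is None else np.asarray(c_grid, dtype=float)

    C_star, pool, curve1, _ = select_iteration1(
        X, y, grid, theta=theta, feature_names=feature_names, eps_w=eps_w
    )
    pool_order = [g for g in feature_names if g in pool]
    if annotation is not None and filter_stage == "before":
        pool_order = _apply_biotype_filter(pool_order, annotation, biotype_spec)
        pool = set(pool_order)
    idx = [feature_names.index(g) for g in pool_order]
    genes, attribution, weights, curve2, _ = select_iteration2(
        X[:, idx], y, target_n, grid, feature_names=pool_order, eps_w=eps_w
    )
    if annotation is not None and filter_stage == "after":
        kept = set(_apply_biotype_filter(sorted(genes), annotation, biotype_spec))
        genes = genes & kept
        attribution = {g: s for g, s in attribution.items() if g in genes}
        weights = {g: w for g, w in weights.items() if g in genes}
    return SelectionResult(
        iteration1_genes=set(pool),
        iteration2_genes=set(genes),
        C_star=C_star,
        theta=theta,
        target_n=target_n,
        subtype_attribution=attribution,
        weight_magnitudes=weights,
        curve_iteration1=curve1,
        curve_iteration2=curve2,
        seed=seed,
    )


def _apply_biotype_filter(genes, annotation, spec):
    spec = spec or BiotypeFilterSpec()
    lookup = annotation.lookup()
    kept = []
    for g in genes:
        if g not in lookup.index:
            continue
        rec = lookup.loc[g]
        if spec.keeps(str(rec["biotype"]), int(rec["length_bp"])):
            kept.append(g)
    return kept


class RecursiveSignatureSelector(BaseEstimator):
    """scikit-learn style transformer running the two-iteration selection.

    ``fit(X, y)`` expects samples x features (a DataFrame's columns are
    used as gene names); ``transform`` keeps the final signature columns.

    Attributes (after fit): ``result_``, ``C_star_``, ``selected_genes_``
    (sorted), ``support_`` (boolean mask over input features).
    """

    def __init__(
        self,
        theta: float = 0.9,
        target_n: int = 50,
        c_grid=None,
        eps_w: float = 1e-6,
        random_state: int | None = None,
    ):
        self.theta = theta
        self.target_n = target_n
        self.c_grid = c_grid
        self.eps_w = eps_w
        self.random_state = random_state

    def fit(self, X, y):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(np.asarray(X).shape[1]))
        values = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        self.result_ = recursive_select(
            values,
            np.asarray(y),
            feature_names=names,
            theta=self.theta,
            target_n=self.target_n,
            c_grid=self.c_grid,
            eps_w=self.eps_w,
            seed=self.random_state,
        )
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.C_star_ = self.result_.C_star
        self.selected_genes_ = sorted(self.result_.iteration2_genes, key=names.index)
        self.support_ = np.array([g in self.result_.iteration2_genes for g in names])
        self.n_features_in_ = len(names)
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


def signature_cv_accuracy(X, y, genes, feature_names, k: int = 10, seed: int | None = None) -> float:
    """Convenience: k-fold CV accuracy of a 2-norm SVM on a gene subset."""
    names = list(feature_names)
    idx = [names.index(g) for g in genes]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return float(cross_val_score(L2NormSVC(), np.asarray(X, dtype=float)[:, idx], np.asarray(y), cv=skf).mean())
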