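"""Prognostic evaluation of a gene signature.

The supervised principal-components (superPC) model screens signature
genes by their univariate Cox proportional-hazards Wald score, keeps genes
whose absolute score exceeds a threshold chosen by cross-validation, and
uses the first principal component of the survivors as a per-patient risk
score (oriented so higher score means higher hazard).  Risk scores are
split into high/low groups with a two-component Gaussian mixture fitted by
EM, and groups are compared with Kaplan-Meier curves, the log-rank test,
and univariate/multivariate Cox models reporting hazard ratios and a
likelihood-ratio explained-variation statistic R^2 = 1 - exp(-LR/n).

Single-covariate Cox fits (the screening scores, computed thousands of
times inside cross-validation) use an in-package Newton solver with the
Efron tie correction; multivariate models, Kaplan-Meier estimation and the
log-rank test go through lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats
from scipy.optimize import brentq
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# single-covariate Cox (Efron ties), Newton's method
# ---------------------------------------------------------------------------

def _cox_loglik_derivs(beta: float, x, time, event):
    """Efron partial log-likelihood, gradient and Hessian for one covariate.

    Fully vectorized: suffix sums give the risk-set aggregates and tied
    events are down-weighted by their within-tie rank (the Efron factor).
    """
    order = np.argsort(time, kind="stable")
    t_s, x_s = time[order], x[order]
    e_s = event[order].astype(bool)
    w = np.exp(beta * x_s)
    wx = w * x_s
    wxx = wx * x_s
    # suffix sums: aggregate over the risk set {time >= t}
    r0_all = np.cumsum(w[::-1])[::-1]
    r1_all = np.cumsum(wx[::-1])[::-1]
    r2_all = np.cumsum(wxx[::-1])[::-1]

    ev = np.flatnonzero(e_s)
    et = t_s[ev]
    uniq, inv, counts = np.unique(et, return_inverse=True, return_counts=True)
    first = np.searchsorted(t_s, uniq, side="left")
    r0, r1, r2 = r0_all[first], r1_all[first], r2_all[first]
    d0 = np.bincount(inv, weights=w[ev])
    d1 = np.bincount(inv, weights=wx[ev])
    d2 = np.bincount(inv, weights=wxx[ev])
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    f = (np.arange(len(et)) - starts[inv]) / counts[inv]

    z0 = r0[inv] - f * d0[inv]
    z1 = r1[inv] - f * d1[inv]
    z2 = r2[inv] - f * d2[inv]
    ratio = z1 / z0
    ll = beta * x_s[ev].sum() - np.log(z0).sum()
    grad = x_s[ev].sum() - ratio.sum()
    hess = -(z2 / z0 - ratio**2).sum()
    return ll, grad, hess


def univariate_cox(x, time, event, max_iter: int = 30, tol: float = 1e-9) -> dict:
    """Fit a one-covariate Cox PH model (Efron ties) by Newton's method.

    Returns coef, se, z, hazard ratio with 95% CI, Wald p, and the
    likelihood-ratio statistic against beta = 0.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("no events observed; Cox model undefined")
    if x.std() == 0:
        raise ValueError("constant covariate")

    ll0, _, _ = _cox_loglik_derivs(0.0, x, time, event)
    beta = 0.0
    ll = ll0
    for _ in range(max_iter):
        ll, grad, hess = _cox_loglik_derivs(beta, x, time, event)
        if hess >= 0:
            break
        step = -grad / hess
        # step-halving to keep the likelihood monotone
        new_beta = beta + step
        for _ in range(30):
            new_ll, _, _ = _cox_loglik_derivs(new_beta, x, time, event)
            if new_ll >= ll - 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2.0
        if abs(new_beta - beta) < tol * max(1.0, abs(beta)):
            beta = new_beta
            break
        beta = new_beta
    ll, grad, hess = _cox_loglik_derivs(beta, x, time, event)
    se = float(np.sqrt(-1.0 / hess)) if hess < 0 else np.inf
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return {
        "coef": float(beta),
        "se": se,
        "z": float(z),
        "hr": float(np.exp(beta)),
        "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
        "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
        "p": float(p),
        "lr_statistic": float(2.0 * (ll - ll0)),
    }


def univariate_cox_scores(X, time, event, gene_names=None) -> pd.DataFrame:
    """Per-gene single-covariate Cox fits on standardized expression.

    Returns a DataFrame indexed by gene with coef/se/z/hr/ci/p columns;
    constant genes are excluded (logged) rather than reported.
    """
    if isinstance(X, pd.DataFrame):
        gene_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if gene_names is None:
            gene_names = [f"g{j}" for j in range(X.shape[1])]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("no events observed")
    rows = {}
    excluded = []
    for j, gene in enumerate(gene_names):
        col = X[:, j]
        sd = col.std()
        if sd == 0:
            excluded.append(gene)
            continue
        rows[gene] = univariate_cox((col - col.mean()) / sd, time, event)
    if excluded:
        logger.warning("excluded %d constant gene(s) from Cox scoring", len(excluded))
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# superPC
# ---------------------------------------------------------------------------

class SuperPC(BaseEstimator):
    """Supervised principal-components survival model (one component).

    Parameters
    ----------
    n_thresholds : int
        Size of the screening-threshold grid (quantiles of the absolute
        univariate Cox Wald scores, always including 0).
    k_folds : int
        Folds of the threshold-selection cross-validation (stratified on
        the event indicator so every fold sees events).
    random_state : int or None

    Attributes
    ----------
    gene_scores_ : pd.Series, signed Wald z per gene
    threshold_ : float, selected |score| cutoff tau
    retained_genes_ : list of genes with |score| > tau
    loadings_ : unit-norm PC1 loadings over the retained genes
    center_, scale_ : per-gene standardization from the training data
    cv_curve_ : DataFrame (threshold, n_retained, lr_statistic)
    """

    def __init__(self, n_thresholds: int = 20, k_folds: int = 10, random_state: int | None = 0):
        self.n_thresholds = n_thresholds
        self.k_folds = k_folds
        self.random_state = random_state

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"g{j}" for j in range(X.shape[1])])

    @staticmethod
    def _pc1(Z: np.ndarray) -> np.ndarray:
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        return vt[0]

    def fit(self, X, time, event):
        Xf = self._as_frame(X)
        if Xf.shape[1] < 2:
            raise ValueError("superPC needs at least 2 genes")
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)

        scores = univariate_cox_scores(Xf, time, event)
        z = scores["z"]
        qs = np.linspace(0.0, 0.95, self.n_thresholds)
        grid = np.unique(np.quantile(np.abs(z.to_numpy()), qs))
        grid[0] = 0.0

        skf = StratifiedKFold(n_splits=self.k_folds, shuffle=True, random_state=self.random_state)
        n = len(Xf)
        oof = {tau: np.full(n, np.nan) for tau in grid}
        valid = {tau: True for tau in grid}
        for train, test in skf.split(Xf, event):
            sub = Xf.iloc[train]
            mu, sd = sub.mean(), sub.std(ddof=0).replace(0.0, np.nan)
            keep_cols = sd.notna()
            sub_sc = scores_fold = None
            scores_fold = univariate_cox_scores(sub.loc[:, keep_cols], time[train], event[train])
            ztr = scores_fold["z"].abs()
            Ztr = ((sub.loc[:, keep_cols] - mu[keep_cols]) / sd[keep_cols]).to_numpy()
            Zte = ((Xf.iloc[test].loc[:, keep_cols] - mu[keep_cols]) / sd[keep_cols]).to_numpy()
            cols = list(sub.loc[:, keep_cols].columns)
            for tau in grid:
                kept = [k for k, g in enumerate(cols) if g in ztr.index and ztr[g] > tau]
                if not kept:
                    valid[tau] = False
                    continue
                v = self._pc1(Ztr[:, kept])
                s_train = Ztr[:, kept] @ v
                # orient so higher score = higher hazard on the training fold
                if univariate_cox_scores(pd.DataFrame({"s": s_train}), time[train], event[train])["coef"].iloc[0] < 0:
                    v = -v
                oof[tau][test] = Zte[:, kept] @ v

        rows = []
        for tau in grid:
            if not valid[tau] or np.isnan(oof[tau]).any():
                continue
            s = oof[tau]
            if s.std() == 0:
                continue
            fit = univariate_cox((s - s.mean()) / s.std(), time, event)
            rows.append({"threshold": float(tau), "n_retained": int((np.abs(z) > tau).sum()), "lr_statistic": fit["lr_statistic"]})
        if not rows:
            raise ValueError("no screening threshold retained genes in every fold")
        curve = pd.DataFrame(rows)
        best = curve.loc[curve["lr_statistic"].idxmax()]
        tau_star = float(best["threshold"])

        retained = list(z.index[np.abs(z) > tau_star])
        if not retained:
            raise ValueError("selected threshold retains no genes")
        self.center_ = Xf[retained].mean()
        self.scale_ = Xf[retained].std(ddof=0)
        if (self.scale_ == 0).any():
            raise ValueError("constant retained gene")
        Z = ((Xf[retained] - self.center_) / self.scale_).to_numpy()
        v = self._pc1(Z)
        s_train = Z @ v
        train_fit = univariate_cox((s_train - s_train.mean()) / s_train.std(), time, event)
        if train_fit["coef"] < 0:
            v = -v
        self.gene_scores_ = z
        self.univariate_table_ = scores
        self.threshold_ = tau_star
        self.retained_genes_ = retained
        self.loadings_ = v
        self.cv_curve_ = curve
        self.n_features_in_ = Xf.shape[1]
        self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)
        return self

    def predict(self, X) -> np.ndarray:
        """Per-sample risk score (higher = higher hazard on training data)."""
        check_is_fitted(self, "loadings_")
        Xf = self._as_frame(X)
        missing = [g for g in self.retained_genes_ if g not in Xf.columns]
        if missing:
            raise KeyError(f"retained genes missing from input: {missing}")
        Z = ((Xf[self.retained_genes_] - self.center_) / self.scale_).to_numpy()
        return Z @ self.loadings_


def fit_superpc(X, time, event, n_thresholds: int = 20, k_folds: int = 10, seed: int | None = 0) -> SuperPC:
    return SuperPC(n_thresholds=n_thresholds, k_folds=k_folds, random_state=seed).fit(X, time, event)


def risk_scores(model: SuperPC, X) -> np.ndarray:
    return model.predict(X)


def top_prognostic_genes(univariate_table: pd.DataFrame, coef_threshold: float = 0.0) -> pd.DataFrame:
    """Genes whose |Cox coefficient| exceeds the threshold, ranked by |z|."""
    table = univariate_table.copy()
    kept = table[table["coef"].abs() > coef_threshold]
    return kept.reindex(kept["z"].abs().sort_values(ascending=False).index)


# ---------------------------------------------------------------------------
# risk grouping
# ---------------------------------------------------------------------------

@dataclass
class RiskGrouping:
    """Two-component Gaussian mixture over risk scores with a derived cutoff."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    cutoff: float
    labels: np.ndarray = field(repr=False)  # 'high'/'low' per sample
    fallback: bool = False

    def __post_init__(self) -> None:
        if not self.fallback:
            lo, hi = sorted(self.means)
            if not (lo < self.cutoff < hi):
                raise ValueError("cutoff must lie strictly between component means")


class GaussianRiskSplit(BaseEstimator):
    """EM fit of a two-component 1-D Gaussian mixture to risk scores.

    The high/low cutoff is the point between the component means where the
    posterior probabilities of the two components are equal.  Degenerate
    fits (a component carrying fewer than two samples' worth of weight, or
    no posterior crossing between the means) fall back to a median split
    with a warning.
    """

    def __init__(self, n_restarts: int = 10, random_state: int | None = 0):
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, scores):
        scores = np.asarray(scores, dtype=float).ravel()
        if scores.size < 10:
            raise ValueError("need at least 10 samples to fit a risk mixture")
        if scores.std() == 0:
            raise ValueError("risk scores are constant")
        gm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            n_init=self.n_restarts,
            init_params="kmeans",
            random_state=self.random_state,
        ).fit(scores.reshape(-1, 1))
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        weights = gm.weights_.ravel()
        order = np.argsort(means)
        means, sds, weights = means[order], sds[order], weights[order]

        fallback = False
        cutoff = np.nan
        if weights.min() * scores.size < 2 or np.isclose(means[0], means[1]):
            fallback = True
        else:
            def logpost_diff(x):
                a = np.log(weights[0]) + stats.norm.logpdf(x, means[0], sds[0])
                b = np.log(weights[1]) + stats.norm.logpdf(x, means[1], sds[1])
                return a - b

            lo, hi = means[0], means[1]
            if logpost_diff(lo) > 0 > logpost_diff(hi):
                cutoff = float(brentq(logpost_diff, lo, hi))
            else:
                fallback = True
        if fallback:
            logger.warning("degenerate mixture fit; falling back to median split")
            cutoff = float(np.median(scores))
        labels = np.where(scores >= cutoff, "high", "low")
        self.grouping_ = RiskGrouping(
            means=means, sds=sds, weights=weights, cutoff=cutoff, labels=labels, fallback=fallback
        )
        return self


def split_risk_groups(scores, seed: int | None = 0) -> RiskGrouping:
    return GaussianRiskSplit(random_state=seed).fit(scores).grouping_


# ---------------------------------------------------------------------------
# group comparison and Cox summaries
# ---------------------------------------------------------------------------

def km_logrank(groups, time, event) -> dict:
    """Kaplan-Meier curves per group plus the two-sided log-rank p-value.

    Returns {'curves': {group: survival DataFrame}, 'p_value': float}.
    """
    groups = np.asarray(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    names = np.unique(groups)
    if names.size < 2:
        raise ValueError("need two non-empty groups for a log-rank test")
    curves = {}
    for g in names:
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=str(g))
        curves[str(g)] = kmf.survival_function_
    a, b = groups == names[0], groups == names[1]
    p_value = np.nan
    if event[a].sum() + event[b].sum() > 0:
        res = _lifelines_logrank(time[a], time[b], event_observed_A=event[a], event_observed_B=event[b])
        p_value = float(res.p_value)
    else:
        logger.warning("no events in either group; log-rank undefined")
    return {"curves": curves, "p_value": p_value}


@dataclass
class CoxSummary:
    """Cox PH fit summary with explained variation."""

    table: pd.DataFrame  # per-covariate: hazard_ratio, ci_low, ci_high, p
    r_squared: float
    lr_statistic: float
    n: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared < 1.0):
            raise ValueError("r_squared must lie in [0, 1)")


DEFAULT_REFERENCE_LEVELS = {
    "race": "White",
    "treatment": "Untreated or other",
    "stage": "T1",
    "histology": "Infiltrating Ductal Carcinoma",
}


def cox_with_r2(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list | None = None,
    reference_levels: dict | None = None,
) -> CoxSummary:
    """Cox PH fit (Efron ties) with HR/CI/p per covariate and
    R^2 = 1 - exp(-LR / n), the likelihood-ratio explained-variation.

    Categorical covariates are dummy-coded against configurable reference
    levels; rows with missing values are dropped complete-case (logged).
    """
    refs = dict(DEFAULT_REFERENCE_LEVELS)
    refs.update(reference_levels or {})
    covariates = list(covariates) if covariates is not None else [
        c for c in df.columns if c not in (duration_col, event_col)
    ]
    work = df[[duration_col, event_col] + covariates].replace("", np.nan)
    n_before = len(work)
    work = work.dropna()
    n_dropped = n_before - len(work)
    if n_dropped:
        logger.warning("dropped %d incomplete row(s) for the Cox model", n_dropped)

    design = work[[duration_col, event_col]].copy()
    design[duration_col] = pd.to_numeric(design[duration_col])
    design[event_col] = pd.to_numeric(design[event_col])
    for cov in covariates:
        col = work[cov]
        if pd.api.types.is_numeric_dtype(col):
            design[cov] = pd.to_numeric(col)
            continue
        levels = sorted(col.astype(str).unique())
        ref = refs.get(cov, levels[0])
        if ref not in levels:
            ref = levels[0]
        for lev in levels:
            if lev == ref:
                continue
            design[f"{cov}[{lev}]"] = (col.astype(str) == lev).astype(float)

    cph = CoxPHFitter()
    cph.fit(design, duration_col=duration_col, event_col=event_col)
    lr = float(cph.log_likelihood_ratio_test().test_statistic)
    n = len(design)
    table = pd.DataFrame(
        {
            "coef": cph.summary["coef"],
            "hazard_ratio": cph.summary["exp(coef)"],
            "ci_low": cph.summary["exp(coef) lower 95%"],
            "ci_high": cph.summary["exp(coef) upper 95%"],
            "p": cph.summary["p"],
        }
    )
    return CoxSummary(
        table=table,
        r_squared=float(1.0 - np.exp(-lr / n)),
        lr_statistic=lr,
        n=n,
        n_dropped=n_dropped,
    )
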