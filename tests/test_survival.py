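import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from genesig.survival import (
    SuperPC,
    cox_with_r2,
    km_logrank,
    split_risk_groups,
    top_prognostic_genes,
    univariate_cox,
    univariate_cox_scores,
)


def simulate_survival(rng, n, beta=0.0, censor_scale=None):
    x = rng.normal(size=n)
    T = rng.exponential(np.exp(-beta * x))
    if censor_scale is None:
        return x, T, np.ones(n, dtype=int)
    C = rng.uniform(0, censor_scale, size=n)
    return x, np.minimum(T, C), (T <= C).astype(int)


class TestUnivariateCox:
    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(1)
        x, t, e = simulate_survival(rng, 150, beta=0.8, censor_scale=3.0)
        t = np.round(t, 2)  # induce ties to exercise the Efron correction
        mine = univariate_cox(x, t, e)
        cph = CoxPHFitter().fit(pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e")
        assert mine["coef"] == pytest.approx(cph.summary["coef"].iloc[0], abs=1e-4)
        assert mine["se"] == pytest.approx(cph.summary["se(coef)"].iloc[0], abs=1e-4)
        assert mine["p"] == pytest.approx(cph.summary["p"].iloc[0], rel=1e-3)

    def test_planted_hazard_recovered(self):
        rng = np.random.default_rng(2)
        hrs = []
        for _ in range(20):
            x, t, e = simulate_survival(rng, 300, beta=1.0, censor_scale=2.5)
            hrs.append(univariate_cox(x, t, e)["hr"])
        assert 2.0 <= np.mean(hrs) <= 3.7  # true e^1 ~ 2.72

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            univariate_cox(np.arange(5.0), np.arange(1.0, 6.0), np.zeros(5, dtype=int))

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            univariate_cox(np.ones(5), np.arange(1.0, 6.0), np.ones(5, dtype=int))

    def test_scores_table_excludes_constant_genes(self):
        rng = np.random.default_rng(3)
        x, t, e = simulate_survival(rng, 80, beta=0.5, censor_scale=4.0)
        X = pd.DataFrame({"good": x, "flat": np.ones(80)})
        table = univariate_cox_scores(X, t, e)
        assert list(table.index) == ["good"]


@pytest.fixture(scope="module")
def prognostic_cohort():
    from genesig.simulate import SimSpec, simulate_cohort

    spec = SimSpec(
        seed=3, n_samples=400, n_genes=36, n_classes=2, n_informative_per_class=1,
        n_prognostic=5, censoring_rate=0.3,
    )
    cohort = simulate_cohort(spec)
    time, event = cohort["clinical"].endpoint("OS")
    return {
        "X": cohort["expression"].data.T,
        "time": time.to_numpy(),
        "event": event.to_numpy(),
        "planted": set(cohort["truth"].prognostic_betas),
    }


class TestSuperPC:
    def test_screens_down_to_prognostic_genes(self, prognostic_cohort):
        model = SuperPC(random_state=0).fit(
            prognostic_cohort["X"], prognostic_cohort["time"], prognostic_cohort["event"]
        )
        retained = set(model.retained_genes_)
        assert len(retained & prognostic_cohort["planted"]) >= 3

    def test_vacuous_threshold_equals_plain_pc1(self, prognostic_cohort):
        X, t, e = prognostic_cohort["X"], prognostic_cohort["time"], prognostic_cohort["event"]
        model = SuperPC(n_thresholds=1, random_state=0).fit(X, t, e)
        assert set(model.retained_genes_) == set(X.columns)
        Z = ((X - X.mean()) / X.std(ddof=0)).to_numpy()
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        pc1 = Z @ vt[0]
        score = model.predict(X)
        corr = np.corrcoef(pc1, score)[0, 1]
        assert abs(corr) > 0.999999

    def test_risk_score_centering_and_duplication(self, prognostic_cohort):
        X, t, e = prognostic_cohort["X"], prognostic_cohort["time"], prognostic_cohort["event"]
        model = SuperPC(random_state=0).fit(X, t, e)
        scores = model.predict(X)
        assert abs(scores.mean()) < 1e-8
        doubled = pd.concat([X, X.iloc[:1]])
        assert model.predict(doubled)[-1] == pytest.approx(scores[0])

    def test_risk_score_oriented_toward_hazard(self, prognostic_cohort):
        X, t, e = prognostic_cohort["X"], prognostic_cohort["time"], prognostic_cohort["event"]
        model = SuperPC(random_state=0).fit(X, t, e)
        s = model.predict(X)
        fit = univariate_cox((s - s.mean()) / s.std(), t, e)
        assert fit["coef"] >= 0

    def test_missing_retained_gene_rejected(self, prognostic_cohort):
        X, t, e = prognostic_cohort["X"], prognostic_cohort["time"], prognostic_cohort["event"]
        model = SuperPC(random_state=0).fit(X, t, e)
        with pytest.raises(KeyError, match="missing"):
            model.predict(X.drop(columns=model.retained_genes_[:1]))

    def test_top_gene_ranking(self, prognostic_cohort):
        X, t, e = prognostic_cohort["X"], prognostic_cohort["time"], prognostic_cohort["event"]
        model = SuperPC(random_state=0).fit(X, t, e)
        table = model.univariate_table_
        everything = top_prognostic_genes(table, coef_threshold=0.0)
        assert len(everything) == len(table)
        assert (everything["z"].abs().diff().dropna() <= 1e-12).all()
        nothing = top_prognostic_genes(table, coef_threshold=table["coef"].abs().max() + 1)
        assert nothing.empty


class TestRiskGrouping:
    def test_bimodal_scores_split_at_valley(self):
        rng = np.random.default_rng(0)
        scores = np.concatenate([rng.normal(0, 1, 200), rng.normal(10, 1, 200)])
        truth = np.array(["low"] * 200 + ["high"] * 200)
        grouping = split_risk_groups(scores, seed=0)
        assert 2.5 < grouping.cutoff < 7.5
        assert (grouping.labels == truth).mean() >= 0.99

    def test_symmetric_mixture_cutoff_near_zero(self):
        rng = np.random.default_rng(1)
        scores = np.concatenate([rng.normal(-3, 1, 300), rng.normal(3, 1, 300)])
        grouping = split_risk_groups(scores, seed=0)
        assert abs(grouping.cutoff) <= 0.2

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            split_risk_groups(np.ones(50))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            split_risk_groups(np.arange(5.0))

    def test_groups_partition_sample(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=120)
        grouping = split_risk_groups(scores, seed=0)
        assert len(grouping.labels) == 120
        assert set(grouping.labels) <= {"high", "low"}


class TestKMLogrank:
    def test_strong_hazard_difference_detected(self):
        rng = np.random.default_rng(3)
        t_a = rng.exponential(1.0, 200)
        t_b = rng.exponential(1.0 / 3.0, 200)  # 3x hazard
        groups = np.array(["low"] * 200 + ["high"] * 200)
        out = km_logrank(groups, np.concatenate([t_a, t_b]), np.ones(400, dtype=int))
        assert out["p_value"] < 0.001
        assert set(out["curves"]) == {"low", "high"}

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two"):
            km_logrank(np.array(["a"] * 10), np.arange(1.0, 11.0), np.ones(10, dtype=int))


class TestCoxWithR2:
    def test_r_squared_matches_lr_formula_and_null_is_small(self):
        rng = np.random.default_rng(4)
        n = 300
        df = pd.DataFrame(
            {
                "time": rng.exponential(1.0, n),
                "event": np.ones(n, dtype=int),
                "noise": rng.normal(size=n),
            }
        )
        out = cox_with_r2(df, "time", "event")
        assert out.r_squared == pytest.approx(1.0 - np.exp(-out.lr_statistic / out.n))
        assert out.r_squared < 0.05

    def test_planted_binary_covariate_recovered(self):
        rng = np.random.default_rng(5)
        n = 500
        group = rng.integers(0, 2, n)
        t = rng.exponential(np.exp(-np.log(2.5) * group))
        df = pd.DataFrame({"time": t, "event": np.ones(n, dtype=int), "group": group.astype(float)})
        out = cox_with_r2(df, "time", "event")
        hr = out.table["hazard_ratio"].iloc[0]
        assert 2.1 <= hr <= 3.0
        assert out.table["ci_low"].iloc[0] <= hr <= out.table["ci_high"].iloc[0]

    def test_categorical_reference_levels_and_complete_case(self):
        rng = np.random.default_rng(6)
        n = 200
        df = pd.DataFrame(
            {
                "time": rng.exponential(1.0, n),
                "event": np.ones(n, dtype=int),
                "race": rng.choice(["White", "Black", "Asian"], n),
                "age": rng.normal(58, 10, n),
            }
        )
        df.loc[df.index[:10], "age"] = np.nan
        out = cox_with_r2(df, "time", "event")
        assert out.n_dropped == 10
        labels = set(out.table.index)
        assert "race[White]" not in labels  # reference level absorbed
        assert {"race[Black]", "race[Asian]", "age"} <= labels
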