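"""Score-outcome regressions, BH-FDR, partial correlations."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from crosstalknet import bh_adjust, fit_score_associations, partial_correlations
from crosstalknet.synthetic import CohortConfig, generate_latent_cohort


def bh_stepup_oracle(p):
    """Literal step-up definition: adj p_(i) = min_{j>=i} min(1, p_(j)*m/j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adjusted = np.empty(m)
    for i in range(m):
        best = 1.0
        for j in range(i, m):
            best = min(best, min(1.0, sorted_p[j] * m / (j + 1)))
        adjusted[i] = best
    out = np.empty(m)
    out[order] = adjusted
    return out


def _covariates(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "age": rng.normal(50, 7, n),
            "sex": rng.binomial(1, 0.6, n).astype(float),
            "BMI": rng.normal(30, 2, n),
        },
        index=[f"s{i}" for i in range(n)],
    )


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.04, 0.03, 0.05]), [0.04, 0.05, 0.05, 0.05]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_monotone_in_rank_and_matches_oracles(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            m = int(rng.integers(1, 21))
            p = rng.uniform(size=m)
            adj = bh_adjust(p)
            assert np.array_equal(adj, bh_stepup_oracle(p))
            np.testing.assert_allclose(
                adj, multipletests(p, method="fdr_bh")[1], atol=1e-12
            )
            order = np.argsort(p, kind="stable")
            assert (np.diff(adj[order]) >= 0).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])


class TestScoreAssociations:
    def test_beta_se_match_closed_form(self):
        rng = np.random.default_rng(20)
        n = 40
        cov = _covariates(n, seed=2)
        scores = pd.DataFrame({"score_1": rng.normal(size=n)}, index=cov.index)
        outcomes = pd.DataFrame(
            {"Glucose (mg/dL)": 100 + 2 * scores["score_1"] + rng.normal(size=n)},
            index=cov.index,
        )
        table = fit_score_associations(scores, outcomes, cov).table
        X = np.column_stack(
            [np.ones(n), scores["score_1"], cov["age"], cov["sex"], cov["BMI"]]
        )
        y = outcomes.iloc[:, 0].to_numpy()
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - X.shape[1])
        se = np.sqrt(sigma2 * np.diag(XtX_inv))
        assert table.loc[0, "beta"] == pytest.approx(beta[1], abs=1e-9)
        assert table.loc[0, "se"] == pytest.approx(se[1], abs=1e-9)

    def test_exact_linear_outcome_flagged_degenerate(self):
        cov = _covariates(30, seed=3)
        scores = pd.DataFrame(
            {"s": np.random.default_rng(30).normal(size=30)}, index=cov.index
        )
        outcomes = pd.DataFrame({"HOMA IR": 2 * scores["s"]}, index=cov.index)
        table = fit_score_associations(scores, outcomes, cov).table
        assert table.loc[0, "beta"] == pytest.approx(2.0, abs=1e-8)
        assert table.loc[0, "flag"] == "degenerate_se"

    def test_constant_outcome_flagged_not_fitted(self):
        cov = _covariates(20, seed=4)
        scores = pd.DataFrame(
            {"s": np.random.default_rng(4).normal(size=20)}, index=cov.index
        )
        outcomes = pd.DataFrame({"HOMA IR": np.full(20, 3.3)}, index=cov.index)
        table = fit_score_associations(scores, outcomes, cov).table
        assert table.loc[0, "flag"] == "constant_outcome"
        assert np.isnan(table.loc[0, "beta"])

    def test_bh_family_is_per_score(self):
        rng = np.random.default_rng(5)
        n = 50
        cov = _covariates(n, seed=5)
        scores = pd.DataFrame(
            {"s1": rng.normal(size=n), "s2": rng.normal(size=n)}, index=cov.index
        )
        outcomes = pd.DataFrame(
            {f"o{k}": rng.normal(size=n) for k in range(4)}, index=cov.index
        )
        table = fit_score_associations(scores, outcomes, cov).table
        for name in ("s1", "s2"):
            sub = table[table["score"] == name]
            np.testing.assert_allclose(
                sub["p_adj"].to_numpy(), bh_adjust(sub["p"].to_numpy())
            )

    def test_listwise_deletion_logged_in_n(self):
        cov = _covariates(25, seed=6)
        scores = pd.DataFrame(
            {"s": np.random.default_rng(6).normal(size=25)}, index=cov.index
        )
        y = np.random.default_rng(7).normal(size=25)
        y[::5] = np.nan
        outcomes = pd.DataFrame({"HOMA IR": y}, index=cov.index)
        table = fit_score_associations(scores, outcomes, cov).table
        assert table.loc[0, "n"] == 20

    def test_recovers_planted_effect_within_3_se(self):
        config = CohortConfig(
            n_subjects=500,
            n_factors=5,
            outcome_effects={"Cholesterol (mg/dL)": {0: 16.0}},
            seed=12,
        )
        cohort = generate_latent_cohort(config)
        from crosstalknet.synthetic import generate_outcomes

        cohort = generate_outcomes(cohort, config)
        f = cohort.latent_factors.iloc[:, 0]
        scores = pd.DataFrame({"s": (f - f.mean()) / f.std(ddof=1)}, index=f.index)
        table = fit_score_associations(scores, cohort.outcomes[["Cholesterol (mg/dL)"]],
                                       cohort.covariates).table
        truth = 16.0 * f.std(ddof=1)  # per 1-SD of the standardized score
        assert abs(table.loc[0, "beta"] - truth) < 3 * table.loc[0, "se"]


class TestPartialCorrelations:
    def test_agrees_with_recursive_formula_and_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(80)
        n = 60
        cov = _covariates(n, seed=8)
        x = rng.normal(size=n) + 0.05 * cov["age"].to_numpy()
        y = 0.5 * x + rng.normal(size=n) + 0.1 * cov["BMI"].to_numpy()
        members = pd.DataFrame({"x": x}, index=cov.index)
        outcomes = pd.DataFrame({"y": y}, index=cov.index)
        pcm = partial_correlations(members, outcomes, cov)
        df = pd.concat([members, outcomes, cov], axis=1)
        ref = pg.partial_corr(df, x="x", y="y", covar=["age", "sex", "BMI"])
        assert pcm.r.loc["x", "y"] == pytest.approx(ref["r"].iloc[0], abs=1e-10)
        assert pcm.p.loc["x", "y"] == pytest.approx(ref["p_val"].iloc[0], abs=1e-10)

        # recursive elimination oracle: partial out covariates one at a time
        def partial_recursive(R, names, x, y, covars):
            if not covars:
                return R.loc[x, y]
            z, rest = covars[0], covars[1:]
            sub = {}
            for a in names:
                for b in names:
                    if a in (z,) or b in (z,):
                        continue
                    num = R.loc[a, b] - R.loc[a, z] * R.loc[b, z]
                    den = np.sqrt((1 - R.loc[a, z] ** 2) * (1 - R.loc[b, z] ** 2))
                    sub[(a, b)] = num / den
            names2 = [a for a in names if a != z]
            R2 = pd.DataFrame(
                [[sub[(a, b)] for b in names2] for a in names2],
                index=names2,
                columns=names2,
            )
            return partial_recursive(R2, names2, x, y, rest)

        R = df.corr()
        r_rec = partial_recursive(R, list(df.columns), "x", "y", ["age", "sex", "BMI"])
        assert pcm.r.loc["x", "y"] == pytest.approx(r_rec, abs=1e-10)

    def test_outcome_equal_to_covariate_has_zero_partial_r(self):
        cov = _covariates(40, seed=9)
        members = pd.DataFrame(
            {"x": np.random.default_rng(9).normal(size=40)}, index=cov.index
        )
        outcomes = pd.DataFrame({"y": cov["age"]}, index=cov.index)
        pcm = partial_correlations(members, outcomes, cov)
        assert abs(pcm.r.loc["x", "y"]) < 1e-10

    def test_null_covariates_match_marginal_correlation(self):
        rng = np.random.default_rng(101)
        n = 5000
        cov = _covariates(n, seed=10)
        x = rng.normal(size=n)
        y = 0.4 * x + rng.normal(size=n)
        pcm = partial_correlations(
            pd.DataFrame({"x": x}, index=cov.index),
            pd.DataFrame({"y": y}, index=cov.index),
            cov,
        )
        marginal = np.corrcoef(x, y)[0, 1]
        assert pcm.r.loc["x", "y"] == pytest.approx(marginal, abs=0.02)

    def test_matrix_bh_adjustment_covers_all_cells(self):
        rng = np.random.default_rng(11)
        n = 50
        cov = _covariates(n, seed=11)
        members = pd.DataFrame(rng.normal(size=(n, 3)), index=cov.index, columns=list("abc"))
        outcomes = pd.DataFrame(rng.normal(size=(n, 2)), index=cov.index, columns=["y1", "y2"])
        pcm = partial_correlations(members, outcomes, cov)
        np.testing.assert_allclose(
            pcm.p_adj.to_numpy().ravel(), bh_adjust(pcm.p.to_numpy().ravel())
        )
        assert (pcm.p_adj.to_numpy() >= pcm.p.to_numpy() - 1e-15).all()
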