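"""Spearman correlation, the Gibbs-sampled Gaussian GLM, DIC and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairflow import association as assoc
from pairflow.association import (
    CollinearityError,
    ModelSpec,
    default_model_set,
    dic,
    exclude_comparisons,
    fit_bayes_glm,
    intra_inter_summary,
    rank_models,
    spearman,
)

FAST_CHAIN = dict(iterations=30_000, burnin=500, thin=10)


def brute_force_spearman(x, y):
    """Independent oracle: average ranks by explicit tie-group enumeration,
    then the textbook Pearson product-moment formula."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


class TestSpearman:
    def test_perfect_monotone(self):
        r = spearman([1, 2, 3, 4], [10, 20, 40, 80])
        assert r.rho == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_tied_vectors_match_brute_force_oracle(self):
        x = [3.0, 1.0, 1.0, 2.0, 5.0, 5.0, 5.0, 4.0]
        y = [1.0, 2.0, 2.0, 2.0, 3.0, 4.0, 4.0, 1.0]
        r = spearman(x, y)
        assert r.rho == pytest.approx(brute_force_spearman(x, y), abs=1e-12)

    def test_matches_scipy_including_p_value(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(0)
        x = rng.integers(0, 5, 30).astype(float)
        y = x + rng.normal(0, 2, 30)
        r = spearman(x, y)
        rho, p = spearmanr(x, y)
        assert r.rho == pytest.approx(rho, abs=1e-12)
        assert r.p == pytest.approx(p, abs=1e-9)

    def test_degenerate_constant_input(self):
        r = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert (r.rho, r.p, r.degenerate) == (0.0, 1.0, True)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
        assert spearman(x, 3 * y + 7).rho == pytest.approx(base, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2])


def synthetic_table(rng, n=30, slope=0.0, predictor="time", noise=1.0):
    """Pair-table-shaped frame with a controllable linear signal."""
    cols = {
        "time_myr": rng.uniform(2.5, 4.2, n),
        "distance_km": rng.uniform(30, 280, n),
        "morphology_pc": rng.uniform(0, 15, n),
        "climate_pc": rng.uniform(5, 105, n),
    }
    y = slope * cols[assoc.PREDICTOR_COLUMNS[predictor]] + rng.normal(0, noise, n)
    df = pd.DataFrame(cols)
    df["clade_admixture_mean_freq"] = y
    df["comparison"] = np.arange(1, n + 1)
    return df


class TestFitBayesGlm:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(1)
        df = synthetic_table(rng, n=50, slope=-3.0, predictor="time", noise=0.1)
        df["clade_admixture_mean_freq"] += 2.0  # intercept
        res = fit_bayes_glm(df, ModelSpec(("time",), seed=2, **FAST_CHAIN))
        slope = res.coefficient("time")
        sd = res.samples[:, 1].std(ddof=1)
        assert abs(slope["mean"] - (-3.0)) < 3 * sd
        icept = res.coefficient("(Intercept)")
        assert icept["ci_lower"] <= icept["mean"] <= icept["ci_upper"]

    def test_null_predictor_is_not_significant(self):
        rng = np.random.default_rng(2)
        df = synthetic_table(rng, n=40, slope=0.0)
        res = fit_bayes_glm(df, ModelSpec(("space",), seed=3, **FAST_CHAIN))
        assert res.coefficient("space")["pmcmc"] > 0.05

    def test_posterior_mean_matches_ols(self, pair_table):
        import statsmodels.api as sm

        res = fit_bayes_glm(pair_table, ModelSpec(("time", "morphology"),
                                                  seed=4, **FAST_CHAIN))
        X = sm.add_constant(pair_table[["time_myr", "morphology_pc"]].to_numpy())
        ols = sm.OLS(pair_table["clade_admixture_mean_freq"].to_numpy(), X).fit()
        for j in range(3):
            draws = res.samples[:, j]
            mcse = draws.std(ddof=1) / np.sqrt(res.coefficient(res.coef_names[j])["ess"])
            assert abs(draws.mean() - ols.params[j]) < 3 * mcse + 1e-9

    def test_pmcmc_bounds_and_ess_cap(self, pair_table):
        res = fit_bayes_glm(pair_table, ModelSpec(("time",), seed=5, **FAST_CHAIN))
        nk = res.spec.n_samples
        for name in res.coef_names:
            row = res.coefficient(name)
            assert 2.0 / nk <= row["pmcmc"] <= 1.0
            assert row["ess"] <= nk

    def test_same_seed_reproduces_chain_and_dic(self, pair_table):
        spec = ModelSpec(("time",), seed=6, **FAST_CHAIN)
        r1 = fit_bayes_glm(pair_table, spec)
        r2 = fit_bayes_glm(pair_table, spec)
        np.testing.assert_array_equal(r1.samples, r2.samples)
        assert dic(r1) == dic(r2)

    def test_collinear_design_rejected(self, pair_table):
        df = pair_table.copy()
        df["distance_km"] = 2.0 * df["time_myr"]  # exact collinearity
        with pytest.raises(CollinearityError):
            fit_bayes_glm(df, ModelSpec(("time", "space"), seed=0, **FAST_CHAIN))


class TestDic:
    def test_true_predictor_beats_wrong_predictor(self):
        rng = np.random.default_rng(7)
        df = synthetic_table(rng, n=40, slope=-2.0, predictor="time", noise=1.0)
        d_true = dic(fit_bayes_glm(df, ModelSpec(("time",), seed=8, **FAST_CHAIN)))
        d_wrong = dic(fit_bayes_glm(df, ModelSpec(("climate",), seed=8, **FAST_CHAIN)))
        assert d_true < d_wrong

    def test_degenerate_residual_variance_guarded(self):
        df = synthetic_table(np.random.default_rng(9), n=20, slope=1.0, noise=0.0)
        with pytest.raises(FloatingPointError):
            fit_bayes_glm(df, ModelSpec(("time",), seed=0, **FAST_CHAIN))


class TestRankModels:
    def test_default_set_has_fourteen_models(self):
        models = default_model_set()
        assert len(models) == 14
        assert ("time", "morphology", "climate") not in models
        assert len(default_model_set(include_all15=True)) == 15

    def test_single_model_set(self, pair_table):
        ranking = rank_models(pair_table, [("time",)], seed=0, **FAST_CHAIN)
        assert len(ranking.table) == 1
        assert ranking.table.loc[0, "delta_dic"] == 0.0

    def test_space_driven_response_puts_space_on_top(self):
        rng = np.random.default_rng(10)
        df = synthetic_table(rng, n=30, slope=0.05, predictor="space", noise=0.5)
        ranking = rank_models(df, seed=1, **FAST_CHAIN)
        top3 = ranking.table.head(3)["predictors"]
        assert all("space" in preds for preds in top3)

    def test_failed_models_annotated_not_fatal(self):
        rng = np.random.default_rng(11)
        df = synthetic_table(rng, n=5, slope=1.0)  # too small for 4-predictor fits
        ranking = rank_models(df, seed=2, **FAST_CHAIN)
        tab = ranking.table
        assert (tab["error"] != "").any()
        ok = tab[tab["error"] == ""]
        assert len(ok) >= 1 and ok["dic"].notna().all()


class TestIntraInterSummary:
    def test_toy_medians_match_hand_computation(self):
        table = pd.DataFrame({
            "comparison": [1, 2, 3, 4],
            "clade_a": ["c1", "c1", "c2", "c3"],
            "clade_b": ["c2", "c3", "c3", "c4"],
            "clade_admixture_mean_freq": [10.0, 2.0, 4.0, 0.0],
            "clade_admixture_prop_ind": [0.5, 0.1, 0.2, 0.0],
            "pop_admixture_mean_freq": [20.0, 1.0, 3.0, 0.0],
            "pop_admixture_prop_ind": [1.0, 0.1, 0.3, 0.0],
        })
        species = {"c1": "X", "c2": "X", "c3": "Y", "c4": "Y"}
        # intra: pairs 1 (c1-c2) and 4 (c3-c4); inter: pairs 2 and 3
        out = intra_inter_summary(table, species)
        intra = out[(out["scope"] == "intraspecific")
                    & (out["metric"] == "clade_admixture_mean_freq")].iloc[0]
        assert intra["n"] == 2
        assert intra["median"] == pytest.approx(5.0)
        assert intra["iqr"] == pytest.approx(5.0)
        inter = out[(out["scope"] == "interspecific")
                    & (out["metric"] == "pop_admixture_mean_freq")].iloc[0]
        assert inter["median"] == pytest.approx(2.0)

    def test_single_group_other_absent(self):
        table = pd.DataFrame({
            "comparison": [1],
            "clade_a": ["c1"], "clade_b": ["c2"],
            "clade_admixture_mean_freq": [1.0],
            "clade_admixture_prop_ind": [0.1],
            "pop_admixture_mean_freq": [1.0],
            "pop_admixture_prop_ind": [0.1],
        })
        out = intra_inter_summary(table, {"c1": "X", "c2": "X"})
        assert set(out["scope"]) == {"intraspecific"}

    def test_unknown_clade_rejected(self):
        table = pd.DataFrame({
            "comparison": [1], "clade_a": ["c1"], "clade_b": ["c9"],
            "clade_admixture_mean_freq": [1.0], "clade_admixture_prop_ind": [0.1],
            "pop_admixture_mean_freq": [1.0], "pop_admixture_prop_ind": [0.1],
        })
        with pytest.raises(ValueError, match="c9"):
            intra_inter_summary(table, {"c1": "X"})


def test_exclude_comparisons(pair_table):
    out = exclude_comparisons(pair_table, [19])
    assert len(out) == 20 and 19 not in set(out["comparison"])
    with pytest.raises(ValueError):
        exclude_comparisons(pair_table, [99])


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(())
    with pytest.raises(ValueError):
        ModelSpec(("gravity",))
    with pytest.raises(ValueError):
        ModelSpec(("time",), iterations=1000, burnin=500, thin=100)
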