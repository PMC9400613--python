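"""Mixed-model fitting, model comparison and NHST battery tests."""

import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from cueuse.encoding_models import (
    SPATIAL_PROBS,
    VALUE_LABELS,
    RegressorTable,
    build_regressor_table,
)
from cueuse.inference import (
    compare_models,
    condition_means,
    fit_lme,
    jzs_bayes_t,
    jzs_bayes_t_stat,
    pairwise_tests,
    rm_anova,
    wald_test,
)

from conftest import make_summaries


def _spatial_summaries(beta0, beta, noise_sd=0.0, n_subjects=8, subject_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    sh = build_regressor_table("sh")
    rows = []
    for s in range(n_subjects):
        u = rng.normal(0, subject_sd) if subject_sd else 0.0
        for p in SPATIAL_PROBS:
            rows.append(dict(subject=s, p_tgt=p,
                             median_rt=beta0 + u + beta * sh[p] + rng.normal(0, noise_sd)))
    return pd.DataFrame(rows)


class TestFitLme:
    def test_noise_free_fit_recovers_generating_coefficient(self):
        fit = fit_lme(_spatial_summaries(480.0, 37.5), build_regressor_table("sh"))
        assert fit.beta_hat == pytest.approx(37.5, abs=1e-4)
        assert fit.intercept == pytest.approx(480.0, abs=1e-3)

    def test_information_criteria_identities(self, tiny_prep):
        for model_id in ("sh", "cf", "rv"):
            fit = fit_lme(tiny_prep["summaries"], build_regressor_table(model_id))
            k = fit.n_params
            assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k)
            assert fit.bic == pytest.approx(-2 * fit.loglik + k * math.log(fit.n_obs))

    def test_affine_transform_of_regressor(self):
        """a*x + b leaves the likelihood unchanged and scales beta by 1/a."""
        data = _spatial_summaries(500.0, 40.0, noise_sd=8.0, subject_sd=25.0, seed=3)
        sh = build_regressor_table("sh")
        scaled = RegressorTable(
            model_id="sh", entries={k: 2.0 * v + 1.0 for k, v in sh.entries.items()}
        )
        f1, f2 = fit_lme(data, sh), fit_lme(data, scaled)
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-5)
        assert f2.beta_hat == pytest.approx(f1.beta_hat / 2.0, rel=1e-5)

    def test_missing_response_rejected(self):
        data = _spatial_summaries(500.0, 40.0)
        data.loc[0, "median_rt"] = np.nan
        with pytest.raises(ValueError):
            fit_lme(data, build_regressor_table("sh"))


class TestCompareModels:
    def test_single_fit_ranks_first(self, tiny_prep):
        fit = fit_lme(tiny_prep["summaries"], build_regressor_table("sh"))
        ranking = compare_models([fit])
        assert ranking["rank"].tolist() == [1]

    def test_equal_fits_reported_as_tie(self, tiny_prep):
        fit = fit_lme(tiny_prep["summaries"], build_regressor_table("sh"))
        ranking = compare_models([fit, fit])
        assert ranking["tied"].all()
        assert ranking["rank"].tolist() == [1, 1]

    def test_mismatched_data_rejected(self, tiny_prep):
        f1 = fit_lme(tiny_prep["summaries"], build_regressor_table("sh"))
        f2 = fit_lme(tiny_prep["summaries"], build_regressor_table("cf"))
        assert f1.n_obs != f2.n_obs  # 3 vs 4 conditions per subject
        with pytest.raises(ValueError):
            compare_models([f1, f2])

    def test_sh_beats_its_counterfactual_null(self, tiny_prep):
        """Selection-history-shaped data reject the spatial counterfactual
        null: the two spatial regressors disagree most at the neutral cue."""
        fits = [fit_lme(tiny_prep["summaries"], build_regressor_table(m))
                for m in ("sh", "sh_cf_null")]
        ranking = compare_models(fits)
        assert ranking.iloc[0]["model_id"] == "sh"


class TestWald:
    def test_two_sigma_slope(self, tiny_prep):
        fit = fit_lme(tiny_prep["summaries"], build_regressor_table("sh"))
        fake = type(fit)(**{**fit.__dict__, "beta_hat": 2.0, "se": 1.0})
        res = wald_test(fake)
        assert res["statistic"] == pytest.approx(4.0)
        assert res["p"] == pytest.approx(0.0455, abs=1e-3)

    def test_zero_slope_gives_p_one(self, tiny_prep):
        fit = fit_lme(tiny_prep["summaries"], build_regressor_table("sh"))
        fake = type(fit)(**{**fit.__dict__, "beta_hat": 0.0, "se": 3.0})
        res = wald_test(fake)
        assert res["statistic"] == 0.0 and res["p"] == 1.0

    def test_zero_se_rejected(self, tiny_prep):
        fit = fit_lme(tiny_prep["summaries"], build_regressor_table("sh"))
        with pytest.raises(ValueError):
            wald_test(type(fit)(**{**fit.__dict__, "se": 0.0}))


class TestRmAnova:
    def test_two_level_factor_needs_no_correction(self, rng):
        rows = [dict(subject=s, cond=c, y=rng.normal(c, 1.0))
                for s in range(12) for c in (0, 1)]
        res = rm_anova(pd.DataFrame(rows), dv="y", within="cond")
        row = res[res["effect"] == "cond"].iloc[0]
        assert row["eps"] == pytest.approx(1.0)
        assert float(row["df1"]) == 1.0 and float(row["df2"]) == 11.0

    def test_two_way_design_reports_all_effects(self, tiny_prep):
        res = rm_anova(tiny_prep["summaries"], dv="median_rt",
                       within=["p_tgt", "value_config"])
        assert set(res["effect"]) == {"p_tgt", "value_config", "p_tgt * value_config"}
        assert ((res["p"] >= 0) & (res["p"] <= 1)).all()
        assert (res["np2"] >= 0).all()

    def test_group_by_condition_mixed_design(self, rng):
        rows = []
        for s in range(20):
            g = "a" if s < 10 else "b"
            for c in range(3):
                effect = c * 2.0 if g == "a" else 0.0
                rows.append(dict(subject=s, group=g, cond=c, y=rng.normal(effect, 1.0)))
        res = rm_anova(pd.DataFrame(rows), dv="y", within="cond", between="group")
        assert "Interaction" in set(res["effect"])

    def test_unbalanced_cells_rejected(self, rng):
        rows = [dict(subject=s, cond=c, y=0.0) for s in range(5) for c in (0, 1)]
        rows.append(dict(subject=0, cond=0, y=1.0))
        with pytest.raises(ValueError):
            rm_anova(pd.DataFrame(rows), dv="y", within="cond")


class TestPairwise:
    def test_identical_conditions(self):
        data = pd.DataFrame(
            [dict(subject=s, condition=c, response=100.0 + s) for s in range(6)
             for c in ("a", "b")]
        )
        res = pairwise_tests(data, [("a", "b")])
        row = res.iloc[0]
        assert row["t"] == 0.0 and row["p"] == 1.0 and row["d"] == 0.0

    def test_null_family_yields_no_discoveries_on_average(self):
        rng = np.random.default_rng(7)
        n_with_discovery = 0
        reps = 200
        for _ in range(reps):
            rows = []
            for s in range(20):
                for c in range(40):
                    rows.append(dict(subject=s, condition=f"c{c}",
                                     response=rng.normal(0, 1)))
            contrasts = [(f"c{2*i}", f"c{2*i+1}") for i in range(20)]
            res = pairwise_tests(pd.DataFrame(rows), contrasts)
            n_with_discovery += res["significant"].any()
        assert n_with_discovery / reps <= 0.07  # BH controls FWER under the global null

    def test_counterfactual_effect_pattern_detected(self):
        """With a 59 ms lT/hD cost and realistic between-subject noise, the
        three lT/hD contrasts are discovered and the null contrasts are not."""
        rng = np.random.default_rng(21)
        cf = build_regressor_table("cf")
        rows = []
        for s in range(60):
            for v in VALUE_LABELS:
                rows.append(dict(subject=s, condition=v,
                                 response=500 + 145 * cf[v] + rng.normal(0, 25)))
        contrasts = [("lT/hD", "hT/hD"), ("lT/hD", "lT/lD"), ("lT/hD", "hT/lD"),
                     ("hT/hD", "lT/lD"), ("hT/hD", "hT/lD"), ("lT/lD", "hT/lD")]
        res = pairwise_tests(pd.DataFrame(rows), contrasts).set_index("contrast")
        assert res.loc["lT/hD - hT/hD", "significant"]
        assert res.loc["lT/hD - lT/lD", "significant"]
        assert res.loc["lT/hD - hT/lD", "significant"]
        assert not res.loc["hT/hD - lT/lD", "significant"]
        assert res.loc["lT/hD - hT/hD", "d"] > 0.8

    def test_too_few_subjects_rejected(self):
        data = pd.DataFrame([dict(subject=0, condition=c, response=1.0) for c in "ab"])
        with pytest.raises(ValueError):
            pairwise_tests(data, [("a", "b")])


class TestJzsBayes:
    def test_null_t_at_large_n_favours_null(self):
        assert jzs_bayes_t_stat(0.0, 147) < 1.0

    def test_monotone_in_t(self):
        bfs = [jzs_bayes_t_stat(t, 30) for t in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(bfs, bfs[1:]))

    @pytest.mark.parametrize("t", [-2.0, 0.0, 0.8, 2.5, 5.0])
    @pytest.mark.parametrize("n", [10, 50, 147])
    def test_matches_independent_quadrature(self, t, n):
        """Cross-check against pingouin's closed-form JZS implementation."""
        ours = jzs_bayes_t_stat(t, n)
        theirs = float(pg.bayesfactor_ttest(t, n, paired=True, r=math.sqrt(2) / 2))
        assert ours == pytest.approx(theirs, rel=1e-4)

    def test_from_differences(self, rng):
        diffs = rng.normal(0.0, 1.0, size=40)
        t = diffs.mean() / (diffs.std(ddof=1) / math.sqrt(len(diffs)))
        assert jzs_bayes_t(diffs) == pytest.approx(jzs_bayes_t_stat(t, 40), rel=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            jzs_bayes_t(np.ones(10))


def test_condition_means_shapes(tiny_prep):
    spatial = condition_means(tiny_prep["summaries"], "spatial")
    value = condition_means(tiny_prep["summaries"], "value")
    assert set(spatial["condition"]) == set(SPATIAL_PROBS)
    assert set(value["condition"]) == set(VALUE_LABELS)
    assert len(spatial) == 3 * tiny_prep["summaries"]["subject"].nunique()
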