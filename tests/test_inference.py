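import warnings

import numpy as np
import pytest
import statsmodels.api as sm

import arealrisk as ar
from arealrisk.inference import (
    DICReport,
    compare_models,
    compute_dic,
    count_significant_effects,
    dic_verdict,
    effective_sample_size,
    split_rhat,
)
from arealrisk.synthetic_data import simulate_study
from conftest import linear_effects, mcmc


@pytest.fixture(scope="module")
def fe_fit_2000(null_study_2000, covariates):
    """Fixed-effects-only fit on a 2,000-area null simulation."""
    spec = ar.ModelSpec(covariates, "linear", "none")
    return ar.fit(
        spec, null_study_2000.outcomes, null_study_2000.scores, mcmc=mcmc(21)
    )


@pytest.fixture(scope="module")
def spatial_fit_small(small_study, covariates):
    spec = ar.ModelSpec(covariates, "linear", "spatial")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ar.fit(
            spec,
            small_study.outcomes,
            small_study.scores,
            lattice=small_study.lattice,
            mcmc=mcmc(22),
        )


class TestNullRecovery:
    def test_intercept_only_recovers_zero(self, null_study_2000):
        spec = ar.ModelSpec((), "linear", "none")
        fr = ar.fit(spec, null_study_2000.outcomes, null_study_2000.scores, mcmc=mcmc(23))
        assert fr.summaries.loc["alpha", "mean"] == pytest.approx(0.0, abs=0.05)

    def test_posterior_matches_ml_oracle(self, fe_fit_2000, null_study_2000, covariates):
        X = sm.add_constant(
            np.column_stack([null_study_2000.scores[k].score for k in covariates])
        )
        glm = sm.GLM(
            null_study_2000.outcomes.observed,
            X,
            family=sm.families.Poisson(),
            offset=np.log(null_study_2000.outcomes.expected),
        ).fit()
        post = fe_fit_2000.summaries["mean"]
        names = ["alpha"] + [f"beta_{k}" for k in covariates]
        for i, name in enumerate(names):
            assert abs(post[name] - glm.params[i]) < 0.02

    def test_pd_close_to_free_parameter_count(self, fe_fit_2000):
        report = compute_dic(fe_fit_2000)
        assert 3.0 <= report.p_d <= 5.0  # 4 free parameters

    def test_quantile_ordering(self, fe_fit_2000):
        s = fe_fit_2000.summaries
        assert (s["q5"] <= s["median"]).all() and (s["median"] <= s["q95"]).all()
        assert (s["q2.5"] <= s["q5"]).all() and (s["q95"] <= s["q97.5"]).all()


class TestSpatialFit:
    def test_credible_intervals_cover_generating_betas(self, spatial_fit_small):
        truth = {"deprivation": 0.157, "fragmentation": 0.134, "rurality": 0.041}
        for name, b in truth.items():
            lo = spatial_fit_small.summaries.loc[f"beta_{name}", "q2.5"]
            hi = spatial_fit_small.summaries.loc[f"beta_{name}", "q97.5"]
            assert lo < b < hi

    def test_sampled_spatial_field_sums_to_zero(self, spatial_fit_small):
        assert spatial_fit_small.constraint_violation < 1e-6

    def test_fitted_rho_positive(self, spatial_fit_small):
        assert (spatial_fit_small.fitted_rho > 0).all()

    def test_significance_count_low_under_null_high_under_clustering(self, covariates):
        lat = ar.make_grid_lattice(20, 20)
        spec = ar.ModelSpec((), "linear", "spatial")
        null = simulate_study(lat, seed=31, spatial_sd=0.0)
        strong = simulate_study(lat, seed=31, spatial_sd=0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f0 = ar.fit(spec, null.outcomes, null.scores, lattice=lat, mcmc=mcmc(31))
            f1 = ar.fit(spec, strong.outcomes, strong.scores, lattice=lat, mcmc=mcmc(31))
        n0 = count_significant_effects(f0, "spatial", 0.90)
        n1 = count_significant_effects(f1, "spatial", 0.90)
        assert n0 <= 0.10 * 400
        assert n1 > max(3 * n0, 40)

    def test_missing_effect_requested(self, fe_fit_2000):
        with pytest.raises(ValueError, match="no 'spatial'"):
            count_significant_effects(fe_fit_2000, "spatial")


class TestErrors:
    def test_spatial_spec_requires_lattice(self, small_study, covariates):
        spec = ar.ModelSpec(covariates, "linear", "spatial")
        with pytest.raises(ValueError, match="lattice"):
            ar.fit(spec, small_study.outcomes, small_study.scores, mcmc=mcmc(1))

    def test_censored_rows_rejected(self, covariates):
        lat = ar.make_grid_lattice(8, 8)
        study = simulate_study(lat, seed=32, censor=True)
        spec = ar.ModelSpec(covariates, "linear", "none")
        with pytest.raises(ValueError, match="censored"):
            ar.fit(spec, study.outcomes, study.scores, mcmc=mcmc(1))

    def test_unknown_covariate_rejected(self, small_study):
        spec = ar.ModelSpec(("employment",), "linear", "none")
        with pytest.raises(ValueError, match="employment"):
            ar.fit(spec, small_study.outcomes, small_study.scores, mcmc=mcmc(1))


class TestDIC:
    def test_degenerate_posterior_has_zero_pd(self):
        r = DICReport(
            mean_deviance=100.0, deviance_at_posterior_mean=100.0, p_d=0.0, dic=100.0
        )
        assert r.dic == r.mean_deviance

    def test_identity_enforced(self):
        with pytest.raises(ValueError, match="identity"):
            DICReport(
                mean_deviance=100.0,
                deviance_at_posterior_mean=90.0,
                p_d=10.0,
                dic=200.0,
            )

    @pytest.mark.parametrize(
        "a,b,verdict",
        [
            (100.0, 104.0, "favours_lower"),
            (100.0, 101.5, "inconclusive"),
            (100.0, 102.5, "inconclusive_leaning"),
        ],
    )
    def test_spiegelhalter_verdicts(self, a, b, verdict):
        assert dic_verdict(a, b) == verdict

    def test_comparison_table_sorted_with_verdicts(self):
        reports = {
            "m1": DICReport(104.0, 100.0, 4.0, 108.0),
            "m2": DICReport(100.0, 98.0, 2.0, 102.0),
            "m3": DICReport(101.0, 99.5, 1.5, 102.5),
        }
        table = compare_models(reports)
        assert list(table.index) == ["m2", "m3", "m1"]
        assert table.loc["m2", "verdict_vs_best"] == "best"
        assert table.loc["m3", "verdict_vs_best"] == "inconclusive"
        assert table.loc["m1", "verdict_vs_best"] == "favours_lower"


class TestDiagnostics:
    def test_split_rhat_near_one_for_iid_chains(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((2, 2000))
        assert split_rhat(chains) == pytest.approx(1.0, abs=0.02)

    def test_split_rhat_detects_disagreeing_chains(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((2, 2000))
        chains[1] += 2.0
        assert split_rhat(chains) > 1.5

    def test_ess_close_to_n_for_iid_draws(self):
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((2, 4000))
        ess = effective_sample_size(chains)
        assert 0.5 * 8000 <= ess <= 1.5 * 8000

    def test_ess_small_for_sticky_chain(self):
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.standard_normal((2, 2000)), axis=1) * 0.05
        assert effective_sample_size(x) < 400


@pytest.fixture(scope="module")
def curved_study():
    lat = ar.make_grid_lattice(18, 18)
    effects = {"rurality": ar.EffectShape("inverted_u", mode=0.0, curvature=0.3)}
    return simulate_study(
        lat, seed=33, effects=effects, spatial_sd=0.0, rate_per_100k=190.0
    )


class TestNonlinearForms:
    @pytest.mark.parametrize("form", ["cubic_spline", "rw1_smooth"])
    def test_smooth_fits_recover_inverted_u(self, curved_study, form):
        spec = ar.ModelSpec(("rurality",), form, "none")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fr = ar.fit(
                spec, curved_study.outcomes, curved_study.scores,
                mcmc=mcmc(34, n_rw1_bins=40),
            )
        curve = fr.effect_curves["rurality"]
        grid = np.linspace(-1.5, 1.5, 7)
        vals = curve(grid)
        # concave: mid-range above both ends
        assert vals[3] > vals[0] + 0.2
        assert vals[3] > vals[-1] + 0.2
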