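import numpy as np
import pytest
import statsmodels.api as sm

import arealrisk as ar
from arealrisk.synthetic_data import (
    EffectShape,
    OutcomeTable,
    indirect_expected_counts,
    morans_i,
    read_outcomes,
    read_truth,
    simulate_icar_field,
    simulate_outcomes,
    simulate_study,
    write_outcomes,
    write_truth,
)
from conftest import linear_effects, SUICIDE_BETAS


class TestExpectedCounts:
    def test_single_band_suicide_scale(self):
        # 10.1 per 100,000 per year over 5 years on 7,600 residents
        e = indirect_expected_counts(
            np.array([10.1e-5 * 5]), np.full((10, 1), 7600.0)
        )
        np.testing.assert_allclose(e, 3.838)

    def test_only_positive_band_matters(self):
        rng = np.random.default_rng(0)
        pops = rng.uniform(100, 1000, size=(20, 3))
        rates = np.array([2e-4, 0.0, 0.0])
        e = indirect_expected_counts(rates, pops)
        np.testing.assert_allclose(e, pops[:, 0] * 2e-4)

    def test_uniform_populations_give_equal_expecteds(self):
        rates = np.array([1e-4, 5e-4, 2e-4])
        pops = np.tile([1000.0, 2000.0, 1500.0], (7, 1))
        e = indirect_expected_counts(rates, pops)
        assert np.ptp(e) == 0

    def test_all_zero_rates_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            indirect_expected_counts(np.zeros(2), np.ones((5, 2)))


class TestIcarField:
    def test_zero_sd_gives_zero_field(self):
        lat = ar.make_grid_lattice(5, 5)
        assert not simulate_icar_field(lat, 0.0, seed=0).any()

    def test_sum_to_zero_and_scale(self):
        lat = ar.make_grid_lattice(15, 15)
        s = simulate_icar_field(lat, 0.3, seed=1)
        assert abs(s.sum()) < 1e-8
        assert s.std() == pytest.approx(0.3, abs=1e-12)

    def test_spatial_clustering(self):
        lat = ar.make_grid_lattice(20, 20)
        s = simulate_icar_field(lat, 0.3, seed=2)
        assert morans_i(s, lat) > 0.2


class TestOutcomes:
    def test_null_model_mean_ratio_near_one(self):
        lat = ar.make_grid_lattice(70, 72)
        study = simulate_study(lat, seed=3, spatial_sd=0.0)
        ratio = (study.outcomes.observed / study.expected).mean()
        assert 0.95 <= ratio <= 1.05

    def test_overall_smr_near_100_under_null(self):
        lat = ar.make_grid_lattice(70, 72)
        study = simulate_study(lat, seed=4, spatial_sd=0.0)
        smr = 100 * study.outcomes.observed.sum() / study.expected.sum()
        assert smr == pytest.approx(100, abs=3)

    def test_log_rate_gradient_matches_generating_slope(self):
        # persons-suicide generating coefficients; the fitted Poisson
        # gradient on deprivation should recover 0.157
        lat = ar.make_grid_lattice(70, 72)
        study = simulate_study(lat, seed=5, effects=linear_effects(), spatial_sd=0.0)
        X = sm.add_constant(
            np.column_stack([study.scores[k].score for k in SUICIDE_BETAS])
        )
        glm = sm.GLM(
            study.outcomes.observed,
            X,
            family=sm.families.Poisson(),
            offset=np.log(study.expected),
        ).fit()
        assert glm.params[1] == pytest.approx(0.157, abs=0.03)

    def test_censoring_flags_follow_disclosure_rule(self):
        lat = ar.make_grid_lattice(12, 12)
        study = simulate_study(lat, seed=6, censor=True)
        y, c = study.outcomes.observed, study.outcomes.censored
        assert np.array_equal(c, y <= 5)

    def test_rho_is_exp_of_linear_predictor(self):
        lat = ar.make_grid_lattice(10, 10)
        study = simulate_study(lat, seed=7, effects=linear_effects(), spatial_sd=0.2)
        lin = study.truth.alpha + study.truth.s + study.truth.h
        for k, e in study.truth.effects.items():
            lin = lin + e(study.scores[k].score)
        np.testing.assert_allclose(study.truth.rho, np.exp(lin), rtol=1e-12)

    def test_inverted_u_truth_gives_unimodal_interior_shr_profile(self):
        lat = ar.make_grid_lattice(50, 50)
        effects = {"rurality": EffectShape("inverted_u", mode=0.0, curvature=0.3)}
        study = simulate_study(
            lat, seed=8, effects=effects, spatial_sd=0.0, rate_per_100k=190.0
        )
        prof = ar.shr_by_score_categories(
            study.outcomes.observed, study.expected, study.scores["rurality"]
        )
        shr = prof["shr"]
        mode_cat = shr.idxmax()
        assert 3 <= mode_cat <= 18  # interior mode
        # both tails sit well below the peak
        assert shr.loc[1] < shr.max() - 20
        assert shr.loc[20] < shr.max() - 20

    def test_heterogeneity_creates_detectable_overdispersion(self):
        lat = ar.make_grid_lattice(40, 50)
        null = simulate_study(lat, seed=9, spatial_sd=0.0, het_sd=0.0)
        over = simulate_study(lat, seed=9, spatial_sd=0.0, het_sd=0.5)

        def dispersion_z(study):
            y, e = study.outcomes.observed, study.expected
            stat = float(((y - e) ** 2 / e).sum())
            return (stat - y.size) / np.sqrt(2 * y.size)

        assert dispersion_z(null) < 3
        assert dispersion_z(over) > 3

    def test_non_finite_predictor_rejected(self):
        lat = ar.make_grid_lattice(3, 3)
        study = simulate_study(lat, seed=10)
        bad = ar.SimulationTruth(
            alpha=np.inf,
            effects={},
            spatial_sd=0.0,
            het_sd=0.0,
            s=np.zeros(9),
            h=np.zeros(9),
        )
        with pytest.raises(ValueError, match="finite"):
            simulate_outcomes(lat, study.scores, bad, study.expected, seed=0)


class TestIO:
    def test_outcome_table_round_trip(self, tmp_path):
        lat = ar.make_grid_lattice(6, 6)
        study = simulate_study(lat, seed=11, censor=True)
        path = tmp_path / "outcomes.tsv"
        write_outcomes(study.outcomes, path)
        back = read_outcomes(path)
        np.testing.assert_array_equal(back.observed, study.outcomes.observed)
        np.testing.assert_allclose(back.expected, study.outcomes.expected)
        np.testing.assert_array_equal(back.censored, study.outcomes.censored)

    def test_truth_round_trip(self, tmp_path):
        lat = ar.make_grid_lattice(5, 5)
        study = simulate_study(lat, seed=12, effects=linear_effects(), spatial_sd=0.1)
        path = tmp_path / "truth.json"
        write_truth(study.truth, path)
        back = read_truth(path)
        np.testing.assert_allclose(back.s, study.truth.s)
        np.testing.assert_allclose(back.rho, study.truth.rho)
        assert back.effects["deprivation"].beta == 0.157

    def test_censored_flags_on_large_counts_rejected(self):
        with pytest.raises(ValueError, match="censor"):
            OutcomeTable(
                np.array([10, 2]), np.array([5.0, 5.0]), np.array([True, False])
            )
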