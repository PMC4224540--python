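"""Interval construction and the cloglog mortality model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import growmort as gm
from growmort import build_intervals, cloglog_eta, cloglog_prob, fit_mortality_glmm
from growmort.pipeline import attach_averaged_canopy


def _census(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "individual_id", "species_id", "census_day",
            "diameter_mm", "canopy_openness_pct", "alive",
        ],
    )


class TestCloglogLink:
    def test_annual_rate_inversion_example(self):
        # the highest species annual mortality corresponds to eta ~ -1.605
        assert cloglog_eta(0.182) == pytest.approx(np.log(-np.log(1 - 0.182)))
        assert cloglog_eta(0.182) == pytest.approx(-1.605, abs=0.001)

    def test_limits(self):
        assert cloglog_prob(-1e6) == pytest.approx(0.0)
        assert cloglog_prob(1e6) == pytest.approx(1.0)

    def test_proportional_hazard_doubling_time(self):
        eta = cloglog_eta(0.1, 1.0)
        assert cloglog_prob(eta, 2.0) == pytest.approx(1 - 0.9**2, rel=1e-12)

    @given(st.floats(1e-8, 1 - 1e-8))
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_identity(self, p):
        assert cloglog_prob(cloglog_eta(p)) == pytest.approx(p, abs=1e-12)

    @given(
        eta=st.floats(-6.0, 1.0),
        dt1=st.floats(0.05, 4.0),
        dt2=st.floats(0.05, 4.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_interval_splitting_consistency(self, eta, dt1, dt2):
        # survival composes multiplicatively under the log-time offset
        p12 = cloglog_prob(eta, dt1 + dt2)
        p1, p2 = cloglog_prob(eta, dt1), cloglog_prob(eta, dt2)
        assert p12 == pytest.approx(1 - (1 - p1) * (1 - p2), rel=1e-9, abs=1e-12)


class TestBuildIntervals:
    def test_counting_with_one_death(self):
        rows = []
        for ind, dies in (("a", False), ("b", False), ("c", True)):
            rows.append((ind, "sp1", 0, 4.0, 5.0, 1))
            rows.append((ind, "sp1", 365, 5.0, 5.0, 1))
            dead = dies
            rows.append((ind, "sp1", 730, np.nan if dead else 6.0, 5.0, 0 if dead else 1))
        iv = build_intervals(_census(rows))
        assert len(iv) == 6
        assert iv["died"].sum() == 1
        # the death is recorded on the second interval of individual c
        assert iv.query("individual_id == 'c'")["died"].tolist() == [0, 1]

    def test_dead_at_first_census_contributes_nothing(self):
        iv = build_intervals(_census([("a", "sp1", 0, np.nan, 5.0, 0)]))
        assert len(iv) == 0

    def test_census_gap_to_years(self):
        rows = [
            ("a", "sp1", 0, 4.0, 5.0, 1),
            ("a", "sp1", 576, 5.0, 5.0, 1),
            ("a", "sp1", 815, 6.0, 5.0, 1),
        ]
        iv = build_intervals(_census(rows))
        np.testing.assert_allclose(
            iv["delta_t_years"], [576 / 365, 239 / 365], rtol=1e-12
        )

    def test_resurrection_rejected(self):
        rows = [
            ("a", "sp1", 0, 4.0, 5.0, 1),
            ("a", "sp1", 365, np.nan, 5.0, 0),
            ("a", "sp1", 730, 6.0, 5.0, 1),
        ]
        with pytest.raises(ValueError, match="alive after death"):
            build_intervals(_census(rows))

    def test_initial_diameter_is_first_recorded(self):
        rows = [
            ("a", "sp1", 0, 4.2, 5.0, 1),
            ("a", "sp1", 365, 5.5, 5.0, 1),
        ]
        iv = build_intervals(_census(rows))
        assert (iv["initial_diameter_mm"] == 4.2).all()


@pytest.fixture(scope="module")
def sim_intervals():
    cfg = gm.SimConfig(seed=11)
    census, _, truth = gm.generate_population(cfg)
    iv = attach_averaged_canopy(census, build_intervals(census))
    return census, iv, truth


class TestGlmmFit:
    def test_degenerate_matches_statsmodels_glm(self):
        # no random effects, single species: an ordinary cloglog GLM
        import statsmodels.api as sm

        cfg = gm.SimConfig(
            n_species=1,
            n_individuals_per_species=800,
            species_mort_annual=[0.12],
            seed=21,
        )
        census, _, _ = gm.generate_population(cfg)
        iv = attach_averaged_canopy(census, build_intervals(census))
        fit = fit_mortality_glmm(iv, random_effects=False)

        use = iv.dropna(subset=["canopy_openness_pct", "initial_diameter_mm"])
        X = np.column_stack(
            [
                np.ones(len(use)),
                use["canopy_openness_pct"],
                use["initial_diameter_mm"],
            ]
        )
        ref = sm.GLM(
            use["died"].to_numpy(),
            X,
            family=sm.families.Binomial(link=sm.families.links.CLogLog()),
            offset=np.log(use["delta_t_years"].to_numpy()),
        ).fit()
        got = np.array(
            [fit.species_intercepts[0], fit.light_slope, fit.size_slope]
        )
        np.testing.assert_allclose(got, ref.params, rtol=1e-5, atol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)

    def test_recovers_species_rates_and_light_slope(self, sim_intervals):
        census, iv, truth = sim_intervals
        fit = fit_mortality_glmm(iv)
        assert fit.converged
        # light slope: right sign and magnitude
        assert fit.light_slope < 0
        assert fit.light_slope == pytest.approx(-0.11, abs=0.06)
        # species annual probabilities at reference covariates
        est = np.array(
            [gm.annual_mortality(fit, s, 4.5, 4.12) for s in fit.species_ids]
        )
        true_p = truth.species["annual_mortality"].to_numpy()
        assert np.corrcoef(est, true_p)[0, 1] > 0.5
        assert np.abs(est - true_p).mean() < 0.05

    def test_annual_mortality_monotone_in_light(self, sim_intervals):
        _, iv, _ = sim_intervals
        fit = fit_mortality_glmm(iv)
        sp = fit.species_ids[0]
        lights = np.linspace(0.5, 26, 12)
        p = np.array([gm.annual_mortality(fit, sp, L, 4.12) for L in lights])
        assert (np.diff(p) < 0).all()

    def test_species_ranking_invariant_to_light_without_interaction(
        self, sim_intervals
    ):
        _, iv, _ = sim_intervals
        fit = fit_mortality_glmm(iv)
        orders = []
        for L in (1.0, 4.5, 20.0):
            p = [gm.annual_mortality(fit, s, L, 4.12) for s in fit.species_ids]
            orders.append(np.argsort(p).tolist())
        assert all(o == orders[0] for o in orders)

    def test_unknown_species_rejected(self, sim_intervals):
        _, iv, _ = sim_intervals
        fit = fit_mortality_glmm(iv)
        with pytest.raises(KeyError):
            gm.annual_mortality(fit, "nonexistent", 4.5, 4.12)

    def test_zero_death_species_warns(self):
        cfg = gm.SimConfig(
            n_species=3,
            n_individuals_per_species=40,
            species_mort_annual=[0.2, 0.2, 0.0001],
            mort_species_cloglog_sd=0.0,
            seed=30,
        )
        census, _, _ = gm.generate_population(cfg)
        iv = attach_averaged_canopy(census, build_intervals(census))
        # deterministic draw: the near-immortal species records no deaths
        assert iv.groupby("species_id")["died"].sum().min() == 0
        with pytest.warns(RuntimeWarning, match="complete separation"):
            fit = fit_mortality_glmm(iv)
        assert fit.messages
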