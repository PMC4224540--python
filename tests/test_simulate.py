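"""Synthetic census generator: determinism, exactness, hazard calibration."""

import numpy as np
import pandas as pd
import pytest

import growmort as gm
from growmort import SimConfig, generate_population


def small_config(**kw):
    base = dict(n_species=4, n_individuals_per_species=10, seed=5)
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        c1, t1, _ = generate_population(small_config())
        c2, t2, _ = generate_population(small_config())
        assert c1.to_csv(index=False) == c2.to_csv(index=False)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_different_seed_differs(self):
        c1, _, _ = generate_population(small_config(seed=5))
        c2, _, _ = generate_population(small_config(seed=6))
        assert c1.to_csv(index=False) != c2.to_csv(index=False)


class TestNoiseFreeDegenerate:
    def test_trajectories_follow_analytic_solution_exactly(self):
        cfg = small_config(
            residual_sd_range=(0.0, 0.0),
            individual_re_sd=(0.0, 0.0, 0.0),
            mort_species_cloglog_mean=-30.0,
            mort_species_cloglog_sd=0.0,
            mort_light_slope=0.0,
            mort_size_slope=0.0,
        )
        census, _, truth = generate_population(cfg)
        assert (census["alive"] == 1).all()
        ind = truth.individuals.set_index("individual_id")
        for iid, g in census.groupby("individual_id"):
            row = ind.loc[iid]
            expected = gm.predict_size(
                row["m0"], row["alpha"], row["beta"], g["census_day"].to_numpy()
            )
            np.testing.assert_allclose(
                g["diameter_mm"].to_numpy(), expected, rtol=1e-12
            )

    def test_no_deaths_when_hazard_off(self):
        cfg = small_config(mort_species_cloglog_mean=-30.0, mort_species_cloglog_sd=0.0)
        census, _, _ = generate_population(cfg)
        assert (census["alive"] == 1).all()


class TestMortalityCalibration:
    def test_annual_death_fraction_matches_binomial_oracle(self):
        # one species, annual mortality 0.10, exactly 1-year interval
        cfg = SimConfig(
            n_species=1,
            n_individuals_per_species=10_000,
            census_days=(365, 730),
            species_mort_annual=[0.1],
            mort_species_cloglog_sd=0.0,
            mort_light_slope=0.0,
            mort_size_slope=0.0,
            seed=2,
        )
        census, _, _ = generate_population(cfg)
        died = (census["alive"] == 0).sum()
        frac = died / 10_000
        assert frac == pytest.approx(0.10, abs=0.01)

    def test_interval_death_rate_matches_cloglog_at_any_gap(self):
        # death probability over an irregular gap must follow the cloglog
        # hazard scaled by interval length (3 binomial SEs at n = 10^4)
        n = 10_000
        cfg = SimConfig(
            n_species=1,
            n_individuals_per_species=n,
            census_days=(576, 815),
            species_mort_annual=[0.12],
            mort_species_cloglog_sd=0.0,
            mort_light_slope=0.0,
            mort_size_slope=0.0,
            seed=9,
        )
        census, _, truth = generate_population(cfg)
        dt = (815 - 576) / 365.0
        eta = truth.species["mort_eta"].iloc[0]
        p = gm.cloglog_prob(eta, dt)
        frac = (census["alive"] == 0).sum() / n
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se

    def test_no_observations_after_death(self):
        census, _, _ = generate_population(small_config(seed=3))
        for _, g in census.groupby("individual_id"):
            alive = g.sort_values("census_day")["alive"].to_numpy()
            if (alive == 0).any():
                # exactly one dead record and it is the last row
                assert alive[-1] == 0
                assert (alive[:-1] == 1).all()


class TestStructure:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(census_days=(815, 576))
        with pytest.raises(ValueError):
            SimConfig(openness_range=(0.0, 26.0))
        with pytest.raises(ValueError):
            SimConfig(true_beta=1.2)
        with pytest.raises(ValueError):
            SimConfig(tradeoff_corr=1.5)

    def test_one_species_per_individual_and_openness_bounds(self):
        census, _, _ = generate_population(small_config())
        n_sp = census.groupby("individual_id")["species_id"].nunique()
        assert (n_sp == 1).all()
        assert census["canopy_openness_pct"].between(0, 100).all()
        assert (census.dropna(subset=["diameter_mm"])["diameter_mm"] > 0).all()

    def test_mean_trajectories_span_reported_extremes(self):
        # slowest/fastest simulated species bracket the deterministic curves
        # of the slowest and fastest reported growth coefficients
        census, _, truth = generate_population(SimConfig(seed=1))
        final = census[census["census_day"] == 3214].dropna(subset=["diameter_mm"])
        by_sp = final.groupby("species_id")["diameter_mm"].mean()
        slow = gm.predict_size(4.12, 0.000427, 0.86, 3214.0)
        fast = gm.predict_size(4.12, 0.000908, 0.86, 3214.0)
        assert by_sp.min() < fast and by_sp.max() > slow


class TestTraitLinks:
    def test_wood_density_correlation_targets_at_many_species(self):
        cfg = SimConfig(n_species=200, n_individuals_per_species=2, seed=12)
        _, traits, truth = generate_population(cfg)
        merged = traits.merge(truth.species, on="species_id")
        sgr = gm.sgr_annual(merged["alpha"].to_numpy(), 0.86, 10.0)
        r_wd_sgr = np.corrcoef(merged["wood_density"], sgr)[0, 1]
        assert r_wd_sgr == pytest.approx(-0.74, abs=0.05)
        r_gm = np.corrcoef(merged["log_alpha"], merged["mort_eta"])[0, 1]
        assert r_gm == pytest.approx(0.54, abs=0.12)

    def test_other_traits_independent_of_demography(self):
        cfg = SimConfig(n_species=200, n_individuals_per_species=2, seed=12)
        _, traits, truth = generate_population(cfg)
        merged = traits.merge(truth.species, on="species_id")
        for col in ("sla", "seed_mass", "leaf_cn"):
            r = np.corrcoef(merged[col], merged["log_alpha"])[0, 1]
            assert abs(r) < 0.2

    def test_zero_loading_gives_near_zero_correlation(self):
        cfg = SimConfig(
            n_species=200,
            n_individuals_per_species=2,
            wd_growth_corr=0.0,
            wd_mort_corr=0.0,
            seed=4,
        )
        _, traits, truth = generate_population(cfg)
        merged = traits.merge(truth.species, on="species_id")
        assert abs(np.corrcoef(merged["wood_density"], merged["log_alpha"])[0, 1]) < 0.2

    def test_perfect_loading_is_deterministic_linear_map(self):
        cfg = SimConfig(
            n_species=50,
            n_individuals_per_species=2,
            wd_growth_corr=-1.0,
            wd_mort_corr=-0.54,  # must equal -tradeoff_corr for a PSD target
            tradeoff_corr=0.54,
            seed=8,
        )
        _, traits, truth = generate_population(cfg)
        merged = traits.merge(truth.species, on="species_id")
        r = np.corrcoef(merged["wood_density"], merged["log_alpha"])[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-9)
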