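"""Correlation matrix, SMA regression and the trade-off summary."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from growmort import correlation_matrix, sma_fit, tradeoff_summary


def exact_corr_pair(r, n, seed=0):
    """Two vectors whose sample Pearson correlation is exactly r."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= x * (x @ z) / (x @ x)  # orthogonalize
    z /= z.std()
    y = r * x + np.sqrt(1 - r**2) * z
    return x, y


class TestCorrelationMatrix:
    def test_identity_line(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5]})
        df["y"] = df["x"]
        r, p, n = correlation_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert p.loc["x", "y"] < 1e-6

    @pytest.mark.parametrize(
        "r_target, n, p_expected, thresh",
        [
            # growth-mortality correlation strength at 15 species: p just
            # under the 0.05 line (one-asterisk significance)
            (0.54, 15, 0.0376, 0.05),
            # wood-density vs SGR strength: p well under 0.01 (two asterisks)
            (-0.74, 15, 0.0016, 0.01),
        ],
    )
    def test_p_values_match_t_distribution_oracle(self, r_target, n, p_expected, thresh):
        x, y = exact_corr_pair(r_target, n, seed=3)
        df = pd.DataFrame({"x": x, "y": y})
        r, p, _ = correlation_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(r_target, abs=1e-12)
        # independent oracle: two-sided t test with n-2 df
        t = r_target * np.sqrt(n - 2) / np.sqrt(1 - r_target**2)
        p_oracle = 2 * stats.t.sf(abs(t), n - 2)
        assert p.loc["x", "y"] == pytest.approx(p_oracle, rel=1e-9)
        assert p.loc["x", "y"] == pytest.approx(p_expected, abs=5e-4)
        assert p.loc["x", "y"] < thresh

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.standard_normal((12, 4)), columns=list("abcd"))
        r, p, n = correlation_matrix(df)
        np.testing.assert_allclose(r.values, r.values.T)
        np.testing.assert_allclose(np.diag(r.values), 1.0)
        assert ((r.values >= -1) & (r.values <= 1)).all()

    def test_pairwise_complete_cases_warn(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.standard_normal((12, 3)), columns=list("abc"))
        df.loc[0, "a"] = np.nan
        with pytest.warns(RuntimeWarning, match="pairwise-complete"):
            r, p, n = correlation_matrix(df)
        assert n.loc["a", "b"] == 11
        assert n.loc["b", "c"] == 12

    def test_zero_variance_flagged(self):
        df = pd.DataFrame({"a": [1.0, 1, 1, 1], "b": [1.0, 2, 3, 4]})
        with pytest.warns(RuntimeWarning, match="undefined"):
            r, _, _ = correlation_matrix(df)
        assert np.isnan(r.loc["a", "b"])

    def test_holm_adjustment_is_monotone(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.standard_normal((10, 4)), columns=list("abcd"))
        _, p_raw, _ = correlation_matrix(df)
        _, p_adj, _ = correlation_matrix(df, holm=True)
        off = ~np.eye(4, dtype=bool)
        assert (p_adj.values[off] >= p_raw.values[off] - 1e-15).all()


class TestSMA:
    def test_exact_line(self):
        x = np.array([0.0, 1, 2, 3])
        fit = sma_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_closed_form_example(self):
        # var x = 5/3, var y = 35/12, cov = 11/6 computed by hand
        fit = sma_fit([1, 2, 3, 4], [1, 3, 2, 5])
        assert fit.slope == pytest.approx(np.sqrt(1.75), abs=1e-4)
        assert fit.slope == pytest.approx(1.3229, abs=1e-4)
        assert fit.intercept == pytest.approx(-0.5572, abs=1e-4)
        assert fit.r == pytest.approx(0.8315, abs=1e-4)

    def test_axis_swap_symmetry_and_centroid(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 20)
        y = 0.4 * x + rng.standard_normal(20)
        f_xy = sma_fit(x, y)
        f_yx = sma_fit(y, x)
        assert f_xy.slope * f_yx.slope == pytest.approx(1.0, rel=1e-12)
        # line passes through the centroid exactly
        assert f_xy.predict(x.mean()) == pytest.approx(y.mean(), rel=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 5, 15)
        y = x + rng.standard_normal(15)
        base = sma_fit(x, y)
        scaled = sma_fit(x, 10.0 * y)
        assert scaled.slope == pytest.approx(10.0 * base.slope, rel=1e-12)

    def test_r_squared_bit_consistent_with_correlation_matrix(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {"x": rng.uniform(0, 1, 15), "y": rng.uniform(0, 1, 15)}
        )
        r, _, _ = correlation_matrix(df)
        fit = sma_fit(df["x"], df["y"])
        assert fit.r_squared == r.loc["x", "y"] ** 2  # identical bits

    def test_sign_convention_and_ci(self):
        x, y = np.array([1.0, 2, 3, 4, 5]), np.array([5.0, 4, 3.5, 2, 1])
        fit = sma_fit(x, y)
        assert fit.slope < 0 and fit.r < 0
        assert fit.slope_ci[0] < fit.slope < fit.slope_ci[1]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            sma_fit([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            sma_fit([1, 2], [1, 2])


class TestTradeoffSummary:
    def test_slope_to_percentage_points(self):
        # an SMA slope of 0.433 on the mortality-vs-SGR plane means a
        # +0.1 yr^-1 SGR increase maps to +4.3 percentage points mortality
        sgr = np.array([0.10, 0.15, 0.20, 0.25, 0.30])
        demog = pd.DataFrame(
            {"species_id": list("abcde"), "sgr_annual": sgr,
             "annual_mortality": 0.433 * sgr}
        )
        out = tradeoff_summary(demog)
        assert out.sma.slope == pytest.approx(0.433, rel=1e-12)
        assert out.mortality_pp_per_0p1_sgr == pytest.approx(4.33, rel=1e-12)
        assert round(out.mortality_pp_per_0p1_sgr, 1) == 4.3

    def test_null_demography_not_significant(self):
        rng = np.random.default_rng(15)
        demog = pd.DataFrame(
            {
                "species_id": [f"s{i}" for i in range(200)],
                "sgr_annual": rng.uniform(0.1, 0.4, 200),
                "annual_mortality": rng.uniform(0.05, 0.2, 200),
            }
        )
        out = tradeoff_summary(demog)
        assert out.sma.p_value > 0.05

    def test_too_few_species_rejected(self):
        demog = pd.DataFrame(
            {"species_id": ["a", "b"], "sgr_annual": [0.1, 0.2],
             "annual_mortality": [0.05, 0.1]}
        )
        with pytest.raises(ValueError):
            tradeoff_summary(demog)
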