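"""Interval-censored mortality: cloglog GLMM with a log-time offset.

A census records survival only at irregular visits, so a death is known only
to have occurred somewhere inside a census interval.  With a constant hazard
h within an interval of length dt years, the death probability is

    p = 1 - exp(-h * dt) = 1 - exp(-exp(eta + log dt)),

i.e. a binomial model with complementary log-log link and offset log(dt):
coefficients are then on an annual hazard scale regardless of how uneven the
census gaps are, and probabilities compose coherently across sub-intervals
(1 - p_12 = (1 - p_1)(1 - p_2)).

The mixed model adds normally distributed random intercepts for individual
and for census occasion (crossed), species fixed intercepts, and fixed
slopes for canopy openness (per %) and initial diameter (per mm).  It is fit
by maximizing a Laplace approximation to the marginal likelihood; the inner
mode over the random effects is found by Fisher scoring, exploiting the fact
that both random-intercept blocks of the penalized information matrix are
diagonal (a small Schur complement handles the crossing).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .growth import DAYS_PER_YEAR

__all__ = [
    "cloglog_prob",
    "cloglog_eta",
    "build_intervals",
    "fit_mortality_glmm",
    "annual_mortality",
    "MortalityFit",
]

logger = logging.getLogger(__name__)

_ETA_CLIP = 30.0


def cloglog_prob(eta, delta_t=1.0):
    """Death probability over ``delta_t`` years at cloglog-scale hazard eta.

    p = 1 - exp(-exp(eta + log delta_t)); numerically guarded so eta -> -inf
    gives 0 and large eta gives 1 without overflow.
    """
    delta_t = np.asarray(delta_t, dtype=float)
    if np.any(delta_t <= 0):
        raise ValueError("delta_t must be > 0")
    x = np.clip(np.asarray(eta, dtype=float) + np.log(delta_t), -_ETA_CLIP, _ETA_CLIP)
    out = -np.expm1(-np.exp(x))
    return out[()] if np.ndim(out) == 0 else out


def cloglog_eta(p, delta_t=1.0):
    """Inverse of :func:`cloglog_prob`: eta = log(-log(1-p)) - log(delta_t)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly in (0, 1)")
    out = np.log(-np.log1p(-p)) - np.log(np.asarray(delta_t, dtype=float))
    return out[()] if np.ndim(out) == 0 else out


def build_intervals(census: pd.DataFrame) -> pd.DataFrame:
    """Explode a census table into per-individual survival intervals.

    One record per consecutive census pair during which the individual was
    alive at the start; ``died`` = 1 iff it was recorded dead at the end.
    ``delta_t_years`` is the day gap / 365.  ``census_index`` is the global
    rank of the interval-end census day (shared across individuals), used
    for the census-occasion random intercept.  ``initial_diameter_mm`` is
    the first recorded diameter of the individual.

    Individuals observed at a single census contribute no intervals (their
    count is logged); a dead-then-alive sequence raises.
    """
    required = {"individual_id", "species_id", "census_day", "alive"}
    missing = required - set(census.columns)
    if missing:
        raise ValueError(f"census table lacks columns: {sorted(missing)}")

    day_rank = {d: i for i, d in enumerate(np.sort(census["census_day"].unique()))}
    rows = []
    n_single = 0
    for ind, g in census.groupby("individual_id", sort=True):
        g = g.sort_values("census_day")
        alive = g["alive"].to_numpy()
        if np.any(np.diff(alive) > 0):
            raise ValueError(f"individual {ind} recorded alive after death")
        if len(g) < 2:
            n_single += 1
            continue
        days = g["census_day"].to_numpy(dtype=float)
        diam = g["diameter_mm"].to_numpy(dtype=float) if "diameter_mm" in g else None
        init = np.nan
        if diam is not None:
            valid = diam[np.isfinite(diam)]
            if valid.size:
                init = float(valid[0])
        openness = (
            g["canopy_openness_pct"].to_numpy(dtype=float)
            if "canopy_openness_pct" in g
            else np.full(len(g), np.nan)
        )
        spid = g["species_id"].iloc[0]
        for j in range(len(g) - 1):
            if alive[j] == 0:
                break
            rows.append(
                (
                    ind,
                    spid,
                    days[j],
                    days[j + 1],
                    (days[j + 1] - days[j]) / DAYS_PER_YEAR,
                    int(alive[j + 1] == 0),
                    openness[j],
                    init,
                    day_rank[days[j + 1]],
                )
            )
    if n_single:
        logger.info("build_intervals: %d single-census individuals skipped", n_single)
    return pd.DataFrame(
        rows,
        columns=[
            "individual_id",
            "species_id",
            "interval_start",
            "interval_end",
            "delta_t_years",
            "died",
            "canopy_openness_pct",
            "initial_diameter_mm",
            "census_index",
        ],
    )


@dataclass
class MortalityFit:
    """Fitted interval-censored cloglog mixed model."""

    species_ids: list
    species_intercepts: np.ndarray  # cloglog scale, annual
    light_slope: float  # per % canopy openness (or per log-% if light_log)
    size_slope: float  # per mm initial diameter
    light_slope_by_species: np.ndarray | None  # interaction model only
    sd_individual: float
    sd_census: float
    loglik: float
    n_obs: int
    n_params: int
    bic: float
    vcov: np.ndarray  # fixed effects, approximate (outer-Hessian based)
    converged: bool
    light_log: bool = False
    messages: list = field(default_factory=list)

    def eta(self, species, light, size):
        try:
            j = self.species_ids.index(species)
        except ValueError:
            raise KeyError(f"species {species!r} not in fitted model") from None
        x_light = np.log(light) if self.light_log else light
        slope = self.light_slope
        if self.light_slope_by_species is not None:
            slope = self.light_slope_by_species[j]
        return self.species_intercepts[j] + slope * x_light + self.size_slope * size


def annual_mortality(fit: MortalityFit, species, light, size):
    """Population-level annual death probability at given covariates.

    Random effects are set to zero, delta_t = 1 year (the Fig-2-style
    prediction scale).
    """
    return cloglog_prob(fit.eta(species, light, size), 1.0)


# ---------------------------------------------------------------------------
# estimation machinery


def _bernoulli_parts(eta_off, y):
    """Log-likelihood, score and Fisher weight per observation, on the eta scale."""
    x = np.clip(eta_off, -_ETA_CLIP, _ETA_CLIP)
    lam = np.exp(x)
    log1mp = -lam  # log(1 - p)
    p = np.clip(-np.expm1(-lam), 1e-12, 1.0 - 1e-12)
    ll = np.where(y == 1, np.log(p), log1mp)
    dp = lam * np.exp(-lam)  # dp/deta
    score = np.where(y == 1, dp / p, -lam)
    w = dp * dp / (p * (1.0 - p))  # expected information
    return ll, score, np.maximum(w, 1e-12)


def _irls_cloglog(X, y, offset, maxiter=50, tol=1e-10, ridge=1e-8):
    """Fixed-effects cloglog GLM by Fisher scoring (for starting values)."""
    beta = np.zeros(X.shape[1])
    eta = X @ beta + offset
    ll_old = -np.inf
    for _ in range(maxiter):
        ll, score, w = _bernoulli_parts(eta, y)
        ll_tot = ll.sum()
        g = X.T @ score
        H = (X * w[:, None]).T @ X + ridge * np.eye(X.shape[1])
        step = np.linalg.solve(H, g)
        # step-halving
        for _ in range(30):
            cand = beta + step
            eta_c = X @ cand + offset
            ll_c = _bernoulli_parts(eta_c, y)[0].sum()
            if ll_c >= ll_tot - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        eta = X @ beta + offset
        if abs(ll_c - ll_old) < tol * (abs(ll_c) + 1):
            break
        ll_old = ll_c
    return beta


class _LaplaceCloglog:
    """Laplace-approximated marginal likelihood for crossed random intercepts."""

    def __init__(self, X, y, offset, ind_idx, cen_idx, n_ind, n_cen):
        self.X, self.y, self.offset = X, y, offset
        self.ind_idx, self.cen_idx = ind_idx, cen_idx
        self.n_ind, self.n_cen = n_ind, n_cen
        self.b = np.zeros(n_ind)
        self.c = np.zeros(n_cen)

    def _eta(self, beta):
        return (
            self.X @ beta + self.offset + self.b[self.ind_idx] + self.c[self.cen_idx]
        )

    def _inner_objective(self, beta, vb, vc):
        ll = _bernoulli_parts(self._eta(beta), self.y)[0].sum()
        return ll - 0.5 * (self.b @ self.b) / vb - 0.5 * (self.c @ self.c) / vc

    def _solve_mode(self, beta, vb, vc, maxiter=60, tol=1e-9):
        """Fisher scoring for the joint (b, c) mode; both blocks diagonal."""
        obj = self._inner_objective(beta, vb, vc)
        for _ in range(maxiter):
            eta = self._eta(beta)
            _, score, w = _bernoulli_parts(eta, self.y)
            gb = np.bincount(self.ind_idx, score, self.n_ind) - self.b / vb
            gc = np.bincount(self.cen_idx, score, self.n_cen) - self.c / vc
            Hbb = np.bincount(self.ind_idx, w, self.n_ind) + 1.0 / vb
            Hcc = np.bincount(self.cen_idx, w, self.n_cen) + 1.0 / vc
            # cross block: sum of w per (individual, census) cell
            flat = self.ind_idx * self.n_cen + self.cen_idx
            Hbc = np.bincount(flat, w, self.n_ind * self.n_cen).reshape(
                self.n_ind, self.n_cen
            )
            # Schur complement on the (small) census block
            inv_bb = 1.0 / Hbb
            S = np.diag(Hcc) - Hbc.T @ (Hbc * inv_bb[:, None])
            rhs_c = gc - Hbc.T @ (gb * inv_bb)
            dc = np.linalg.solve(S, rhs_c)
            db = (gb - Hbc @ dc) * inv_bb
            # step-halving on the penalized objective
            b0, c0 = self.b.copy(), self.c.copy()
            scale = 1.0
            for _ in range(30):
                self.b = b0 + scale * db
                self.c = c0 + scale * dc
                new = self._inner_objective(beta, vb, vc)
                if new >= obj - 1e-10:
                    break
                scale *= 0.5
            if new < obj:  # no improvement at all: revert
                self.b, self.c = b0, c0
                new = obj
                break
            if abs(new - obj) < tol * (abs(new) + 1.0):
                obj = new
                break
            obj = new
        return obj

    def logdet_H(self, beta, vb, vc):
        _, _, w = _bernoulli_parts(self._eta(beta), self.y)
        Hbb = np.bincount(self.ind_idx, w, self.n_ind) + 1.0 / vb
        Hcc = np.bincount(self.cen_idx, w, self.n_cen) + 1.0 / vc
        flat = self.ind_idx * self.n_cen + self.cen_idx
        Hbc = np.bincount(flat, w, self.n_ind * self.n_cen).reshape(
            self.n_ind, self.n_cen
        )
        inv_bb = 1.0 / Hbb
        S = np.diag(Hcc) - Hbc.T @ (Hbc * inv_bb[:, None])
        sign, logdet_S = np.linalg.slogdet(S)
        if sign <= 0:
            return np.inf
        return np.log(Hbb).sum() + logdet_S

    def marginal_loglik(self, beta, log_sb, log_sc):
        vb = np.exp(2.0 * log_sb)
        vc = np.exp(2.0 * log_sc)
        # restart the inner solve so the objective is a pure function of the
        # parameters (warm starts leave hysteresis noise that breaks the
        # outer quasi-Newton line search)
        self.b = np.zeros(self.n_ind)
        self.c = np.zeros(self.n_cen)
        pen = self._solve_mode(beta, vb, vc)
        logdet = self.logdet_H(beta, vb, vc)
        return (
            pen
            - 0.5 * (self.n_ind * np.log(vb) + self.n_cen * np.log(vc))
            - 0.5 * logdet
        )


def _mortality_design(
    intervals: pd.DataFrame, include_interaction: bool, light_log: bool
):
    species_ids = sorted(intervals["species_id"].unique())
    sp_map = {s: j for j, s in enumerate(species_ids)}
    sp = intervals["species_id"].map(sp_map).to_numpy()
    n_sp = len(species_ids)
    light = intervals["canopy_openness_pct"].to_numpy(dtype=float)
    if light_log:
        light = np.log(light)
    size = intervals["initial_diameter_mm"].to_numpy(dtype=float)
    n = len(intervals)
    S = np.zeros((n, n_sp))
    S[np.arange(n), sp] = 1.0
    if include_interaction:
        X = np.hstack([S, S * light[:, None], size[:, None]])
        names = (
            [f"intercept[{s}]" for s in species_ids]
            + [f"light[{s}]" for s in species_ids]
            + ["size"]
        )
    else:
        X = np.hstack([S, light[:, None], size[:, None]])
        names = [f"intercept[{s}]" for s in species_ids] + ["light", "size"]
    return X, names, species_ids, sp


def fit_mortality_glmm(
    intervals: pd.DataFrame,
    include_interaction: bool = False,
    light_log: bool = False,
    random_effects: bool = True,
    maxiter: int = 200,
) -> MortalityFit:
    """Fit the interval-censored cloglog mortality model.

    Parameters
    ----------
    intervals : DataFrame
        Output of :func:`build_intervals`; the ``canopy_openness_pct`` column
        should already hold the per-individual averaged covariate if the
        averaging rule is wanted (see pipeline).
    include_interaction : bool
        Fit species-specific light slopes instead of a common one (for the
        BIC interaction test).
    light_log : bool
        Use log openness instead of raw % (sensitivity option).
    random_effects : bool
        If False, fit the plain fixed-effects GLM (degenerate case).

    Notes
    -----
    A species with zero observed deaths has no finite maximum for its
    intercept; the optimizer's box bound then acts as a boundary estimate
    and a warning is recorded on the fit.
    """
    use = intervals.dropna(
        subset=["canopy_openness_pct", "initial_diameter_mm"]
    ).reset_index(drop=True)
    if use["species_id"].nunique() < 2:
        logger.info("fitting mortality model with a single species")
    if use["died"].sum() == 0:
        raise ValueError("no deaths in interval data; mortality model unidentified")

    X, names, species_ids, sp = _mortality_design(use, include_interaction, light_log)
    y = use["died"].to_numpy(dtype=float)
    offset = np.log(use["delta_t_years"].to_numpy(dtype=float))
    ind_codes, _ = pd.factorize(use["individual_id"], sort=True)
    cen_codes, _ = pd.factorize(use["census_index"], sort=True)
    n_ind = ind_codes.max() + 1
    n_cen = cen_codes.max() + 1
    p = X.shape[1]
    n = len(use)

    beta0 = _irls_cloglog(X, y, offset)
    messages = []
    deaths_by_species = use.groupby("species_id")["died"].sum()
    zero_death = deaths_by_species[deaths_by_species == 0].index.tolist()
    if zero_death:
        messages.append(
            f"species with zero deaths (boundary intercepts): {zero_death}"
        )
        warnings.warn(
            f"complete separation: no deaths for species {zero_death}; "
            "their intercepts are boundary estimates",
            RuntimeWarning,
            stacklevel=2,
        )

    if not random_effects:
        eta = X @ beta0 + offset
        ll, _, w = _bernoulli_parts(eta, y)
        loglik = float(ll.sum())
        H = (X * w[:, None]).T @ X
        vcov = np.linalg.pinv(H)
        k = p
        fit = _pack_fit(
            species_ids, beta0, include_interaction, light_log,
            0.0, 0.0, loglik, n, k, vcov, True, messages,
        )
        return fit

    lap = _LaplaceCloglog(X, y, offset, ind_codes, cen_codes, n_ind, n_cen)

    def negll(params):
        beta = params[:p]
        return -lap.marginal_loglik(beta, params[p], params[p + 1])

    x0 = np.concatenate([beta0, [np.log(0.3), np.log(0.3)]])
    bounds = [(-12.0, 8.0)] * p + [(-6.0, 2.0)] * 2
    res = optimize.minimize(
        negll,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
    )
    beta_hat = res.x[:p]
    sd_b, sd_c = np.exp(res.x[p]), np.exp(res.x[p + 1])
    loglik = -res.fun
    k = p + 2

    # fixed-effect vcov from the conditional expected information at the mode
    eta = X @ beta_hat + offset + lap.b[ind_codes] + lap.c[cen_codes]
    _, _, w = _bernoulli_parts(eta, y)
    vcov = np.linalg.pinv((X * w[:, None]).T @ X)

    converged = bool(res.success) or res.status == 1  # maxiter hit still usable
    if not res.success:
        messages.append(f"optimizer: {res.message}")
    return _pack_fit(
        species_ids, beta_hat, include_interaction, light_log,
        sd_b, sd_c, loglik, n, k, vcov, converged, messages,
    )


def _pack_fit(
    species_ids, beta, include_interaction, light_log,
    sd_b, sd_c, loglik, n, k, vcov, converged, messages,
):
    n_sp = len(species_ids)
    if include_interaction:
        intercepts = beta[:n_sp]
        slopes = beta[n_sp : 2 * n_sp]
        light_slope = float(np.mean(slopes))
        size_slope = float(beta[-1])
        by_species = slopes.copy()
    else:
        intercepts = beta[:n_sp]
        light_slope = float(beta[n_sp])
        size_slope = float(beta[n_sp + 1])
        by_species = None
    return MortalityFit(
        species_ids=list(species_ids),
        species_intercepts=np.asarray(intercepts, dtype=float),
        light_slope=light_slope,
        size_slope=size_slope,
        light_slope_by_species=by_species,
        sd_individual=float(sd_b),
        sd_census=float(sd_c),
        loglik=float(loglik),
        n_obs=int(n),
        n_params=int(k),
        bic=float(-2.0 * loglik + k * np.log(n)),
        vcov=vcov,
        converged=converged,
        light_log=light_log,
        messages=messages,
    )
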