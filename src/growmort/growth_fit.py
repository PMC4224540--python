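"""Nonlinear mixed-effects estimation of the power-law growth model.

Model for observed diameter y_ij of individual i at time t_ij:

    y_ij = M(t_ij; alpha_i, beta_i, m0_i) + e_ij,    e_ij ~ N(0, sigma_s(i)^2)

with M the analytic power-law solution, individual parameters

    alpha_i = a_{species(i)} + gamma * log(openness_i) + b1_i
    beta_i  = beta0 + b2_i
    m0_i    = mu0 + b3_i

and independent individual random effects (b1, b2, b3) ~ N(0, diag(d^2)).
Species intercepts on alpha, a common light slope (optionally per-species for
the interaction model), a common beta and M0, and per-species residual
standard deviations (heteroscedastic option) are the fixed parameters.

Estimation alternates two steps in the style of Lindstrom & Bates:

1. PNLS: with variance parameters fixed, Gauss-Newton on the penalized
   nonlinear least-squares criterion jointly in the fixed effects and all
   individual random effects (block elimination keeps the linear algebra at
   one p x p solve plus independent 3 x 3 solves per individual).
2. LME: linearize the model about the current estimates and maximize the
   resulting linear mixed-model likelihood (ML or REML; residual variance
   and the GLS fixed effects are profiled out) over relative random-effect
   and residual-variance parameters.

The reported log-likelihood is the linear-approximation value at
convergence, the same quantity classical NLME software reports; BIC always
uses the ML variant.  Internally time is rescaled to units of 1000 days so
alpha-type parameters are O(1); all reported values are converted back to
the per-day scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .growth import average_canopy_table

__all__ = [
    "prepare_growth_data",
    "fit_growth_nlme",
    "compare_bic",
    "pseudo_r2",
    "trajectory_ci",
    "GrowthFit",
    "GrowthData",
]

logger = logging.getLogger(__name__)

_TSCALE = 1000.0  # internal time unit, days
_ALPHA_FLOOR = 1e-8  # on the internal (per 1000 d) scale
_M0_FLOOR = 0.1
_BETA_GUARD = 1e-6


@dataclass
class GrowthData:
    """Prepared (padded) growth arrays on the internal time scale."""

    y: np.ndarray  # (N, T) diameters, mm; 0-padded
    t: np.ndarray  # (N, T) times in units of 1000 days; 0-padded
    mask: np.ndarray  # (N, T) bool, True where observed
    n_i: np.ndarray  # (N,) observations per individual
    sp: np.ndarray  # (N,) species codes
    log_light: np.ndarray  # (N,) log averaged canopy openness
    species_ids: list
    individual_ids: list
    n_excluded: int

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())

    def fingerprint(self):
        return (self.n_obs, round(float(self.y[self.mask].sum()), 6))

    def groups(self):
        """Indices of individuals grouped by observation count (for batching)."""
        out = []
        for n in np.unique(self.n_i):
            out.append((int(n), np.where(self.n_i == n)[0]))
        return out


def prepare_growth_data(
    census: pd.DataFrame, min_measures: int = 3, canopy_threshold: float = 160.0
) -> GrowthData:
    """Assemble fitting arrays from a long census table.

    Applies the canopy-averaging rule (mean openness while height <= 160 cm)
    to build the per-individual light covariate, keeps rows with a recorded
    diameter, and excludes individuals with fewer than ``min_measures``
    diameter measures (they remain available to the mortality model).
    """
    light = average_canopy_table(census, threshold=canopy_threshold)
    obs = census.dropna(subset=["diameter_mm"]).sort_values(
        ["individual_id", "census_day"]
    )
    counts = obs.groupby("individual_id").size()
    keep = counts[counts >= min_measures].index
    n_excluded = int((counts < min_measures).sum())
    if n_excluded:
        logger.info(
            "prepare_growth_data: excluded %d individuals with < %d measures",
            n_excluded,
            min_measures,
        )
    obs = obs[obs["individual_id"].isin(keep)]
    if obs.empty:
        raise ValueError("no individuals with enough diameter measures")

    ind_ids = list(pd.unique(obs["individual_id"]))
    ind_map = {v: k for k, v in enumerate(ind_ids)}
    species_ids = sorted(obs["species_id"].unique())
    sp_map = {v: k for k, v in enumerate(species_ids)}

    N = len(ind_ids)
    T = int(obs.groupby("individual_id").size().max())
    y = np.zeros((N, T))
    t = np.zeros((N, T))
    mask = np.zeros((N, T), dtype=bool)
    sp = np.zeros(N, dtype=int)
    for ind, g in obs.groupby("individual_id", sort=False):
        k = ind_map[ind]
        n = len(g)
        y[k, :n] = g["diameter_mm"].to_numpy()
        t[k, :n] = g["census_day"].to_numpy() / _TSCALE
        mask[k, :n] = True
        sp[k] = sp_map[g["species_id"].iloc[0]]
    ll = np.log(light.reindex(ind_ids).to_numpy(dtype=float))
    if np.any(~np.isfinite(ll)):
        raise ValueError("missing canopy openness for some fitted individuals")
    return GrowthData(
        y=y,
        t=t,
        mask=mask,
        n_i=mask.sum(axis=1),
        sp=sp,
        log_light=ll,
        species_ids=species_ids,
        individual_ids=ind_ids,
        n_excluded=n_excluded,
    )


class _Structure:
    """Fixed-effect design: maps theta to per-individual (alpha, beta, m0)."""

    def __init__(self, data: GrowthData, alpha_formula: str):
        S = len(data.species_ids)
        N = len(data.n_i)
        dummies = np.zeros((N, S))
        dummies[np.arange(N), data.sp] = 1.0
        if alpha_formula == "species+light":
            Xa = np.hstack([dummies, data.log_light[:, None]])
            a_names = [f"alpha[{s}]" for s in data.species_ids] + ["light_slope"]
        elif alpha_formula == "species*light":
            Xa = np.hstack([dummies, dummies * data.log_light[:, None]])
            a_names = [f"alpha[{s}]" for s in data.species_ids] + [
                f"light_slope[{s}]" for s in data.species_ids
            ]
        elif alpha_formula == "species":
            Xa = dummies
            a_names = [f"alpha[{s}]" for s in data.species_ids]
        else:
            raise ValueError(f"unknown alpha_formula {alpha_formula!r}")
        self.alpha_formula = alpha_formula
        self.Xa = Xa
        self.names = a_names + ["beta", "m0"]
        self.p = Xa.shape[1] + 2
        self.i_beta = Xa.shape[1]
        self.i_m0 = Xa.shape[1] + 1
        self.n_species = S

    def phi(self, theta, b):
        alpha = self.Xa @ theta[: self.Xa.shape[1]] + b[:, 0]
        beta = theta[self.i_beta] + b[:, 1]
        m0 = theta[self.i_m0] + b[:, 2]
        return alpha, beta, m0


def _model_jac(theta, b, data: GrowthData, struct: _Structure):
    """f, d f/d theta, d f/d b on the padded grid (masked entries zeroed).

    Overflow in rejected trial steps (extreme beta draws during line search)
    is expected and silenced; non-finite objectives are rejected upstream.
    """
    with np.errstate(over="ignore", invalid="ignore"):
        alpha, beta, m0 = struct.phi(theta, b)
        alpha = np.maximum(alpha, _ALPHA_FLOOR)
        m0 = np.maximum(m0, _M0_FLOOR)
        k = 1.0 - beta
        k = np.where(np.abs(k) < _BETA_GUARD, np.sign(k + 1e-300) * _BETA_GUARD, k)
        t = data.t
        m0k = m0**k
        u = m0k[:, None] + (alpha * k)[:, None] * t
        u = np.maximum(u, 1e-8)
        inv_k = 1.0 / k
        f = u ** inv_k[:, None]
        u_pow = u ** (inv_k - 1.0)[:, None]
        df_da = t * u_pow
        df_dm0 = u_pow * (m0 ** (k - 1.0))[:, None]
        du_db = -(m0k * np.log(m0))[:, None] - alpha[:, None] * t
        df_db = f * (
            np.log(u) * (inv_k**2)[:, None] + du_db * (inv_k / 1.0)[:, None] / u
        )
        m = data.mask
        f = np.where(m, f, 0.0)
        Jb = np.stack(
            [np.where(m, df_da, 0.0), np.where(m, df_db, 0.0), np.where(m, df_dm0, 0.0)],
            axis=2,
        )
        # fixed-effect Jacobian: alpha block is df/da * Xa, then beta and m0 columns
        Jf = np.concatenate(
            [
                Jb[:, :, 0][:, :, None] * struct.Xa[:, None, :],
                Jb[:, :, 1][:, :, None],
                Jb[:, :, 2][:, :, None],
            ],
            axis=2,
        )
        return f, Jf, Jb



def _quiet(fn):
    """Run fn with overflow/invalid warnings silenced (rejected trial steps)."""
    import functools

    @functools.wraps(fn)
    def wrapper(*a, **k):
        with np.errstate(over="ignore", invalid="ignore"):
            return fn(*a, **k)

    return wrapper

@_quiet
def _pnls(theta, b, data, struct, D_abs, sig_obs, maxiter=15, tol=1e-10):
    """Penalized Gauss-Newton in (theta, b) with per-individual elimination."""
    Dinv = 1.0 / np.maximum(D_abs, 1e-18)
    w_obs = np.where(data.mask, 1.0 / sig_obs[:, None] ** 2, 0.0)

    def objective(th, bb):
        f, _, _ = _model_jac(th, bb, data, struct)
        r = np.where(data.mask, data.y - f, 0.0)
        return float((r**2 * w_obs).sum() + ((bb**2) * Dinv).sum())

    obj = objective(theta, b)
    p = struct.p
    for _ in range(maxiter):
        f, Jf, Jb = _model_jac(theta, b, data, struct)
        r = np.where(data.mask, data.y - f, 0.0)
        # per-individual pieces
        JbW = Jb * w_obs[:, :, None]
        A = np.einsum("ntk,ntl->nkl", JbW, Jb)  # (N,3,3)
        A += np.diag(Dinv)[None, :, :]
        Ainv = np.linalg.inv(A)
        JfW = Jf * w_obs[:, :, None]
        C = np.einsum("ntp,ntk->npk", JfW, Jb)  # (N,p,3)
        g_b = np.einsum("ntk,nt->nk", JbW, r) - b * Dinv[None, :]
        g_f = np.einsum("ntp,nt->np", JfW, r)
        CA = np.einsum("npk,nkl->npl", C, Ainv)
        M = np.einsum("ntp,ntq->pq", JfW, Jf) - np.einsum("npk,nqk->pq", CA, C)
        rhs = g_f.sum(axis=0) - np.einsum("npk,nk->p", CA, g_b)
        try:
            d_theta = np.linalg.solve(M + 1e-10 * np.eye(p), rhs)
        except np.linalg.LinAlgError:
            break
        d_b = np.einsum("nkl,nl->nk", Ainv, g_b - np.einsum("npk,p->nk", C, d_theta))
        scale = 1.0
        improved = False
        for _ in range(25):
            cand_t = theta + scale * d_theta
            cand_b = b + scale * d_b
            new = objective(cand_t, cand_b)
            if new <= obj + 1e-12:
                improved = True
                break
            scale *= 0.5
        if not improved:
            break
        theta, b = cand_t, cand_b
        if obj - new < tol * (abs(new) + 1.0):
            obj = new
            break
        obj = new
    return theta, b


def _lme_eval(xi, w, Jf, Jb, data, struct, per_species_var, reml):
    """Profiled linear mixed-model log-likelihood of the linearized problem.

    xi = (log relative RE sds (3), log relative residual sds per non-reference
    species).  Returns (loglik, theta_gls, sigma2, M, blups).
    """
    p = struct.p
    S = struct.n_species
    delta2 = np.exp(2.0 * xi[:3])
    if per_species_var:
        lam = np.concatenate([[1.0], np.exp(xi[3:])])
    else:
        lam = np.ones(S)
    lam_i = lam[data.sp]

    M = np.zeros((p, p))
    rhs = np.zeros(p)
    quad_w = 0.0
    logdet = 0.0
    N = 0
    cache = []
    for n, idx in data.groups():
        Jg = Jb[idx, :n, :]
        Xg = Jf[idx, :n, :]
        wg = w[idx, :n]
        V = np.einsum("mik,mjk->mij", Jg * delta2[None, None, :], Jg)
        V += (lam_i[idx] ** 2)[:, None, None] * np.eye(n)[None, :, :]
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return -np.inf, None, None, None, None
        logdet += 2.0 * np.log(np.einsum("mii->mi", L)).sum()
        Vi_X = np.linalg.solve(V, Xg)
        Vi_w = np.linalg.solve(V, wg[:, :, None])[:, :, 0]
        M += np.einsum("mip,miq->pq", Xg, Vi_X)
        rhs += np.einsum("mip,mi->p", Xg, Vi_w)
        quad_w += float((wg * Vi_w).sum())
        N += n * len(idx)
        cache.append((n, idx, V, Jg, Xg, wg))
    try:
        theta = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        return -np.inf, None, None, None, None
    quad = max(quad_w - theta @ rhs, 1e-12)
    if reml:
        dof = N - p
        sigma2 = quad / dof
        sign, logdet_M = np.linalg.slogdet(M)
        ll = -0.5 * (
            dof * np.log(2.0 * np.pi * sigma2) + logdet + logdet_M + dof
        )
    else:
        sigma2 = quad / N
        ll = -0.5 * (N * np.log(2.0 * np.pi * sigma2) + logdet + N)

    blups = np.zeros((len(data.n_i), 3))
    for n, idx, V, Jg, Xg, wg in cache:
        resid = wg - np.einsum("mip,p->mi", Xg, theta)
        Vi_r = np.linalg.solve(V, resid[:, :, None])[:, :, 0]
        blups[idx] = delta2[None, :] * np.einsum("mik,mi->mk", Jg, Vi_r)
    return float(ll), theta, float(sigma2), M, blups


@_quiet
def _solve_modes(theta, b, data, struct, D_abs, sig_obs, maxiter=40):
    """Conditional modes of the random effects at fixed theta (penalized GN)."""
    Dinv = 1.0 / np.maximum(D_abs, 1e-18)
    w_obs = np.where(data.mask, 1.0 / sig_obs[:, None] ** 2, 0.0)
    for _ in range(maxiter):
        f, _, Jb = _model_jac(theta, b, data, struct)
        r = np.where(data.mask, data.y - f, 0.0)
        JbW = Jb * w_obs[:, :, None]
        A = (
            np.einsum("ntk,ntl->nkl", JbW, Jb)
            + np.diag(Dinv)[None]
            + 1e-10 * np.eye(3)[None]
        )
        g = np.einsum("ntk,nt->nk", JbW, r) - b * Dinv[None]
        db = np.linalg.solve(A, g[..., None])[..., 0]
        o1 = float((r**2 * w_obs).sum() + ((b**2) * Dinv).sum())
        scale = 1.0
        for _ in range(25):
            bn = b + scale * db
            f2, _, _ = _model_jac(theta, bn, data, struct)
            r2 = np.where(data.mask, data.y - f2, 0.0)
            o2 = float((r2**2 * w_obs).sum() + ((bn**2) * Dinv).sum())
            if o2 <= o1 + 1e-12:
                break
            scale *= 0.5
        if not (o2 <= o1):
            break
        b = bn
        if o1 - o2 < 1e-11 * (abs(o2) + 1.0):
            break
    return b


def _corrected_laplace_nll(data, struct, per_species_var, b_start):
    """Second-order (exact-Hessian) Laplace marginal negative log-likelihood.

    The alternating scheme's likelihood drops the residual-weighted curvature
    of the model function from the Hessian of the inner integrand (a
    Gauss-Newton/Fisher approximation), which leaves an O(sigma^2) bias in
    the scaling exponent.  This objective restores the curvature term, with
    d2f/db2 obtained by central differences of the analytic Jacobian; it is
    used to polish the estimates after the alternating scheme converges.
    The inner mode always restarts from ``b_start`` so the objective is a
    pure function of the parameters.
    """
    p, S = struct.p, struct.n_species
    eye3 = np.eye(3)

    @_quiet
    def nll(x):
        theta = x[:p]
        D = np.exp(2.0 * np.clip(x[p : p + 3], -14, 7))
        if per_species_var:
            sig_sp = np.exp(np.clip(x[p + 3 : p + 3 + S], -10, 4))
        else:
            sig_sp = np.full(S, np.exp(np.clip(x[p + 3], -10, 4)))
        sig = sig_sp[data.sp]
        Dinv = 1.0 / D
        w_obs = np.where(data.mask, 1.0 / sig[:, None] ** 2, 0.0)
        b = b_start.copy()
        # inner penalized Gauss-Newton for the conditional mode
        o_prev = np.inf
        for _ in range(60):
            f, _, Jb = _model_jac(theta, b, data, struct)
            r = np.where(data.mask, data.y - f, 0.0)
            JbW = Jb * w_obs[:, :, None]
            A = (
                np.einsum("ntk,ntl->nkl", JbW, Jb)
                + np.diag(Dinv)[None]
                + 1e-10 * eye3[None]
            )
            g = np.einsum("ntk,nt->nk", JbW, r) - b * Dinv[None]
            db = np.linalg.solve(A, g[..., None])[..., 0]
            o1 = float((r**2 * w_obs).sum() + ((b**2) * Dinv).sum())
            scale = 1.0
            for _ in range(25):
                bn = b + scale * db
                f2, _, _ = _model_jac(theta, bn, data, struct)
                r2 = np.where(data.mask, data.y - f2, 0.0)
                o2 = float((r2**2 * w_obs).sum() + ((bn**2) * Dinv).sum())
                if o2 <= o1 + 1e-12:
                    break
                scale *= 0.5
            if not (o2 <= o1):
                break
            b = bn
            if o1 - o2 < 1e-10 * (abs(o2) + 1.0):
                break
        f, _, Jb = _model_jac(theta, b, data, struct)
        r = np.where(data.mask, data.y - f, 0.0)
        JbW = Jb * w_obs[:, :, None]
        H = np.einsum("ntk,ntl->nkl", JbW, Jb)
        eps = 1e-4
        for k in range(3):
            bp = b.copy()
            bp[:, k] += eps
            bm = b.copy()
            bm[:, k] -= eps
            dJ = (
                _model_jac(theta, bp, data, struct)[2]
                - _model_jac(theta, bm, data, struct)[2]
            ) / (2 * eps)
            H[:, :, k] -= np.einsum("nt,ntl->nl", r * w_obs, dJ)
        H = 0.5 * (H + np.transpose(H, (0, 2, 1))) + np.diag(Dinv)[None]
        sign, logdet = np.linalg.slogdet(H)
        if np.any(sign <= 0):
            return 1e8
        llik = (
            -0.5 * float((r**2 * w_obs).sum())
            - float((data.n_i * np.log(sig)).sum())
            - 0.5 * data.n_obs * np.log(2.0 * np.pi)
        )
        pen = -0.5 * float(((b**2) * Dinv).sum()) - 0.5 * len(data.n_i) * float(
            np.log(D).sum()
        )
        return -(llik + pen - 0.5 * float(logdet.sum()))

    return nll


@dataclass
class GrowthFit:
    """Fitted power-law growth NLME (all rates on the per-day scale)."""

    species_ids: list
    fixed_names: list
    theta: np.ndarray  # day scale: alpha entries mm mm^-1 day^-1
    vcov: np.ndarray  # day scale
    alpha_by_species: np.ndarray  # at log openness 0
    light_slope: float  # d alpha_day / d log openness (nan if absent)
    light_slope_by_species: np.ndarray | None
    beta: float
    m0: float
    re_sd: np.ndarray  # (alpha_day, beta, m0)
    resid_sd_by_species: np.ndarray
    loglik: float  # under the requested method
    loglik_ml: float
    method: str
    n_obs: int
    n_params: int
    bic: float
    pseudo_r2: float
    pseudo_r2_marginal: float
    fitted: np.ndarray  # conditional fitted values, observation order
    observed: np.ndarray
    alpha_formula: str
    per_species_variance: bool
    converged: bool
    n_iter: int
    data_fingerprint: tuple = ()
    messages: list = field(default_factory=list)

    def beta_ci(self, level: float = 0.95):
        from scipy import stats

        j = self.fixed_names.index("beta")
        se = float(np.sqrt(self.vcov[j, j]))
        z = stats.norm.ppf(0.5 + level / 2.0)
        return self.beta - z * se, self.beta + z * se

    def alpha_at(self, species, openness_pct):
        """Growth coefficient (day scale) for a species at given % openness."""
        j = self.species_ids.index(species)
        a = self.alpha_by_species[j]
        if self.light_slope_by_species is not None:
            a += self.light_slope_by_species[j] * np.log(openness_pct)
        elif np.isfinite(self.light_slope):
            a += self.light_slope * np.log(openness_pct)
        return a


def fit_growth_nlme(
    census: pd.DataFrame,
    alpha_formula: str = "species+light",
    per_species_variance: bool = True,
    method: str = "REML",
    min_measures: int = 3,
    max_outer: int = 40,
    tol: float = 1e-7,
    refine: bool = False,
    refine_maxiter: int = 80,
    data: GrowthData | None = None,
) -> GrowthFit:
    """Fit the power-law growth curve as a nonlinear mixed-effects model.

    Parameters
    ----------
    census : DataFrame
        Long census table (see simulate module for the column contract).
    alpha_formula : {"species+light", "species*light", "species"}
        Fixed-effect structure on the growth coefficient.
    per_species_variance : bool
        Allow a distinct residual SD per species (heteroscedastic option).
    method : {"REML", "ML"}
        Criterion for the variance step; BIC is always built from the ML
        log-likelihood so fits remain comparable.
    data : GrowthData, optional
        Pre-built arrays (skips table preparation), e.g. to share one
        prepared dataset across the model variants being compared.
    """
    if method.upper() not in ("REML", "ML"):
        raise ValueError("method must be 'REML' or 'ML'")
    reml = method.upper() == "REML"
    if data is None:
        data = prepare_growth_data(census, min_measures=min_measures)
    struct = _Structure(data, alpha_formula)
    S = struct.n_species
    p = struct.p

    # --- starting values -------------------------------------------------
    # per-individual two-point estimate of alpha at beta = beta_start
    beta_start = 0.8
    k0 = 1.0 - beta_start
    first = np.argmax(data.mask, axis=1)
    last = data.mask.shape[1] - 1 - np.argmax(data.mask[:, ::-1], axis=1)
    yi0 = data.y[np.arange(len(first)), first]
    yi1 = data.y[np.arange(len(first)), last]
    ti0 = data.t[np.arange(len(first)), first]
    ti1 = data.t[np.arange(len(first)), last]
    dt = np.maximum(ti1 - ti0, 1e-6)
    alpha_ind = np.clip((yi1**k0 - yi0**k0) / (k0 * dt), 1e-4, 10.0)
    theta = np.zeros(p)
    for j in range(S):
        m = data.sp == j
        theta[j] = np.median(alpha_ind[m]) if m.any() else np.median(alpha_ind)
    theta[struct.i_beta] = beta_start
    theta[struct.i_m0] = float(yi0.mean())
    b = np.zeros((len(data.n_i), 3))

    n_var = 3 + (S - 1 if per_species_variance else 0)
    xi = np.concatenate([np.log([0.3, 0.1, 3.0]), np.zeros(n_var - 3)])
    sigma2 = 0.09  # 0.3 mm
    bounds = [(-12.0, 6.0)] * 3 + [(-4.0, 4.0)] * (n_var - 3)

    ll_old = -np.inf
    ll = -np.inf
    converged = False
    messages = []
    it = 0
    for it in range(1, max_outer + 1):
        delta2 = np.exp(2.0 * xi[:3])
        lam = (
            np.concatenate([[1.0], np.exp(xi[3:])])
            if per_species_variance
            else np.ones(S)
        )
        D_abs = sigma2 * delta2
        sig_obs = np.sqrt(sigma2) * lam[data.sp]
        theta, b = _pnls(theta, b, data, struct, D_abs, sig_obs)

        f, Jf, Jb = _model_jac(theta, b, data, struct)
        w = np.where(
            data.mask,
            data.y - f + np.einsum("ntp,p->nt", Jf, theta)
            + np.einsum("ntk,nk->nt", Jb, b),
            0.0,
        )

        def negll(x):
            val = _lme_eval(x, w, Jf, Jb, data, struct, per_species_variance, reml)[0]
            return np.inf if not np.isfinite(val) else -val

        res = optimize.minimize(
            negll,
            xi,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200 if it == 1 else 60, "ftol": 1e-12},
        )
        xi = res.x
        ll, theta_gls, sigma2, M, blups = _lme_eval(
            xi, w, Jf, Jb, data, struct, per_species_variance, reml
        )
        if theta_gls is None:
            messages.append("variance step failed; keeping previous estimates")
            break
        theta, b = theta_gls, blups
        if np.isfinite(ll_old) and abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_old = ll

    if not converged:
        messages.append(f"outer loop stopped after {it} iterations without meeting tol")

    # final conditional refit of random effects and likelihood bookkeeping
    delta2 = np.exp(2.0 * xi[:3])
    lam = (
        np.concatenate([[1.0], np.exp(xi[3:])]) if per_species_variance else np.ones(S)
    )
    theta, b = _pnls(theta, b, data, struct, sigma2 * delta2, np.sqrt(sigma2) * lam[data.sp])
    f, Jf, Jb = _model_jac(theta, b, data, struct)
    w = np.where(
        data.mask,
        data.y - f + np.einsum("ntp,p->nt", Jf, theta)
        + np.einsum("ntk,nk->nt", Jb, b),
        0.0,
    )
    ll, theta_fin, sigma2, M, blups = _lme_eval(
        xi, w, Jf, Jb, data, struct, per_species_variance, reml
    )
    ll_ml = (
        ll
        if not reml
        else _lme_eval(xi, w, Jf, Jb, data, struct, per_species_variance, False)[0]
    )
    theta = theta_fin

    re_internal = np.sqrt(sigma2 * np.exp(2.0 * xi[:3]))
    sig_sp = np.sqrt(sigma2) * lam
    if refine:
        # polish with the curvature-corrected Laplace objective (reduces the
        # O(sigma^2) linearization bias, mainly in beta)
        nll = _corrected_laplace_nll(data, struct, per_species_variance, blups)
        if per_species_variance:
            x0 = np.concatenate(
                [theta, np.log(np.maximum(re_internal, 1e-8)), np.log(sig_sp)]
            )
        else:
            x0 = np.concatenate(
                [theta, np.log(np.maximum(re_internal, 1e-8)), [np.log(sig_sp[0])]]
            )
        res = optimize.minimize(
            nll,
            x0,
            method="L-BFGS-B",
            options={"maxiter": refine_maxiter, "ftol": 1e-12},
        )
        if np.isfinite(res.fun) and res.fun < nll(x0) + 1e-9:
            theta = res.x[:p]
            re_internal = np.exp(res.x[p : p + 3])
            if per_species_variance:
                sig_sp = np.exp(res.x[p + 3 : p + 3 + S])
            else:
                sig_sp = np.full(S, np.exp(res.x[p + 3]))
            ll_ml = -float(res.fun)
            messages.append(
                f"laplace refinement applied ({res.nit} iterations)"
            )
            # refresh conditional modes, linearization and vcov at the
            # refined parameters
            blups = _solve_modes(
                theta, blups, data, struct, re_internal**2, sig_sp[data.sp]
            )
            f, Jf, Jb = _model_jac(theta, blups, data, struct)
            w = np.where(
                data.mask,
                data.y - f + np.einsum("ntp,p->nt", Jf, theta)
                + np.einsum("ntk,nk->nt", Jb, blups),
                0.0,
            )
            sigma2 = sig_sp[0] ** 2
            xi_ref = np.concatenate(
                [
                    np.log(np.maximum(re_internal, 1e-12) / sig_sp[0]),
                    np.log(sig_sp[1:] / sig_sp[0]) if per_species_variance else [],
                ]
            )
            ll_v, _, sigma2, M, _ = _lme_eval(
                xi_ref, w, Jf, Jb, data, struct, per_species_variance, reml
            )
            if M is None:
                messages.append("vcov refresh failed; keeping pre-refinement vcov")
            else:
                ll = ll_v
        else:
            messages.append("laplace refinement did not improve; discarded")

    f_cond, _, _ = _model_jac(theta, blups, data, struct)

    yv = data.y[data.mask]
    fv = f_cond[data.mask]
    r2_cond = _safe_sq_corr(yv, fv)
    f_marg, _, _ = _model_jac(theta, np.zeros_like(blups), data, struct)
    r2_marg = _safe_sq_corr(yv, f_marg[data.mask])

    vcov_int = sigma2 * np.linalg.inv(M)
    # convert alpha-type entries from per-1000-day to per-day scale
    scale = np.ones(p)
    for j, nm in enumerate(struct.names):
        if nm.startswith("alpha") or nm.startswith("light_slope"):
            scale[j] = 1.0 / _TSCALE
    theta_day = theta * scale
    vcov_day = vcov_int * np.outer(scale, scale)

    n_params = p + 3 + (S if per_species_variance else 1)
    n_obs = data.n_obs
    re_sd = re_internal.copy()
    re_sd[0] /= _TSCALE

    if alpha_formula == "species+light":
        light_slope = float(theta_day[S])
        by_sp = None
    elif alpha_formula == "species*light":
        light_slope = float("nan")
        by_sp = theta_day[S : 2 * S].copy()
    else:
        light_slope = float("nan")
        by_sp = None

    return GrowthFit(
        species_ids=list(data.species_ids),
        fixed_names=list(struct.names),
        theta=theta_day,
        vcov=vcov_day,
        alpha_by_species=theta_day[:S].copy(),
        light_slope=light_slope,
        light_slope_by_species=by_sp,
        beta=float(theta_day[struct.i_beta]),
        m0=float(theta_day[struct.i_m0]),
        re_sd=re_sd,
        resid_sd_by_species=sig_sp,
        loglik=float(ll),
        loglik_ml=float(ll_ml),
        method=method.upper(),
        n_obs=n_obs,
        n_params=n_params,
        bic=float(-2.0 * ll_ml + n_params * np.log(n_obs)),
        pseudo_r2=r2_cond,
        pseudo_r2_marginal=r2_marg,
        fitted=fv,
        observed=yv,
        alpha_formula=alpha_formula,
        per_species_variance=per_species_variance,
        converged=converged,
        n_iter=it,
        data_fingerprint=data.fingerprint(),
        messages=messages,
    )


def _safe_sq_corr(a, b):
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("pseudo-R2 undefined: constant values")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def pseudo_r2(fit: GrowthFit) -> float:
    """Squared Pearson correlation of conditional fitted vs observed values."""
    return _safe_sq_corr(fit.observed, fit.fitted)


def compare_bic(fits, labels=None) -> pd.DataFrame:
    """Rank model fits by BIC under the two-point rule.

    All fits must be on the same data (checked via an observation
    fingerprint) with ML log-likelihoods available.  The preferred model is
    the simplest one whose BIC is within 2 points of the minimum, i.e. an
    extra term must buy a BIC drop of more than 2 to be kept.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    fps = {f.data_fingerprint for f in fits if getattr(f, "data_fingerprint", ())}
    if len(fps) > 1:
        raise ValueError("fits were made on different datasets")
    if labels is None:
        labels = [getattr(f, "alpha_formula", f"model{i}") for i, f in enumerate(fits)]
    tab = pd.DataFrame(
        {
            "model": labels,
            "n_params": [f.n_params for f in fits],
            "loglik_ml": [f.loglik_ml for f in fits],
            "bic": [f.bic for f in fits],
        }
    )
    tab["delta_bic"] = tab["bic"] - tab["bic"].min()
    eligible = tab[tab["delta_bic"] <= 2.0]
    pref = eligible.sort_values(["n_params", "bic"]).index[0]
    tab["preferred"] = False
    tab.loc[pref, "preferred"] = True
    return tab.sort_values("bic").reset_index(drop=True)


def trajectory_ci(
    fit: GrowthFit,
    species,
    openness_pct: float,
    t_days,
    n_draws: int = 1000,
    seed: int = 0,
    level: float = 0.95,
):
    """Parametric-draw confidence band for the population growth trajectory.

    Draws fixed-effect vectors from N(theta_hat, vcov), evaluates the
    analytic power-law solution for the given species and canopy openness at
    each time, and returns per-time percentile bands.

    Returns a DataFrame with columns t_day, median, lower, upper, point.
    """
    from .growth import predict_size

    t_days = np.asarray(t_days, dtype=float)
    j = fit.species_ids.index(species)
    vcov = 0.5 * (fit.vcov + fit.vcov.T)
    eigvals = np.linalg.eigvalsh(vcov)
    if eigvals.min() < -1e-10 * max(eigvals.max(), 1e-30):
        raise ValueError("fixed-effect covariance is not positive semi-definite")
    rng = np.random.default_rng(seed)
    if np.allclose(vcov, 0):
        draws = np.tile(fit.theta, (n_draws, 1))
    else:
        draws = rng.multivariate_normal(fit.theta, vcov, size=n_draws, method="svd")

    names = fit.fixed_names
    i_beta = names.index("beta")
    i_m0 = names.index("m0")
    a = draws[:, j]
    if "light_slope" in names:
        a = a + draws[:, names.index("light_slope")] * np.log(openness_pct)
    elif f"light_slope[{fit.species_ids[j]}]" in names:
        a = a + draws[:, names.index(f"light_slope[{fit.species_ids[j]}]")] * np.log(
            openness_pct
        )
    a = np.maximum(a, 1e-8)
    beta = np.clip(draws[:, i_beta], None, 0.9999)
    m0 = np.maximum(draws[:, i_m0], _M0_FLOOR)
    curves = predict_size(m0[:, None], a[:, None], beta[:, None], t_days[None, :])
    lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
    point_a = max(fit.alpha_at(species, openness_pct), 1e-8)
    point = predict_size(fit.m0, point_a, min(fit.beta, 0.9999), t_days)
    return pd.DataFrame(
        {
            "t_day": t_days,
            "point": point,
            "median": np.percentile(curves, 50, axis=0),
            "lower": np.percentile(curves, lo, axis=0),
            "upper": np.percentile(curves, hi, axis=0),
        }
    )
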