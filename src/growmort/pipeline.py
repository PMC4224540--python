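"""End-to-end orchestration: simulate -> fit growth -> fit mortality -> trade-off.

All intermediate tables are plain UTF-8 CSV with fixed headers; the run
manifest is JSON and records the package version, seed, a config hash and
every headline estimate, so an identical seed + config reproduces an
identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .growth_fit import fit_growth_nlme
from .growth import average_canopy_table
from .mortality import build_intervals, fit_mortality_glmm
from .simulate import SimConfig, generate_population
from .tradeoff import correlation_matrix, sma_fit, species_demography, tradeoff_summary

__all__ = ["RunConfig", "run_pipeline", "attach_averaged_canopy"]

CENSUS_COLUMNS = [
    "individual_id",
    "species_id",
    "census_day",
    "diameter_mm",
    "height_cm",
    "canopy_openness_pct",
    "alive",
]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "growmort_run"
    seed: int = 0
    census_csv: str | None = None  # None -> simulate
    traits_csv: str | None = None
    reference_size: float = 10.0  # mm, demography reference
    reference_light: float = 4.5  # % canopy openness
    growth_method: str = "REML"
    per_species_variance: bool = True
    min_measures: int = 3
    canopy_threshold_cm: float = 160.0
    simulate_only: bool = False
    sim: SimConfig | None = None

    def to_dict(self):
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(self.sim).items()
            }
        return d

    def hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def attach_averaged_canopy(
    census: pd.DataFrame, intervals: pd.DataFrame, threshold: float = 160.0
) -> pd.DataFrame:
    """Replace per-census openness in interval records by the averaged covariate."""
    avg = average_canopy_table(census, threshold=threshold)
    out = intervals.copy()
    out["canopy_openness_pct"] = out["individual_id"].map(avg)
    return out


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all outputs under ``config.out_dir``.

    Returns the manifest dict (also written to manifest.json).  Stage
    failures propagate with their own diagnostics; outputs written before
    the failure are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "growmort",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
    }

    if config.census_csv is not None:
        census = pd.read_csv(config.census_csv)
        traits = pd.read_csv(config.traits_csv) if config.traits_csv else None
        truth = None
    else:
        sim = config.sim if config.sim is not None else SimConfig(seed=config.seed)
        census, traits, truth = generate_population(sim, seed=config.seed)
        census.to_csv(out / "census.csv", index=False)
        traits.to_csv(out / "traits.csv", index=False)
        truth.to_json(out / "truth.json")
    manifest["n_census_rows"] = int(len(census))

    if config.simulate_only:
        _write_manifest(manifest, out)
        return manifest

    growth = fit_growth_nlme(
        census,
        method=config.growth_method,
        per_species_variance=config.per_species_variance,
        min_measures=config.min_measures,
    )
    lo, hi = growth.beta_ci()
    manifest["growth"] = {
        "beta": growth.beta,
        "beta_ci95": [lo, hi],
        "m0_mm": growth.m0,
        "light_slope_per_day": growth.light_slope,
        "light_slope_annual": growth.light_slope * 365.0,
        "alpha_by_species": dict(
            zip(growth.species_ids, growth.alpha_by_species.tolist())
        ),
        "pseudo_r2": growth.pseudo_r2,
        "loglik": growth.loglik,
        "bic": growth.bic,
        "n_obs": growth.n_obs,
        "converged": growth.converged,
    }
    _growth_summary_csv(growth, out / "growth_fit.csv")

    intervals = build_intervals(census)
    intervals = attach_averaged_canopy(
        census, intervals, threshold=config.canopy_threshold_cm
    )
    intervals.to_csv(out / "intervals.csv", index=False)
    mort = fit_mortality_glmm(intervals)
    manifest["mortality"] = {
        "light_slope_per_pct": mort.light_slope,
        "size_slope_per_mm": mort.size_slope,
        "species_intercepts": dict(
            zip(mort.species_ids, mort.species_intercepts.tolist())
        ),
        "sd_individual": mort.sd_individual,
        "sd_census": mort.sd_census,
        "loglik": mort.loglik,
        "bic": mort.bic,
        "n_intervals": mort.n_obs,
        "converged": mort.converged,
    }

    demog = species_demography(
        growth, mort,
        reference_size=config.reference_size,
        reference_light=config.reference_light,
    )
    demog.to_csv(out / "species_demography.csv", index=False)

    trade = tradeoff_summary(demog)
    manifest["tradeoff"] = {
        "sma_slope": trade.sma.slope,
        "sma_intercept": trade.sma.intercept,
        "r": trade.sma.r,
        "r_squared": trade.sma.r_squared,
        "p_value": trade.sma.p_value,
        "mortality_pp_per_0p1_sgr": trade.mortality_pp_per_0p1_sgr,
    }

    if traits is not None:
        table = traits.merge(demog, on="species_id")
        cols = [
            c
            for c in ["wood_density", "seed_mass", "leaf_cn", "sla",
                      "sgr_annual", "annual_mortality"]
            if c in table.columns
        ]
        r, p, n = correlation_matrix(table, columns=cols)
        r.to_csv(out / "correlations_r.csv")
        p.to_csv(out / "correlations_p.csv")
        manifest["correlations"] = {
            f"{a}~{b}": float(r.loc[a, b])
            for i, a in enumerate(cols)
            for b in cols[i + 1 :]
        }
        if "wood_density" in cols:
            wd_sgr = sma_fit(table["wood_density"], table["sgr_annual"])
            wd_mort = sma_fit(table["wood_density"], table["annual_mortality"])
            manifest["wood_density_sma"] = {
                "sgr_r2": wd_sgr.r_squared,
                "sgr_slope": wd_sgr.slope,
                "mortality_r2": wd_mort.r_squared,
                "mortality_slope": wd_mort.slope,
            }

    _write_manifest(manifest, out)
    return manifest


def _growth_summary_csv(growth, path):
    rows = [
        ("beta", growth.beta),
        ("m0_mm", growth.m0),
        ("light_slope_per_day", growth.light_slope),
        ("pseudo_r2", growth.pseudo_r2),
        ("loglik", growth.loglik),
        ("bic", growth.bic),
    ]
    rows += [
        (f"alpha[{s}]", a)
        for s, a in zip(growth.species_ids, growth.alpha_by_species)
    ]
    rows += [
        (f"resid_sd[{s}]", sd)
        for s, sd in zip(growth.species_ids, growth.resid_sd_by_species)
    ]
    pd.DataFrame(rows, columns=["parameter", "value"]).to_csv(path, index=False)


def _write_manifest(manifest: dict, out: Path):
    with open(out / "manifest.json", "w") as fh:
        json.dump(_round_floats(manifest), fh, indent=1, sort_keys=True)
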