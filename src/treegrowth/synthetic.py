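"""Synthetic tree inventories with the study's statistical structure.

Emulates the field design: 503 trees with DBH >= 2 cm across 12 populations
split evenly between 2 ecological zones, size-dependent pruning and
debarking intensities, wood density and leaf mass per area drawn around the
species means, a reserve effect on wood density, and one-year growth
generated from the hump-shaped model. The latent generating parameters
travel in a separate truth side-channel so the analysis columns stay blind.

All draws flow from one seeded generator stream in a fixed order: DBH,
pruning, debarking, WD, LMA, then the growth response; the same seed gives
bit-identical output.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import expit, ndtri
from scipy.stats import norm

from .model import MODEL_3, GrowthModelSpec, GrowthParams, design_matrix, mean_log_agr
from .traits import LMA_MEAN, LMA_SD, WD_MEAN, WD_SD

__all__ = ["GeneratorConfig", "default_growth_truth", "generate_tree_records", "generate_reserve_trait_set"]


def default_growth_truth() -> Tuple[GrowthParams, GrowthModelSpec]:
    """Published final-model structure as the generating truth.

    Coefficients are the pruning, wood-density and interaction effects of
    the retained interaction model; the size parameters (Dopt 8.76 cm,
    sigma 0.51) come from the covariate-free model.
    """
    return (
        GrowthParams(gmax_base=0.41, dopt=8.76, sigma=0.51, theta=(-0.18, -0.10, 0.12)),
        MODEL_3,
    )


class GeneratorConfig(BaseModel):
    """Knobs of the synthetic inventory; defaults are the study conditions."""

    model_config = ConfigDict(arbitrary_types_allowed=True, extra="forbid", frozen=True)

    n_trees: int = Field(default=503, ge=1)
    n_populations: int = Field(default=12, ge=1)
    n_zones: int = Field(default=2, ge=1)
    dbh_median: float = Field(default=10.0, gt=0, description="median of the lognormal DBH law, cm")
    dbh_log_sd: float = Field(default=0.8, gt=0)
    dbh_min: float = Field(default=2.0, gt=0, description="lower truncation of DBH, cm")
    wd_mean: float = Field(default=WD_MEAN, gt=0)
    wd_sd: float = Field(default=WD_SD, gt=0)
    lma_mean: float = Field(default=LMA_MEAN, gt=0)
    lma_sd: float = Field(default=LMA_SD, gt=0)
    reserve_wd_effect: float = Field(
        default=0.06,
        ge=0,
        description="expected WD difference (outside minus inside reserve), g cm^-3",
    )
    prun_size_slope: float = Field(default=1.0, ge=0)
    debark_size_slope: float = Field(default=1.0, ge=0)
    disturbance_concentration: float = Field(
        default=4.0, gt=0, description="beta concentration of intensity noise around the logistic trend"
    )
    growth_truth: Optional[Tuple[GrowthParams, GrowthModelSpec]] = None
    seed: int = 0

    @model_validator(mode="after")
    def _check_design(self) -> "GeneratorConfig":
        if not (self.n_trees >= self.n_populations >= self.n_zones >= 1):
            raise ValueError("require n_trees >= n_populations >= n_zones >= 1")
        return self

    def resolved_truth(self) -> Tuple[GrowthParams, GrowthModelSpec]:
        params, spec = self.growth_truth or default_growth_truth()
        params.check_matches(spec)
        return params, spec


def _truncated_lognormal(
    n: int, median: float, log_sd: float, lower: float, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF sampling of a lognormal truncated below at ``lower``."""
    mu = np.log(median)
    a = norm.cdf((np.log(lower) - mu) / log_sd)
    u = a + (1.0 - a) * rng.random(n)
    return np.exp(mu + log_sd * ndtri(u))


def _size_dependent_intensity(
    z_logdbh: np.ndarray, slope: float, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    """Intensity in [0, 1]: beta noise around a logistic trend in log-size.

    With slope 0 the trend is flat at 0.5 and intensity is independent of
    size; positive slopes make intensity increase with DBH in rank.
    """
    base = np.clip(expit(slope * z_logdbh), 1e-3, 1 - 1e-3)
    return rng.beta(base * concentration, (1.0 - base) * concentration)


def generate_tree_records(config: GeneratorConfig) -> Tuple[pd.DataFrame, Dict]:
    """Generate one synthetic inventory.

    Returns ``(records, truth)``: the analysis table (one row per tree, the
    TreeRecord schema) and a truth dictionary holding the generating
    parameters, kept out of the analysis columns. Populations are assigned
    to zones round-robin and trees to populations round-robin, so groups
    are as balanced as possible; alternating populations are flagged
    in-reserve. The reserve wood-density offset is split symmetrically
    (inside -effect/2, outside +effect/2) so the species-level mean stays
    at ``wd_mean`` while the outside-minus-inside difference equals
    ``reserve_wd_effect``.
    """
    params, spec = config.resolved_truth()
    rng = np.random.default_rng(config.seed)
    n = config.n_trees

    pop_ids = np.arange(n) % config.n_populations
    pop_zone = np.arange(config.n_populations) % config.n_zones
    pop_reserve = (np.arange(config.n_populations) % 2) == 0
    zone = np.array([f"zone_{pop_zone[p] + 1}" for p in pop_ids])
    in_reserve = pop_reserve[pop_ids]

    dbh_t0 = _truncated_lognormal(n, config.dbh_median, config.dbh_log_sd, config.dbh_min, rng)
    z = (np.log(dbh_t0) - np.log(dbh_t0).mean()) / max(np.log(dbh_t0).std(), 1e-12)
    prun = _size_dependent_intensity(z, config.prun_size_slope, config.disturbance_concentration, rng)
    debark = _size_dependent_intensity(z, config.debark_size_slope, config.disturbance_concentration, rng)

    wd_loc = config.wd_mean + np.where(in_reserve, -0.5, 0.5) * config.reserve_wd_effect
    wd = rng.normal(wd_loc, config.wd_sd, size=n)
    lma = rng.normal(config.lma_mean, config.lma_sd, size=n)

    records = pd.DataFrame(
        {
            "tree_id": [f"t{i:04d}" for i in range(n)],
            "population_id": [f"pop_{p + 1:02d}" for p in pop_ids],
            "zone": zone,
            "in_reserve": in_reserve,
            "dbh_t0": dbh_t0,
            "debark": debark,
            "prun": prun,
            "wd": wd,
            "lma": lma,
        }
    )

    try:
        X = design_matrix(records, spec)
    except ValueError as err:
        raise ValueError(f"growth_truth spec is incompatible with generated columns: {err}") from err
    mu = mean_log_agr(dbh_t0, params, spec, X=X)
    agr = np.expm1(rng.normal(mu, params.sigma))
    records["dbh_t1"] = records["dbh_t0"] + agr
    records["agr"] = records["dbh_t1"] - records["dbh_t0"]
    records = records[
        [
            "tree_id", "population_id", "zone", "in_reserve",
            "dbh_t0", "dbh_t1", "agr", "debark", "prun", "wd", "lma",
        ]
    ]

    truth = {
        "params": dataclasses.asdict(params),
        "spec": {
            "covariates": list(spec.covariates),
            "interactions": [list(i) for i in spec.interactions],
            "trait_standardization": {
                t: {"mean": s.mean, "sd": s.sd} for t, s in spec.trait_standardization.items()
            },
        },
        "config": config.model_dump(exclude={"growth_truth"}),
    }
    return records, truth


def generate_reserve_trait_set(config: GeneratorConfig) -> Tuple[pd.DataFrame, Dict]:
    """Inventory for the reserve wood-density comparison.

    Same generator as :func:`generate_tree_records` (which already assigns
    half the populations to reserves and offsets WD); exposed separately so
    the reserve analysis reads as its own design.
    """
    if config.reserve_wd_effect < 0:
        raise ValueError("reserve_wd_effect must be >= 0")
    return generate_tree_records(config)
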