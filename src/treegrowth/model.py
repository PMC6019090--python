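"""Hump-shaped size-dependent growth model with covariates on Gmax.

The response is the one-year absolute diameter growth rate AGR (cm yr^-1),
modelled on the log(AGR+1) scale as a Gaussian-in-log-size hump:

    log(AGR_i + 1) ~ Normal( Gmax_i * exp(-1/2 * ln(DBH_i / Dopt)^2), sigma^2 )

Gmax is the peak of log(AGR+1), reached exactly at DBH = Dopt, and carries a
linear predictor in the disturbance intensities (debarking and pruning
fractions in [0, 1]) and z-scored functional traits (WD, LMA), optionally
with trait-by-disturbance interactions under strong heredity:

    Gmax_i = gmax_base + sum_k theta_k x_ik + sum_jk theta_jk x_ij x_ik

Dopt and sigma never carry covariates. Natural logarithms throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .traits import TraitStandardization, REFERENCE_WD_STD, REFERENCE_LMA_STD

__all__ = [
    "TreeRecord",
    "GrowthModelSpec",
    "GrowthParams",
    "COVARIATE_NAMES",
    "TRAIT_COVARIATES",
    "model_spec",
    "MODEL_0",
    "MODEL_1",
    "MODEL_2",
    "MODEL_3",
    "design_matrix",
    "gmax_linear",
    "mean_log_agr",
    "log_likelihood",
    "simulate_agr",
]

COVARIATE_NAMES = ("debark", "prun", "wd", "lma")
TRAIT_COVARIATES = ("wd", "lma")
INTERACTION_CANDIDATES = (("debark", "wd"), ("debark", "lma"), ("prun", "wd"), ("prun", "lma"))


@dataclass(frozen=True)
class TreeRecord:
    """One tree's censuses, disturbance history, traits and labels.

    The atomic observation: DBH at two consecutive censuses (cm), the
    derived AGR (cm yr^-1), pruning and debarking intensities as fractions
    in [0, 1], wood density (g cm^-3), leaf mass per area (g m^-2) and
    grouping labels. Inventories are handled as pandas DataFrames with one
    column per field; this class documents and validates the row schema.
    """

    tree_id: str
    population_id: str
    zone: str
    in_reserve: bool
    dbh_t0: float
    dbh_t1: float
    debark: float
    prun: float
    wd: float
    lma: float

    @property
    def agr(self) -> float:
        return self.dbh_t1 - self.dbh_t0

    def __post_init__(self) -> None:
        if self.dbh_t0 < 2:
            raise ValueError(f"dbh_t0 must be >= 2 cm, got {self.dbh_t0}")
        if self.agr <= -1:
            raise ValueError(f"agr must be > -1 (log(AGR+1) response), got {self.agr}")
        for name in ("debark", "prun"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                hint = " (values in (1, 100] look like percent; divide by 100)" if 1 < v <= 100 else ""
                raise ValueError(f"{name} must lie in [0, 1], got {v}{hint}")
        if not self.wd > 0:
            raise ValueError(f"wd must be > 0, got {self.wd}")
        if not self.lma > 0:
            raise ValueError(f"lma must be > 0, got {self.lma}")


@dataclass(frozen=True)
class GrowthModelSpec:
    """Which covariates and interactions enter the Gmax linear predictor.

    ``covariates`` is an ordered subset of debark/prun/wd/lma;
    ``interactions`` an ordered subset of the four trait-by-disturbance
    pairs. Strong heredity is enforced: both constituents of every
    interaction must appear among the covariates. Traits are entered as
    z-scores; ``trait_standardization`` records the location/scale per trait
    so raw-scale predictions are exact.
    """

    covariates: Tuple[str, ...] = ()
    interactions: Tuple[Tuple[str, str], ...] = ()
    trait_standardization: Mapping[str, TraitStandardization] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in self.covariates:
            if c not in COVARIATE_NAMES:
                raise ValueError(f"unknown covariate {c!r}")
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("duplicate covariates")
        if len(set(self.interactions)) != len(self.interactions):
            raise ValueError("duplicate interactions")
        for a, b in self.interactions:
            if (a, b) not in INTERACTION_CANDIDATES:
                raise ValueError(f"unknown interaction {a}x{b}")
            if a not in self.covariates or b not in self.covariates:
                raise ValueError(
                    f"strong heredity violated: interaction {a}x{b} requires both main effects"
                )

    @property
    def term_names(self) -> Tuple[str, ...]:
        return tuple(self.covariates) + tuple(f"{a}:{b}" for a, b in self.interactions)

    @property
    def n_terms(self) -> int:
        return len(self.covariates) + len(self.interactions)

    def with_standardization(self, std: Mapping[str, TraitStandardization]) -> "GrowthModelSpec":
        merged = dict(self.trait_standardization)
        merged.update(std)
        return replace(self, trait_standardization=merged)

    def standardization_from(self, records: pd.DataFrame) -> "GrowthModelSpec":
        """Fill any missing trait standardization from sample mean/SD (ddof=1)."""
        std = dict(self.trait_standardization)
        for t in TRAIT_COVARIATES:
            if t in self.covariates and t not in std:
                std[t] = TraitStandardization(
                    float(records[t].mean()), float(records[t].std(ddof=1))
                )
        return replace(self, trait_standardization=std)


def model_spec(which: int) -> GrowthModelSpec:
    """The four published model structures.

    Model 0: size only. Model 1: debarking + pruning. Model 2: WD + LMA.
    Model 3: pruning + WD + pruning-by-WD interaction (the structure the
    forward selection retains). Trait standardizations default to the
    species reference values.
    """
    ref = {"wd": REFERENCE_WD_STD, "lma": REFERENCE_LMA_STD}
    if which == 0:
        return GrowthModelSpec()
    if which == 1:
        return GrowthModelSpec(covariates=("debark", "prun"))
    if which == 2:
        return GrowthModelSpec(covariates=("wd", "lma"), trait_standardization=ref)
    if which == 3:
        return GrowthModelSpec(
            covariates=("prun", "wd"),
            interactions=(("prun", "wd"),),
            trait_standardization=ref,
        )
    raise ValueError(f"model must be 0..3, got {which}")


MODEL_0 = model_spec(0)
MODEL_1 = model_spec(1)
MODEL_2 = model_spec(2)
MODEL_3 = model_spec(3)


@dataclass(frozen=True)
class GrowthParams:
    """A full parameter vector for simulation or a posterior draw.

    ``gmax_base`` is the peak log(AGR+1) for an undisturbed average tree
    (Gmax / Gmax1 / Gmax2 / Gmax3 depending on the spec), ``dopt`` the DBH
    (cm) at which growth peaks, ``sigma`` the residual SD on the log scale,
    and ``theta`` one coefficient per spec term, in spec term order.
    """

    gmax_base: float
    dopt: float
    sigma: float
    theta: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.dopt > 0:
            raise ValueError(f"dopt must be > 0, got {self.dopt}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        object.__setattr__(self, "theta", tuple(float(t) for t in self.theta))

    def check_matches(self, spec: GrowthModelSpec) -> None:
        if len(self.theta) != spec.n_terms:
            raise ValueError(
                f"theta has {len(self.theta)} coefficients but the spec has "
                f"{spec.n_terms} terms ({', '.join(spec.term_names) or 'none'})"
            )


def _covariate_column(records: pd.DataFrame, name: str, spec: GrowthModelSpec) -> np.ndarray:
    if name not in records.columns:
        raise ValueError(f"records are missing covariate column {name!r} required by the model")
    col = records[name].to_numpy(dtype=float)
    if name in TRAIT_COVARIATES:
        std = spec.trait_standardization.get(name)
        if std is None:
            raise ValueError(
                f"no standardization for trait {name!r}; call "
                "spec.standardization_from(records) or supply one explicitly"
            )
        col = std.transform(col)
    return col


def design_matrix(records: pd.DataFrame, spec: GrowthModelSpec) -> np.ndarray:
    """n x k matrix of model terms, covariates first then interactions.

    Trait columns are z-scored through the spec's standardization;
    disturbance columns stay on the raw [0, 1] fraction scale.
    """
    n = len(records)
    cols = {}
    for c in spec.covariates:
        cols[c] = _covariate_column(records, c, spec)
    out = np.empty((n, spec.n_terms), dtype=float)
    for j, c in enumerate(spec.covariates):
        out[:, j] = cols[c]
    for j, (a, b) in enumerate(spec.interactions, start=len(spec.covariates)):
        out[:, j] = cols[a] * cols[b]
    return out


def gmax_linear(
    params: GrowthParams,
    spec: GrowthModelSpec,
    X: Optional[np.ndarray] = None,
    records: Optional[pd.DataFrame] = None,
    warn_negative: bool = True,
) -> np.ndarray:
    """Per-tree Gmax_i = gmax_base + X theta.

    Accepts a prebuilt design matrix or builds one from records. Negative
    Gmax_i (possible under extreme covariates) is allowed but warned about:
    the mean growth curve then dips below the log(AGR+1) = 0 line.
    """
    params.check_matches(spec)
    if X is None:
        if records is None:
            if spec.n_terms:
                raise ValueError("covariate values required: pass X or records")
            X = np.zeros((1, 0))
        else:
            X = design_matrix(records, spec)
    g = params.gmax_base + (X @ np.asarray(params.theta) if spec.n_terms else 0.0)
    g = np.broadcast_to(np.asarray(g, dtype=float), (X.shape[0],)).copy()
    if warn_negative and np.any(g < 0):
        warnings.warn("Gmax_i is negative for some trees; mean growth dips below zero there")
    return g


def mean_log_agr(
    dbh,
    params: GrowthParams,
    spec: GrowthModelSpec = MODEL_0,
    X: Optional[np.ndarray] = None,
    records: Optional[pd.DataFrame] = None,
) -> np.ndarray:
    """Model mean of log(AGR+1): Gmax_i * exp(-1/2 ln(DBH/Dopt)^2).

    Maximized exactly at dbh = dopt and log-symmetric around it:
    mean(dopt*r) == mean(dopt/r) for every r > 0.
    """
    dbh = np.asarray(dbh, dtype=float)
    if np.any(dbh <= 0):
        raise ValueError("dbh must be > 0")
    hump = np.exp(-0.5 * np.log(dbh / params.dopt) ** 2)
    if spec.n_terms == 0 and X is None and records is None:
        return params.gmax_base * hump
    g = gmax_linear(params, spec, X=X, records=records, warn_negative=False)
    return g * hump


def _validate_agr(records: pd.DataFrame) -> np.ndarray:
    agr = records["agr"].to_numpy(dtype=float)
    bad = agr <= -1
    if np.any(bad):
        ids = records.loc[bad, "tree_id"].tolist() if "tree_id" in records else list(np.where(bad)[0])
        raise ValueError(f"agr <= -1 for trees {ids}; log(AGR+1) is undefined there")
    return agr


def log_likelihood(
    records: pd.DataFrame, params: GrowthParams, spec: GrowthModelSpec = MODEL_0
) -> float:
    """Gaussian log-likelihood of ln(AGR+1) under the hump model."""
    agr = _validate_agr(records)
    y = np.log1p(agr)
    mu = mean_log_agr(records["dbh_t0"].to_numpy(dtype=float), params, spec, records=records)
    s2 = params.sigma**2
    return float(-0.5 * len(y) * np.log(2 * np.pi * s2) - 0.5 * np.sum((y - mu) ** 2) / s2)


def simulate_agr(
    dbh,
    params: GrowthParams,
    spec: GrowthModelSpec = MODEL_0,
    X: Optional[np.ndarray] = None,
    records: Optional[pd.DataFrame] = None,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Draw AGR from the generative model: exp(Normal(mean, sigma^2)) - 1.

    Every draw exceeds -1 by construction. With sigma -> 0 the draws
    collapse onto exp(mean) - 1.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    mu = mean_log_agr(dbh, params, spec, X=X, records=records)
    y = rng.normal(mu, params.sigma)
    return np.expm1(y)
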