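"""Functional trait computation and standardization.

Wood density (WD, g cm^-3) is oven-dry mass divided by fresh core volume,
the wood-economics-spectrum trait. Leaf mass per area (LMA, g m^-2) is leaf
dry mass divided by one-sided leaf area, the leaf-economics-spectrum trait.
Traits enter the growth model as z-scores centred on "an average tree", so a
:class:`TraitStandardization` travels with every fitted model to make
raw-scale back-transforms exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "WoodCore",
    "LeafSample",
    "TraitStandardization",
    "WD_MEAN",
    "WD_SD",
    "LMA_MEAN",
    "LMA_SD",
    "REFERENCE_WD_STD",
    "REFERENCE_LMA_STD",
    "core_volume",
    "wood_density",
    "leaf_mass_per_area",
    "standardize_trait",
    "traits_from_measurements",
]

#: Species-level wood density mean, g cm^-3.
WD_MEAN = 0.56
#: Wood density standard deviation, g cm^-3, reconstructed from a reported
#: standard error of 0.005 at n = 503 (0.005 * sqrt(503) ~= 0.1121). Only
#: this reading is arithmetically consistent with the 0.73 g cm^-3
#: zero-pruning-cost threshold derived downstream.
WD_SD = 0.005 * math.sqrt(503)
#: Species-level leaf mass per area mean, g m^-2.
LMA_MEAN = 58.17
#: Leaf mass per area standard deviation, g m^-2 (reported spread read as SD).
LMA_SD = 7.62


@dataclass(frozen=True)
class WoodCore:
    """A cylindrical increment-borer wood core.

    Parameters
    ----------
    length_cm : float
        Core length, cm. Must be positive.
    diameter_cm : float
        Core cross-section diameter, cm. Must be positive.
    dry_mass_g : float
        Oven-dry mass, g. Must be non-negative.
    """

    length_cm: float
    diameter_cm: float
    dry_mass_g: float

    def __post_init__(self) -> None:
        if not self.length_cm > 0:
            raise ValueError(f"core length must be > 0, got {self.length_cm}")
        if not self.diameter_cm > 0:
            raise ValueError(f"core diameter must be > 0, got {self.diameter_cm}")
        if self.dry_mass_g < 0:
            raise ValueError(f"core dry mass must be >= 0, got {self.dry_mass_g}")


@dataclass(frozen=True)
class LeafSample:
    """One leaf's area and dry mass (trees contribute several leaves).

    Area is one-sided leaf area in m^2; dry mass in g.
    """

    area_m2: float
    dry_mass_g: float

    def __post_init__(self) -> None:
        if not self.area_m2 > 0:
            raise ValueError(f"leaf area must be > 0, got {self.area_m2}")
        if self.dry_mass_g < 0:
            raise ValueError(f"leaf dry mass must be >= 0, got {self.dry_mass_g}")


@dataclass(frozen=True)
class TraitStandardization:
    """Location/scale pair mapping a raw trait to a z-score and back."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"standardization sd must be > 0, got {self.sd}")

    def transform(self, values):
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def inverse(self, zscores):
        return np.asarray(zscores, dtype=float) * self.sd + self.mean


#: Reference standardizations for the study species, used when a model is
#: parameterized from published coefficients rather than refit from data.
REFERENCE_WD_STD = TraitStandardization(WD_MEAN, WD_SD)
REFERENCE_LMA_STD = TraitStandardization(LMA_MEAN, LMA_SD)


def core_volume(core: WoodCore) -> float:
    """Fresh volume of a cylindrical wood core, cm^3: pi (D/2)^2 L."""
    return math.pi * (core.diameter_cm / 2.0) ** 2 * core.length_cm


def wood_density(dry_mass_g: float, volume_cm3: float) -> float:
    """Wood density, g cm^-3: oven-dry mass over fresh volume.

    The ratio direction is dry mass / fresh volume: that is the only
    direction consistent with a species mean of ~0.56 g cm^-3.
    """
    if not volume_cm3 > 0:
        raise ValueError(f"core volume must be > 0, got {volume_cm3}")
    if dry_mass_g < 0:
        raise ValueError(f"dry mass must be >= 0, got {dry_mass_g}")
    return dry_mass_g / volume_cm3


def leaf_mass_per_area(samples: "LeafSample | Iterable[LeafSample]") -> float:
    """Tree-level LMA, g m^-2: unweighted mean of per-leaf dry mass / area."""
    if isinstance(samples, LeafSample):
        samples = [samples]
    values = [s.dry_mass_g / s.area_m2 for s in samples]
    if not values:
        raise ValueError("at least one leaf sample is required")
    return float(np.mean(values))


def standardize_trait(
    values: Sequence[float],
    std: Optional[TraitStandardization] = None,
) -> Tuple[np.ndarray, TraitStandardization]:
    """Z-score a trait series, returning the standardization used.

    When ``std`` is None the location/scale are estimated from the series
    (ddof=1); the series then needs length >= 2 and nonzero variance.
    """
    arr = np.asarray(values, dtype=float)
    if std is None:
        if arr.size < 2:
            raise ValueError("need >= 2 values to estimate a standardization")
        sd = float(np.std(arr, ddof=1))
        if not sd > 0:
            raise ValueError("trait series has zero variance; supply an explicit standardization")
        std = TraitStandardization(float(np.mean(arr)), sd)
    return std.transform(arr), std


def traits_from_measurements(
    cores: pd.DataFrame, leaves: pd.DataFrame
) -> pd.DataFrame:
    """Per-tree WD and LMA from raw measurement tables.

    ``cores`` columns: tree_id, core_length_cm, core_diameter_cm,
    core_dry_mass_g (one row per tree). ``leaves`` columns: tree_id,
    leaf_area_m2, leaf_dry_mass_g (typically three rows per tree). Returns a
    frame with columns tree_id, wd, lma suitable for merging into an
    inventory table.
    """
    wd_rows = []
    for row in cores.itertuples(index=False):
        core = WoodCore(row.core_length_cm, row.core_diameter_cm, row.core_dry_mass_g)
        wd_rows.append((row.tree_id, wood_density(core.dry_mass_g, core_volume(core))))
    wd_df = pd.DataFrame(wd_rows, columns=["tree_id", "wd"])

    lma_rows = []
    for tree_id, grp in leaves.groupby("tree_id", sort=False):
        samples = [
            LeafSample(a, m)
            for a, m in zip(grp["leaf_area_m2"], grp["leaf_dry_mass_g"])
        ]
        lma_rows.append((tree_id, leaf_mass_per_area(samples)))
    lma_df = pd.DataFrame(lma_rows, columns=["tree_id", "lma"])
    return wd_df.merge(lma_df, on="tree_id", how="outer")
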