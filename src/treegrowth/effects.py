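"""Derived disturbance quantities and descriptive growth summaries.

Everything here is computed from a fitted (or published) parameter vector
of the interaction model: the pruning-cost surface over size and wood
density, the wood-density threshold at which the pruning cost vanishes,
the reserve/non-reserve wood-density comparison, binned growth boxplot
summaries, and predicted growth trajectories with posterior envelopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .mcmc import PosteriorResult
from .model import GrowthModelSpec, GrowthParams, mean_log_agr
from .traits import TraitStandardization

__all__ = [
    "PruningCostGrid",
    "BinnedGrowthSummary",
    "TTestResult",
    "pruning_cost",
    "zero_cost_wd",
    "reserve_wd_test",
    "binned_agr_summary",
    "predicted_trajectory",
    "plot_pruning_cost",
]


def _require_interaction_terms(spec: GrowthModelSpec) -> Tuple[int, int]:
    terms = spec.term_names
    if "prun" not in terms or "prun:wd" not in terms:
        raise ValueError(
            "pruning-cost quantities need a spec with a 'prun' main effect and a "
            f"'prun:wd' interaction; this spec has terms {list(terms) or 'none'}"
        )
    return terms.index("prun"), terms.index("prun:wd")


def _wd_std(spec: GrowthModelSpec, std: Optional[TraitStandardization]) -> TraitStandardization:
    std = std or spec.trait_standardization.get("wd")
    if std is None:
        raise ValueError("a wood-density standardization is required")
    return std


@dataclass(frozen=True)
class PruningCostGrid:
    """Predicted growth lost to full pruning over a DBH x WD lattice.

    ``cost[i, j]`` is (not-pruned minus pruned) predicted AGR in cm yr^-1
    at ``dbh_grid[i]``, ``wd_grid[j]`` (raw g cm^-3 scale). Positive values
    mean pruning reduces growth.
    """

    dbh_grid: np.ndarray
    wd_grid: np.ndarray
    cost: np.ndarray

    def __post_init__(self) -> None:
        for g, nm in ((self.dbh_grid, "dbh"), (self.wd_grid, "wd")):
            if np.any(np.diff(g) <= 0):
                raise ValueError(f"{nm} grid must be strictly increasing")
        if not np.all(np.isfinite(self.cost)):
            raise ValueError("cost surface contains non-finite values")
        if self.cost.shape != (self.dbh_grid.size, self.wd_grid.size):
            raise ValueError("cost shape does not match grids")

    def to_frame(self) -> pd.DataFrame:
        """Long format: dbh_cm, wd_g_cm3, cost_cm_yr."""
        dd, ww = np.meshgrid(self.dbh_grid, self.wd_grid, indexing="ij")
        return pd.DataFrame(
            {"dbh_cm": dd.ravel(), "wd_g_cm3": ww.ravel(), "cost_cm_yr": self.cost.ravel()}
        )


def pruning_cost(
    params: GrowthParams,
    spec: GrowthModelSpec,
    dbh_grid: Sequence[float],
    wd_grid: Sequence[float],
    std: Optional[TraitStandardization] = None,
) -> PruningCostGrid:
    """Back-transformed growth difference between prun=0 and prun=1 trees.

    cost(dbh, wd) = (exp(mu_unpruned) - 1) - (exp(mu_pruned) - 1) with wd
    z-scored through ``std`` (defaulting to the spec's) and every other
    covariate held at zero (an average, undisturbed tree).
    """
    i_p, i_pw = _require_interaction_terms(spec)
    params.check_matches(spec)
    std = _wd_std(spec, std)
    dbh = np.asarray(dbh_grid, dtype=float)
    z = std.transform(np.asarray(wd_grid, dtype=float))
    hump = np.exp(-0.5 * np.log(dbh / params.dopt) ** 2)[:, None]
    th = np.asarray(params.theta)
    gmax_unpruned = params.gmax_base + np.zeros_like(z)[None, :]
    gmax_pruned = params.gmax_base + th[i_p] + th[i_pw] * z[None, :]
    if "wd" in spec.covariates:
        i_wd = spec.term_names.index("wd")
        gmax_unpruned = gmax_unpruned + th[i_wd] * z[None, :]
        gmax_pruned = gmax_pruned + th[i_wd] * z[None, :]
    cost = np.expm1(gmax_unpruned * hump) - np.expm1(gmax_pruned * hump)
    return PruningCostGrid(dbh_grid=dbh, wd_grid=np.asarray(wd_grid, float), cost=cost)


def zero_cost_wd(
    params: GrowthParams,
    spec: GrowthModelSpec,
    std: Optional[TraitStandardization] = None,
) -> float:
    """Raw wood density at which the pruning cost vanishes.

    Solves theta_P + theta_PxWD * z = 0 and maps the root back to the raw
    scale: std.mean + std.sd * (-theta_P / theta_PxWD). With the published
    interaction-model coefficients and the species standardization this is
    ~0.73 g cm^-3: denser-wooded trees pay no growth cost for pruning.
    """
    i_p, i_pw = _require_interaction_terms(spec)
    params.check_matches(spec)
    std = _wd_std(spec, std)
    th_p, th_pw = params.theta[i_p], params.theta[i_pw]
    if th_pw == 0:
        if th_p == 0:
            warnings.warn("theta_P and theta_PxWD are both zero: the cost vanishes at every WD")
            return std.mean
        raise ValueError("no interaction (theta_PxWD = 0): the pruning cost never vanishes")
    if th_p == 0:
        warnings.warn("theta_P is zero: threshold degenerates to the mean WD")
    return float(std.mean + std.sd * (-th_p / th_pw))


@dataclass(frozen=True)
class TTestResult:
    """Two-sample comparison of WD between outside- and inside-reserve trees."""

    mean_difference: float  # outside minus inside, g cm^-3
    t_statistic: float
    dof: float
    p_value: float
    n_outside: int
    n_inside: int


def reserve_wd_test(records: pd.DataFrame, welch: bool = False) -> TTestResult:
    """Student's (pooled-variance) t-test of wood density by reserve status.

    The difference is signed outside minus inside; the field expectation is
    a positive difference (reserve trees have lighter wood). Welch's
    unequal-variance variant is available behind ``welch=True``.
    """
    inside = records.loc[records["in_reserve"].astype(bool), "wd"].to_numpy(dtype=float)
    outside = records.loc[~records["in_reserve"].astype(bool), "wd"].to_numpy(dtype=float)
    if inside.size < 2 or outside.size < 2:
        raise ValueError("both reserve groups need >= 2 trees")
    if np.var(inside) == 0 and np.var(outside) == 0:
        raise ValueError("zero variance in both groups: t-test undefined")
    res = stats.ttest_ind(outside, inside, equal_var=not welch)
    if welch:
        v1, v2 = np.var(outside, ddof=1) / outside.size, np.var(inside, ddof=1) / inside.size
        dof = (v1 + v2) ** 2 / (v1**2 / (outside.size - 1) + v2**2 / (inside.size - 1))
    else:
        dof = outside.size + inside.size - 2
    return TTestResult(
        mean_difference=float(outside.mean() - inside.mean()),
        t_statistic=float(res.statistic),
        dof=float(dof),
        p_value=float(res.pvalue),
        n_outside=int(outside.size),
        n_inside=int(inside.size),
    )


@dataclass(frozen=True)
class BinnedGrowthSummary:
    """Boxplot-style AGR summaries per log-spaced DBH bin (Tukey whiskers)."""

    bin_edges: np.ndarray  # length n_bins + 1, cm
    counts: np.ndarray
    q1: np.ndarray
    median: np.ndarray
    q3: np.ndarray
    whisker_lo: np.ndarray
    whisker_hi: np.ndarray
    outliers: Tuple[Tuple[float, ...], ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dbh_lo_cm": self.bin_edges[:-1],
                "dbh_hi_cm": self.bin_edges[1:],
                "n": self.counts,
                "q1": self.q1,
                "median": self.median,
                "q3": self.q3,
                "whisker_lo": self.whisker_lo,
                "whisker_hi": self.whisker_hi,
                "n_outliers": [len(o) for o in self.outliers],
            }
        )


def binned_agr_summary(records: pd.DataFrame, n_bins: int = 8) -> BinnedGrowthSummary:
    """Quartiles, 1.5 IQR whiskers and outliers of AGR per DBH bin.

    Bins are equal-width on the log-DBH scale. Whiskers reach the most
    extreme observations within 1.5 interquartile ranges of the box;
    anything beyond is listed as an outlier.
    """
    if len(records) == 0:
        raise ValueError("no records to summarize")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    dbh = records["dbh_t0"].to_numpy(dtype=float)
    agr = records["agr"].to_numpy(dtype=float)
    edges = np.exp(np.linspace(np.log(dbh.min()), np.log(dbh.max()) + 1e-12, n_bins + 1))
    idx = np.clip(np.digitize(dbh, edges) - 1, 0, n_bins - 1)
    q1 = np.full(n_bins, np.nan)
    med = np.full(n_bins, np.nan)
    q3 = np.full(n_bins, np.nan)
    wlo = np.full(n_bins, np.nan)
    whi = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    outliers: List[Tuple[float, ...]] = []
    for b in range(n_bins):
        vals = agr[idx == b]
        counts[b] = vals.size
        if vals.size == 0:
            outliers.append(())
            continue
        q1[b], med[b], q3[b] = np.percentile(vals, [25, 50, 75])
        iqr = q3[b] - q1[b]
        inside = vals[(vals >= q1[b] - 1.5 * iqr) & (vals <= q3[b] + 1.5 * iqr)]
        wlo[b], whi[b] = inside.min(), inside.max()
        outliers.append(tuple(sorted(vals[(vals < wlo[b]) | (vals > whi[b])])))
    return BinnedGrowthSummary(
        bin_edges=edges, counts=counts, q1=q1, median=med, q3=q3,
        whisker_lo=wlo, whisker_hi=whi, outliers=tuple(outliers),
    )


def predicted_trajectory(
    result: PosteriorResult,
    covariate_profile: Dict[str, float],
    dbh_grid: Sequence[float],
    max_draws: int = 2000,
) -> pd.DataFrame:
    """Predicted AGR (cm yr^-1) over DBH with a 95% posterior envelope.

    ``covariate_profile`` fixes each raw-scale covariate the spec uses
    (e.g. {"prun": 1.0, "wd": 0.56}); traits are standardized through the
    spec. Returns columns dbh_cm, median, lo_2.5%, hi_97.5% computed over
    posterior draws of exp(mean_log_agr) - 1.
    """
    spec = result.spec
    profile = pd.DataFrame([covariate_profile]) if covariate_profile else None
    dbh = np.asarray(dbh_grid, dtype=float)
    chains, kept, P = result.draws.shape
    flat = result.draws.reshape(chains * kept, P)
    S = min(max_draws, flat.shape[0])
    sel = np.linspace(0, flat.shape[0] - 1, S).astype(int)
    preds = np.empty((S, dbh.size))
    from .model import design_matrix

    X = design_matrix(profile, spec) if spec.n_terms else np.zeros((1, 0))
    k = X.shape[1]
    for s, row in enumerate(flat[sel]):
        gmax_i = row[0] + (X[0] @ row[1 : 1 + k] if k else 0.0)
        mu = gmax_i * np.exp(-0.5 * np.log(dbh / row[-2]) ** 2)
        preds[s] = np.expm1(mu)
    lo, med, hi = np.percentile(preds, [2.5, 50, 97.5], axis=0)
    return pd.DataFrame({"dbh_cm": dbh, "median": med, "lo_2.5%": lo, "hi_97.5%": hi})


def plot_pruning_cost(grid: PruningCostGrid, ax=None):
    """Filled-contour rendering of the pruning-cost surface (optional)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    cs = ax.contourf(grid.dbh_grid, grid.wd_grid, grid.cost.T, levels=15, cmap="viridis")
    ax.set_xscale("log")
    ax.set_xlabel("DBH (cm)")
    ax.set_ylabel("wood density (g cm$^{-3}$)")
    ax.figure.colorbar(cs, ax=ax, label="pruning cost (cm yr$^{-1}$)")
    return ax
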