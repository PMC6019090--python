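"""Derived disturbance quantities from the fitted interaction model.

Computes (i) the pruning-cost surface — predicted growth of a not-pruned
minus a fully pruned tree over DBH and wood density, (ii) the wood density
above which pruning carries no growth cost, (iii) the reserve vs outside
wood-density comparison, (iv) binned growth summaries, and (v) predicted
growth trajectories for pruned and unpruned trees.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from treegrowth.effects import (
    binned_agr_summary,
    plot_pruning_cost,
    pruning_cost,
    reserve_wd_test,
    zero_cost_wd,
)
from treegrowth.io import read_tree_table, write_json
from treegrowth.model import MODEL_3, GrowthParams

parser = argparse.ArgumentParser()
parser.add_argument("--results", type=Path, default=Path("results"))
parser.add_argument("--welch", action="store_true")
args = parser.parse_args()

inventory = args.results / "inventory.csv"
draws_path = args.results / "draws_model3.csv"
for p in (inventory, draws_path):
    if not p.exists():
        raise SystemExit(f"{p} not found: run analysis scripts 01 and 02 first")
records = read_tree_table(inventory)
draws = pd.read_csv(draws_path)

spec = MODEL_3.standardization_from(records)
post_mean = {c: float(draws[c].mean()) for c in ("gmax", "prun", "wd", "prun:wd", "dopt", "sigma")}
params = GrowthParams(
    post_mean["gmax"], post_mean["dopt"], post_mean["sigma"],
    (post_mean["prun"], post_mean["wd"], post_mean["prun:wd"]),
)

dbh_grid = np.geomspace(2, 80, 60)
wd_grid = np.linspace(records["wd"].quantile(0.01), records["wd"].quantile(0.99), 40)
grid = pruning_cost(params, spec, dbh_grid, wd_grid)
grid.to_frame().to_csv(args.results / "pruning_cost.csv", index=False)
peak = np.unravel_index(np.argmax(grid.cost), grid.cost.shape)
print(f"pruning cost peaks at {grid.cost.max():.3f} cm/yr "
      f"(DBH {grid.dbh_grid[peak[0]]:.1f} cm, WD {grid.wd_grid[peak[1]]:.2f} g cm^-3)")

threshold = zero_cost_wd(params, spec)
print(f"zero-cost wood density: {threshold:.3f} g cm^-3 "
      "(denser-wooded trees pay no growth cost for pruning)")

ttest = reserve_wd_test(records, welch=args.welch)
print(f"reserve comparison: WD outside - inside = {ttest.mean_difference:+.3f} g cm^-3, "
      f"t = {ttest.t_statistic:.2f}, dof = {ttest.dof:.0f}, p = {ttest.p_value:.2e}")

binned = binned_agr_summary(records, n_bins=8)
binned.to_frame().to_csv(args.results / "binned_growth.csv", index=False)

from treegrowth.mcmc import PosteriorResult  # reconstruct draws for envelopes

names = ("gmax", "prun", "wd", "prun:wd", "dopt", "sigma")
arr = draws[list(names)].to_numpy()[None, :, :]
res = PosteriorResult(
    names=names, spec=spec, draws=np.concatenate([arr, arr]), loglik=np.zeros((2, arr.shape[1])),
    point=post_mean, mean=post_mean,
    ci={n: (float(np.percentile(draws[n], 2.5)), float(np.percentile(draws[n], 97.5))) for n in names},
    rhat={}, ess={}, acceptance={}, fixed={}, n_records=len(records),
)
from treegrowth.effects import predicted_trajectory

curves = []
for label, prun in (("not_pruned", 0.0), ("pruned", 1.0)):
    c = predicted_trajectory(res, {"prun": prun, "wd": float(records["wd"].mean())}, dbh_grid)
    c["profile"] = label
    curves.append(c)
pd.concat(curves).to_csv(args.results / "trajectories.csv", index=False)

write_json(
    {"zero_cost_wd_g_cm3": threshold,
     "max_pruning_cost_cm_yr": float(grid.cost.max()),
     "reserve_test": dataclasses.asdict(ttest)},
    args.results / "effects.json",
)

try:
    ax = plot_pruning_cost(grid)
    ax.figure.savefig(args.results / "pruning_cost.png", dpi=150, bbox_inches="tight")
    print(f"wrote surface figure to {args.results / 'pruning_cost.png'}")
except Exception as err:  # headless rendering is best-effort
    print(f"figure skipped: {err}")
print(f"wrote pruning_cost.csv, binned_growth.csv, trajectories.csv, effects.json")
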