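# treegrowth

Bayesian analysis of how chronic human disturbance — branch pruning for
fodder and trunk debarking for medicine — affects size-dependent stem
growth in savanna trees, and how intraspecific functional traits (wood
density, leaf mass per area) mediate that response. The study system is
*Afzelia africana* in Benin: inventories of trees measured at two
consecutive censuses across populations inside and outside forest
reserves. Because no field data are deposited, a first-class synthetic
generator reproduces the study design (503 trees with DBH ≥ 2 cm, 12
populations in 2 ecological zones, size-dependent disturbance
intensities) so every stage of the analysis is testable end to end.

## Model

The one-year absolute growth rate AGR (cm yr⁻¹) follows a hump-shaped
ontogenetic trajectory on the log scale:

```
log(AGRᵢ + 1) ~ Normal( Gmaxᵢ · exp(−½ · ln²(DBHᵢ / Dopt)), σ² )
Gmaxᵢ = Gmax + θ_D·Debarkᵢ + θ_P·Prunᵢ + θ_WD·WDᵢ + θ_LMA·LMAᵢ + θ_P−WD·Prunᵢ·WDᵢ + …
```

`Gmax` is the peak of log(AGR+1), reached exactly at `DBH = Dopt`;
disturbance intensities are fractions in [0, 1] and traits enter as
z-scores, so `Gmax` describes an average undisturbed tree. Four nested
structures are built in: Model 0 (size only), Model 1 (debarking +
pruning), Model 2 (WD + LMA), Model 3 (pruning + WD + pruning×WD, the
structure retained by forward selection). Inference is adaptive
random-walk Metropolis-within-Gibbs MCMC with weakly informative priors;
interactions are selected forward under strong heredity with a WAIC
improvement threshold of 2.

Derived quantities include the pruning-cost surface
`cost(DBH, WD) = (e^{μ(prun=0)} − 1) − (e^{μ(prun=1)} − 1)` and the wood
density at which this cost vanishes,
`WD* = mean_WD + sd_WD · (−θ_P / θ_P−WD)` — with the published
coefficients, ≈ 0.73 g cm⁻³: denser-wooded trees pay essentially no
growth cost for pruning.

## Worked example

```sh
python analysis/01_simulate_inventory.py --seed 0
python analysis/02_fit_growth_models.py --seed 0
python analysis/03_select_interactions.py --seed 0
python analysis/04_disturbance_effects.py
```

The first script prints the design of the generated inventory:

```
inventory: 503 trees, 12 populations, 2 zones, 252 trees inside reserves
DBH range 2.0-92.4 cm
traits: WD 0.566 +/- 0.111 g cm^-3, LMA 57.85 +/- 7.60 g m^-2
prun vs DBH rank correlation: 0.74 (size-dependent by design)
```

The fitting script prints Table-style summaries per model; for the
interaction model on this inventory:

```
Model 3 (WAIC 761.0)
parameter  ml_value   mean  ci_2.5%  ci_97.5%
     gmax     0.442  0.417    0.298     0.546
     prun    -0.223 -0.157   -0.390     0.110
       wd    -0.109 -0.103   -0.227     0.009
  prun:wd     0.105  0.098   -0.105     0.314
     dopt     9.515  8.885    6.060    12.607
    sigma     0.505  0.513    0.481     0.549
```

i.e. the generating values (0.41, −0.18, −0.10, 0.12, 8.76, 0.51) are
recovered within their posterior uncertainty. The effects script then
reports, from this fit:

```
pruning cost peaks at 0.611 cm/yr (DBH 9.0 cm, WD 0.30 g cm^-3)
zero-cost wood density: 0.740 g cm^-3
reserve comparison: WD outside - inside = +0.053 g cm^-3, t = 5.54, p = 4.92e-08
```

Pruning costs the most around the diameter of peak growth and for light
wood; the fitted zero-cost threshold lands near the 0.73 g cm⁻³ the
published coefficients imply. Forward selection on any one inventory may
or may not retain `prun:wd` — the evidence at these effect sizes is
marginal (see `docs/methods.md`); the per-candidate WAIC audit trail is
written to `results/selection.json`.

A `treegrowth` console command exposes the same pipeline
(`simulate`, `traits`, `fit`, `select`, `effects`, `report`) for use on
real inventory CSVs; see `treegrowth --help`.

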