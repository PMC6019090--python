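# Methods

## Growth model

The response is the one-year diameter increment AGR = DBH(t+1) − DBH(t)
in cm yr⁻¹, modelled through log(AGR + 1) so that shrinkage (negative
increments down to −1 cm, e.g. bark loss or measurement reversal) stays
in the support. The mean is a Gaussian-in-log-size hump,

  E[log(AGRᵢ+1)] = Gmaxᵢ · exp(−½ ln²(DBHᵢ/Dopt)),

with homoscedastic Gaussian noise (SD σ) on the log scale. `Gmax` is the
peak log-growth, attained exactly at `Dopt` and log-symmetric around it;
all logarithms are natural. Covariates act on `Gmax` only — placing them
on `Dopt` or σ is deliberately unsupported (weak identifiability and no
biological hypothesis). Disturbance covariates are intensity fractions:
`prun` is the proportion of branches pruned, `debark` the proportion of
trunk bark area wounded, both in [0, 1], so a coefficient is the effect
of full disturbance relative to none. Values in (1, 100] are rejected
with a percent-conversion hint rather than silently rescaled. Traits
enter as z-scores so the intercept describes "an average tree"; the
standardization object travels with the model specification, making
raw-scale back-transforms exact. `Gmaxᵢ` may go negative under extreme
covariate combinations; that is allowed (the mean curve dips below zero)
but warned about, since it usually signals an implausible parameter
vector rather than biology.

Interactions obey strong heredity: `prun:wd` can only enter alongside
both `prun` and `wd`. The four canonical structures are Model 0 (no
covariates), Model 1 (`debark`, `prun`), Model 2 (`wd`, `lma`) and
Model 3 (`prun`, `wd`, `prun:wd`).

### A note on two scale ambiguities

Two published conventions only reconcile under specific readings, both
implemented as defaults:

- **Wood density** is oven-dry mass over fresh cylinder volume
  (π(D/2)²L). The species mean of 0.56 g cm⁻³ is only consistent with
  this direction of the ratio, not its inverse.
- **WD standardization SD.** The species WD spread is quoted as
  "± 0.005", which at n = 503 can only be a standard error; the implied
  SD, 0.005·√503 ≈ 0.1121 g cm⁻³, is the default z-scale. This is the
  unique reading under which the Model 3 coefficients (θ_P = −0.18,
  θ_P−WD = 0.12) place the zero-pruning-cost threshold at
  0.56 + 0.1121·1.5 ≈ 0.73 g cm⁻³. The LMA spread (± 7.62 g m⁻²) is
  conversely treated as an SD; the two traits use different conventions,
  which the trait module documents rather than hides.

## Inference

Sampling is adaptive random-walk Metropolis-within-Gibbs: one Gaussian
proposal per free parameter per sweep, with `Dopt` and σ sampled on the
log scale. Proposal scales adapt every 50 burn-in iterations by a
Robbins–Monro step toward ~30% acceptance and are frozen afterwards.
Defaults are 4 chains × 20 000 iterations with the first half discarded;
the config enforces ≥ 2 chains and ≥ 1000 retained draws per chain. Most
analyses here use 2 chains × 4000–6000 iterations, which on these
posteriors gives stable means and intervals in under a second per fit on
one CPU; chain counts and lengths are ordinary knobs, not calibrations.

Priors are weakly informative and configurable per parameter:
Normal(0, 10²) on `gmax` and every θ (the response lives on a ±1 scale,
so this is effectively flat), log-uniform on [2, 200] cm for `Dopt`
(spanning sapling to the species' maximum diameter), half-Cauchy(1) for
σ. Parameters can also be fixed outright, which is how the closed-form
conjugate sub-case used by the tests is exposed. Initialization bins
log-DBH into 8 bins, starts `gmax` at the best bin's mean response and
`Dopt` at that bin's centre (clipped into the prior support), θ at ~0,
and jitters all of it per chain for overdispersed starts.

Reported per parameter: the retained draw with the highest data
likelihood (the "maximum likelihood value" convention of the source
tables — one defensible reading among several; posterior means and
medians are also exposed), percentile 95% credibility intervals,
split-R̂ and bulk ESS via arviz. R̂ > 1.05 or ESS < 400 attach warnings
to the result without suppressing it. Model 1/Model 3 fits at short
chain lengths routinely warn (ESS ≈ 80–150) because `gmax`, `prun` and
`dopt` are posterior-correlated; the recovery experiments show the
resulting Monte-Carlo noise is small relative to sampling variability
across datasets. `Dopt` and σ are re-estimated in every model structure.

WAIC is computed in-package from pointwise log-likelihoods of up to 1000
evenly thinned draws (lppd minus the pointwise-variance penalty, on the
deviance scale) and is cross-checked against arviz in the test suite.

## Forward selection

From Model 0, each remaining candidate interaction is trialled with its
main effects added; the best-scoring candidate is adopted if its WAIC is
at least 2 below the current model's, else selection stops. Ties break
by input order; a failed fit is logged and skipped. An alternative
criterion (adopt when the interaction's 95% CI excludes zero) sits
behind a flag. The full per-step score log is returned and serialized.

**Power at the published effect sizes is marginal, by design of the
problem rather than of this package.** With the published Model 3
coefficients as truth (θ_P = −0.18, θ_WD = −0.10, θ_P−WD = 0.12, σ =
0.51, n = 503) the expected in-sample deviance gain of the true
candidate over Model 0 is only ≈ 3.5 with a seed-to-seed spread of ~10
(measured with an independent least-squares oracle), so the true
interaction both wins and clears the threshold in only about half of
generated datasets; occasionally a spurious candidate wins outright.
This mirrors the published uncertainty itself — the reported 95% CI of
the interaction coefficient spans zero — and is reported as-is rather
than papered over with a stronger synthetic signal.

## Synthetic inventories

The generator emulates the study design, with all draws from a single
seeded stream in fixed order (DBH, pruning, debarking, WD, LMA, growth):

- **Design**: 503 trees over 12 populations assigned round-robin to 2
  zones and round-robin to trees, so groups are balanced to within one;
  alternating populations are flagged in-reserve (6 of 12).
- **Size**: DBH lognormal with median 10 cm and log-SD 0.8, truncated
  below at the 2 cm census threshold by inverse-CDF sampling — a
  right-skewed stand structure peaking near the growth optimum. The law
  is configurable; nothing downstream assumes it.
- **Disturbance**: intensity = Beta-distributed noise (concentration 4)
  around a logistic trend in standardized log-DBH with slope 1 per
  intensity. Slope 0 decouples intensity from size; positive slopes give
  the size-dependence the field studies describe. Intensities are
  continuous in (0, 1); exact zeros (never-pruned trees) are not
  generated, which understates the field contrast between reserve and
  non-reserve trees.
- **Traits**: WD ~ Normal(0.56, 0.1121) g cm⁻³ with the reserve effect
  (default 0.06) split symmetrically — inside-reserve means lowered by
  half the effect, outside raised by half — so the expected
  outside-minus-inside difference equals the configured effect while the
  species-level mean stays at 0.56. LMA ~ Normal(58.17, 7.62) g m⁻²,
  independent of WD. No trait–size correlation is generated.
- **Growth**: simulated from a configurable truth (parameters + model
  structure); the default is the final interaction model (Gmax 0.41,
  θ_P −0.18, θ_WD −0.10, θ_P−WD 0.12) with Dopt 8.76 cm and σ 0.51
  taken from the size-only model, whose values are the only published
  ones. The generating parameters are returned only through a separate
  truth side-channel (written as `truth.json`), never as analysis
  columns.

What passing recovery tests therefore show: the inference machinery is
unbiased and calibrated *when the model is true and the covariate design
is as generated*. They cannot certify behaviour under field realities
the generator omits: measurement error in DBH, zero-inflated and
reserve-structured pruning, trait–size or trait–trait correlation,
population-level random effects, or model misspecification.

## Numerical and degenerate-input conventions

- AGR ≤ −1 anywhere raises with the offending tree ids (the log response
  is undefined there); the generator cannot produce such records.
- A covariate with zero variance (nobody pruned) is an error at fit
  time, not a silent non-identifiability.
- Zero-variance series cannot define a standardization; standardize
  requires n ≥ 2 or an explicit location/scale.
- `zero_cost_wd`: θ_P−WD = 0 with θ_P ≠ 0 is an error (the cost never
  vanishes); θ_P = 0 degenerates to the mean WD with a warning; both
  zero warns that every WD is costless.
- The reserve comparison is a pooled-variance Student's t-test (as
  named by the source), signed outside minus inside; Welch's variant is
  a flag. Identical groups give t = 0, p = 1.
- Binned growth summaries use equal-width bins on log-DBH and Tukey
  1.5·IQR whiskers; the "minimum and maximum" whisker description in the
  source figure conflicts with its own outlier dots, and the Tukey
  convention resolves that conflict. Whisker-covered points and outliers
  partition each bin exactly.
- Seeded runs are bit-identical, including on-disk artifacts; every
  pipeline output embeds the seed and a configuration hash.

## Problem sizes

Recovery experiments simulate n = 503 trees per replicate (the study
size). The test suite averages 20 replicates for coverage checks, 60 for
the pruning-coefficient recovery (its per-dataset sampling SD, ~0.14 on
the log scale, is the largest of the recovered quantities), and 200 for
the reserve comparison; the acceptance script uses 48 replicates for the
size-only recovery and 96 for the pruning coefficient. Replicate counts
control only Monte-Carlo error of the reported averages.

## Known limitations

- The sampler is a random-walk scheme: adequate for these ≤ 7-parameter
  posteriors, slow-mixing beyond that; no gradient-based kernel.
- "Maximum likelihood value" is read as the best-likelihood retained
  draw; a frequentist MLE or MAP would differ slightly (the recovery
  experiments show the difference is well inside sampling noise).
- The published maximum pruning cost ("up to 0.35 cm yr⁻¹") is not
  reproduced as a target: it depends on the interaction model's own
  `Dopt` and σ, which were not published. With Model 0 values
  substituted, the surface peaks near 9 cm DBH at low WD, matching the
  published pattern qualitatively.
- Selection consistency at the published effect sizes is ~50% (see
  above); the package reports its audit trail so users can see how
  marginal any single selection outcome is.
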