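"""Forward selection over trait-by-disturbance interaction terms.

Starting from the covariate-free model, each remaining candidate
interaction is trialled with its two main effects added (strong heredity),
every trial model is fitted by MCMC, and the candidate with the best
selection score is adopted if it improves on the current model; otherwise
selection stops. The default score is WAIC with a drop of at least 2
counting as an improvement; a credibility-interval criterion (adopt the
candidate whose interaction CI excludes zero most decisively) is available
behind a flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mcmc import McmcConfig, PosteriorResult, PriorSpec, fit_model, waic
from .model import INTERACTION_CANDIDATES, MODEL_0, GrowthModelSpec

__all__ = ["SelectionResult", "forward_select_interactions"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a forward-selection run with a full audit trail.

    ``steps`` holds one entry per step with every candidate's score and the
    decision taken, so the path can be replayed from the log alone.
    """

    final_spec: GrowthModelSpec
    steps: Tuple[Dict, ...]
    stopping_reason: str
    final_fit: Optional[PosteriorResult] = None

    def to_dict(self) -> Dict:
        return {
            "final_covariates": list(self.final_spec.covariates),
            "final_interactions": [f"{a}:{b}" for a, b in self.final_spec.interactions],
            "steps": list(self.steps),
            "stopping_reason": self.stopping_reason,
        }


def _extend(spec: GrowthModelSpec, pair: Tuple[str, str]) -> GrowthModelSpec:
    """Current spec plus one interaction and whichever mains it still lacks."""
    covs = list(spec.covariates)
    for c in pair:
        if c not in covs:
            covs.append(c)
    return GrowthModelSpec(
        covariates=tuple(covs),
        interactions=tuple(spec.interactions) + (pair,),
        trait_standardization=dict(spec.trait_standardization),
    )


def forward_select_interactions(
    records: pd.DataFrame,
    candidates: Sequence[Tuple[str, str]] = INTERACTION_CANDIDATES,
    priors: Optional[PriorSpec] = None,
    mcmc: Optional[McmcConfig] = None,
    criterion: str = "waic",
    waic_improvement: float = 2.0,
) -> SelectionResult:
    """Build an interaction model forward from the covariate-free model.

    Candidate order breaks exact ties. Per-fit seeds are derived
    deterministically from the MCMC seed, the step and the candidate
    index, so identical inputs yield identical paths. A fit that fails is
    logged, skipped with a warning, and selection continues.
    """
    if criterion not in ("waic", "ci"):
        raise ValueError("criterion must be 'waic' or 'ci'")
    for pair in candidates:
        if tuple(pair) not in INTERACTION_CANDIDATES:
            raise ValueError(f"unknown candidate interaction {pair!r}")
    mcmc = mcmc or McmcConfig()
    base_ss = np.random.SeedSequence(mcmc.seed)

    def seeded(step: int, slot: int) -> McmcConfig:
        child = np.random.SeedSequence(entropy=base_ss.entropy, spawn_key=(step, slot))
        seed = int(child.generate_state(1)[0] % (2**31))
        return McmcConfig(
            chains=mcmc.chains, iterations=mcmc.iterations, burn_frac=mcmc.burn_frac,
            adapt_window=mcmc.adapt_window, target_accept=mcmc.target_accept, seed=seed,
        )

    current = MODEL_0
    current_fit = fit_model(records, current, priors=priors, mcmc=seeded(0, 0))
    current_score = waic(records, current_fit).waic if criterion == "waic" else None
    remaining = [tuple(p) for p in candidates]
    steps: List[Dict] = []
    reason = "no candidates supplied" if not remaining else ""

    step_no = 0
    while remaining:
        step_no += 1
        trials: List[Dict] = []
        best = None
        for slot, pair in enumerate(remaining, start=1):
            trial_spec = _extend(current, pair)
            entry: Dict = {"candidate": f"{pair[0]}:{pair[1]}"}
            try:
                fit = fit_model(records, trial_spec, priors=priors, mcmc=seeded(step_no, slot))
            except Exception as err:  # fit failure: log, skip candidate
                entry["error"] = str(err)
                warnings.warn(f"fit failed for candidate {pair}: {err}")
                log.warning("candidate %s skipped: %s", pair, err)
                trials.append(entry)
                continue
            if criterion == "waic":
                score = waic(records, fit).waic
                entry["waic"] = score
                improves = current_score - score >= waic_improvement
                margin = current_score - score
            else:
                name = f"{pair[0]}:{pair[1]}"
                flat = fit.draws_flat(name)
                zstat = abs(float(flat.mean())) / max(float(flat.std(ddof=1)), 1e-300)
                entry["interaction_z"] = zstat
                entry["ci"] = list(fit.ci[name])
                improves = fit.excludes_zero(name)
                margin = zstat
            entry["improves"] = bool(improves)
            trials.append(entry)
            if improves and (best is None or margin > best[0]):
                best = (margin, pair, fit, entry)
        decision = {"step": step_no, "current_terms": list(current.term_names), "trials": trials}
        if criterion == "waic":
            decision["current_waic"] = current_score
        if best is None:
            decision["decision"] = "stop"
            steps.append(decision)
            reason = "no candidate improved the model"
            break
        _, pair, fit, entry = best
        current = _extend(current, pair)
        current_fit = fit
        if criterion == "waic":
            current_score = entry["waic"]
        remaining.remove(pair)
        decision["decision"] = f"add {pair[0]}:{pair[1]}"
        steps.append(decision)
        if not remaining:
            reason = "all candidates adopted"
    return SelectionResult(
        final_spec=current_fit.spec,
        steps=tuple(steps),
        stopping_reason=reason,
        final_fit=current_fit,
    )
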