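import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from treegrowth.mcmc import McmcConfig, PosteriorResult
from treegrowth.model import MODEL_0, GrowthParams
from treegrowth.synthetic import GeneratorConfig, generate_tree_records

#: reduced sampler settings shared by the MCMC-heavy tests; 2 chains of
#: 4000 keep 2000 post-burn draws each, enough for stable means and CIs
QUICK_MCMC = dict(chains=2, iterations=4000)


def quick_mcmc(seed: int, **over) -> McmcConfig:
    kw = dict(QUICK_MCMC, seed=seed)
    kw.update(over)
    return McmcConfig(**kw)


@pytest.fixture(scope="session")
def default_records() -> pd.DataFrame:
    """One default synthetic inventory (final-model truth), 503 trees."""
    records, _ = generate_tree_records(GeneratorConfig(seed=1))
    return records


@pytest.fixture(scope="session")
def model0_records() -> pd.DataFrame:
    """Inventory simulated from the covariate-free model."""
    truth = GrowthParams(0.36, 8.76, 0.51)
    records, _ = generate_tree_records(
        GeneratorConfig(seed=5, growth_truth=(truth, MODEL_0))
    )
    return records


def constant_posterior(params: GrowthParams, spec, n: int = 50) -> PosteriorResult:
    """A point-mass PosteriorResult: every draw equals ``params``."""
    names = ("gmax", *spec.term_names, "dopt", "sigma")
    row = np.array([params.gmax_base, *params.theta, params.dopt, params.sigma])
    draws = np.tile(row, (2, n, 1))
    values = dict(zip(names, row))
    return PosteriorResult(
        names=names,
        spec=spec,
        draws=draws,
        loglik=np.zeros((2, n)),
        point=dict(values),
        mean=dict(values),
        ci={k: (float(v), float(v)) for k, v in values.items()},
        rhat={k: 1.0 for k in names},
        ess={k: float(2 * n) for k in names},
        acceptance={k: 1.0 for k in names},
        fixed={},
        n_records=0,
    )
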