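import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from treegrowth.model import (
    MODEL_0,
    MODEL_1,
    MODEL_2,
    MODEL_3,
    GrowthModelSpec,
    GrowthParams,
    TreeRecord,
    design_matrix,
    gmax_linear,
    log_likelihood,
    mean_log_agr,
    simulate_agr,
)
from treegrowth.traits import REFERENCE_WD_STD

P0 = GrowthParams(0.36, 8.76, 0.51)


def _records(n=20, seed=0, **cols):
    rng = np.random.default_rng(seed)
    base = {
        "tree_id": [f"t{i}" for i in range(n)],
        "dbh_t0": rng.uniform(2, 60, n),
        "agr": rng.uniform(-0.3, 2.0, n),
        "debark": rng.uniform(0, 1, n),
        "prun": rng.uniform(0, 1, n),
        "wd": rng.normal(0.56, 0.11, n),
        "lma": rng.normal(58, 7.6, n),
    }
    base.update(cols)
    return pd.DataFrame(base)


class TestMeanLogAgr:
    def test_peak_value_at_dopt(self):
        assert mean_log_agr(8.76, P0) == pytest.approx(0.36)

    def test_one_log_unit_from_peak(self):
        # at dbh = dopt*e the exponent is -1/2 exactly
        assert mean_log_agr(8.76 * math.e, P0) == pytest.approx(0.36 * math.exp(-0.5))

    @given(r=st.floats(0.05, 20), dopt=st.floats(2, 100), gmax=st.floats(-1, 2))
    def test_log_symmetry_around_dopt(self, r, dopt, gmax):
        p = GrowthParams(gmax, dopt, 0.5)
        assert mean_log_agr(dopt * r, p) == pytest.approx(
            mean_log_agr(dopt / r, p), rel=1e-10, abs=1e-12
        )

    @given(dbh=st.floats(0.1, 500))
    def test_peak_dominates_everywhere(self, dbh):
        assert mean_log_agr(P0.dopt, P0) >= mean_log_agr(dbh, P0)

    def test_nonpositive_dbh_rejected(self):
        with pytest.raises(ValueError):
            mean_log_agr(0.0, P0)

    def test_models_reduce_to_size_only_at_zero_theta(self):
        rec = _records(n=15, seed=3)
        base = mean_log_agr(rec["dbh_t0"], P0)
        for spec in (MODEL_1, MODEL_2, MODEL_3):
            spec = spec.standardization_from(rec)
            p = GrowthParams(0.36, 8.76, 0.51, (0.0,) * spec.n_terms)
            np.testing.assert_allclose(
                mean_log_agr(rec["dbh_t0"], p, spec, records=rec), base, rtol=1e-12
            )


class TestGmaxLinear:
    def test_empty_spec_returns_base(self):
        assert gmax_linear(P0, MODEL_0)[0] == pytest.approx(0.36)

    def test_fully_pruned_tree_disturbance_model(self):
        # published disturbance-model row: 0.44 - 0.24*1 + 0.12*0 = 0.20
        p = GrowthParams(0.44, 8.76, 0.51, (0.12, -0.24))
        rec = pd.DataFrame({"debark": [0.0], "prun": [1.0]})
        assert gmax_linear(p, MODEL_1, records=rec)[0] == pytest.approx(0.20)

    def test_pruning_terms_cancel_at_threshold_wood_density(self):
        # at z_wd = 1.5 the pruning main effect and the interaction cancel:
        # 0.41 - 0.18 - 0.15 + 0.18 = 0.26, identical to the unpruned 0.26
        p = GrowthParams(0.41, 8.76, 0.51, (-0.18, -0.10, 0.12))
        wd_raw = REFERENCE_WD_STD.inverse([1.5])[0]
        pruned = pd.DataFrame({"prun": [1.0], "wd": [wd_raw]})
        unpruned = pd.DataFrame({"prun": [0.0], "wd": [wd_raw]})
        g1 = gmax_linear(p, MODEL_3, records=pruned)[0]
        g0 = gmax_linear(p, MODEL_3, records=unpruned)[0]
        assert g1 == pytest.approx(0.26, abs=1e-9)
        assert g1 == pytest.approx(g0, abs=1e-12)

    def test_missing_covariate_named_in_error(self):
        p = GrowthParams(0.44, 8.76, 0.51, (0.12, -0.24))
        with pytest.raises(ValueError, match="prun"):
            gmax_linear(p, MODEL_1, records=pd.DataFrame({"debark": [0.1]}))

    def test_theta_length_must_match_spec(self):
        with pytest.raises(ValueError, match="terms"):
            gmax_linear(GrowthParams(0.4, 8.76, 0.5, (0.1,)), MODEL_1,
                        records=pd.DataFrame({"debark": [0.1], "prun": [0.2]}))

    def test_negative_gmax_is_allowed_but_warned(self):
        p = GrowthParams(0.1, 8.76, 0.51, (0.0, -0.9))
        rec = pd.DataFrame({"debark": [0.0], "prun": [1.0]})
        with pytest.warns(UserWarning, match="negative"):
            g = gmax_linear(p, MODEL_1, records=rec)
        assert g[0] == pytest.approx(-0.8)


class TestLogLikelihood:
    def test_zero_residual_density(self):
        mu = mean_log_agr(10.0, P0)
        rec = pd.DataFrame({"tree_id": ["a"], "dbh_t0": [10.0], "agr": [math.expm1(mu)]})
        expected = -0.5 * math.log(2 * math.pi * 0.51**2)
        assert log_likelihood(rec, P0) == pytest.approx(expected, abs=1e-12)

    def test_additive_over_records(self):
        rec = _records(n=7, seed=1)
        total = log_likelihood(rec, P0)
        parts = sum(log_likelihood(rec.iloc[[i]], P0) for i in range(len(rec)))
        assert total == pytest.approx(parts, abs=1e-10)

    def test_matches_brute_force_normal_density_sum(self):
        rec = _records(n=20, seed=2)
        spec = MODEL_3.standardization_from(rec)
        p = GrowthParams(0.41, 8.76, 0.51, (-0.18, -0.10, 0.12))
        # independent oracle: per-record normal logpdf summation
        z = spec.trait_standardization["wd"].transform(rec["wd"])
        mu = (0.41 - 0.18 * rec["prun"] - 0.10 * z + 0.12 * rec["prun"] * z) * np.exp(
            -0.5 * np.log(rec["dbh_t0"] / 8.76) ** 2
        )
        oracle = float(norm.logpdf(np.log1p(rec["agr"]), loc=mu, scale=0.51).sum())
        assert log_likelihood(rec, p, spec) == pytest.approx(oracle, abs=1e-10)

    def test_invariant_to_record_order(self):
        rec = _records(n=30, seed=4)
        shuffled = rec.sample(frac=1.0, random_state=9).reset_index(drop=True)
        assert log_likelihood(rec, P0) == pytest.approx(
            log_likelihood(shuffled, P0), abs=1e-9
        )

    def test_agr_at_or_below_minus_one_lists_offenders(self):
        rec = _records(n=4, seed=5)
        rec.loc[2, "agr"] = -1.0
        with pytest.raises(ValueError, match="t2"):
            log_likelihood(rec, P0)


class TestSimulateAgr:
    def test_degenerate_noise_hits_the_mean_curve(self):
        p = GrowthParams(0.36, 8.76, 1e-12)
        dbh = np.array([3.0, 8.76, 40.0])
        agr = simulate_agr(dbh, p, seed=0)
        np.testing.assert_allclose(agr, np.expm1(mean_log_agr(dbh, p)), atol=1e-9)

    def test_monte_carlo_mean_matches_model_mean(self):
        n = 100_000
        agr = simulate_agr(np.full(n, 10.0), P0, seed=11)
        target = mean_log_agr(10.0, P0)
        se = P0.sigma / math.sqrt(n)
        assert abs(np.log1p(agr).mean() - target) < 3 * se

    def test_support_always_above_minus_one(self):
        agr = simulate_agr(np.full(5000, 5.0), GrowthParams(0.1, 8.76, 2.0), seed=3)
        assert np.all(agr > -1)

    def test_seeded_draws_are_reproducible(self):
        a = simulate_agr(np.linspace(2, 50, 100), P0, seed=42)
        b = simulate_agr(np.linspace(2, 50, 100), P0, seed=42)
        np.testing.assert_array_equal(a, b)


class TestSpecAndRecordValidation:
    def test_strong_heredity_enforced(self):
        with pytest.raises(ValueError, match="heredity"):
            GrowthModelSpec(covariates=("prun",), interactions=(("prun", "wd"),))

    def test_published_model_structures(self):
        assert MODEL_0.term_names == ()
        assert MODEL_1.term_names == ("debark", "prun")
        assert MODEL_2.term_names == ("wd", "lma")
        assert MODEL_3.term_names == ("prun", "wd", "prun:wd")

    def test_percent_scale_pruning_rejected_with_hint(self):
        with pytest.raises(ValueError, match="percent"):
            TreeRecord("t", "p", "z", False, 10.0, 10.5, 0.1, 45.0, 0.5, 58.0)

    def test_small_negative_agr_is_valid(self):
        r = TreeRecord("t", "p", "z", False, 10.0, 9.5, 0.1, 0.2, 0.5, 58.0)
        assert r.agr == pytest.approx(-0.5)

    def test_design_matrix_orders_mains_then_interactions(self):
        rec = _records(n=5, seed=6)
        spec = MODEL_3.standardization_from(rec)
        X = design_matrix(rec, spec)
        z = spec.trait_standardization["wd"].transform(rec["wd"])
        np.testing.assert_allclose(X[:, 2], X[:, 0] * X[:, 1])
        np.testing.assert_allclose(X[:, 1], z)
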