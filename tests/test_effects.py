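import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import constant_posterior
from treegrowth.effects import (
    binned_agr_summary,
    predicted_trajectory,
    pruning_cost,
    reserve_wd_test,
    zero_cost_wd,
)
from treegrowth.model import MODEL_0, MODEL_3, GrowthParams
from treegrowth.traits import REFERENCE_WD_STD, TraitStandardization

P3 = GrowthParams(0.41, 8.76, 0.51, (-0.18, -0.10, 0.12))
SPEC3 = MODEL_3  # carries the reference trait standardization


class TestZeroCostWd:
    def test_published_threshold(self):
        # theta_P = -0.18, theta_PxWD = 0.12, mean 0.56, sd ~0.1121 -> ~0.73
        assert zero_cost_wd(P3, SPEC3) == pytest.approx(0.728, abs=2e-3)

    def test_zero_main_effect_degenerates_to_mean(self):
        p = GrowthParams(0.41, 8.76, 0.51, (0.0, -0.10, 0.12))
        with pytest.warns(UserWarning, match="degenerates"):
            assert zero_cost_wd(p, SPEC3) == pytest.approx(0.56)

    def test_no_interaction_is_an_error(self):
        p = GrowthParams(0.41, 8.76, 0.51, (-0.18, -0.10, 0.0))
        with pytest.raises(ValueError, match="never vanishes"):
            zero_cost_wd(p, SPEC3)

    def test_cost_changes_sign_across_the_threshold(self):
        wd_star = zero_cost_wd(P3, SPEC3)
        grid = pruning_cost(P3, SPEC3, [8.76], [wd_star - 0.1, wd_star + 0.1])
        assert grid.cost[0, 0] > 0 > grid.cost[0, 1]


class TestPruningCost:
    def test_null_effects_give_zero_surface(self):
        p = GrowthParams(0.41, 8.76, 0.51, (0.0, -0.10, 0.0))
        grid = pruning_cost(p, SPEC3, np.geomspace(2, 80, 10), np.linspace(0.3, 0.8, 5))
        np.testing.assert_allclose(grid.cost, 0.0, atol=1e-14)

    def test_cost_vanishes_at_threshold_for_every_size(self):
        wd_star = REFERENCE_WD_STD.inverse([1.5])[0]
        grid = pruning_cost(P3, SPEC3, np.geomspace(2, 100, 25), [wd_star])
        np.testing.assert_allclose(grid.cost[:, 0], 0.0, atol=1e-12)

    def test_intermediate_sizes_pay_the_highest_cost(self):
        grid = pruning_cost(P3, SPEC3, [P3.dopt, 4 * P3.dopt], [0.35])
        assert grid.cost[0, 0] > grid.cost[1, 0] > 0

    def test_requires_interaction_terms(self):
        with pytest.raises(ValueError, match="prun:wd"):
            pruning_cost(GrowthParams(0.36, 8.76, 0.51), MODEL_0, [5.0], [0.5])

    def test_grid_must_be_monotone(self):
        with pytest.raises(ValueError, match="increasing"):
            pruning_cost(P3, SPEC3, [10.0, 5.0], [0.5])


def _pooled_t_oracle(x, y):
    """Textbook pooled-variance two-sample t-test."""
    from scipy.stats import t as tdist

    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    t = (np.mean(x) - np.mean(y)) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * tdist.sf(abs(t), nx + ny - 2)
    return t, p


def _reserve_frame(outside, inside):
    return pd.DataFrame(
        {
            "wd": np.concatenate([outside, inside]),
            "in_reserve": [False] * len(outside) + [True] * len(inside),
        }
    )


class TestReserveWdTest:
    def test_identical_groups(self):
        res = reserve_wd_test(_reserve_frame([0.5, 0.6, 0.7], [0.5, 0.6, 0.7]))
        assert res.mean_difference == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_example(self):
        out, ins = [0.5, 0.6, 0.7], [0.6, 0.7, 0.8]
        res = reserve_wd_test(_reserve_frame(out, ins))
        t, p = _pooled_t_oracle(out, ins)
        assert res.mean_difference == pytest.approx(-0.1)
        assert res.t_statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        assert res.dof == 4

    @given(
        data=st.data(),
        n1=st.integers(3, 20),
        n2=st.integers(3, 20),
    )
    def test_matches_textbook_formula_on_random_inputs(self, data, n1, n2):
        vals = st.floats(0.2, 1.2)
        out = data.draw(st.lists(vals, min_size=n1, max_size=n1))
        ins = data.draw(st.lists(vals, min_size=n2, max_size=n2))
        if np.var(out) + np.var(ins) == 0:
            return
        res = reserve_wd_test(_reserve_frame(out, ins))
        t, p = _pooled_t_oracle(out, ins)
        assert res.t_statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            reserve_wd_test(_reserve_frame([0.5, 0.6], [0.7]))

    def test_welch_variant_differs_under_unequal_variance(self):
        out = [0.4, 0.5, 0.6, 0.7, 0.8]
        ins = [0.59, 0.60, 0.61]
        student = reserve_wd_test(_reserve_frame(out, ins))
        welch = reserve_wd_test(_reserve_frame(out, ins), welch=True)
        assert student.dof == 6
        assert welch.dof != student.dof


class TestBinnedSummary:
    def test_single_bin_quartiles(self):
        rec = pd.DataFrame({"dbh_t0": [10.0] * 5, "agr": [1.0, 2.0, 3.0, 4.0, 5.0]})
        s = binned_agr_summary(rec, n_bins=1)
        assert (s.q1[0], s.median[0], s.q3[0]) == (2.0, 3.0, 4.0)
        assert s.counts[0] == 5
        assert s.outliers[0] == ()

    def test_identical_values_give_zero_width_box(self):
        rec = pd.DataFrame({"dbh_t0": np.linspace(2, 50, 40), "agr": [0.3] * 40})
        s = binned_agr_summary(rec, n_bins=4)
        assert np.nanmax(s.q3 - s.q1) == 0.0
        assert all(o == () for o in s.outliers)

    def test_counts_conserved_and_partition_disjoint(self, default_records):
        s = binned_agr_summary(default_records, n_bins=8)
        assert s.counts.sum() == len(default_records)
        for b in range(8):
            inside = ((default_records["agr"] >= s.whisker_lo[b]) & (default_records["agr"] <= s.whisker_hi[b]))
            # every bin's records are either within the whiskers or outliers
            in_bin = np.clip(
                np.digitize(default_records["dbh_t0"], s.bin_edges) - 1, 0, 7
            ) == b
            n_outliers = len(s.outliers[b])
            assert inside[in_bin].sum() + n_outliers == s.counts[b]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            binned_agr_summary(pd.DataFrame({"dbh_t0": [], "agr": []}))


class TestPredictedTrajectory:
    def test_point_mass_posterior_has_zero_width_envelope(self):
        res = constant_posterior(P3, SPEC3)
        out = predicted_trajectory(res, {"prun": 0.0, "wd": 0.56}, np.geomspace(2, 50, 10))
        np.testing.assert_allclose(out["hi_97.5%"] - out["lo_2.5%"], 0.0, atol=1e-14)

    def test_envelope_contains_median(self, model0_records):
        from treegrowth.mcmc import fit_model
        from conftest import quick_mcmc

        res = fit_model(model0_records, MODEL_0, mcmc=quick_mcmc(4, iterations=2000))
        out = predicted_trajectory(res, {}, np.geomspace(2, 60, 15), max_draws=400)
        assert (out["lo_2.5%"] <= out["median"]).all()
        assert (out["median"] <= out["hi_97.5%"]).all()

    def test_difference_of_trajectories_equals_pruning_cost(self):
        res = constant_posterior(P3, SPEC3)
        dbh = np.geomspace(2, 50, 12)
        wd = 0.45
        unpruned = predicted_trajectory(res, {"prun": 0.0, "wd": wd}, dbh)
        pruned = predicted_trajectory(res, {"prun": 1.0, "wd": wd}, dbh)
        grid = pruning_cost(P3, SPEC3, dbh, [wd])
        np.testing.assert_allclose(
            (unpruned["median"] - pruned["median"]).to_numpy(), grid.cost[:, 0], atol=1e-12
        )
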