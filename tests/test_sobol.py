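"""Sobol' estimators against analytic values and the double-loop MC oracle."""

import numpy as np
import pytest

from fluxsens import (
    analyze,
    bootstrap_confidence,
    estimate_first_order,
    estimate_total_order,
    evaluate_function,
    interaction_gap,
    rank_factors,
)
from fluxsens.errors import DegenerateOutputError
from fluxsens.fixtures import (
    additive_function,
    centered_product_function,
    min_function,
)
from fluxsens.saltelli import saltelli_design
from fluxsens.sobol import EvaluationSet, SensitivityResult, estimate_second_order
from oracles import double_loop_sobol

N = 1024


def _indices(f, D, bounds, second_order=False):
    design = saltelli_design(N, D, bounds=[bounds] * D, second_order=second_order)
    evals = evaluate_function(f, design)
    return design, evals


class TestAnalyticFixtures:
    def test_additive_symmetric_halves(self):
        design, evals = _indices(lambda X: X[:, 0] + X[:, 1], 2, (0.0, 1.0))
        S1 = estimate_first_order(evals, design)
        ST = estimate_total_order(evals, design)
        assert np.allclose(S1, 0.5, atol=0.05)
        assert np.allclose(ST, 0.5, atol=0.05)
        assert np.allclose(ST, S1, atol=0.05)  # no interactions

    def test_centered_product_pure_interaction(self):
        design, evals = _indices(centered_product_function, 2, (0.0, 1.0))
        assert np.allclose(estimate_first_order(evals, design), 0.0, atol=0.05)
        assert np.allclose(estimate_total_order(evals, design), 1.0, atol=0.05)

    def test_min_coupled_analytic_values(self):
        # E[min | X_i = x] = x - x^2/2 gives Var 1/45 against Var(min) = 1/18
        design, evals = _indices(min_function, 2, (-10.0, 0.0))
        assert np.allclose(estimate_first_order(evals, design), 0.4, atol=0.05)
        assert np.allclose(estimate_total_order(evals, design), 0.6, atol=0.05)

    def test_weighted_additive_variance_shares(self):
        f = additive_function((2.0, 1.0))
        design, evals = _indices(f, 2, (-10.0, 0.0))
        assert np.allclose(estimate_first_order(evals, design), [0.8, 0.2], atol=0.05)


class TestOracleCrossCheck:
    @pytest.mark.parametrize(
        "f,D,bounds",
        [
            (min_function, 2, (0.0, 1.0)),
            (additive_function((1.0, 1.0)), 2, (0.0, 1.0)),
        ],
    )
    def test_within_three_standard_errors(self, f, D, bounds):
        design, evals = _indices(f, D, bounds)
        S1 = estimate_first_order(evals, design)
        ST = estimate_total_order(evals, design)
        o_S1, o_ST, o_S1_se, o_ST_se = double_loop_sobol(
            f, D, n_outer=300, n_inner=300, seed=7
        )
        # 3 oracle standard errors plus a small allowance for the QMC
        # estimator's own error at N=1024
        assert np.all(np.abs(S1 - o_S1) <= 3 * o_S1_se + 0.02)
        assert np.all(np.abs(ST - o_ST) <= 3 * o_ST_se + 0.02)


class TestSecondOrder:
    def test_product_interaction_captured(self):
        design, evals = _indices(centered_product_function, 2, (0.0, 1.0), second_order=True)
        S2 = estimate_second_order(evals, design)
        assert S2[0, 1] == pytest.approx(1.0, abs=0.1)

    def test_requires_second_order_design(self):
        design, evals = _indices(min_function, 2, (0.0, 1.0))
        with pytest.raises(ValueError):
            estimate_second_order(evals, design)


class TestBootstrap:
    def test_shapes_and_nonnegative(self):
        design, evals = _indices(min_function, 2, (0.0, 1.0))
        s1c, stc = bootstrap_confidence(evals, design, n_boot=50, seed=3)
        assert s1c.shape == stc.shape == (2,)
        assert np.all(s1c >= 0) and np.all(stc >= 0)

    def test_deterministic_under_seed(self):
        design, evals = _indices(min_function, 2, (0.0, 1.0))
        a = bootstrap_confidence(evals, design, n_boot=30, seed=11)
        b = bootstrap_confidence(evals, design, n_boot=30, seed=11)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_halfwidths_shrink_with_n(self):
        f = additive_function((1.0, 1.0))
        widths = []
        for n in (256, 4096):
            design = saltelli_design(n, 2)
            evals = evaluate_function(f, design)
            s1c, stc = bootstrap_confidence(evals, design, n_boot=100, seed=5)
            widths.append(np.mean(np.concatenate([s1c, stc])))
        assert widths[1] < widths[0]


class TestDegenerateAndGaps:
    def test_constant_output_raises(self):
        design = saltelli_design(16, 2)
        evals = EvaluationSet(Y=np.full(design.n_rows, 3.0))
        with pytest.raises(DegenerateOutputError, match="3.0"):
            estimate_first_order(evals, design)

    def test_additive_gap_near_zero(self):
        design, evals = _indices(additive_function((1.0, 1.0)), 2, (-10.0, 0.0))
        result = analyze(evals, design, n_boot=20, seed=0)
        assert np.allclose(interaction_gap(result), 0.0, atol=0.05)

    def test_min_coupled_gap(self):
        design, evals = _indices(min_function, 2, (-10.0, 0.0))
        result = analyze(evals, design, n_boot=20, seed=0)
        assert np.allclose(interaction_gap(result), 0.2, atol=0.05)

    def test_negative_gaps_preserved(self):
        result = SensitivityResult(
            factor_names=["a", "b"],
            S1=np.array([0.5, 0.3]),
            ST=np.array([0.45, 0.5]),
        )
        assert interaction_gap(result)[0] == pytest.approx(-0.05)


class TestRanking:
    def test_descending_order(self):
        result = SensitivityResult(
            factor_names=["a", "b", "c"],
            S1=np.array([0.3, 0.5, 0.1]),
            ST=np.array([0.3, 0.5, 0.1]),
        )
        assert rank_factors(result, by="first") == ["b", "a", "c"]

    def test_ties_break_lexicographically(self):
        result = SensitivityResult(
            factor_names=["z", "a", "m"],
            S1=np.array([0.2, 0.2, 0.2]),
            ST=np.array([0.2, 0.2, 0.2]),
        )
        assert rank_factors(result, by="total") == ["a", "m", "z"]

    def test_first_and_total_orders_can_differ(self):
        # factor a: strong main effect, no interaction; factor b: weak main
        # effect but dominant interaction pushes its total above a's
        result = SensitivityResult(
            factor_names=["a", "b"],
            S1=np.array([0.35, 0.25]),
            ST=np.array([0.40, 0.65]),
        )
        assert rank_factors(result, by="first") != rank_factors(result, by="total")

    def test_result_tables_and_rankings_consistent(self):
        design, evals = _indices(additive_function((2.0, 1.0)), 2, (-10.0, 0.0))
        result = analyze(evals, design, n_boot=20, seed=1)
        table = result.to_table()
        assert list(table.columns[:5]) == ["factor", "S1", "S1_conf", "ST", "ST_conf"]
        assert result.ranking_first[0] == "x0"  # higher yield dominates
        assert sorted(result.ranking_total) == sorted(result.factor_names)
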