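"""Tests for the genetic-programming symbolic regression engine."""

import numpy as np
import pytest

from odclearn import symreg
from odclearn.symreg import (
    Node,
    OperatorSet,
    SRConfig,
    evaluate_expression,
    fit_symbolic,
    fold_constants,
    learned_model_predict,
    match_canonical_form,
    parse_expression,
    prune_negligible,
)


def sample_inputs(rng, n=120):
    X = np.empty((n, 5))
    X[:, 0] = rng.uniform(7.0, 7.6, n)
    X[:, 1] = rng.uniform(3, 9, n)
    X[:, 2] = rng.uniform(0, 0.02, n)
    X[:, 3] = rng.uniform(35, 39, n)
    X[:, 4] = np.exp(rng.uniform(np.log(2), np.log(15), n))
    return X


class TestEvaluation:
    def test_ground_truth_expression(self, rng):
        expr = parse_expression("0.25*cos(6.283185307179586*ln(p)) - 0.55")
        X = sample_inputs(rng)
        expected = 0.25 * np.cos(2 * np.pi * np.log(X[:, 4])) - 0.55
        np.testing.assert_allclose(evaluate_expression(expr, X), expected, atol=1e-12)

    def test_identity_expression(self, rng):
        X = sample_inputs(rng)
        np.testing.assert_array_equal(evaluate_expression("p", X), X[:, 4])

    def test_expression_constant_along_unused_inputs(self, rng):
        expr = parse_expression("cos(ln(p))")
        X = sample_inputs(rng)
        X2 = X.copy()
        X2[:, 0] += 0.1  # vary pH only
        np.testing.assert_array_equal(
            evaluate_expression(expr, X), evaluate_expression(expr, X2)
        )

    def test_protected_division_and_log_stay_finite(self, rng):
        X = sample_inputs(rng)
        p = Node("var", var=4)
        zero = Node("sub", (p, Node("var", var=4)))
        cases = [
            Node("div", (Node("const", value=1.0), zero)),   # 1 / 0
            Node("ln", (zero.copy(),)),                      # ln 0
            Node("ln", (Node("const", value=-3.0),)),        # ln of negative
            Node("exp", (Node("mul", (p, p)),)),             # overflow guard
        ]
        for expr in cases:
            out = evaluate_expression(expr, X)
            assert np.all(np.isfinite(out))

    def test_parse_round_trip(self, rng):
        X = sample_inputs(rng)
        expr = parse_expression("(0.3 * sin(2.0 * ln(p))) - (pH / 4.0)")
        back = parse_expression(expr.to_string())
        np.testing.assert_allclose(
            evaluate_expression(expr, X), evaluate_expression(back, X), atol=1e-12
        )


class TestCompiledEvaluation:
    def test_compiled_matches_recursive_on_random_trees(self, rng):
        from odclearn.symreg import OperatorSet, _random_tree, compile_tree

        X = sample_inputs(rng, 60)
        tree_rng = np.random.default_rng(99)
        ops = OperatorSet()
        for _ in range(40):
            tree = _random_tree(tree_rng, ops, depth=4, n_vars=5, full=False)
            consts = np.array([c.value for c in tree.const_nodes()])
            fn = compile_tree(tree)
            with np.errstate(all="ignore"):
                a = tree.evaluate(X)
                b = fn(X, consts)
            np.testing.assert_array_equal(a, b)


class TestSimplification:
    def test_fold_constants(self):
        expr = parse_expression("(2.0 + 3.0) * p")
        folded = fold_constants(expr)
        assert folded.size() <= 3
        X = np.ones((1, 5)) * 2.0
        assert folded.evaluate(X)[0] == pytest.approx(10.0)

    def test_prune_drops_negligible_terms(self, rng):
        X = sample_inputs(rng)
        y = 0.25 * np.cos(2 * np.pi * np.log(X[:, 4])) - 0.55
        expr = parse_expression(
            "0.25*cos(6.283185307179586*ln(p)) - 0.55 + 1e-15*p"
        )
        pruned, mse = prune_negligible(expr, X, y)
        assert mse < 1e-12
        assert "1e-15" not in pruned.to_string()
        assert pruned.size() <= 9


class TestSearch:
    def test_linear_recovery(self, rng):
        X = sample_inputs(rng)
        y = 2.0 * X[:, 0] + 1.0
        res = fit_symbolic(X, y, config=SRConfig(seed=0))
        assert res.best.mse < 1e-8

    def test_constant_target(self, rng):
        X = sample_inputs(rng)
        y = np.full(len(X), 3.25)
        res = fit_symbolic(X, y, config=SRConfig(seed=0, generations=4, population_size=64))
        assert res.best.mse < 1e-10
        assert res.best.complexity <= 3

    @pytest.mark.parametrize(
        "target_seed, expression",
        [
            (0, "0.8*exp(0.2*T_scaled)"),
            (1, "sin(1.5*p) + 0.3"),
            (2, "pH * PCO2 / 10.0"),
            (3, "ln(p) * -0.7"),
            (4, "cos(2.0*ln(p)) * 0.5 - 0.1"),
        ],
    )
    def test_in_space_recovery(self, rng, target_seed, expression):
        # targets generated by small expressions over the operator set are
        # recovered essentially exactly at the default budget
        X = sample_inputs(np.random.default_rng(100 + target_seed))
        if "T_scaled" in expression:
            expression = expression.replace("T_scaled", "(T / 40.0)")
        y = evaluate_expression(parse_expression(expression), X)
        res = fit_symbolic(X, y, config=SRConfig(seed=target_seed))
        assert res.best.mse < 1e-6

    def test_determinism(self, rng):
        X = sample_inputs(rng)
        y = 0.5 * np.log(X[:, 4]) - 0.2
        cfg = SRConfig(seed=3, generations=5, population_size=64)
        r1 = fit_symbolic(X, y, config=cfg)
        r2 = fit_symbolic(X, y, config=cfg)
        assert r1.best.to_string() == r2.best.to_string()
        assert r1.best.mse == r2.best.mse

    def test_warm_start_never_worse(self, rng):
        X = sample_inputs(rng)
        y = 0.25 * np.cos(2 * np.pi * np.log(X[:, 4])) - 0.55 + 0.01 * rng.normal(size=len(X))
        cfg = SRConfig(seed=5, generations=6, population_size=64)
        first = fit_symbolic(X, y, config=cfg)
        resumed = fit_symbolic(X, y, config=cfg, warm_start=first)
        assert resumed.best_mse <= first.best_mse + 1e-15

    def test_too_few_pairs_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_symbolic(np.zeros((5, 5)), np.zeros(5))


class TestLearnedModel:
    def test_zero_expression_reference(self):
        expr = Node("const", value=0.0)
        X = np.array([[7.40, 5.33, 0.0, 37.0, 7.0]])
        assert learned_model_predict(expr, X)[0] == pytest.approx(0.867, abs=1e-12)

    def test_ground_truth_substitution(self, rng):
        from odclearn.sa_model import sa_predict_matrix
        from odclearn.synthetic import ground_truth_a4

        expr = parse_expression("0.25*cos(6.283185307179586*ln(p)) - 0.55")
        X = sample_inputs(rng)
        np.testing.assert_allclose(
            learned_model_predict(expr, X),
            sa_predict_matrix(X, a4_override=ground_truth_a4(X[:, 4])),
            atol=1e-10,
        )


class TestCanonicalForm:
    def test_reported_low_noise_expression(self):
        # the published low-noise distillation: 0.2476 cos(6.2762 ln p) - 0.5477
        fit = match_canonical_form(parse_expression("0.2476*cos(6.2762*ln(p)) - 0.5477"))
        assert fit is not None
        assert fit.alpha == pytest.approx(0.2476, abs=1e-9)
        assert fit.beta == pytest.approx(6.2762, abs=1e-9)
        assert fit.gamma == pytest.approx(-0.5477, abs=1e-9)

    def test_non_matching_forms(self):
        assert match_canonical_form(parse_expression("2.0*p + 1.0")) is None
        # cosine of p itself (the high-noise failure mode) is not in the family
        assert match_canonical_form(parse_expression("0.26*cos(p - 1.43) - 0.57")) is None

    def test_phase_folding(self):
        fit = match_canonical_form(
            parse_expression("-0.25*cos(6.283185307179586*ln(p) + 3.14159265358979) - 0.55")
        )
        assert fit is not None
        assert fit.alpha == pytest.approx(0.25, abs=1e-6)
        assert fit.beta == pytest.approx(2 * np.pi, abs=1e-9)
        assert fit.gamma == pytest.approx(-0.55, abs=1e-9)
        assert fit.phase == pytest.approx(0.0, abs=1e-6)

    def test_sin_folded_into_cosine(self):
        fit = match_canonical_form(parse_expression("0.3*sin(2.0*ln(p)) + 0.1"))
        assert fit is not None
        assert fit.beta == pytest.approx(2.0, abs=1e-9)
        assert abs(fit.alpha) == pytest.approx(0.3, abs=1e-9)

    def test_negative_frequency_normalized(self):
        fit = match_canonical_form(parse_expression("0.25*cos(-6.2832*ln(p)) - 0.55"))
        assert fit is not None
        assert fit.beta == pytest.approx(6.2832, abs=1e-9)
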