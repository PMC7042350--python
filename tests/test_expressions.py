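"""Expression trees: protected evaluation, parsing, fixtures, sign analysis."""

import hashlib
from importlib import resources

import numpy as np
import pytest
import sympy

from gyretrend import gp
from gyretrend.expressions import (
    Binary, Const, Unary, Var,
    N_VARIABLES, NotSumOfProducts, ParseError,
    complexity, depth, evaluate, fixture_equation_texts, fixture_equations,
    parse, sign_table, term_sign_analysis, to_text, variables_used,
)


def rec(**kw):
    """A single feature record as a length-12 vector (defaults 0)."""
    x = np.zeros(12)
    for k, v in kw.items():
        x[int(k[1:]) - 1] = v
    return x


class TestEvaluate:
    def test_published_eq5_constant_term(self):
        eq5 = fixture_equations()[4]
        assert evaluate(eq5, rec())[0] == pytest.approx(1.196e5)

    def test_published_eq5_density_term(self):
        # 1.196e5 - 1.18e5 * 1 = 1600 at x4=1, other terms zero
        eq5 = fixture_equations()[4]
        assert evaluate(eq5, rec(x4=1.0))[0] == pytest.approx(1600.0)

    @pytest.mark.parametrize("text,x,expected", [
        ("2*x1 + 3", rec(x1=5.0), 13.0),
        ("x5^2", rec(x5=3.0), 9.0),
        ("gauss(x1)", rec(x1=0.0), 1.0),
        ("logistic(x1)", rec(x1=0.0), 0.5),
    ])
    def test_arithmetic(self, text, x, expected):
        assert evaluate(parse(text), x)[0] == pytest.approx(expected)

    @pytest.mark.parametrize("text,x", [
        ("ln(x6)", rec(x6=0.0)),        # log of non-positive
        ("x1 / x6", rec(x1=1.0)),       # division by zero
        ("asin(x1)", rec(x1=2.0)),      # inverse trig out of domain
        ("1 + ln(x6 - 5)", rec(x6=1.0)),  # non-finite propagates upward
    ])
    def test_protected_ops_flag_not_raise(self, text, x):
        out = evaluate(parse(text), x)
        assert not np.isfinite(out[0])

    def test_malformed_tree_is_a_structural_error(self):
        with pytest.raises(TypeError):
            evaluate("not a tree", rec())  # type: ignore[arg-type]


class TestParse:
    def test_small_expression_node_count_and_roundtrip(self):
        e = parse("2*x1 + sin(x2)")
        # nodes: +, *, 2, x1, sin, x2
        assert complexity(e) == 6
        X = np.random.default_rng(0).normal(size=(10, 12))
        np.testing.assert_allclose(evaluate(parse(to_text(e)), X), evaluate(e, X))

    def test_variable_out_of_range(self):
        with pytest.raises(ParseError):
            parse("x13")

    def test_unbalanced_parentheses_reports_position(self):
        with pytest.raises(ParseError, match="position"):
            parse("sin(x1")

    def test_unknown_identifier(self):
        with pytest.raises(ParseError):
            parse("foo(x1)")

    def test_power_expands_to_multiplication(self):
        e = parse("x3^2")
        assert isinstance(e, Binary) and e.op == "*"
        assert evaluate(e, rec(x3=4.0))[0] == 16.0

    def test_scientific_notation_forms(self):
        assert evaluate(parse("1.18e5"), rec())[0] == 1.18e5
        assert evaluate(parse("2.427e-7"), rec())[0] == 2.427e-7
        assert evaluate(parse("1e5"), rec())[0] == 1e5

    @pytest.mark.parametrize("seed", range(50))
    def test_roundtrip_preserves_evaluation_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        cfg = gp.GPConfig(max_depth=5)
        tree = gp._random_tree(cfg, rng, 5, full=seed % 2 == 0)
        X = rng.uniform(-3, 3, size=(20, 12))
        a = evaluate(tree, X)
        b = evaluate(parse(to_text(tree)), X)
        mask = np.isfinite(a)
        assert np.array_equal(mask, np.isfinite(b))
        np.testing.assert_allclose(a[mask], b[mask], rtol=1e-12)


class TestFixtures:
    def test_ten_equations_parse(self):
        eqs = fixture_equations()
        assert len(eqs) == 10

    def test_transcription_frozen_by_checksum(self):
        raw = resources.files("gyretrend.data").joinpath("equations.txt").read_bytes()
        digest = hashlib.sha256(raw).hexdigest()
        assert digest == "87673c36a13bb993701018f3c3d5ca41172c199e251c6f91910dda144dda47bf"

    def test_eq10_contains_high_frequency_fucoxanthin_term(self):
        assert "57.83*sin(1959*x9)" in fixture_equation_texts()[9].replace(" ", "")

    def test_eq5_uses_exactly_three_variables(self):
        assert variables_used(fixture_equations()[4]) == {4, 5, 11}


class TestSignAnalysis:
    def test_temperature_negative_in_nine_of_ten(self):
        labels = [term_sign_analysis(e, 5).label for e in fixture_equations()]
        assert labels.count("negative") == 9

    def test_density_gradient_negative_in_eight_of_ten(self):
        labels = [term_sign_analysis(e, 4).label for e in fixture_equations()]
        assert labels.count("negative") == 8

    def test_day_of_year_absent_from_all(self):
        assert all(term_sign_analysis(e, 2).label == "absent"
                   for e in fixture_equations())

    def test_fucoxanthin_positive_in_seven_of_ten(self):
        labels = [term_sign_analysis(e, 9).label for e in fixture_equations()]
        assert labels.count("positive") == 7

    def test_oscillatory_wrapper_is_mixed(self):
        assert term_sign_analysis(parse("sin(x3)"), 3).label == "mixed"

    def test_squared_negative_term(self):
        # -c * x3 * x5^2 decreases in x5 over the positive range
        e = parse("10 - 0.00675*x3*x5^2")
        assert term_sign_analysis(e, 5).label == "negative"

    def test_division_falls_back_with_warning(self):
        with pytest.warns(UserWarning):
            with pytest.raises(NotSumOfProducts):
                term_sign_analysis(parse("x1 / x2"), 1)

    def test_sign_table_covers_all_variables(self):
        table = sign_table(fixture_equations()[3])
        assert set(table) == set(range(1, 13))
        assert table[5] == "negative" and table[9] == "positive"


class TestInvariants:
    @pytest.mark.parametrize("seed", range(20))
    def test_complexity_additive_and_positive(self, seed):
        rng = np.random.default_rng(seed)
        cfg = gp.GPConfig()
        tree = gp._random_tree(cfg, rng, 6, full=False)
        assert complexity(tree) >= 1
        if isinstance(tree, Binary):
            assert complexity(tree) == 1 + complexity(tree.left) + complexity(tree.right)
        elif isinstance(tree, Unary):
            assert complexity(tree) == 1 + complexity(tree.child)
        assert depth(tree) <= 6


_SYMPY_UNARY = {
    "sin": sympy.sin, "cos": sympy.cos, "tan": sympy.tan,
    "asin": sympy.asin, "acos": sympy.acos, "atan": sympy.atan,
    "sinh": sympy.sinh, "cosh": sympy.cosh, "tanh": sympy.tanh,
    "exp": sympy.exp, "ln": sympy.log,
    "logistic": lambda u: 1 / (1 + sympy.exp(-u)),
    "gauss": lambda u: sympy.exp(-u**2),
    "negate": lambda u: -u,
}
_SYMS = sympy.symbols("x1:13")


def _to_sympy(node):
    if isinstance(node, Const):
        return sympy.Float(node.value)
    if isinstance(node, Var):
        return _SYMS[node.index - 1]
    if isinstance(node, Unary):
        return _SYMPY_UNARY[node.op](_to_sympy(node.child))
    ops = {"+": lambda a, b: a + b, "-": lambda a, b: a - b,
           "*": lambda a, b: a * b, "/": lambda a, b: a / b}
    return ops[node.op](_to_sympy(node.left), _to_sympy(node.right))


def test_evaluation_agrees_with_symbolic_oracle():
    """1,000 random trees x random inputs vs an independent sympy route,
    1e-9 relative tolerance, protected-fallback rows excluded."""
    cfg = gp.GPConfig(max_depth=4)
    rng = np.random.default_rng(123)
    checked = 0
    for _ in range(1000):
        tree = gp._random_tree(cfg, rng, 4, full=False)
        X = rng.uniform(-2.0, 2.0, size=(5, 12))
        mine = evaluate(tree, X)
        try:
            f = sympy.lambdify(_SYMS, _to_sympy(tree), modules="numpy")
        except KeyError:
            continue  # tree simplifies to a symbolic infinity (exact 1/0)
        with np.errstate(all="ignore"):
            ref = np.asarray(f(*[X[:, i] for i in range(12)]), dtype=complex)
        ref = np.where(np.abs(ref.imag) > 1e-12, np.nan, ref.real)
        ref = np.broadcast_to(ref, mine.shape)
        mask = np.isfinite(mine) & np.isfinite(ref)
        if mask.any():
            np.testing.assert_allclose(mine[mask], ref[mask],
                                       rtol=1e-9, atol=1e-9)
            checked += int(mask.sum())
    assert checked > 1000  # plenty of non-degenerate comparisons happened
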