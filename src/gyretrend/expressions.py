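"""Expression trees over the symbolic-regression function set.

The model space is the classic Koza-style tree language used by commercial
symbolic-regression tools: binary arithmetic (+, -, *, /), the trigonometric
functions and their hyperbolic and inverse versions, exp, natural log, the
logistic function, and the Gaussian kernel ``gauss(u) = exp(-u**2)``.
Terminals are real constants and the twelve predictor variables ``x1``..``x12``
(Julian day, day of year, mixed-layer depth, density gradient, mean
temperature, nitrate, phosphate, silicate, fucoxanthin, chlorophyll b,
chlorophyll a, lutein+zeaxanthin).

Evaluation is vectorised over a feature matrix and uses *protected*
semantics: division by (near-)zero, log of a non-positive value and inverse
trigonometric calls outside [-1, 1] yield a non-finite value that propagates
upward instead of raising.  The fitness layer maps any non-finite output to
the worst possible fitness.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterator, Sequence

import numpy as np

__all__ = [
    "N_VARIABLES",
    "FEATURE_COLUMNS",
    "Const",
    "Var",
    "Unary",
    "Binary",
    "Expression",
    "ParseError",
    "NotSumOfProducts",
    "SignClassification",
    "evaluate",
    "parse",
    "to_text",
    "complexity",
    "depth",
    "fixture_equations",
    "fixture_equation_texts",
    "term_sign_analysis",
    "sign_table",
]

N_VARIABLES = 12

#: CSV/table column for each variable index (x1..x12), in order.
FEATURE_COLUMNS = (
    "jday", "yday", "mld", "dgrad", "temp", "no3",
    "po4", "sio2", "fuco", "chlb", "chla", "lutzea",
)

_DIV_EPS = 1e-12


def _protected_div(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.divide(a, b, where=np.abs(b) >= _DIV_EPS,
                    out=np.full(np.broadcast(a, b).shape, np.nan))
    return out


def _ln(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return np.log(a, where=a > 0, out=np.full(a.shape, np.nan))


def _logistic(a: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-a))


def _gauss(a: np.ndarray) -> np.ndarray:
    return np.exp(-np.square(a))


UNARY_OPS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sin": np.sin,
    "cos": np.cos,
    "tan": np.tan,
    "asin": np.arcsin,
    "acos": np.arccos,
    "atan": np.arctan,
    "sinh": np.sinh,
    "cosh": np.cosh,
    "tanh": np.tanh,
    "exp": np.exp,
    "ln": _ln,
    "logistic": _logistic,
    "gauss": _gauss,
    "negate": np.negative,
}

BINARY_OPS: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "+": np.add,
    "-": np.subtract,
    "*": np.multiply,
    "/": _protected_div,
}

# Unary wrappers whose output sign is known regardless of the argument.
_POSITIVE_UNARY = {"exp", "cosh", "gauss", "logistic", "acos"}
# Odd, monotone-increasing wrappers: output sign equals argument sign.
_SIGN_PRESERVING_UNARY = {"sinh", "tanh", "atan", "asin"}
# Bounded oscillatory wrappers.
_OSCILLATORY_UNARY = {"sin", "cos", "tan"}


@dataclass(frozen=True)
class Const:
    value: float

    def copy(self) -> "Const":
        return Const(self.value)


@dataclass(frozen=True)
class Var:
    index: int  # 1-based, in 1..12

    def __post_init__(self) -> None:
        if not (1 <= self.index <= N_VARIABLES):
            raise ValueError(f"variable index {self.index} outside 1..{N_VARIABLES}")

    def copy(self) -> "Var":
        return Var(self.index)


@dataclass(frozen=True)
class Unary:
    op: str
    child: "Expression"

    def __post_init__(self) -> None:
        if self.op not in UNARY_OPS:
            raise ValueError(f"unknown unary operator {self.op!r}")

    def copy(self) -> "Unary":
        return Unary(self.op, self.child.copy())


@dataclass(frozen=True)
class Binary:
    op: str
    left: "Expression"
    right: "Expression"

    def __post_init__(self) -> None:
        if self.op not in BINARY_OPS:
            raise ValueError(f"unknown binary operator {self.op!r}")

    def copy(self) -> "Binary":
        return Binary(self.op, self.left.copy(), self.right.copy())


Expression = Const | Var | Unary | Binary


def evaluate(expr: Expression, X: np.ndarray | Sequence[float]) -> np.ndarray:
    """Evaluate ``expr`` over a feature matrix.

    Parameters
    ----------
    expr
        The expression tree.
    X
        Array of shape ``(n, 12)`` (or a single length-12 record) giving the
        predictor values for ``x1``..``x12``.

    Returns
    -------
    ndarray of shape ``(n,)``.  Rows where a protected operation failed are
    non-finite (nan/inf); malformed trees raise ``TypeError`` instead.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != N_VARIABLES:
        raise ValueError(f"feature matrix must have {N_VARIABLES} columns, got {X.shape[1]}")
    with np.errstate(all="ignore"):
        out = _eval(expr, X)
    return np.broadcast_to(out, (X.shape[0],)).astype(float, copy=True)


def _eval(expr: Expression, X: np.ndarray) -> np.ndarray:
    if isinstance(expr, Const):
        return np.full(X.shape[0], float(expr.value))
    if isinstance(expr, Var):
        return X[:, expr.index - 1]
    if isinstance(expr, Unary):
        return UNARY_OPS[expr.op](_eval(expr.child, X))
    if isinstance(expr, Binary):
        return BINARY_OPS[expr.op](_eval(expr.left, X), _eval(expr.right, X))
    raise TypeError(f"malformed expression node: {expr!r}")


def complexity(expr: Expression) -> int:
    """Node count; >= 1 and additive over subtrees."""
    if isinstance(expr, (Const, Var)):
        return 1
    if isinstance(expr, Unary):
        return 1 + complexity(expr.child)
    return 1 + complexity(expr.left) + complexity(expr.right)


def depth(expr: Expression) -> int:
    """Depth of the tree; a lone terminal has depth 1."""
    if isinstance(expr, (Const, Var)):
        return 1
    if isinstance(expr, Unary):
        return 1 + depth(expr.child)
    return 1 + max(depth(expr.left), depth(expr.right))


def variables_used(expr: Expression) -> set[int]:
    if isinstance(expr, Var):
        return {expr.index}
    if isinstance(expr, Const):
        return set()
    if isinstance(expr, Unary):
        return variables_used(expr.child)
    return variables_used(expr.left) | variables_used(expr.right)


# ---------------------------------------------------------------------------
# Parsing / printing
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    """Raised on malformed expression text; carries the token position."""

    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN_RE = re.compile(
    r"\s*(?:"
    r"(?P<number>\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z_0-9]*)"
    r"|(?P<op>[-+*/^()])"
    r")"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos].isspace():
                pos += 1
                continue
            raise ParseError(f"unknown token {text[pos]!r}", pos)
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser for the printed-equation dialect.

    Grammar (integer powers are expanded to repeated multiplication, so
    ``x5^2`` parses to ``x5*x5``; there is no power operator in the
    function set)::

        expr   := term (('+'|'-') term)*
        term   := unary (('*'|'/') unary)*
        unary  := '-' unary | power
        power  := atom ('^' integer)?
        atom   := number | variable | func '(' expr ')' | '(' expr ')'
    """

    def __init__(self, text: str) -> None:
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of input", len(self.text))
        self.i += 1
        return tok

    def expect_op(self, op: str) -> None:
        tok = self.peek()
        if tok is None or tok[0] != "op" or tok[1] != op:
            pos = tok[2] if tok else len(self.text)
            raise ParseError(f"expected {op!r}", pos)
        self.i += 1

    def parse(self) -> Expression:
        e = self.expr()
        tok = self.peek()
        if tok is not None:
            raise ParseError(f"unexpected trailing token {tok[1]!r}", tok[2])
        return e

    def expr(self) -> Expression:
        e = self.term()
        while (tok := self.peek()) and tok[0] == "op" and tok[1] in "+-":
            self.i += 1
            rhs = self.term()
            e = Binary(tok[1], e, rhs)
        return e

    def term(self) -> Expression:
        e = self.unary()
        while (tok := self.peek()) and tok[0] == "op" and tok[1] in "*/":
            self.i += 1
            rhs = self.unary()
            e = Binary(tok[1], e, rhs)
        return e

    def unary(self) -> Expression:
        tok = self.peek()
        if tok and tok[0] == "op" and tok[1] == "-":
            self.i += 1
            child = self.unary()
            if isinstance(child, Const):
                return Const(-child.value)
            return Unary("negate", child)
        return self.power()

    def power(self) -> Expression:
        base = self.atom()
        tok = self.peek()
        if tok and tok[0] == "op" and tok[1] == "^":
            self.i += 1
            exp_tok = self.next()
            if exp_tok[0] != "number" or not exp_tok[1].isdigit():
                raise ParseError("exponent must be a positive integer", exp_tok[2])
            n = int(exp_tok[1])
            if n < 1:
                raise ParseError("exponent must be >= 1", exp_tok[2])
            e = base
            for _ in range(n - 1):
                e = Binary("*", e, base.copy())
            return e
        return base

    def atom(self) -> Expression:
        tok = self.next()
        kind, value, pos = tok
        if kind == "number":
            return Const(float(value))
        if kind == "name":
            if re.fullmatch(r"x\d+", value):
                idx = int(value[1:])
                if not (1 <= idx <= N_VARIABLES):
                    raise ParseError(f"variable {value} out of range x1..x{N_VARIABLES}", pos)
                return Var(idx)
            if value in UNARY_OPS:
                self.expect_op("(")
                child = self.expr()
                self.expect_op(")")
                return Unary(value, child)
            raise ParseError(f"unknown identifier {value!r}", pos)
        if kind == "op" and value == "(":
            e = self.expr()
            self.expect_op(")")
            return e
        raise ParseError(f"unexpected token {value!r}", pos)


def parse(text: str) -> Expression:
    """Parse infix text (the printed-equation dialect) into an Expression."""
    return _Parser(text).parse()


def _fmt_const(v: float) -> str:
    if v == int(v) and abs(v) < 1e15:
        return repr(int(v))
    return repr(v)


def to_text(expr: Expression, _parent_prec: int = 0) -> str:
    """Render an expression as parseable infix text (round-trips via parse)."""
    if isinstance(expr, Const):
        s = _fmt_const(expr.value)
        if expr.value < 0 and _parent_prec > 0:
            return f"({s})"
        return s
    if isinstance(expr, Var):
        return f"x{expr.index}"
    if isinstance(expr, Unary):
        if expr.op == "negate":
            inner = to_text(expr.child, 3)
            s = f"-{inner}"
            return f"({s})" if _parent_prec >= 2 else s
        return f"{expr.op}({to_text(expr.child, 0)})"
    prec = 1 if expr.op in "+-" else 2
    left = to_text(expr.left, prec - 1 if expr.op in "+*" else prec - 1)
    # right side binds tighter for non-associative - and /
    right = to_text(expr.right, prec if expr.op in "-/" else prec - 1)
    s = f"{left} {expr.op} {right}"
    if _parent_prec >= prec:
        return f"({s})"
    return s


# ---------------------------------------------------------------------------
# Fixture equations
# ---------------------------------------------------------------------------

def fixture_equation_texts() -> list[str]:
    """The ten published replicate equations, as printed, one string each."""
    text = resources.files("gyretrend.data").joinpath("equations.txt").read_text()
    lines = [ln.strip() for ln in text.splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    return lines


def fixture_equations() -> list[Expression]:
    """Parse the ten fixture equations; returned in publication order."""
    return [parse(t) for t in fixture_equation_texts()]


# ---------------------------------------------------------------------------
# Structural sign analysis
# ---------------------------------------------------------------------------

class NotSumOfProducts(ValueError):
    """The expression could not be expanded into a top-level sum of products."""


@dataclass
class SignClassification:
    """Monotonic-direction label of one variable within an expression.

    ``label`` is one of ``absent``, ``positive``, ``negative``, ``mixed``;
    ``terms`` lists (term-sign, term-text) for every additive term that
    contains the variable.
    """

    variable: int
    label: str
    terms: list[tuple[str, str]] = field(default_factory=list)


def _expand_terms(expr: Expression, sign: int = 1) -> Iterator[tuple[int, list[Expression]]]:
    """Yield (sign, factors) for each additive term, distributing products
    over sums where needed."""
    if isinstance(expr, Binary) and expr.op == "+":
        yield from _expand_terms(expr.left, sign)
        yield from _expand_terms(expr.right, sign)
        return
    if isinstance(expr, Binary) and expr.op == "-":
        yield from _expand_terms(expr.left, sign)
        yield from _expand_terms(expr.right, -sign)
        return
    if isinstance(expr, Unary) and expr.op == "negate":
        yield from _expand_terms(expr.child, -sign)
        return
    if isinstance(expr, Binary) and expr.op == "*":
        left_terms = list(_expand_terms(expr.left, 1))
        right_terms = list(_expand_terms(expr.right, 1))
        for ls, lf in left_terms:
            for rs, rf in right_terms:
                yield sign * ls * rs, lf + rf
        return
    if isinstance(expr, Binary) and expr.op == "/":
        raise NotSumOfProducts("division present; not a sum of products")
    # atom: constant, variable, or unary-wrapped factor
    yield sign, [expr]


def _factor_sign(factor: Expression, assumptions: dict[int, int]) -> int | None:
    """Sign of one multiplicative factor under the range assumptions.

    Returns +1, -1, or None (indeterminate).
    """
    if isinstance(factor, Const):
        if factor.value > 0:
            return 1
        if factor.value < 0:
            return -1
        return None
    if isinstance(factor, Var):
        return assumptions.get(factor.index)
    if isinstance(factor, Unary):
        if factor.op in _POSITIVE_UNARY:
            return 1
        if factor.op in _SIGN_PRESERVING_UNARY:
            inner = _term_sign(list(_expand_terms(factor.child)), assumptions)
            return inner
        if factor.op == "negate":
            s = _factor_sign(factor.child, assumptions)
            return None if s is None else -s
        return None  # oscillatory or log: indeterminate
    return None


def _term_sign(terms: list[tuple[int, list[Expression]]],
               assumptions: dict[int, int]) -> int | None:
    """Sign of a sum of product terms, if all terms agree; else None."""
    signs = set()
    for s, factors in terms:
        t = s
        for f in factors:
            fs = _factor_sign(f, assumptions)
            if fs is None:
                return None
            t *= fs
        signs.add(t)
    if signs == {1}:
        return 1
    if signs == {-1}:
        return -1
    return None


def _contains_var(expr: Expression, index: int) -> bool:
    return index in variables_used(expr)


def _var_inside_oscillatory(factor: Expression, index: int) -> bool:
    """True if x_index occurs inside a sin/cos/tan wrapper within this factor."""
    if isinstance(factor, (Const, Var)):
        return False
    if isinstance(factor, Unary):
        if factor.op in _OSCILLATORY_UNARY and _contains_var(factor.child, index):
            return True
        return _var_inside_oscillatory(factor.child, index)
    return (_var_inside_oscillatory(factor.left, index)
            or _var_inside_oscillatory(factor.right, index))


DEFAULT_SIGN_ASSUMPTIONS: dict[int, int] = {i: 1 for i in range(1, N_VARIABLES + 1)}
"""All twelve predictors assumed positive in-range: days, depths, ratios,
temperatures (deg C at this site), and concentrations are all > 0."""


def term_sign_analysis(expr: Expression, variable_index: int,
                       assumptions: dict[int, int] | None = None,
                       ) -> SignClassification:
    """Classify the monotonic direction of one variable in an expression.

    The expression is expanded into a top-level sum of products.  For each
    additive term containing the variable, the term's direction is the sign
    of its constant coefficient times the signs of its co-factors under the
    range ``assumptions`` (all variables positive by default).  A term where
    the variable sits inside a bounded oscillatory wrapper (sin/cos/tan) is
    ``mixed``.  Per-term labels combine to ``negative`` (all negative),
    ``positive`` (all positive), or ``mixed``.
    """
    if assumptions is None:
        assumptions = DEFAULT_SIGN_ASSUMPTIONS
    if not (1 <= variable_index <= N_VARIABLES):
        raise ValueError(f"variable index {variable_index} outside 1..{N_VARIABLES}")
    try:
        terms = list(_expand_terms(expr))
    except NotSumOfProducts:
        warnings.warn(
            "expression is not a sum of products; structural sign analysis "
            "unavailable — use the empirical derivative-sign report from the "
            "sensitivity module instead", stacklevel=2)
        raise

    labels: list[str] = []
    term_records: list[tuple[str, str]] = []
    for s, factors in terms:
        if not any(_contains_var(f, variable_index) for f in factors):
            continue
        text = _product_text(s, factors)
        if any(_var_inside_oscillatory(f, variable_index) for f in factors):
            labels.append("mixed")
            term_records.append(("mixed", text))
            continue
        t: int | None = s
        for f in factors:
            if isinstance(f, Var) and f.index == variable_index:
                continue  # occurrences of the target: positive in-range
            fs = _factor_sign(f, assumptions)
            if fs is None:
                t = None
                break
            t *= fs
        if t is None:
            labels.append("mixed")
            term_records.append(("mixed", text))
        else:
            lab = "positive" if t > 0 else "negative"
            labels.append(lab)
            term_records.append((lab, text))

    if not labels:
        return SignClassification(variable_index, "absent", [])
    if all(l == "negative" for l in labels):
        return SignClassification(variable_index, "negative", term_records)
    if all(l == "positive" for l in labels):
        return SignClassification(variable_index, "positive", term_records)
    return SignClassification(variable_index, "mixed", term_records)


def _product_text(sign: int, factors: list[Expression]) -> str:
    body = " * ".join(to_text(f, 2) for f in factors)
    return f"-({body})" if sign < 0 else body


def sign_table(expr: Expression,
               assumptions: dict[int, int] | None = None) -> dict[int, str]:
    """Label every variable x1..x12 for one expression."""
    return {i: term_sign_analysis(expr, i, assumptions).label
            for i in range(1, N_VARIABLES + 1)}
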