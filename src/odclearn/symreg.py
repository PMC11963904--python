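"""Symbolic distillation of the grey-box network by genetic programming.

Searches the space of expressions built from unary {sin, cos, ln, exp} and
binary {+, -, /, *} operators over the five model inputs, fitting the
trained network's input/output pairs.  The engine is a compact
tree-based genetic-programming implementation: tournament selection,
subtree crossover, several mutation kinds, a hall of fame kept as a
Pareto front over (MSE, complexity), and numeric constants refined by
local least-squares with random restarts (restarts matter: the frequency
of an oscillatory term has many local optima).

``ln`` and ``/`` are protected (log of |x| bounded away from zero, divisor
bounded away from zero) rather than penalized, so every expression is
evaluable on the training domain.

The distilled expression is plugged back into the mechanistic model as the
a4 term, giving the interpretable "learned model".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import sympy as sp

from .sa_model import sa_predict_matrix
from .synthetic import INPUT_COLUMNS

__all__ = [
    "OperatorSet",
    "SRConfig",
    "Node",
    "ExpressionTree",
    "SRResult",
    "fit_symbolic",
    "evaluate_expression",
    "learned_model_predict",
    "match_canonical_form",
    "CanonicalCosLogFit",
    "parse_expression",
]

VAR_NAMES = tuple(INPUT_COLUMNS)

_UNARY_FUNCS: Dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sin": np.sin,
    "cos": np.cos,
    "ln": lambda x: np.log(np.maximum(np.abs(x), 1e-12)),
    "exp": lambda x: np.exp(np.clip(x, -60.0, 60.0)),
}
_BINARY_NAMES = ("add", "sub", "mul", "div")
_BINARY_SYMBOLS = {"add": "+", "sub": "-", "mul": "*", "div": "/"}


@dataclass(frozen=True)
class OperatorSet:
    unary: Tuple[str, ...] = ("sin", "cos", "ln", "exp")
    binary: Tuple[str, ...] = ("add", "sub", "mul", "div")

    def __post_init__(self) -> None:
        for u in self.unary:
            if u not in _UNARY_FUNCS:
                raise ValueError(f"unknown unary operator {u!r}")
        for b in self.binary:
            if b not in _BINARY_NAMES:
                raise ValueError(f"unknown binary operator {b!r}")


@dataclass(frozen=True)
class SRConfig:
    population_size: int = 160
    generations: int = 24
    max_size: int = 30
    parsimony: float = 1e-3
    tournament_size: int = 3
    p_crossover: float = 0.45
    p_subtree_mutation: float = 0.15
    p_point_mutation: float = 0.1
    p_const_mutation: float = 0.1
    p_insert_mutation: float = 0.1
    p_delete_mutation: float = 0.05
    elitism: int = 2
    optimize_constants: bool = True
    const_restarts: int = 3
    const_opt_rounds: int = 2
    const_opt_iters: int = 20
    max_opt_constants: int = 5
    polish_restarts: int = 6
    early_stop_rel_mse: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size <= 0 or self.generations <= 0 or self.max_size <= 0:
            raise ValueError("population, generations and max size must be positive")


class Node:
    """Expression-tree node: 'const', 'var', or an operator name."""

    __slots__ = ("op", "children", "value", "var")

    def __init__(self, op: str, children: Tuple["Node", ...] = (), value: float = 0.0, var: int = 0):
        self.op = op
        self.children = children
        self.value = value
        self.var = var

    # ---- basic structure ----
    def size(self) -> int:
        return 1 + sum(c.size() for c in self.children)

    def copy(self) -> "Node":
        return Node(self.op, tuple(c.copy() for c in self.children), self.value, self.var)

    def nodes(self) -> List["Node"]:
        out = [self]
        for c in self.children:
            out.extend(c.nodes())
        return out

    def const_nodes(self) -> List["Node"]:
        return [n for n in self.nodes() if n.op == "const"]

    def structure_key(self) -> str:
        if self.op == "const":
            return "C"
        if self.op == "var":
            return VAR_NAMES[self.var]
        return f"{self.op}({','.join(c.structure_key() for c in self.children)})"

    # ---- numeric evaluation ----
    def evaluate(self, X: np.ndarray) -> np.ndarray:
        if self.op == "const":
            return np.full(X.shape[0], self.value)
        if self.op == "var":
            return X[:, self.var]
        if self.op in _UNARY_FUNCS:
            return _UNARY_FUNCS[self.op](self.children[0].evaluate(X))
        a = self.children[0].evaluate(X)
        b = self.children[1].evaluate(X)
        if self.op == "add":
            return a + b
        if self.op == "sub":
            return a - b
        if self.op == "mul":
            return a * b
        if self.op == "div":
            safe = np.where(np.abs(b) < 1e-9, np.where(b < 0, -1e-9, 1e-9), b)
            return a / safe
        raise ValueError(f"unknown operator {self.op!r}")

    def to_string(self) -> str:
        if self.op == "const":
            return repr(float(self.value))
        if self.op == "var":
            return VAR_NAMES[self.var]
        if self.op in _UNARY_FUNCS:
            return f"{self.op}({self.children[0].to_string()})"
        sym = _BINARY_SYMBOLS[self.op]
        return f"({self.children[0].to_string()} {sym} {self.children[1].to_string()})"

    def __repr__(self) -> str:
        return f"Node<{self.to_string()}>"


@dataclass
class ExpressionTree:
    """A candidate expression with its fit quality and complexity."""

    root: Node
    mse: float
    complexity: int
    selected: bool = False

    def to_string(self) -> str:
        return self.root.to_string()


def evaluate_expression(expr: Node | ExpressionTree | str, X: np.ndarray) -> np.ndarray:
    """Numeric evaluation of an expression on an (n, 5) input matrix."""
    if isinstance(expr, str):
        expr = parse_expression(expr)
    root = expr.root if isinstance(expr, ExpressionTree) else expr
    X = np.atleast_2d(np.asarray(X, float))
    return root.evaluate(X)


def learned_model_predict(expr, X: np.ndarray) -> np.ndarray:
    """Mechanistic model with a4 given by the learned expression."""
    X = np.atleast_2d(np.asarray(X, float))
    a4 = evaluate_expression(expr, X)
    return sa_predict_matrix(X, a4_override=a4)


# --------------------------------------------------------------------------
# random tree construction and variation operators
# --------------------------------------------------------------------------

def _random_terminal(rng, n_vars: int, p_const: float = 0.3) -> Node:
    if rng.random() < p_const:
        return Node("const", value=float(rng.normal(0.0, 2.0)))
    return Node("var", var=int(rng.integers(n_vars)))


def _random_tree(rng, ops: OperatorSet, depth: int, n_vars: int, full: bool) -> Node:
    if depth <= 0 or (not full and rng.random() < 0.3):
        return _random_terminal(rng, n_vars)
    if rng.random() < 0.4 and ops.unary:
        op = ops.unary[rng.integers(len(ops.unary))]
        return Node(op, (_random_tree(rng, ops, depth - 1, n_vars, full),))
    op = ops.binary[rng.integers(len(ops.binary))]
    return Node(
        op,
        (
            _random_tree(rng, ops, depth - 1, n_vars, full),
            _random_tree(rng, ops, depth - 1, n_vars, full),
        ),
    )


def _template_population(ops: OperatorSet, n_vars: int, rng) -> List[Node]:
    """Systematic seed library: C * u1(C * u2(v)) + C for every ordered pair of
    unary operators (including "no operator") and every variable.

    Guarantees that each small unary-chain structure is present in the
    initial generation and therefore gets constant-optimization attention;
    random subtree initialization alone rarely keeps such chains alive long
    enough for their constants to be fitted.
    """
    chains = [None, *ops.unary]
    out: List[Node] = []
    for v in range(n_vars):
        for u1 in chains:
            for u2 in chains:
                inner: Node = Node("var", var=v)
                inner = Node("mul", (Node("const", value=float(rng.normal(0, 2))), inner))
                if u2 is not None:
                    inner = Node(u2, (inner,))
                    inner = Node("mul", (Node("const", value=float(rng.normal(0, 2))), inner))
                if u1 is not None:
                    inner = Node(u1, (inner,))
                body = Node("mul", (inner, Node("const", value=float(rng.normal(0, 2)))))
                out.append(Node("add", (body, Node("const", value=float(rng.normal(0, 1))))))
    return out


def _replace_node(root: Node, target: Node, repl: Node) -> Node:
    if root is target:
        return repl
    if not root.children:
        return root
    return Node(
        root.op,
        tuple(_replace_node(c, target, repl) for c in root.children),
        root.value,
        root.var,
    )


def _crossover(rng, a: Node, b: Node, max_size: int) -> Node:
    nodes_a = a.nodes()
    nodes_b = b.nodes()
    ta = nodes_a[rng.integers(len(nodes_a))]
    tb = nodes_b[rng.integers(len(nodes_b))]
    child = _replace_node(a, ta, tb.copy())
    return child if child.size() <= max_size else a.copy()


def _subtree_mutation(rng, a: Node, ops: OperatorSet, n_vars: int, max_size: int) -> Node:
    nodes = a.nodes()
    t = nodes[rng.integers(len(nodes))]
    repl = _random_tree(rng, ops, int(rng.integers(1, 4)), n_vars, full=False)
    child = _replace_node(a, t, repl)
    return child if child.size() <= max_size else a.copy()


def _point_mutation(rng, a: Node, ops: OperatorSet, n_vars: int) -> Node:
    a = a.copy()
    nodes = a.nodes()
    t = nodes[rng.integers(len(nodes))]
    if t.op == "const":
        t.value = float(rng.normal(0.0, 2.0))
    elif t.op == "var":
        t.var = int(rng.integers(n_vars))
    elif t.op in _UNARY_FUNCS:
        t.op = ops.unary[rng.integers(len(ops.unary))]
    else:
        t.op = ops.binary[rng.integers(len(ops.binary))]
    return a


def fold_constants(node: Node) -> Node:
    """Collapse variable-free subtrees into single constants."""
    if not node.children:
        return node
    children = tuple(fold_constants(c) for c in node.children)
    node = Node(node.op, children, node.value, node.var)
    if all(c.op == "const" for c in children):
        with np.errstate(all="ignore"):
            val = node.evaluate(np.zeros((1, len(VAR_NAMES))))[0]
        if np.isfinite(val):
            return Node("const", value=float(val))
    return node


def simplify_identities(node: Node) -> Node:
    """Remove exact algebraic no-ops (x+0, x*1, x*0, ...) introduced by pruning."""
    if not node.children:
        return node
    children = tuple(simplify_identities(c) for c in node.children)
    node = Node(node.op, children, node.value, node.var)
    a = children[0]
    b = children[1] if len(children) > 1 else None
    is_zero = lambda n: n is not None and n.op == "const" and n.value == 0.0
    is_one = lambda n: n is not None and n.op == "const" and n.value == 1.0
    if node.op == "add":
        if is_zero(a):
            return b
        if is_zero(b):
            return a
    elif node.op == "sub":
        if is_zero(b):
            return a
    elif node.op == "mul":
        if is_zero(a) or is_zero(b):
            return Node("const", value=0.0)
        if is_one(a):
            return b
        if is_one(b):
            return a
    elif node.op == "div":
        if is_zero(a):
            return Node("const", value=0.0)
        if is_one(b):
            return a
    return fold_constants(node)


def prune_negligible(node: Node, X: np.ndarray, y: np.ndarray, rel_tol: float = 0.05) -> Tuple[Node, float]:
    """Zero out constants whose removal barely changes the fit.

    Tries each constant in turn; keeps the zeroed (and identity-simplified)
    version when the MSE stays within ``(1 + rel_tol)`` of the current value
    plus a tiny absolute slack.  Returns the pruned tree and its MSE.
    """

    def mse_of(n: Node) -> float:
        with np.errstate(all="ignore"):
            pred = n.evaluate(X)
        if not np.all(np.isfinite(pred)):
            return float("inf")
        return float(np.mean((pred - y) ** 2))

    node = fold_constants(node.copy())
    best_mse = mse_of(node)
    slack = 1e-9 * float(np.var(y)) + 1e-30
    improved = True
    while improved:
        improved = False
        for c in node.const_nodes():
            if c.value == 0.0:
                continue
            old = c.value
            c.value = 0.0
            candidate = simplify_identities(node.copy())
            cand_mse = mse_of(candidate)
            if cand_mse <= best_mse * (1.0 + rel_tol) + slack:
                node = candidate
                best_mse = cand_mse
                improved = True
                break
            c.value = old
    return node, best_mse


def _insert_mutation(rng, a: Node, ops: OperatorSet, max_size: int) -> Node:
    """Wrap a random subtree in a unary operator or a binary op with a constant."""
    nodes = a.nodes()
    t = nodes[rng.integers(len(nodes))]
    if rng.random() < 0.4 and ops.unary:
        repl = Node(ops.unary[rng.integers(len(ops.unary))], (t.copy(),))
    else:
        op = ops.binary[rng.integers(len(ops.binary))]
        const = Node("const", value=float(rng.normal(0.0, 2.0)))
        pair = (t.copy(), const) if rng.random() < 0.5 else (const, t.copy())
        repl = Node(op, pair)
    child = _replace_node(a, t, repl)
    return child if child.size() <= max_size else a.copy()


def _delete_mutation(rng, a: Node) -> Node:
    """Replace a random operator node by one of its children (hoist)."""
    nodes = [n for n in a.nodes() if n.children]
    if not nodes:
        return a.copy()
    t = nodes[rng.integers(len(nodes))]
    keep = t.children[rng.integers(len(t.children))]
    return _replace_node(a, t, keep.copy())


def _const_mutation(rng, a: Node) -> Node:
    a = a.copy()
    consts = a.const_nodes()
    if not consts:
        return a
    t = consts[rng.integers(len(consts))]
    if rng.random() < 0.5:
        t.value = float(t.value * 2.0 ** rng.normal(0.0, 1.0))
    else:
        t.value = float(t.value + rng.normal(0.0, 1.0))
    return a


# --------------------------------------------------------------------------
# fitness with cached constant optimization
# --------------------------------------------------------------------------

def _pln(x):
    return np.log(np.maximum(np.abs(x), 1e-12))


def _pexp(x):
    return np.exp(np.clip(x, -60.0, 60.0))


def _pdiv(a, b):
    return a / np.where(np.abs(b) < 1e-9, np.where(b < 0, -1e-9, 1e-9), b)


_COMPILE_NS = {"np": np, "_pln": _pln, "_pexp": _pexp, "_pdiv": _pdiv}


def compile_tree(node: Node):
    """Compile a tree into ``fn(X, consts) -> values``.

    The generated expression mirrors :meth:`Node.evaluate` operation for
    operation (same protected semantics, same evaluation order), replacing
    the Python recursion with one compiled numpy expression — the hot path
    of constant optimization.  ``consts`` must be ordered as
    ``node.const_nodes()``.
    """
    counter = [0]

    def emit(n: Node) -> str:
        if n.op == "const":
            i = counter[0]
            counter[0] += 1
            return f"np.full(_n, C[{i}])" if not n.children else ""
        if n.op == "var":
            return f"X[:, {n.var}]"
        if n.op == "sin":
            return f"np.sin({emit(n.children[0])})"
        if n.op == "cos":
            return f"np.cos({emit(n.children[0])})"
        if n.op == "ln":
            return f"_pln({emit(n.children[0])})"
        if n.op == "exp":
            return f"_pexp({emit(n.children[0])})"
        a = emit(n.children[0])
        b = emit(n.children[1])
        if n.op == "add":
            return f"({a} + {b})"
        if n.op == "sub":
            return f"({a} - {b})"
        if n.op == "mul":
            return f"({a} * {b})"
        if n.op == "div":
            return f"_pdiv({a}, {b})"
        raise ValueError(f"unknown operator {n.op!r}")

    src = emit(node)
    code = compile(src, "<expr>", "eval")

    def fn(X: np.ndarray, C) -> np.ndarray:
        return eval(code, _COMPILE_NS, {"X": X, "C": C, "_n": X.shape[0]})

    return fn


def _lm_fit(fn, X, y, x0, max_iter=25):
    """Minimal Levenberg-Marquardt fit of compiled-tree constants.

    Forward-difference jacobian, multiplicative damping.  Orders of
    magnitude less per-call overhead than a general-purpose solver, which
    matters because the engine runs thousands of these little fits.
    """

    def resid(C):
        with np.errstate(all="ignore"):
            pred = fn(X, C)
        return np.where(np.isfinite(pred), pred - y, 1e6)

    C = np.asarray(x0, float).copy()
    k = len(C)
    r = resid(C)
    cost = float(r @ r)
    lam = 1e-3
    J = np.empty((len(y), k))
    for _ in range(max_iter):
        for i in range(k):
            h = 1e-6 * max(abs(C[i]), 1.0)
            Cp = C.copy()
            Cp[i] += h
            J[:, i] = (resid(Cp) - r) / h
        JTJ = J.T @ J
        JTr = J.T @ r
        diag = np.diag(np.diag(JTJ) + 1e-12)
        accepted = False
        step = None
        for _ in range(8):
            try:
                step = np.linalg.solve(JTJ + lam * diag, -JTr)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            Cn = C + step
            rn = resid(Cn)
            costn = float(rn @ rn)
            if np.isfinite(costn) and costn < cost:
                C, r, cost = Cn, rn, costn
                lam = max(lam * 0.3, 1e-12)
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            break
        if np.max(np.abs(step)) < 1e-10 * (1.0 + np.max(np.abs(C))):
            break
    return C, cost


def _refit_constants(node: Node, consts, X, y, rng, restarts: int, max_iter: int = 40) -> None:
    """Best-of-restarts Levenberg-Marquardt fit of a tree's constants, in place."""
    fn = compile_tree(node)
    x0s = [np.array([c.value for c in consts])]
    for _ in range(restarts):
        x0s.append(rng.uniform(-10.0, 10.0, size=len(consts)))
    best_vals, best_cost = None, np.inf
    for x0 in x0s:
        if not np.all(np.isfinite(x0)):
            continue
        vals, cost = _lm_fit(fn, X, y, x0, max_iter=max_iter)
        if cost < best_cost and np.all(np.isfinite(vals)):
            best_cost, best_vals = cost, vals
    if best_vals is not None:
        for c, v in zip(consts, best_vals):
            c.value = float(v)


class _Evaluator:
    """MSE evaluation with per-structure caching of optimized constants.

    Each unique structure gets up to ``const_opt_rounds`` optimization rounds
    across the whole run; each round restarts the local least-squares fit
    from the current constants, the cached best, and a handful of random
    initial points.  Later re-encounters of the structure reuse the cache.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, config: SRConfig, rng):
        self.X = X
        self.y = y
        self.config = config
        self.rng = rng
        self.cache: Dict[str, Dict] = {}
        self.var_y = float(np.var(y)) if len(y) else 0.0

    def _mse(self, node: Node) -> float:
        with np.errstate(all="ignore"):
            pred = node.evaluate(self.X)
        if not np.all(np.isfinite(pred)):
            return float("inf")
        return float(np.mean((pred - self.y) ** 2))

    def _optimize_constants(self, node: Node, cached: Optional[np.ndarray]) -> None:
        consts = node.const_nodes()
        if not consts or not self.config.optimize_constants:
            return
        k = len(consts)
        fn = compile_tree(node)

        inits = [np.array([c.value for c in consts])]
        if cached is not None and len(cached) == k:
            inits.append(cached)
        # small structures are cheap to refit and benefit most from restarts
        # (e.g. the frequency of an oscillatory term is highly multimodal)
        if k <= 4:
            n_restarts = 2 * self.config.const_restarts
        elif k <= self.config.max_opt_constants:
            n_restarts = self.config.const_restarts
        else:
            n_restarts = 0
        for _ in range(n_restarts):
            inits.append(self.rng.uniform(-10.0, 10.0, size=k))

        best_vals, best_cost = None, float("inf")
        for x0 in inits:
            if not np.all(np.isfinite(x0)):
                continue
            vals, cost = _lm_fit(fn, self.X, self.y, x0, max_iter=self.config.const_opt_iters)
            if cost < best_cost and np.all(np.isfinite(vals)):
                best_cost, best_vals = cost, vals
        if best_vals is not None:
            for c, v in zip(consts, best_vals):
                c.value = float(v)

    def evaluate(self, node: Node) -> float:
        """Returns raw MSE; may rewrite the node's constants in place."""
        key = node.structure_key()
        entry = self.cache.get(key)
        consts = node.const_nodes()
        if entry is None:
            entry = {"consts": None, "mse": float("inf"), "rounds": 0}
            self.cache[key] = entry
        rounds_cap = (
            2 * self.config.const_opt_rounds
            if len(consts) <= 4
            else self.config.const_opt_rounds
        )
        if consts and entry["rounds"] < rounds_cap:
            self._optimize_constants(node, entry["consts"])
            entry["rounds"] += 1
        elif consts and entry["consts"] is not None:
            for c, v in zip(consts, entry["consts"]):
                c.value = float(v)
        mse = self._mse(node)
        if consts and mse < entry["mse"]:
            entry["mse"] = mse
            entry["consts"] = np.array([c.value for c in consts])
        elif consts and entry["consts"] is not None and entry["mse"] < mse:
            for c, v in zip(consts, entry["consts"]):
                c.value = float(v)
            mse = entry["mse"]
        return mse

    def fitness(self, mse: float, size: int) -> float:
        return mse * (1.0 + self.config.parsimony * size)


@dataclass
class SRResult:
    """Ranked Pareto front over (MSE, complexity) plus run state for warm starts."""

    expressions: List[ExpressionTree]
    best: ExpressionTree
    population: List[Node] = field(repr=False, default_factory=list)
    best_mse: float = float("inf")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "expression": [e.to_string() for e in self.expressions],
                "mse": [e.mse for e in self.expressions],
                "complexity": [e.complexity for e in self.expressions],
                "selected": [e.selected for e in self.expressions],
            }
        )


def _pareto_front(entries: List[Tuple[float, int, Node]]) -> List[Tuple[float, int, Node]]:
    """Non-dominated set over (mse, complexity), lowest complexity first."""
    best_by_size: Dict[int, Tuple[float, Node]] = {}
    for mse, size, node in entries:
        if not np.isfinite(mse):
            continue
        cur = best_by_size.get(size)
        if cur is None or mse < cur[0]:
            best_by_size[size] = (mse, node)
    front = []
    best_so_far = float("inf")
    for size in sorted(best_by_size):
        mse, node = best_by_size[size]
        if mse < best_so_far:
            front.append((mse, size, node))
            best_so_far = mse
    return front


def _select_expression(front: List[ExpressionTree]) -> int:
    """Score-based model selection over the Pareto front.

    The score of a front entry is the drop in log-MSE per unit of added
    complexity relative to the previous (simpler) entry; the selected
    expression is the highest-scoring one.  This picks the elbow of the
    fit/complexity trade-off rather than the raw minimum, which tends to
    overfit the regression targets' idiosyncrasies.
    """
    # below ~1e-18 differences in MSE are numerical noise, not signal; the
    # floor stops the rule from "improving" on an already-exact simple fit
    floor = 1e-18
    scores = [0.0]
    for prev, cur in zip(front[:-1], front[1:]):
        d_complex = max(cur.complexity - prev.complexity, 1)
        scores.append(
            (np.log(max(prev.mse, floor)) - np.log(max(cur.mse, floor))) / d_complex
        )
    return int(np.argmax(scores))


def fit_symbolic(
    X: np.ndarray,
    y: np.ndarray,
    operator_set: Optional[OperatorSet] = None,
    config: Optional[SRConfig] = None,
    warm_start: Optional[SRResult] = None,
) -> SRResult:
    """Genetic-programming search for expressions fitting ``y`` from ``X``.

    Returns the Pareto front over (MSE, node count), with the selected
    expression marked per the score/complexity trade-off rule.  Deterministic
    given ``config.seed``.
    """
    ops = operator_set or OperatorSet()
    config = config or SRConfig()
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    if len(y) < 10:
        raise ValueError("need at least 10 input/output pairs")
    n_vars = X.shape[1]
    rng = np.random.default_rng(config.seed)
    ev = _Evaluator(X, y, config, rng)
    stop_mse = max(config.early_stop_rel_mse * max(ev.var_y, 1e-30), 1e-14)

    # initial population: systematic unary-chain templates plus ramped
    # half-and-half random trees, optionally seeded by warm start
    population: List[Node] = []
    if warm_start is not None:
        population.extend(n.copy() for n in warm_start.population[: config.population_size])
    else:
        population.extend(_template_population(ops, n_vars, rng)[: config.population_size])
    depth_cycle = (2, 3, 4)
    i = 0
    while len(population) < config.population_size:
        population.append(
            _random_tree(rng, ops, depth_cycle[i % 3], n_vars, full=(i % 2 == 0))
        )
        i += 1

    hall: List[Tuple[float, int, Node]] = []
    if warm_start is not None:
        hall.extend((e.mse, e.complexity, e.root.copy()) for e in warm_start.expressions)

    fitnesses = np.empty(len(population))
    mses = np.empty(len(population))
    for gen in range(config.generations):
        for idx, node in enumerate(population):
            mse = ev.evaluate(node)
            mses[idx] = mse
            fitnesses[idx] = ev.fitness(mse, node.size())
            hall.append((mse, node.size(), node.copy()))
        hall = _pareto_front(hall)
        if hall and hall[-1][0] < stop_mse:
            break
        if gen == config.generations - 1:
            break

        def tournament() -> Node:
            idxs = rng.integers(len(population), size=config.tournament_size)
            return population[idxs[np.argmin(fitnesses[idxs])]]

        order = np.argsort(fitnesses)
        next_pop: List[Node] = [population[j].copy() for j in order[: config.elitism]]
        thresholds = np.cumsum(
            [
                config.p_crossover,
                config.p_subtree_mutation,
                config.p_point_mutation,
                config.p_const_mutation,
                config.p_insert_mutation,
                config.p_delete_mutation,
            ]
        )
        while len(next_pop) < config.population_size:
            r = rng.random()
            parent = tournament()
            if r < thresholds[0]:
                child = _crossover(rng, parent.copy(), tournament(), config.max_size)
            elif r < thresholds[1]:
                child = _subtree_mutation(rng, parent.copy(), ops, n_vars, config.max_size)
            elif r < thresholds[2]:
                child = _point_mutation(rng, parent, ops, n_vars)
            elif r < thresholds[3]:
                child = _const_mutation(rng, parent)
            elif r < thresholds[4]:
                child = _insert_mutation(rng, parent.copy(), ops, config.max_size)
            elif r < thresholds[5]:
                child = _delete_mutation(rng, parent)
            else:
                child = parent.copy()
            next_pop.append(fold_constants(child))
        population = next_pop

    if not hall:
        raise RuntimeError("no finite-fitness expression found")

    # final polish: thorough constant refit of the leading candidates (after
    # folding away variable-free subtrees), plus a unary-operator
    # neighborhood search around each front entry — swapping e.g. a sin for
    # a cos and refitting constants rescues structures whose constants were
    # trapped in the wrong local optimum during the run
    polished: List[Tuple[float, int, Node]] = []

    def refit_and_add(node: Node) -> None:
        node = fold_constants(node.copy())
        consts = node.const_nodes()
        if consts and len(consts) <= config.max_opt_constants + 2:
            _refit_constants(node, consts, X, y, rng, config.polish_restarts)
        node, new_mse = prune_negligible(node, X, y)
        if np.isfinite(new_mse):
            polished.append((new_mse, node.size(), node))

    for mse, size, node in hall:
        refit_and_add(node)
        if size <= 15:
            for i, n in enumerate(node.nodes()):
                if n.op in _UNARY_FUNCS:
                    for alt in ops.unary:
                        if alt == n.op:
                            continue
                        variant = node.copy()
                        variant.nodes()[i].op = alt
                        refit_and_add(variant)
    hall = _pareto_front(hall + polished)

    front = [
        ExpressionTree(root=node, mse=mse, complexity=size)
        for mse, size, node in hall
    ]
    sel = _select_expression(front)
    front[sel].selected = True
    best = front[sel]
    return SRResult(
        expressions=front,
        best=best,
        population=population,
        best_mse=min(e.mse for e in front),
    )


# --------------------------------------------------------------------------
# canonical-form matching and parsing (sympy-backed)
# --------------------------------------------------------------------------

# all five inputs are physically positive; the assumption lets sympy fold
# the protected |.| inside ln and split log products
_SYMBOLS = sp.symbols(" ".join(VAR_NAMES), positive=True)
_SYMBOL_MAP = dict(zip(VAR_NAMES, _SYMBOLS))
_P = _SYMBOL_MAP["p"]


def _protected_log(x):
    """Symbolic counterpart of the engine's ln: log of the absolute value."""
    return sp.log(sp.Abs(x))


def _tree_to_sympy(node: Node) -> sp.Expr:
    if node.op == "const":
        return sp.Float(node.value)
    if node.op == "var":
        return _SYMBOLS[node.var]
    if node.op in _UNARY_FUNCS:
        f = {"sin": sp.sin, "cos": sp.cos, "ln": _protected_log, "exp": sp.exp}[node.op]
        return f(_tree_to_sympy(node.children[0]))
    a, b = (_tree_to_sympy(c) for c in node.children)
    return {"add": a + b, "sub": a - b, "mul": a * b, "div": a / b}[node.op]


def _sympy_to_tree(e: sp.Expr) -> Node:
    if e.is_Number:
        return Node("const", value=float(e))
    if e.is_Symbol:
        name = str(e)
        if name not in VAR_NAMES:
            raise ValueError(f"unknown variable {name!r}")
        return Node("var", var=VAR_NAMES.index(name))
    if isinstance(e, sp.Add):
        args = [_sympy_to_tree(a) for a in e.args]
        out = args[0]
        for a in args[1:]:
            out = Node("add", (out, a))
        return out
    if isinstance(e, sp.Mul):
        args = [_sympy_to_tree(a) for a in e.args]
        out = args[0]
        for a in args[1:]:
            out = Node("mul", (out, a))
        return out
    if isinstance(e, sp.Pow):
        base, expo = e.args
        if expo == -1:
            return Node("div", (Node("const", value=1.0), _sympy_to_tree(base)))
        if expo.is_Integer and int(expo) > 0:
            out = _sympy_to_tree(base)
            for _ in range(int(expo) - 1):
                out = Node("mul", (out, _sympy_to_tree(base)))
            return out
        if expo.is_Integer and int(expo) < 0:
            return Node(
                "div",
                (Node("const", value=1.0), _sympy_to_tree(sp.Pow(base, -expo))),
            )
        raise ValueError(f"unsupported power {e}")
    if isinstance(e, sp.Abs):
        # the engine's ln is already protected; a bare |.| is transparent here
        return _sympy_to_tree(e.args[0])
    fmap = {sp.sin: "sin", sp.cos: "cos", sp.log: "ln", sp.exp: "exp"}
    for cls, name in fmap.items():
        if isinstance(e, cls):
            return Node(name, (_sympy_to_tree(e.args[0]),))
    raise ValueError(f"cannot convert sympy expression {e} to a tree")


def parse_expression(s: str) -> Node:
    """Parse a plain-text infix expression (``ln`` accepted for log)."""
    e = sp.sympify(s, locals={**_SYMBOL_MAP, "ln": sp.log})
    return _sympy_to_tree(sp.nsimplify(e, rational=False))


@dataclass(frozen=True)
class CanonicalCosLogFit:
    """Coefficients of the family alpha * cos(beta * ln p + phase) + gamma."""

    alpha: float
    beta: float
    gamma: float
    phase: float = 0.0


def match_canonical_form(expr) -> Optional[CanonicalCosLogFit]:
    """Detect the cosine-of-log-pressure family and extract its coefficients.

    Normalizes algebraically (sin folded into cos, beta made positive,
    phases of 0 or pi folded into the sign of alpha).  Returns ``None`` for
    expressions outside the family — e.g. a cosine of p itself rather than
    of ln p, or any dependence on the other four inputs.
    """
    root = expr.root if isinstance(expr, ExpressionTree) else expr
    if isinstance(root, str):
        root = parse_expression(root)
    try:
        e = _tree_to_sympy(root)
        e = sp.expand(sp.expand_log(sp.expand_trig(sp.together(e)), force=False))
    except Exception:
        return None
    other_syms = set(_SYMBOLS) - {_P}
    if e.free_symbols & other_syms:
        return None

    logp = sp.log(_P)
    gamma = sp.Float(0)
    trig_terms = []
    for term in sp.Add.make_args(e):
        if term.free_symbols:
            trig_terms.append(term)
        else:
            gamma += term

    # sin(u)*a + cos(u)*b from expand_trig of a phase would appear as two terms
    # sharing the same argument; recombine them.
    by_arg: Dict[sp.Expr, Dict[str, sp.Expr]] = {}
    for term in trig_terms:
        coeff, rest = term.as_independent(_P)
        trigs = [f for f in sp.Mul.make_args(rest) if isinstance(f, (sp.sin, sp.cos))]
        if len(trigs) != 1 or sp.Mul(*[f for f in sp.Mul.make_args(rest) if f not in trigs]) != 1:
            return None
        trig = trigs[0]
        arg = trig.args[0]
        slot = by_arg.setdefault(arg, {"sin": sp.Float(0), "cos": sp.Float(0)})
        slot["sin" if isinstance(trig, sp.sin) else "cos"] += coeff
    if len(by_arg) != 1:
        return None
    (arg, parts), = by_arg.items()

    try:
        poly = sp.Poly(arg, logp) if arg.has(logp) else None
        if poly is None or poly.degree() != 1:
            return None
        beta = poly.coeff_monomial(logp)
        phi0 = poly.coeff_monomial(1)
        if (
            beta.free_symbols
            or phi0.free_symbols
            or sp.simplify(arg - beta * logp - phi0) != 0
        ):
            return None
    except (sp.PolynomialError, sp.SympifyError):
        return None

    # a*cos(u) + b*sin(u) = R*cos(u - atan2(b, a))
    a = float(parts["cos"])
    b = float(parts["sin"])
    alpha = math.hypot(a, b)
    if alpha == 0.0:
        return None
    phase = float(phi0) - math.atan2(b, a)
    beta = float(beta)
    if beta < 0:  # cos is even: cos(-beta*u + phi) = cos(beta*u - phi)
        beta, phase = -beta, -phase
    phase = math.remainder(phase, 2.0 * math.pi)
    if abs(abs(phase) - math.pi) < 1e-9:
        alpha, phase = -alpha, 0.0
    elif abs(phase) < 1e-9:
        phase = 0.0
    return CanonicalCosLogFit(
        alpha=alpha, beta=beta, gamma=float(gamma), phase=phase
    )
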