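"""Shared helpers: random generators and independent mini-oracles.

The expression oracle here is a third, deliberately naive implementation
(numeric 0/1/None encoding, substitution then reduction) sharing no code
with either the package evaluator or the package replay oracle.
"""

from __future__ import annotations

import random

import pytest

from cigx.document import (
    Action,
    Goal,
    GuidelineDocument,
    Node,
    Precondition,
    Rule,
)
from cigx.expr import (
    AndExpr,
    Bindings,
    Comparison,
    ConstExpr,
    InRangeExpr,
    InSetExpr,
    LiteralValue,
    NotExpr,
    OrExpr,
    ParenExpr,
    SymbolRef,
)

BOOL_SYMBOLS = ("s/a", "s/b", "s/c", "s/d")


# ---------------------------------------------------------------------------
# Independent truth-table/substitution oracle (tri-valued: 1, 0, None)


def truth_table_oracle(expr, env):
    """env: path -> plain python value (bool/int/float/str/date), or absent."""

    def leaf_cmp(op, a, b):
        import numbers

        numeric = isinstance(a, numbers.Real) and not isinstance(a, bool)
        b_numeric = isinstance(b, numbers.Real) and not isinstance(b, bool)
        if numeric != b_numeric or (not numeric and type(a) is not type(b)):
            raise AssertionError("oracle saw incomparable kinds")
        return {
            "eq": a == b,
            "ne": a != b,
            "gt": a > b,
            "lt": a < b,
            "ge": a >= b,
            "le": a <= b,
        }[op]

    def sub(e):
        if isinstance(e, ConstExpr):
            return 1 if e.truth else 0
        if isinstance(e, ParenExpr):
            return sub(e.inner)
        if isinstance(e, NotExpr):
            v = sub(e.operand)
            return None if v is None else 1 - v
        if isinstance(e, AndExpr):
            vals = [sub(o) for o in e.operands]
            if 0 in vals:
                return 0
            return None if None in vals else 1
        if isinstance(e, OrExpr):
            vals = [sub(o) for o in e.operands]
            if 1 in vals:
                return 1
            return None if None in vals else 0
        if isinstance(e, Comparison):
            if e.left.path not in env:
                return None
            a = env[e.left.path]
            if isinstance(e.right, SymbolRef):
                if e.right.path not in env:
                    return None
                b = env[e.right.path]
            else:
                b = e.right.value
            return 1 if leaf_cmp(e.op, a, b) else 0
        if isinstance(e, InSetExpr):
            if not e.members:
                return 0
            if e.symbol.path not in env:
                return None
            a = env[e.symbol.path]
            return 1 if any(leaf_cmp("eq", a, m.value) for m in e.members) else 0
        if isinstance(e, InRangeExpr):
            if e.symbol.path not in env:
                return None
            a = env[e.symbol.path]
            ok = True
            if e.lower is not None:
                ok = ok and leaf_cmp("ge" if e.lower_inclusive else "gt", a, e.lower.value)
            if e.upper is not None:
                ok = ok and leaf_cmp("le" if e.upper_inclusive else "lt", a, e.upper.value)
            return 1 if ok else 0
        raise TypeError(e)

    return {1: "true", 0: "false", None: "unknown"}[sub(expr)]


def bindings_from_env(env):
    def lit(v):
        if isinstance(v, bool):
            return LiteralValue("boolean", v)
        if isinstance(v, int):
            return LiteralValue("integer", v)
        if isinstance(v, float):
            return LiteralValue("decimal", v)
        return LiteralValue("text", v)

    return Bindings({k: lit(v) for k, v in env.items()})


# ---------------------------------------------------------------------------
# Random expression trees


def random_expr(rng: random.Random, depth: int, symbols=BOOL_SYMBOLS, rich=False):
    """A random tree; boolean-symbol leaves, optionally richer leaf kinds."""
    if depth <= 0 or rng.random() < 0.25:
        roll = rng.random()
        if roll < 0.25:
            return ConstExpr(rng.random() < 0.5)
        sym = SymbolRef(rng.choice(symbols))
        if not rich or roll < 0.75:
            return Comparison(
                rng.choice(("eq", "ne")), sym, LiteralValue("boolean", rng.random() < 0.5)
            )
        isym = SymbolRef(rng.choice(symbols).replace("s/", "n/"))
        if roll < 0.85:
            return Comparison(
                rng.choice(("gt", "lt", "ge", "le")),
                isym,
                LiteralValue("integer", rng.randrange(-5, 6)),
            )
        if roll < 0.93:
            return InSetExpr(
                isym,
                tuple(
                    LiteralValue("integer", rng.randrange(-5, 6))
                    for _ in range(rng.randrange(0, 4))
                ),
            )
        lo = rng.randrange(-5, 3)
        return InRangeExpr(
            isym,
            lower=LiteralValue("integer", lo),
            upper=LiteralValue("integer", lo + rng.randrange(0, 6)),
            lower_inclusive=rng.random() < 0.7,
            upper_inclusive=rng.random() < 0.7,
        )
    op = rng.choice(("and", "or", "not", "paren"))
    if op == "not":
        return NotExpr(random_expr(rng, depth - 1, symbols, rich))
    if op == "paren":
        return ParenExpr(random_expr(rng, depth - 1, symbols, rich))
    n = rng.randrange(2, 4)
    operands = tuple(random_expr(rng, depth - 1, symbols, rich) for _ in range(n))
    return AndExpr(operands) if op == "and" else OrExpr(operands)


def all_bool_envs(symbols=BOOL_SYMBOLS):
    """Every total boolean assignment over the symbol pool."""
    envs = []
    n = len(symbols)
    for mask in range(2**n):
        envs.append({s: bool(mask >> i & 1) for i, s in enumerate(symbols)})
    return envs


# ---------------------------------------------------------------------------
# Random guideline documents (small, boolean-path conditions)

ENGINE_PATHS = ("w/p0", "w/p1", "w/p2", "w/p3", "w/p4")
TRIGGERS = (
    "time_passage",
    "clinical_data_pattern",
    "diagnostic_test_value",
    "treatment_result",
)


def random_document(rng: random.Random, max_nodes=10, max_rules=3) -> GuidelineDocument:
    n_nodes = rng.randrange(1, max_nodes + 1)
    ids = iter(f"n{i}" for i in range(n_nodes))

    def cond():
        return random_expr(rng, rng.randrange(0, 3), symbols=ENGINE_PATHS)

    def make_node(budget):
        nid = next(ids)
        rules = []
        for r in range(rng.randrange(0, max_rules + 1)):
            actions = [Action(kind="message", payload=f"{nid}-r{r}")]
            if rng.random() < 0.3:
                actions.append(
                    Action(
                        kind="calculation",
                        payload=f"{nid}-r{r}-calc",
                        assignments=(
                            (
                                rng.choice(ENGINE_PATHS),
                                LiteralValue("boolean", rng.random() < 0.5),
                            ),
                        ),
                    )
                )
            rules.append(
                Rule(
                    id=f"r{r}",
                    precondition=Precondition(rng.choice(TRIGGERS), cond()),
                    actions=tuple(actions),
                )
            )
        children = []
        while budget[0] > 0 and rng.random() < 0.4:
            budget[0] -= 1
            children.append(make_node(budget))
        return Node(
            id=nid,
            goal=Goal(cond()),
            rules=tuple(rules),
            children=tuple(children),
            complete_on_action=rng.random() < 0.2,
        )

    budget = [n_nodes - 1]
    tops = [make_node(budget)]
    while budget[0] > 0:
        budget[0] -= 1
        tops.append(make_node(budget))
    return GuidelineDocument(id="rand", title="random", version="0", nodes=tuple(tops))


@pytest.fixture
def rng():
    return random.Random(20261002)


# ---------------------------------------------------------------------------
# Trace auditing (latching and gating invariants)


def audit_trace(doc, trace):
    """Assert the two execution invariants on a finished run's trace:

    * gating — no rule is evaluated in a cycle in which any ancestor's goal
      gate was not TRUE;
    * latching — once a node is completed, neither it nor any descendant
      evaluates rules or fires actions in later cycles.
    """
    from cigx.engine import (
        ActionFired,
        GoalSatisfied,
        NodeEvaluated,
        NodeSkippedCompleted,
        RuleEvaluated,
    )
    from cigx.expr import TRUE
    from cigx.document import iter_nodes

    parent = {}
    for node, _, par in iter_nodes(doc):
        parent[node.id] = par

    def ancestors(nid):
        while parent[nid] is not None:
            nid = parent[nid]
            yield nid

    gates = {}
    completed_after = {}  # node -> first cycle in which it may no longer act
    for rec in trace:
        if isinstance(rec, NodeEvaluated):
            gates[(rec.cycle, rec.node_id)] = rec.gate_result
        elif isinstance(rec, GoalSatisfied):
            completed_after.setdefault(rec.node_id, rec.cycle)
        elif isinstance(rec, NodeSkippedCompleted):
            completed_after.setdefault(rec.node_id, rec.cycle - 1)

    for rec in trace:
        if isinstance(rec, RuleEvaluated):
            cyc, nid = rec.cycle, rec.node_id
        elif isinstance(rec, ActionFired):
            cyc, nid = rec.cycle, rec.fired.node_id
        else:
            continue
        for anc in ancestors(nid):
            assert gates.get((cyc, anc)) is TRUE, (
                f"cycle {cyc}: node {nid} acted under non-TRUE ancestor {anc}"
            )
        for scope in (nid, *ancestors(nid)):
            done = completed_after.get(scope)
            assert done is None or cyc <= done, (
                f"cycle {cyc}: node {nid} acted after {scope} completed at {done}"
            )
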