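"""Three-valued evaluation of the condition language."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cigx.errors import TypeMismatch
from cigx.expr import (
    FALSE,
    TRUE,
    UNKNOWN,
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
    evaluate,
    referenced_symbols,
)

from conftest import (
    BOOL_SYMBOLS,
    all_bool_envs,
    bindings_from_env,
    random_expr,
    truth_table_oracle,
)

CFU = "labs/urine_culture/cfu"


def _b(env):
    return bindings_from_env(env)


class TestLeaves:
    def test_cfu_over_threshold_is_true(self):
        expr = Comparison("gt", SymbolRef(CFU), LiteralValue("integer", 100_000))
        assert evaluate(expr, _b({CFU: 150_000})) is TRUE
        assert evaluate(expr, _b({CFU: 100_000})) is FALSE
        assert evaluate(expr, _b({})) is UNKNOWN

    def test_constant_logic_needs_no_bindings(self):
        expr = AndExpr((ConstExpr(True), NotExpr(ConstExpr(False))))
        assert evaluate(expr, Bindings()) is TRUE

    def test_empty_in_set_is_false_even_when_bound_or_unbound(self):
        expr = InSetExpr(SymbolRef("dx/code"), ())
        assert evaluate(expr, _b({"dx/code": "O23.1"})) is FALSE
        assert evaluate(expr, Bindings()) is FALSE

    def test_in_set_membership(self):
        expr = InSetExpr(
            SymbolRef("dx/code"),
            (LiteralValue("text", "O23.1"), LiteralValue("text", "N39.0")),
        )
        assert evaluate(expr, _b({"dx/code": "N39.0"})) is TRUE
        assert evaluate(expr, _b({"dx/code": "Z00.0"})) is FALSE
        assert evaluate(expr, Bindings()) is UNKNOWN

    @pytest.mark.parametrize(
        "lower,upper,li,ui,value,expected",
        [
            (10, 20, True, True, 10, TRUE),
            (10, 20, False, True, 10, FALSE),
            (10, 20, True, False, 20, FALSE),
            (10, None, True, True, 1_000_000, TRUE),
            (None, 20, True, True, -5, TRUE),
        ],
    )
    def test_in_range_bounds_and_inclusivity(self, lower, upper, li, ui, value, expected):
        expr = InRangeExpr(
            SymbolRef("n/x"),
            lower=LiteralValue("integer", lower) if lower is not None else None,
            upper=LiteralValue("integer", upper) if upper is not None else None,
            lower_inclusive=li,
            upper_inclusive=ui,
        )
        assert evaluate(expr, _b({"n/x": value})) is expected

    def test_numeric_promotion_integer_decimal(self):
        expr = Comparison("ge", SymbolRef("n/x"), LiteralValue("decimal", 2.5))
        assert evaluate(expr, _b({"n/x": 3})) is TRUE

    def test_cross_kind_comparison_is_an_error_not_unknown(self):
        expr = Comparison("eq", SymbolRef("n/x"), LiteralValue("text", "3"))
        with pytest.raises(TypeMismatch):
            evaluate(expr, _b({"n/x": 3}))

    def test_boolean_ordering_is_an_error(self):
        expr = Comparison("gt", SymbolRef("s/a"), LiteralValue("boolean", False))
        with pytest.raises(TypeMismatch):
            evaluate(expr, _b({"s/a": True}))

    def test_symbol_vs_symbol_comparison(self):
        expr = Comparison("lt", SymbolRef("n/x"), SymbolRef("n/y"))
        assert evaluate(expr, _b({"n/x": 1, "n/y": 2})) is TRUE
        assert evaluate(expr, _b({"n/x": 1})) is UNKNOWN


class TestInvariants:
    def test_invalid_constructions_rejected(self):
        with pytest.raises(ValueError):
            SymbolRef("1bad/path")
        with pytest.raises(ValueError):
            AndExpr((ConstExpr(True),))
        with pytest.raises(ValueError):
            InRangeExpr(SymbolRef("n/x"))  # no bounds
        with pytest.raises(ValueError):
            InRangeExpr(
                SymbolRef("n/x"),
                lower=LiteralValue("integer", 5),
                upper=LiteralValue("integer", 1),
            )
        with pytest.raises(ValueError):
            InSetExpr(
                SymbolRef("n/x"),
                (LiteralValue("integer", 1), LiteralValue("text", "a")),
            )

    def test_referenced_symbols(self):
        assert referenced_symbols(ConstExpr(True)) == frozenset()
        one = Comparison("gt", SymbolRef(CFU), LiteralValue("integer", 1))
        assert referenced_symbols(one) == {CFU}
        tree = AndExpr(
            (
                one,
                Comparison("eq", SymbolRef("s/a"), LiteralValue("boolean", True)),
                NotExpr(Comparison("eq", SymbolRef("s/a"), SymbolRef("s/b"))),
            )
        )
        assert referenced_symbols(tree) == {CFU, "s/a", "s/b"}


def _partial_envs(rng, env, k=3):
    """A few partial sub-environments of a total env."""
    keys = sorted(env)
    out = [{}]
    for _ in range(k):
        kept = [key for key in keys if rng.random() < 0.5]
        out.append({key: env[key] for key in kept})
    return out


class TestOracleEquivalence:
    def test_exhaustive_shallow_trees_match_truth_table_oracle(self):
        """Every tree to depth 3 over boolean leaves agrees with the
        substitution oracle on every total binding (and the empty one)."""
        leaves = [ConstExpr(True), ConstExpr(False)] + [
            Comparison("eq", SymbolRef(s), LiteralValue("boolean", True))
            for s in BOOL_SYMBOLS
        ]
        pool = list(leaves)
        for _depth in (2, 3):
            new = [NotExpr(e) for e in pool[:90]]
            new += [ParenExpr(e) for e in pool[:30]]
            new += [AndExpr((a, b)) for a in pool[:45] for b in pool[:45]]
            new += [OrExpr((a, b)) for a in pool[:45] for b in pool[:45]]
            pool = leaves + new
        envs = all_bool_envs() + [{}]
        for expr in pool:
            for env in envs:
                assert evaluate(expr, bindings_from_env(env)).value == truth_table_oracle(
                    expr, env
                ), (expr, env)

    def test_random_deep_trees_match_oracle_on_total_and_partial_bindings(self):
        rng = random.Random(7)
        int_env = {f"n/{s[-1]}": rng.randrange(-5, 6) for s in BOOL_SYMBOLS}
        for _ in range(1000):
            expr = random_expr(rng, depth=5, rich=True)
            total = dict(all_bool_envs()[rng.randrange(16)], **int_env)
            for env in _partial_envs(rng, total, k=2) + [total]:
                assert evaluate(expr, bindings_from_env(env)).value == truth_table_oracle(
                    expr, env
                )


@st.composite
def _trees(draw):
    seed = draw(st.integers(0, 2**16))
    depth = draw(st.integers(0, 4))
    return random_expr(random.Random(seed), depth)


class TestKleeneLaws:
    @settings(max_examples=200, derandomize=True)
    @given(_trees(), st.integers(0, 2**16))
    def test_double_negation_and_de_morgan(self, expr, env_seed):
        rng = random.Random(env_seed)
        total = all_bool_envs()[rng.randrange(16)]
        env = {k: v for k, v in total.items() if rng.random() < 0.7}
        b = bindings_from_env(env)
        assert evaluate(NotExpr(NotExpr(expr)), b) is evaluate(expr, b)
        other = random_expr(rng, 2)
        lhs = evaluate(NotExpr(AndExpr((expr, other))), b)
        rhs = evaluate(OrExpr((NotExpr(expr), NotExpr(other))), b)
        assert lhs is rhs

    @settings(max_examples=150, derandomize=True)
    @given(_trees(), st.integers(0, 2**16))
    def test_paren_transparency(self, expr, env_seed):
        rng = random.Random(env_seed)
        env = {k: v for k, v in all_bool_envs()[rng.randrange(16)].items() if rng.random() < 0.8}
        b = bindings_from_env(env)
        assert evaluate(ParenExpr(expr), b) is evaluate(expr, b)

    @settings(max_examples=150, derandomize=True)
    @given(_trees(), st.integers(0, 2**16))
    def test_monotone_missingness(self, expr, env_seed):
        """A definite result under a partial binding survives every total
        extension of that binding."""
        rng = random.Random(env_seed)
        total = all_bool_envs()[rng.randrange(16)]
        partial = {k: v for k, v in total.items() if rng.random() < 0.5}
        before = evaluate(expr, bindings_from_env(partial))
        if before is not UNKNOWN:
            assert evaluate(expr, bindings_from_env(total)) is before
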