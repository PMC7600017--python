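"""Independent replay oracle for guideline execution.

This module re-derives the expected fired actions of a run by direct
recursion over the document model and the raw event list, sharing no code
with :mod:`cigx.engine` or :mod:`cigx.expr`: it carries its own
three-valued condition evaluator (over plain python values) and its own
fact list, statuses and firing bookkeeping.  It exists purely as a
cross-check — tests compare the engine's output against it on every
simulated stream and on randomly generated documents.
"""

from __future__ import annotations

from datetime import datetime
from typing import List, Optional, Tuple

from .document import GuidelineDocument
from .expr import (
    AndExpr,
    Comparison,
    ConstExpr,
    InRangeExpr,
    InSetExpr,
    NotExpr,
    OrExpr,
    ParenExpr,
    SymbolRef,
)
from .state import Observation, TimeAdvance

_EPOCH = datetime(1970, 1, 1)

ActionSummary = Tuple[str, Optional[str], str, str]  # node, rule, kind, payload


def _plain(lit):
    """Reduce a literal to a comparable plain value keyed by family."""
    if lit.kind in ("integer", "decimal"):
        return ("num", float(lit.value))
    return (lit.kind, lit.value)


def _cmp_vals(op, a, b):
    fa, va = a
    fb, vb = b
    if fa != fb:
        raise ValueError(f"incomparable kinds {fa}/{fb}")
    if fa == "boolean" and op not in ("eq", "ne"):
        raise ValueError("no ordering on booleans")
    return {
        "eq": va == vb,
        "ne": va != vb,
        "gt": va > vb,
        "lt": va < vb,
        "ge": va >= vb,
        "le": va <= vb,
    }[op]


def _eval(expr, env) -> str:
    """Three-valued evaluation: returns 'T', 'F' or 'U'."""
    if isinstance(expr, ConstExpr):
        return "T" if expr.truth else "F"
    if isinstance(expr, ParenExpr):
        return _eval(expr.inner, env)
    if isinstance(expr, NotExpr):
        return {"T": "F", "F": "T", "U": "U"}[_eval(expr.operand, env)]
    if isinstance(expr, AndExpr):
        vals = [_eval(o, env) for o in expr.operands]
        if "F" in vals:
            return "F"
        return "U" if "U" in vals else "T"
    if isinstance(expr, OrExpr):
        vals = [_eval(o, env) for o in expr.operands]
        if "T" in vals:
            return "T"
        return "U" if "U" in vals else "F"
    if isinstance(expr, Comparison):
        if expr.left.path not in env:
            return "U"
        left = env[expr.left.path]
        if isinstance(expr.right, SymbolRef):
            if expr.right.path not in env:
                return "U"
            right = env[expr.right.path]
        else:
            right = _plain(expr.right)
        return "T" if _cmp_vals(expr.op, left, right) else "F"
    if isinstance(expr, InSetExpr):
        if not expr.members:
            return "F"
        if expr.symbol.path not in env:
            return "U"
        v = env[expr.symbol.path]
        return "T" if any(_cmp_vals("eq", v, _plain(m)) for m in expr.members) else "F"
    if isinstance(expr, InRangeExpr):
        if expr.symbol.path not in env:
            return "U"
        v = env[expr.symbol.path]
        ok = True
        if expr.lower is not None:
            ok = ok and _cmp_vals(
                "ge" if expr.lower_inclusive else "gt", v, _plain(expr.lower)
            )
        if expr.upper is not None:
            ok = ok and _cmp_vals(
                "le" if expr.upper_inclusive else "lt", v, _plain(expr.upper)
            )
        return "T" if ok else "F"
    raise TypeError(f"unknown expression {expr!r}")


def _paths_of(expr) -> set:
    out = set()
    stack = [expr]
    while stack:
        e = stack.pop()
        if isinstance(e, ParenExpr):
            stack.append(e.inner)
        elif isinstance(e, NotExpr):
            stack.append(e.operand)
        elif isinstance(e, (AndExpr, OrExpr)):
            stack.extend(e.operands)
        elif isinstance(e, Comparison):
            out.add(e.left.path)
            if isinstance(e.right, SymbolRef):
                out.add(e.right.path)
        elif isinstance(e, (InSetExpr, InRangeExpr)):
            out.add(e.symbol.path)
    return out


class _Replay:
    """A from-scratch interpreter for one run over one document."""

    def __init__(self, document: GuidelineDocument, max_cycles: int = 100):
        self.doc = document
        self.max_cycles = max_cycles
        self.cycles_used = 0
        self.facts: List[tuple] = []  # (path, family-value pair, timestamp)
        self.clock = _EPOCH
        self.done: set = set()
        self.asked: set = set()
        self.marks: dict = {}
        self.fired: List[ActionSummary] = []

    # -- state ------------------------------------------------------------

    def record(self, path, family_value, ts):
        self.facts.append((path, family_value, ts))

    def env(self) -> dict:
        view = {}
        for path, fv, ts in self.facts:
            if ts <= self.clock:
                view[path] = fv
        return view

    # -- one cycle ---------------------------------------------------------

    def cycle(self, allowed=None) -> Tuple[int, int]:
        """Returns (number of actions fired, number of nodes completed)."""
        if self.cycles_used >= self.max_cycles:
            raise RuntimeError("oracle cycle limit reached")
        self.cycles_used += 1
        n_fired = n_done = 0

        def emit(node_id, rule_id, action):
            nonlocal n_fired
            self.fired.append((node_id, rule_id, action.kind, action.payload))
            n_fired += 1
            for path, lit in action.assignments:
                self.record(path, _plain(lit), self.clock)

        def walk(node):
            nonlocal n_fired, n_done
            if node.id in self.done:
                return
            acted = False
            for rule in node.rules:
                if allowed is not None and rule.precondition.trigger_kind not in allowed:
                    continue
                if _eval(rule.precondition.condition, self.env()) == "T":
                    key = (node.id, rule.id)
                    stamp = self.marks.get(key)
                    if stamp is None or stamp != (len(self.facts), self.clock):
                        for action in rule.actions:
                            emit(node.id, rule.id, action)
                        self.marks[key] = (len(self.facts), self.clock)
                        acted = True
            gate = _eval(node.goal.conditions, self.env())
            if gate == "U":
                bound = set(self.env())
                for path in sorted(_paths_of(node.goal.conditions) - bound):
                    if (node.id, path) not in self.asked:
                        self.asked.add((node.id, path))
                        self.fired.append((node.id, None, "data_request", path))
                        n_fired += 1
            if gate == "T":
                for child in node.children:
                    walk(child)
                self.done.add(node.id)
                n_done += 1
            if node.complete_on_action and acted and node.id not in self.done:
                self.done.add(node.id)
                n_done += 1

        for top in self.doc.nodes:
            walk(top)
        return n_fired, n_done

    # -- drivers -----------------------------------------------------------

    def apply_event(self, event):
        if isinstance(event, TimeAdvance):
            if event.at == self.clock:
                return
            if event.at < self.clock:
                raise ValueError("clock regression in oracle replay")
            self.clock = event.at
            self.cycle(allowed={"time_passage"})
        elif isinstance(event, Observation):
            self.record(event.path, _plain(event.value), event.timestamp)
            kind = {
                "reported": "clinical_data_pattern",
                "diagnostic_test": "diagnostic_test_value",
                "treatment_result": "treatment_result",
                "derived": "clinical_data_pattern",
            }[event.provenance]
            self.cycle(allowed={kind})
        else:
            raise TypeError(f"not an event: {event!r}")

    def settle(self):
        while True:
            fired, completed = self.cycle()
            if fired == 0 and completed == 0:
                return


def expected_actions_oracle(
    document: GuidelineDocument, event_stream, max_cycles: int = 100
) -> List[ActionSummary]:
    """Expected (node, rule, kind, payload) firings for a full run."""
    replay = _Replay(document, max_cycles=max_cycles)
    for event in event_stream:
        replay.apply_event(event)
    replay.settle()
    return replay.fired


def oracle_single_cycle(document: GuidelineDocument, observations) -> List[ActionSummary]:
    """Expected firings for one unrestricted cycle from a fresh engine."""
    replay = _Replay(document)
    for obs in observations:
        replay.record(obs.path, _plain(obs.value), _EPOCH)
    replay.cycle()
    return replay.fired
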