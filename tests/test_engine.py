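"""Engine semantics: firing, gating, latching, triggers, quiescence."""

from datetime import datetime, timedelta

import pytest

from cigx.document import (
    Action,
    Goal,
    GuidelineDocument,
    Node,
    Precondition,
    Rule,
)
from cigx.engine import (
    ActionFired,
    EngineState,
    NodeSkippedCompleted,
    RuleEvaluated,
    handle_event,
    run_cycle,
    run_events,
    run_to_quiescence,
    trace_to_lines,
)
from cigx.errors import CycleLimitExceeded
from cigx.expr import Comparison, ConstExpr, LiteralValue, SymbolRef
from cigx.fixtures import build_bacteriuria_document, build_cyclic_document
from cigx.state import Observation, StateStore, TimeAdvance

from conftest import audit_trace

T1 = datetime(2026, 1, 1, 9)
CFU = "labs/urine_culture/cfu"


def _cfu_event(value, ts=T1):
    return Observation(CFU, LiteralValue("integer", value), ts, "diagnostic_test")


def _doc(*nodes):
    return GuidelineDocument(id="g", title="t", version="1", nodes=tuple(nodes))


def _rule(rid, trigger, condition, *actions):
    return Rule(id=rid, precondition=Precondition(trigger, condition), actions=actions)


def _kinds(fired):
    return [f.action.kind for f in fired]


class TestBacteriuriaExample:
    def test_high_cfu_triggers_antibiotic_order_and_node_stays_active(self):
        doc = build_bacteriuria_document()
        engine, store = EngineState(doc), StateStore(clock=T1)
        store.record_observation(_cfu_event(150_000))
        fired, engine, store, trace = run_cycle(engine, store)
        rule_fired = [f for f in fired if f.rule_id is not None]
        assert [(f.rule_id, f.action.kind) for f in rule_fired] == [
            ("high_cfu", "medication_order")
        ]
        assert engine.status("bacteriuria") == "active"

    def test_empty_store_requests_goal_path_and_orders_nothing(self):
        doc = build_bacteriuria_document()
        fired, engine, store, trace = run_events(doc, [])
        assert [(f.action.kind, f.action.payload) for f in fired] == [
            ("data_request", "labs/urine_culture/bacteria_present")
        ]

    def test_two_tier_discrimination_same_goal_different_actions(self):
        """A high count picks the first-line order; a later lower-but-
        positive count picks the alternative recommendation under the same
        goal."""
        doc = build_bacteriuria_document()
        engine, store = EngineState(doc), StateStore(clock=T1)
        first, *_ = handle_event(engine, store, _cfu_event(150_000))
        store.advance_clock(T1 + timedelta(days=7))
        second, *_ = handle_event(
            engine, store, _cfu_event(50_000, T1 + timedelta(days=7))
        )
        assert _kinds([f for f in first if f.rule_id]) == ["medication_order"]
        assert _kinds([f for f in second if f.rule_id]) == ["recommendation", "alert"]


class TestLatchingAndGating:
    def test_satisfied_goal_latches_node(self):
        node = Node(
            id="a",
            goal=Goal(ConstExpr(True)),
            rules=(_rule("r", "time_passage", ConstExpr(True), Action(kind="message")),),
        )
        engine, store = EngineState(_doc(node)), StateStore()
        fired1, _, _, tr1 = run_cycle(engine, store)
        assert engine.status("a") == "completed"
        fired2, _, _, tr2 = run_cycle(engine, store)
        assert fired2 == []
        assert any(isinstance(r, NodeSkippedCompleted) for r in tr2)

    def test_children_gated_by_parent_goal(self):
        child = Node(
            id="child",
            goal=Goal(ConstExpr(False)),
            rules=(
                _rule("cr", "clinical_data_pattern", ConstExpr(True), Action(kind="message", payload="child acted")),
            ),
        )
        gate_expr = Comparison("eq", SymbolRef("w/open"), LiteralValue("boolean", True))
        parent = Node(id="parent", goal=Goal(gate_expr), children=(child,))
        doc = _doc(parent)

        # gate FALSE: child rules never evaluated
        engine, store = EngineState(doc), StateStore()
        store.record_observation(
            Observation("w/open", LiteralValue("boolean", False), store.clock)
        )
        fired, _, _, trace = run_cycle(engine, store)
        assert not any(isinstance(r, RuleEvaluated) for r in trace)
        assert fired == []

        # gate TRUE: child fires in that cycle, then the parent latches
        engine, store = EngineState(doc), StateStore()
        store.record_observation(
            Observation("w/open", LiteralValue("boolean", True), store.clock)
        )
        fired, _, _, trace = run_cycle(engine, store)
        assert [f.action.payload for f in fired] == ["child acted"]
        assert engine.status("parent") == "completed"
        fired2, _, _, _ = run_cycle(engine, store)
        assert fired2 == []
        audit_trace(doc, trace)

    def test_unknown_gate_blocks_children_and_requests_data(self):
        child = Node(
            id="child",
            goal=Goal(ConstExpr(False)),
            rules=(_rule("cr", "time_passage", ConstExpr(True), Action(kind="message")),),
        )
        gate = Comparison("eq", SymbolRef("w/open"), LiteralValue("boolean", True))
        parent = Node(id="parent", goal=Goal(gate), children=(child,))
        engine, store = EngineState(_doc(parent)), StateStore()
        fired, _, _, trace = run_cycle(engine, store)
        assert [(f.action.kind, f.action.payload) for f in fired] == [
            ("data_request", "w/open")
        ]
        assert not any(isinstance(r, RuleEvaluated) for r in trace)

    def test_data_requests_deduplicated_across_cycles(self):
        node = Node(
            id="a",
            goal=Goal(Comparison("eq", SymbolRef("w/x"), LiteralValue("boolean", True))),
        )
        engine, store = EngineState(_doc(node)), StateStore()
        fired1, *_ = run_cycle(engine, store)
        fired2, *_ = run_cycle(engine, store)
        assert _kinds(fired1) == ["data_request"]
        assert fired2 == []

    def test_complete_on_action_latches_regardless_of_goal(self):
        node = Node(
            id="a",
            goal=Goal(ConstExpr(False)),
            complete_on_action=True,
            rules=(_rule("r", "time_passage", ConstExpr(True), Action(kind="alert")),),
        )
        engine, store = EngineState(_doc(node)), StateStore()
        fired, *_ = run_cycle(engine, store)
        assert _kinds(fired) == ["alert"]
        assert engine.status("a") == "completed"


class TestTriggerScoping:
    PATH_FOR_TRIGGER = {
        "clinical_data_pattern": "reported",
        "diagnostic_test_value": "diagnostic_test",
        "treatment_result": "treatment_result",
    }

    def _mixed_doc(self):
        rules = tuple(
            _rule(f"r_{t}", t, ConstExpr(True), Action(kind="message", payload=t))
            for t in (
                "time_passage",
                "clinical_data_pattern",
                "diagnostic_test_value",
                "treatment_result",
            )
        )
        return _doc(Node(id="mixed", goal=Goal(ConstExpr(False)), rules=rules))

    def test_each_event_kind_fires_only_matching_rules(self):
        doc = self._mixed_doc()
        engine, store = EngineState(doc), StateStore()
        events = [
            TimeAdvance(T1),
            Observation("w/a", LiteralValue("integer", 1), T1, "reported"),
            Observation("w/b", LiteralValue("integer", 1), T1, "diagnostic_test"),
            Observation("w/c", LiteralValue("integer", 1), T1, "treatment_result"),
        ]
        expected = [
            "time_passage",
            "clinical_data_pattern",
            "diagnostic_test_value",
            "treatment_result",
        ]
        for event, want in zip(events, expected):
            fired, *_ = handle_event(engine, store, event)
            assert [f.action.payload for f in fired] == [want]

    def test_time_advance_with_no_time_rules_fires_nothing(self):
        node = Node(
            id="a",
            goal=Goal(ConstExpr(False)),
            rules=(_rule("r", "treatment_result", ConstExpr(True), Action(kind="message")),),
        )
        engine, store = EngineState(_doc(node)), StateStore()
        fired, *_ = handle_event(engine, store, TimeAdvance(T1))
        assert fired == []


class TestQuiescence:
    def test_bacteriuria_run_reaches_confirmed_fixpoint(self):
        doc = build_bacteriuria_document()
        engine, store = EngineState(doc), StateStore(clock=T1)
        handle_event(engine, store, _cfu_event(150_000))
        fired, engine, store, _ = run_to_quiescence(engine, store)
        # fixpoint is stable: one more cycle fires nothing
        again, *_ = run_cycle(engine, store)
        assert again == []

    def test_empty_document_quiesces_immediately(self):
        doc = _doc(Node(id="only", goal=Goal(ConstExpr(False))))
        engine, store = EngineState(doc), StateStore()
        fired, engine, store, trace = run_to_quiescence(engine, store)
        assert fired == []
        assert engine.cycle == 1

    def test_cyclic_fixture_hits_cycle_limit_with_repeating_set(self):
        doc = build_cyclic_document()
        seed_event = Observation("sim/flag", LiteralValue("boolean", False), T1, "reported")
        with pytest.raises(CycleLimitExceeded) as exc_info:
            run_events(doc, [TimeAdvance(T1), seed_event])
        exc = exc_info.value
        assert exc.max_cycles == 100
        assert ("cyclic", "flip_on", "calculation") in exc.repeating_actions
        assert ("cyclic", "flip_off", "calculation") in exc.repeating_actions


class TestIntraCycleVisibility:
    def test_derived_values_visible_to_later_nodes_same_cycle(self):
        first = Node(
            id="first",
            goal=Goal(ConstExpr(False)),
            rules=(
                _rule(
                    "calc",
                    "time_passage",
                    ConstExpr(True),
                    Action(
                        kind="calculation",
                        payload="set flag",
                        assignments=(("w/flag", LiteralValue("boolean", True)),),
                    ),
                ),
            ),
        )
        second = Node(
            id="second",
            goal=Goal(ConstExpr(False)),
            rules=(
                _rule(
                    "consume",
                    "time_passage",
                    Comparison("eq", SymbolRef("w/flag"), LiteralValue("boolean", True)),
                    Action(kind="message", payload="saw flag"),
                ),
            ),
        )
        engine, store = EngineState(_doc(first, second)), StateStore()
        fired, *_ = run_cycle(engine, store)
        assert [f.action.payload for f in fired] == ["set flag", "saw flag"]
        obs = store.observations[-1]
        assert (obs.path, obs.provenance) == ("w/flag", "derived")


class TestDeterminism:
    def test_identical_runs_produce_identical_traces(self):
        doc = build_bacteriuria_document()
        events = [TimeAdvance(T1), _cfu_event(50_000)]

        def one_run():
            fired, _, _, trace = run_events(doc, list(events))
            return trace_to_lines(trace)

        assert one_run() == one_run()
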