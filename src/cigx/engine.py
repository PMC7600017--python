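"""Match-and-resolve execution of a guideline against the patient state.

Each *cycle* walks the node hierarchy depth-first in document order.  For
an active node, every rule's precondition is evaluated against the current
state snapshot and, when it holds, the rule's actions fire (derived-value
assignments are written back immediately, so later rules in the same cycle
see them).  After its rules, the node's goal is evaluated: a TRUE goal
gives the node's children one evaluation pass and then latches the node as
completed — it never executes again.  A FALSE or UNKNOWN goal gates the
subtree closed, and an UNKNOWN goal additionally synthesises a
``data_request`` for each unbound path it references (once per node/path
per run), so missing information is asked for instead of acted on.

Events enter through :func:`handle_event`: the observation or clock
advance is applied to the store and only rules whose trigger kind matches
the event kind may fire in the immediately following cycle.
:func:`run_to_quiescence` then iterates unrestricted cycles to a fixpoint.

Firing is refractory: a rule whose precondition remains TRUE does not fire
again until new information (a new observation or a clock change) has
arrived since its last firing.  This is what lets runs reach quiescence
while still allowing genuinely cyclic rule sets (whose calculations keep
appending state) to be caught by the cycle limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, List, Optional, Tuple, Union

from .document import Action, GuidelineDocument, Node, Rule, iter_nodes
from .errors import CycleLimitExceeded, TypeMismatch
from .expr import FALSE, TRUE, UNKNOWN, TruthValue, evaluate, referenced_symbols
from .state import Event, Observation, StateStore, TimeAdvance

#: provenance of an observation event -> trigger kind scoped for that cycle
TRIGGER_FOR_PROVENANCE = {
    "reported": "clinical_data_pattern",
    "diagnostic_test": "diagnostic_test_value",
    "treatment_result": "treatment_result",
    "derived": "clinical_data_pattern",
}

ACTIVE = "active"
COMPLETED = "completed"


@dataclass(frozen=True)
class FiredAction:
    node_id: str
    rule_id: Optional[str]  # None for synthesised data requests
    action: Action
    cycle: int
    timestamp: datetime


# ---- trace records -------------------------------------------------------


@dataclass(frozen=True)
class NodeEvaluated:
    cycle: int
    node_id: str
    gate_result: TruthValue


@dataclass(frozen=True)
class RuleEvaluated:
    cycle: int
    node_id: str
    rule_id: str
    precondition_result: TruthValue


@dataclass(frozen=True)
class ActionFired:
    cycle: int
    fired: FiredAction


@dataclass(frozen=True)
class GoalSatisfied:
    cycle: int
    node_id: str


@dataclass(frozen=True)
class NodeSkippedCompleted:
    cycle: int
    node_id: str


@dataclass(frozen=True)
class NodeSkippedGated:
    cycle: int
    node_id: str


TraceRecord = Union[
    NodeEvaluated,
    RuleEvaluated,
    ActionFired,
    GoalSatisfied,
    NodeSkippedCompleted,
    NodeSkippedGated,
]


class EngineState:
    """Per-run engine status: node statuses, cycle counter, bookkeeping."""

    def __init__(self, document: GuidelineDocument, max_cycles: int = 100):
        if max_cycles < 1:
            raise ValueError("max_cycles must be positive")
        self.document = document
        self.max_cycles = max_cycles
        self.cycle = 0
        self.statuses = {node.id: ACTIVE for node, _, _ in iter_nodes(document)}
        # (node_id, path) pairs already asked for -- request-storm guard
        self._requested: set = set()
        # (node_id, rule_id) -> (observation count, clock) at last firing
        self._fire_marks: dict = {}

    def status(self, node_id: str) -> str:
        return self.statuses[node_id]

    def complete(self, node_id: str) -> None:
        self.statuses[node_id] = COMPLETED  # never transitions back


def run_cycle(
    engine: EngineState,
    store: StateStore,
    allowed_triggers: Optional[frozenset] = None,
) -> Tuple[List[FiredAction], EngineState, StateStore, List[TraceRecord]]:
    """Execute one evaluation cycle; returns fired actions and trace."""
    if engine.cycle >= engine.max_cycles:
        raise CycleLimitExceeded(engine.max_cycles, [])
    cycle = engine.cycle
    fired: List[FiredAction] = []
    trace: List[TraceRecord] = []

    def fire(node_id, rule_id, action):
        rec = FiredAction(node_id, rule_id, action, cycle, store.clock)
        fired.append(rec)
        trace.append(ActionFired(cycle, rec))
        for path, value in action.assignments:
            store.record_observation(
                Observation(path, value, timestamp=store.clock, provenance="derived")
            )

    def should_fire(node, rule):
        mark = engine._fire_marks.get((node.id, rule.id))
        return mark is None or mark != (len(store.observations), store.clock)

    def visit(node: Node):
        if engine.status(node.id) == COMPLETED:
            trace.append(NodeSkippedCompleted(cycle, node.id))
            return
        fired_any = False
        for rule in node.rules:
            if (
                allowed_triggers is not None
                and rule.precondition.trigger_kind not in allowed_triggers
            ):
                continue
            try:
                result = evaluate(rule.precondition.condition, store.snapshot())
            except TypeMismatch as exc:
                raise TypeMismatch(
                    f"node {node.id!r} rule {rule.id!r}: {exc}"
                ) from None
            trace.append(RuleEvaluated(cycle, node.id, rule.id, result))
            if result is TRUE and should_fire(node, rule):
                for action in rule.actions:
                    fire(node.id, rule.id, action)
                engine._fire_marks[(node.id, rule.id)] = (
                    len(store.observations),
                    store.clock,
                )
                fired_any = True
        try:
            gate = evaluate(node.goal.conditions, store.snapshot())
        except TypeMismatch as exc:
            raise TypeMismatch(f"node {node.id!r} goal: {exc}") from None
        trace.append(NodeEvaluated(cycle, node.id, gate))
        if gate is UNKNOWN:
            bound = store.snapshot().paths()
            for path in sorted(referenced_symbols(node.goal.conditions) - bound):
                if (node.id, path) not in engine._requested:
                    engine._requested.add((node.id, path))
                    fire(node.id, None, Action(kind="data_request", payload=path))
        if gate is TRUE:
            for child in node.children:
                visit(child)
            engine.complete(node.id)
            trace.append(GoalSatisfied(cycle, node.id))
        else:
            for child in node.children:
                trace.append(NodeSkippedGated(cycle, child.id))
        if node.complete_on_action and fired_any:
            engine.complete(node.id)

    for top in engine.document.nodes:
        visit(top)
    engine.cycle += 1
    return fired, engine, store, trace


def handle_event(
    engine: EngineState, store: StateStore, event: Event
) -> Tuple[List[FiredAction], EngineState, StateStore, List[TraceRecord]]:
    """Apply one event and run the trigger-scoped cycle it provokes."""
    if isinstance(event, TimeAdvance):
        if event.at == store.clock:  # zero advance: no event, no cycle
            return [], engine, store, []
        store.advance_clock(event.at)
        allowed = frozenset({"time_passage"})
    elif isinstance(event, Observation):
        store.record_observation(event)
        allowed = frozenset({TRIGGER_FOR_PROVENANCE[event.provenance]})
    else:
        raise TypeError(f"not an event: {event!r}")
    return run_cycle(engine, store, allowed_triggers=allowed)


def run_to_quiescence(
    engine: EngineState, store: StateStore
) -> Tuple[List[FiredAction], EngineState, StateStore, List[TraceRecord]]:
    """Iterate unrestricted cycles until a fixpoint (or the cycle limit).

    The fixpoint is confirmed: the final cycle fired nothing and changed no
    node status.  On cycle-limit exhaustion the raised
    :class:`CycleLimitExceeded` carries the repeating action set plus the
    partial trace (``exc.trace`` / ``exc.fired``) for diagnosis.
    """
    all_fired: List[FiredAction] = []
    trace: List[TraceRecord] = []
    last_fired: List[FiredAction] = []
    while True:
        if engine.cycle >= engine.max_cycles:
            exc = CycleLimitExceeded(
                engine.max_cycles,
                [(f.node_id, f.rule_id, f.action.kind) for f in last_fired],
            )
            exc.trace = trace
            exc.fired = all_fired
            raise exc
        before = dict(engine.statuses)
        fired, _, _, tr = run_cycle(engine, store)
        all_fired.extend(fired)
        trace.extend(tr)
        if not fired and engine.statuses == before:
            return all_fired, engine, store, trace
        last_fired = fired


def run_events(
    document: GuidelineDocument,
    events: Iterable[Event],
    max_cycles: int = 100,
    store: Optional[StateStore] = None,
) -> Tuple[List[FiredAction], EngineState, StateStore, List[TraceRecord]]:
    """Convenience driver: handle each event in turn, then run to fixpoint."""
    engine = EngineState(document, max_cycles=max_cycles)
    store = store if store is not None else StateStore()
    all_fired: List[FiredAction] = []
    trace: List[TraceRecord] = []
    try:
        for event in events:
            fired, _, _, tr = handle_event(engine, store, event)
            all_fired.extend(fired)
            trace.extend(tr)
        fired, _, _, tr = run_to_quiescence(engine, store)
    except CycleLimitExceeded as exc:
        exc.trace = trace + getattr(exc, "trace", [])
        exc.fired = all_fired + getattr(exc, "fired", [])
        raise
    all_fired.extend(fired)
    trace.extend(tr)
    return all_fired, engine, store, trace


# --------------------------------------------------------------------------
# Trace / action export


def _truth_text(t: TruthValue) -> str:
    return t.value


def trace_to_lines(trace: Iterable[TraceRecord]) -> List[str]:
    """Line-delimited structured form: one record per line, stable fields."""
    lines = []
    for rec in trace:
        if isinstance(rec, NodeEvaluated):
            lines.append(
                f"{rec.cycle}\tNodeEvaluated\tnode={rec.node_id}\t"
                f"gate={_truth_text(rec.gate_result)}"
            )
        elif isinstance(rec, RuleEvaluated):
            lines.append(
                f"{rec.cycle}\tRuleEvaluated\tnode={rec.node_id}\t"
                f"rule={rec.rule_id}\tresult={_truth_text(rec.precondition_result)}"
            )
        elif isinstance(rec, ActionFired):
            f = rec.fired
            lines.append(
                f"{rec.cycle}\tActionFired\tnode={f.node_id}\t"
                f"rule={f.rule_id or '-'}\tkind={f.action.kind}\t"
                f"payload={f.action.payload}"
            )
        elif isinstance(rec, GoalSatisfied):
            lines.append(f"{rec.cycle}\tGoalSatisfied\tnode={rec.node_id}")
        elif isinstance(rec, NodeSkippedCompleted):
            lines.append(f"{rec.cycle}\tNodeSkippedCompleted\tnode={rec.node_id}")
        elif isinstance(rec, NodeSkippedGated):
            lines.append(f"{rec.cycle}\tNodeSkippedGated\tnode={rec.node_id}")
        else:
            raise TypeError(f"unknown trace record {rec!r}")
    return lines


def render_trace(trace: Iterable[TraceRecord]) -> str:
    """Human-readable rendering (indentation-free, one sentence per line)."""
    out = []
    for rec in trace:
        if isinstance(rec, NodeEvaluated):
            out.append(
                f"[cycle {rec.cycle}] node {rec.node_id}: goal is "
                f"{_truth_text(rec.gate_result)}"
            )
        elif isinstance(rec, RuleEvaluated):
            out.append(
                f"[cycle {rec.cycle}] node {rec.node_id}, rule {rec.rule_id}: "
                f"precondition is {_truth_text(rec.precondition_result)}"
            )
        elif isinstance(rec, ActionFired):
            f = rec.fired
            who = f"rule {f.rule_id}" if f.rule_id else "missing-data check"
            out.append(
                f"[cycle {rec.cycle}] node {f.node_id}, {who} fired "
                f"{f.action.kind}: {f.action.payload}"
            )
        elif isinstance(rec, GoalSatisfied):
            out.append(f"[cycle {rec.cycle}] node {rec.node_id} completed its goal")
        elif isinstance(rec, NodeSkippedCompleted):
            out.append(f"[cycle {rec.cycle}] node {rec.node_id} skipped (completed)")
        elif isinstance(rec, NodeSkippedGated):
            out.append(f"[cycle {rec.cycle}] node {rec.node_id} skipped (gated)")
    return "\n".join(out) + ("\n" if out else "")


_ACTIONS_HEADER = (
    "timestamp\tpath\ttype\tvalue\tprovenance\tkind\tnode\trule\tpayload"
)


def fired_actions_to_text(fired: Iterable[FiredAction]) -> str:
    """Event-stream-like TSV with added action-kind (and context) fields.

    Actions carrying assignments list their first assignment in the
    path/type/value columns; others leave them empty.
    """
    lines = [_ACTIONS_HEADER]
    for f in fired:
        if f.action.assignments:
            path, value = f.action.assignments[0]
            p, t, v, prov = path, value.kind, value.to_text(), "derived"
        else:
            p = t = v = prov = ""
        lines.append(
            "\t".join(
                (
                    f.timestamp.isoformat(),
                    p,
                    t,
                    v,
                    prov,
                    f.action.kind,
                    f.node_id,
                    f.rule_id or "-",
                    f.action.payload,
                )
            )
        )
    return "\n".join(lines) + "\n"
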