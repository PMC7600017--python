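"""Guideline document model: hierarchical nodes of goals, rules and actions.

A document is an ordered tree.  Every node carries a *goal* — the boolean
completion criterion that, once satisfied, retires the node — plus an
ordered list of rules (a triggered precondition guarding one or more
actions) and child nodes.  Document order is the canonical evaluation
order; rule precedence is expressed purely through ordering and hierarchy.

Reading and writing go through the bundled XSD (``schema/cigx.xsd``), so
every document the loader accepts, and every document the writer emits,
is schema-valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Optional, Tuple

from lxml import etree

from .errors import DuplicateIdError, ParseError, ValidationError
from .expr import (
    NS,
    BoolExpr,
    LiteralValue,
    expression_to_element,
    parse_expression,
)

_Q = "{%s}" % NS

TRIGGER_KINDS = (
    "time_passage",
    "clinical_data_pattern",
    "diagnostic_test_value",
    "treatment_result",
)

ACTION_KINDS = (
    "data_request",
    "message",
    "alert",
    "recommendation",
    "calculation",
    "medication_order",
    "lab_test_request",
    "procedure_request",
    "referral",
    "notification",
)


@dataclass(frozen=True)
class Goal:
    """A node's completion criterion."""

    conditions: BoolExpr
    description: str = ""


@dataclass(frozen=True)
class Precondition:
    trigger_kind: str
    condition: BoolExpr

    def __post_init__(self):
        if self.trigger_kind not in TRIGGER_KINDS:
            raise ValueError(f"unknown trigger kind {self.trigger_kind!r}")


@dataclass(frozen=True)
class Action:
    """An engine output: advice, an order, a request, or a derived-value write.

    ``assignments`` are (semantic path, literal) pairs written into the
    patient state when the action fires; this is how a ``calculation``
    action materialises derived values.
    """

    kind: str
    payload: str = ""
    assignments: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "assignments", tuple(self.assignments))
        if self.kind not in ACTION_KINDS:
            raise ValueError(f"unknown action kind {self.kind!r}")
        for path, value in self.assignments:
            if not isinstance(value, LiteralValue):
                raise ValueError("assignment values must be LiteralValues")
        if self.kind == "calculation" and not self.assignments:
            raise ValueError("calculation actions require at least one assignment")


@dataclass(frozen=True)
class Rule:
    id: str
    precondition: Precondition
    actions: tuple

    def __post_init__(self):
        object.__setattr__(self, "actions", tuple(self.actions))
        if not self.actions:
            raise ValueError(f"rule {self.id!r} has no actions")


@dataclass(frozen=True)
class Node:
    id: str
    goal: Goal
    label: str = ""
    rules: tuple = ()
    children: tuple = ()
    complete_on_action: bool = False

    def __post_init__(self):
        object.__setattr__(self, "rules", tuple(self.rules))
        object.__setattr__(self, "children", tuple(self.children))
        seen = set()
        for r in self.rules:
            if r.id in seen:
                raise DuplicateIdError(f"duplicate rule id {r.id!r} in node {self.id!r}")
            seen.add(r.id)


@dataclass(frozen=True)
class GuidelineDocument:
    id: str
    title: str
    version: str
    nodes: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        if not self.nodes:
            raise ValidationError(["a guideline requires at least one node"])
        seen = set()
        for node, _, _ in iter_nodes(self):
            if node.id in seen:
                raise DuplicateIdError(f"duplicate node id {node.id!r}")
            seen.add(node.id)

    def node_by_id(self, node_id: str) -> Node:
        for node, _, _ in iter_nodes(self):
            if node.id == node_id:
                return node
        raise KeyError(node_id)


def iter_nodes(
    doc: GuidelineDocument,
) -> Iterator[Tuple[Node, int, Optional[str]]]:
    """Depth-first pre-order traversal yielding (node, depth, parent id)."""

    def walk(node, depth, parent_id):
        yield node, depth, parent_id
        for child in node.children:
            yield from walk(child, depth + 1, node.id)

    for top in doc.nodes:
        yield from walk(top, 0, None)


# --------------------------------------------------------------------------
# Schema validation


def _schema_dir():
    return resources.files("cigx") / "schema"


def load_schema(name: str = "cigx.xsd") -> etree.XMLSchema:
    with resources.as_file(_schema_dir() / name) as path:
        return etree.XMLSchema(etree.parse(str(path)))


_SCHEMA_CACHE: dict = {}


def _schema(name="cigx.xsd") -> etree.XMLSchema:
    if name not in _SCHEMA_CACHE:
        _SCHEMA_CACHE[name] = load_schema(name)
    return _SCHEMA_CACHE[name]


@dataclass(frozen=True)
class Violation:
    element_path: str
    message: str

    def __str__(self):
        return f"{self.element_path}: {self.message}"


def validate_document(xml_bytes: bytes) -> list:
    """Validate bytes against the guideline XSD; violations come back as data."""
    try:
        root = etree.fromstring(xml_bytes)
    except etree.XMLSyntaxError as exc:
        return [Violation("/", f"not well-formed XML: {exc}")]
    schema = _schema()
    if schema.validate(root):
        return []
    return [
        Violation(err.path or "/", err.message) for err in schema.error_log
    ]


def validate_expression_fragment(xml_bytes: bytes) -> list:
    """Validate a bare expression fragment (wrapped in <conditions>)."""
    try:
        root = etree.fromstring(xml_bytes)
    except etree.XMLSyntaxError as exc:
        return [Violation("/", f"not well-formed XML: {exc}")]
    if etree.QName(root).localname != "conditions":
        wrapper = etree.Element(_Q + "conditions", nsmap={None: NS})
        wrapper.append(root)
        root = wrapper
    schema = _schema("cigx-expr.xsd")
    if schema.validate(root):
        return []
    return [Violation(err.path or "/", err.message) for err in schema.error_log]


# --------------------------------------------------------------------------
# Reading


def load_document(xml_bytes: bytes) -> GuidelineDocument:
    violations = validate_document(xml_bytes)
    if violations:
        raise ValidationError(violations)
    root = etree.fromstring(xml_bytes)
    return GuidelineDocument(
        id=root.get("id"),
        title=root.get("title"),
        version=root.get("version"),
        nodes=[_load_node(n) for n in root.iterchildren(_Q + "node")],
    )


def load_document_file(path) -> GuidelineDocument:
    with open(path, "rb") as fh:
        return load_document(fh.read())


def _load_node(elem) -> Node:
    goal_elem = elem.find(_Q + "goal")
    desc = goal_elem.findtext(_Q + "description", default="")
    cond_elem = goal_elem.find(_Q + "conditions")
    children_exprs = [c for c in cond_elem if isinstance(c.tag, str)]
    goal = Goal(conditions=parse_expression(children_exprs[0]), description=desc)
    return Node(
        id=elem.get("id"),
        label=elem.get("label", ""),
        goal=goal,
        complete_on_action=elem.get("complete-on-action", "false") in ("true", "1"),
        rules=[_load_rule(r) for r in elem.iterchildren(_Q + "rule")],
        children=[_load_node(n) for n in elem.iterchildren(_Q + "node")],
    )


def _load_rule(elem) -> Rule:
    pre = elem.find(_Q + "precondition")
    expr_children = [c for c in pre if isinstance(c.tag, str)]
    precondition = Precondition(
        trigger_kind=pre.get("trigger"),
        condition=parse_expression(expr_children[0]),
    )
    actions = []
    for act in elem.iterchildren(_Q + "action"):
        assignments = []
        for asg in act.iterchildren(_Q + "assign"):
            assignments.append(
                (asg.get("path"), LiteralValue.from_text(asg.get("type"), asg.get("value")))
            )
        actions.append(
            Action(
                kind=act.get("kind"),
                payload=act.findtext(_Q + "payload", default=""),
                assignments=assignments,
            )
        )
    return Rule(id=elem.get("id"), precondition=precondition, actions=actions)


# --------------------------------------------------------------------------
# Writing


def write_document(doc: GuidelineDocument) -> bytes:
    root = etree.Element(_Q + "guideline", nsmap={None: NS})
    root.set("id", doc.id)
    root.set("title", doc.title)
    root.set("version", doc.version)
    for node in doc.nodes:
        root.append(_node_to_element(node))
    out = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    leftover = validate_document(out)
    if leftover:  # defensive: writer must only emit schema-valid XML
        raise ValidationError(leftover)
    return out


def write_document_file(doc: GuidelineDocument, path) -> None:
    data = write_document(doc)
    with open(path, "wb") as fh:
        fh.write(data)


def _node_to_element(node: Node):
    elem = etree.Element(_Q + "node")
    elem.set("id", node.id)
    if node.label:
        elem.set("label", node.label)
    if node.complete_on_action:
        elem.set("complete-on-action", "true")
    goal = etree.SubElement(elem, _Q + "goal")
    if node.goal.description:
        desc = etree.SubElement(goal, _Q + "description")
        desc.text = node.goal.description
    cond = etree.SubElement(goal, _Q + "conditions")
    cond.append(expression_to_element(node.goal.conditions))
    for rule in node.rules:
        relem = etree.SubElement(elem, _Q + "rule")
        relem.set("id", rule.id)
        pre = etree.SubElement(relem, _Q + "precondition")
        pre.set("trigger", rule.precondition.trigger_kind)
        pre.append(expression_to_element(rule.precondition.condition))
        for action in rule.actions:
            aelem = etree.SubElement(relem, _Q + "action")
            aelem.set("kind", action.kind)
            payload = etree.SubElement(aelem, _Q + "payload")
            payload.text = action.payload
            for path, value in action.assignments:
                asg = etree.SubElement(aelem, _Q + "assign")
                asg.set("path", path)
                asg.set("type", value.kind)
                asg.set("value", value.to_text())
    for child in node.children:
        elem.append(_node_to_element(child))
    return elem
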