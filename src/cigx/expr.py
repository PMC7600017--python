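"""Boolean condition language used by guideline goals and preconditions.

Expressions are finite trees of logical connectives (``and``, ``or``,
``not``), comparisons between a *symbol* (a semantic path into the patient
state) and a literal value or second symbol, set membership (``in-set``),
interval membership (``in-range``) and an explicit parenthesis node.

Evaluation is three-valued (Kleene): a leaf over an unbound symbol yields
UNKNOWN, and UNKNOWN propagates through the connectives unless the bound
operands already force the result (``FALSE and UNKNOWN`` is FALSE,
``TRUE or UNKNOWN`` is TRUE).  This is what lets the inference engine both
refuse to act on missing patient data and know exactly which paths to
request.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date, datetime
from enum import Enum
from typing import Iterable, Mapping, Optional, Union

from lxml import etree

from .errors import ParseError, TypeMismatch

NS = "urn:cigx:1"
_Q = "{%s}" % NS

VALUE_KINDS = ("boolean", "integer", "decimal", "text", "date", "datetime")
_NUMERIC = frozenset({"integer", "decimal"})

_SEGMENT = r"[A-Za-z_][A-Za-z0-9_]*"
PATH_RE = re.compile(rf"^{_SEGMENT}(/{_SEGMENT})*$")


class TruthValue(Enum):
    """Kleene three-valued truth."""

    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"

    def __bool__(self):  # guard against accidental two-valued use
        raise TypeError("TruthValue is three-valued; compare explicitly")


TRUE, FALSE, UNKNOWN = TruthValue.TRUE, TruthValue.FALSE, TruthValue.UNKNOWN


def kleene_not(a: TruthValue) -> TruthValue:
    if a is TRUE:
        return FALSE
    if a is FALSE:
        return TRUE
    return UNKNOWN


def kleene_and(values: Iterable[TruthValue]) -> TruthValue:
    result = TRUE
    for v in values:
        if v is FALSE:
            return FALSE
        if v is UNKNOWN:
            result = UNKNOWN
    return result


def kleene_or(values: Iterable[TruthValue]) -> TruthValue:
    result = FALSE
    for v in values:
        if v is TRUE:
            return TRUE
        if v is UNKNOWN:
            result = UNKNOWN
    return result


@dataclass(frozen=True)
class SymbolRef:
    """A reference to a patient-state concept by its semantic path."""

    path: str

    def __post_init__(self):
        if not isinstance(self.path, str) or not PATH_RE.match(self.path):
            raise ValueError(f"invalid semantic path: {self.path!r}")


@dataclass(frozen=True)
class LiteralValue:
    """A typed constant: boolean, integer, decimal, text, date or datetime."""

    kind: str
    value: object

    def __post_init__(self):
        if self.kind not in VALUE_KINDS:
            raise ValueError(f"unknown value kind: {self.kind!r}")
        v = self.value
        ok = {
            "boolean": lambda: isinstance(v, bool),
            "integer": lambda: isinstance(v, int) and not isinstance(v, bool),
            "decimal": lambda: isinstance(v, (int, float))
            and not isinstance(v, bool)
            and float(v) == float(v)
            and abs(float(v)) != float("inf"),
            "text": lambda: isinstance(v, str),
            "date": lambda: isinstance(v, date) and not isinstance(v, datetime),
            "datetime": lambda: isinstance(v, datetime),
        }[self.kind]()
        if not ok:
            raise ValueError(f"value {v!r} does not match kind {self.kind!r}")
        if self.kind == "decimal":
            object.__setattr__(self, "value", float(v))

    def to_text(self) -> str:
        if self.kind == "boolean":
            return "true" if self.value else "false"
        if self.kind in ("date", "datetime"):
            return self.value.isoformat()
        if self.kind == "decimal":
            return repr(self.value)
        return str(self.value)

    @staticmethod
    def from_text(kind: str, text: str) -> "LiteralValue":
        text = text if text is not None else ""
        try:
            if kind == "boolean":
                if text not in ("true", "false"):
                    raise ValueError(text)
                return LiteralValue("boolean", text == "true")
            if kind == "integer":
                return LiteralValue("integer", int(text))
            if kind == "decimal":
                return LiteralValue("decimal", float(text))
            if kind == "text":
                return LiteralValue("text", text)
            if kind == "date":
                return LiteralValue("date", date.fromisoformat(text))
            if kind == "datetime":
                return LiteralValue("datetime", datetime.fromisoformat(text))
        except ValueError as exc:
            raise ParseError(f"malformed {kind} literal {text!r}: {exc}") from None
        raise ParseError(f"unknown value kind {kind!r}")


class Bindings:
    """Immutable snapshot mapping semantic paths to literal values.

    Absence of a path (``get`` returning ``None``) is the representation of
    "value unknown" and is distinguishable from every bound value.
    """

    __slots__ = ("_entries",)

    def __init__(self, entries: Optional[Mapping[str, LiteralValue]] = None):
        self._entries = dict(entries or {})

    def get(self, path: str) -> Optional[LiteralValue]:
        return self._entries.get(path)

    def __contains__(self, path: str) -> bool:
        return path in self._entries

    def paths(self):
        return frozenset(self._entries)

    def as_dict(self) -> dict:
        return dict(self._entries)

    def __repr__(self):
        return f"Bindings({self._entries!r})"


# --------------------------------------------------------------------------
# Expression tree


class BoolExpr:
    """Abstract base for every expression variant."""

    __slots__ = ()


@dataclass(frozen=True)
class ConstExpr(BoolExpr):
    truth: bool

    def __post_init__(self):
        if not isinstance(self.truth, bool):
            raise ValueError("ConstExpr truth must be a bool")


@dataclass(frozen=True)
class AndExpr(BoolExpr):
    operands: tuple

    def __post_init__(self):
        object.__setattr__(self, "operands", tuple(self.operands))
        _check_operands(self.operands, minimum=2)


@dataclass(frozen=True)
class OrExpr(BoolExpr):
    operands: tuple

    def __post_init__(self):
        object.__setattr__(self, "operands", tuple(self.operands))
        _check_operands(self.operands, minimum=2)


@dataclass(frozen=True)
class NotExpr(BoolExpr):
    operand: BoolExpr

    def __post_init__(self):
        _check_operands((self.operand,), minimum=1)


@dataclass(frozen=True)
class ParenExpr(BoolExpr):
    """Explicit parenthesis; semantically transparent."""

    inner: BoolExpr

    def __post_init__(self):
        _check_operands((self.inner,), minimum=1)


COMPARISON_OPS = ("eq", "ne", "gt", "lt", "ge", "le")


@dataclass(frozen=True)
class Comparison(BoolExpr):
    op: str
    left: SymbolRef
    right: Union[LiteralValue, SymbolRef]

    def __post_init__(self):
        if self.op not in COMPARISON_OPS:
            raise ValueError(f"unknown comparison op {self.op!r}")
        if not isinstance(self.left, SymbolRef):
            raise ValueError("comparison left side must be a SymbolRef")
        if not isinstance(self.right, (LiteralValue, SymbolRef)):
            raise ValueError("comparison right side must be a LiteralValue or SymbolRef")


@dataclass(frozen=True)
class InSetExpr(BoolExpr):
    symbol: SymbolRef
    members: tuple = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "members", tuple(self.members))
        if not isinstance(self.symbol, SymbolRef):
            raise ValueError("in-set symbol must be a SymbolRef")
        kinds = set()
        for m in self.members:
            if not isinstance(m, LiteralValue):
                raise ValueError("in-set members must be LiteralValues")
            kinds.add("numeric" if m.kind in _NUMERIC else m.kind)
        if len(kinds) > 1:
            raise ValueError("in-set members must share one comparable kind")


@dataclass(frozen=True)
class InRangeExpr(BoolExpr):
    symbol: SymbolRef
    lower: Optional[LiteralValue] = None
    upper: Optional[LiteralValue] = None
    lower_inclusive: bool = True
    upper_inclusive: bool = True

    def __post_init__(self):
        if not isinstance(self.symbol, SymbolRef):
            raise ValueError("in-range symbol must be a SymbolRef")
        if self.lower is None and self.upper is None:
            raise ValueError("in-range requires at least one bound")
        for b in (self.lower, self.upper):
            if b is not None and not isinstance(b, LiteralValue):
                raise ValueError("in-range bounds must be LiteralValues")
        if self.lower is not None and self.upper is not None:
            if not _kinds_comparable(self.lower.kind, self.upper.kind):
                raise ValueError("in-range bounds must be of one comparable kind")
            if _ordering_key(self.lower) > _ordering_key(self.upper):
                raise ValueError("in-range lower bound exceeds upper bound")


def _check_operands(operands, minimum):
    if len(operands) < minimum:
        raise ValueError(f"operator requires at least {minimum} operand(s)")
    for o in operands:
        if not isinstance(o, BoolExpr):
            raise ValueError(f"operand {o!r} is not a BoolExpr")


def _kinds_comparable(a: str, b: str) -> bool:
    return a == b or (a in _NUMERIC and b in _NUMERIC)


def _ordering_key(lit: LiteralValue):
    return float(lit.value) if lit.kind in _NUMERIC else lit.value


# --------------------------------------------------------------------------
# Evaluation


def evaluate(expr: BoolExpr, bindings: Bindings) -> TruthValue:
    """Evaluate ``expr`` against a binding snapshot, Kleene-style.

    Raises :class:`TypeMismatch` when a comparison pairs non-comparable
    kinds under the concrete binding (numeric kinds promote to each other;
    everything else must match exactly, and booleans only support eq/ne).
    """
    if isinstance(expr, ConstExpr):
        return TRUE if expr.truth else FALSE
    if isinstance(expr, ParenExpr):
        return evaluate(expr.inner, bindings)
    if isinstance(expr, NotExpr):
        return kleene_not(evaluate(expr.operand, bindings))
    if isinstance(expr, AndExpr):
        return kleene_and(evaluate(o, bindings) for o in expr.operands)
    if isinstance(expr, OrExpr):
        return kleene_or(evaluate(o, bindings) for o in expr.operands)
    if isinstance(expr, Comparison):
        left = bindings.get(expr.left.path)
        right = (
            bindings.get(expr.right.path)
            if isinstance(expr.right, SymbolRef)
            else expr.right
        )
        if left is None or right is None:
            return UNKNOWN
        return _compare(expr.op, left, right)
    if isinstance(expr, InSetExpr):
        if not expr.members:  # empty set: vacuously false, even when unbound
            return FALSE
        value = bindings.get(expr.symbol.path)
        if value is None:
            return UNKNOWN
        for m in expr.members:
            if _compare("eq", value, m) is TRUE:
                return TRUE
        return FALSE
    if isinstance(expr, InRangeExpr):
        value = bindings.get(expr.symbol.path)
        if value is None:
            return UNKNOWN
        result = TRUE
        if expr.lower is not None:
            op = "ge" if expr.lower_inclusive else "gt"
            result = kleene_and((result, _compare(op, value, expr.lower)))
        if expr.upper is not None:
            op = "le" if expr.upper_inclusive else "lt"
            result = kleene_and((result, _compare(op, value, expr.upper)))
        return result
    raise TypeError(f"not a BoolExpr: {expr!r}")


def _compare(op: str, left: LiteralValue, right: LiteralValue) -> TruthValue:
    if not _kinds_comparable(left.kind, right.kind):
        raise TypeMismatch(
            f"cannot compare kind {left.kind!r} with kind {right.kind!r}"
        )
    if left.kind == "boolean" and op not in ("eq", "ne"):
        raise TypeMismatch("ordering comparisons are undefined for booleans")
    a, b = _ordering_key(left), _ordering_key(right)
    result = {
        "eq": a == b,
        "ne": a != b,
        "gt": a > b,
        "lt": a < b,
        "ge": a >= b,
        "le": a <= b,
    }[op]
    return TRUE if result else FALSE


def referenced_symbols(expr: BoolExpr) -> frozenset:
    """All semantic paths appearing anywhere in the tree."""
    paths = set()

    def walk(e):
        if isinstance(e, (ParenExpr,)):
            walk(e.inner)
        elif isinstance(e, NotExpr):
            walk(e.operand)
        elif isinstance(e, (AndExpr, OrExpr)):
            for o in e.operands:
                walk(o)
        elif isinstance(e, Comparison):
            paths.add(e.left.path)
            if isinstance(e.right, SymbolRef):
                paths.add(e.right.path)
        elif isinstance(e, (InSetExpr, InRangeExpr)):
            paths.add(e.symbol.path)

    walk(expr)
    return frozenset(paths)


# --------------------------------------------------------------------------
# XML parsing / serialization (namespace urn:cigx:1)

_LOGICAL = {"and": AndExpr, "or": OrExpr}


def _local(elem) -> str:
    qname = etree.QName(elem)
    if qname.namespace not in (None, NS):
        raise ParseError(
            f"element {qname.text!r} is not in namespace {NS}", _elem_path(elem)
        )
    return qname.localname


def _elem_path(elem) -> str:
    try:
        return elem.getroottree().getpath(elem)
    except Exception:  # detached element
        return etree.QName(elem).localname


def parse_expression(xml_fragment) -> BoolExpr:
    """Parse an expression from bytes, text, or an lxml element."""
    if isinstance(xml_fragment, (bytes, str)):
        try:
            elem = etree.fromstring(
                xml_fragment.encode() if isinstance(xml_fragment, str) else xml_fragment
            )
        except etree.XMLSyntaxError as exc:
            raise ParseError(f"malformed XML: {exc}") from None
    else:
        elem = xml_fragment
    return _parse_elem(elem)


def _parse_elem(elem) -> BoolExpr:
    name = _local(elem)
    children = [c for c in elem if isinstance(c.tag, str)]
    try:
        if name == "true":
            return ConstExpr(True)
        if name == "false":
            return ConstExpr(False)
        if name in _LOGICAL:
            if len(children) < 2:
                raise ParseError(f"<{name}> requires >=2 operands", _elem_path(elem))
            return _LOGICAL[name]([_parse_elem(c) for c in children])
        if name == "not":
            if len(children) != 1:
                raise ParseError("<not> requires exactly 1 operand", _elem_path(elem))
            return NotExpr(_parse_elem(children[0]))
        if name == "paren":
            if len(children) != 1:
                raise ParseError("<paren> requires exactly 1 child", _elem_path(elem))
            return ParenExpr(_parse_elem(children[0]))
        if name in COMPARISON_OPS:
            if len(children) != 2 or _local(children[0]) != "symbol":
                raise ParseError(
                    f"<{name}> requires <symbol> then <value> or <symbol>",
                    _elem_path(elem),
                )
            left = _parse_symbol(children[0])
            right_name = _local(children[1])
            if right_name == "value":
                right = _parse_value(children[1])
            elif right_name == "symbol":
                right = _parse_symbol(children[1])
            else:
                raise ParseError(
                    f"unexpected comparison operand <{right_name}>", _elem_path(elem)
                )
            return Comparison(name, left, right)
        if name == "in-set":
            symbol = _attr_symbol(elem)
            members = []
            for c in children:
                if _local(c) != "value":
                    raise ParseError(
                        f"<in-set> may only contain <value>, got <{_local(c)}>",
                        _elem_path(elem),
                    )
                members.append(_parse_value(c))
            return InSetExpr(symbol, members)
        if name == "in-range":
            symbol = _attr_symbol(elem)
            kind = elem.get("type")
            if kind is None:
                raise ParseError("<in-range> requires a type attribute", _elem_path(elem))
            lower = elem.get("lower")
            upper = elem.get("upper")
            return InRangeExpr(
                symbol,
                lower=LiteralValue.from_text(kind, lower) if lower is not None else None,
                upper=LiteralValue.from_text(kind, upper) if upper is not None else None,
                lower_inclusive=_parse_flag(elem.get("lower-inclusive", "true"), elem),
                upper_inclusive=_parse_flag(elem.get("upper-inclusive", "true"), elem),
            )
    except ValueError as exc:
        raise ParseError(str(exc), _elem_path(elem)) from None
    raise ParseError(f"unknown expression element <{name}>", _elem_path(elem))


def _parse_flag(text: str, elem) -> bool:
    if text in ("true", "1"):
        return True
    if text in ("false", "0"):
        return False
    raise ParseError(f"malformed boolean attribute {text!r}", _elem_path(elem))


def _attr_symbol(elem) -> SymbolRef:
    path = elem.get("symbol")
    if path is None:
        raise ParseError("missing symbol attribute", _elem_path(elem))
    return SymbolRef(path)


def _parse_symbol(elem) -> SymbolRef:
    path = elem.get("path")
    if path is None:
        raise ParseError("<symbol> requires a path attribute", _elem_path(elem))
    return SymbolRef(path)


def _parse_value(elem) -> LiteralValue:
    kind = elem.get("type")
    if kind is None:
        raise ParseError("<value> requires a type attribute", _elem_path(elem))
    return LiteralValue.from_text(kind, elem.text or "")


def expression_to_element(expr: BoolExpr, nsmap=None) -> etree._Element:
    """Build the lxml element for ``expr`` (used when embedding in documents)."""
    if nsmap is None:
        nsmap = {None: NS}

    def make(tag, parent=None):
        if parent is None:
            return etree.Element(_Q + tag, nsmap=nsmap)
        return etree.SubElement(parent, _Q + tag)

    def build(e, parent=None):
        if isinstance(e, ConstExpr):
            return make("true" if e.truth else "false", parent)
        if isinstance(e, AndExpr) or isinstance(e, OrExpr):
            elem = make("and" if isinstance(e, AndExpr) else "or", parent)
            for o in e.operands:
                build(o, elem)
            return elem
        if isinstance(e, NotExpr):
            elem = make("not", parent)
            build(e.operand, elem)
            return elem
        if isinstance(e, ParenExpr):
            elem = make("paren", parent)
            build(e.inner, elem)
            return elem
        if isinstance(e, Comparison):
            elem = make(e.op, parent)
            sym = make("symbol", elem)
            sym.set("path", e.left.path)
            if isinstance(e.right, SymbolRef):
                right = make("symbol", elem)
                right.set("path", e.right.path)
            else:
                right = make("value", elem)
                right.set("type", e.right.kind)
                right.text = e.right.to_text()
            return elem
        if isinstance(e, InSetExpr):
            elem = make("in-set", parent)
            elem.set("symbol", e.symbol.path)
            for m in e.members:
                v = make("value", elem)
                v.set("type", m.kind)
                v.text = m.to_text()
            return elem
        if isinstance(e, InRangeExpr):
            elem = make("in-range", parent)
            elem.set("symbol", e.symbol.path)
            kind = (e.lower or e.upper).kind
            elem.set("type", kind)
            if e.lower is not None:
                elem.set("lower", e.lower.to_text())
            if e.upper is not None:
                elem.set("upper", e.upper.to_text())
            if not e.lower_inclusive:
                elem.set("lower-inclusive", "false")
            if not e.upper_inclusive:
                elem.set("upper-inclusive", "false")
            return elem
        raise TypeError(f"not a BoolExpr: {e!r}")

    return build(expr)


def serialize_expression(expr: BoolExpr) -> bytes:
    """Serialize to an XML fragment that round-trips through parse_expression."""
    return etree.tostring(expression_to_element(expr))
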