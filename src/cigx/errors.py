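"""Exception hierarchy shared across the package."""


class CigxError(Exception):
    """Base class for all cigx errors."""


class ParseError(CigxError):
    """Raised when an XML fragment cannot be turned into a model object.

    Carries the element path of the offending element when known.
    """

    def __init__(self, message: str, element_path: str | None = None):
        self.element_path = element_path
        if element_path:
            message = f"{message} (at {element_path})"
        super().__init__(message)


class TypeMismatch(CigxError):
    """A comparison was attempted between non-comparable value kinds."""


class ValidationError(CigxError):
    """A document failed XSD or invariant validation; wraps the violations."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(str(v) for v in self.violations) or "invalid document")


class DuplicateIdError(CigxError):
    """Two nodes (or two rules within a node) share an identifier."""


class ClockRegression(CigxError):
    """Attempt to move the simulated clock backwards."""


class CycleLimitExceeded(CigxError):
    """The engine failed to reach quiescence within max_cycles.

    ``repeating_actions`` holds the (node, rule, kind) triples fired in the
    final cycle, to help diagnose the loop.
    """

    def __init__(self, max_cycles: int, repeating_actions):
        self.max_cycles = max_cycles
        self.repeating_actions = sorted(set(repeating_actions))
        super().__init__(
            f"no fixpoint after {max_cycles} cycles; repeating actions: "
            f"{self.repeating_actions}"
        )
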