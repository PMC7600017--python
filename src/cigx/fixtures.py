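"""Built-in guideline documents: bacteriuria, miniature antenatal, cyclic.

The bacteriuria document encodes the classic urinary-tract scenario: the
goal is a patient free of bacteria in the urine, and treatment rules are
triggered by the colony-forming-unit (CFU) count of a urine culture.  A
count strictly over 100,000 CFU triggers a first-line antibiotic order; a
lower-but-significant count — here the conventional (10,000; 100,000]
significant-bacteriuria band, a fixture configuration choice — triggers an
alternative-treatment recommendation plus a physician alert under the same
goal.

The antenatal document realises three decision situations of a miniature
antenatal-care guideline: obstetrical risk evaluation (a pre-eclampsia
alert on hypertension with proteinuria), gestational-age-keyed
recommendations driven by the passage of time, and a referral from primary
to secondary care once risk flags accumulate.  Its clinical thresholds
(140 mmHg systolic, the week windows) are illustrative configuration, not
normative guideline content.

The cyclic document is a deliberately pathological rule set whose two
calculations flip a flag back and forth forever; it exists to exercise the
engine's cycle limit.
"""

from __future__ import annotations

from importlib import resources

from .document import (
    Action,
    Goal,
    GuidelineDocument,
    Node,
    Precondition,
    Rule,
)
from .expr import (
    AndExpr,
    Comparison,
    ConstExpr,
    InRangeExpr,
    LiteralValue,
    SymbolRef,
)

#: [fixture configuration] CFU threshold above which (strictly) the
#: first-line antibiotic order fires.
HIGH_CFU_THRESHOLD = 100_000
#: [fixture configuration] conventional significant-bacteriuria floor for
#: the lower, alternative-treatment band.
LOW_CFU_FLOOR = 10_000

CFU_PATH = "labs/urine_culture/cfu"
BACTERIA_PATH = "labs/urine_culture/bacteria_present"


def _sym(path):
    return SymbolRef(path)


def _int(v):
    return LiteralValue("integer", v)


def _bool(v):
    return LiteralValue("boolean", v)


def build_bacteriuria_document() -> GuidelineDocument:
    """Two-tier treatment choice for bacteriuria, keyed to the CFU count."""
    goal = Goal(
        conditions=Comparison("eq", _sym(BACTERIA_PATH), _bool(False)),
        description="Patient free of bacteria in the urine",
    )
    high = Rule(
        id="high_cfu",
        precondition=Precondition(
            "diagnostic_test_value",
            Comparison("gt", _sym(CFU_PATH), _int(HIGH_CFU_THRESHOLD)),
        ),
        actions=(
            Action(
                kind="medication_order",
                payload="first-line antibiotic course (empiric, per local antibiogram)",
            ),
        ),
    )
    low = Rule(
        id="low_cfu",
        precondition=Precondition(
            "diagnostic_test_value",
            AndExpr(
                (
                    Comparison("gt", _sym(CFU_PATH), _int(LOW_CFU_FLOOR)),
                    Comparison("le", _sym(CFU_PATH), _int(HIGH_CFU_THRESHOLD)),
                )
            ),
        ),
        actions=(
            Action(
                kind="recommendation",
                payload="alternative treatment matched to patient condition "
                "at lower colony count",
            ),
            Action(
                kind="alert",
                payload="notify physician: bacteriuria persists at lower CFU",
            ),
        ),
    )
    node = Node(
        id="bacteriuria",
        label="Bacteriuria treatment",
        goal=goal,
        rules=(high, low),
    )
    return GuidelineDocument(
        id="bacteriuria_example",
        title="Bacteriuria treatment choice",
        version="1.0",
        nodes=(node,),
    )


def build_antenatal_document() -> GuidelineDocument:
    """Miniature antenatal guideline: booking, risk, schedule, referral."""
    booking_advice = Node(
        id="booking_advice",
        label="Booking advice",
        goal=Goal(ConstExpr(False), description="one-shot advice under the booking gate"),
        rules=(
            Rule(
                id="visit_plan",
                precondition=Precondition(
                    "clinical_data_pattern",
                    Comparison("eq", _sym("pregnancy/registered"), _bool(True)),
                ),
                actions=(
                    Action(
                        kind="message",
                        payload="antenatal booking confirmed; visit plan issued",
                    ),
                ),
            ),
        ),
    )
    booking = Node(
        id="booking",
        label="Antenatal booking",
        goal=Goal(
            Comparison("eq", _sym("pregnancy/registered"), _bool(True)),
            description="Patient registered for antenatal care",
        ),
        children=(booking_advice,),
    )

    risk = Node(
        id="risk_evaluation",
        label="Obstetrical risk evaluation",
        complete_on_action=True,
        goal=Goal(
            ConstExpr(False),
            description="latches once the pre-eclampsia alert has been raised",
        ),
        rules=(
            Rule(
                id="preeclampsia_pattern",
                precondition=Precondition(
                    "clinical_data_pattern",
                    AndExpr(
                        (
                            Comparison("ge", _sym("exam/bp_systolic"), _int(140)),
                            Comparison(
                                "eq", _sym("labs/urine_protein/present"), _bool(True)
                            ),
                        )
                    ),
                ),
                actions=(
                    Action(
                        kind="alert",
                        payload="possible pre-eclampsia: hypertension with "
                        "proteinuria; urgent clinical review",
                    ),
                    Action(
                        kind="calculation",
                        payload="flag pre-eclampsia risk",
                        assignments=(("risk/preeclampsia", _bool(True)),),
                    ),
                ),
            ),
        ),
    )

    ga = _sym("pregnancy/gestational_age_weeks")
    windows = (
        ("ga_11_16", 11, 16, "offer dating ultrasound and first-trimester screening"),
        ("ga_18_22", 18, 22, "schedule fetal anatomy ultrasound"),
        ("ga_24_28", 24, 28, "offer oral glucose tolerance test for gestational diabetes"),
        ("ga_30_34", 30, 34, "offer Tdap vaccination and assess fetal growth"),
        ("ga_35_40", 35, 40, "offer group B streptococcus screening"),
    )
    schedule = Node(
        id="gestational_advice",
        label="Gestational-age-keyed advice",
        goal=Goal(
            Comparison("ge", ga, _int(39)),
            description="schedule-driven advice complete once term is reached",
        ),
        rules=tuple(
            Rule(
                id=rid,
                precondition=Precondition(
                    "time_passage",
                    InRangeExpr(ga, lower=_int(lo), upper=_int(hi)),
                ),
                actions=(Action(kind="recommendation", payload=payload),),
            )
            for rid, lo, hi, payload in windows
        ),
    )

    referral = Node(
        id="referral",
        label="Care-level referral",
        complete_on_action=True,
        goal=Goal(
            ConstExpr(False),
            description="latches once the referral has been suggested",
        ),
        rules=(
            Rule(
                id="refer_secondary",
                precondition=Precondition(
                    "clinical_data_pattern",
                    Comparison("eq", _sym("risk/preeclampsia"), _bool(True)),
                ),
                actions=(
                    Action(
                        kind="referral",
                        payload="transfer from primary to secondary antenatal care",
                    ),
                ),
            ),
        ),
    )

    return GuidelineDocument(
        id="antenatal_mini",
        title="Miniature antenatal care guideline",
        version="1.0",
        nodes=(booking, risk, schedule, referral),
    )


def build_cyclic_document() -> GuidelineDocument:
    """Pathological rule set: two calculations flip one flag forever."""
    flag = _sym("sim/flag")
    node = Node(
        id="cyclic",
        label="Deliberately non-quiescent rule set",
        goal=Goal(ConstExpr(False), description="never satisfied"),
        rules=(
            Rule(
                id="flip_on",
                precondition=Precondition(
                    "clinical_data_pattern", Comparison("eq", flag, _bool(False))
                ),
                actions=(
                    Action(
                        kind="calculation",
                        payload="set flag",
                        assignments=(("sim/flag", _bool(True)),),
                    ),
                ),
            ),
            Rule(
                id="flip_off",
                precondition=Precondition(
                    "clinical_data_pattern", Comparison("eq", flag, _bool(True))
                ),
                actions=(
                    Action(
                        kind="calculation",
                        payload="clear flag",
                        assignments=(("sim/flag", _bool(False)),),
                    ),
                ),
            ),
        ),
    )
    return GuidelineDocument(
        id="cyclic_example",
        title="Cycle-limit demonstration",
        version="1.0",
        nodes=(node,),
    )


BUILDERS = {
    "bacteriuria": build_bacteriuria_document,
    "antenatal": build_antenatal_document,
    "cyclic": build_cyclic_document,
}


def fixture_bytes(name: str) -> bytes:
    """Raw XML of a shipped fixture document (bacteriuria/antenatal/cyclic)."""
    return (resources.files("cigx") / "fixtures" / f"{name}.xml").read_bytes()
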