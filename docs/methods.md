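# Methods

This note records the execution model implemented by `cigx`, the semantic
choices made where a guideline formalism leaves room for interpretation,
the tunable parameters and their defaults, and the limitations of what the
shipped tests demonstrate.

## Document model

A guideline is an XML document (namespace `urn:cigx:1`) validated against
the bundled XSD (`src/cigx/schema/cigx.xsd`, which includes
`cigx-expr.xsd` for the expression sublanguage).  The structure is a tree
of **nodes**.  Each node carries:

- a **goal**: a Boolean condition over patient-state paths that the node
  exists to bring about;
- zero or more **rules**: a *precondition* (a trigger kind plus a
  condition) and one or more *actions*;
- zero or more child nodes.

Trigger kinds form a closed enumeration of four values: `time_passage`,
`clinical_data_pattern`, `diagnostic_test_value`, `treatment_result`.
Action kinds form a closed enumeration of ten values: `data_request`,
`message`, `alert`, `recommendation`, `calculation`, `medication_order`,
`lab_test_request`, `procedure_request`, `referral`, `notification`.
`calculation` actions carry assignments that write derived values back
into the patient state.

Schema validation is structural (XSD 1.0 via `lxml`); semantic checks
(unique identifiers, calculation actions carrying assignments, well-formed
paths) happen at load time and are reported as violations, not exceptions
from deep inside a parser.

## Expression semantics

Conditions use **Kleene three-valued logic** with values TRUE, FALSE,
UNKNOWN.  A comparison whose symbol is unbound in the current state
evaluates to UNKNOWN; the connectives follow the strong Kleene tables
(e.g. FALSE ∧ UNKNOWN = FALSE, TRUE ∨ UNKNOWN = TRUE).  This is the
standard treatment of missing clinical data: absence of evidence must not
silently become evidence of absence.

Typed literals cover `boolean`, `integer`, `decimal`, `text`, `date`,
`datetime`.  Integers and decimals compare under numeric promotion; any
other cross-kind comparison, or an ordering comparison on booleans, raises
a type error rather than guessing.  Degenerate forms are given explicit
meanings: an empty `in-set` test is FALSE regardless of bindings (vacuous
membership), and an `in-range` test requires at least one bound, each
independently inclusive or exclusive.

## Patient state and time

The state store is **append-only**: observations are (path, typed value,
timestamp, provenance) records and are never mutated.  A simulated clock
advances monotonically; the visible snapshot at any moment is
latest-visible-wins per path, and observations timestamped in the future
remain invisible until the clock reaches them.  Provenance
(`reported`, `diagnostic_test`, `treatment_result`, `derived`) records how
each value entered the store and determines which trigger kind an incoming
observation activates.

## Engine semantics

Each **cycle** visits the node tree in document order.  Per node:

1. evaluate the node's rules; a rule whose precondition is TRUE fires its
   actions (appending any `calculation` assignments to the store with
   `derived` provenance — visible to later evaluations in the same cycle);
2. evaluate the node's goal gate;
3. if the gate is UNKNOWN, synthesize one `data_request` per unbound path
   referenced by the goal (deduplicated per node and path across the run);
4. if the gate is TRUE, evaluate the children this cycle, then **latch**
   the node complete — it is never visited again;
5. if the gate is FALSE, children are **gated** off.

Nodes flagged `complete-on-action` latch when any of their rules fires,
for duties that are discharged by doing rather than by a verifiable state
change (e.g. making a referral).

**Refractory firing.** Naively, a precondition that stays TRUE would fire
its actions on every cycle and no run would ever quiesce.  The engine
therefore re-fires a rule only when *new information* has arrived since
its last firing: each firing records the store's observation count and
clock, and the rule stays refractory until one of them changes.  This
preserves the intended behaviours at both extremes — ordinary runs reach a
confirmed fixpoint (a further cycle fires nothing), while a document whose
own `calculation` actions keep changing the state (the shipped `cyclic`
fixture) genuinely cycles and is stopped by the cycle limit, reporting the
repeating action set.

**Event handling.** An incoming event runs one cycle restricted to rules
of the matching trigger kind (clock advance → `time_passage`; observation
provenance maps as above), followed by unrestricted cycles to quiescence.
A clock advance to the current time is a no-op.

## Simulator and oracles

The simulator (`cigx.simulate`) draws each patient an exclusive scenario —
`high_cfu_bacteriuria`, `low_cfu_bacteriuria`, `hypertension_proteinuria`,
or `uncomplicated` — from a configured prevalence map and emits a
deterministic event stream from a seeded `numpy` generator: scheduled
visits with gestational age, blood pressure, urinalysis, a booking urine
culture, and (for bacteriuria scenarios) a clearing follow-up culture.

Correctness is cross-checked against **independent oracles that share no
code with the engine or evaluator**: a substitution-based truth-table
oracle for expressions, a recursive single-cycle oracle, and a full-run
replay oracle predicting the complete action sequence for an event stream.
The tests require exact agreement, exhaustively for small expression and
document spaces and over seeded random samples for larger ones.

## Parameters and defaults

| Parameter | Default | Rationale |
| --- | --- | --- |
| `max_cycles` | 100 | Non-pathological fixtures quiesce in ≤ 4 cycles; 100 leaves wide headroom while bounding pathological documents quickly. |
| Cohort size `n_patients` | 100 | Large enough for scenario-mix checks, small enough to audit 10 seeds × 2 documents in seconds. |
| Visit schedule | weeks 12, 20, 26, 32, 36 | A conventional antenatal cadence covering every advice window in the fixture. |
| Scenario prevalence | 0.05 each, remainder uncomplicated | Complication-enriched relative to population rates so small cohorts still exercise every pathway. |
| High-tier CFU boundary | strictly > 100,000/ml | Classical significant-bacteriuria cutoff; the boundary value itself falls in the lower tier. |
| Low-tier CFU floor | > 10,000/ml | Counts at or below are treated as contamination and fire nothing. |

All defaults are overridable (profile files for the simulator,
`--max-cycles` on the CLI, constructor arguments in the API).

## Limitations

- **Expressiveness.** No temporal operators (e.g. "sustained for two
  visits"), no aggregation over observation history (the engine sees the
  latest value per path), no arithmetic inside conditions — derived values
  must be produced by `calculation` assignments with static values.
  Gestational age is therefore an observed input, not a computed one.
- **Determinism by construction.** Conflict resolution is document order;
  there is no priority or preference mechanism between simultaneously
  applicable rules.
- **Simulator scope.** Streams are schematic: uniform noise within
  scenario, no missed visits, no measurement error structure, no
  physiological trajectories.  Passing cohort tests shows the engine
  matches its specification on these streams, not that the fixture
  guidelines are clinically adequate, and the fixtures are illustrative
  encodings, not clinical advice.
- **Scale of exhaustive checks.** Exhaustive verification covers
  expressions to depth 3 over four symbols and documents of ≤ 10 nodes
  over five Boolean paths — sizes chosen so the suite runs in seconds;
  beyond them, confidence is sample-based.
- **XSD 1.0.** Co-occurrence constraints (e.g. `calculation` requiring
  assignments) are enforced at load time in Python, not in the schema.
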