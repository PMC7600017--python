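# cigx — an executable XML encoding for clinical guidelines

`cigx` is a small knowledge-representation language and inference engine for
**computer-interpretable clinical guidelines**.  Clinical practice guidelines
are usually published as narrative text; to drive decision support at the
point of care they must be re-expressed in a machine-readable form with
unambiguous execution semantics.  `cigx` provides that form:

- an **XML document model** (namespace `urn:cigx:1`, validated against a
  shipped XSD) in which a guideline is a hierarchy of *nodes*, each with a
  *goal* (a condition the node tries to achieve), *rules* (precondition →
  actions), and child nodes;
- a **three-valued Boolean expression language** (Kleene logic: a condition
  over missing patient data evaluates to *unknown*, not *false*), with
  comparisons, set membership, and interval tests over typed clinical values;
- a **timestamped patient-state store** with a simulated clock —
  observations recorded for the future stay invisible until the clock
  reaches them;
- a **match-and-resolve engine** with state-machine semantics: rules fire
  when their preconditions hold against the current state, goals *latch*
  (a satisfied node is permanently complete and never re-fires), parents
  *gate* their children (inner nodes are only evaluated once the outer
  node's goal holds), and unknown goals synthesize `data_request` actions
  naming exactly the missing data paths;
- a **seeded synthetic encounter simulator** producing antenatal-care event
  streams, paired with an independently implemented oracle that predicts
  the expected action sequence for cross-validation;
- a `cigx` **command-line tool** to validate documents, run event streams,
  and simulate cohorts.

The executable question the package answers is the classic one: *given an
encoded guideline and a stream of patient data, which actions should the
care process take, and when?*

## Worked example: asymptomatic bacteriuria in pregnancy

The shipped `bacteriuria` fixture encodes a two-tier treatment guideline.
Its single node has the goal *no bacteria present in urine culture* and two
rules keyed on the colony-forming-unit (CFU) count of the culture:

- **strictly more than 100,000 CFU/ml** → order a first-line antibiotic
  course;
- **more than 10,000 and up to 100,000 CFU/ml** → recommend confirmatory
  repeat culture and alert the clinician.

Export the fixture and run a visit that reports a positive culture at
150,000 CFU/ml:

```sh
cigx fixture bacteriuria bacteriuria.xml
cat > visit.tsv <<'EOF'
timestamp	path	type	value	provenance
2026-03-30T09:00:00		time		
2026-03-30T09:00:00	labs/urine_culture/bacteria_present	boolean	true	diagnostic_test
2026-03-30T09:00:00	labs/urine_culture/cfu	integer	150000	diagnostic_test
EOF
cigx run bacteriuria.xml --events visit.tsv --out out
```

This prints `run: 2 action(s) fired` and writes `out/run.actions.tsv`:

```
timestamp	path	type	value	provenance	kind	node	rule	payload
2026-03-30T09:00:00					data_request	bacteriuria	-	labs/urine_culture/bacteria_present
2026-03-30T09:00:00					medication_order	bacteriuria	high_cfu	first-line antibiotic course (empiric, per local antibiogram)
```

Read bottom-up from the trace in `out/run.trace.txt`: at the clock advance
the node's goal is *unknown* (no culture yet), so the engine requests the
missing datum; once the CFU count arrives the `high_cfu` rule evaluates
*true* and fires the medication order:

```
0	NodeEvaluated	node=bacteriuria	gate=unknown
0	ActionFired	node=bacteriuria	rule=-	kind=data_request	payload=labs/urine_culture/bacteria_present
1	RuleEvaluated	node=bacteriuria	rule=high_cfu	result=unknown
1	RuleEvaluated	node=bacteriuria	rule=low_cfu	result=unknown
1	NodeEvaluated	node=bacteriuria	gate=false
2	RuleEvaluated	node=bacteriuria	rule=high_cfu	result=true
2	ActionFired	node=bacteriuria	rule=high_cfu	kind=medication_order	payload=first-line antibiotic course (empiric, per local antibiogram)
2	RuleEvaluated	node=bacteriuria	rule=low_cfu	result=false
2	NodeEvaluated	node=bacteriuria	gate=false
3	RuleEvaluated	node=bacteriuria	rule=high_cfu	result=true
3	RuleEvaluated	node=bacteriuria	rule=low_cfu	result=false
3	NodeEvaluated	node=bacteriuria	gate=false
```

The boundary is strict: a count of exactly 100,000 fires the lower-tier
recommendation and alert, never the antibiotic order; 100,001 fires the
order.

The larger `antenatal` fixture encodes a miniature antenatal guideline
(booking, preeclampsia risk evaluation, gestational-window advice,
secondary-care referral).  Simulated cohorts can be checked against the
independent oracle end to end:

```sh
cigx fixture antenatal antenatal.xml
cat > cohort.profile <<'EOF'
seed = 11
n_patients = 8
prevalence.hypertension_proteinuria = 0.3
prevalence.high_cfu_bacteriuria = 0.2
EOF
cigx simulate cohort.profile antenatal.xml --out sim
```

prints `8/8 patients agree with oracle` and writes each patient's event
stream (`sim/p0000.events.tsv`, …) for replay with `cigx run`.

Other commands: `cigx validate DOC.xml` (XSD + semantic checks, exit 0/1/2)
and `cigx schema --export DIR` (copies the bundled XSDs).

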