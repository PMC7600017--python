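"""Seeded synthetic antenatal encounter streams.

Each simulated patient is assigned one exclusive scenario (drawn from the
profile's prevalence map) and produces one event stream: a clock advance
at each scheduled visit followed by the visit's observations.  Streams are
deterministic given the seed and are valid encounter files for the engine.

What is emulated: visit cadence over gestational weeks, routine vitals
(systolic blood pressure), urinalysis protein, a booking urine culture
with its CFU count, and — for bacteriuria scenarios — a clearing follow-up
culture two visits later.  Gestational age is emitted as a reported
observation in completed weeks at every visit.  What is *not* emulated:
physiological trajectories, measurement error structure, missed visits, or
any within-scenario clinical heterogeneity beyond uniform noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Dict, List, Tuple

import numpy as np

from .expr import LiteralValue
from .state import Event, Observation, TimeAdvance

SCENARIOS = (
    "high_cfu_bacteriuria",
    "low_cfu_bacteriuria",
    "hypertension_proteinuria",
    "uncomplicated",
)

DEFAULT_PREVALENCE = {
    "high_cfu_bacteriuria": 0.05,
    "low_cfu_bacteriuria": 0.05,
    "hypertension_proteinuria": 0.05,
    # remainder of probability mass is "uncomplicated"
}

DEFAULT_SCHEDULE = (12, 20, 26, 32, 36)

_LMP = date(2026, 1, 5)  # shared nominal last menstrual period
_VISIT_HOUR = 9


@dataclass(frozen=True)
class PatientProfile:
    """Configuration of a simulated cohort."""

    seed: int = 0
    n_patients: int = 100
    prevalence: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    visit_schedule: Tuple[int, ...] = DEFAULT_SCHEDULE

    def __post_init__(self):
        object.__setattr__(self, "visit_schedule", tuple(self.visit_schedule))
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        for name in self.prevalence:
            if name not in SCENARIOS:
                raise ValueError(f"unknown scenario {name!r}")
        total = sum(self.prevalence.values())
        if any(p < 0 for p in self.prevalence.values()) or total > 1 + 1e-9:
            raise ValueError("prevalence probabilities must be in [0,1], sum <= 1")
        if list(self.visit_schedule) != sorted(set(self.visit_schedule)):
            raise ValueError("visit_schedule must be strictly increasing")


@dataclass(frozen=True)
class PatientEncounters:
    patient_id: str
    scenario: str
    events: Tuple[Event, ...]


def load_profile(path, seed_override: int | None = None) -> PatientProfile:
    """Read a plain-text key=value profile file.

    Recognised keys: ``seed``, ``n_patients``, ``visit_schedule`` (comma
    separated weeks) and ``prevalence.<scenario>``.  Lines starting with
    ``#`` are comments.
    """
    kwargs: dict = {}
    prevalence: Dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, _, value = (part.strip() for part in line.partition("="))
            if key == "seed":
                kwargs["seed"] = int(value)
            elif key == "n_patients":
                kwargs["n_patients"] = int(value)
            elif key == "visit_schedule":
                kwargs["visit_schedule"] = tuple(
                    int(tok) for tok in value.split(",") if tok.strip()
                )
            elif key.startswith("prevalence."):
                prevalence[key.split(".", 1)[1]] = float(value)
            else:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    if prevalence:
        kwargs["prevalence"] = prevalence
    if seed_override is not None:
        kwargs["seed"] = seed_override
    return PatientProfile(**kwargs)


def _visit_instant(week: int) -> datetime:
    d = _LMP + timedelta(weeks=week)
    return datetime(d.year, d.month, d.day, _VISIT_HOUR)


def _obs(path, kind, value, ts, provenance="reported") -> Observation:
    return Observation(path, LiteralValue(kind, value), ts, provenance)


def _draw_scenario(rng, prevalence) -> str:
    u = float(rng.random())
    cum = 0.0
    for name in SCENARIOS[:3]:
        cum += prevalence.get(name, 0.0)
        if u < cum:
            return name
    return "uncomplicated"  # remaining probability mass


def generate_encounters(profile: PatientProfile) -> List[PatientEncounters]:
    """Deterministic per-patient event streams for the profile's cohort."""
    rng = np.random.default_rng(profile.seed)
    patients = []
    for i in range(profile.n_patients):
        scenario = _draw_scenario(rng, profile.prevalence)
        events = _patient_events(rng, scenario, profile.visit_schedule)
        patients.append(
            PatientEncounters(
                patient_id=f"p{i:04d}", scenario=scenario, events=tuple(events)
            )
        )
    return patients


def _patient_events(rng, scenario: str, schedule) -> List[Event]:
    hypertensive = scenario == "hypertension_proteinuria"
    bacteriuric = scenario in ("high_cfu_bacteriuria", "low_cfu_bacteriuria")
    events: List[Event] = []
    for v, week in enumerate(schedule):
        ts = _visit_instant(week)
        events.append(TimeAdvance(ts))
        events.append(_obs("pregnancy/gestational_age_weeks", "integer", week, ts))
        if v == 0:
            events.append(_obs("pregnancy/lmp_date", "date", _LMP, ts))
            events.append(_obs("pregnancy/registered", "boolean", True, ts))
        if hypertensive:
            bp = 142 + int(rng.integers(0, 28))
        else:
            bp = 100 + int(rng.integers(0, 30))  # always < 140
        events.append(_obs("exam/bp_systolic", "integer", bp, ts))
        events.append(
            _obs("labs/urine_protein/present", "boolean", hypertensive, ts)
        )
        if v == 0:
            events.extend(_culture(rng, scenario, ts))
        if bacteriuric and v == 2:
            # follow-up culture after treatment: infection cleared.  The
            # count is reported before the interpretation so no evaluation
            # ever sees the old count next to the new culture status.
            events.append(
                _obs("labs/urine_culture/cfu", "integer", 0, ts, "diagnostic_test")
            )
            events.append(
                _obs(
                    "labs/urine_culture/bacteria_present",
                    "boolean",
                    False,
                    ts,
                    "diagnostic_test",
                )
            )
    return events


def _culture(rng, scenario: str, ts) -> List[Observation]:
    if scenario == "high_cfu_bacteriuria":
        cfu = 150_000 + int(rng.integers(0, 650_000))
        present = True
    elif scenario == "low_cfu_bacteriuria":
        cfu = 20_001 + int(rng.integers(0, 80_000))  # within (10^4, 10^5]
        present = True
    else:
        cfu = int(rng.integers(0, 1_000))
        present = False
    return [
        _obs("labs/urine_culture/bacteria_present", "boolean", present, ts, "diagnostic_test"),
        _obs("labs/urine_culture/cfu", "integer", cfu, ts, "diagnostic_test"),
    ]
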