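"""Serial clinical observation (SCO) engine.

SCO manages at-risk neonates by scheduled structured examinations (default
ages 1, 3, 6, 12, 18, 24, 36 and 48 h) instead of risk-triggered laboratory
workups.  Each assessment is graded *none* / *minor* / *major*:

* minor -- mild respiratory distress (RR > 60/min without need of support),
  tachycardia > 160 bpm, metabolic acidosis (base excess <= -10 mmol/L), or
  mild temperature instability (< 36 degC, or > 37.5 and < 38 degC);
* major -- moderate/severe respiratory distress requiring support, hypoxia
  while unsupported, poor perfusion (refill >= 3 s) or shock, temperature
  >= 38 degC, grayish/pale/marbled skin, worsening wellbeing, apnoea,
  lethargy, irritability, or seizures.

Infants with minor symptoms are re-examined at 2-h intervals and receive no
testing or antibiotics while symptoms stay mild and non-progressive.  A
major symptom, worsening of minor symptoms, or minor symptoms persisting
12-24 h trigger a "rule out sepsis" laboratory evaluation; the antibiotic
decision after evaluation is a configurable policy (deterministic default:
treat only when a major finding is present).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cohort import (
    DecisionOutcome,
    NeonateRecord,
    Observation,
    RespiratorySupport,
    Strategy,
    TriageLocation,
)
from .intervals import finding_intervals, time_reaching

__all__ = [
    "SymptomGradeLevel",
    "SymptomGrade",
    "TreatPolicy",
    "ScoConfig",
    "grade_observation",
    "schedule_observations",
    "run_sco",
    "triage",
]


class SymptomGradeLevel(str, enum.Enum):
    NONE = "none"
    MINOR = "minor"
    MAJOR = "major"


class TreatPolicy(str, enum.Enum):
    MAJOR_ONLY = "major_only"
    ALWAYS_ON_EVAL = "always_on_eval"
    PROBABILISTIC = "probabilistic"


@dataclass(frozen=True)
class SymptomGrade:
    level: SymptomGradeLevel
    findings: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "findings", tuple(self.findings))

    @property
    def minor_findings(self) -> tuple[str, ...]:
        return tuple(f for f in self.findings if f.startswith("minor:"))


@dataclass(frozen=True)
class ScoConfig:
    """Thresholds and policy knobs of the updated SCO rule set."""

    schedule_hours: tuple[float, ...] = (1, 3, 6, 12, 18, 24, 36, 48)
    reeval_interval_hours: float = 2.0
    minor_persistence_hours: float = 12.0  # admissible 12-24
    rr_minor_cutoff: float = 60.0
    hr_minor_cutoff: float = 160.0
    base_excess_cutoff: float = -10.0
    temp_minor_low_c: float = 36.0
    temp_minor_high_c: float = 37.5
    temp_major_c: float = 38.0
    refill_major_s: float = 3.0
    spo2_cutoff_pct: float = 90.0
    treat_policy: TreatPolicy = TreatPolicy.MAJOR_ONLY
    treat_probability: float = 0.5

    def __post_init__(self):
        if len(self.schedule_hours) == 0:
            raise ValueError("observation schedule must be non-empty")
        if any(b <= a for a, b in zip(self.schedule_hours, self.schedule_hours[1:])):
            raise ValueError("observation schedule must be strictly increasing")
        if self.reeval_interval_hours <= 0:
            raise ValueError("re-evaluation interval must be > 0")
        if not 12.0 <= self.minor_persistence_hours <= 24.0:
            raise ValueError("minor persistence must lie in [12, 24] hours")


_MAJOR_SUPPORT = (RespiratorySupport.NCPAP, RespiratorySupport.MECHANICAL_VENTILATION)
_SIMPLE_MAJOR_FLAGS = (
    "poor_perfusion_or_shock",
    "abnormal_skin_color",
    "worsening_wellbeing",
    "apnoea",
    "lethargy",
    "irritability",
    "seizure",
)


def grade_observation(
    obs: Observation, config: Optional[ScoConfig] = None
) -> SymptomGrade:
    """Grade a single observation; pure function of (observation, config)."""
    config = config or ScoConfig()
    findings: list[str] = []

    tachypnea = obs.resp_rate_bpm is not None and obs.resp_rate_bpm > config.rr_minor_cutoff
    supported = obs.respiratory_support is not RespiratorySupport.NONE
    if obs.respiratory_support in _MAJOR_SUPPORT or (
        tachypnea and obs.increased_effort and supported
    ):
        findings.append("major:respiratory_distress_requiring_support")
    if (
        obs.spo2_pct is not None
        and obs.spo2_pct < config.spo2_cutoff_pct
        and not supported
    ):
        findings.append("major:hypoxia")
    if obs.capillary_refill_s is not None and obs.capillary_refill_s >= config.refill_major_s:
        findings.append("major:capillary_refill")
    if obs.temp_c is not None and obs.temp_c >= config.temp_major_c:
        findings.append("major:fever")
    for flag in _SIMPLE_MAJOR_FLAGS:
        if getattr(obs, flag):
            findings.append(f"major:{flag}")

    if not findings:
        if tachypnea:
            findings.append("minor:tachypnea")
        if obs.heart_rate_bpm is not None and obs.heart_rate_bpm > config.hr_minor_cutoff:
            findings.append("minor:tachycardia")
        if (
            obs.base_excess_mmol_l is not None
            and obs.base_excess_mmol_l <= config.base_excess_cutoff
        ):
            findings.append("minor:metabolic_acidosis")
        if obs.temp_c is not None and (
            obs.temp_c < config.temp_minor_low_c
            or config.temp_minor_high_c < obs.temp_c < config.temp_major_c
        ):
            findings.append("minor:temperature_instability")

    if any(f.startswith("major:") for f in findings):
        level = SymptomGradeLevel.MAJOR
    elif findings:
        level = SymptomGradeLevel.MINOR
    else:
        level = SymptomGradeLevel.NONE
    return SymptomGrade(level=level, findings=tuple(findings))


def _grade_at(record: NeonateRecord, t: float, config: ScoConfig) -> SymptomGrade:
    """Grade at clock time t = grade of the latest observation at or before t."""
    latest = None
    for obs in record.timeline:
        if obs.age_hours <= t:
            latest = obs
        else:
            break
    if latest is None:
        return SymptomGrade(SymptomGradeLevel.NONE)
    return grade_observation(latest, config)


def schedule_observations(
    record: NeonateRecord, config: Optional[ScoConfig] = None
) -> list[float]:
    """Assessment times: the standard schedule plus 2-h re-evaluations.

    After any minor-grade assessment the infant is re-examined every
    ``reeval_interval_hours`` until the grade returns to none or escalation
    (a major grade) occurs; re-evaluations never extend past the last
    scheduled check.
    """
    config = config or ScoConfig()
    horizon = config.schedule_hours[-1]
    pending = list(config.schedule_hours)
    out: list[float] = []
    while pending:
        t = pending.pop(0)
        out.append(t)
        grade = _grade_at(record, t, config)
        if grade.level is SymptomGradeLevel.MAJOR:
            break  # escalation: evaluation supersedes routine checks
        if grade.level is SymptomGradeLevel.MINOR:
            nxt = t + config.reeval_interval_hours
            if nxt <= horizon and (not pending or nxt < pending[0]):
                pending.insert(0, nxt)
    return out


def run_sco(
    record: NeonateRecord,
    config: Optional[ScoConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> DecisionOutcome:
    """Apply the updated SCO rule set to one record.

    Laboratory evaluation is triggered at the earliest of: a major-grade
    observation; worsening of minor symptoms (strictly more distinct minor
    findings than the previous minor assessment); or minor symptoms
    persisting for ``minor_persistence_hours`` (union of minor intervals).
    Asymptomatic infants are never evaluated and never treated.
    """
    config = config or ScoConfig()
    tl = record.timeline
    grades = [grade_observation(o, config) for o in tl]
    times = [o.age_hours for o in tl]

    first_major: Optional[float] = None
    worsening_at: Optional[float] = None
    prev: Optional[SymptomGrade] = None
    for t, g in zip(times, grades):
        if g.level is SymptomGradeLevel.MAJOR and first_major is None:
            first_major = t
        if (
            worsening_at is None
            and prev is not None
            and prev.level is SymptomGradeLevel.MINOR
            and g.level is SymptomGradeLevel.MINOR
            and len(set(g.minor_findings)) > len(set(prev.minor_findings))
        ):
            worsening_at = t
        prev = g

    minor_ivs = finding_intervals(
        times, [g.level is SymptomGradeLevel.MINOR for g in grades]
    )
    persistence_at = time_reaching(minor_ivs, config.minor_persistence_hours)

    triggers = [t for t in (first_major, worsening_at, persistence_at) if t is not None]
    eval_time = min(triggers) if triggers else None
    evaluated = eval_time is not None

    antibiotics = False
    abx_time: Optional[float] = None
    if evaluated:
        if config.treat_policy is TreatPolicy.MAJOR_ONLY:
            later_majors = [
                t
                for t, g in zip(times, grades)
                if g.level is SymptomGradeLevel.MAJOR and t >= eval_time
            ]
            if later_majors:
                antibiotics = True
                abx_time = later_majors[0]
        elif config.treat_policy is TreatPolicy.ALWAYS_ON_EVAL:
            antibiotics = True
            abx_time = eval_time
        elif config.treat_policy is TreatPolicy.PROBABILISTIC:
            if rng is None:
                raise ValueError("probabilistic treat policy requires an rng")
            if rng.random() < config.treat_probability:
                antibiotics = True
                abx_time = eval_time

    return DecisionOutcome(
        id=record.id,
        strategy=Strategy.SCO,
        evaluated=evaluated,
        antibiotics=antibiotics,
        recommendation=f"sco_{'evaluate' if evaluated else 'observe'}",
        triage=triage(record, grades),
        evaluation_time_hours=eval_time,
        antibiotics_time_hours=abx_time,
    )


def triage(
    record: NeonateRecord, grade_history: Sequence[SymptomGrade]
) -> TriageLocation:
    """Admission location under local practice.

    NICU for nCPAP/mechanical ventilation or severe illness (vasoactive
    drugs, seizures); intermediate care for supplemental O2 or high-flow
    nasal cannula, and for asymptomatic infants of 34 weeks' gestation;
    rooming-in with the mother otherwise.
    """
    tl = record.timeline
    if any(
        o.respiratory_support in _MAJOR_SUPPORT or o.vasoactive_drugs or o.seizure
        for o in tl
    ):
        return TriageLocation.NICU
    if any(
        o.respiratory_support
        in (RespiratorySupport.SUPPLEMENTAL_O2, RespiratorySupport.HFNC)
        for o in tl
    ):
        return TriageLocation.INTERMEDIATE_CARE
    asymptomatic = all(g.level is SymptomGradeLevel.NONE for g in grade_history)
    if asymptomatic and record.maternal.gestational_age_weeks < 35.0:
        return TriageLocation.INTERMEDIATE_CARE
    return TriageLocation.ROOMING_IN
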