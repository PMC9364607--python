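"""Domain types for neonatal early-onset-sepsis (EOS) cohorts, with CSV I/O.

A cohort is a list of :class:`NeonateRecord`: maternal risk-factor profile,
birth context (5-min Apgar, delivery-room support), and a timestamped
observation timeline of vitals and categorical clinical flags.  Records are
serialised to two plain CSV files: one row per record (cohort file) and one
row per observation (long-format timeline file keyed by record id).

Absent vitals mean "not measured" and are never imputed; downstream
classifiers treat them as non-abnormal.  All temperatures are degrees
Celsius, all times decimal hours since birth (age 0 = at birth).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "DeliveryMode",
    "GbsStatus",
    "RespiratorySupport",
    "Strategy",
    "TriageLocation",
    "MaternalProfile",
    "Observation",
    "NeonateRecord",
    "DecisionOutcome",
    "SchemaError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "COHORT_COLUMNS",
    "OBSERVATION_COLUMNS",
]


class DeliveryMode(str, enum.Enum):
    VAGINAL = "vaginal"
    CESAREAN = "cesarean"


class GbsStatus(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


class RespiratorySupport(str, enum.Enum):
    NONE = "none"
    SUPPLEMENTAL_O2 = "supplemental_o2"
    HFNC = "hfnc"
    NCPAP = "ncpap"
    MECHANICAL_VENTILATION = "mechanical_ventilation"


class Strategy(str, enum.Enum):
    SCO = "sco"
    NSC = "nsc"


class TriageLocation(str, enum.Enum):
    ROOMING_IN = "rooming_in"
    INTERMEDIATE_CARE = "intermediate_care"
    NICU = "nicu"


class SchemaError(ValueError):
    """A required column is missing or a value cannot be parsed."""


class ValidationError(ValueError):
    """A record violates a domain invariant; names the record id and field."""

    def __init__(self, record_id: str, field_name: str, message: str):
        self.record_id = record_id
        self.field_name = field_name
        super().__init__(f"record {record_id!r}, field {field_name!r}: {message}")


@dataclass(frozen=True)
class MaternalProfile:
    """Maternal risk factors entering the EOS prior.

    Gestational age is restricted to >= 34.0 weeks (study inclusion: all
    live births at >= 34 weeks of gestation).
    """

    gestational_age_weeks: float
    delivery_mode: DeliveryMode = DeliveryMode.VAGINAL
    gbs_status: GbsStatus = GbsStatus.UNKNOWN
    gbs_bacteriuria: bool = False
    prior_gbs_infant: bool = False
    rom_hours: float = 0.0
    max_intrapartum_temp_c: float = 37.0
    iap_given: bool = False
    iap_adequate: bool = False

    def validate(self, record_id: str = "<unknown>") -> None:
        if self.gestational_age_weeks < 34.0:
            raise ValidationError(
                record_id,
                "gestational_age_weeks",
                f"{self.gestational_age_weeks} is below the >=34 weeks inclusion rule",
            )
        if self.rom_hours < 0:
            raise ValidationError(record_id, "rom_hours", "must be >= 0")
        if not 30.0 <= self.max_intrapartum_temp_c <= 43.0:
            raise ValidationError(
                record_id,
                "max_intrapartum_temp_c",
                f"{self.max_intrapartum_temp_c} outside plausible range 30-43 degC",
            )
        if self.iap_adequate and not self.iap_given:
            raise ValidationError(
                record_id, "iap_adequate", "iap_adequate implies iap_given"
            )


@dataclass(frozen=True)
class Observation:
    """One timestamped clinical assessment.

    Vitals are Optional: ``None`` means not measured at this assessment.
    Categorical flags default to False and are considered assessed at every
    observation.
    """

    age_hours: float
    heart_rate_bpm: Optional[float] = None
    resp_rate_bpm: Optional[float] = None
    temp_c: Optional[float] = None
    spo2_pct: Optional[float] = None
    base_excess_mmol_l: Optional[float] = None
    capillary_refill_s: Optional[float] = None
    respiratory_support: RespiratorySupport = RespiratorySupport.NONE
    increased_effort: bool = False
    vasoactive_drugs: bool = False
    seizure: bool = False
    apnoea: bool = False
    lethargy: bool = False
    irritability: bool = False
    poor_perfusion_or_shock: bool = False
    abnormal_skin_color: bool = False
    worsening_wellbeing: bool = False

    def validate(self, record_id: str = "<unknown>") -> None:
        if self.age_hours < 0:
            raise ValidationError(record_id, "age_hours", "must be >= 0")
        if self.spo2_pct is not None and not 0 <= self.spo2_pct <= 100:
            raise ValidationError(record_id, "spo2_pct", "must be in [0, 100]")
        if self.capillary_refill_s is not None and self.capillary_refill_s < 0:
            raise ValidationError(record_id, "capillary_refill_s", "must be >= 0")


@dataclass(frozen=True)
class NeonateRecord:
    """One infant: maternal profile, birth context, observation timeline."""

    id: str
    maternal: MaternalProfile
    apgar_5min: int = 10
    delivery_room_support_only: bool = False
    timeline: tuple[Observation, ...] = field(default_factory=tuple)
    prior_override_per_1000: Optional[float] = None
    true_eos: Optional[bool] = None

    def __post_init__(self):
        object.__setattr__(self, "timeline", tuple(self.timeline))

    @property
    def late_preterm(self) -> bool:
        """Gestational age 34 to <37 completed weeks."""
        return self.maternal.gestational_age_weeks < 37.0

    def validate(self) -> None:
        self.maternal.validate(self.id)
        if not 0 <= self.apgar_5min <= 10:
            raise ValidationError(self.id, "apgar_5min", "must be in [0, 10]")
        ages = [o.age_hours for o in self.timeline]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValidationError(
                self.id, "timeline", "age_hours must be strictly increasing"
            )
        for obs in self.timeline:
            obs.validate(self.id)


@dataclass(frozen=True)
class DecisionOutcome:
    """Per-strategy management decision for one record."""

    id: str
    strategy: Strategy
    evaluated: bool
    antibiotics: bool
    recommendation: str
    triage: TriageLocation
    evaluation_time_hours: Optional[float] = None
    antibiotics_time_hours: Optional[float] = None

    def validate(self) -> None:
        if self.strategy is Strategy.SCO and self.antibiotics and not self.evaluated:
            raise ValidationError(
                self.id, "antibiotics", "antibiotics implies evaluated under SCO"
            )
        if self.evaluated != (self.evaluation_time_hours is not None):
            raise ValidationError(
                self.id,
                "evaluation_time_hours",
                "present iff evaluated",
            )


# ---------------------------------------------------------------------------
# CSV serialisation
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "id",
    "gestational_age_weeks",
    "delivery_mode",
    "gbs_status",
    "gbs_bacteriuria",
    "prior_gbs_infant",
    "rom_hours",
    "max_intrapartum_temp_c",
    "iap_given",
    "iap_adequate",
    "apgar_5min",
    "delivery_room_support_only",
    "prior_override_per_1000",
    "true_eos",
]

OBSERVATION_COLUMNS = [
    "id",
    "age_hours",
    "heart_rate_bpm",
    "resp_rate_bpm",
    "temp_c",
    "spo2_pct",
    "base_excess_mmol_l",
    "capillary_refill_s",
    "respiratory_support",
    "increased_effort",
    "vasoactive_drugs",
    "seizure",
    "apnoea",
    "lethargy",
    "irritability",
    "poor_perfusion_or_shock",
    "abnormal_skin_color",
    "worsening_wellbeing",
]

_OBS_FLAGS = OBSERVATION_COLUMNS[9:]
_OBS_VITALS = OBSERVATION_COLUMNS[2:8]


def _fmt_bool(x: Optional[bool]) -> str:
    if x is None:
        return ""
    return "true" if x else "false"


def _parse_bool(x, record_id: str, col: str, allow_absent: bool = False):
    if x is None or (isinstance(x, float) and pd.isna(x)) or x == "":
        if allow_absent:
            return None
        return False
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise SchemaError(f"record {record_id!r}: cannot parse boolean {col}={x!r}")


def _opt_float(x) -> Optional[float]:
    if x is None or x == "" or (isinstance(x, float) and pd.isna(x)):
        return None
    return float(x)


def observation_paths(path) -> Path:
    """Companion long-format observations file for a cohort CSV path."""
    p = Path(path)
    return p.with_name(p.stem + ".observations.csv")


def write_cohort(records: Sequence[NeonateRecord], path) -> None:
    """Write a cohort CSV plus its companion observations CSV.

    Absent optional values become empty cells.  Column order is fixed
    (``COHORT_COLUMNS`` / ``OBSERVATION_COLUMNS``) so identical cohorts are
    byte-identical on disk.
    """
    path = Path(path)
    rows = []
    obs_rows = []
    for rec in records:
        m = rec.maternal
        rows.append(
            {
                "id": rec.id,
                "gestational_age_weeks": repr(float(m.gestational_age_weeks)),
                "delivery_mode": m.delivery_mode.value,
                "gbs_status": m.gbs_status.value,
                "gbs_bacteriuria": _fmt_bool(m.gbs_bacteriuria),
                "prior_gbs_infant": _fmt_bool(m.prior_gbs_infant),
                "rom_hours": repr(float(m.rom_hours)),
                "max_intrapartum_temp_c": repr(float(m.max_intrapartum_temp_c)),
                "iap_given": _fmt_bool(m.iap_given),
                "iap_adequate": _fmt_bool(m.iap_adequate),
                "apgar_5min": str(rec.apgar_5min),
                "delivery_room_support_only": _fmt_bool(rec.delivery_room_support_only),
                "prior_override_per_1000": ""
                if rec.prior_override_per_1000 is None
                else repr(float(rec.prior_override_per_1000)),
                "true_eos": _fmt_bool(rec.true_eos),
            }
        )
        for obs in rec.timeline:
            row = {"id": rec.id, "age_hours": repr(float(obs.age_hours))}
            for col in _OBS_VITALS:
                v = getattr(obs, col)
                row[col] = "" if v is None else repr(float(v))
            row["respiratory_support"] = obs.respiratory_support.value
            for col in _OBS_FLAGS:
                row[col] = _fmt_bool(getattr(obs, col))
            obs_rows.append(row)

    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(
        path, index=False, lineterminator="\n"
    )
    pd.DataFrame(obs_rows, columns=OBSERVATION_COLUMNS).to_csv(
        observation_paths(path), index=False, lineterminator="\n"
    )


def read_cohort(path, observations_path=None) -> list[NeonateRecord]:
    """Read and validate a cohort CSV (+ companion observations CSV).

    Raises :class:`SchemaError` if a required column is missing and
    :class:`ValidationError` (naming record id and field) on any invariant
    violation.  Row order is preserved.
    """
    path = Path(path)
    if observations_path is None:
        observations_path = observation_paths(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing required column(s): {missing}")

    timelines: dict[str, list[Observation]] = {}
    obs_path = Path(observations_path)
    if obs_path.exists():
        odf = pd.read_csv(obs_path, dtype=str, keep_default_na=False)
        omissing = [c for c in OBSERVATION_COLUMNS if c not in odf.columns]
        if omissing:
            raise SchemaError(
                f"observations file missing required column(s): {omissing}"
            )
        for row in odf.itertuples(index=False):
            rid = row.id
            obs = Observation(
                age_hours=float(row.age_hours),
                heart_rate_bpm=_opt_float(row.heart_rate_bpm),
                resp_rate_bpm=_opt_float(row.resp_rate_bpm),
                temp_c=_opt_float(row.temp_c),
                spo2_pct=_opt_float(row.spo2_pct),
                base_excess_mmol_l=_opt_float(row.base_excess_mmol_l),
                capillary_refill_s=_opt_float(row.capillary_refill_s),
                respiratory_support=RespiratorySupport(row.respiratory_support),
                **{f: _parse_bool(getattr(row, f), rid, f) for f in _OBS_FLAGS},
            )
            timelines.setdefault(rid, []).append(obs)

    records = []
    for row in df.itertuples(index=False):
        rid = row.id
        maternal = MaternalProfile(
            gestational_age_weeks=float(row.gestational_age_weeks),
            delivery_mode=DeliveryMode(row.delivery_mode),
            gbs_status=GbsStatus(row.gbs_status),
            gbs_bacteriuria=_parse_bool(row.gbs_bacteriuria, rid, "gbs_bacteriuria"),
            prior_gbs_infant=_parse_bool(row.prior_gbs_infant, rid, "prior_gbs_infant"),
            rom_hours=float(row.rom_hours),
            max_intrapartum_temp_c=float(row.max_intrapartum_temp_c),
            iap_given=_parse_bool(row.iap_given, rid, "iap_given"),
            iap_adequate=_parse_bool(row.iap_adequate, rid, "iap_adequate"),
        )
        rec = NeonateRecord(
            id=rid,
            maternal=maternal,
            apgar_5min=int(row.apgar_5min),
            delivery_room_support_only=_parse_bool(
                row.delivery_room_support_only, rid, "delivery_room_support_only"
            ),
            timeline=tuple(timelines.get(rid, ())),
            prior_override_per_1000=_opt_float(row.prior_override_per_1000),
            true_eos=_parse_bool(row.true_eos, rid, "true_eos", allow_absent=True),
        )
        rec.validate()
        records.append(rec)
    return records


def outcomes_to_frame(outcomes: Iterable[DecisionOutcome]) -> pd.DataFrame:
    """Flatten decision outcomes to a DataFrame for CSV export."""
    rows = []
    for o in outcomes:
        rows.append(
            {
                "id": o.id,
                "strategy": o.strategy.value,
                "evaluated": o.evaluated,
                "antibiotics": o.antibiotics,
                "recommendation": o.recommendation,
                "triage": o.triage.value,
                "evaluation_time_hours": o.evaluation_time_hours,
                "antibiotics_time_hours": o.antibiotics_time_hours,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "strategy",
            "evaluated",
            "antibiotics",
            "recommendation",
            "triage",
            "evaluation_time_hours",
            "antibiotics_time_hours",
        ],
    )
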