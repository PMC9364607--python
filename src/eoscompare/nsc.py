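"""Neonatal sepsis risk calculator (NSC) engine.

The NSC converts a maternal-risk-factor prior probability of early-onset
sepsis (EOS) into a posterior via a likelihood-ratio update keyed to the
infant's clinical presentation in the first hours of life:

    posterior odds = prior odds x LR(category)

with default likelihood ratios 0.41 (well appearing), 5.0 (equivocal) and
21.2 (clinical illness), a baseline incidence of 0.6 EOS cases per 1,000
live births, risk strata at 0.65 and 1.54 per 1,000, and management
recommendations switching at posterior risks of 1 and 3 per 1,000.

The published regression for the maternal prior is not reproduced here:
``compute_prior`` is a pluggable interface (per-record override column or
configured odds multipliers); with neither configured every infant carries
the baseline incidence as its prior.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional

from .cohort import (
    DecisionOutcome,
    MaternalProfile,
    NeonateRecord,
    RespiratorySupport,
    Strategy,
    TriageLocation,
)
from .intervals import finding_intervals, total_duration

__all__ = [
    "PresentationCategory",
    "RiskStratum",
    "NscRecommendation",
    "NscConfig",
    "RiskEstimate",
    "compute_prior",
    "classify_presentation",
    "bayes_posterior",
    "recommend",
    "run_nsc",
    "RECOMMENDATION_SEVERITY",
]


class PresentationCategory(str, enum.Enum):
    WELL_APPEARING = "well_appearing"
    EQUIVOCAL = "equivocal"
    CLINICAL_ILLNESS = "clinical_illness"


class RiskStratum(str, enum.Enum):
    LOW = "low"
    MIDDLE = "middle"
    HIGH = "high"


class NscRecommendation(str, enum.Enum):
    """The five NSC management recommendations, in increasing severity."""

    ROUTINE_VITALS = "routine_vitals"
    ENHANCED_VITALS = "enhanced_vitals"
    CULTURE_AND_VITALS = "culture_and_vitals"
    STRONGLY_CONSIDER_ANTIBIOTICS = "strongly_consider_antibiotics"
    EMPIRIC_ANTIBIOTICS = "empiric_antibiotics"

    @property
    def implies_evaluation(self) -> bool:
        """True when the recommendation involves a 'rule out sepsis' workup."""
        return self in (
            NscRecommendation.CULTURE_AND_VITALS,
            NscRecommendation.STRONGLY_CONSIDER_ANTIBIOTICS,
            NscRecommendation.EMPIRIC_ANTIBIOTICS,
        )

    @property
    def implies_antibiotics(self) -> bool:
        return self in (
            NscRecommendation.STRONGLY_CONSIDER_ANTIBIOTICS,
            NscRecommendation.EMPIRIC_ANTIBIOTICS,
        )


RECOMMENDATION_SEVERITY = {r: i for i, r in enumerate(NscRecommendation)}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class NscConfig:
    """All NSC thresholds, likelihood ratios and decision cutoffs.

    Risks are expressed per 1,000 live births throughout.  Temperature
    cutoffs are the Fahrenheit instability bounds (>100.4 degF, <97.5 degF)
    canonicalised to Celsius.
    """

    incidence_per_1000: float = 0.6
    lr_well: float = 0.41
    lr_equivocal: float = 5.0
    lr_clinical: float = 21.2
    strata_cutoffs_per_1000: tuple[float, float] = (0.65, 1.54)
    decision_thresholds_per_1000: tuple[float, float] = (1.0, 3.0)
    assessment_window_hours: float = 4.0
    persistence_hours_single: float = 4.0
    persistence_hours_multi: float = 2.0
    o2_duration_hours: float = 2.0
    hr_cutoff_bpm: float = 160.0
    rr_cutoff_bpm: float = 60.0
    temp_high_c: float = 38.0
    temp_low_c: float = 36.4
    apgar5_cutoff: int = 5
    spo2_cutoff_pct: float = 90.0
    odds_scale_update: bool = True
    prior_coefficients: Optional[Mapping[str, float]] = None

    def __post_init__(self):
        if min(self.lr_well, self.lr_equivocal, self.lr_clinical) <= 0:
            raise ConfigurationError("likelihood ratios must be > 0")
        if not self.strata_cutoffs_per_1000[0] < self.strata_cutoffs_per_1000[1]:
            raise ConfigurationError("strata cutoffs must be strictly increasing")
        if not (
            self.decision_thresholds_per_1000[0] < self.decision_thresholds_per_1000[1]
        ):
            raise ConfigurationError("decision thresholds must be strictly increasing")
        if min(
            self.assessment_window_hours,
            self.persistence_hours_single,
            self.persistence_hours_multi,
            self.o2_duration_hours,
        ) <= 0:
            raise ConfigurationError("window/persistence hours must be > 0")

    def likelihood_ratio(self, category: PresentationCategory) -> float:
        return {
            PresentationCategory.WELL_APPEARING: self.lr_well,
            PresentationCategory.EQUIVOCAL: self.lr_equivocal,
            PresentationCategory.CLINICAL_ILLNESS: self.lr_clinical,
        }[category]


@dataclass(frozen=True)
class RiskEstimate:
    """Prior and posterior EOS risk for one infant (per 1,000 live births)."""

    prior_per_1000: float
    category: PresentationCategory
    likelihood_ratio: float
    posterior_per_1000: float
    stratum: RiskStratum


def _matches(maternal: MaternalProfile, key: str) -> bool:
    """Resolve a prior-coefficient key against the maternal profile.

    A key is either a flag attribute name (truthiness) or ``attr=value`` for
    enum-valued attributes (e.g. ``gbs_status=positive``).
    """
    if "=" in key:
        attr, _, value = key.partition("=")
        got = getattr(maternal, attr)
        got = got.value if isinstance(got, enum.Enum) else str(got)
        return got == value
    return bool(getattr(maternal, key))


def compute_prior(
    maternal: MaternalProfile,
    config: NscConfig,
    override: Optional[float] = None,
) -> float:
    """Prior EOS risk per 1,000 live births for one infant.

    An explicit per-record ``override`` wins.  Otherwise, if
    ``config.prior_coefficients`` maps maternal covariates to odds
    multipliers, the baseline incidence is rescaled multiplicatively on the
    odds scale by every matching covariate; with no coefficients the
    baseline incidence is returned unchanged.
    """
    if override is not None:
        if override <= 0:
            raise ConfigurationError("prior override must be positive")
        return float(override)
    base = config.incidence_per_1000
    if base <= 0:
        raise ConfigurationError("incidence_per_1000 must be positive")
    if not config.prior_coefficients:
        return base
    p = base / 1000.0
    odds = p / (1.0 - p)
    for key, multiplier in config.prior_coefficients.items():
        if multiplier <= 0:
            raise ConfigurationError(f"odds multiplier for {key!r} must be positive")
        if _matches(maternal, key):
            odds *= multiplier
    prior = 1000.0 * odds / (1.0 + odds)
    if prior <= 0:
        raise ConfigurationError("computed prior is non-positive")
    return prior


# ---------------------------------------------------------------------------
# Temporal presentation classification
# ---------------------------------------------------------------------------

_PERSISTENT_SUPPORT = (
    RespiratorySupport.NCPAP,
    RespiratorySupport.HFNC,
    RespiratorySupport.MECHANICAL_VENTILATION,
)


def _abnormality_durations(
    record: NeonateRecord, config: NscConfig
) -> dict[str, float]:
    """Union durations (hours) of each equivocal-qualifying abnormality.

    Only abnormal intervals *starting* within the assessment window count,
    but a qualifying interval accrues duration until the vital is next
    re-measured (the persistence of an abnormality first charted inside the
    window may only be confirmed by later observations).
    """
    tl = record.timeline
    times = [o.age_hours for o in tl]
    w = config.assessment_window_hours

    def dur(abnormal, measured=None) -> float:
        ivs = finding_intervals(times, abnormal, measured)
        return total_duration([iv for iv in ivs if iv[0] <= w])

    hr_m = [o.heart_rate_bpm is not None for o in tl]
    rr_m = [o.resp_rate_bpm is not None for o in tl]
    t_m = [o.temp_c is not None for o in tl]
    return {
        "tachycardia": dur(
            [o.heart_rate_bpm is not None and o.heart_rate_bpm > config.hr_cutoff_bpm for o in tl],
            hr_m,
        ),
        "tachypnea": dur(
            [o.resp_rate_bpm is not None and o.resp_rate_bpm > config.rr_cutoff_bpm for o in tl],
            rr_m,
        ),
        "temperature_instability": dur(
            [
                o.temp_c is not None
                and (o.temp_c > config.temp_high_c or o.temp_c < config.temp_low_c)
                for o in tl
            ],
            t_m,
        ),
        "respiratory_distress_no_o2": dur(
            [
                o.increased_effort
                and o.respiratory_support is RespiratorySupport.NONE
                for o in tl
            ]
        ),
    }


def classify_presentation(
    record: NeonateRecord, config: Optional[NscConfig] = None
) -> PresentationCategory:
    """Classify the infant's presentation within the assessment window.

    Clinical illness: persistent need for nCPAP/HFNC/mechanical ventilation
    outside the delivery room; vasoactive drugs; seizure or 5-min Apgar
    below the cutoff; or cumulative supplemental-O2 need beyond the O2
    duration cutoff.  Equivocal: one abnormality persisting beyond the
    single-abnormality cutoff, or two or more abnormalities each persisting
    beyond the multi-abnormality cutoff (intermittent abnormality durations
    accumulate over the union of abnormal intervals).  Otherwise well
    appearing.  An empty timeline with a normal birth context is well
    appearing.
    """
    config = config or NscConfig()
    w = config.assessment_window_hours
    within = [o for o in record.timeline if o.age_hours <= w]

    if record.apgar_5min < config.apgar5_cutoff:
        return PresentationCategory.CLINICAL_ILLNESS
    if any(o.vasoactive_drugs or o.seizure for o in within):
        return PresentationCategory.CLINICAL_ILLNESS
    if not record.delivery_room_support_only and any(
        o.respiratory_support in _PERSISTENT_SUPPORT for o in within
    ):
        return PresentationCategory.CLINICAL_ILLNESS

    times = [o.age_hours for o in record.timeline]
    o2_ivs = finding_intervals(
        times,
        [
            o.respiratory_support is RespiratorySupport.SUPPLEMENTAL_O2
            for o in record.timeline
        ],
    )
    o2_hours = total_duration([iv for iv in o2_ivs if iv[0] <= w])
    if not record.delivery_room_support_only and o2_hours > config.o2_duration_hours:
        return PresentationCategory.CLINICAL_ILLNESS

    durations = _abnormality_durations(record, config)
    if any(d > config.persistence_hours_single for d in durations.values()):
        return PresentationCategory.EQUIVOCAL
    if sum(d > config.persistence_hours_multi for d in durations.values()) >= 2:
        return PresentationCategory.EQUIVOCAL
    return PresentationCategory.WELL_APPEARING


def bayes_posterior(
    prior_per_1000: float,
    category: PresentationCategory,
    config: Optional[NscConfig] = None,
) -> RiskEstimate:
    """Likelihood-ratio update of the prior EOS risk.

    Default is the odds-scale update (posterior odds = prior odds x LR);
    setting ``config.odds_scale_update = False`` switches to naive
    multiplication on the probability scale (documented alternative; the
    two agree closely at risks of a few per 1,000).
    """
    config = config or NscConfig()
    if not 0 < prior_per_1000 < 1000:
        raise ValueError("prior must be in (0, 1000) per 1,000 live births")
    lr = config.likelihood_ratio(PresentationCategory(category))
    if config.odds_scale_update:
        p = prior_per_1000 / 1000.0
        odds = p / (1.0 - p) * lr
        posterior = 1000.0 * odds / (1.0 + odds)
    else:
        posterior = min(prior_per_1000 * lr, 1000.0)
    low, high = config.strata_cutoffs_per_1000
    if posterior < low:
        stratum = RiskStratum.LOW
    elif posterior <= high:
        stratum = RiskStratum.MIDDLE
    else:
        stratum = RiskStratum.HIGH
    return RiskEstimate(
        prior_per_1000=prior_per_1000,
        category=PresentationCategory(category),
        likelihood_ratio=lr,
        posterior_per_1000=posterior,
        stratum=stratum,
    )


def recommend(
    prior_per_1000: float,
    estimate: RiskEstimate,
    config: Optional[NscConfig] = None,
) -> NscRecommendation:
    """Map posterior risk and presentation category to a management action.

    Default decision table (risks per 1,000; lower/upper thresholds 1 and 3):

    * empiric antibiotics -- posterior > upper threshold OR clinical illness
    * strongly consider antibiotics -- equivocal with posterior <= upper
    * blood culture + vitals -- well appearing, posterior in [lower, upper]
    * enhanced vitals (no culture) -- posterior < lower but prior > lower
    * routine vitals -- otherwise
    """
    config = config or NscConfig()
    lower, upper = config.decision_thresholds_per_1000
    post = estimate.posterior_per_1000
    if post > upper or estimate.category is PresentationCategory.CLINICAL_ILLNESS:
        return NscRecommendation.EMPIRIC_ANTIBIOTICS
    if estimate.category is PresentationCategory.EQUIVOCAL:
        return NscRecommendation.STRONGLY_CONSIDER_ANTIBIOTICS
    if post >= lower:
        return NscRecommendation.CULTURE_AND_VITALS
    if prior_per_1000 > lower:
        return NscRecommendation.ENHANCED_VITALS
    return NscRecommendation.ROUTINE_VITALS


_TRIAGE_BY_RECOMMENDATION = {
    NscRecommendation.ROUTINE_VITALS: TriageLocation.ROOMING_IN,
    NscRecommendation.ENHANCED_VITALS: TriageLocation.ROOMING_IN,
    NscRecommendation.CULTURE_AND_VITALS: TriageLocation.ROOMING_IN,
    NscRecommendation.STRONGLY_CONSIDER_ANTIBIOTICS: TriageLocation.NICU,
    NscRecommendation.EMPIRIC_ANTIBIOTICS: TriageLocation.NICU,
}


def run_nsc(
    record: NeonateRecord, config: Optional[NscConfig] = None
) -> tuple[RiskEstimate, NscRecommendation, DecisionOutcome]:
    """Score one record end to end: prior, category, posterior, decision.

    The decision time is the end of the assessment window (infants are
    scored on their presentation within the first hours of life); the two
    antibiotic-implying recommendations carry NICU-level monitoring.
    """
    config = config or NscConfig()
    prior = compute_prior(record.maternal, config, record.prior_override_per_1000)
    category = classify_presentation(record, config)
    estimate = bayes_posterior(prior, category, config)
    rec = recommend(prior, estimate, config)
    evaluated = rec.implies_evaluation
    outcome = DecisionOutcome(
        id=record.id,
        strategy=Strategy.NSC,
        evaluated=evaluated,
        antibiotics=rec.implies_antibiotics,
        recommendation=rec.value,
        triage=_TRIAGE_BY_RECOMMENDATION[rec],
        evaluation_time_hours=config.assessment_window_hours if evaluated else None,
        antibiotics_time_hours=(
            config.assessment_window_hours if rec.implies_antibiotics else None
        ),
    )
    return estimate, rec, outcome
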