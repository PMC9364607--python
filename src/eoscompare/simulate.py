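"""Seeded synthetic neonate cohorts.

The generator emulates the structure of a single-centre cohort of 3,445
live births at >= 34 weeks' gestation: risk-factor prevalences (vaginal
delivery, GBS screening and colonisation, prolonged rupture of membranes,
intrapartum fever, IAP), a 7.66% rate of symptoms of suspected EOS split
68/19/13% between onset at birth, at 1-6 h and after 6 h, and symptom
trajectories with minor/major grades that resolve or progress over the
first 48 h (latent episode duration: log-normal, median 72 h, quartiles
roughly 1:5 apart as reported).

All randomness flows from one integer seed.  Record-level attributes are
drawn vectorised from ``default_rng(SeedSequence(seed, spawn_key=(0,)))``;
the timeline of record *i* is drawn from its own stream
``SeedSequence(seed, spawn_key=(1, i))`` so any record's timeline can be
regenerated independently.  Identical parameters give byte-identical
cohort CSVs.

Generated vitals are constructed to reproduce the intended symptom grade
exactly when passed through :func:`eoscompare.sco.grade_observation`
(inverse-grading consistency), so the decision engines see internally
consistent charts.  Asymptomatic records carry an empty timeline: vitals
that were never charted abnormal are "not measured", which both engines
treat as non-abnormal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    DeliveryMode,
    GbsStatus,
    MaternalProfile,
    NeonateRecord,
    Observation,
    RespiratorySupport,
)

__all__ = [
    "CohortParams",
    "Episode",
    "generate_cohort",
    "generate_cohort_frame",
    "generate_timeline",
    "draw_episode",
]

ONSET_CLASSES = ("at_birth", "h1_6", "after_6")


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class CohortParams:
    """Calibration of the synthetic cohort.

    Defaults are the observed cohort's prevalences and timing structure;
    probabilities conditional on late-preterm birth are exposed where the
    source tables print both strata (IAP, prolonged membrane rupture).
    """

    n: int = 3445
    seed: int = 0
    p_late_preterm: float = 178 / 3445
    ga_late_median: float = 36.14
    ga_late_iqr: tuple[float, float] = (35.29, 36.57)
    ga_term_median: float = 39.71
    ga_term_iqr: tuple[float, float] = (39.0, 40.29)
    p_vaginal: float = 0.7724
    p_screened: float = 0.9517
    p_gbs_pos_given_screened: float = 0.2184
    p_gbs_bacteriuria: float = 0.0134
    p_prior_gbs_infant: float = 2 / 3445
    p_prom: float = 0.1573
    p_prom_late_preterm: Optional[float] = 0.2303
    p_prom_term: Optional[float] = 0.1531
    p_temp_ge_37_5: float = 110 / 3445
    p_temp_ge_38: float = 0.0105
    p_iap: float = 0.2963
    p_iap_late_preterm: Optional[float] = 0.5505
    p_iap_term: Optional[float] = 0.2825
    p_iap_adequate_given_iap: float = 0.5632
    p_symptomatic: float = 264 / 3445
    onset_split: tuple[float, float, float] = (0.6818, 0.1856, 0.1326)
    p_major: float = 0.25
    duration_median_hours: float = 72.0
    duration_log_sigma: float = math.log(5.0) / (2 * 0.6745)  # IQR ratio 120/24
    progression_delay_max_hours: float = 2.0
    obs_interval_hours: float = 2.0
    horizon_hours: float = 48.0
    p_apgar_low_given_major_at_birth: float = 0.05
    p_dr_support_only: float = 0.01
    minor_finding_probs: tuple[tuple[str, float], ...] = (
        ("tachypnea", 0.6),
        ("tachycardia", 0.2),
        ("hypothermia", 0.1),
        ("acidosis", 0.1),
    )
    major_kind_probs: tuple[tuple[str, float], ...] = (
        ("respiratory", 0.7),
        ("fever", 0.15),
        ("perfusion", 0.15),
    )
    support_probs: tuple[tuple[str, float], ...] = (
        ("mechanical_ventilation", 0.07),
        ("ncpap", 0.38),
        ("hfnc", 0.25),
        ("supplemental_o2", 0.30),
    )
    eos_incidence_per_1000: float = 0.6

    def __post_init__(self):
        if self.n < 0:
            raise ParameterError("n must be >= 0")
        probs = {
            "p_late_preterm": self.p_late_preterm,
            "p_vaginal": self.p_vaginal,
            "p_screened": self.p_screened,
            "p_gbs_pos_given_screened": self.p_gbs_pos_given_screened,
            "p_gbs_bacteriuria": self.p_gbs_bacteriuria,
            "p_prior_gbs_infant": self.p_prior_gbs_infant,
            "p_prom": self.p_prom,
            "p_temp_ge_37_5": self.p_temp_ge_37_5,
            "p_temp_ge_38": self.p_temp_ge_38,
            "p_iap": self.p_iap,
            "p_iap_adequate_given_iap": self.p_iap_adequate_given_iap,
            "p_symptomatic": self.p_symptomatic,
            "p_major": self.p_major,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name}={p} outside [0, 1]")
        if abs(sum(self.onset_split) - 1.0) > 1e-6:
            raise ParameterError("onset_split must sum to 1")
        if not 0 <= self.eos_incidence_per_1000 <= 1000:
            raise ParameterError("eos_incidence_per_1000 outside [0, 1000]")

    # -- derived distribution parameters ------------------------------------

    def gumbel_temp_params(self) -> tuple[float, float]:
        """(mu, beta) of the Gumbel maternal-temperature model.

        Two-point quantile matching so that both the >=37.5 degC subgroup
        and the >=38 degC prevalence emerge from one right-skewed
        continuous distribution.
        """
        z1 = -math.log(-math.log(1.0 - self.p_temp_ge_37_5))
        z2 = -math.log(-math.log(1.0 - self.p_temp_ge_38))
        beta = (38.0 - 37.5) / (z2 - z1)
        mu = 37.5 - beta * z1
        return mu, beta


def _truncnorm(
    rng: np.random.Generator,
    median: float,
    iqr: tuple[float, float],
    bounds: tuple[float, float],
    size: int,
) -> np.ndarray:
    """Truncated normal matched to a printed median and IQR."""
    scale = (iqr[1] - iqr[0]) / (2 * 0.6745)
    a = (bounds[0] - median) / scale
    b = (bounds[1] - median) / scale
    return stats.truncnorm.rvs(a, b, loc=median, scale=scale, size=size, random_state=rng)


def _weighted_choice(rng: np.random.Generator, pairs) -> str:
    names = [k for k, _ in pairs]
    probs = np.asarray([p for _, p in pairs], dtype=float)
    return names[rng.choice(len(names), p=probs / probs.sum())]


def generate_cohort_frame(params: CohortParams) -> pd.DataFrame:
    """Vectorised record-level draws (no timelines).

    Returns one row per record with the cohort CSV attributes plus the
    latent generator state (``symptomatic``, ``onset_class``, ``is_major``)
    used to build timelines.
    """
    n = params.n
    rng = np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(0,)))
    lp = rng.random(n) < params.p_late_preterm
    ga = np.empty(n)
    n_lp = int(lp.sum())
    ga[lp] = _truncnorm(rng, params.ga_late_median, params.ga_late_iqr, (34.0, 36.99), n_lp)
    ga[~lp] = _truncnorm(rng, params.ga_term_median, params.ga_term_iqr, (37.0, 43.0), n - n_lp)

    vaginal = rng.random(n) < params.p_vaginal
    screened = rng.random(n) < params.p_screened
    gbs_pos = screened & (rng.random(n) < params.p_gbs_pos_given_screened)
    bacteriuria = rng.random(n) < params.p_gbs_bacteriuria
    prior_gbs = rng.random(n) < params.p_prior_gbs_infant

    p_prom = np.where(
        lp,
        params.p_prom if params.p_prom_late_preterm is None else params.p_prom_late_preterm,
        params.p_prom if params.p_prom_term is None else params.p_prom_term,
    )
    prom = rng.random(n) < p_prom
    rom = np.where(prom, 18.0 + rng.exponential(8.0, n), rng.uniform(0.0, 18.0, n))

    mu, beta = params.gumbel_temp_params()
    temp = np.clip(rng.gumbel(mu, beta, n), 35.0, 42.5)

    p_iap = np.where(
        lp,
        params.p_iap if params.p_iap_late_preterm is None else params.p_iap_late_preterm,
        params.p_iap if params.p_iap_term is None else params.p_iap_term,
    )
    iap = rng.random(n) < p_iap
    iap_adequate = iap & (rng.random(n) < params.p_iap_adequate_given_iap)

    true_eos = rng.random(n) < params.eos_incidence_per_1000 / 1000.0
    symptomatic = (rng.random(n) < params.p_symptomatic) | true_eos
    onset_idx = rng.choice(3, size=n, p=np.asarray(params.onset_split))
    onset_idx[true_eos] = 0  # proven EOS presents at birth
    is_major = (rng.random(n) < params.p_major) | true_eos

    apgar = np.where(rng.random(n) < 0.85, 10, 9)
    low_apgar = (
        symptomatic
        & is_major
        & (onset_idx == 0)
        & (rng.random(n) < params.p_apgar_low_given_major_at_birth)
    )
    apgar[low_apgar] = rng.integers(3, 5, size=n)[low_apgar]
    dr_support = (~symptomatic) & (rng.random(n) < params.p_dr_support_only)

    width = max(6, len(str(max(n - 1, 0))))
    return pd.DataFrame(
        {
            "id": [f"n{i:0{width}d}" for i in range(n)],
            "gestational_age_weeks": ga,
            "late_preterm": lp,
            "vaginal": vaginal,
            "screened": screened,
            "gbs_positive": gbs_pos,
            "gbs_bacteriuria": bacteriuria,
            "prior_gbs_infant": prior_gbs,
            "prom": prom,
            "rom_hours": rom,
            "max_intrapartum_temp_c": temp,
            "iap_given": iap,
            "iap_adequate": iap_adequate,
            "apgar_5min": apgar,
            "delivery_room_support_only": dr_support,
            "true_eos": true_eos,
            "symptomatic": symptomatic,
            "onset_class": [ONSET_CLASSES[i] for i in onset_idx],
            "is_major": is_major,
        }
    )


@dataclass(frozen=True)
class Episode:
    """Latent symptom episode driving one synthetic timeline."""

    onset_hours: float
    duration_hours: float
    progression_delay_hours: float
    minor_finding: str
    major_kind: Optional[str]
    support: RespiratorySupport


def draw_episode(
    onset_class: str,
    is_major: bool,
    params: CohortParams,
    rng: np.random.Generator,
) -> Episode:
    """Draw onset time, latent duration and manifestation of one episode.

    The latent duration is log-normal with the configured median; the
    observable timeline is truncated at the 48-h horizon, so durations are
    exposed here for calibration checks.
    """
    if onset_class == "at_birth":
        onset = 0.0
    elif onset_class == "h1_6":
        onset = rng.uniform(1.0, 6.0)
    elif onset_class == "after_6":
        onset = rng.uniform(6.0, 24.0)
    else:
        raise ParameterError(f"unknown onset class {onset_class!r}")
    duration = rng.lognormal(
        math.log(params.duration_median_hours), params.duration_log_sigma
    )
    delay = rng.uniform(0.0, params.progression_delay_max_hours) if is_major else 0.0
    minor_finding = _weighted_choice(rng, params.minor_finding_probs)
    major_kind = _weighted_choice(rng, params.major_kind_probs) if is_major else None
    support = RespiratorySupport.NONE
    if major_kind == "respiratory":
        support = RespiratorySupport(_weighted_choice(rng, params.support_probs))
    return Episode(onset, duration, delay, minor_finding, major_kind, support)


def _normal_vitals(t: float, rng: np.random.Generator) -> dict:
    return {
        "age_hours": float(t),
        "heart_rate_bpm": float(rng.uniform(110.0, 150.0)),
        "resp_rate_bpm": float(rng.uniform(35.0, 55.0)),
        "temp_c": float(rng.uniform(36.5, 37.3)),
        "spo2_pct": float(rng.uniform(96.0, 100.0)),
    }


def _realize(
    t: float, grade: str, ep: Episode, rng: np.random.Generator
) -> Observation:
    """Sample vitals reproducing the intended grade under SCO grading."""
    kw = _normal_vitals(t, rng)
    if grade == "minor":
        if ep.minor_finding == "tachypnea":
            kw["resp_rate_bpm"] = float(rng.uniform(62.0, 80.0))
        elif ep.minor_finding == "tachycardia":
            kw["heart_rate_bpm"] = float(rng.uniform(162.0, 185.0))
        elif ep.minor_finding == "hypothermia":
            kw["temp_c"] = float(rng.uniform(35.2, 35.9))
        elif ep.minor_finding == "acidosis":
            kw["base_excess_mmol_l"] = float(rng.uniform(-14.0, -10.5))
    elif grade == "major":
        if ep.major_kind == "respiratory":
            kw["resp_rate_bpm"] = float(rng.uniform(65.0, 90.0))
            kw["spo2_pct"] = float(rng.uniform(92.0, 98.0))
            return Observation(
                respiratory_support=ep.support, increased_effort=True, **kw
            )
        if ep.major_kind == "fever":
            kw["temp_c"] = float(rng.uniform(38.1, 39.0))
        elif ep.major_kind == "perfusion":
            kw["capillary_refill_s"] = float(rng.uniform(3.0, 5.0))
            return Observation(poor_perfusion_or_shock=True, **kw)
    return Observation(**kw)


def generate_timeline(
    onset_class: str,
    is_major: bool,
    params: CohortParams,
    rng: np.random.Generator,
) -> tuple[Observation, ...]:
    """Observation timeline over 0-48 h realising one symptom episode.

    Vitals are charted on a regular grid (default every 2 h) plus the onset
    and, for progressive episodes, the minor-to-major transition time; each
    observation's vitals are sampled to reproduce the intended grade under
    ``sco.grade_observation``.
    """
    ep = draw_episode(onset_class, is_major, params, rng)
    grid = np.arange(0.0, params.horizon_hours + 1e-9, params.obs_interval_hours)
    times = sorted(
        {round(float(t), 6) for t in grid}
        | {round(ep.onset_hours, 6), round(ep.onset_hours + ep.progression_delay_hours, 6)}
    )
    end = ep.onset_hours + ep.duration_hours
    major_from = ep.onset_hours + ep.progression_delay_hours
    out = []
    for t in times:
        if t > params.horizon_hours:
            continue
        if t < ep.onset_hours or t >= end:
            grade = "none"
        elif is_major and t >= major_from:
            grade = "major"
        else:
            grade = "minor"
        out.append(_realize(t, grade, ep, rng))
    return tuple(out)


def generate_cohort(params: CohortParams) -> list[NeonateRecord]:
    """Generate exactly ``params.n`` validated records (deterministic in seed)."""
    frame = generate_cohort_frame(params)
    records: list[NeonateRecord] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        if row.symptomatic:
            tl_rng = np.random.default_rng(
                np.random.SeedSequence(params.seed, spawn_key=(1, i))
            )
            timeline = generate_timeline(row.onset_class, row.is_major, params, tl_rng)
        else:
            timeline = ()
        maternal = MaternalProfile(
            gestational_age_weeks=float(row.gestational_age_weeks),
            delivery_mode=DeliveryMode.VAGINAL if row.vaginal else DeliveryMode.CESAREAN,
            gbs_status=(
                GbsStatus.POSITIVE
                if row.gbs_positive
                else (GbsStatus.NEGATIVE if row.screened else GbsStatus.UNKNOWN)
            ),
            gbs_bacteriuria=bool(row.gbs_bacteriuria),
            prior_gbs_infant=bool(row.prior_gbs_infant),
            rom_hours=float(row.rom_hours),
            max_intrapartum_temp_c=float(row.max_intrapartum_temp_c),
            iap_given=bool(row.iap_given),
            iap_adequate=bool(row.iap_adequate),
        )
        rec = NeonateRecord(
            id=row.id,
            maternal=maternal,
            apgar_5min=int(row.apgar_5min),
            delivery_room_support_only=bool(row.delivery_room_support_only),
            timeline=timeline,
            true_eos=bool(row.true_eos),
        )
        rec.validate()
        records.append(rec)
    return records
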