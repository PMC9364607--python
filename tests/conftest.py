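"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from eoscompare.cohort import (
    MaternalProfile,
    NeonateRecord,
    Observation,
    RespiratorySupport,
)


def obs(t: float, **kwargs) -> Observation:
    return Observation(age_hours=t, **kwargs)


def rec(
    id: str = "r1",
    ga: float = 39.0,
    timeline=(),
    apgar: int = 10,
    **maternal_kwargs,
) -> NeonateRecord:
    return NeonateRecord(
        id=id,
        maternal=MaternalProfile(gestational_age_weeks=ga, **maternal_kwargs),
        apgar_5min=apgar,
        timeline=tuple(timeline),
    )


def brute_force_mcnemar_exact(b: int, c: int) -> float:
    """Exact two-sided McNemar p by enumerating all 2^(b+c) discordant
    assignments under marginal homogeneity (each discordant pair equally
    likely to fall in either off-diagonal cell)."""
    m = b + c
    if m == 0:
        return 1.0
    k = min(b, c)
    count = sum(1 for mask in range(2**m) if bin(mask).count("1") <= k)
    return min(1.0, 2.0 * count / 2**m)


def random_timeline(rng: np.random.Generator) -> tuple[Observation, ...]:
    """Random plausible chart: mixed normal/abnormal vitals, sparse flags."""
    n = int(rng.integers(0, 10))
    times = np.sort(rng.uniform(0.0, 48.0, size=n))
    times = np.unique(np.round(times, 3))
    out = []
    supports = list(RespiratorySupport)
    for t in times:
        support = (
            supports[int(rng.integers(0, len(supports)))]
            if rng.random() < 0.2
            else RespiratorySupport.NONE
        )
        # respiratory support is only charted alongside respiratory distress
        supported = support is not RespiratorySupport.NONE
        out.append(
            Observation(
                age_hours=float(t),
                heart_rate_bpm=float(rng.uniform(100, 190)) if rng.random() < 0.8 else None,
                resp_rate_bpm=float(rng.uniform(61, 90))
                if supported
                else (float(rng.uniform(30, 90)) if rng.random() < 0.8 else None),
                temp_c=float(rng.uniform(35.0, 39.0)) if rng.random() < 0.7 else None,
                spo2_pct=float(rng.uniform(85, 100)) if rng.random() < 0.5 else None,
                base_excess_mmol_l=float(rng.uniform(-15, 2)) if rng.random() < 0.3 else None,
                capillary_refill_s=float(rng.uniform(1, 5)) if rng.random() < 0.3 else None,
                respiratory_support=support,
                increased_effort=supported or bool(rng.random() < 0.15),
                apnoea=bool(rng.random() < 0.05),
                lethargy=bool(rng.random() < 0.05),
                poor_perfusion_or_shock=bool(rng.random() < 0.05),
            )
        )
    return tuple(out)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
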