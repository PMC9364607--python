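"""Paired-proportion statistics for matched strategy decisions.

Each neonate receives a decision from both strategies, so strategy
comparison is a matched-pairs problem: the unit of analysis is the 2x2
paired table

    ==============  ==============  =============
                     NSC no          NSC yes
    SCO no           a               b
    SCO yes          c               d
    ==============  ==============  =============

Only the discordant cells (b, c) carry information about a difference in
marginal rates; McNemar's test (exact binomial by default, since discordant
counts in this setting can be as small as 0-5) and the paired difference of
marginal proportions (b - c)/n with Wald or Newcombe square-and-add
confidence intervals are provided.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import DecisionOutcome, NeonateRecord

__all__ = [
    "PairedTable",
    "McNemarVariant",
    "McNemarResult",
    "CiMethod",
    "PairedDifference",
    "build_paired_table",
    "mcnemar_test",
    "paired_difference",
    "presentation_difference_pct",
    "summarize_rates",
]


class PairingError(ValueError):
    pass


@dataclass(frozen=True)
class PairedTable:
    """2x2 matched decision table; a = both no, d = both yes."""

    a: int
    b: int  # SCO no, NSC yes
    c: int  # SCO yes, NSC no
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be >= 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def sco_marginal(self) -> int:
        return self.c + self.d

    @property
    def nsc_marginal(self) -> int:
        return self.b + self.d

    def sco_rate_pct(self) -> float:
        return 100.0 * self.sco_marginal / self.n

    def nsc_rate_pct(self) -> float:
        return 100.0 * self.nsc_marginal / self.n


class McNemarVariant(str, enum.Enum):
    EXACT_BINOMIAL = "exact_binomial"
    CHI2 = "chi2"
    CHI2_CONTINUITY = "chi2_continuity"


@dataclass(frozen=True)
class McNemarResult:
    variant: McNemarVariant
    p_value: float
    statistic: Optional[float] = None


class CiMethod(str, enum.Enum):
    WALD_PAIRED = "wald_paired"
    NEWCOMBE_PAIRED = "newcombe_paired"


@dataclass(frozen=True)
class PairedDifference:
    """Difference of marginal percentages, NSC minus SCO = (b - c)/n x 100."""

    diff_pct: float
    ci_low_pct: float
    ci_high_pct: float
    method: CiMethod


def build_paired_table(
    outcomes_sco: Sequence[DecisionOutcome],
    outcomes_nsc: Sequence[DecisionOutcome],
    field: str = "antibiotics",
    records: Optional[Sequence[NeonateRecord]] = None,
    filter: Optional[Callable[[NeonateRecord], bool]] = None,
) -> PairedTable:
    """Cross-tabulate one decision field across the two matched strategies.

    Outcome lists must cover the same record ids.  An optional record
    predicate (e.g. late preterm, GA < 37 weeks) restricts the table; it
    requires ``records`` to resolve ids.
    """
    if field not in ("antibiotics", "evaluated"):
        raise ValueError("field must be 'antibiotics' or 'evaluated'")
    sco_by_id = {o.id: o for o in outcomes_sco}
    nsc_by_id = {o.id: o for o in outcomes_nsc}
    if set(sco_by_id) != set(nsc_by_id):
        raise PairingError("SCO and NSC outcome lists cover different record ids")
    keep = set(sco_by_id)
    if filter is not None:
        if records is None:
            raise PairingError("a record filter requires the records")
        by_id = {r.id: r for r in records}
        missing = keep - set(by_id)
        if missing:
            raise PairingError(f"records missing for ids: {sorted(missing)[:5]}")
        keep = {i for i in keep if filter(by_id[i])}
    a = b = c = d = 0
    for rid in keep:
        s = bool(getattr(sco_by_id[rid], field))
        m = bool(getattr(nsc_by_id[rid], field))
        if s and m:
            d += 1
        elif s:
            c += 1
        elif m:
            b += 1
        else:
            a += 1
    return PairedTable(a, b, c, d)


def mcnemar_test(
    table: PairedTable,
    variant: McNemarVariant = McNemarVariant.EXACT_BINOMIAL,
) -> McNemarResult:
    """McNemar's test of marginal homogeneity on the discordant cells.

    Exact variant: two-sided p = min(1, 2 P(X <= min(b, c))) with
    X ~ Binomial(b + c, 1/2); chi-square variants use (b - c)^2/(b + c)
    with or without the continuity correction.  b + c = 0 gives p = 1.
    """
    variant = McNemarVariant(variant)
    b, c = table.b, table.c
    m = b + c
    if m == 0:
        return McNemarResult(variant=variant, p_value=1.0, statistic=None)
    if variant is McNemarVariant.EXACT_BINOMIAL:
        p = min(1.0, 2.0 * float(sps.binom.cdf(min(b, c), m, 0.5)))
        return McNemarResult(variant=variant, p_value=p, statistic=None)
    if variant is McNemarVariant.CHI2:
        stat = (b - c) ** 2 / m
    else:
        stat = (abs(b - c) - 1) ** 2 / m
    p = float(sps.chi2.sf(stat, df=1))
    return McNemarResult(variant=variant, p_value=p, statistic=float(stat))


def _wilson(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return centre - half, centre + half


def paired_difference(
    table: PairedTable,
    method: CiMethod = CiMethod.WALD_PAIRED,
    z: float = 1.959963984540054,
) -> PairedDifference:
    """Point difference (b - c)/n x 100 with a 95% confidence interval.

    ``wald_paired``: diff +/- z sqrt(b + c - (b - c)^2/n)/n.
    ``newcombe_paired``: square-and-add of the Wilson limits of the two
    marginal proportions (conservative; ignores the pairing correlation).
    Rounding is applied only at report time.
    """
    method = CiMethod(method)
    n = table.n
    if n == 0:
        raise ValueError("paired difference undefined for an empty table")
    b, c = table.b, table.c
    diff = (b - c) / n
    if method is CiMethod.WALD_PAIRED:
        se = np.sqrt(max(b + c - (b - c) ** 2 / n, 0.0)) / n
        lo, hi = diff - z * se, diff + z * se
    else:
        p_nsc = table.nsc_marginal / n
        p_sco = table.sco_marginal / n
        l_n, u_n = _wilson(table.nsc_marginal, n, z)
        l_s, u_s = _wilson(table.sco_marginal, n, z)
        lo = diff - float(np.hypot(p_nsc - l_n, u_s - p_sco))
        hi = diff + float(np.hypot(u_n - p_nsc, p_sco - l_s))
    return PairedDifference(
        diff_pct=100.0 * diff,
        ci_low_pct=100.0 * lo,
        ci_high_pct=100.0 * hi,
        method=method,
    )


def presentation_difference_pct(
    table: PairedTable, mode: str = "direct", decimals: int = 2
) -> float:
    """Difference of marginal percentages as presented in a report.

    ``direct``: round((b - c)/n x 100, decimals).  ``rounded_marginals``:
    difference of the two marginal percentages each first rounded to
    ``decimals`` (some published tables present the difference this way).
    """
    if mode == "direct":
        return round(100.0 * (table.b - table.c) / table.n, decimals)
    if mode == "rounded_marginals":
        return round(
            round(table.nsc_rate_pct(), decimals) - round(table.sco_rate_pct(), decimals),
            decimals,
        )
    raise ValueError("mode must be 'direct' or 'rounded_marginals'")


# ---------------------------------------------------------------------------
# Stratified rate summaries
# ---------------------------------------------------------------------------

STRATA = ("all", "late_preterm", "term", "maternal_fever")


def _stratum_predicate(name: str) -> Callable[[NeonateRecord], bool]:
    if name == "all":
        return lambda r: True
    if name == "late_preterm":
        return lambda r: r.maternal.gestational_age_weeks < 37.0
    if name == "term":
        return lambda r: r.maternal.gestational_age_weeks >= 37.0
    if name == "maternal_fever":
        return lambda r: r.maternal.max_intrapartum_temp_c >= 37.5
    raise ValueError(f"unknown stratum {name!r}")


def summarize_rates(
    records: Sequence[NeonateRecord],
    outcomes_sco: Sequence[DecisionOutcome],
    outcomes_nsc: Sequence[DecisionOutcome],
    estimates: Optional[dict] = None,
    strata: Iterable[str] = STRATA,
) -> pd.DataFrame:
    """Counts and percentages per stratum for both strategies.

    One row per stratum: cohort size, symptomatic infants (any non-empty
    timeline with an abnormal grade is approximated by SCO evaluation or a
    non-empty timeline), evaluations and antibiotics per strategy, triage
    occupancy, and NSC risk-stratum occupancy when estimates are supplied.
    An empty stratum yields a row of zeros.
    """
    from .sco import SymptomGradeLevel, grade_observation  # local to avoid cycle

    sco_by_id = {o.id: o for o in outcomes_sco}
    nsc_by_id = {o.id: o for o in outcomes_nsc}
    rows = []
    for name in strata:
        pred = _stratum_predicate(name)
        recs = [r for r in records if pred(r)]
        n = len(recs)
        row: dict = {"stratum": name, "n": n}

        def pct(k: int) -> float:
            return 100.0 * k / n if n else 0.0

        symptomatic = sum(
            any(
                grade_observation(o).level is not SymptomGradeLevel.NONE
                for o in r.timeline
            )
            for r in recs
        )
        row["symptomatic"] = symptomatic
        row["symptomatic_pct"] = pct(symptomatic)
        for label, by_id in (("sco", sco_by_id), ("nsc", nsc_by_id)):
            ev = sum(by_id[r.id].evaluated for r in recs if r.id in by_id)
            ab = sum(by_id[r.id].antibiotics for r in recs if r.id in by_id)
            row[f"{label}_evaluated"] = ev
            row[f"{label}_evaluated_pct"] = pct(ev)
            row[f"{label}_antibiotics"] = ab
            row[f"{label}_antibiotics_pct"] = pct(ab)
        for loc in ("rooming_in", "intermediate_care", "nicu"):
            k = sum(
                sco_by_id[r.id].triage.value == loc for r in recs if r.id in sco_by_id
            )
            row[f"triage_{loc}"] = k
        if estimates:
            for stratum_name in ("low", "middle", "high"):
                k = sum(
                    estimates[r.id].stratum.value == stratum_name
                    for r in recs
                    if r.id in estimates
                )
                row[f"nsc_stratum_{stratum_name}"] = k
        rows.append(row)
    return pd.DataFrame(rows)
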