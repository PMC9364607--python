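"""Matched comparison of the two EOS management strategies.

The public modelling surface follows the model / results convention:
:class:`StrategyComparison` is built from a cohort (in memory or from CSV),
``fit()`` runs both decision engines over every record and returns a
:class:`StrategyComparisonResults` carrying the per-record decisions, the
paired 2x2 tables for antibiotics and "rule out sepsis" evaluations (overall
and per stratum), McNemar p-values, paired marginal differences with
confidence intervals, and a ``summary()`` text report mirroring the paired
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .cohort import DecisionOutcome, NeonateRecord, read_cohort
from .nsc import NscConfig, RiskEstimate, run_nsc
from .sco import ScoConfig, run_sco
from .stats import (
    CiMethod,
    McNemarResult,
    McNemarVariant,
    PairedDifference,
    PairedTable,
    build_paired_table,
    mcnemar_test,
    paired_difference,
    summarize_rates,
    _stratum_predicate,
)

__all__ = ["StrategyComparison", "StrategyComparisonResults", "ComparisonCell"]

_FIELDS = ("antibiotics", "evaluated")
_DEFAULT_STRATA = ("all", "late_preterm")


@dataclass(frozen=True)
class ComparisonCell:
    """One paired table plus its statistics.

    ``difference`` is None for an empty stratum (undefined at n = 0).
    """

    field: str
    stratum: str
    table: PairedTable
    mcnemar: McNemarResult
    difference: Optional[PairedDifference]


class StrategyComparison:
    """Matched SCO-vs-NSC comparison over one cohort.

    Parameters
    ----------
    records : validated neonate records.
    nsc_config, sco_config : engine configurations (defaults: published
        thresholds).
    strata : record strata to tabulate in addition to the whole cohort.
    mcnemar_variant, ci_method : statistics options.
    """

    def __init__(
        self,
        records: Sequence[NeonateRecord],
        nsc_config: Optional[NscConfig] = None,
        sco_config: Optional[ScoConfig] = None,
        strata: Sequence[str] = _DEFAULT_STRATA,
        mcnemar_variant: McNemarVariant = McNemarVariant.EXACT_BINOMIAL,
        ci_method: CiMethod = CiMethod.WALD_PAIRED,
    ):
        self.records = list(records)
        self.nsc_config = nsc_config or NscConfig()
        self.sco_config = sco_config or ScoConfig()
        self.strata = tuple(strata)
        self.mcnemar_variant = McNemarVariant(mcnemar_variant)
        self.ci_method = CiMethod(ci_method)

    @classmethod
    def from_csv(cls, cohort_path, observations_path=None, **kwargs) -> "StrategyComparison":
        return cls(read_cohort(cohort_path, observations_path), **kwargs)

    def fit(self) -> "StrategyComparisonResults":
        outcomes_sco: list[DecisionOutcome] = []
        outcomes_nsc: list[DecisionOutcome] = []
        estimates: dict[str, RiskEstimate] = {}
        for rec in self.records:
            outcomes_sco.append(run_sco(rec, self.sco_config))
            estimate, _, outcome = run_nsc(rec, self.nsc_config)
            estimates[rec.id] = estimate
            outcomes_nsc.append(outcome)

        cells: dict[tuple[str, str], ComparisonCell] = {}
        for f in _FIELDS:
            for stratum in ("all",) + tuple(s for s in self.strata if s != "all"):
                pred = None if stratum == "all" else _stratum_predicate(stratum)
                table = build_paired_table(
                    outcomes_sco,
                    outcomes_nsc,
                    field=f,
                    records=self.records,
                    filter=pred,
                )
                cells[(f, stratum)] = ComparisonCell(
                    field=f,
                    stratum=stratum,
                    table=table,
                    mcnemar=mcnemar_test(table, self.mcnemar_variant),
                    difference=(
                        paired_difference(table, self.ci_method) if table.n else None
                    ),
                )
        rates = summarize_rates(self.records, outcomes_sco, outcomes_nsc, estimates)
        return StrategyComparisonResults(
            model=self,
            outcomes_sco=outcomes_sco,
            outcomes_nsc=outcomes_nsc,
            risk_estimates=estimates,
            cells=cells,
            rate_summary=rates,
        )


@dataclass
class StrategyComparisonResults:
    """Fitted comparison: decisions, paired tables, and statistics."""

    model: StrategyComparison
    outcomes_sco: list[DecisionOutcome]
    outcomes_nsc: list[DecisionOutcome]
    risk_estimates: dict[str, RiskEstimate]
    cells: dict[tuple[str, str], ComparisonCell]
    rate_summary: pd.DataFrame = field(repr=False, default=None)

    def cell(self, field: str = "antibiotics", stratum: str = "all") -> ComparisonCell:
        return self.cells[(field, stratum)]

    def paired_table(self, field: str = "antibiotics", stratum: str = "all") -> PairedTable:
        return self.cells[(field, stratum)].table

    def to_frame(self) -> pd.DataFrame:
        """One row per (field, stratum) with cells, rates, diff, CI and p."""
        rows = []
        for (f, s), cell in sorted(self.cells.items()):
            t, d, m = cell.table, cell.difference, cell.mcnemar
            empty = t.n == 0
            rows.append(
                {
                    "field": f,
                    "stratum": s,
                    "a_both_no": t.a,
                    "b_sco_no_nsc_yes": t.b,
                    "c_sco_yes_nsc_no": t.c,
                    "d_both_yes": t.d,
                    "n": t.n,
                    "sco_rate_pct": 0.0 if empty else t.sco_rate_pct(),
                    "nsc_rate_pct": 0.0 if empty else t.nsc_rate_pct(),
                    "diff_pct": None if d is None else d.diff_pct,
                    "ci_low_pct": None if d is None else d.ci_low_pct,
                    "ci_high_pct": None if d is None else d.ci_high_pct,
                    "p_value": m.p_value,
                }
            )
        return pd.DataFrame(rows)

    def risk_scores(self) -> pd.Series:
        """Posterior EOS risk per 1,000 live births, indexed by record id."""
        return pd.Series(
            {rid: e.posterior_per_1000 for rid, e in self.risk_estimates.items()},
            name="posterior_per_1000",
        )

    def summary(self) -> str:
        """Human-readable paired tables with marginals, differences and p."""
        lines = ["Matched comparison of SCO vs NSC decisions", ""]
        label = {"antibiotics": "antibiotic use", "evaluated": "'rule out sepsis' evaluations"}
        for (f, s), cell in sorted(self.cells.items()):
            t, d, m = cell.table, cell.difference, cell.mcnemar
            if d is None:
                lines += [f"{label[f].capitalize()} -- stratum: {s}: empty stratum", ""]
                continue
            lines += [
                f"{label[f].capitalize()} -- stratum: {s} (n = {t.n})",
                f"{'':>14}{'NSC no':>10}{'NSC yes':>10}{'total (%)':>16}",
                f"{'SCO no':>14}{t.a:>10}{t.b:>10}{t.a + t.b:>10}"
                f" ({100 * (t.a + t.b) / t.n:5.1f})",
                f"{'SCO yes':>14}{t.c:>10}{t.d:>10}{t.c + t.d:>10}"
                f" ({t.sco_rate_pct():5.1f})",
                f"{'total (%)':>14}{t.a + t.c:>10}{t.b + t.d:>10}{t.n:>10} (100.0)",
                f"  NSC marginal {t.nsc_rate_pct():.1f}%  vs  SCO marginal "
                f"{t.sco_rate_pct():.1f}%",
                f"  difference (NSC - SCO) {d.diff_pct:.2f}%  "
                f"95% CI [{d.ci_low_pct:.2f}, {d.ci_high_pct:.2f}]  "
                f"({d.method.value}); McNemar {m.variant.value} p = {m.p_value:.4g}",
                "",
            ]
        return "\n".join(lines)

    def plot_risk_scores(self, ax=None):
        """Box plot of posterior risk scores: whole cohort vs the infants
        each strategy would treat (optional matplotlib dependency)."""
        import matplotlib.pyplot as plt

        scores = self.risk_scores()
        sco_ids = [o.id for o in self.outcomes_sco if o.antibiotics]
        nsc_ids = [o.id for o in self.outcomes_nsc if o.antibiotics]
        groups = [scores.values, scores.loc[nsc_ids].values, scores.loc[sco_ids].values]
        if ax is None:
            _, ax = plt.subplots()
        ax.boxplot(groups, tick_labels=["all", "NSC antibiotics", "SCO antibiotics"])
        ax.set_ylabel("posterior EOS risk per 1,000 live births")
        return ax
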