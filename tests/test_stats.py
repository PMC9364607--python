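"""Paired tables, McNemar variants, marginal differences, rate summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eoscompare.cohort import DecisionOutcome, Strategy, TriageLocation
from eoscompare.stats import (
    CiMethod,
    McNemarVariant,
    PairedTable,
    PairingError,
    build_paired_table,
    mcnemar_test,
    paired_difference,
    presentation_difference_pct,
    summarize_rates,
)

from conftest import brute_force_mcnemar_exact, rec

TABLE_4A = PairedTable(3254, 126, 5, 60)
TABLE_4B = PairedTable(3231, 76, 20, 118)
TABLE_5A = PairedTable(130, 33, 0, 15)
TABLE_5B = PairedTable(127, 18, 1, 32)


def _outcome(rid, strategy, yes):
    return DecisionOutcome(
        id=rid,
        strategy=strategy,
        evaluated=yes,
        antibiotics=yes,
        recommendation="x",
        triage=TriageLocation.ROOMING_IN,
        evaluation_time_hours=4.0 if yes else None,
    )


def _outcome_lists(table: PairedTable):
    sco, nsc = [], []
    spec = [(False, False)] * table.a + [(False, True)] * table.b
    spec += [(True, False)] * table.c + [(True, True)] * table.d
    for i, (s, m) in enumerate(spec):
        rid = f"r{i}"
        sco.append(_outcome(rid, Strategy.SCO, s))
        nsc.append(_outcome(rid, Strategy.NSC, m))
    return sco, nsc


class TestBuildPairedTable:
    def test_perfect_agreement_has_no_discordance(self):
        sco, nsc = _outcome_lists(PairedTable(7, 0, 0, 3))
        t = build_paired_table(sco, nsc, "antibiotics")
        assert (t.b, t.c) == (0, 0) and t.n == 10

    def test_reconstructs_full_cohort_antibiotic_table(self):
        sco, nsc = _outcome_lists(TABLE_4A)
        t = build_paired_table(sco, nsc, "antibiotics")
        assert (t.a, t.b, t.c, t.d) == (3254, 126, 5, 60)

    def test_record_filter_restricts_counts(self):
        sco, nsc = _outcome_lists(PairedTable(4, 2, 1, 1))
        records = [rec(id=f"r{i}", ga=36.0 if i < 4 else 40.0) for i in range(8)]
        t = build_paired_table(
            sco, nsc, "antibiotics", records=records,
            filter=lambda r: r.maternal.gestational_age_weeks < 37.0,
        )
        assert t.n == 4

    def test_id_mismatch_raises(self):
        sco, nsc = _outcome_lists(PairedTable(1, 1, 1, 1))
        with pytest.raises(PairingError):
            build_paired_table(sco[:-1], nsc, "antibiotics")

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.tuples(*[st.integers(0, 40)] * 4))
    def test_marginal_identity(self, cells):
        t = PairedTable(*cells)
        assert t.nsc_marginal - t.sco_marginal == t.b - t.c
        assert t.n == t.a + t.b + t.c + t.d


class TestMcNemar:
    def test_exact_matches_brute_force_enumeration(self):
        for m in range(0, 13):
            for b in range(m + 1):
                c = m - b
                p = mcnemar_test(PairedTable(0, b, c, 0)).p_value
                assert p == pytest.approx(brute_force_mcnemar_exact(b, c), abs=1e-12)

    def test_exact_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        rng = np.random.default_rng(3)
        for _ in range(50):
            b, c = int(rng.integers(0, 80)), int(rng.integers(0, 80))
            if b + c == 0:
                continue
            ours = mcnemar_test(PairedTable(10, b, c, 10)).p_value
            ref = sm_mcnemar([[10, b], [c, 10]], exact=True).pvalue
            assert ours == pytest.approx(float(ref), rel=1e-9)

    def test_published_table_significances(self):
        assert mcnemar_test(TABLE_4A).p_value < 1e-4
        assert mcnemar_test(TABLE_4B).p_value < 1e-4
        assert mcnemar_test(TABLE_5A).p_value < 1e-4
        assert mcnemar_test(TABLE_5B).p_value < 1e-4

    def test_symmetric_discordance_p_one(self):
        assert mcnemar_test(PairedTable(0, 4, 4, 0)).p_value == 1.0
        assert mcnemar_test(PairedTable(5, 0, 0, 5)).p_value == 1.0

    def test_small_discordance_exact_value(self):
        # Binomial(4, 1/2): two-sided 2 x (1 + 4)/16
        assert mcnemar_test(PairedTable(0, 3, 1, 0)).p_value == pytest.approx(0.625)

    def test_continuity_corrected_chi2_tracks_exact_at_large_m(self):
        for b, c in [(30, 25), (55, 45), (40, 28), (70, 60)]:
            exact = mcnemar_test(PairedTable(0, b, c, 0)).p_value
            cc = mcnemar_test(
                PairedTable(0, b, c, 0), McNemarVariant.CHI2_CONTINUITY
            ).p_value
            assert cc == pytest.approx(exact, rel=0.10)

    def test_chi2_statistic_formulas(self):
        r = mcnemar_test(PairedTable(0, 30, 25, 0), McNemarVariant.CHI2)
        assert r.statistic == pytest.approx((30 - 25) ** 2 / 55)
        rcc = mcnemar_test(PairedTable(0, 30, 25, 0), McNemarVariant.CHI2_CONTINUITY)
        assert rcc.statistic == pytest.approx((abs(30 - 25) - 1) ** 2 / 55)


class TestPairedDifference:
    def test_full_cohort_antibiotic_difference(self):
        d = paired_difference(TABLE_4A)
        assert round(d.diff_pct, 2) == 3.51
        assert d.ci_low_pct <= d.diff_pct <= d.ci_high_pct

    def test_evaluation_difference(self):
        assert presentation_difference_pct(TABLE_4B, "direct", 2) == 1.63

    def test_symmetric_table_zero_difference(self):
        assert paired_difference(PairedTable(10, 6, 6, 2)).diff_pct == 0.0

    def test_late_preterm_differences_match_presentation_modes(self):
        # one-decimal marginals 27.0 - 8.4 = 18.6; direct is 18.5 at one decimal
        assert round(TABLE_5A.nsc_rate_pct(), 1) == 27.0
        assert round(TABLE_5A.sco_rate_pct(), 1) == 8.4
        assert presentation_difference_pct(TABLE_5A, "rounded_marginals", 1) == 18.6
        assert presentation_difference_pct(TABLE_5A, "direct", 1) == 18.5
        assert round(TABLE_5B.nsc_rate_pct(), 1) == 28.1
        assert presentation_difference_pct(TABLE_5B, "direct", 1) == 9.6

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.tuples(
            st.integers(1, 500), st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
        )
    )
    def test_ci_contains_point_estimate(self, cells):
        t = PairedTable(*cells)
        for method in CiMethod:
            d = paired_difference(t, method)
            assert d.ci_low_pct <= d.diff_pct + 1e-9
            assert d.diff_pct <= d.ci_high_pct + 1e-9

    def test_ci_width_shrinks_with_n(self):
        widths = []
        for k in (1, 10, 100):
            t = PairedTable(3254 * k, 126 * k, 5 * k, 60 * k)
            d = paired_difference(t)
            widths.append(d.ci_high_pct - d.ci_low_pct)
        assert widths[0] > widths[1] > widths[2]

    def test_empty_table_undefined(self):
        with pytest.raises(ValueError):
            paired_difference(PairedTable(0, 0, 0, 0))


class TestRateSummary:
    def _fixture(self):
        # 10 records: 3 late preterm; antibiotics under SCO for 2 (1 LP)
        records = [rec(id=f"r{i}", ga=36.0 if i < 3 else 40.0) for i in range(10)]
        sco = [_outcome(f"r{i}", Strategy.SCO, i in (0, 5)) for i in range(10)]
        nsc = [_outcome(f"r{i}", Strategy.NSC, i in (0, 1, 5)) for i in range(10)]
        return records, sco, nsc

    def test_stratified_counts_and_percentages(self):
        records, sco, nsc = self._fixture()
        df = summarize_rates(records, sco, nsc).set_index("stratum")
        assert df.loc["all", "n"] == 10
        assert df.loc["all", "sco_antibiotics"] == 2
        assert df.loc["all", "sco_antibiotics_pct"] == pytest.approx(20.0)
        assert df.loc["late_preterm", "n"] == 3
        assert df.loc["late_preterm", "nsc_antibiotics"] == 2
        assert df.loc["term", "n"] == 7

    def test_empty_stratum_is_zero_row(self):
        records, sco, nsc = self._fixture()  # nobody has maternal fever
        df = summarize_rates(records, sco, nsc).set_index("stratum")
        assert df.loc["maternal_fever", "n"] == 0
        assert df.loc["maternal_fever", "sco_antibiotics_pct"] == 0.0

    def test_empty_cohort_all_zero(self):
        df = summarize_rates([], [], []).set_index("stratum")
        assert (df["n"] == 0).all()
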