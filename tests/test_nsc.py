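"""Sepsis risk calculator: prior, temporal classification, Bayes update,
recommendation table, and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eoscompare.cohort import MaternalProfile, RespiratorySupport
from eoscompare.nsc import (
    RECOMMENDATION_SEVERITY,
    NscConfig,
    NscRecommendation,
    PresentationCategory,
    RiskEstimate,
    RiskStratum,
    bayes_posterior,
    compute_prior,
    classify_presentation,
    recommend,
)

from conftest import obs, rec


def odds_update_oracle(prior_per_1000: float, lr: float) -> float:
    """Independent odds-arithmetic oracle for the LR update."""
    p = prior_per_1000 / 1000.0
    odds = p / (1 - p) * lr
    return 1000.0 * odds / (1 + odds)


class TestPrior:
    def test_baseline_incidence_passthrough(self):
        m = MaternalProfile(gestational_age_weeks=39.0)
        assert compute_prior(m, NscConfig()) == 0.6

    def test_override_wins(self):
        m = MaternalProfile(gestational_age_weeks=39.0)
        assert compute_prior(m, NscConfig(), override=2.5) == 2.5

    def test_single_odds_multiplier(self):
        # 0.6/1000 -> odds 0.0006/0.9994, doubled, back-converted
        m = MaternalProfile(gestational_age_weeks=39.0, iap_given=True)
        cfg = NscConfig(prior_coefficients={"iap_given": 2.0})
        expected = odds_update_oracle(0.6, 2.0)
        assert compute_prior(m, cfg) == pytest.approx(expected, rel=1e-12)
        assert compute_prior(m, cfg) == pytest.approx(1.1993, abs=5e-4)

    def test_enum_valued_covariate_key(self):
        from eoscompare.cohort import GbsStatus

        m = MaternalProfile(gestational_age_weeks=39.0, gbs_status=GbsStatus.POSITIVE)
        cfg = NscConfig(prior_coefficients={"gbs_status=positive": 3.0})
        assert compute_prior(m, cfg) == pytest.approx(odds_update_oracle(0.6, 3.0))
        m2 = MaternalProfile(gestational_age_weeks=39.0)
        assert compute_prior(m2, cfg) == 0.6


class TestClassification:
    def test_low_apgar_is_clinical_illness(self):
        r = rec(apgar=4)
        assert classify_presentation(r) is PresentationCategory.CLINICAL_ILLNESS

    def test_persistent_single_abnormality_is_equivocal(self):
        # tachypnea charted continuously from 0 h to 4.5 h
        tl = [obs(t, resp_rate_bpm=70.0) for t in (0.0, 1.5, 3.0, 4.5)]
        assert classify_presentation(rec(timeline=tl)) is PresentationCategory.EQUIVOCAL

    def test_empty_timeline_normal_birth_is_well_appearing(self):
        assert classify_presentation(rec()) is PresentationCategory.WELL_APPEARING

    def test_two_abnormalities_over_two_hours_equivocal(self):
        tl = [
            obs(t, heart_rate_bpm=170.0, resp_rate_bpm=65.0) for t in (0.0, 1.0, 2.5)
        ]
        assert classify_presentation(rec(timeline=tl)) is PresentationCategory.EQUIVOCAL

    def test_short_single_abnormality_stays_well_appearing(self):
        tl = [obs(0.0, resp_rate_bpm=70.0), obs(2.0, resp_rate_bpm=45.0)]
        assert (
            classify_presentation(rec(timeline=tl))
            is PresentationCategory.WELL_APPEARING
        )

    def test_ncpap_outside_delivery_room_is_clinical_illness(self):
        tl = [obs(1.0, respiratory_support=RespiratorySupport.NCPAP)]
        assert classify_presentation(rec(timeline=tl)) is PresentationCategory.CLINICAL_ILLNESS

    def test_delivery_room_only_support_excluded(self):
        r = rec(timeline=[obs(0.0, respiratory_support=RespiratorySupport.NCPAP)])
        r_dr = type(r)(
            id=r.id,
            maternal=r.maternal,
            apgar_5min=r.apgar_5min,
            delivery_room_support_only=True,
            timeline=r.timeline,
        )
        assert classify_presentation(r_dr) is PresentationCategory.WELL_APPEARING

    def test_prolonged_supplemental_o2_is_clinical_illness(self):
        tl = [
            obs(t, respiratory_support=RespiratorySupport.SUPPLEMENTAL_O2, spo2_pct=94.0)
            for t in (0.0, 1.0, 2.0, 2.5)
        ]
        assert classify_presentation(rec(timeline=tl)) is PresentationCategory.CLINICAL_ILLNESS

    def test_interval_splitting_invariance(self):
        coarse = [obs(0.0, resp_rate_bpm=75.0), obs(4.5, resp_rate_bpm=40.0)]
        fine = [obs(t, resp_rate_bpm=75.0) for t in (0.0, 1.0, 2.0, 3.0)] + [
            obs(4.5, resp_rate_bpm=40.0)
        ]
        assert classify_presentation(rec(timeline=coarse)) == classify_presentation(
            rec(timeline=fine)
        )


class TestBayesUpdate:
    @pytest.mark.parametrize(
        "category, expected, stratum",
        [
            (PresentationCategory.WELL_APPEARING, 0.2460, RiskStratum.LOW),
            (PresentationCategory.EQUIVOCAL, 2.9928, RiskStratum.HIGH),
            (PresentationCategory.CLINICAL_ILLNESS, 12.568, RiskStratum.HIGH),
        ],
    )
    def test_posterior_matches_odds_oracle(self, category, expected, stratum):
        est = bayes_posterior(0.6, category)
        oracle = odds_update_oracle(0.6, est.likelihood_ratio)
        assert est.posterior_per_1000 == pytest.approx(oracle, rel=1e-12)
        assert est.posterior_per_1000 == pytest.approx(expected, abs=1e-3)
        assert est.stratum is stratum

    def test_unit_likelihood_ratio_is_identity(self):
        cfg = NscConfig(lr_well=1.0)
        for prior in (0.1, 0.6, 3.7, 50.0):
            est = bayes_posterior(prior, PresentationCategory.WELL_APPEARING, cfg)
            assert est.posterior_per_1000 == pytest.approx(prior, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        prior=st.floats(0.05, 100.0),
        lr=st.floats(0.05, 50.0),
        bump=st.floats(1e-3, 10.0),
    )
    def test_posterior_monotone_in_prior_and_lr(self, prior, lr, bump):
        cfg = NscConfig(lr_well=lr)
        cfg_up = NscConfig(lr_well=lr + bump)
        cat = PresentationCategory.WELL_APPEARING
        base = bayes_posterior(prior, cat, cfg).posterior_per_1000
        assert bayes_posterior(prior + bump, cat, cfg).posterior_per_1000 > base
        assert bayes_posterior(prior, cat, cfg_up).posterior_per_1000 > base

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(prior=st.floats(0.05, 20.0))
    def test_odds_and_naive_updates_agree_at_low_risk(self, prior):
        # posterior <= 20/1000 regime: relative gap below 3%
        for cat in PresentationCategory:
            exact = bayes_posterior(prior, cat).posterior_per_1000
            naive = bayes_posterior(
                prior, cat, NscConfig(odds_scale_update=False)
            ).posterior_per_1000
            if max(exact, naive) <= 20.0:
                assert naive == pytest.approx(exact, rel=0.03)

    def test_prior_bounds_enforced(self):
        with pytest.raises(ValueError):
            bayes_posterior(0.0, PresentationCategory.WELL_APPEARING)
        with pytest.raises(ValueError):
            bayes_posterior(1000.0, PresentationCategory.WELL_APPEARING)


class TestRecommendation:
    def test_well_appearing_low_risk_routine(self):
        est = bayes_posterior(0.6, PresentationCategory.WELL_APPEARING)
        assert recommend(0.6, est) is NscRecommendation.ROUTINE_VITALS

    def test_clinical_illness_always_empiric(self):
        for prior in (0.1, 0.6, 5.0):
            est = bayes_posterior(prior, PresentationCategory.CLINICAL_ILLNESS)
            assert recommend(prior, est) is NscRecommendation.EMPIRIC_ANTIBIOTICS

    def test_elevated_prior_low_posterior_enhanced_vitals(self):
        est = bayes_posterior(2.0, PresentationCategory.WELL_APPEARING)
        assert est.posterior_per_1000 == pytest.approx(0.8212, abs=1e-3)
        assert recommend(2.0, est) is NscRecommendation.ENHANCED_VITALS

    def test_equivocal_at_upper_threshold_strongly_consider(self):
        est = RiskEstimate(
            prior_per_1000=0.6,
            category=PresentationCategory.EQUIVOCAL,
            likelihood_ratio=5.0,
            posterior_per_1000=3.0,
            stratum=RiskStratum.HIGH,
        )
        assert recommend(0.6, est) is NscRecommendation.STRONGLY_CONSIDER_ANTIBIOTICS

    def test_mid_posterior_well_appearing_culture(self):
        est = bayes_posterior(3.0, PresentationCategory.WELL_APPEARING)
        assert 1.0 <= est.posterior_per_1000 <= 3.0
        assert recommend(3.0, est) is NscRecommendation.CULTURE_AND_VITALS

    def test_severity_nondecreasing_in_posterior(self):
        for cat in (PresentationCategory.WELL_APPEARING, PresentationCategory.EQUIVOCAL):
            prev = -1
            for post in np.linspace(0.05, 20.0, 120):
                est = RiskEstimate(
                    prior_per_1000=0.6,
                    category=cat,
                    likelihood_ratio=1.0,
                    posterior_per_1000=float(post),
                    stratum=RiskStratum.LOW,
                )
                sev = RECOMMENDATION_SEVERITY[recommend(0.6, est)]
                assert sev >= prev
                prev = sev

    def test_implication_flags(self):
        assert {r for r in NscRecommendation if r.implies_antibiotics} == {
            NscRecommendation.STRONGLY_CONSIDER_ANTIBIOTICS,
            NscRecommendation.EMPIRIC_ANTIBIOTICS,
        }
        assert {r for r in NscRecommendation if r.implies_evaluation} == {
            NscRecommendation.CULTURE_AND_VITALS,
            NscRecommendation.STRONGLY_CONSIDER_ANTIBIOTICS,
            NscRecommendation.EMPIRIC_ANTIBIOTICS,
        }
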