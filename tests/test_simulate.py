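"""Synthetic KB and cohort generators, and the end-to-end study simulator."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from milescreen.kb import LanguageDomain, dumps_kb, validate_kb
from milescreen.simulate import (
    AbilityModel,
    CohortConfig,
    KbGenConfig,
    gen_cohort,
    gen_kb,
    simulate_study,
)
from milescreen.stats import age_band, latest_per_child


class TestGenKb:
    def test_default_shape(self, synth_kb):
        assert synth_kb.n_questions == 108
        assert synth_kb.coverage_range == (1, 36)
        assert validate_kb(synth_kb) == []

    def test_every_month_has_three_to_six_questions(self):
        for seed in range(6):
            kb = gen_kb(KbGenConfig(seed=seed))
            for node in kb.months.values():
                assert 3 <= len(node.question_ids) <= 6

    def test_domain_counts_equal_quotas(self, synth_kb):
        counts = {d: 0 for d in LanguageDomain}
        for q in synth_kb.questions.values():
            counts[q.domain] += 1
        assert counts == synth_kb.quotas

    def test_sensory_items_confined_to_first_year(self, synth_kb):
        for q in synth_kb.questions.values():
            if q.domain is LanguageDomain.sensory_reception:
                assert max(q.applicable_months) <= 12

    def test_same_seed_gives_byte_identical_kbs(self):
        a = dumps_kb(gen_kb(KbGenConfig(seed=42)))
        b = dumps_kb(gen_kb(KbGenConfig(seed=42)))
        assert a == b
        assert a != dumps_kb(gen_kb(KbGenConfig(seed=43)))

    def test_zero_quotas_infeasible(self):
        with pytest.raises(ValueError, match="at least"):
            gen_kb(KbGenConfig(quotas={d: 0 for d in LanguageDomain}))

    def test_overfull_quotas_infeasible(self):
        quotas = {LanguageDomain.sensory_reception: 0,
                  LanguageDomain.language_perception: 0,
                  LanguageDomain.production: 500,
                  LanguageDomain.pragmatics: 0}
        with pytest.raises(ValueError, match="at most"):
            gen_kb(KbGenConfig(quotas=quotas))

    def test_sensory_needs_first_year_coverage(self):
        with pytest.raises(ValueError, match="sensory"):
            gen_kb(KbGenConfig(coverage_range=(13, 36)))

    def test_multi_month_links_are_consecutive(self):
        kb = gen_kb(KbGenConfig(seed=3, multi_month_fraction=0.8))
        spans = [q.applicable_months for q in kb.questions.values()
                 if len(q.applicable_months) > 1]
        assert spans, "expected some multi-month questions"
        for months in spans:
            assert months == list(range(months[0], months[-1] + 1))


class TestGenCohort:
    def test_default_marginals_match_exactly(self):
        cohort = gen_cohort(CohortConfig(seed=11))
        assert len(cohort) == 218
        df = pd.DataFrame({
            "center": [c.center.value for c in cohort.children],
            "gender": [c.gender.value for c in cohort.children],
            "weeks": [c.gestational_weeks for c in cohort.children],
        })
        assert df["center"].value_counts().to_dict() == {
            "nursery_school": 134, "psychopedagogical_center": 84}
        assert df["gender"].value_counts().to_dict() == {
            "male": 119, "female": 99}
        assert (df["weeks"] < 37).sum() == 8

    def test_age_bands_match_cohort_cells(self):
        cohort = gen_cohort(CohortConfig(seed=2))
        bands = pd.Series([
            age_band((cohort.reference_date.year - c.birth_date.year) * 12
                     + cohort.reference_date.month - c.birth_date.month
                     - (cohort.reference_date.day < c.birth_date.day))
            for c in cohort.children]).value_counts().to_dict()
        assert bands == {"13-24": 102, "25-36": 90, "<=12": 26}

    def test_risk_factor_counts(self):
        cohort = gen_cohort(CohortConfig(seed=4))
        children = cohort.children
        assert sum(1 for c in children if c.family_history_ndd) == 2
        bilingual = [c for c in children if c.bilingual]
        assert len(bilingual) == 10
        assert all(c.center.value == "nursery_school" for c in bilingual)
        preterm = [c for c in children
                   if any(b.value == "preterm" for b in c.birth_complications)]
        assert len(preterm) == 8

    def test_empty_cohort(self):
        cohort = gen_cohort(CohortConfig.with_size(
            0, preterm_count=0, birth_complication_count=0,
            family_history_count=0, bilingual_female=0, bilingual_male=0))
        assert len(cohort) == 0

    def test_scaled_cohort_preserves_total(self):
        cohort = gen_cohort(CohortConfig.with_size(500, seed=1))
        assert len(cohort) == 500

    def test_impairment_labels_are_bernoulli(self):
        cfg = CohortConfig.with_size(2000, impairment_prevalence=0.3, seed=9)
        cohort = gen_cohort(cfg)
        rate = np.mean(list(cohort.impaired.values()))
        assert abs(rate - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 2000)


class TestAbilityModel:
    def test_p_yes_strictly_increases_with_age(self):
        m = AbilityModel(slope=0.5)
        ps = [m.p_yes(t, anchor_month=12, theta=0.0, impaired=False)
              for t in np.linspace(8, 20, 25)]
        assert all(b > a for a, b in zip(ps, ps[1:]))

    def test_impairment_shift_lowers_p_yes(self):
        m = AbilityModel()
        assert (m.p_yes(12, 12, 0.0, impaired=True)
                < m.p_yes(12, 12, 0.0, impaired=False))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            AbilityModel(slope=-1)
        with pytest.raises(ValueError):
            AbilityModel(dk_rate=1.5)


class TestSimulateStudy:
    def test_seed_reproducibility(self, synth_kb):
        cohort = gen_cohort(CohortConfig.with_size(60, seed=3))
        a = simulate_study(synth_kb, cohort, seed=5)
        b = simulate_study(synth_kb, cohort, seed=5)
        assert a.sessions.equals(b.sessions)
        assert a.answers.equals(b.answers)
        c = simulate_study(synth_kb, cohort, seed=6)
        assert not a.sessions.equals(c.sessions)

    def test_healthy_cohort_with_dominant_abilities_is_all_typical(
            self, synth_kb):
        cohort = gen_cohort(CohortConfig.with_size(
            120, impairment_prevalence=0.0, seed=8))
        records = simulate_study(
            synth_kb, cohort,
            AbilityModel(slope=20.0, dk_rate=0.0), seed=8)
        final = latest_per_child(records)
        assert set(final.sessions["suggestion"]) == {"typical_development"}

    def test_accept_always_gives_full_accuracy(self, synth_kb):
        from milescreen.stats import accuracy
        cohort = gen_cohort(CohortConfig.with_size(40, seed=2))
        records = simulate_study(synth_kb, cohort, seed=2)
        assert accuracy(records).pct == 100.0

    def test_repeat_suggestions_trigger_follow_up_sessions(self, synth_kb):
        cohort = gen_cohort(CohortConfig.with_size(
            200, impairment_prevalence=0.5, seed=6))
        records = simulate_study(synth_kb, cohort, seed=6)
        per_child = records.sessions.groupby("child_id").size()
        assert per_child.max() == 2
        assert per_child.min() == 1
        assert (per_child == 2).any()

    def test_yes_rate_nondecreasing_in_age_gap(self, synth_kb):
        """Mean pass rate rises with months past the question's anchor."""
        cohort = gen_cohort(CohortConfig.with_size(
            400, impairment_prevalence=0.2, seed=12))
        records = simulate_study(synth_kb, cohort,
                                 AbilityModel(slope=2.0, dk_rate=0.0),
                                 seed=12)
        anchors = {qid: q.anchor_month
                   for qid, q in synth_kb.questions.items()}
        merged = records.answers.merge(
            records.sessions[["child_id", "evaluation_date", "age_months"]],
            on=["child_id", "evaluation_date"])
        merged["gap"] = merged["age_months"] - merged["question_id"].map(anchors)
        rates = (merged.assign(yes=merged["answer"] == "yes")
                 .groupby("gap")["yes"].agg(["mean", "count"]))
        rates = rates[rates["count"] >= 30]
        assert (rates["mean"].diff().dropna() >= -0.05).all()
        assert rates["mean"].iloc[-1] > rates["mean"].iloc[0]
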