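"""Age modifiers, fuzzy union, and record scoring."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rascore as rc
from conftest import make_record


class TestModifiedAge:
    @pytest.mark.parametrize(
        "smoker, oophorectomy, expected",
        [
            (False, rc.Oophorectomy.NONE, 50),
            (False, rc.Oophorectomy.UNILATERAL, 51),
            (True, rc.Oophorectomy.NONE, 52),
            (True, rc.Oophorectomy.UNILATERAL, 53),
        ],
    )
    def test_all_four_modifier_cases(self, smoker, oophorectomy, expected):
        assert rc.modified_age(50, smoker, oophorectomy) == expected

    def test_bilateral_oophorectomy_is_an_error(self):
        with pytest.raises(ValueError):
            rc.modified_age(50, False, rc.Oophorectomy.BILATERAL)


class TestFuzzyUnion:
    def test_identities(self):
        assert rc.fuzzy_union(0.0, 0.5) == 0.5
        assert rc.fuzzy_union(1.0, 0.3) == 1.0
        assert rc.fuzzy_union(0.5, 0.5) == 0.75

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rc.fuzzy_union(1.2, 0.5)
        with pytest.raises(ValueError):
            rc.fuzzy_union(0.5, -0.1)

    @given(
        a=st.floats(min_value=0, max_value=1),
        b=st.floats(min_value=0, max_value=1),
    )
    def test_commutative_bounded_and_dominating(self, a, b):
        u = rc.fuzzy_union(a, b)
        assert u == rc.fuzzy_union(b, a)
        assert 0.0 <= u <= 1.0 + 1e-15
        assert u >= max(a, b) - 1e-15


class TestScore:
    def test_amenorrheic_66_year_old_scores_near_one(self):
        rec = make_record(age=66, periods_last_12m=0,
                          regularity=rc.Regularity.STOPPED)
        scored = rc.score(rec)
        assert scored.ras == pytest.approx(0.9999257340585448, rel=1e-9)
        assert scored.mu_a_value == pytest.approx(0.9088676876859695, rel=1e-9)

    def test_regular_50_year_old_driven_by_age_curve_alone(self):
        # mu_A clamps to 0 at 12 periods under the published coefficients
        scored = rc.score(make_record(age=50, periods_last_12m=12))
        assert scored.mu_a_value == 0.0
        assert scored.ras == pytest.approx(0.44373926085883497, rel=1e-9)

    def test_degenerate_model_scores_zero(self):
        model = rc.RASModel(
            mu_a=rc.MuAParams(0, 0, 0, 0, 0, 0),
            mu_b=rc.MuBParams(0, 0, -1e9),
        )
        assert rc.score(make_record(), model).ras == 0.0

    def test_ineligible_record_raises_with_reason(self):
        with pytest.raises(ValueError, match="pregnant"):
            rc.score(make_record(pregnant=True))

    def test_union_identity_holds_on_scored_record(self):
        s = rc.score(make_record(age=53, periods_last_12m=4,
                                 regularity=rc.Regularity.IRREGULAR_FEW_MONTHS))
        assert s.ras == pytest.approx(
            s.mu_a_value + s.mu_b_value - s.mu_a_value * s.mu_b_value
        )

    def test_no_modifiers_flag_uses_raw_age(self):
        rec = make_record(smoker_current=True,
                          oophorectomy=rc.Oophorectomy.UNILATERAL)
        with_mod = rc.score(rec)
        without = rc.score(rec, rc.RASModel(modifiers_enabled=False))
        assert with_mod.m_age == 53 and without.m_age == 50
        assert with_mod.ras > without.ras

    @given(
        age=st.integers(min_value=38, max_value=66),
        periods=st.integers(min_value=0, max_value=15),
        smoker=st.booleans(),
        oo=st.sampled_from([rc.Oophorectomy.NONE, rc.Oophorectomy.UNILATERAL]),
        regularity=st.sampled_from([rc.Regularity.REGULAR,
                                    rc.Regularity.IRREGULAR_FEW_MONTHS]),
    )
    def test_ras_in_unit_interval_and_dominates_components(
        self, age, periods, smoker, oo, regularity
    ):
        rec = make_record(age=age, periods_last_12m=periods, smoker_current=smoker,
                          oophorectomy=oo, regularity=regularity)
        s = rc.score(rec)
        assert 0.0 <= s.ras <= 1.0
        assert s.ras >= max(s.mu_a_value, s.mu_b_value) - 1e-15

    def test_nondecreasing_in_age_at_fixed_periods(self):
        for periods in (0, 6, 12):
            scores = [
                rc.score(make_record(age=a, periods_last_12m=periods,
                                     regularity=rc.Regularity.IRREGULAR_FEW_MONTHS)).ras
                for a in range(38, 67)
            ]
            assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_smoking_and_oophorectomy_never_decrease_score(self):
        for age in range(38, 67):
            base = rc.score(make_record(age=age)).ras
            smoking = rc.score(make_record(age=age, smoker_current=True)).ras
            one_ovary = rc.score(
                make_record(age=age, oophorectomy=rc.Oophorectomy.UNILATERAL)
            ).ras
            assert smoking >= base and one_ovary >= base


class TestScoreBatch:
    def test_order_preserved_and_all_scored(self):
        recs = [make_record(id=f"r{i}", age=40 + i) for i in range(3)]
        scored = rc.score_batch(recs)
        assert [s.id for s in scored] == ["r0", "r1", "r2"]
        assert all(s.ras is not None for s in scored)

    def test_ineligible_record_carries_reason_without_aborting(self):
        recs = [make_record(id="a"), make_record(id="b", pregnant=True),
                make_record(id="c")]
        scored = rc.score_batch(recs)
        assert scored[1].ras is None
        assert scored[1].excluded_reasons == (rc.EligibilityReason.PREGNANT,)
        assert scored[0].ras is not None and scored[2].ras is not None

    def test_deterministic(self, default_cohort):
        sub = default_cohort[:200]
        assert rc.score_batch(sub) == rc.score_batch(sub)
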