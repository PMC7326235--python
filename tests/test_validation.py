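"""Hormone classification, ROC/AUC, and quartile summaries."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rascore as rc
from conftest import make_record


def brute_force_auc(scores, labels):
    """Independent Mann-Whitney oracle: count positive-negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestClassifyByHormones:
    def test_anchor_class_examples(self):
        assert (
            rc.classify_by_hormones(11, 264) is rc.MenopausalClass.NONMENOPAUSAL
        )
        assert (
            rc.classify_by_hormones(124, 12) is rc.MenopausalClass.POSTMENOPAUSAL
        )
        assert (
            rc.classify_by_hormones(50, 100) is rc.MenopausalClass.PERIMENOPAUSAL
        )

    def test_both_rules_require_both_hormones(self):
        # high FSH alone is not postmenopausal if estradiol is still high
        assert (
            rc.classify_by_hormones(90, 200) is rc.MenopausalClass.PERIMENOPAUSAL
        )
        # low FSH alone is not nonmenopausal if estradiol is low
        assert (
            rc.classify_by_hormones(10, 50) is rc.MenopausalClass.PERIMENOPAUSAL
        )

    def test_missing_or_negative_hormone_rejected(self):
        with pytest.raises(ValueError):
            rc.classify_by_hormones(None, 100)
        with pytest.raises(ValueError):
            rc.classify_by_hormones(-1, 100)

    def test_inconsistent_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            rc.HormoneCutoffs(fsh_nonmeno_max=90, fsh_postmeno_min=80)


class TestROC:
    def test_perfect_separation(self):
        assert rc.roc([1, 2, 3, 4], [False, False, True, True]).auc == 1.0

    def test_perfect_inversion(self):
        assert rc.roc([1, 2, 3, 4], [True, True, False, False]).auc == 0.0

    def test_tie_counted_half(self):
        # four positive-negative pairs; one tie contributes 0.5
        assert rc.roc([1, 2, 2, 3], [False, True, False, True]).auc == 0.875

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            rc.roc([1, 2, 3], [True, True, True])

    def test_curve_anchored_and_monotone(self):
        rng = np.random.default_rng(5)
        result = rc.roc(rng.random(100), rng.random(100) < 0.4)
        fpr, tpr = zip(*result.points)
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert all(b >= a for a, b in zip(fpr, fpr[1:]))
        assert all(b >= a for a, b in zip(tpr, tpr[1:]))

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(6)
        labels = rng.random(200) < 0.5
        scores = rng.random(200) + labels
        result = rc.roc(scores, labels)
        assert result.ci_low <= result.auc <= result.ci_high
        assert result.ci_method == "DeLong"

    @given(st.data())
    def test_matches_brute_force_pair_counting(self, data):
        n = data.draw(st.integers(min_value=2, max_value=50))
        # coarse grid forces ties to be exercised
        scores = data.draw(
            st.lists(st.integers(min_value=0, max_value=8),
                     min_size=n, max_size=n)
        )
        labels = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        if not (any(labels) and not all(labels)):
            labels[0], labels[-1] = True, False
        result = rc.roc([float(s) for s in scores], labels)
        assert result.auc == pytest.approx(brute_force_auc(scores, labels))

    def test_antisymmetry_under_score_negation_and_label_flip(self):
        rng = np.random.default_rng(7)
        scores = rng.integers(0, 10, 80).astype(float)
        labels = rng.random(80) < 0.5
        auc = rc.roc(scores, labels).auc
        flipped = rc.roc(-scores, [not l for l in labels]).auc
        assert auc == pytest.approx(flipped)

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(11)
        scores = rng.random(2000)
        labels = rng.random(2000) < 0.5
        assert abs(rc.roc(scores, labels).auc - 0.5) < 0.06


class TestValidateAgainstHormones:
    def test_both_contrasts_on_default_synthetic_cohort(self, eligible_cohort):
        results = rc.ReproductiveAgeingScore.from_records(
            eligible_cohort, apply_filters=False
        ).fit()
        roc1, roc2 = results.validate(eligible_cohort)
        assert roc1.auc > 0.8
        assert roc2.auc > 0.8

    def test_single_class_cohort_rejected(self):
        recs = [
            make_record(id=f"r{i}", age=40 + i, fsh=10.0, estradiol=300.0)
            for i in range(5)
        ]
        scored = rc.score_batch(recs)
        with pytest.raises(ValueError):
            rc.validate_against_hormones(scored, recs)

    def test_records_without_hormones_skipped(self):
        recs = [
            make_record(id="a", age=40, fsh=10.0, estradiol=300.0),
            make_record(id="b", age=60, periods_last_12m=0,
                        regularity=rc.Regularity.STOPPED, fsh=120.0, estradiol=10.0),
            make_record(id="c", age=50),  # no hormone panel
        ]
        scored = rc.score_batch(recs)
        roc1, _ = rc.validate_against_hormones(scored, recs)
        assert roc1.n_positive + roc1.n_negative == 2


class TestQuartileSummary:
    def test_boundary_binning_after_rounding(self):
        recs = [make_record(id=f"r{i}") for i in range(4)]
        scored = [
            rc.ScoredRecord(id="r0", ras=0.10),
            rc.ScoredRecord(id="r1", ras=0.30),
            rc.ScoredRecord(id="r2", ras=0.60),
            rc.ScoredRecord(id="r3", ras=0.90),
        ]
        table = rc.quartile_summary(scored, recs)
        assert table.loc["n"].tolist() == [1, 1, 1, 1]

    def test_all_low_scores_populate_first_bin_only(self):
        recs = [make_record(id=f"r{i}") for i in range(3)]
        scored = [rc.ScoredRecord(id=f"r{i}", ras=0.05 * i) for i in range(3)]
        table = rc.quartile_summary(scored, recs)
        assert table.loc["n"].tolist() == [3, 0, 0, 0]

    def test_bin_counts_sum_to_scored_records(self, eligible_cohort):
        scored = rc.RASResults.published().score_cohort(eligible_cohort)
        table = rc.quartile_summary(scored, eligible_cohort)
        assert table.loc["n"].sum() == len(eligible_cohort)

    def test_percentages_sum_to_100(self, eligible_cohort):
        scored = rc.RASResults.published().score_cohort(eligible_cohort)
        table = rc.quartile_summary(scored, eligible_cohort)
        pct = table.loc[["pct_regular", "pct_irregular", "pct_amenorrhea"]]
        populated = table.loc["n"] > 0
        assert np.allclose(pct.loc[:, populated].sum(), 100.0)

    def test_fsh_median_increases_across_bins(self, eligible_cohort):
        scored = rc.RASResults.published().score_cohort(eligible_cohort)
        table = rc.quartile_summary(scored, eligible_cohort)
        medians = [
            float(s.split(" ")[0]) for s in table.loc["fsh_median_iqr"] if s
        ]
        assert all(b > a for a, b in zip(medians, medians[1:]))
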