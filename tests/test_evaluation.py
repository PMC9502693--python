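import numpy as np
import pytest

from cardiovoice import (
    ClassifierConfig,
    ConfusionTable,
    ScreenFeatures,
    cohort_summary,
    loso_evaluate,
    mcr_per_class,
    mtr_per_class,
    overall_mcr,
)
from cardiovoice.beat_sync import BeatFeatureMatrix

UNIVERSITY = ConfusionTable(np.array([[569, 65, 45], [51, 454, 77], [23, 48, 705]]))
PILOT = ConfusionTable(np.array([[113, 12, 15], [6, 96, 18], [5, 17, 138]]))


class TestMetrics:
    def test_university_cohort_table(self):
        np.testing.assert_allclose(
            np.round(mcr_per_class(UNIVERSITY), 2), [16.20, 21.99, 9.15]
        )
        np.testing.assert_allclose(
            np.round(mtr_per_class(UNIVERSITY), 2), [11.51, 19.93, 14.75]
        )
        assert round(overall_mcr(UNIVERSITY), 2) == 15.17

    def test_pilot_cohort_table(self):
        np.testing.assert_allclose(np.round(mcr_per_class(PILOT), 2), [19.29, 20.00, 13.75])
        np.testing.assert_allclose(np.round(mtr_per_class(PILOT), 2), [8.87, 23.20, 19.30])
        assert round(overall_mcr(PILOT), 2) == 17.38

    def test_diagonal_table_is_all_zero(self):
        t = ConfusionTable(np.diag([7, 6, 8]))
        assert np.all(mcr_per_class(t) == 0)
        assert np.all(mtr_per_class(t) == 0)
        assert overall_mcr(t) == 0

    def test_empty_row_flagged_as_nan(self):
        t = ConfusionTable(np.array([[0, 0, 0], [1, 5, 0], [0, 2, 8]]))
        assert np.isnan(mcr_per_class(t)[0])
        assert not np.any(np.isnan(mtr_per_class(t)))

    def test_row_and_column_decompositions_agree(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = ConfusionTable(rng.integers(1, 60, size=(3, 3)))
            c = t.counts
            off = t.total - np.trace(c)
            lhs = np.nansum(mcr_per_class(t) * c.sum(axis=1))
            rhs = np.nansum(mtr_per_class(t) * c.sum(axis=0))
            assert lhs == pytest.approx(100.0 * off)
            assert rhs == pytest.approx(100.0 * off)


class TestCohortSummary:
    def test_two_participant_hand_arithmetic(self):
        # 10% and 20% overall MCR -> mean 15, SE 5
        a = ConfusionTable(np.diag([3, 3, 3]) + np.array([[0, 1, 0], [0, 0, 0], [0, 0, 0]]))
        assert overall_mcr(a) == 10.0
        b = ConfusionTable(np.diag([3, 2, 3]) + np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]]))
        assert overall_mcr(b) == 20.0
        summary = cohort_summary([a, b])
        assert summary.mean_mcr == pytest.approx(15.0)
        assert summary.se_mcr == pytest.approx(5.0)

    def test_identical_tables_pool_to_mean(self):
        t = ConfusionTable(np.array([[5, 1, 1], [0, 5, 1], [1, 0, 7]]))
        s = cohort_summary([t] * 4)
        assert s.pooled_mcr == pytest.approx(s.mean_mcr)

    def test_pooled_equals_metric_of_summed_tables(self):
        rng = np.random.default_rng(1)
        tables = [ConfusionTable(rng.integers(0, 40, (3, 3)) + np.eye(3, dtype=int)) for _ in range(6)]
        s = cohort_summary(tables)
        summed = np.sum([t.counts for t in tables], axis=0)
        assert s.pooled_mcr == pytest.approx(overall_mcr(ConfusionTable(summed)))

    def test_single_participant_se_undefined(self):
        s = cohort_summary([UNIVERSITY])
        assert np.isnan(s.se_mcr)
        assert s.mean_mcr == pytest.approx(overall_mcr(UNIVERSITY))


def _screens(rng, separation=8.0, beats=12):
    """A synthetic 21-screen participant with direct feature-level effects."""
    screens = []
    j = 0
    for level, count in zip((1, 2, 3), (7, 6, 8)):
        for _ in range(count):
            j += 1
            x = rng.normal(level * separation, 1.0, size=(beats, 10))
            screens.append(
                ScreenFeatures(
                    j,
                    level,
                    BeatFeatureMatrix("c", x, np.arange(beats, dtype=float), level=level),
                )
            )
    return screens


class TestLoso:
    def test_sequence_confusion_totals_21(self):
        rng = np.random.default_rng(2)
        res = loso_evaluate(_screens(rng), ClassifierConfig(seed=0), "p1")
        assert res.sequence_confusion.total == 21
        np.testing.assert_array_equal(res.sequence_confusion.counts.sum(axis=1), [7, 6, 8])
        assert len(res.screen_predictions) == 21
        assert res.beat_confusion.total == 21 * 12

    def test_separable_screens_classified_perfectly(self):
        rng = np.random.default_rng(3)
        res = loso_evaluate(_screens(rng, separation=10.0), ClassifierConfig(seed=0), "p1")
        assert overall_mcr(res.sequence_confusion) == 0.0

    def test_strict_design_enforced(self):
        rng = np.random.default_rng(4)
        screens = _screens(rng)[:-1]  # 20 screens
        with pytest.raises(ValueError, match="7/6/8"):
            loso_evaluate(screens, ClassifierConfig(seed=0))
        # lenient flag accepts the 7/6/7 layout
        res = loso_evaluate(screens, ClassifierConfig(seed=0), allow_lenient=True)
        assert res.sequence_confusion.total == 20

    def test_lenient_still_needs_two_screens_per_level(self):
        rng = np.random.default_rng(5)
        screens = [s for s in _screens(rng) if not (s.level == 2 and s.screen_index > 8)]
        with pytest.raises(ValueError, match=">= 2 screens"):
            loso_evaluate(screens, ClassifierConfig(seed=0), allow_lenient=True)

    def test_loso_reproducible(self):
        rng_a = np.random.default_rng(6)
        rng_b = np.random.default_rng(6)
        cfg = ClassifierConfig(kind="tree_ensemble", n_trees=20, seed=9)
        res_a = loso_evaluate(_screens(rng_a, separation=2.0), cfg, "p")
        res_b = loso_evaluate(_screens(rng_b, separation=2.0), cfg, "p")
        assert res_a.screen_predictions == res_b.screen_predictions
        np.testing.assert_array_equal(
            res_a.beat_confusion.counts, res_b.beat_confusion.counts
        )
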