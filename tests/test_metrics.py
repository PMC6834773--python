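"""Metric battery: worked examples, brute-force oracles, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpra_leakage.metrics import (
    MetricError,
    au_prc,
    auc_roc,
    binarize,
    direction_metrics,
    evaluate,
    regression_metrics,
)
from mpra_leakage.models import PredictionSet


def pairwise_auc(scores, labels):
    """O(n^2) oracle: fraction of positive/negative pairs correctly ordered,
    ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def stepwalk_ap(scores, labels):
    """O(n^2) oracle: walk the ranked list block by block of tied scores and
    accumulate precision at each recall step."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = labels.sum()
    distinct = sorted(set(scores), reverse=True)
    ap = 0.0
    seen = 0
    tp = 0
    for threshold in distinct:
        block = scores == threshold
        seen += block.sum()
        new_tp = labels[block].sum()
        tp += new_tp
        if new_tp:
            ap += new_tp * tp / seen
    return ap / n_pos


class TestAucRoc:
    def test_perfect_separation(self):
        assert auc_roc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_three_of_four_pairs(self):
        assert auc_roc([0.9, 0.3, 0.8, 0.2], [1, 1, 0, 0]) == 0.75

    def test_all_ties_give_half(self):
        assert auc_roc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_single_class_named_in_error(self):
        with pytest.raises(MetricError, match="positive"):
            auc_roc([0.1, 0.2], [0, 0])
        with pytest.raises(MetricError, match="negative"):
            auc_roc([0.1, 0.2], [1, 1])

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            scores = rng.choice([0.1, 0.25, 0.5, 0.8], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            assert auc_roc(scores, labels) == pytest.approx(
                pairwise_auc(scores, labels), abs=1e-12
            )

    def test_negation_antisymmetry_without_ties(self):
        rng = np.random.default_rng(1)
        scores = rng.permutation(np.linspace(0, 1, 30))
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        assert auc_roc(-scores, labels) == pytest.approx(
            1.0 - auc_roc(scores, labels), abs=1e-12
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        scores = rng.random(40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        perm = rng.permutation(40)
        assert auc_roc(scores[perm], labels[perm]) == pytest.approx(
            auc_roc(scores, labels), abs=1e-12
        )

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        for _ in range(20):
            scores = rng.choice([0.2, 0.4, 0.9], size=30)
            labels = rng.integers(0, 2, size=30)
            labels[:2] = [0, 1]
            assert auc_roc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-9
            )


class TestAuPrc:
    def test_perfect_ranking(self):
        assert au_prc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_handwalked_example(self):
        # ranked: 0.9(+), 0.8(-), 0.3(+), 0.2(-); precision steps 1/1 and 2/3
        assert au_prc([0.9, 0.3, 0.8, 0.2], [1, 1, 0, 0]) == pytest.approx(
            (1 + 2 / 3) / 2
        )

    def test_zero_positives_rejected(self):
        with pytest.raises(MetricError):
            au_prc([0.5, 0.6], [0, 0])

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(4)
        n = 10_000
        prevalence = 0.3
        labels = (rng.random(n) < prevalence).astype(int)
        scores = rng.random(n)
        assert au_prc(scores, labels) == pytest.approx(labels.mean(), abs=0.03)

    def test_matches_stepwalk_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            scores = rng.choice([0.1, 0.25, 0.5, 0.8], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() == 0:
                continue
            assert au_prc(scores, labels) == pytest.approx(
                stepwalk_ap(scores, labels), abs=1e-9
            )

    def test_agrees_with_sklearn_average_precision(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(6)
        for _ in range(20):
            scores = rng.choice([0.2, 0.4, 0.9], size=30)
            labels = rng.integers(0, 2, size=30)
            labels[:2] = [0, 1]
            assert au_prc(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-9
            )


@st.composite
def scored_instances(draw):
    n = draw(st.integers(min_value=2, max_value=40))
    levels = draw(st.lists(st.floats(0, 1, allow_nan=False), min_size=2,
                           max_size=6, unique=True))
    scores = [draw(st.sampled_from(levels)) for _ in range(n)]
    labels = [draw(st.integers(0, 1)) for _ in range(n)]
    # guarantee both classes
    labels[0], labels[1] = 0, 1
    return np.array(scores), np.array(labels)


class TestMetricProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(scored_instances())
    def test_auc_matches_pairwise_oracle_property(self, instance):
        scores, labels = instance
        assert auc_roc(scores, labels) == pytest.approx(
            pairwise_auc(scores, labels), abs=1e-12
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(scored_instances())
    def test_ap_matches_stepwalk_oracle_property(self, instance):
        scores, labels = instance
        assert au_prc(scores, labels) == pytest.approx(
            stepwalk_ap(scores, labels), abs=1e-9
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(scored_instances(), st.randoms(use_true_random=False))
    def test_both_metrics_permutation_invariant(self, instance, rnd):
        scores, labels = instance
        perm = np.array(rnd.sample(range(len(scores)), len(scores)))
        assert auc_roc(scores[perm], labels[perm]) == pytest.approx(
            auc_roc(scores, labels), abs=1e-12
        )
        assert au_prc(scores[perm], labels[perm]) == pytest.approx(
            au_prc(scores, labels), abs=1e-12
        )


class TestRegressionMetrics:
    def test_identity_prediction(self):
        m = regression_metrics([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert m["MAE_c"] == 0 and m["MSE_c"] == 0 and m["ME_c"] == 0
        assert m["PCC_c"] == pytest.approx(1.0)

    def test_constant_shift(self):
        m = regression_metrics([0.2, 0.6, 1.0], [0.1, 0.5, 0.9])
        assert m["ME_c"] == pytest.approx(0.1)
        assert m["MAE_c"] == pytest.approx(0.1)
        assert m["PCC_c"] == pytest.approx(1.0)

    def test_exact_anti_order(self):
        m = regression_metrics([0.1, 0.2, 0.3], [0.3, 0.2, 0.1])
        assert m["PCC_c"] == pytest.approx(-1.0)
        assert m["SCC_c"] == pytest.approx(-1.0)

    def test_constant_vector_reports_missing(self):
        m = regression_metrics([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert np.isnan(m["PCC_c"]) and np.isnan(m["SCC_c"])
        assert m["MAE_c"] >= 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(MetricError):
            regression_metrics([0.1], [0.1, 0.2])


class TestDirectionMetrics:
    def test_perfect_hard_labels(self):
        m = direction_metrics([-1, 0, 1], [-1, 0, 1])
        assert m["PCC_d"] == pytest.approx(1.0)

    def test_all_zero_truth_missing(self):
        m = direction_metrics([0.5, -0.5, 0.1], [0, 0, 0])
        assert np.isnan(m["PCC_d"]) and np.isnan(m["SCC_d"])

    def test_negated_truth(self):
        m = direction_metrics([1.0, 0.0, -1.0], [-1, 0, 1])
        assert m["PCC_d"] == pytest.approx(-1.0)


class TestBinarize:
    def test_combines_up_and_down_classes(self):
        assert list(binarize([-1, 0, 1])) == [1, 0, 1]

    def test_all_zeros(self):
        assert list(binarize([0, 0])) == [0, 0]

    def test_rejects_other_values(self):
        with pytest.raises(MetricError):
            binarize([2, 0])


class TestEvaluate:
    def test_pooled_equals_concatenated_computation(self, small_dataset):
        from mpra_leakage.layouts import SplitConfig, build_layout

        rng = np.random.default_rng(0)
        layout = build_layout(small_dataset, SplitConfig())
        scores = rng.random(len(small_dataset.snvs))
        preds = PredictionSet(
            snv_index=small_dataset.snv_ids, predicted_confidence=scores
        )
        reports = evaluate(preds, small_dataset, layout)
        pooled = next(r for r in reports if r.scope == "pooled")
        mask = layout.validation_mask
        truth = small_dataset.confidences()[mask]
        dirs = small_dataset.directions()[mask]
        expected_auc = auc_roc(scores[mask], np.abs(dirs))
        assert pooled.metrics["AUCROC"] == pytest.approx(expected_auc, abs=1e-12)
        assert pooled.metrics["MAE_c"] == pytest.approx(
            np.mean(np.abs(scores[mask] - truth))
        )
        assert pooled.n == int(mask.sum())

    def test_single_class_reporter_flagged_not_fabricated(self):
        from mpra_leakage.core import Reporter, ReporterKind, SNVRecord
        from mpra_leakage.layouts import SplitLayout

        rep = Reporter("solo", "ct", ReporterKind.PROMOTER, "chrS", 0, 2, "AC")

        class _DS:
            reporters = [rep]
            snvs = [
                SNVRecord("solo", 0, "A", "C", 0.0, 0),
                SNVRecord("solo", 0, "A", "G", 0.01, 0),
                SNVRecord("solo", 0, "A", "T", 0.02, 0),
                SNVRecord("solo", 1, "C", "A", 0.03, 0),
                SNVRecord("solo", 1, "C", "G", 0.04, 0),
                SNVRecord("solo", 1, "C", "T", 0.05, 0),
            ]

        ds = _DS()
        layout = SplitLayout(
            snv_ids=[s.snv_id for s in ds.snvs],
            labels=np.ones(6, dtype=np.int8),
            position_labels={"solo": np.ones(2, dtype=np.int8)},
        )
        preds = PredictionSet(
            snv_index=[s.snv_id for s in ds.snvs],
            predicted_confidence=np.linspace(0, 0.2, 6),
        )
        (solo, pooled) = evaluate(preds, ds, layout)
        assert np.isnan(solo.metrics["AUCROC"])
        assert "single_class" in solo.flags
        assert "low_support" in solo.flags

    def test_missing_predictions_rejected(self, small_dataset):
        from mpra_leakage.layouts import SplitConfig, build_layout

        layout = build_layout(small_dataset, SplitConfig())
        preds = PredictionSet(
            snv_index=small_dataset.snv_ids[:10],
            predicted_confidence=np.zeros(10),
        )
        with pytest.raises(MetricError):
            evaluate(preds, small_dataset, layout)
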