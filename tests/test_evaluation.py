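"""Recall, precision, Filtering Term, batch aggregation and sweeps."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litriage.classifier import COARSE_GRID, train_comprehensive
from litriage.evaluation import (
    ConfusionCounts,
    EvaluationReport,
    compare_weighting_schemes,
    confusion,
    estimate_recall_subsampled,
    evaluate_batches,
    evaluate_documents,
    filtering_term,
    pn_ratio_sweep,
    precision,
    recall,
    report_table,
)
from litriage.synthetic import SyntheticConfig, generate_corpus

SMALL_CONFIG = SyntheticConfig(
    n_pos=24,
    n_neg=72,
    vocab_size=300,
    n_discriminative_shared=6,
    p_feat_in_pos=0.9,
    p_feat_in_neg=0.02,
    doc_length=60.0,
    corpus_tag="evalsim",
    seed=11,
)
SMALL_SIZES = (5, 10, 25)

counts_strategy = st.tuples(
    st.integers(0, 100), st.integers(0, 100), st.integers(0, 100), st.integers(0, 100)
).filter(lambda t: sum(t) > 0)


class TestConfusion:
    def test_all_correct(self):
        truth = {f"d{i}": i < 4 for i in range(10)}
        assert confusion(truth, truth) == ConfusionCounts(4, 0, 6, 0)

    def test_everything_predicted_positive(self):
        truth = {f"d{i}": i < 4 for i in range(10)}
        predicted = {d: True for d in truth}
        assert confusion(predicted, truth) == ConfusionCounts(4, 6, 0, 0)

    def test_empty_sets_tally_zero(self):
        assert confusion({}, {}) == ConfusionCounts(0, 0, 0, 0)

    def test_prediction_outside_truth_rejected(self):
        with pytest.raises(ValueError, match="missing from truth"):
            confusion({"ghost": True}, {"d": True})


class TestPointMetrics:
    def test_low_occurrence_worked_example(self):
        # 1 TP + 1 FP among 100 papers: perfect recall, precision collapses to
        # 0.5, but the curator reads only 2% of the stream
        c = ConfusionCounts(tp=1, fp=1, tn=98, fn=0)
        assert recall(c) == 1.0
        assert precision(c) == 0.5
        assert filtering_term(c) == 2.0

    def test_balanced_counterpart_restores_precision(self):
        c = ConfusionCounts(tp=50, fp=1, tn=49, fn=0)
        assert round(precision(c), 2) == 0.98

    def test_undefined_metrics_are_nan_with_warning(self):
        with pytest.warns(UserWarning, match="recall undefined"):
            assert math.isnan(recall(ConfusionCounts(0, 3, 7, 0)))
        with pytest.warns(UserWarning, match="precision undefined"):
            assert math.isnan(precision(ConfusionCounts(0, 0, 7, 3)))

    def test_filtering_term_extremes(self):
        assert filtering_term(ConfusionCounts(4, 6, 0, 0)) == 100.0
        assert filtering_term(ConfusionCounts(0, 0, 6, 4)) == 0.0
        with pytest.raises(ValueError):
            filtering_term(ConfusionCounts(0, 0, 0, 0))

    @given(counts_strategy)
    @settings(derandomize=True, deadline=None)
    def test_filtering_term_bounded_and_composition_invariant(self, table):
        c = ConfusionCounts(*table)
        ft = filtering_term(c)
        assert 0.0 <= ft <= 100.0
        # FT depends only on predicted positives and the total: swapping FN
        # and TN (same predictions over a different truth) leaves it unchanged
        assert ft == filtering_term(ConfusionCounts(c.tp, c.fp, c.fn, c.tn))


@pytest.fixture(scope="module")
def small_model_and_corpus():
    corpus = generate_corpus(SMALL_CONFIG)
    model = train_comprehensive(
        list(corpus), SMALL_CONFIG.datatype, sizes=SMALL_SIZES, grid=COARSE_GRID
    )
    return model, corpus


class TestBatches:
    def test_identical_batches_have_zero_sd(self, small_model_and_corpus):
        model, corpus = small_model_and_corpus
        batch = list(corpus)[:30]
        report = evaluate_batches(model, [batch] * 5)
        assert report.sd_recall == 0.0
        assert report.sd_ft == 0.0
        assert len(report.reports) == 5

    def test_single_batch_sd_undefined(self, small_model_and_corpus):
        model, corpus = small_model_and_corpus
        report = evaluate_batches(model, [list(corpus)[:30]])
        assert math.isnan(report.sd_recall)

    def test_mean_is_unweighted_across_batches(self, small_model_and_corpus):
        model, corpus = small_model_and_corpus
        docs = list(corpus)
        batches = [docs[:20], docs[20:50], docs[50:]]
        report = evaluate_batches(model, batches)
        assert report.mean_ft == pytest.approx(
            np.mean([r.ft_percent for r in report.reports])
        )

    def test_no_batches_rejected(self, small_model_and_corpus):
        model, _ = small_model_and_corpus
        with pytest.raises(ValueError):
            evaluate_batches(model, [])


class TestSubsampledRecall:
    def test_clean_predictions_estimate_full_recall(self):
        truth = {f"d{i}": i < 5 for i in range(30)}
        assert estimate_recall_subsampled(truth, truth, n_sample=10, seed=0) == 1.0

    def test_hidden_false_negatives_lower_the_estimate(self):
        truth = {f"d{i}": i < 10 for i in range(40)}
        predicted = {d: (truth[d] and int(d[1:]) < 5) for d in truth}  # half missed
        est = estimate_recall_subsampled(predicted, truth, n_sample=35, seed=1)
        assert est < 1.0


class TestSweeps:
    def test_pn_sweep_reports_each_feasible_ratio(self, small_model_and_corpus):
        _, corpus = small_model_and_corpus
        results, best = pn_ratio_sweep(
            corpus,
            SMALL_CONFIG.datatype,
            ratios=(1.0, 2.0),
            n_replicates=2,
            sizes=SMALL_SIZES,
            grid=COARSE_GRID,
            seed=3,
        )
        assert [r.ratio for r in results] == [1.0, 2.0]
        assert all(len(r.reports) == 2 for r in results)
        assert best in results

    def test_infeasible_ratio_skipped_with_warning(self, small_model_and_corpus):
        _, corpus = small_model_and_corpus
        with pytest.warns(UserWarning, match="skipped"):
            results, _ = pn_ratio_sweep(
                corpus,
                SMALL_CONFIG.datatype,
                ratios=(1.0, 50.0),
                n_replicates=2,
                sizes=SMALL_SIZES,
                grid=COARSE_GRID,
                seed=3,
            )
        assert [r.ratio for r in results] == [1.0]

    def test_weighting_comparison_yields_one_row_per_pair(
        self, small_model_and_corpus
    ):
        _, corpus = small_model_and_corpus
        docs = list(corpus)
        table = compare_weighting_schemes(
            docs,
            SMALL_CONFIG.datatype,
            schemes=("boolean_chi2", "tfidf_chi2", "tfidf_all"),
            eval_sets={"a": docs[:30], "b": docs[30:60]},
            sizes=SMALL_SIZES,
            grid=COARSE_GRID,
        )
        assert len(table) == 6
        assert set(table.columns) >= {"scheme", "eval_set", "recall", "precision"}


def test_report_table_flattens_reports():
    reports = {
        "x": EvaluationReport.from_confusion(ConfusionCounts(4, 1, 10, 1)),
        "y": EvaluationReport.from_confusion(ConfusionCounts(2, 2, 12, 0)),
    }
    table = report_table(reports)
    assert list(table.name) == ["x", "y"]
    assert table.loc[0, "recall"] == pytest.approx(0.8)


def test_evaluate_documents_scores_against_labels(small_model_and_corpus):
    model, corpus = small_model_and_corpus
    report = evaluate_documents(model, list(corpus))
    total = report.confusion.total
    assert total == len(corpus)
    assert 0.0 <= report.ft_percent <= 100.0
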