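"""Replicated synthetic experiments mirroring the production study designs.

Each function runs one seeded, self-contained experiment on a generated
corpus: ensemble union/confidence behaviour, cross-corpus training-set
pooling, the positive:negative ratio sweep, and the weighting-scheme
comparison.  They are shared by the test suite and the acceptance script so
both measure exactly the same procedures.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classifier import (
    COARSE_GRID,
    ComprehensiveModel,
    predict_many,
    train_comprehensive,
)
from .corpus import build_negative_set, odd_even_split, pool_corpora
from .evaluation import (
    EvaluationReport,
    compare_weighting_schemes,
    evaluate_documents,
    evaluate_predictions,
    pn_ratio_sweep,
)
from .features import full_ranking, score_features
from .synthetic import (
    cross_corpus_configs,
    generate_corpus,
    generate_cross_corpus_pair,
    low_occurrence_config,
    separable_config,
    specific_feature_names,
    shared_feature_names,
    weighting_configs,
)


@dataclass
class EnsembleRun:
    """One seeded train/test run of the comprehensive ensemble."""

    model: ComprehensiveModel
    test_docs: list
    report: EvaluationReport
    component_reports: list
    cutoff_reports: dict  # cutoff -> (predicted-positive id set, report)


def run_ensemble(seed: int) -> EnsembleRun:
    """Train on the odd chronological half of a separable corpus, test on the
    even half; evaluate the union ensemble, each single component, and every
    confidence cutoff."""
    config = separable_config(seed)
    corpus = generate_corpus(config)
    positives = corpus.positives(config.datatype)
    negatives = build_negative_set(corpus, config.datatype)
    train, test = odd_even_split(positives, negatives)
    model = train_comprehensive(
        train, config.datatype, grid=COARSE_GRID, seed=seed
    )
    report = evaluate_documents(model, test)
    truth = {d.doc_id: config.datatype in d.labels for d in test}
    component_reports = []
    for comp in model.components:
        votes = comp.predict_docs(test)
        predicted = {d.doc_id: bool(v) for d, v in zip(test, votes)}
        component_reports.append(evaluate_predictions(predicted, truth))
    cutoff_reports = {}
    for cutoff in (None, "low", "medium", "high"):
        preds = predict_many(model, test, cutoff=cutoff)
        positive_ids = frozenset(p.doc_id for p in preds if p.is_positive)
        cutoff_reports[cutoff] = (positive_ids, evaluate_predictions(preds, truth))
    return EnsembleRun(
        model=model,
        test_docs=test,
        report=report,
        component_reports=component_reports,
        cutoff_reports=cutoff_reports,
    )


@dataclass
class CrossCorpusRun:
    """Pooled versus single-corpus training, evaluated on the second corpus."""

    recall_single: float
    recall_pooled: float
    specific_rank_single: dict
    specific_rank_pooled: dict
    shared_rank_pooled: dict


def run_cross_corpus(seed: int) -> CrossCorpusRun:
    """Train on corpus A alone versus the pooled A+B training set and compare
    recall on B's held-out test half; also compare the chi-square ranks of
    A-specific and shared planted features under both training sets."""
    config_a, config_b = cross_corpus_configs(seed)
    corpus_a, corpus_b = generate_cross_corpus_pair(config_a, config_b)
    datatype = config_a.datatype
    train_a, _ = odd_even_split(
        corpus_a.positives(datatype), build_negative_set(corpus_a, datatype)
    )
    train_b, test_b = odd_even_split(
        corpus_b.positives(datatype), build_negative_set(corpus_b, datatype)
    )
    model_single = train_comprehensive(
        train_a, datatype, grid=COARSE_GRID, seed=seed
    )
    pooled = pool_corpora(train_a, train_b)
    model_pooled = train_comprehensive(
        pooled, datatype, grid=COARSE_GRID, seed=seed
    )
    recall_single = evaluate_documents(model_single, test_b, datatype).recall
    recall_pooled = evaluate_documents(model_pooled, test_b, datatype).recall

    def ranking(train_docs):
        pos = [d for d in train_docs if datatype in d.labels]
        neg = [d for d in train_docs if datatype not in d.labels]
        ranks = full_ranking(score_features(pos, neg, compute_mi=False))
        worst = len(ranks) + 1
        return ranks, worst

    ranks_single, worst_single = ranking(train_a)
    ranks_pooled, worst_pooled = ranking(pooled)
    a_specific = specific_feature_names(config_a)
    shared = shared_feature_names(config_a)
    return CrossCorpusRun(
        recall_single=recall_single,
        recall_pooled=recall_pooled,
        specific_rank_single={
            f: ranks_single.get(f, worst_single) for f in a_specific
        },
        specific_rank_pooled={
            f: ranks_pooled.get(f, worst_pooled) for f in a_specific
        },
        shared_rank_pooled={f: ranks_pooled.get(f, worst_pooled) for f in shared},
    )


def run_pn_sweep(seed: int, n_replicates: int = 10):
    """Sweep the training PN ratio on the low-occurrence study corpus."""
    config = low_occurrence_config(seed)
    corpus = generate_corpus(config)
    return pn_ratio_sweep(
        corpus,
        config.datatype,
        n_replicates=n_replicates,
        grid=COARSE_GRID,
        seed=seed,
    )


def run_weighting_comparison(seed: int) -> pd.DataFrame:
    """Boolean vs TF-IDF (with and without feature selection) on evaluation
    sets with 1:1 and 2:1 negative:positive composition."""
    train_cfg, eval_cfg = weighting_configs(seed)
    train_corpus = generate_corpus(train_cfg)
    eval_corpus = generate_corpus(eval_cfg)
    datatype = train_cfg.datatype
    eval_pos = eval_corpus.positives(datatype)
    eval_neg = build_negative_set(eval_corpus, datatype)
    eval_sets = {
        "test_1to1": eval_pos + eval_neg[: len(eval_pos)],
        "test_2to1": eval_pos + eval_neg[: 2 * len(eval_pos)],
    }
    return compare_weighting_schemes(
        list(train_corpus),
        datatype,
        eval_sets=eval_sets,
        grid=COARSE_GRID,
        seed=seed,
    )
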