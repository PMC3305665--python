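"""Evaluation: recall, precision, the Filtering Term, batches, and sweeps.

Triage quality is judged by recall = TP/(TP+FN) and precision = TP/(TP+FP),
but for data types of low occurrence precision is dominated by the class
imbalance of the evaluation set.  The Filtering Term,

    FT = 100 * (TP + FP) / (TP + FP + TN + FN)   [percent],

is the fraction of the stream a curator must still read after filtering and is
the operative workload measure: lower is better at fixed recall.  This module
also aggregates weekly-style validation batches (mean +/- sample SD), sweeps
the positive:negative training ratio for low-occurrence data types, and runs
the Boolean-vs-TF-IDF weighting comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import (
    COARSE_GRID,
    ComprehensiveModel,
    predict_many,
    train_comprehensive,
)
from .corpus import Corpus, _chron_key, build_negative_set
from .features import DEFAULT_SIZES

logger = logging.getLogger(__name__)

DEFAULT_PN_RATIOS = (1.0, 1.5, 2.0, 3.0, 6.0)
DEFAULT_FT_CEILING = 25.0


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(predicted, truth: Mapping[str, bool]) -> ConfusionCounts:
    """Tally a 2x2 confusion table for one data type.

    ``predicted`` is either a mapping doc_id -> bool or an iterable of
    predictions with ``doc_id``/``is_positive`` attributes.  Every predicted
    document must appear in ``truth``.
    """
    if isinstance(predicted, Mapping):
        items = list(predicted.items())
    else:
        items = [(p.doc_id, p.is_positive) for p in predicted]
    tp = fp = tn = fn = 0
    for doc_id, flag in items:
        if doc_id not in truth:
            raise ValueError(f"predicted document {doc_id!r} missing from truth")
        actual = truth[doc_id]
        if flag and actual:
            tp += 1
        elif flag and not actual:
            fp += 1
        elif not flag and actual:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def recall(c: ConfusionCounts) -> float:
    """TP/(TP+FN); NaN with a warning when no true positives exist."""
    if c.tp + c.fn == 0:
        warnings.warn("recall undefined: no positive documents", stacklevel=2)
        return float("nan")
    return c.tp / (c.tp + c.fn)


def precision(c: ConfusionCounts) -> float:
    """TP/(TP+FP); NaN with a warning when nothing was predicted positive."""
    if c.tp + c.fp == 0:
        warnings.warn("precision undefined: no predicted positives", stacklevel=2)
        return float("nan")
    return c.tp / (c.tp + c.fp)


def filtering_term(c: ConfusionCounts) -> float:
    """100 * (TP+FP) / total — percent of the stream left to read."""
    if c.total == 0:
        raise ValueError("filtering term undefined on an empty evaluation set")
    return 100.0 * (c.tp + c.fp) / c.total


@dataclass(frozen=True)
class EvaluationReport:
    confusion: ConfusionCounts
    recall: float
    precision: float
    ft_percent: float

    @classmethod
    def from_confusion(cls, c: ConfusionCounts) -> "EvaluationReport":
        return cls(
            confusion=c,
            recall=recall(c),
            precision=precision(c),
            ft_percent=filtering_term(c),
        )


def evaluate_predictions(predicted, truth: Mapping[str, bool]) -> EvaluationReport:
    return EvaluationReport.from_confusion(confusion(predicted, truth))


def evaluate_documents(
    model: ComprehensiveModel,
    docs: Sequence,
    datatype: str | None = None,
    cutoff: str | None = None,
) -> EvaluationReport:
    """Predict a document set with the ensemble and score against its labels."""
    datatype = datatype or model.datatype
    preds = predict_many(model, docs, cutoff=cutoff)
    truth = {d.doc_id: datatype in d.labels for d in docs}
    return evaluate_predictions(preds, truth)


def _nan_mean_sd(values: Sequence[float]) -> tuple[float, float, int]:
    arr = np.asarray(values, dtype=float)
    defined = arr[~np.isnan(arr)]
    n_undefined = int(np.isnan(arr).sum())
    if n_undefined:
        logger.warning("%d undefined metric values excluded from aggregation", n_undefined)
    mean = float(defined.mean()) if defined.size else float("nan")
    sd = float(defined.std(ddof=1)) if defined.size >= 2 else float("nan")
    return mean, sd, n_undefined


@dataclass(frozen=True)
class BatchReport:
    """Per-batch reports with mean and sample SD across batches."""

    reports: tuple
    mean_recall: float
    sd_recall: float
    mean_precision: float
    sd_precision: float
    mean_ft: float
    sd_ft: float
    n_undefined: int


def evaluate_batches(
    model: ComprehensiveModel,
    batches: Sequence[Sequence],
    datatype: str | None = None,
    cutoff: str | None = None,
) -> BatchReport:
    """Evaluate periodic validation batches; batch sizes may vary.

    Means are unweighted across batches (each batch counts once regardless of
    size); SD is the sample (n-1) standard deviation, undefined for a single
    batch.  Undefined per-batch metrics are excluded with a logged count.
    """
    if not batches:
        raise ValueError("at least one batch is required")
    reports = tuple(
        evaluate_documents(model, batch, datatype=datatype, cutoff=cutoff)
        for batch in batches
    )
    mean_r, sd_r, und_r = _nan_mean_sd([r.recall for r in reports])
    mean_p, sd_p, und_p = _nan_mean_sd([r.precision for r in reports])
    mean_f, sd_f, und_f = _nan_mean_sd([r.ft_percent for r in reports])
    return BatchReport(
        reports=reports,
        mean_recall=mean_r,
        sd_recall=sd_r,
        mean_precision=mean_p,
        sd_precision=sd_p,
        mean_ft=mean_f,
        sd_ft=sd_f,
        n_undefined=und_r + und_p + und_f,
    )


@dataclass(frozen=True)
class PNSweepResult:
    """Replicated evaluation at one positive:negative training ratio."""

    ratio: float
    reports: tuple
    mean_recall: float
    sd_recall: float
    mean_precision: float
    mean_ft: float
    sd_ft: float


def pn_ratio_sweep(
    corpus: Corpus,
    datatype: str,
    ratios: Sequence[float] = DEFAULT_PN_RATIOS,
    *,
    n_replicates: int = 10,
    test_fraction: float = 0.25,
    ft_ceiling: float = DEFAULT_FT_CEILING,
    scheme: str = "boolean_chi2",
    sizes: Sequence[int] = DEFAULT_SIZES,
    grid: tuple = COARSE_GRID,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[list, PNSweepResult]:
    """Sweep the training positive:negative ratio for a low-occurrence type.

    For each replicate one positive train/test split and one held-out negative
    test set are drawn; every ratio then reuses that same positive training
    set while drawing the prescribed number of training negatives from the
    remaining pool (nested sampling without replacement).  Each ratio is
    summarized over its replicates; the "best" ratio is the one with the
    highest mean recall among ratios whose mean FT stays at or below
    ``ft_ceiling`` (all ratios qualify, with a warning, if none do).
    """
    pos = sorted(corpus.positives(datatype), key=_chron_key)
    neg = sorted(build_negative_set(corpus, datatype), key=_chron_key)
    n_test_pos = max(1, int(round(test_fraction * len(pos))))
    n_test_neg = max(1, int(round(test_fraction * len(neg))))
    if n_test_pos >= len(pos) or n_test_neg >= len(neg):
        raise ValueError("test_fraction leaves no training documents")

    splits = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        perm_pos = rng.permutation(len(pos))
        perm_neg = rng.permutation(len(neg))
        splits.append(
            (
                [pos[i] for i in perm_pos[n_test_pos:]],  # train positives
                [pos[i] for i in perm_pos[:n_test_pos]],  # test positives
                [neg[i] for i in perm_neg[n_test_neg:]],  # negative train pool
                [neg[i] for i in perm_neg[:n_test_neg]],  # test negatives
            )
        )

    results: list[PNSweepResult] = []
    for ratio in ratios:
        needed = int(round(ratio * len(splits[0][0])))
        if needed > len(splits[0][2]):
            warnings.warn(
                f"ratio 1:{ratio:g} skipped: needs {needed} training negatives, "
                f"pool has {len(splits[0][2])}",
                stacklevel=2,
            )
            continue
        reports = []
        for rep, (train_p, test_p, neg_pool, test_n) in enumerate(splits):
            n_train_neg = int(round(ratio * len(train_p)))
            train = train_p + neg_pool[:n_train_neg]
            test = test_p + test_n
            model = train_comprehensive(
                train,
                datatype,
                scheme=scheme,
                sizes=sizes,
                grid=grid,
                cv_folds=cv_folds,
                seed=(seed + 9973 * rep) % (2**31),
            )
            reports.append(evaluate_documents(model, test, datatype))
        mean_r, sd_r, _ = _nan_mean_sd([r.recall for r in reports])
        mean_p, _, _ = _nan_mean_sd([r.precision for r in reports])
        mean_f, sd_f, _ = _nan_mean_sd([r.ft_percent for r in reports])
        results.append(
            PNSweepResult(
                ratio=ratio,
                reports=tuple(reports),
                mean_recall=mean_r,
                sd_recall=sd_r,
                mean_precision=mean_p,
                mean_ft=mean_f,
                sd_ft=sd_f,
            )
        )
    if not results:
        raise ValueError("no ratio was feasible for the available negative pool")
    qualifying = [r for r in results if r.mean_ft <= ft_ceiling]
    if not qualifying:
        warnings.warn(
            f"no ratio kept mean FT <= {ft_ceiling:g}%; selecting among all",
            stacklevel=2,
        )
        qualifying = results
    best = max(qualifying, key=lambda r: r.mean_recall)
    return results, best


def compare_weighting_schemes(
    train_docs: Sequence,
    datatype: str,
    schemes: Sequence[str] = ("boolean_chi2", "tfidf_chi2", "tfidf_all"),
    eval_sets: Mapping[str, Sequence] | None = None,
    *,
    sizes: Sequence[int] = DEFAULT_SIZES,
    grid: tuple = COARSE_GRID,
    cv_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Train once per weighting scheme and evaluate on each evaluation set.

    Returns a tidy table with one row per (scheme, eval_set): confusion
    counts, recall, precision and FT.  Evaluation sets may have different
    negative:positive compositions (e.g. 1:1 and 2:1).
    """
    if not eval_sets:
        raise ValueError("at least one evaluation set is required")
    rows = []
    for scheme in schemes:
        model = train_comprehensive(
            train_docs,
            datatype,
            scheme=scheme,
            sizes=sizes,
            grid=grid,
            cv_folds=cv_folds,
            seed=seed,
        )
        for name, docs in eval_sets.items():
            report = evaluate_documents(model, docs, datatype)
            c = report.confusion
            rows.append(
                {
                    "scheme": scheme,
                    "eval_set": name,
                    "tp": c.tp,
                    "fp": c.fp,
                    "tn": c.tn,
                    "fn": c.fn,
                    "recall": report.recall,
                    "precision": report.precision,
                    "ft_percent": report.ft_percent,
                }
            )
    return pd.DataFrame(rows)


def estimate_recall_subsampled(
    predicted,
    truth: Mapping[str, bool],
    n_sample: int = 20,
    seed: int = 0,
) -> float:
    """Estimate recall by auditing a random sample of predicted negatives.

    Mirrors the production shortcut of examining the false negatives among a
    handful of randomly selected predicted-negative papers: the sampled
    false-negative rate is extrapolated to the whole predicted-negative pool.
    """
    if isinstance(predicted, Mapping):
        items = list(predicted.items())
    else:
        items = [(p.doc_id, p.is_positive) for p in predicted]
    for doc_id, _ in items:
        if doc_id not in truth:
            raise ValueError(f"predicted document {doc_id!r} missing from truth")
    tp = sum(1 for doc_id, flag in items if flag and truth[doc_id])
    pred_neg = sorted(doc_id for doc_id, flag in items if not flag)
    if not pred_neg:
        return 1.0 if tp else float("nan")
    rng = np.random.default_rng(seed)
    size = min(n_sample, len(pred_neg))
    sample = rng.choice(pred_neg, size=size, replace=False)
    fn_rate = sum(1 for doc_id in sample if truth[doc_id]) / size
    fn_est = fn_rate * len(pred_neg)
    if tp + fn_est == 0:
        warnings.warn("subsampled recall undefined: no positives found", stacklevel=2)
        return float("nan")
    return tp / (tp + fn_est)


def report_table(reports: Mapping[str, EvaluationReport]) -> pd.DataFrame:
    """Flatten named evaluation reports into a tidy metric table."""
    rows = []
    for name, report in reports.items():
        c = report.confusion
        rows.append(
            {
                "name": name,
                "tp": c.tp,
                "fp": c.fp,
                "tn": c.tn,
                "fn": c.fn,
                "recall": report.recall,
                "precision": report.precision,
                "ft_percent": report.ft_percent,
            }
        )
    return pd.DataFrame(rows)
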