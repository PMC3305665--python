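"""The nine-component comprehensive SVM ensemble.

One binary RBF-kernel SVM is trained per feature-list size (top 10 ... top 400
chi-square ranked features) for a given data type under one-versus-rest: a
paper counts as positive if it carries the target data type, alone or among
other labels.  A document is flagged by the ensemble if *any* component votes
positive (union combination), which trades a tolerable amount of precision
for the high recall biocuration requires.  The number of positive votes
(0-9) is banded into a confidence level — none, low (1-3), medium (4-6),
high (7-9) — and an optional confidence cutoff reclassifies lower-confidence
positives as negative.

Hyperparameters (C, gamma) are selected per component by seeded, stratified
5-fold cross-validation accuracy over a log2 grid, then the component is
refit on the full training set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import (
    DEFAULT_SIZES,
    RankedFeatureList,
    nested_feature_lists,
    score_features,
)
from .vectors import (
    WEIGHTING_SCHEMES,
    TfidfStats,
    boolean_matrix,
    fit_tfidf,
    tfidf_matrix,
)

# log2 lattice recommended by the libsvm practical guide
GUIDE_GRID = (
    tuple(2.0 ** e for e in range(-5, 16, 2)),
    tuple(2.0 ** e for e in range(-15, 4, 2)),
)
# 3x3 sub-lattice of the guide grid, for replicated experiments
COARSE_GRID = (
    (2.0 ** -1, 2.0 ** 3, 2.0 ** 7),
    (2.0 ** -7, 2.0 ** -3, 2.0 ** 1),
)

CONFIDENCE_LEVELS = ("none", "low", "medium", "high")
CONFIDENCE_RANK = {level: i for i, level in enumerate(CONFIDENCE_LEVELS)}

MODEL_FORMAT = "litriage-model"
MODEL_FORMAT_VERSION = 1


class ModelIOError(RuntimeError):
    """Raised when a model archive cannot be read or has the wrong format."""


@dataclass
class ComponentModel:
    """One trained SVM over a single ranked feature list."""

    datatype: str
    k: int
    flist: RankedFeatureList | None
    C: float
    gamma: float
    svm: SVC
    scheme: str = "boolean_chi2"
    tfidf_stats: TfidfStats | None = None
    cv_accuracy: float = float("nan")

    def vectorize(self, docs: Sequence) -> np.ndarray:
        if self.scheme == "boolean_chi2":
            if self.flist is None:
                raise ValueError("boolean component lacks a feature list")
            return boolean_matrix(docs, self.flist)
        if self.tfidf_stats is None:
            raise ValueError("tfidf component lacks fitted statistics")
        return tfidf_matrix(docs, self.tfidf_stats)

    def predict_docs(self, docs: Sequence) -> np.ndarray:
        """Boolean per-document votes of this single component."""
        if not docs:
            return np.zeros(0, dtype=bool)
        return self.svm.predict(self.vectorize(docs)).astype(bool)


def train_component(
    train_vectors: np.ndarray,
    train_labels: Sequence,
    *,
    cv_folds: int = 5,
    grid: tuple = GUIDE_GRID,
    seed: int = 0,
    datatype: str = "",
    k: int = 0,
    flist: RankedFeatureList | None = None,
    scheme: str = "boolean_chi2",
    tfidf_stats: TfidfStats | None = None,
) -> ComponentModel:
    """Grid-search (C, gamma) by CV accuracy and refit on the full set.

    Selection is deterministic: folds are seeded and stratified by class, and
    ties are broken by the first best point in grid scan order (C outer,
    gamma inner).
    """
    X = np.asarray(train_vectors, dtype=float)
    y = np.asarray(train_labels, dtype=bool)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    cs, gammas = grid
    folds = min(cv_folds, int(counts.min()))
    if folds >= 2:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = list(skf.split(X, y))
    else:
        split = []  # too few per class to cross-validate; score on training fit
    best: tuple | None = None
    for c_val in cs:
        for g_val in gammas:
            accs = []
            if split:
                for tr, te in split:
                    clf = SVC(kernel="rbf", C=c_val, gamma=g_val)
                    clf.fit(X[tr], y[tr])
                    accs.append(clf.score(X[te], y[te]))
            else:
                clf = SVC(kernel="rbf", C=c_val, gamma=g_val)
                clf.fit(X, y)
                accs.append(clf.score(X, y))
            acc = float(np.mean(accs))
            if best is None or acc > best[0]:
                best = (acc, c_val, g_val)
    assert best is not None
    acc, c_val, g_val = best
    final = SVC(kernel="rbf", C=c_val, gamma=g_val)
    final.fit(X, y)
    return ComponentModel(
        datatype=datatype,
        k=k,
        flist=flist,
        C=c_val,
        gamma=g_val,
        svm=final,
        scheme=scheme,
        tfidf_stats=tfidf_stats,
        cv_accuracy=acc,
    )


def confidence_level(positive_count: int, n_components: int = 9) -> str:
    """Band a positive-vote count into none/low/medium/high.

    With nine components the bands are 0, 1-3, 4-6 and 7-9; for other ensemble
    sizes the 1..n range is split into thirds the same way.
    """
    if not 0 <= positive_count <= n_components:
        raise ValueError(
            f"positive_count {positive_count} outside 0..{n_components}"
        )
    if positive_count == 0:
        return "none"
    third = n_components / 3
    if positive_count <= math.ceil(third):
        return "low"
    if positive_count <= math.ceil(2 * third):
        return "medium"
    return "high"


@dataclass(frozen=True)
class Prediction:
    doc_id: str
    datatype: str
    positive_count: int
    is_positive: bool
    confidence: str


@dataclass
class ComprehensiveModel:
    """Per-size SVM components combined by union of positive votes."""

    datatype: str
    components: tuple
    scheme: str = "boolean_chi2"
    confidence_cutoff: str | None = None

    @property
    def n_components(self) -> int:
        return len(self.components)


def train_comprehensive(
    train_docs: Sequence,
    datatype: str,
    *,
    scheme: str = "boolean_chi2",
    sizes: Sequence[int] = DEFAULT_SIZES,
    grid: tuple = GUIDE_GRID,
    cv_folds: int = 5,
    seed: int = 0,
    confidence_cutoff: str | None = None,
) -> ComprehensiveModel:
    """Train the comprehensive ensemble for one data type.

    The one-versus-rest training classes are derived from the documents'
    label sets, the chi-square ranking is computed once, and one component is
    trained per requested size.  When the vocabulary is smaller than a
    requested size the truncated list is used; components whose inputs are
    identical share one deterministic fit.  Under ``tfidf_all`` there is no
    feature selection, so the ensemble reduces to a single component over the
    full training vocabulary.
    """
    if scheme not in WEIGHTING_SCHEMES:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    if confidence_cutoff is not None and confidence_cutoff not in CONFIDENCE_LEVELS:
        raise ValueError(f"unknown confidence cutoff {confidence_cutoff!r}")
    docs = list(train_docs)
    y = [datatype in d.labels for d in docs]
    if not any(y):
        raise ValueError(f"data type {datatype!r} absent from the training documents")
    if all(y):
        raise ValueError("training set has no negative documents")

    if scheme == "tfidf_all":
        stats = fit_tfidf(docs)
        X = tfidf_matrix(docs, stats)
        comp = train_component(
            X,
            y,
            cv_folds=cv_folds,
            grid=grid,
            seed=seed,
            datatype=datatype,
            k=len(stats.features),
            flist=None,
            scheme=scheme,
            tfidf_stats=stats,
        )
        return ComprehensiveModel(
            datatype=datatype,
            components=(comp,),
            scheme=scheme,
            confidence_cutoff=confidence_cutoff,
        )

    pos = [d for d in docs if datatype in d.labels]
    neg = [d for d in docs if datatype not in d.labels]
    scores = score_features(pos, neg, compute_mi=False)
    lists = nested_feature_lists(scores, sizes)
    components = []
    cache: dict = {}
    for flist in lists:
        key = flist.features
        if key in cache:
            fitted = cache[key]
            components.append(replace(fitted, k=flist.size_k, flist=flist))
            continue
        if scheme == "boolean_chi2":
            stats = None
            X = boolean_matrix(docs, flist)
        else:  # tfidf_chi2
            stats = fit_tfidf(docs, flist)
            X = tfidf_matrix(docs, stats)
        comp = train_component(
            X,
            y,
            cv_folds=cv_folds,
            grid=grid,
            seed=seed,
            datatype=datatype,
            k=flist.size_k,
            flist=flist,
            scheme=scheme,
            tfidf_stats=stats,
        )
        cache[key] = comp
        components.append(comp)
    return ComprehensiveModel(
        datatype=datatype,
        components=tuple(components),
        scheme=scheme,
        confidence_cutoff=confidence_cutoff,
    )


def _vote_counts(model: ComprehensiveModel, docs: Sequence) -> np.ndarray:
    votes = np.zeros(len(docs), dtype=int)
    memo: dict = {}
    for comp in model.components:
        key = (comp.scheme, comp.flist.features if comp.flist is not None else None)
        if key not in memo:
            memo[key] = comp.predict_docs(docs).astype(int)
        votes += memo[key]
    return votes


def _resolve_cutoff(model: ComprehensiveModel, cutoff) -> str | None:
    if cutoff is not None and cutoff not in CONFIDENCE_LEVELS:
        raise ValueError(f"unknown confidence cutoff {cutoff!r}")
    return cutoff if cutoff is not None else model.confidence_cutoff


def predict_many(
    model: ComprehensiveModel, docs: Sequence, cutoff: str | None = None
) -> list:
    """Ensemble predictions for a document batch.

    A document is positive when at least one component votes positive; with a
    confidence cutoff of low/medium/high, positives below the cutoff band are
    reclassified as negative (their vote count and confidence are reported
    unchanged).
    """
    cutoff = _resolve_cutoff(model, cutoff)
    min_rank = CONFIDENCE_RANK[cutoff] if cutoff else 1
    counts = _vote_counts(model, docs)
    out = []
    for doc, count in zip(docs, counts):
        conf = confidence_level(int(count), model.n_components)
        out.append(
            Prediction(
                doc_id=doc.doc_id,
                datatype=model.datatype,
                positive_count=int(count),
                is_positive=CONFIDENCE_RANK[conf] >= min_rank,
                confidence=conf,
            )
        )
    return out


def predict_comprehensive(
    model: ComprehensiveModel, doc, cutoff: str | None = None
) -> Prediction:
    """Ensemble prediction for a single document."""
    return predict_many(model, [doc], cutoff=cutoff)[0]


def save_model(model: ComprehensiveModel, path: str | Path) -> None:
    """Serialize a model (feature lists, scaling stats, SVMs) to one archive."""
    joblib.dump(
        {"format": MODEL_FORMAT, "version": MODEL_FORMAT_VERSION, "model": model},
        path,
    )


def load_model(path: str | Path) -> ComprehensiveModel:
    """Load a model archive, validating format and version."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupt or truncated archive
        raise ModelIOError(f"cannot read model archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise ModelIOError(f"{path} is not a litriage model archive")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ModelIOError(
            f"unsupported model format version {payload.get('version')!r}"
        )
    model = payload["model"]
    if not isinstance(model, ComprehensiveModel):
        raise ModelIOError(f"{path} does not contain a comprehensive model")
    return model
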