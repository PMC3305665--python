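"""Document vectorization: Boolean (production) and TF-IDF (comparison) schemes.

The production scheme assigns 1 if a ranked feature is present in a document
and 0 if not — within-document frequency is deliberately ignored because
curatable evidence often resides in a few sentences.  TF-IDF variants are
provided for the weighting-scheme comparison experiments: raw term frequency
times natural-log inverse document frequency, with per-feature min-max
scaling fitted on the training set (mirroring libsvm-style data scaling).
All statistics are derived from training documents only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.datasets import dump_svmlight_file, load_svmlight_file

WEIGHTING_SCHEMES = ("boolean_chi2", "tfidf_chi2", "tfidf_all")


def _feature_names(flist) -> tuple:
    """Accept a RankedFeatureList or a plain sequence of feature names."""
    features = getattr(flist, "features", None)
    if features is not None:
        return tuple(features)
    return tuple(flist)


def boolean_vector(doc, flist) -> np.ndarray:
    """0/1 vector over the feature list: 1 iff the feature is in the document."""
    names = _feature_names(flist)
    return np.array([1.0 if f in doc.tokens else 0.0 for f in names])


def boolean_matrix(docs: Sequence, flist) -> np.ndarray:
    names = _feature_names(flist)
    index = {f: j for j, f in enumerate(names)}
    out = np.zeros((len(docs), len(names)))
    for i, doc in enumerate(docs):
        for token in doc.tokens:
            j = index.get(token)
            if j is not None:
                out[i, j] = 1.0
    return out


@dataclass(frozen=True)
class TfidfStats:
    """Training-set statistics for TF-IDF vectorization.

    ``idf[j] = ln(n_train / df_j)``; ``lo``/``hi`` are the training min/max of
    each feature's raw tf-idf value, used for min-max scaling to [0, 1] on the
    training set (test values are scaled with the same affine map and may fall
    outside the unit interval).
    """

    features: tuple
    idf: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n_train: int


def fit_tfidf(train_docs: Sequence, features=None) -> TfidfStats:
    """Fit IDF and scaling statistics on the training set only.

    With ``features=None`` the full (sorted) training vocabulary is used — the
    no-feature-selection comparison mode.  Features absent from every training
    document are dropped.
    """
    if not train_docs:
        raise ValueError("cannot fit TF-IDF on an empty training set")
    if features is None:
        vocab: set = set()
        for doc in train_docs:
            vocab |= doc.tokens
        names = tuple(sorted(vocab))
    else:
        names = _feature_names(features)
    n = len(train_docs)
    df = np.array([sum(1 for d in train_docs if f in d.tokens) for f in names])
    keep = df > 0
    names = tuple(f for f, k in zip(names, keep) if k)
    df = df[keep]
    idf = np.log(n / df)
    raw = _raw_tfidf(train_docs, names, idf)
    return TfidfStats(
        features=names,
        idf=idf,
        lo=raw.min(axis=0),
        hi=raw.max(axis=0),
        n_train=n,
    )


def _raw_tfidf(docs: Sequence, names: tuple, idf: np.ndarray) -> np.ndarray:
    index = {f: j for j, f in enumerate(names)}
    out = np.zeros((len(docs), len(names)))
    for i, doc in enumerate(docs):
        counts = doc.token_counts
        items = counts.items() if counts is not None else ((t, 1) for t in doc.tokens)
        for token, tf in items:
            j = index.get(token)
            if j is not None and tf:
                out[i, j] = tf * idf[j]
    return out


def tfidf_matrix(docs: Sequence, stats: TfidfStats) -> np.ndarray:
    """Scaled TF-IDF vectors; tokens unseen in training are ignored."""
    raw = _raw_tfidf(docs, stats.features, stats.idf)
    span = stats.hi - stats.lo
    safe = np.where(span > 0, span, 1.0)
    scaled = (raw - stats.lo) / safe
    scaled[:, span <= 0] = 0.0
    return scaled


def tfidf_vector(doc, stats: TfidfStats) -> np.ndarray:
    return tfidf_matrix([doc], stats)[0]


def write_sparse(X: np.ndarray, y: Sequence, path: str | Path) -> None:
    """Write vectors in the SVM-light/libsvm sparse text format (1-based)."""
    dump_svmlight_file(X, np.asarray(y, dtype=float), str(path), zero_based=False)


def read_sparse(path: str | Path, n_features: int | None = None):
    """Read an SVM-light/libsvm sparse file; returns (dense X, y)."""
    X, y = load_svmlight_file(str(path), n_features=n_features, zero_based=False)
    return np.asarray(X.todense()), y
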