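"""Chi-square feature scoring and nested ranked feature lists.

Curatable evidence usually occupies a small stretch of a paper, so features
are scored on document-level presence only.  For each candidate token a 2x2
contingency table against the target data type is tallied over the training
set, scored with the chi-square statistic (no continuity correction), and the
vocabulary is ranked.  The ensemble consumes nested prefixes of this ranking:
by default the top 10, 25, 50, 75, 100, 150, 200, 300 and 400 features.

Mutual information is computed alongside for inspection, but ranking always
uses chi-square: gaps between adjacent chi-square scores separate informative
from background tokens far more sharply.
"""

from __future__ import annotations

import csv
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

DEFAULT_SIZES = (10, 25, 50, 75, 100, 150, 200, 300, 400)


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 presence/class counts for one feature against one data type.

    ``n11``: positive documents containing the feature; ``n10``: negative
    documents containing it; ``n01``/``n00``: positive/negative documents
    lacking it.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def count_contingency(
    train_pos: Sequence, train_neg: Sequence
) -> dict:
    """Tally per-feature contingency counts over the training set.

    One entry per token present in at least one training document; counts are
    document frequencies (within-document repetition is ignored).
    """
    if not train_pos or not train_neg:
        raise ValueError("both training classes must be non-empty")
    pos_df: Counter = Counter()
    for doc in train_pos:
        pos_df.update(doc.tokens)
    neg_df: Counter = Counter()
    for doc in train_neg:
        neg_df.update(doc.tokens)
    n_pos, n_neg = len(train_pos), len(train_neg)
    out = {}
    for feature in sorted(set(pos_df) | set(neg_df)):
        n11 = pos_df.get(feature, 0)
        n10 = neg_df.get(feature, 0)
        out[feature] = ContingencyCounts(n11, n10, n_pos - n11, n_neg - n10)
    return out


def chi_square_score(c: ContingencyCounts) -> float:
    """Chi-square statistic of a 2x2 table, without continuity correction.

    Computed as N*(n11*n00 - n10*n01)^2 / product of the four marginals, in
    exact integer arithmetic with a single final division, so the score is
    exactly invariant under swapping the class labels.  Degenerate tables
    (any zero marginal) score 0 rather than raising.
    """
    n = c.n
    if n == 0:
        raise ValueError("empty contingency table")
    present = c.n11 + c.n10
    absent = c.n01 + c.n00
    pos = c.n11 + c.n01
    neg = c.n10 + c.n00
    if 0 in (present, absent, pos, neg):
        return 0.0
    det = c.n11 * c.n00 - c.n10 * c.n01
    return (n * det * det) / (present * absent * pos * neg)


def mutual_information_score(c: ContingencyCounts) -> float:
    """Mutual information (bits) between feature presence and the class."""
    n = c.n
    if n == 0:
        raise ValueError("empty contingency table")
    present = c.n11 + c.n10
    absent = c.n01 + c.n00
    pos = c.n11 + c.n01
    neg = c.n10 + c.n00
    total = 0.0
    for cell, row, col in (
        (c.n11, pos, present),
        (c.n10, neg, present),
        (c.n01, pos, absent),
        (c.n00, neg, absent),
    ):
        if cell:
            total += (cell / n) * math.log2(n * cell / (row * col))
    # clamp tiny negative rounding residue
    return max(total, 0.0)


@dataclass(frozen=True)
class FeatureScore:
    feature: str
    chi2: float
    mi: float | None
    counts: ContingencyCounts


def score_features(
    train_pos: Sequence, train_neg: Sequence, compute_mi: bool = True
) -> dict:
    """Score every training-set token against the target class."""
    tables = count_contingency(train_pos, train_neg)
    return {
        feature: FeatureScore(
            feature=feature,
            chi2=chi_square_score(counts),
            mi=mutual_information_score(counts) if compute_mi else None,
            counts=counts,
        )
        for feature, counts in tables.items()
    }


@dataclass(frozen=True)
class RankedFeatureList:
    """Features ordered by descending chi-square, truncated to ``size_k``."""

    size_k: int
    entries: tuple

    @property
    def features(self) -> tuple:
        return tuple(s.feature for s in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def _rank_key(score: FeatureScore) -> tuple:
    # ties: higher chi2 first, then larger positive-class presence, then name
    return (-score.chi2, -score.counts.n11, score.feature)


def rank_features(scores: Mapping[str, FeatureScore], k: int) -> RankedFeatureList:
    """Top-``k`` features by chi-square with a total, reproducible order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(scores.values(), key=_rank_key)
    return RankedFeatureList(size_k=k, entries=tuple(ordered[:k]))


def full_ranking(scores: Mapping[str, FeatureScore]) -> dict:
    """Map feature -> 1-based chi-square rank over the whole vocabulary."""
    ordered = sorted(scores.values(), key=_rank_key)
    return {s.feature: i + 1 for i, s in enumerate(ordered)}


def nested_feature_lists(
    scores: Mapping[str, FeatureScore], sizes: Sequence[int] = DEFAULT_SIZES
) -> list:
    """Nested top-k lists (prefixes of one ranking) for the ensemble sizes."""
    if not scores:
        raise ValueError("cannot rank an empty score map")
    if not sizes or any(k < 1 for k in sizes):
        raise ValueError("sizes must be positive")
    sizes = tuple(sorted(sizes))
    full = rank_features(scores, max(sizes))
    return [RankedFeatureList(size_k=k, entries=full.entries[:k]) for k in sizes]


def write_feature_list(flist: RankedFeatureList, path: str | Path) -> None:
    """Write a ranked list as TSV: rank, feature, chi2, n11, n10, n01, n00."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["rank", "feature", "chi2", "n11", "n10", "n01", "n00"])
        for rank, s in enumerate(flist.entries, start=1):
            c = s.counts
            writer.writerow(
                [rank, s.feature, f"{s.chi2:.10g}", c.n11, c.n10, c.n01, c.n00]
            )


def read_feature_list(path: str | Path) -> RankedFeatureList:
    """Read a TSV feature list written by :func:`write_feature_list`."""
    entries = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            counts = ContingencyCounts(
                int(row["n11"]), int(row["n10"]), int(row["n01"]), int(row["n00"])
            )
            entries.append(
                FeatureScore(
                    feature=row["feature"],
                    chi2=float(row["chi2"]),
                    mi=None,
                    counts=counts,
                )
            )
    return RankedFeatureList(size_k=len(entries), entries=tuple(entries))
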