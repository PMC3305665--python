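"""Labeled document corpora: ingestion, tokenization, and split construction.

A triage corpus is a collection of full-text papers, each carrying a set of
data-type labels assigned by curators (possibly empty, meaning the paper holds
no curatable data), a tag naming the source database, and an integer key that
orders papers chronologically.  This module loads such corpora from disk,
tokenizes text into bag-of-words form, constructs the one-versus-rest negative
sets, and builds the chronological odd/even and replicated random train/test
partitions used throughout the pipeline.
"""

from __future__ import annotations

import csv
import dataclasses
import re
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

_TOKEN_RE = re.compile(r"[a-z0-9]+")


class CorpusError(ValueError):
    """Raised for malformed corpora, label tables, or infeasible splits."""


def tokenize(text: str) -> Counter:
    """Tokenize ``text`` into a multiset of lowercase alphanumeric tokens.

    Tokens are maximal runs of ``[a-z0-9]`` after case folding; tokens of
    length one are dropped.  No stemming and no stop-word removal are applied,
    so gene names, author surnames, years and method terms (e.g. ``dsrna``)
    all survive as candidate features.

    Returns a :class:`collections.Counter` mapping token -> occurrence count.
    """
    return Counter(tok for tok in _TOKEN_RE.findall(text.lower()) if len(tok) > 1)


@dataclass(frozen=True, eq=False)
class Document:
    """One paper: bag of tokens plus curation metadata.

    ``tokens`` is the presence set used for Boolean vectors and chi-square
    counting; ``token_counts`` retains within-document frequencies for the
    TF-IDF weighting modes.
    """

    doc_id: str
    tokens: frozenset
    token_counts: Mapping[str, int] | None
    labels: frozenset
    corpus_tag: str = ""
    order_key: int = 0

    @classmethod
    def from_text(
        cls,
        doc_id: str,
        text: str,
        labels: Iterable[str] = (),
        corpus_tag: str = "",
        order_key: int = 0,
    ) -> "Document":
        counts = tokenize(text)
        return cls(
            doc_id=doc_id,
            tokens=frozenset(counts),
            token_counts=dict(counts),
            labels=frozenset(labels),
            corpus_tag=corpus_tag,
            order_key=order_key,
        )

    def count(self, token: str) -> int:
        """In-document occurrence count of ``token`` (presence fallback = 1)."""
        if self.token_counts is not None:
            return int(self.token_counts.get(token, 0))
        return 1 if token in self.tokens else 0


@dataclass
class Corpus:
    """A collection of documents with unique ids."""

    documents: list

    def __post_init__(self) -> None:
        seen: set = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise CorpusError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)
        by_tag: dict = {}
        for doc in self.documents:
            key = (doc.corpus_tag, doc.order_key)
            if key in by_tag:
                warnings.warn(
                    f"order_key {doc.order_key} duplicated within corpus "
                    f"{doc.corpus_tag!r}; ties broken by doc_id",
                    stacklevel=2,
                )
                break
            by_tag[key] = doc.doc_id

    @property
    def datatype_inventory(self) -> frozenset:
        """Union of all label sets present in the corpus."""
        out: set = set()
        for doc in self.documents:
            out |= doc.labels
        return frozenset(out)

    def positives(self, datatype: str) -> list:
        """Documents labeled with ``datatype`` (alone or among other labels)."""
        return [d for d in self.documents if datatype in d.labels]

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)


LABELS_COLUMNS = ("doc_id", "labels", "corpus_tag", "order_key")


def load_corpus(text_dir: str | Path, labels_table: str | Path) -> Corpus:
    """Load a corpus from a directory of ``.txt`` files and a labels table.

    The labels table is tab-separated UTF-8 with a header row and columns
    ``doc_id``, ``labels`` (semicolon-delimited, empty allowed), ``corpus_tag``
    and ``order_key``.  Every row must name a file ``<doc_id>.txt`` present in
    ``text_dir``.
    """
    text_dir = Path(text_dir)
    documents: list = []
    seen: set = set()
    with open(labels_table, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        fields = reader.fieldnames or []
        missing = [c for c in LABELS_COLUMNS if c not in fields]
        if missing:
            raise CorpusError(
                f"labels table {labels_table} lacks required columns {missing}"
            )
        for lineno, row in enumerate(reader, start=2):
            doc_id = (row.get("doc_id") or "").strip()
            if not doc_id:
                raise CorpusError(f"{labels_table} line {lineno}: empty doc_id")
            if doc_id in seen:
                raise CorpusError(
                    f"{labels_table} line {lineno}: duplicate doc_id {doc_id!r}"
                )
            seen.add(doc_id)
            path = text_dir / f"{doc_id}.txt"
            if not path.is_file():
                raise CorpusError(
                    f"{labels_table} line {lineno}: missing text file {path}"
                )
            try:
                order_key = int((row.get("order_key") or "").strip())
            except ValueError as exc:
                raise CorpusError(
                    f"{labels_table} line {lineno}: malformed order_key "
                    f"{row.get('order_key')!r}"
                ) from exc
            labels = frozenset(
                part.strip()
                for part in (row.get("labels") or "").split(";")
                if part.strip()
            )
            documents.append(
                Document.from_text(
                    doc_id,
                    path.read_text(encoding="utf-8"),
                    labels=labels,
                    corpus_tag=(row.get("corpus_tag") or "").strip(),
                    order_key=order_key,
                )
            )
    return Corpus(documents)


def build_negative_set(corpus: Corpus, target: str) -> list:
    """Negative documents for ``target`` under one-versus-rest.

    The negative set combines papers labeled as containing no curatable data
    (empty label set) with papers positive only for other data types.  Any
    paper carrying ``target`` — alone or among other labels — is excluded.
    """
    if target not in corpus.datatype_inventory:
        raise CorpusError(f"unknown data type {target!r}")
    return [d for d in corpus if target not in d.labels]


def _chron_key(doc: Document) -> tuple:
    return (doc.order_key, doc.doc_id)


def _odd_even(docs: Sequence[Document]) -> tuple[list, list]:
    ordered = sorted(docs, key=_chron_key)
    return ordered[0::2], ordered[1::2]


def odd_even_split(
    positives: Sequence[Document], negatives: Sequence[Document]
) -> tuple[list, list]:
    """Chronological odd/even split, applied to each class pool independently.

    Each pool is sorted by ``order_key`` (ties broken by ``doc_id``); papers at
    odd 1-based ranks go to training, even ranks to testing.  Returns
    ``(train, test)`` lists containing both classes; class membership is
    recovered downstream from the documents' labels.
    """
    train_pos, test_pos = _odd_even(positives)
    train_neg, test_neg = _odd_even(negatives)
    if positives and not test_pos:
        warnings.warn("odd/even split left no positive test documents", stacklevel=2)
    return train_pos + train_neg, test_pos + test_neg


@dataclass(frozen=True)
class SplitSpec:
    """Parameters for replicated random train/test construction.

    ``pn_ratio`` is the number of negative training documents drawn per
    positive training document (a 1:r positive:negative ratio).
    """

    mode: str = "replicated_random"
    test_fraction: float = 0.25
    n_replicates: int = 10
    pn_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"odd_even_chronological", "random_fraction", "replicated_random"}:
            raise CorpusError(f"unknown split mode {self.mode!r}")
        if not 0.0 < self.test_fraction < 1.0:
            raise CorpusError("test_fraction must lie in (0, 1)")
        if self.n_replicates < 1:
            raise CorpusError("n_replicates must be >= 1")
        if self.pn_ratio <= 0:
            raise CorpusError("pn_ratio must be positive")
        if self.seed < 0:
            raise CorpusError("seed must be non-negative")


def replicated_random_split(
    positives: Sequence[Document],
    negatives: Sequence[Document],
    spec: SplitSpec,
) -> list:
    """Draw ``spec.n_replicates`` independent random train/test pairs.

    Within each replicate a ``spec.test_fraction`` share of each class is held
    out for testing and the negative training pool is subsampled without
    replacement so that train positives:negatives matches ``1:spec.pn_ratio``.
    Fully deterministic given ``spec.seed``; metric reports are meant to be
    averaged over the replicates downstream.
    """
    pos = sorted(positives, key=_chron_key)
    neg = sorted(negatives, key=_chron_key)
    n_test_pos = int(round(spec.test_fraction * len(pos)))
    n_test_neg = int(round(spec.test_fraction * len(neg)))
    if n_test_pos < 1 or n_test_neg < 1:
        raise CorpusError("test_fraction implies an empty test set for one class")
    if n_test_pos >= len(pos) or n_test_neg >= len(neg):
        raise CorpusError("test_fraction leaves no training documents for one class")
    replicates = []
    for rep in range(spec.n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, rep]))
        perm_pos = rng.permutation(len(pos))
        test_p = [pos[i] for i in perm_pos[:n_test_pos]]
        train_p = [pos[i] for i in perm_pos[n_test_pos:]]
        perm_neg = rng.permutation(len(neg))
        test_n = [neg[i] for i in perm_neg[:n_test_neg]]
        remaining = [neg[i] for i in perm_neg[n_test_neg:]]
        n_train_neg = int(round(spec.pn_ratio * len(train_p)))
        if n_train_neg > len(remaining):
            raise CorpusError(
                f"negative pool too small: need {n_train_neg} training negatives "
                f"for ratio 1:{spec.pn_ratio:g}, only {len(remaining)} available"
            )
        train_n = remaining[:n_train_neg]
        train = sorted(train_p, key=_chron_key) + sorted(train_n, key=_chron_key)
        test = sorted(test_p, key=_chron_key) + sorted(test_n, key=_chron_key)
        replicates.append((train, test))
    return replicates


def pool_corpora(
    set_a: Sequence[Document], set_b: Sequence[Document]
) -> list:
    """Concatenate two training sets so they are scored as one pool.

    Corpus tags are preserved.  If raw doc_ids collide between the sets, ids
    are namespaced as ``<corpus_tag>:<doc_id>``; a collision surviving
    namespacing is an error.
    """
    docs = list(set_a) + list(set_b)
    ids = [d.doc_id for d in docs]
    if len(set(ids)) == len(ids):
        return docs
    namespaced = [
        dataclasses.replace(d, doc_id=f"{d.corpus_tag}:{d.doc_id}") for d in docs
    ]
    new_ids = [d.doc_id for d in namespaced]
    if len(set(new_ids)) != len(new_ids):
        raise CorpusError("doc_id collision persists after corpus_tag namespacing")
    return namespaced
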