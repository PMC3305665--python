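"""Corpus ingestion, tokenization and split construction."""

from __future__ import annotations

import warnings
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litriage.corpus import (
    Corpus,
    CorpusError,
    SplitSpec,
    build_negative_set,
    load_corpus,
    odd_even_split,
    pool_corpora,
    replicated_random_split,
    tokenize,
)

from conftest import make_doc


@pytest.mark.parametrize(
    ("text", "expected"),
    [
        ("RNAi dsRNA RNAi", {"rnai": 2, "dsrna": 1}),
        ("", {}),
        ("Fire (1998); Timmons.", {"fire": 1, "1998": 1, "timmons": 1}),
        ("C. elegans unc-22 RNAi", {"elegans": 1, "unc": 1, "22": 1, "rnai": 1}),
    ],
)
def test_tokenize_casefolds_and_splits_alphanumeric_runs(text, expected):
    assert tokenize(text) == Counter(expected)


class TestLoadCorpus:
    @staticmethod
    def _write(tmp_path, rows, texts):
        text_dir = tmp_path / "docs"
        text_dir.mkdir()
        for doc_id, text in texts.items():
            (text_dir / f"{doc_id}.txt").write_text(text, encoding="utf-8")
        table = tmp_path / "labels.tsv"
        lines = ["doc_id\tlabels\tcorpus_tag\torder_key"] + rows
        table.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return text_dir, table

    def test_loads_one_document_per_row(self, tmp_path):
        text_dir, table = self._write(
            tmp_path,
            ["a\trnai\twb\t1", "b\trnai;phenotype\twb\t2", "c\t\twb\t3"],
            {"a": "dsRNA injection", "b": "unc-22 phenotype", "c": "review article"},
        )
        corpus = load_corpus(text_dir, table)
        assert len(corpus) == 3
        by_id = {d.doc_id: d for d in corpus}
        assert by_id["b"].labels == {"rnai", "phenotype"}
        assert by_id["c"].labels == frozenset()
        assert by_id["a"].tokens == {"dsrna", "injection"}
        assert corpus.datatype_inventory == {"rnai", "phenotype"}

    def test_missing_file_error_names_the_file(self, tmp_path):
        text_dir, table = self._write(
            tmp_path, ["a\trnai\twb\t1", "ghost\t\twb\t2"], {"a": "x y"}
        )
        with pytest.raises(CorpusError, match="ghost"):
            load_corpus(text_dir, table)

    def test_duplicate_doc_id_rejected(self, tmp_path):
        text_dir, table = self._write(
            tmp_path, ["a\trnai\twb\t1", "a\t\twb\t2"], {"a": "x y"}
        )
        with pytest.raises(CorpusError, match="duplicate"):
            load_corpus(text_dir, table)

    def test_malformed_order_key_names_the_line(self, tmp_path):
        text_dir, table = self._write(tmp_path, ["a\trnai\twb\tnotanint"], {"a": "x"})
        with pytest.raises(CorpusError, match="line 2"):
            load_corpus(text_dir, table)

    def test_missing_columns_rejected(self, tmp_path):
        table = tmp_path / "bad.tsv"
        table.write_text("doc_id\tlabels\n", encoding="utf-8")
        with pytest.raises(CorpusError, match="columns"):
            load_corpus(tmp_path, table)


class TestNegativeSet:
    def test_other_type_positives_and_unlabeled_are_negatives(self, small_corpus):
        negatives = {d.doc_id for d in build_negative_set(small_corpus, "rnai")}
        # d2 (antibody only) and d5 (phenotype) are positives for other types;
        # d4/d6 carry no curatable data; d1/d3 carry the target label
        assert negatives == {"d2", "d4", "d5", "d6"}

    def test_unknown_target_rejected(self, small_corpus):
        with pytest.raises(CorpusError, match="unknown"):
            build_negative_set(small_corpus, "nosuchtype")

    def test_disjoint_from_positives_for_every_type(self, small_corpus):
        for datatype in small_corpus.datatype_inventory:
            pos = {d.doc_id for d in small_corpus.positives(datatype)}
            neg = {d.doc_id for d in build_negative_set(small_corpus, datatype)}
            assert not pos & neg
            assert pos | neg == {d.doc_id for d in small_corpus}


class TestOddEvenSplit:
    def test_odd_ranks_train_even_ranks_test(self):
        pos = [make_doc(f"p{k}", order_key=k) for k in (12, 11, 20, 15)]
        train, test = odd_even_split(pos, [])
        assert [d.order_key for d in train] == [11, 15]
        assert [d.order_key for d in test] == [12, 20]

    def test_single_positive_goes_to_train_with_warning(self):
        with pytest.warns(UserWarning, match="no positive test"):
            train, test = odd_even_split([make_doc("p", order_key=1)], [])
        assert [d.doc_id for d in train] == ["p"]
        assert test == []

    def test_empty_pools_give_empty_split(self):
        assert odd_even_split([], []) == ([], [])

    @given(st.lists(st.integers(0, 10_000), min_size=2, max_size=40, unique=True))
    @settings(derandomize=True, deadline=None)
    def test_partitions_each_class_with_near_equal_halves(self, keys):
        docs = [make_doc(f"d{k}", order_key=k) for k in keys]
        train, test = odd_even_split(docs, [])
        assert {d.doc_id for d in train} | {d.doc_id for d in test} == {
            d.doc_id for d in docs
        }
        assert not {d.doc_id for d in train} & {d.doc_id for d in test}
        assert len(train) - len(test) in (0, 1)


class TestReplicatedRandomSplit:
    @staticmethod
    def _pools(n_pos=24, n_neg=120):
        pos = [make_doc(f"p{i}", labels={"t"}, order_key=i) for i in range(n_pos)]
        neg = [make_doc(f"n{i}", order_key=i) for i in range(n_neg)]
        return pos, neg

    def test_same_seed_reproduces_identical_replicates(self):
        pos, neg = self._pools()
        spec = SplitSpec(n_replicates=10, pn_ratio=2.0, seed=42)
        first = replicated_random_split(pos, neg, spec)
        second = replicated_random_split(pos, neg, spec)
        assert len(first) == 10
        for (tr1, te1), (tr2, te2) in zip(first, second):
            assert [d.doc_id for d in tr1] == [d.doc_id for d in tr2]
            assert [d.doc_id for d in te1] == [d.doc_id for d in te2]

    def test_different_seeds_differ(self):
        pos, neg = self._pools()
        a = replicated_random_split(pos, neg, SplitSpec(seed=1))
        b = replicated_random_split(pos, neg, SplitSpec(seed=2))
        assert any(
            {d.doc_id for d in ta} != {d.doc_id for d in tb}
            for (ta, _), (tb, _) in zip(a, b)
        )

    def test_training_ratio_matches_pn_ratio(self):
        pos, neg = self._pools()
        spec = SplitSpec(test_fraction=0.25, pn_ratio=2.0, seed=0)
        for train, _ in replicated_random_split(pos, neg, spec):
            n_pos_train = sum(1 for d in train if "t" in d.labels)
            n_neg_train = sum(1 for d in train if "t" not in d.labels)
            assert n_pos_train == 18  # 24 positives, a quarter held out
            assert n_neg_train == 36

    def test_insufficient_negative_pool_rejected(self):
        pos, neg = self._pools(n_pos=40, n_neg=40)
        with pytest.raises(CorpusError, match="pool too small"):
            replicated_random_split(pos, neg, SplitSpec(pn_ratio=6.0, seed=0))


class TestPoolCorpora:
    def test_pooling_concatenates_training_sets(self):
        a = [make_doc(f"wb{i}", labels={"rnai"}, corpus_tag="wb") for i in range(170)]
        b = [make_doc(f"fb{i}", labels={"rnai"}, corpus_tag="fb") for i in range(170)]
        pooled = pool_corpora(a, b)
        assert len(pooled) == 340
        assert {d.corpus_tag for d in pooled} == {"wb", "fb"}

    def test_empty_second_set_is_identity(self):
        a = [make_doc("x"), make_doc("y")]
        assert pool_corpora(a, []) == a
        assert pool_corpora([], a) == a

    def test_collisions_namespaced_by_corpus_tag(self):
        a = [make_doc("1", corpus_tag="wb")]
        b = [make_doc("1", corpus_tag="fb")]
        pooled = pool_corpora(a, b)
        assert {d.doc_id for d in pooled} == {"wb:1", "fb:1"}

    def test_collision_without_distinct_tags_rejected(self):
        with pytest.raises(CorpusError, match="collision"):
            pool_corpora([make_doc("1")], [make_doc("1")])

    def test_associative(self):
        a = [make_doc("a1"), make_doc("a2")]
        b = [make_doc("b1")]
        c = [make_doc("c1")]
        left = [d.doc_id for d in pool_corpora(pool_corpora(a, b), c)]
        right = [d.doc_id for d in pool_corpora(a, pool_corpora(b, c))]
        assert left == right


def test_corpus_rejects_duplicate_ids():
    with pytest.raises(CorpusError, match="duplicate"):
        Corpus([make_doc("a"), make_doc("a")])


def test_corpus_warns_on_duplicate_order_keys():
    with pytest.warns(UserWarning, match="order_key"):
        Corpus([make_doc("a", order_key=1), make_doc("b", order_key=1)])
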