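from __future__ import annotations

import pytest

from litriage.corpus import Corpus, Document


def make_doc(
    doc_id: str,
    tokens=(),
    labels=(),
    corpus_tag: str = "",
    order_key: int = 0,
    text: str | None = None,
) -> Document:
    """Build a document either from explicit tokens or from raw text."""
    if text is not None:
        return Document.from_text(
            doc_id, text, labels=labels, corpus_tag=corpus_tag, order_key=order_key
        )
    return Document(
        doc_id=doc_id,
        tokens=frozenset(tokens),
        token_counts={t: 1 for t in tokens},
        labels=frozenset(labels),
        corpus_tag=corpus_tag,
        order_key=order_key,
    )


@pytest.fixture
def small_corpus() -> Corpus:
    """Six documents covering positives, other-type positives and unlabeled."""
    return Corpus(
        [
            make_doc("d1", {"rnai", "dsrna", "worm"}, {"rnai"}, "wb", 1),
            make_doc("d2", {"antibody", "stain"}, {"antibody"}, "wb", 2),
            make_doc("d3", {"rnai", "antibody"}, {"rnai", "antibody"}, "wb", 3),
            make_doc("d4", {"gene", "worm"}, (), "wb", 4),
            make_doc("d5", {"phenotype", "allele"}, {"phenotype"}, "wb", 5),
            make_doc("d6", {"dsrna", "gene"}, (), "wb", 6),
        ]
    )
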