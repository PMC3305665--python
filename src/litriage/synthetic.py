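"""Synthetic labeled corpora with planted statistical structure.

The generator emulates the properties of curated full-text collections that
the pipeline depends on: a shared Zipf-like background vocabulary (so
chi-square ranking must beat realistic high-frequency noise), planted
discriminative tokens that occur more often in positive documents,
corpus-specific tokens tied to one literature (the analogue of a heavily
cited author's surname), multi-corpus collections with shared signal, and
evaluation streams whose positive occurrence rate can be pushed down to ~1%.

Documents are emitted as actual token streams — plain text that is run back
through the production tokenizer — so the whole pipeline is exercised
end-to-end, and :func:`write_corpus` materializes the on-disk layout
(``docs/*.txt`` + ``labels.tsv`` + a JSON manifest) that
:func:`litriage.corpus.load_corpus` ingests.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Corpus, Document

_TAG_RE = re.compile(r"^[a-z][a-z0-9]*$")


class SyntheticConfigError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one generated corpus.

    Planted features occur in a positive document with probability
    ``p_feat_in_pos`` (corpus-specific ones with ``p_specific_in_pos`` when
    set) and in a negative document with ``p_feat_in_neg``.  ``doc_length``
    is the mean number of background tokens per document (Poisson), drawn
    from a Zipf-like distribution over ``vocab_size`` word types.
    ``occurrence_rate`` governs the positive fraction of generated
    evaluation streams.  ``other_label_rate`` labels that share of negatives
    with a distinct data type, exercising the negative-set construction rule.
    """

    n_pos: int = 120
    n_neg: int = 360
    vocab_size: int = 1500
    n_discriminative_shared: int = 12
    n_discriminative_specific: int = 0
    p_feat_in_pos: float = 0.7
    p_feat_in_neg: float = 0.05
    p_specific_in_pos: float | None = None
    doc_length: float = 120.0
    zipf_exponent: float = 1.1
    occurrence_rate: float = 0.05
    datatype: str = "rnai"
    other_label_rate: float = 0.1
    corpus_tag: str = "syntha"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pos, self.n_neg) < 1:
            raise SyntheticConfigError("n_pos and n_neg must be positive")
        if self.vocab_size < 1:
            raise SyntheticConfigError("vocab_size must be positive")
        if self.n_discriminative_shared < 0 or self.n_discriminative_specific < 0:
            raise SyntheticConfigError("planted feature counts must be >= 0")
        probs = [self.p_feat_in_pos, self.p_feat_in_neg, self.other_label_rate]
        if self.p_specific_in_pos is not None:
            probs.append(self.p_specific_in_pos)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise SyntheticConfigError("probabilities must lie in [0, 1]")
        if self.p_feat_in_pos <= self.p_feat_in_neg:
            raise SyntheticConfigError(
                "planted features must be more frequent in positives"
            )
        if self.p_specific_in_pos is not None and (
            self.p_specific_in_pos <= self.p_feat_in_neg
        ):
            raise SyntheticConfigError(
                "corpus-specific features must be more frequent in positives"
            )
        if not 0.0 < self.occurrence_rate <= 1.0:
            raise SyntheticConfigError("occurrence_rate must lie in (0, 1]")
        if self.doc_length <= 0 or self.zipf_exponent <= 0:
            raise SyntheticConfigError("doc_length and zipf_exponent must be positive")
        if not _TAG_RE.match(self.corpus_tag) or not _TAG_RE.match(self.datatype):
            raise SyntheticConfigError(
                "corpus_tag and datatype must be lowercase alphanumeric tokens"
            )
        if self.seed < 0:
            raise SyntheticConfigError("seed must be non-negative")


def shared_feature_names(config: SyntheticConfig) -> tuple:
    """Organism-independent planted tokens, named after the data type."""
    return tuple(
        f"{config.datatype}mark{i:02d}" for i in range(config.n_discriminative_shared)
    )


def specific_feature_names(config: SyntheticConfig) -> tuple:
    """Corpus-specific planted tokens, named after the corpus tag."""
    return tuple(
        f"{config.corpus_tag}mark{i:02d}"
        for i in range(config.n_discriminative_specific)
    )


def _background_weights(config: SyntheticConfig) -> np.ndarray:
    ranks = np.arange(1, config.vocab_size + 1, dtype=float)
    weights = ranks ** (-config.zipf_exponent)
    return weights / weights.sum()


def _doc_text(
    rng: np.random.Generator,
    config: SyntheticConfig,
    positive: bool,
    shared: Sequence[str],
    specific: Sequence[str],
    weights: np.ndarray,
) -> str:
    n_background = int(rng.poisson(config.doc_length))
    indices = rng.choice(config.vocab_size, size=n_background, p=weights)
    words = [f"w{j:05d}" for j in indices]
    p_shared = config.p_feat_in_pos if positive else config.p_feat_in_neg
    p_specific = (
        (config.p_specific_in_pos or config.p_feat_in_pos)
        if positive
        else config.p_feat_in_neg
    )
    for feature in shared:
        if rng.random() < p_shared:
            words.append(feature)
    for feature in specific:
        if rng.random() < p_specific:
            words.append(feature)
    rng.shuffle(words)
    lines = [" ".join(words[i : i + 12]) for i in range(0, len(words), 12)]
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class _SimDoc:
    doc_id: str
    text: str
    labels: tuple
    order_key: int


def _generate_records(
    config: SyntheticConfig,
    shared: Sequence[str] | None = None,
    stream: int = 0,
    flags: Sequence[bool] | None = None,
) -> list:
    """Generate raw document records; ``flags`` overrides the class layout."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, stream]))
    if shared is None:
        shared = shared_feature_names(config)
    specific = specific_feature_names(config)
    weights = _background_weights(config)
    if flags is None:
        flags = [True] * config.n_pos + [False] * config.n_neg
    records = []
    for i, positive in enumerate(flags):
        if positive:
            labels: tuple = (config.datatype,)
        elif rng.random() < config.other_label_rate:
            labels = ("otherdata",)
        else:
            labels = ()
        records.append(
            _SimDoc(
                doc_id=f"{config.corpus_tag}{i:05d}",
                text=_doc_text(rng, config, positive, shared, specific, weights),
                labels=labels,
                order_key=i + 1,
            )
        )
    return records


def _records_to_corpus(records: Sequence[_SimDoc], corpus_tag: str) -> Corpus:
    return Corpus(
        [
            Document.from_text(
                rec.doc_id,
                rec.text,
                labels=rec.labels,
                corpus_tag=corpus_tag,
                order_key=rec.order_key,
            )
            for rec in records
        ]
    )


def generate_corpus(
    config: SyntheticConfig, shared_features: Sequence[str] | None = None
) -> Corpus:
    """Generate a labeled corpus: ``n_pos`` positives then ``n_neg`` negatives.

    Fully reproducible from ``config.seed``.  Documents are generated as text
    and re-tokenized through the production tokenizer.
    """
    return _records_to_corpus(
        _generate_records(config, shared=shared_features), config.corpus_tag
    )


def generate_stream(
    config: SyntheticConfig, n_docs: int, stream_id: int = 1
) -> Corpus:
    """Generate an incoming-paper stream with Bernoulli(occurrence_rate) positives."""
    if n_docs < 1:
        raise SyntheticConfigError("n_docs must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 500_000 + stream_id]))
    flags = [bool(rng.random() < config.occurrence_rate) for _ in range(n_docs)]
    return _records_to_corpus(
        _generate_records(config, stream=500_000 + stream_id, flags=flags),
        config.corpus_tag,
    )


def generate_cross_corpus_pair(
    config_a: SyntheticConfig,
    config_b: SyntheticConfig,
    shared_features: Sequence[str] | None = None,
) -> tuple[Corpus, Corpus]:
    """Two corpora sharing organism-independent signal.

    Shared discriminative features are planted in the positives of both
    corpora; each corpus's specific features are planted only in its own
    positives (and at background rate in its own negatives).  The specific
    feature name sets must be disjoint.
    """
    if config_a.datatype != config_b.datatype:
        raise SyntheticConfigError("cross-corpus pair must target one data type")
    if shared_features is None:
        if config_a.n_discriminative_shared != config_b.n_discriminative_shared:
            raise SyntheticConfigError(
                "configs disagree on the number of shared features"
            )
        shared_features = shared_feature_names(config_a)
    spec_a = set(specific_feature_names(config_a))
    spec_b = set(specific_feature_names(config_b))
    if spec_a & spec_b:
        raise SyntheticConfigError(
            f"corpus-specific feature sets overlap: {sorted(spec_a & spec_b)}"
        )
    if set(shared_features) & (spec_a | spec_b):
        raise SyntheticConfigError("shared features overlap corpus-specific ones")
    return (
        generate_corpus(config_a, shared_features=shared_features),
        generate_corpus(config_b, shared_features=shared_features),
    )


def write_corpus(
    config: SyntheticConfig,
    out_dir: str | Path,
    shared_features: Sequence[str] | None = None,
) -> tuple[Path, Path, Path]:
    """Materialize a generated corpus in the standard on-disk layout.

    Writes ``docs/<doc_id>.txt``, ``labels.tsv`` and ``manifest.json`` (the
    full config and seed) under ``out_dir``; returns the three paths.
    """
    out_dir = Path(out_dir)
    text_dir = out_dir / "docs"
    text_dir.mkdir(parents=True, exist_ok=True)
    records = _generate_records(config, shared=shared_features)
    for rec in records:
        (text_dir / f"{rec.doc_id}.txt").write_text(rec.text, encoding="utf-8")
    labels_path = out_dir / "labels.tsv"
    lines = ["doc_id\tlabels\tcorpus_tag\torder_key"]
    for rec in records:
        lines.append(
            f"{rec.doc_id}\t{';'.join(rec.labels)}\t{config.corpus_tag}\t{rec.order_key}"
        )
    labels_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    manifest_path = out_dir / "manifest.json"
    manifest = {"generator": "litriage.synthetic", "config": dataclasses.asdict(config)}
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return text_dir, labels_path, manifest_path


# --------------------------------------------------------------------------
# Named study conditions used by the replicated experiments.


def separable_config(seed: int, corpus_tag: str = "synthsep") -> SyntheticConfig:
    """Strongly separable corpus for ensemble and confidence experiments."""
    return SyntheticConfig(
        n_pos=80,
        n_neg=160,
        vocab_size=800,
        n_discriminative_shared=15,
        p_feat_in_pos=0.8,
        p_feat_in_neg=0.02,
        doc_length=100.0,
        corpus_tag=corpus_tag,
        seed=seed,
    )


def low_occurrence_config(seed: int) -> SyntheticConfig:
    """Overlapping-class corpus with a large negative pool for PN sweeps."""
    return SyntheticConfig(
        n_pos=60,
        n_neg=600,
        vocab_size=1200,
        n_discriminative_shared=8,
        p_feat_in_pos=0.5,
        p_feat_in_neg=0.12,
        doc_length=100.0,
        occurrence_rate=0.05,
        corpus_tag="synthlo",
        seed=seed,
    )


def cross_corpus_configs(seed: int) -> tuple[SyntheticConfig, SyntheticConfig]:
    """Two-organism pair: shared signal plus stronger corpus-specific signal."""
    common = dict(
        n_pos=80,
        n_neg=240,
        vocab_size=1000,
        n_discriminative_shared=8,
        n_discriminative_specific=6,
        p_feat_in_pos=0.5,
        p_specific_in_pos=0.75,
        p_feat_in_neg=0.05,
        doc_length=100.0,
    )
    return (
        SyntheticConfig(corpus_tag="wormsim", seed=seed, **common),
        SyntheticConfig(corpus_tag="flysim", seed=seed + 10_007, **common),
    )


def weighting_configs(seed: int) -> tuple[SyntheticConfig, SyntheticConfig]:
    """Balanced training corpus and a fresh evaluation corpus for the
    Boolean-vs-TF-IDF comparison.

    The regime of interest is weak per-feature signal diluted in a large
    background vocabulary — the situation real full text presents — where
    ranking-based selection is what keeps the informative tokens visible to
    the classifier.
    """
    common = dict(
        vocab_size=6000,
        n_discriminative_shared=10,
        p_feat_in_pos=0.45,
        p_feat_in_neg=0.05,
        doc_length=180.0,
    )
    train_cfg = SyntheticConfig(
        n_pos=100, n_neg=100, corpus_tag="synthwt", seed=seed, **common
    )
    eval_cfg = SyntheticConfig(
        n_pos=60, n_neg=120, corpus_tag="synthwe", seed=seed + 20_011, **common
    )
    return train_cfg, eval_cfg
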