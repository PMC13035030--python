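"""Synthetic corpora with planted seed co-occurrence and topic structure.

The generator emulates the statistical skeleton the analysis assumes of
a real retrieval corpus: documents composed of sentences; a minority of
sentences carrying one of the two seed lemmas; topic-specific
vocabularies that preferentially co-occur with seeds inside sentences;
a background vocabulary producing noise everywhere; and a document-level
pandemic descriptor present in most but not all documents.  Topic
membership is document-level and hard (one topic per document).

Generated lemmas are pre-lemmatized tokens; the optional ``inflect``
mode appends a regular plural suffix to every topic and seed lemma
occurrence so the rule lemmatizer's suffix handling is exercised
end-to-end.  Everything is a pure function of the spec, including
``rng_seed``.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Mapping, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from sklearn.metrics import adjusted_rand_score

from .corpus import Corpus, Document
from .errors import ValidationError
from .network import Partition

SEED_CYCLE = ("fehlinformation", "desinformation")


class SyntheticSpec(BaseModel):
    """Parameters of one synthetic corpus.

    Defaults describe a well-separated regime: 3 topics of 10 lemmas,
    strong within-topic seed co-occurrence (p_topic_lemma = 0.8) over a
    weak background (p_noise_lemma = 0.02), with roughly a third of
    sentences carrying a seed, mirroring a focused retrieval query where
    the query terms appear in a minority of sentences of each hit.
    """

    model_config = ConfigDict(frozen=True)

    n_docs: int = Field(default=500, ge=1)
    sentences_per_doc: Tuple[int, int] = (3, 8)
    k_topics: int = Field(default=3, ge=1)
    vocab_per_topic: int = Field(default=10, ge=1)
    background_vocab: int = Field(default=50, ge=1)
    p_seed_sentence: float = Field(default=0.3, gt=0.0, le=1.0)
    p_topic_lemma: float = Field(default=0.8, gt=0.0, le=1.0)
    p_noise_lemma: float = Field(default=0.02, ge=0.0, lt=1.0)
    p_descriptor_doc: float = Field(default=0.9, gt=0.0, le=1.0)
    rng_seed: int = 0
    inflect: bool = False

    @model_validator(mode="after")
    def _check_range(self) -> "SyntheticSpec":
        lo, hi = self.sentences_per_doc
        if lo < 1 or hi < lo:
            raise ValueError(
                f"sentences_per_doc must be a (min, max) range with 1 <= min <= max, "
                f"got {self.sentences_per_doc}"
            )
        return self


class GroundTruth(BaseModel):
    """Planted structure of a generated corpus.

    ``expected_freq`` is the expected seed co-occurrence frequency of
    each topic lemma: ``p_topic_lemma`` times the realized share of seed
    sentences belonging to the lemma's topic.
    """

    model_config = ConfigDict(frozen=True)

    lemma_topic: Mapping[str, int]
    doc_topic: Mapping[str, int]
    expected_freq: Mapping[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.model_dump(), ensure_ascii=False, sort_keys=True, indent=1),
            encoding="utf-8",
        )


def topic_lemma(topic: int, i: int) -> str:
    # base ends in "-ung" so the inflected surface "...ungen" reduces
    # back to the base under the rule lemmatizer
    return f"t{topic}wort{i}ung"


def background_lemma(j: int) -> str:
    return f"rausch{j}"


def _surface(lemma: str, inflect: bool) -> str:
    return lemma + "en" if inflect else lemma


def generate(spec: SyntheticSpec) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus and its ground truth from a spec.

    Per document: one topic drawn uniformly, a sentence count drawn
    uniformly from ``sentences_per_doc``, and a descriptor token
    ("covid") prepended to the first sentence with ``p_descriptor_doc``.
    Per sentence: seed status with ``p_seed_sentence``; a seed sentence
    carries one seed lemma (deterministically alternating between the
    two seeds), each active-topic lemma independently with
    ``p_topic_lemma`` and each background lemma with ``p_noise_lemma``;
    a non-seed sentence draws background lemmas only (at least one, so
    every sentence has text).
    """
    rng = np.random.default_rng(spec.rng_seed)
    lo, hi = spec.sentences_per_doc
    topics = list(range(spec.k_topics))
    topic_vocab = {
        t: [topic_lemma(t, i) for i in range(spec.vocab_per_topic)] for t in topics
    }
    bg_vocab = [background_lemma(j) for j in range(spec.background_vocab)]

    documents: list[Document] = []
    doc_topic: dict[str, int] = {}
    seed_sent_by_topic = {t: 0 for t in topics}
    n_seed_sentences = 0
    seed_cursor = 0
    base_date = _dt.date(2019, 9, 1)

    for d in range(spec.n_docs):
        topic = int(rng.integers(spec.k_topics))
        n_sent = int(rng.integers(lo, hi + 1))
        has_descriptor = bool(rng.random() < spec.p_descriptor_doc)
        sentences: list[str] = []
        for s in range(n_sent):
            tokens: list[str] = []
            if rng.random() < spec.p_seed_sentence:
                n_seed_sentences += 1
                seed_sent_by_topic[topic] += 1
                tokens.append(_surface(SEED_CYCLE[seed_cursor % 2], spec.inflect))
                seed_cursor += 1
                mask = rng.random(spec.vocab_per_topic) < spec.p_topic_lemma
                tokens.extend(
                    _surface(w, spec.inflect)
                    for w, keep in zip(topic_vocab[topic], mask) if keep
                )
                noise = rng.random(spec.background_vocab) < spec.p_noise_lemma
                tokens.extend(w for w, keep in zip(bg_vocab, noise) if keep)
            else:
                noise = rng.random(spec.background_vocab) < spec.p_noise_lemma
                tokens.extend(w for w, keep in zip(bg_vocab, noise) if keep)
                if not tokens:
                    tokens.append(bg_vocab[int(rng.integers(spec.background_vocab))])
            sentences.append(" ".join(tokens) + ".")
        if has_descriptor:
            sentences[0] = "covid " + sentences[0]
        doc_id = f"syn{d:05d}"
        doc_topic[doc_id] = topic
        documents.append(
            Document(
                doc_id=doc_id,
                text=" ".join(sentences),
                date=base_date + _dt.timedelta(days=d % 1300),
                source=f"quelle{topic}",
                language="de",
                channel="social",
            )
        )

    lemma_topic = {w: t for t, ws in topic_vocab.items() for w in ws}
    expected_freq = {
        w: (
            spec.p_topic_lemma * seed_sent_by_topic[t] / n_seed_sentences
            if n_seed_sentences else 0.0
        )
        for w, t in lemma_topic.items()
    }
    truth = GroundTruth(
        lemma_topic=lemma_topic, doc_topic=doc_topic, expected_freq=expected_freq
    )
    corpus = Corpus(
        tuple(documents),
        provenance=f"synthetic(rng_seed={spec.rng_seed}, n_docs={spec.n_docs})",
    )
    return corpus, truth


def recovery_score(truth: GroundTruth, partition: Partition) -> float:
    """Adjusted Rand index between planted topics and modularity classes.

    Restricted to planted topic lemmas that made it into the clustered
    network; 1.0 iff the clusterings agree up to relabeling.
    """
    if not partition.assignment:
        raise ValidationError("partition is empty")
    common = sorted(set(truth.lemma_topic) & set(partition.assignment))
    if not common:
        raise ValidationError("no overlap between planted lemmas and partition")
    labels_true = [truth.lemma_topic[l] for l in common]
    labels_pred = [partition.assignment[l] for l in common]
    return float(adjusted_rand_score(labels_true, labels_pred))
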