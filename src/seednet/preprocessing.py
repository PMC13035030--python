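"""Descriptor filtering, sentence segmentation and lemmatization.

The co-occurrence window of the whole analysis is the sentence, so the
segmenter here defines the statistic's denominator.  Segmentation is
rule-based and deterministic: terminator characters ``. ! ?`` split,
guarded by a per-run abbreviation list ("Dr.", "z.B.", ...), and newline
boundaries also split because social-media posts often lack terminal
punctuation.

Lemmatization is pluggable via :class:`LemmatizerBackend`.  The shipped
default, :class:`RuleLemmatizer`, is a deterministic dictionary plus
suffix-rule reducer that handles the regular German noun-plural patterns
relevant here (``-ionen → -ion``, ``-ungen → -ung``, ...).  It is
idempotent: feeding its own output back through it is a no-op.  A
statistical NLP backend can be dropped in by subclassing the interface.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from . import _stopwords
from .corpus import Corpus, Document, RunConfig, SeedLexicon, nfc
from .errors import ConfigurationError, SeednetError

logger = logging.getLogger(__name__)

# Word tokens: runs of word characters (no underscore), with internal
# hyphens kept so "covid-19" and "corona-impfung" are single tokens.
_TOKEN_RE = re.compile(r"[^\W_]+(?:-[^\W_]+)*", re.UNICODE)

_SENTENCE_SPLIT_RE = re.compile(r"(?<=[.!?])\s+")

#: Abbreviations that must not terminate a sentence (lowercase, with dot).
DEFAULT_ABBREVIATIONS = frozenset({
    "dr.", "prof.", "z.b.", "u.a.", "bzw.", "ca.", "nr.", "usw.", "vgl.",
    "inkl.", "evtl.", "st.", "abs.", "art.", "mio.", "mrd.",
    "m.", "mme.", "mlle.", "mr.", "mrs.", "ms.", "no.", "etc.", "sig.",
})


def tokenize(text: str) -> list[str]:
    """Lowercased, NFC-normalized word tokens of ``text``."""
    return [nfc(tok.lower()) for tok in _TOKEN_RE.findall(text)]


def load_wordlist(path: str | Path) -> frozenset[str]:
    """Read a plain-text word list (one entry per line, UTF-8)."""
    entries = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = nfc(line.strip().lower())
        if line:
            entries.add(line)
    return frozenset(entries)


def filter_by_descriptors(corpus: Corpus, lexicon: SeedLexicon) -> Corpus:
    """Keep only documents containing at least one descriptor term.

    Matching is case-insensitive and whole-token: "coronavirus" does not
    match the descriptor "corona", but both are on the default list.
    """
    if not lexicon.descriptor_terms:
        raise ConfigurationError("descriptor filtering needs a non-empty list")
    kept = [
        doc for doc in corpus
        if lexicon.descriptor_terms.intersection(tokenize(doc.text))
    ]
    logger.info(
        "descriptor filter: %d of %d documents retained (%d removed)",
        len(kept), len(corpus), len(corpus) - len(kept),
    )
    return corpus.subset(kept, "descriptor-filter")


def segment_sentences(
    doc: Document,
    abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS,
) -> list[str]:
    """Split a document body into raw sentence strings.

    Newlines always split; within a line, splits occur after ``. ! ?``
    followed by whitespace unless the preceding token is a known
    abbreviation.  A text with no terminator is one sentence.
    """
    sentences: list[str] = []
    for line in doc.text.splitlines():
        line = line.strip()
        if not line:
            continue
        parts = _SENTENCE_SPLIT_RE.split(line)
        merged: list[str] = []
        for part in parts:
            if merged and _ends_with_abbreviation(merged[-1], abbreviations):
                merged[-1] = merged[-1] + " " + part
            else:
                merged.append(part)
        sentences.extend(p for p in merged if p.strip())
    return sentences


def _ends_with_abbreviation(chunk: str, abbreviations: frozenset[str]) -> bool:
    last = chunk.rsplit(None, 1)[-1].lower() if chunk.split() else ""
    return last in abbreviations


class LemmatizerBackend:
    """Interface contract for lemmatizers.

    Implementations must be deterministic (same input, same output) and
    must never emit empty lemmas.
    """

    name: str = "abstract"
    supported_languages: frozenset[str] = frozenset()

    def lemmatize(self, tokens: Sequence[str], language: str) -> list[str]:
        raise NotImplementedError

    def supports(self, language: str) -> bool:
        return language in self.supported_languages


# Regular German noun-plural suffix reductions, longest first.  Each
# replacement is itself a fixed point of the rule table (idempotence).
_SUFFIX_RULES: tuple[tuple[str, str], ...] = (
    ("schaften", "schaft"),
    ("heiten", "heit"),
    ("keiten", "keit"),
    ("ionen", "ion"),
    ("ungen", "ung"),
    ("täten", "tät"),
    ("ien", "ie"),
)

_DEFAULT_LEMMA_DICT: Mapping[str, str] = {
    "fehlinformationen": "fehlinformation",
    "desinformationen": "desinformation",
    "misinformationen": "misinformation",
    "verschwörungstheorien": "verschwörungstheorie",
    "medien": "medium",
    "viren": "virus",
    "massnahmen": "massnahme",
    "maßnahmen": "maßnahme",
    "impfungen": "impfung",
}


class RuleLemmatizer(LemmatizerBackend):
    """Deterministic dictionary + suffix-rule lemmatizer.

    Exact dictionary entries win; otherwise the first matching suffix
    rule applies, provided the remaining stem keeps at least
    ``min_stem`` characters.  Tokens it cannot analyze pass through
    unchanged, so the backend is language-agnostic and safe as a
    fallback for any of the supported codes.
    """

    name = "rule"
    supported_languages = frozenset({"de", "fr", "it", "en", "und"})

    def __init__(self, extra_dictionary: Mapping[str, str] | None = None,
                 min_stem: int = 3):
        self._dict = dict(_DEFAULT_LEMMA_DICT)
        if extra_dictionary:
            self._dict.update(extra_dictionary)
        self._min_stem = min_stem

    def lemmatize(self, tokens: Sequence[str], language: str) -> list[str]:
        return [self._lemma(tok) for tok in tokens if tok]

    def _lemma(self, token: str) -> str:
        hit = self._dict.get(token)
        if hit is not None:
            return hit
        for suffix, repl in _SUFFIX_RULES:
            if token.endswith(suffix) and len(token) - len(suffix) >= self._min_stem:
                return token[: -len(suffix)] + repl
        return token


@dataclass(frozen=True)
class TokenizedSentence:
    """Ordered lemmas of one sentence; the co-occurrence window."""

    doc_id: str
    sent_index: int
    lemmas: tuple[str, ...]
    contains_seed: bool

    def __post_init__(self) -> None:
        if not self.lemmas:
            raise SeednetError(
                f"empty TokenizedSentence ({self.doc_id}, {self.sent_index})"
            )


def _stopword_set(config: RunConfig, language: str) -> frozenset[str]:
    if config.stopword_policy == "none":
        return frozenset()
    if config.stopword_policy == "custom-file":
        return load_wordlist(config.stopword_file)  # type: ignore[arg-type]
    return _stopwords.BY_LANGUAGE.get(language, frozenset())


def lemmatize_corpus(
    corpus: Corpus,
    backend: LemmatizerBackend,
    lexicon: SeedLexicon,
    config: RunConfig,
    abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS,
) -> list[TokenizedSentence]:
    """Segment, tokenize and lemmatize every document of ``corpus``.

    Per sentence: tokens are lowercased and NFC-normalized; tokens with
    no alphabetic character (numbers, punctuation) are dropped; surface
    forms listed in the lexicon are mapped straight onto their seed
    lemma; remaining tokens go through the backend; stopwords are
    removed per ``config.stopword_policy`` (seed lemmas are never
    removed).  Sentences left empty are not emitted.  ``contains_seed``
    is set iff a seed lemma is present after all mapping.
    """
    out: list[TokenizedSentence] = []
    surface_map = dict(lexicon.extra_seed_surface_forms)
    for doc in corpus:
        if not backend.supports(doc.language):
            raise SeednetError(
                f"backend {backend.name!r} does not support language "
                f"{doc.language!r} of document {doc.doc_id!r}"
            )
        stop = _stopword_set(config, doc.language)
        try:
            raw_sentences = segment_sentences(doc, abbreviations)
        except Exception as exc:  # pragma: no cover - defensive
            raise SeednetError(f"segmentation failed for {doc.doc_id!r}: {exc}")
        for sent_index, raw in enumerate(raw_sentences):
            tokens = [t for t in tokenize(raw) if any(c.isalpha() for c in t)]
            if not tokens:
                continue
            lemmas: list[str] = []
            for tok in tokens:
                if tok in surface_map:
                    lemmas.append(surface_map[tok])
                    continue
                lemma = backend.lemmatize([tok], doc.language)
                if not lemma or not lemma[0]:
                    raise SeednetError(
                        f"backend {backend.name!r} emitted an empty lemma "
                        f"for token {tok!r} in document {doc.doc_id!r}"
                    )
                mapped = surface_map.get(lemma[0], lemma[0])
                lemmas.append(mapped)
            lemmas = [
                l for l in lemmas if l in lexicon.seed_lemmas or l not in stop
            ]
            if not lemmas:
                continue
            out.append(
                TokenizedSentence(
                    doc_id=doc.doc_id,
                    sent_index=sent_index,
                    lemmas=tuple(lemmas),
                    contains_seed=bool(set(lemmas) & lexicon.seed_lemmas),
                )
            )
    logger.info("lemmatized %d sentences from %d documents", len(out), len(corpus))
    return out
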