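"""Corpus domain types and tabular I/O.

A :class:`Corpus` is an ordered, duplicate-free collection of
:class:`Document` records read from a CSV or JSONL export of a news or
social-media retrieval tool.  Column names vary between export vintages,
so ingestion is driven by an explicit ``schema_map`` rather than
auto-detection: the caller states which column holds the text, the date,
the source and the language.  All text is UTF-8 and is normalized to
Unicode NFC at ingestion so that umlauts and accented characters compare
equal regardless of how the exporting tool encoded them.

The :class:`SeedLexicon` bundles the focal ("seed") lemmas that condition
the whole analysis, the topical descriptor word list used for corpus
filtering, and surface forms in other languages that are mapped onto the
seed lemmas so multilingual mentions pool into one statistic.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

SUPPORTED_LANGUAGES = frozenset({"de", "fr", "it", "en", "und"})
CHANNELS = frozenset({"news", "social"})

#: Default seed lemmas: the German lemmas for "misinformation" and
#: "disinformation" that condition the co-occurrence statistic.
DEFAULT_SEED_LEMMAS = frozenset({"fehlinformation", "desinformation"})

#: Surface forms in the other corpus languages that are pooled onto the
#: two seed lemmas before any counting happens.
DEFAULT_SEED_SURFACE_FORMS: Mapping[str, str] = {
    "misinformation": "fehlinformation",
    "disinformation": "desinformation",
    "désinformation": "desinformation",
    "disinformazione": "desinformation",
}

#: The 15-term pandemic descriptor list used to drop off-topic documents.
#: Matching is case-insensitive and whole-token; "covid-19" is one token.
DEFAULT_DESCRIPTOR_TERMS = frozenset({
    "covid", "corona", "virus", "covid-19", "coronavirus",
    "pandemic", "epidemic", "outbreak",
    "pandémie", "épidémie",
    "pandemie", "epidemie", "seuche",
    "pandemia", "epidemia",
})


def nfc(s: str) -> str:
    """Normalize a string to Unicode NFC."""
    return unicodedata.normalize("NFC", s)


@dataclass(frozen=True)
class Document:
    """One corpus record: a news article or a social-media post.

    ``text`` is the raw body; it must be non-empty after whitespace
    stripping.  ``date`` may be ``None`` when the source date could not
    be parsed (the analysis is not longitudinal, so records are kept).
    """

    doc_id: str
    text: str
    date: _dt.date | None
    source: str
    language: str
    channel: str

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValidationError(f"document {self.doc_id!r} has empty text")
        if self.language not in SUPPORTED_LANGUAGES:
            raise ValidationError(
                f"document {self.doc_id!r} has unsupported language "
                f"{self.language!r}; expected one of {sorted(SUPPORTED_LANGUAGES)}"
            )
        if self.channel not in CHANNELS:
            raise ValidationError(
                f"document {self.doc_id!r} has unknown channel {self.channel!r}"
            )


@dataclass(frozen=True)
class Corpus:
    """An ordered document collection with stable, deterministic order."""

    documents: tuple[Document, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise ValidationError(f"duplicate doc_id {doc.doc_id!r} in corpus")
            seen.add(doc.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def subset(self, keep: Iterable[Document], provenance_suffix: str) -> "Corpus":
        """Return a sub-corpus in original order with annotated provenance."""
        kept = tuple(keep)
        return Corpus(kept, provenance=f"{self.provenance}|{provenance_suffix}")


def _check_lowercase_nfc(entries: Iterable[str], what: str) -> None:
    for e in entries:
        if e != e.lower() or e != nfc(e):
            raise ValidationError(
                f"{what} entry {e!r} must be lowercase and NFC-normalized"
            )


@dataclass(frozen=True)
class SeedLexicon:
    """Seed lemmas, descriptor word list and pooled surface forms."""

    seed_lemmas: frozenset[str] = DEFAULT_SEED_LEMMAS
    descriptor_terms: frozenset[str] = DEFAULT_DESCRIPTOR_TERMS
    extra_seed_surface_forms: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SEED_SURFACE_FORMS)
    )

    def __post_init__(self) -> None:
        if not self.seed_lemmas:
            raise ConfigurationError("seed_lemmas must be non-empty")
        if not self.descriptor_terms:
            raise ConfigurationError("descriptor_terms must be non-empty")
        _check_lowercase_nfc(self.seed_lemmas, "seed_lemmas")
        _check_lowercase_nfc(self.descriptor_terms, "descriptor_terms")
        _check_lowercase_nfc(self.extra_seed_surface_forms, "extra_seed_surface_forms")
        for surface, seed in self.extra_seed_surface_forms.items():
            if seed not in self.seed_lemmas:
                raise ConfigurationError(
                    f"surface form {surface!r} maps to {seed!r}, not a seed lemma"
                )


STOPWORD_POLICIES = frozenset({"none", "builtin", "custom-file"})


@dataclass(frozen=True)
class RunConfig:
    """All tunable knobs of one analysis run.

    ``resolution`` is the modularity resolution parameter gamma; values
    below 1 favour coarser (fewer, larger) clusters.  The default 0.5
    targets broad thematic groupings rather than fine-grained ones.
    """

    resolution: float = 0.5
    top_k: int = 30
    min_node_freq: float = 0.0
    min_edge_count: int = 1
    rng_seed: int = 0
    language_filter: str | None = None
    stopword_policy: str = "builtin"
    stopword_file: str | None = None
    date_format: str | None = None  # strptime pattern; None = ISO-8601

    def __post_init__(self) -> None:
        if not self.resolution > 0:
            raise ConfigurationError("resolution must be > 0")
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")
        if not 0.0 <= self.min_node_freq <= 1.0:
            raise ConfigurationError("min_node_freq must be in [0, 1]")
        if self.min_edge_count < 0:
            raise ConfigurationError("min_edge_count must be >= 0")
        if self.language_filter is not None and self.language_filter not in SUPPORTED_LANGUAGES:
            raise ConfigurationError(
                f"language_filter {self.language_filter!r} not supported"
            )
        if self.stopword_policy not in STOPWORD_POLICIES:
            raise ConfigurationError(
                f"stopword_policy must be one of {sorted(STOPWORD_POLICIES)}"
            )
        if self.stopword_policy == "custom-file" and not self.stopword_file:
            raise ConfigurationError("stopword_policy 'custom-file' needs stopword_file")


_CONFIG_INT_KEYS = {"top_k", "min_edge_count", "rng_seed"}
_CONFIG_FLOAT_KEYS = {"resolution", "min_node_freq"}


def load_run_config(path: str | Path) -> RunConfig:
    """Read a flat ``key = value`` configuration file into a RunConfig.

    Unknown keys raise a :class:`ConfigurationError`; blank lines and
    ``#`` comments are ignored.
    """
    kwargs: dict[str, object] = {}
    valid = set(RunConfig.__dataclass_fields__)
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in valid:
            raise ConfigurationError(f"{path}:{lineno}: unknown config key {key!r}")
        if key in _CONFIG_INT_KEYS:
            kwargs[key] = int(value)
        elif key in _CONFIG_FLOAT_KEYS:
            kwargs[key] = float(value)
        elif key in {"language_filter", "stopword_file", "date_format"} and (
            value == "" or value.lower() == "none"
        ):
            kwargs[key] = None
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)  # type: ignore[arg-type]


def _parse_date(value: object, fmt: str | None, doc_id: str) -> _dt.date | None:
    if value is None:
        return None
    text = str(value).strip()
    if not text:
        return None
    try:
        if fmt is None:
            return _dt.date.fromisoformat(text[:10])
        return _dt.datetime.strptime(text, fmt).date()
    except ValueError:
        logger.warning("document %s: unparseable date %r kept as null", doc_id, text)
        return None


def read_corpus(
    path: str | Path,
    schema_map: Mapping[str, str],
    channel: str,
    *,
    date_format: str | None = None,
) -> Corpus:
    """Read a CSV or JSONL document table into a :class:`Corpus`.

    ``schema_map`` maps the logical fields ``text``, ``date``, ``source``,
    ``language`` (and optionally ``doc_id``) onto column names of the
    file.  A missing ``language`` mapping yields language ``"und"``; a
    missing ``doc_id`` mapping numbers the rows in file order.  Rows with
    empty text are dropped and counted in the log.

    Format is chosen by extension: ``.jsonl``/``.ndjson`` are read as one
    JSON object per line, anything else as RFC-4180 CSV.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"corpus file not found: {path}")
    if "text" not in schema_map:
        raise ConfigurationError("schema_map must map the 'text' field")
    if path.suffix.lower() in {".jsonl", ".ndjson"}:
        frame = pd.read_json(path, lines=True, dtype=str)
    else:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    frame = frame.fillna("")
    for logical, column in schema_map.items():
        if column not in frame.columns:
            raise ConfigurationError(
                f"schema_map field {logical!r} refers to absent column {column!r}"
            )

    documents: list[Document] = []
    dropped = 0
    for i, row in enumerate(frame.itertuples(index=False)):
        record = dict(zip(frame.columns, row))
        text = nfc(str(record[schema_map["text"]]))
        if not text.strip():
            dropped += 1
            continue
        doc_id = (
            nfc(str(record[schema_map["doc_id"]]))
            if "doc_id" in schema_map
            else f"{channel}-{i:06d}"
        )
        language = (
            nfc(str(record[schema_map["language"]])).strip().lower() or "und"
            if "language" in schema_map
            else "und"
        )
        documents.append(
            Document(
                doc_id=doc_id,
                text=text,
                date=_parse_date(
                    record.get(schema_map["date"]) if "date" in schema_map else None,
                    date_format,
                    doc_id,
                ),
                source=nfc(str(record[schema_map["source"]])) if "source" in schema_map else "",
                language=language,
                channel=channel,
            )
        )
    logger.info(
        "read %d documents from %s (%d empty rows dropped)", len(documents), path, dropped
    )
    return Corpus(tuple(documents), provenance=str(path))


# --- corpus serialization (used by the synthetic generator and CLI) ---

_CORPUS_COLUMNS = ("doc_id", "text", "date", "source", "language", "channel")


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as CSV or JSONL (chosen by extension).

    The written file round-trips through :func:`read_corpus` with the
    identity schema map.
    """
    path = Path(path)
    rows = [
        {
            "doc_id": d.doc_id,
            "text": d.text,
            "date": d.date.isoformat() if d.date else "",
            "source": d.source,
            "language": d.language,
            "channel": d.channel,
        }
        for d in corpus
    ]
    if path.suffix.lower() in {".jsonl", ".ndjson"}:
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, ensure_ascii=False, sort_keys=True) + "\n")
    else:
        pd.DataFrame(rows, columns=list(_CORPUS_COLUMNS)).to_csv(
            path, index=False, encoding="utf-8", lineterminator="\n"
        )


CORPUS_SCHEMA_MAP: Mapping[str, str] = {
    "doc_id": "doc_id", "text": "text", "date": "date",
    "source": "source", "language": "language",
}
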