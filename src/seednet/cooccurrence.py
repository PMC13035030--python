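"""Seed co-occurrence frequency statistic and pairwise sentence counts.

The statistic is conditional: for a lemma ℓ,

    freq(ℓ) = (# seed sentences containing ℓ) / (# seed sentences),

where a *seed sentence* is a sentence containing at least one seed
lemma.  This is the only reading of a "range 0–1" association frequency
under which 1.0 is attainable (a lemma present in every seed sentence).
Lemma multiplicity within a sentence is collapsed to presence/absence:
the statistic counts sentences, not token pairs.

Lemmas that never co-occur with a seed are simply absent from ``freq``
("crossed cells" in a tabular rendering); zero frequencies are never
stored.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .corpus import SeedLexicon
from .errors import NoSeedSentencesError
from .preprocessing import TokenizedSentence


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (lexicographic) key of an unordered lemma pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class CooccurrenceTable:
    """Per-lemma seed co-occurrence frequencies and pairwise counts.

    ``lemma_totals`` counts seed sentences per lemma and includes the
    seed lemmas themselves; ``freq`` excludes them (their conditional
    frequency is 1 by construction when a single seed is used, and
    uninformative otherwise).  ``pair_counts`` is keyed by lexicographic
    lemma pairs and covers seed lemmas too.
    """

    n_seed_sentences: int
    freq: Mapping[str, float]
    pair_counts: Mapping[tuple[str, str], int]
    lemma_totals: Mapping[str, int]
    seed_lemmas: frozenset[str] = field(default_factory=frozenset)

    def pair_count(self, a: str, b: str) -> int:
        return self.pair_counts.get(pair_key(a, b), 0)


def collect_seed_sentences(
    sentences: Iterable[TokenizedSentence],
) -> list[TokenizedSentence]:
    """Return exactly the sentences flagged ``contains_seed``, in order."""
    return [s for s in sentences if s.contains_seed]


def compute_frequencies(
    seed_sentences: Sequence[TokenizedSentence],
    lexicon: SeedLexicon,
) -> CooccurrenceTable:
    """Count seed-sentence occurrences and pairwise co-occurrences.

    Raises :class:`NoSeedSentencesError` on empty input — a corpus in
    which the seed terms never occur is a failed analysis, not an empty
    table.
    """
    if not seed_sentences:
        raise NoSeedSentencesError("no seed sentences found")
    totals: Counter[str] = Counter()
    pairs: Counter[tuple[str, str]] = Counter()
    for sent in seed_sentences:
        present = sorted(set(sent.lemmas))
        totals.update(present)
        pairs.update(combinations(present, 2))
    n = len(seed_sentences)
    freq = {
        lemma: count / n
        for lemma, count in totals.items()
        if lemma not in lexicon.seed_lemmas
    }
    return CooccurrenceTable(
        n_seed_sentences=n,
        freq=freq,
        pair_counts=dict(pairs),
        lemma_totals=dict(totals),
        seed_lemmas=frozenset(lexicon.seed_lemmas),
    )


def top_k_lemmas(table: CooccurrenceTable, k: int) -> list[tuple[str, float]]:
    """The ``k`` most seed-associated lemmas.

    Sorted by frequency descending; ties break lexicographically so the
    ranking is total and reproducible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(table.freq.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]
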