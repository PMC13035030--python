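"""Shared fixtures and independent oracles.

The oracles here are deliberately naive (double loops, exhaustive
set-partition enumeration, pair-counting ARI) and independent of the
package's implementation paths; they exist to pin down expected values,
not to be fast.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pytest

from seednet import RunConfig, SeedLexicon, SemanticNetwork, TokenizedSentence


@pytest.fixture
def lexicon() -> SeedLexicon:
    return SeedLexicon()


@pytest.fixture
def config() -> RunConfig:
    return RunConfig(rng_seed=0)


def make_sentences(
    lemma_lists: Iterable[Sequence[str]],
    seeds: frozenset[str] = frozenset({"fehlinformation", "desinformation"}),
    doc_id: str = "d0",
) -> list[TokenizedSentence]:
    """Build TokenizedSentence records from bare lemma lists."""
    return [
        TokenizedSentence(
            doc_id=doc_id,
            sent_index=i,
            lemmas=tuple(lemmas),
            contains_seed=bool(set(lemmas) & seeds),
        )
        for i, lemmas in enumerate(lemma_lists)
    ]


# ---------------------------------------------------------------- oracles

def brute_force_cooccurrence(
    sentence_lemmas: Sequence[Sequence[str]],
    seed_lemmas: frozenset[str],
):
    """Double-loop reference for the conditional frequency statistic.

    Returns (n_seed_sentences, freq, pair_counts, lemma_totals) computed
    with nothing but nested loops over sentences and vocabulary.
    """
    seed_sents = [set(s) for s in sentence_lemmas if set(s) & seed_lemmas]
    n = len(seed_sents)
    vocab = sorted({l for s in seed_sents for l in s})
    totals = {}
    for lemma in vocab:
        count = 0
        for s in seed_sents:
            if lemma in s:
                count += 1
        totals[lemma] = count
    freq = {l: c / n for l, c in totals.items() if l not in seed_lemmas}
    pairs = {}
    for a, b in combinations(vocab, 2):
        count = 0
        for s in seed_sents:
            if a in s and b in s:
                count += 1
        if count:
            pairs[(a, b)] = count
    return n, freq, pairs, totals


def set_partitions(items: Sequence):
    """Yield every set partition of ``items`` (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1:]
        yield [[first]] + partition


def nx_modularity(network: SemanticNetwork, blocks: list[list[str]],
                  gamma: float) -> float:
    """networkx as the independent modularity oracle."""
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    for (a, b), w in network.edges.items():
        g.add_edge(a, b, weight=float(w))
    return nx.community.modularity(
        g, [set(b) for b in blocks], weight="weight", resolution=gamma
    )


def exhaustive_best_partition(network: SemanticNetwork, gamma: float):
    """Globally optimal Q over all set partitions (independent oracle)."""
    best_q, best_blocks = -np.inf, None
    for blocks in set_partitions(sorted(network.nodes)):
        q = nx_modularity(network, blocks, gamma)
        if q > best_q:
            best_q, best_blocks = q, blocks
    return best_q, best_blocks


def pair_counting_ari(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Adjusted Rand index from the raw pair-counting contingency."""
    n = len(labels_a)
    same_a = same_b = same_both = 0
    for i, j in combinations(range(n), 2):
        a = labels_a[i] == labels_a[j]
        b = labels_b[i] == labels_b[j]
        same_a += a
        same_b += b
        same_both += a and b
    n_pairs = n * (n - 1) // 2
    expected = same_a * same_b / n_pairs if n_pairs else 0.0
    maximum = (same_a + same_b) / 2
    if maximum == expected:
        return 1.0
    return (same_both - expected) / (maximum - expected)


def make_network(edges: dict[tuple[str, str], float],
                 sizes: dict[str, float] | None = None) -> SemanticNetwork:
    nodes = sorted({n for e in edges for n in e})
    return SemanticNetwork(
        nodes={n: (sizes or {}).get(n, 1.0) for n in nodes}, edges=dict(edges)
    )


def triangle_pair() -> SemanticNetwork:
    """Two disjoint unit-weight triangles on nodes a..f."""
    return make_network({
        ("a", "b"): 1, ("a", "c"): 1, ("b", "c"): 1,
        ("d", "e"): 1, ("d", "f"): 1, ("e", "f"): 1,
    })


def random_small_network(rng: np.random.Generator, n_nodes: int,
                         p: float = 0.5, max_weight: int = 3) -> SemanticNetwork:
    names = [f"n{i}" for i in range(n_nodes)]
    edges = {}
    for a, b in combinations(names, 2):
        if rng.random() < p:
            edges[(a, b)] = int(rng.integers(1, max_weight + 1))
    if not edges:  # keep at least one edge so the graph is non-degenerate
        edges[(names[0], names[1])] = 1
    return make_network(edges)
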