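"""Weighted semantic network, modularity and Louvain clustering.

Nodes are lemmas sized by their seed co-occurrence frequency (seed
lemmas get size 1.0 — they are in every seed sentence by construction);
edge weights are sentence co-occurrence counts.  Thematic clusters are
modularity classes of the resolution-scaled Newman–Girvan quality

    Q_γ = Σ_c [ W_c / W  −  γ · (S_c / 2W)² ]

where ``W`` is the total edge weight of the graph, ``W_c`` the weight
inside community ``c``, ``S_c`` the summed weighted degree of its nodes
and ``γ`` the resolution parameter.  ``γ = 1`` recovers classic
modularity; ``γ < 1`` down-weights the null-model term and yields
coarser clusters (the pipeline default is 0.5).  Edge weights enter as
weights, not binarized: edge strength is meaningful here.

The optimizer is a from-scratch two-phase Louvain: greedy local moves
over nodes in a seeded-shuffled order until no move improves Q_γ, then
aggregation of communities into super-nodes, repeated until stable.
All tie-breaking is deterministic (keep the current community on a tied
gain, otherwise lowest community id), so a run is fully reproducible
from ``rng_seed``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cooccurrence import CooccurrenceTable, pair_key
from .corpus import RunConfig, SeedLexicon
from .errors import EmptyNetworkError, ValidationError


@dataclass(frozen=True)
class SemanticNetwork:
    """Undirected weighted lemma graph.

    ``nodes`` maps lemma → size (the node's frequency); ``edges`` maps
    lexicographically ordered lemma pairs → positive weight.  No
    self-loops; every edge endpoint is a node.
    """

    nodes: Mapping[str, float]
    edges: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValidationError(f"self-loop on {a!r}")
            if a not in self.nodes or b not in self.nodes:
                raise ValidationError(f"edge ({a!r}, {b!r}) has a missing endpoint")
            if w <= 0:
                raise ValidationError(f"non-positive weight on ({a!r}, {b!r})")

    @property
    def total_weight(self) -> float:
        return float(sum(self.edges.values()))

    def degrees(self, weighted: bool = True) -> dict[str, float]:
        deg = {n: 0.0 for n in self.nodes}
        for (a, b), w in self.edges.items():
            wt = float(w) if weighted else 1.0
            deg[a] += wt
            deg[b] += wt
        return deg


@dataclass(frozen=True)
class Partition:
    """A modularity-class assignment with its quality score."""

    assignment: Mapping[str, int]
    resolution: float
    modularity: float

    def __post_init__(self) -> None:
        ids = sorted(set(self.assignment.values()))
        if ids and ids != list(range(len(ids))):
            raise ValidationError("community ids must be dense integers from 0")
        if self.modularity > 1.0 + 1e-12:
            raise ValidationError("modularity cannot exceed 1")

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))


def build_network(
    table: CooccurrenceTable,
    lexicon: SeedLexicon,
    config: RunConfig,
) -> SemanticNetwork:
    """Build the semantic network from a co-occurrence table.

    Nodes: the seed lemmas (those observed in the corpus) plus every
    lemma with frequency ≥ ``config.min_node_freq``.  Edges: lemma
    pairs — including seed–lemma pairs — whose sentence co-occurrence
    count is ≥ ``config.min_edge_count``.  Non-seed nodes left without
    any edge are dropped; if no edge survives at all the network is
    empty and an :class:`EmptyNetworkError` is raised.
    """
    seeds_present = {s for s in lexicon.seed_lemmas if s in table.lemma_totals}
    candidates = set(seeds_present)
    candidates.update(
        lemma for lemma, f in table.freq.items() if f >= config.min_node_freq
    )
    threshold = max(config.min_edge_count, 1)
    edges: dict[tuple[str, str], float] = {}
    for (a, b), count in table.pair_counts.items():
        if count >= threshold and a in candidates and b in candidates:
            edges[pair_key(a, b)] = float(count)
    touched = {n for e in edges for n in e}
    nodes = {
        lemma: (1.0 if lemma in seeds_present else table.freq[lemma])
        for lemma in sorted(candidates)
        if lemma in touched or lemma in seeds_present
    }
    if not edges:
        raise EmptyNetworkError(
            "empty network: no edge meets min_edge_count="
            f"{config.min_edge_count}"
        )
    return SemanticNetwork(nodes=nodes, edges=edges)


def modularity(
    network: SemanticNetwork,
    partition: Partition | Mapping[str, int],
    resolution: float | None = None,
    weighted: bool = True,
) -> float:
    """Resolution-scaled Newman–Girvan modularity of a partition."""
    if isinstance(partition, Partition):
        assignment = partition.assignment
        gamma = partition.resolution if resolution is None else resolution
    else:
        assignment = partition
        if resolution is None:
            raise ValidationError("resolution required with a bare assignment")
        gamma = resolution
    for node in network.nodes:
        if node not in assignment:
            raise ValidationError(f"node {node!r} missing from partition")
    w_total = network.total_weight if weighted else float(len(network.edges))
    if w_total == 0:
        return 0.0
    intra: dict[int, float] = defaultdict(float)
    degree_sum: dict[int, float] = defaultdict(float)
    for (a, b), w in network.edges.items():
        wt = float(w) if weighted else 1.0
        ca, cb = assignment[a], assignment[b]
        degree_sum[ca] += wt
        degree_sum[cb] += wt
        if ca == cb:
            intra[ca] += wt
    q = 0.0
    for c in degree_sum:
        q += intra.get(c, 0.0) / w_total - gamma * (degree_sum[c] / (2.0 * w_total)) ** 2
    return q


def _local_moves(
    adjacency: list[dict[int, float]],
    degrees: list[float],
    m: float,
    gamma: float,
    order: Sequence[int],
) -> list[int]:
    """One Louvain level: greedy node moves until no gain remains.

    Gains are compared on the scale ΔQ·2m² = 2m·k_{i,c} − γ·S_c·k_i,
    which is exact for integer weights, so tie-breaking (keep current
    community, else lowest id) never depends on float round-off.
    """
    n = len(adjacency)
    comm = list(range(n))
    comm_degree = degrees.copy()
    while True:
        moved = 0
        for i in order:
            ci = comm[i]
            weight_to: dict[int, float] = defaultdict(float)
            for j, w in adjacency[i].items():
                weight_to[comm[j]] += w
            comm_degree[ci] -= degrees[i]
            best_comm = ci
            best_gain = 2.0 * m * weight_to.get(ci, 0.0) - gamma * comm_degree[ci] * degrees[i]
            for c in sorted(weight_to):
                if c == ci:
                    continue
                gain = 2.0 * m * weight_to[c] - gamma * comm_degree[c] * degrees[i]
                if gain > best_gain:
                    best_comm, best_gain = c, gain
                elif gain == best_gain and best_comm != ci and c < best_comm:
                    best_comm = c
            comm_degree[best_comm] += degrees[i]
            if best_comm != ci:
                comm[i] = best_comm
                moved += 1
        if moved == 0:
            return comm


def louvain(
    network: SemanticNetwork,
    config: RunConfig,
    weighted: bool = True,
    n_restarts: int = 10,
) -> Partition:
    """Multi-start two-phase Louvain maximization of Q_γ.

    Greedy Louvain is order-dependent and can stall in a local optimum,
    so the optimizer runs ``n_restarts`` independent passes whose node
    visiting orders are permutations drawn sequentially from a single
    generator seeded with ``config.rng_seed``, and keeps the partition
    with the highest Q_γ (first one found wins ties).  Identical seeds
    therefore give identical partitions.
    """
    if not network.nodes:
        raise EmptyNetworkError("cannot cluster an empty network")
    rng = np.random.default_rng(config.rng_seed)
    best: Partition | None = None
    for _ in range(max(1, n_restarts)):
        part = _louvain_once(network, config.resolution, rng, weighted)
        if best is None or part.modularity > best.modularity + 1e-15:
            best = part
    return best


def _louvain_once(
    network: SemanticNetwork,
    gamma: float,
    rng: np.random.Generator,
    weighted: bool,
) -> Partition:
    names = sorted(network.nodes)
    index = {name: i for i, name in enumerate(names)}
    n = len(names)
    adjacency: list[dict[int, float]] = [dict() for _ in range(n)]
    self_loops = [0.0] * n
    for (a, b), w in network.edges.items():
        wt = float(w) if weighted else 1.0
        adjacency[index[a]][index[b]] = adjacency[index[a]].get(index[b], 0.0) + wt
        adjacency[index[b]][index[a]] = adjacency[index[b]].get(index[a], 0.0) + wt
    m = sum(sum(d.values()) for d in adjacency) / 2.0
    if m == 0.0:
        assignment = {name: i for i, name in enumerate(names)}
        return Partition(assignment=assignment, resolution=gamma, modularity=0.0)

    node_to_comm = list(range(n))  # original node -> current super-node community
    while True:
        size = len(adjacency)
        degrees = [sum(adjacency[i].values()) + 2.0 * self_loops[i] for i in range(size)]
        order = [int(i) for i in rng.permutation(size)]
        comm = _local_moves(adjacency, degrees, m, gamma, order)
        labels = sorted(set(comm))
        if len(labels) == size:
            break
        relabel = {old: new for new, old in enumerate(labels)}
        comm = [relabel[c] for c in comm]
        node_to_comm = [comm[c] for c in node_to_comm]
        # aggregate communities into super-nodes
        k = len(labels)
        new_adj: list[dict[int, float]] = [dict() for _ in range(k)]
        new_self = [0.0] * k
        for i in range(size):
            ci = comm[i]
            new_self[ci] += self_loops[i]
            for j, w in adjacency[i].items():
                cj = comm[j]
                if ci == cj:
                    if i < j:
                        new_self[ci] += w
                else:
                    new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
        adjacency, self_loops = new_adj, new_self

    # densify final ids in order of first appearance over sorted node names
    final: dict[str, int] = {}
    dense: dict[int, int] = {}
    for name in names:
        c = node_to_comm[index[name]]
        if c not in dense:
            dense[c] = len(dense)
        final[name] = dense[c]
    q = modularity(network, final, resolution=gamma, weighted=weighted)
    return Partition(assignment=final, resolution=gamma, modularity=q)


@dataclass(frozen=True)
class ClusterInfo:
    """One ranked thematic cluster of the report."""

    cluster_id: int
    rank: int
    members: tuple[str, ...]  # sorted by node size descending, then lemma
    n_nodes: int
    total_size: float


def rank_clusters(
    partition: Partition,
    network: SemanticNetwork,
) -> list[ClusterInfo]:
    """Rank modularity classes by prominence.

    Largest node count first; ties broken by total node size
    (descending), then by the lexicographically smallest member.
    """
    members: dict[int, list[str]] = defaultdict(list)
    for node in network.nodes:
        if node not in partition.assignment:
            raise ValidationError(f"node {node!r} missing from partition")
        members[partition.assignment[node]].append(node)
    entries = []
    for cid, lemmas in members.items():
        ordered = tuple(sorted(lemmas, key=lambda l: (-network.nodes[l], l)))
        total = float(sum(network.nodes[l] for l in lemmas))
        entries.append((cid, ordered, len(lemmas), total))
    entries.sort(key=lambda e: (-e[2], -e[3], min(e[1])))
    return [
        ClusterInfo(cluster_id=cid, rank=r, members=ordered, n_nodes=n, total_size=total)
        for r, (cid, ordered, n, total) in enumerate(entries, start=1)
    ]
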