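"""Network construction, modularity closed forms, Louvain optimality, GEXF."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from conftest import (exhaustive_best_partition, make_network, make_sentences,
                      nx_modularity, random_small_network, triangle_pair)
from seednet import (EmptyNetworkError, Partition, RunConfig, SeedLexicon,
                     ValidationError, build_network, compute_frequencies,
                     louvain, modularity, rank_clusters, read_gexf,
                     write_gexf)

LEXICON = SeedLexicon()


def _cfg(resolution=1.0, seed=0, **kw):
    return RunConfig(resolution=resolution, rng_seed=seed, **kw)


class TestBuildNetwork:
    def _table(self):
        sents = make_sentences([
            ["fehlinformation", "a", "b"],
            ["fehlinformation", "a", "b"],
            ["desinformation", "b", "c"],
        ])
        return compute_frequencies(sents, LEXICON)

    def test_threshold_semantics_error_when_nothing_survives(self):
        table = self._table()
        with pytest.raises(EmptyNetworkError, match="empty network"):
            build_network(table, LEXICON, _cfg(min_edge_count=5))

    def test_edge_weights_are_sentence_counts(self):
        net = build_network(self._table(), LEXICON, _cfg(min_edge_count=1))
        assert net.edges[("a", "b")] == 2
        assert net.edges[("b", "c")] == 1
        # seed--lemma links carry their pair counts too
        assert net.edges[("a", "fehlinformation")] == 2

    def test_increasing_min_edge_count_never_adds_edges(self):
        table = self._table()
        edges1 = set(build_network(table, LEXICON, _cfg(min_edge_count=1)).edges)
        edges2 = set(build_network(table, LEXICON, _cfg(min_edge_count=2)).edges)
        assert edges2 <= edges1

    def test_seed_node_size_is_one_others_their_frequency(self):
        net = build_network(self._table(), LEXICON, _cfg())
        assert net.nodes["fehlinformation"] == 1.0
        assert net.nodes["a"] == pytest.approx(2 / 3)

    def test_min_node_freq_drops_rare_lemmas(self):
        net = build_network(self._table(), LEXICON, _cfg(min_node_freq=0.5))
        assert "c" not in net.nodes  # freq 1/3 < 0.5


class TestModularityClosedForms:
    def test_single_community_is_one_minus_gamma(self):
        for gamma in (0.25, 0.5, 1.0, 2.0):
            for net in (triangle_pair(),
                        random_small_network(np.random.default_rng(3), 6)):
                part = {n: 0 for n in net.nodes}
                assert modularity(net, part, resolution=gamma) == pytest.approx(
                    1.0 - gamma
                )

    def test_two_triangles_natural_partition_is_half(self):
        net = triangle_pair()
        part = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1}
        assert modularity(net, part, resolution=1.0) == pytest.approx(0.5)
        # exhaustive enumeration confirms 0.5 is the global optimum
        best_q, best_blocks = exhaustive_best_partition(net, 1.0)
        assert best_q == pytest.approx(0.5)
        assert sorted(map(sorted, best_blocks)) == [list("abc"), list("def")]

    def test_agrees_with_networkx_on_random_partitions(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            net = random_small_network(rng, int(rng.integers(3, 8)))
            labels = {n: int(rng.integers(0, 3)) for n in net.nodes}
            gamma = float(rng.uniform(0.2, 2.0))
            blocks: dict[int, list[str]] = {}
            for n, c in labels.items():
                blocks.setdefault(c, []).append(n)
            assert modularity(net, labels, resolution=gamma) == pytest.approx(
                nx_modularity(net, list(blocks.values()), gamma), abs=1e-12
            )

    def test_missing_node_raises_naming_it(self):
        net = triangle_pair()
        with pytest.raises(ValidationError, match="'f'"):
            modularity(net, {n: 0 for n in "abcde"}, resolution=1.0)

    def test_invariant_under_community_relabeling(self):
        net = triangle_pair()
        p1 = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1}
        p2 = {"a": 5, "b": 5, "c": 5, "d": 2, "e": 2, "f": 2}
        assert modularity(net, p1, resolution=0.7) == modularity(
            net, p2, resolution=0.7
        )


class TestLouvain:
    def test_recovers_two_triangles(self):
        part = louvain(triangle_pair(), _cfg(resolution=1.0))
        groups = {}
        for node, c in part.assignment.items():
            groups.setdefault(c, set()).add(node)
        assert sorted(map(sorted, groups.values())) == [list("abc"), list("def")]
        assert part.modularity == pytest.approx(0.5)

    def test_complete_graph_is_one_community(self):
        names = [f"k{i}" for i in range(5)]
        edges = {(a, b): 1 for i, a in enumerate(names) for b in names[i + 1:]}
        net = make_network(edges)
        best_q, _ = exhaustive_best_partition(net, 1.0)
        part = louvain(net, _cfg(resolution=1.0))
        assert part.n_communities == 1
        assert part.modularity == pytest.approx(best_q)

    def test_reported_q_is_self_consistent(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            net = random_small_network(rng, int(rng.integers(4, 9)))
            cfg = _cfg(resolution=float(rng.uniform(0.3, 1.5)), seed=trial)
            part = louvain(net, cfg)
            assert part.modularity == pytest.approx(
                modularity(net, part), abs=1e-12
            )

    def test_never_worse_than_singletons(self):
        rng = np.random.default_rng(13)
        for trial in range(10):
            net = random_small_network(rng, int(rng.integers(3, 9)), p=0.4)
            cfg = _cfg(resolution=float(rng.uniform(0.3, 2.0)), seed=trial)
            part = louvain(net, cfg)
            singletons = {n: i for i, n in enumerate(sorted(net.nodes))}
            assert part.modularity >= modularity(
                net, singletons, resolution=cfg.resolution
            ) - 1e-12

    def test_gamma_to_zero_merges_connected_graph(self):
        rng = np.random.default_rng(17)
        for trial in range(5):
            net = random_small_network(rng, 7, p=0.6)
            part = louvain(net, _cfg(resolution=1e-6, seed=trial))
            # ignore isolated nodes: they stay singletons with no pull
            touched = {n for e in net.edges for n in e}
            comms = {part.assignment[n] for n in touched}
            import networkx as nx
            g = nx.Graph(list(net.edges))
            if nx.is_connected(g):
                assert len(comms) == 1

    def test_determinism_same_seed_same_partition(self):
        net = random_small_network(np.random.default_rng(19), 8, p=0.5)
        a = louvain(net, _cfg(resolution=0.5, seed=42))
        b = louvain(net, _cfg(resolution=0.5, seed=42))
        assert a == b


class TestRankClusters:
    def _net_and_partition(self):
        sizes = {"a": 0.9, "b": 0.8, "c": 0.7, "d": 0.6, "e": 0.5,
                 "p": 0.4, "q": 0.3, "r": 0.2, "x": 0.9, "y": 0.1, "z": 0.1}
        edges = {("a", "b"): 1, ("b", "c"): 1, ("c", "d"): 1, ("d", "e"): 1,
                 ("p", "q"): 1, ("q", "r"): 1, ("x", "y"): 1, ("y", "z"): 1}
        net = make_network(edges, sizes)
        assignment = {"a": 0, "b": 0, "c": 0, "d": 0, "e": 0,
                      "p": 1, "q": 1, "r": 1, "x": 2, "y": 2, "z": 2}
        part = Partition(assignment=assignment, resolution=1.0, modularity=0.0)
        return net, part

    def test_size_then_total_size_then_lemma_rule(self):
        net, part = self._net_and_partition()
        report = rank_clusters(part, net)
        assert [c.n_nodes for c in report] == [5, 3, 3]
        # both 3-node clusters: {x,y,z} total 1.1 beats {p,q,r} total 0.9
        assert report[1].members[0] == "x"
        assert report[2].members[0] == "p"
        assert [c.rank for c in report] == [1, 2, 3]

    def test_members_sorted_by_size_descending(self):
        net, part = self._net_and_partition()
        report = rank_clusters(part, net)
        assert report[0].members == ("a", "b", "c", "d", "e")

    def test_singletons_rank_lexicographically(self):
        net = make_network({("a", "b"): 1, ("c", "d"): 1})
        part = Partition(
            assignment={"a": 0, "b": 1, "c": 2, "d": 3},
            resolution=1.0, modularity=0.0,
        )
        report = rank_clusters(part, net)
        assert [c.members[0] for c in report] == ["a", "b", "c", "d"]


class TestGexf:
    def test_roundtrip_exact(self, tmp_path):
        net = make_network({("a", "b"): 2, ("b", "c"): 1},
                           {"a": 0.5, "b": 1.0, "c": 0.25})
        part = {"a": 0, "b": 0, "c": 1}
        path = tmp_path / "net.gexf"
        write_gexf(net, part, path)
        net2, part2 = read_gexf(path)
        assert net2.nodes == net.nodes
        assert net2.edges == net.edges
        assert part2 == part

    def test_empty_partition_is_an_error(self, tmp_path):
        net = make_network({("a", "b"): 1})
        with pytest.raises(ValidationError):
            write_gexf(net, {}, tmp_path / "x.gexf")

    def test_byte_identical_across_runs(self, tmp_path):
        net = make_network({("a", "b"): 3, ("a", "c"): 1},
                           {"a": 1 / 3, "b": 2 / 3, "c": 0.125})
        part = {"a": 0, "b": 1, "c": 0}
        p1, p2 = tmp_path / "1.gexf", tmp_path / "2.gexf"
        write_gexf(net, part, p1)
        write_gexf(net, part, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_declares_gexf_13(self, tmp_path):
        net = make_network({("a", "b"): 1})
        path = tmp_path / "v.gexf"
        write_gexf(net, {"a": 0, "b": 0}, path)
        content = path.read_text(encoding="utf-8")
        assert 'version="1.3"' in content
        assert "http://gexf.net/1.3" in content
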