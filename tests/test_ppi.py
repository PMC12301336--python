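"""Biased random walks and skip-gram network embedding."""

import networkx as nx
import numpy as np
import pytest

from synfuse.ppi import (NodeEmbeddingTable, PPINetwork, WalkConfig,
                         embed_network, generate_biased_walks, train_skipgram,
                         transition_probs)


def path_graph():
    g = nx.Graph()
    g.add_edge("A", "B")
    g.add_edge("B", "C")
    return PPINetwork(g)


def two_cliques(k=6):
    g = nx.Graph()
    for base in (0, 100):
        for i in range(k):
            for j in range(i + 1, k):
                g.add_edge(f"G{base + i}", f"G{base + j}")
    g.add_edge("G0", "G100")
    return PPINetwork(g)


class TestTransitionProbs:
    def test_unbiased_path_step(self):
        nbrs, probs = transition_probs(path_graph(), "A", "B", WalkConfig())
        assert nbrs == ["A", "C"]
        assert np.allclose(probs, [0.5, 0.5])

    def test_inout_bias(self):
        _, probs = transition_probs(path_graph(), "A", "B", WalkConfig(q=0.5))
        assert np.allclose(probs, [1 / 3, 2 / 3])

    def test_triangle_all_positive(self):
        g = nx.complete_graph(3)
        net = PPINetwork(nx.relabel_nodes(g, str))
        _, probs = transition_probs(net, "0", "1", WalkConfig(p=2, q=0.3))
        assert np.all(probs > 0)

    def test_sums_to_one_vs_bruteforce_enumeration(self):
        """Exhaustive (prev, cur) states on random graphs up to 10 nodes."""
        rng = np.random.default_rng(0)
        for trial in range(5):
            g = nx.gnp_random_graph(rng.integers(4, 11), 0.5, seed=int(rng.integers(1e6)))
            net = PPINetwork(nx.relabel_nodes(g, str))
            cfg = WalkConfig(p=float(rng.uniform(0.2, 3)), q=float(rng.uniform(0.2, 3)))
            for u, v in g.edges:
                nbrs, probs = transition_probs(net, str(u), str(v), cfg)
                if not nbrs:
                    continue
                assert probs.sum() == pytest.approx(1.0, abs=1e-12)
                # brute force: recompute unnormalized weights independently
                raw = []
                for x in nbrs:
                    if x == str(u):
                        raw.append(1 / cfg.p)
                    elif g.has_edge(int(x), u):
                        raw.append(1.0)
                    else:
                        raw.append(1 / cfg.q)
                assert np.allclose(probs, np.array(raw) / np.sum(raw))


class TestWalks:
    def test_counts_and_start_coverage(self):
        net = two_cliques(4)
        cfg = WalkConfig(walks_per_node=3, walk_length=10, seed=0)
        walks = generate_biased_walks(net, cfg)
        assert len(walks) == 3 * net.n_nodes
        starts = {w[0] for w in walks}
        assert starts == set(net.nodes)

    def test_steps_follow_edges(self):
        net = two_cliques(4)
        for cfg in (WalkConfig(seed=1, walks_per_node=2, walk_length=8),
                    WalkConfig(seed=1, walks_per_node=2, walk_length=8, p=0.5, q=2.0)):
            for walk in generate_biased_walks(net, cfg):
                for a, b in zip(walk, walk[1:]):
                    assert net.graph.has_edge(a, b)

    def test_isolated_node_yields_length_one(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_node("LONER")
        walks = generate_biased_walks(PPINetwork(g), WalkConfig(walks_per_node=2,
                                                                walk_length=5, seed=0))
        loner_walks = [w for w in walks if w[0] == "LONER"]
        assert loner_walks and all(w == ["LONER"] for w in loner_walks)

    def test_deterministic_per_seed(self):
        net = two_cliques(5)
        cfg = WalkConfig(seed=7, walks_per_node=2, walk_length=12, p=0.7, q=1.3)
        assert generate_biased_walks(net, cfg) == generate_biased_walks(net, cfg)


class TestSkipgram:
    def test_dimension_contract(self):
        net = two_cliques(4)
        cfg = WalkConfig(dim=4, seed=0, walks_per_node=3, walk_length=10,
                         iterations=10)
        table = train_skipgram(generate_biased_walks(net, cfg), cfg)
        assert table.vectors.shape == (net.n_nodes, 4)
        assert np.isfinite(table.vectors).all()

    def test_deterministic_per_seed(self):
        net = two_cliques(4)
        cfg = WalkConfig(dim=8, seed=3, walks_per_node=3, walk_length=10,
                         iterations=15)
        t1 = train_skipgram(generate_biased_walks(net, cfg), cfg)
        t2 = train_skipgram(generate_biased_walks(net, cfg), cfg)
        assert np.array_equal(t1.vectors, t2.vectors)

    def test_uncovered_node_raises(self):
        walks = [["A", "B"], ["B", "A"]]
        with pytest.raises(ValueError, match="ORPHAN"):
            train_skipgram(walks, WalkConfig(dim=4), nodes=["A", "B", "ORPHAN"])

    def test_community_separation(self):
        """Within-clique cosine similarity beats cross-clique similarity."""
        net = two_cliques(6)
        cfg = WalkConfig(dim=16, seed=0, walks_per_node=10, walk_length=40,
                         window=5, iterations=150)
        table = embed_network(net, cfg)
        V = table.vectors / np.linalg.norm(table.vectors, axis=1, keepdims=True)
        idx = {g: i for i, g in enumerate(table.genes)}
        c1 = [idx[f"G{i}"] for i in range(6)]
        c2 = [idx[f"G{100 + i}"] for i in range(6)]
        S = V @ V.T
        within = np.mean([S[i, j] for c in (c1, c2) for i in c for j in c if i != j])
        cross = np.mean([S[i, j] for i in c1 for j in c2])
        assert within > cross


class TestEmbedNetwork:
    def test_cache_hit_bitwise_identical(self, tmp_path):
        net = two_cliques(4)
        cfg = WalkConfig(dim=8, seed=2, walks_per_node=2, walk_length=10,
                         iterations=10)
        t1 = embed_network(net, cfg, cache_dir=tmp_path)
        files = list(tmp_path.glob("ppi_embedding_*.npy"))
        assert len(files) == 1
        # poison the trainer: a cache hit must not recompute
        t2 = embed_network(net, cfg, cache_dir=tmp_path)
        assert np.array_equal(t1.vectors, t2.vectors)
        assert t1.genes == t2.genes

    def test_degenerate_edgeless_network(self, caplog):
        g = nx.Graph()
        g.add_nodes_from(["A", "B", "C"])
        cfg = WalkConfig(dim=4, seed=0, walks_per_node=2, walk_length=5,
                         iterations=5)
        with caplog.at_level("WARNING"):
            table = embed_network(PPINetwork(g), cfg)
        assert len(table) == 3
        assert "degenerate" in caplog.text

    def test_landmark_scale_node_count(self):
        """The full-shape network yields one embedding per landmark gene."""
        g = nx.barabasi_albert_graph(978, 2, seed=5)
        net = PPINetwork(nx.relabel_nodes(g, lambda i: f"G{i:04d}"))
        cfg = WalkConfig(dim=16, seed=0, walks_per_node=2, walk_length=10,
                         iterations=5)
        table = embed_network(net, cfg)
        assert len(table) == 978

    def test_missing_gene_gets_zero_vector(self, caplog):
        net = two_cliques(4)
        cfg = WalkConfig(dim=8, seed=0, walks_per_node=2, walk_length=10,
                         iterations=5)
        table = embed_network(net, cfg)
        with caplog.at_level("WARNING"):
            M = table.matrix_for(["G0", "NOT_IN_NET"])
        assert np.array_equal(M[1], np.zeros(8))
        assert "absent" in caplog.text
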