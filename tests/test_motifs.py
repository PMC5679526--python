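"""Motif ids, enumeration, null model and composition."""

import itertools

import networkx as nx
import numpy as np
import pytest

from loopmed import (
    canonical_id,
    compose_motifs,
    decode_motif_id,
    enumerate_subgraphs,
    motif_significance,
    randomize_graph,
    sample_subgraphs,
)

STAR4 = np.array([[0, 1, 1, 1], [0, 0, 0, 0], [0, 0, 0, 0], [0, 0, 0, 0]])
BIFAN = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [0, 0, 0, 0], [0, 0, 0, 0]])


def brute_force_counts(g: nx.DiGraph, k: int) -> dict[int, int]:
    """Oracle: loop over all C(n, k) subsets with a connectivity check."""
    und = nx.Graph(g)
    counts: dict[int, int] = {}
    for subset in itertools.combinations(g.nodes, k):
        if not nx.is_connected(und.subgraph(subset)):
            continue
        nodes = list(subset)
        adj = np.zeros((k, k), dtype=int)
        for i, u in enumerate(nodes):
            for j, v in enumerate(nodes):
                if i != j and g.has_edge(u, v):
                    adj[i, j] = 1
        cid = canonical_id(adj)
        counts[cid] = counts.get(cid, 0) + 1
    return counts


def random_digraph(n, p, seed):
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u in range(n):
        for v in range(n):
            if u != v and rng.random() < p:
                g.add_edge(u, v)
    return g


class TestCanonicalId:
    def test_single_source_star_is_14(self):
        assert canonical_id(STAR4) == 14

    def test_empty_graph_is_zero(self):
        assert canonical_id(np.zeros((3, 3), dtype=int)) == 0

    def test_invariant_under_relabeling(self, rng):
        for _ in range(500):
            k = int(rng.integers(3, 5))
            adj = (rng.random((k, k)) < 0.4).astype(int)
            np.fill_diagonal(adj, 0)
            perm = rng.permutation(k)
            assert canonical_id(adj) == canonical_id(adj[np.ix_(perm, perm)])

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            canonical_id(np.eye(3, dtype=int))


class TestDecode:
    def test_known_patterns(self):
        adj = decode_motif_id(14, 4)
        assert (adj[3] == [1, 1, 1, 0]).all() and adj[:3].sum() == 0
        assert (decode_motif_id(0, 3) == 0).all()

    def test_round_trip_all_canonical_3node_ids(self):
        canonical = set()
        for bits in itertools.product([0, 1], repeat=6):
            adj = np.zeros((3, 3), dtype=int)
            off = [(i, j) for i in range(3) for j in range(3) if i != j]
            for (i, j), b in zip(off, bits):
                adj[i, j] = b
            canonical.add(canonical_id(adj))
        for cid in canonical:
            assert canonical_id(decode_motif_id(cid, 3)) == cid

    def test_diagonal_bit_rejected(self):
        with pytest.raises(ValueError, match="simple"):
            decode_motif_id(1 << 8, 3)  # bit (0,0) of a 3x3 matrix


class TestEnumerate:
    def test_single_triad(self):
        g = nx.DiGraph([("m", "t"), ("m", "g"), ("t", "g")])
        counts = enumerate_subgraphs(g, 3)
        assert sum(counts.values()) == 1

    def test_disjoint_triads_pool_by_isomorphism(self):
        g = nx.DiGraph([("m", "t"), ("m", "g"), ("t", "g"),
                        ("M", "T"), ("M", "G"), ("T", "G")])
        counts = enumerate_subgraphs(g, 3)
        assert len(counts) == 1 and list(counts.values()) == [2]

    @pytest.mark.parametrize("k", [3, 4])
    def test_matches_brute_force_on_random_graphs(self, k):
        for seed in range(5):
            g = random_digraph(n=9 + seed % 4, p=0.18, seed=seed)
            assert enumerate_subgraphs(g, k) == brute_force_counts(g, k)

    def test_k_larger_than_graph(self):
        g = nx.DiGraph([("a", "b")])
        assert enumerate_subgraphs(g, 3) == {}


class TestSampleSubgraphs:
    def test_single_class_concentration_one(self):
        g = nx.DiGraph([("m", "t"), ("m", "g"), ("t", "g")])
        conc = sample_subgraphs(g, 3, n_samples=100, seed=0)
        assert list(conc.values()) == [1.0]

    def test_converges_to_exact_concentrations(self):
        g = random_digraph(10, 0.3, seed=3)
        exact = enumerate_subgraphs(g, 3)
        total = sum(exact.values())
        est = sample_subgraphs(g, 3, n_samples=50000, seed=1)
        assert abs(sum(est.values()) - 1.0) < 1e-9
        for cid, cnt in exact.items():
            assert est.get(cid, 0.0) == pytest.approx(cnt / total, abs=0.02)

    def test_deterministic_under_seed(self):
        g = random_digraph(12, 0.2, seed=5)
        assert sample_subgraphs(g, 3, 2000, seed=9) == sample_subgraphs(g, 3, 2000, seed=9)

    def test_invalid_sample_count(self):
        with pytest.raises(ValueError):
            sample_subgraphs(nx.DiGraph([("a", "b")]), 3, 0, seed=0)


class TestRandomize:
    def test_single_edge_unchanged(self):
        g = nx.DiGraph([("a", "b")])
        assert set(randomize_graph(g, seed=0).edges) == {("a", "b")}

    def test_degree_sequences_always_preserved(self, rng):
        for seed in range(20):
            g = random_digraph(15, 0.15, seed=seed)
            r = randomize_graph(g, seed=int(rng.integers(2**31)))
            assert dict(g.in_degree) == dict(r.in_degree)
            assert dict(g.out_degree) == dict(r.out_degree)
            assert not any(u == v for u, v in r.edges)

    def test_randomization_mixes(self):
        g = random_digraph(12, 0.25, seed=7)
        orig = set(g.edges)
        differing = sum(
            set(randomize_graph(g, seed=s).edges) != orig for s in range(100)
        )
        assert differing > 50


class TestSignificance:
    def test_low_count_never_significant(self):
        g = nx.DiGraph([("m", "t"), ("m", "g"), ("t", "g")])
        records = motif_significance(g, 3, n_random=50, seed=0)
        assert all(not r.significant for r in records)  # count 1 < 5

    def test_p_value_floor(self):
        g = random_digraph(12, 0.3, seed=2)
        for r in motif_significance(g, 3, n_random=100, seed=0):
            assert r.p >= 1.0 / 101

    def test_planted_bifan_detected(self):
        g = nx.DiGraph()
        for i in range(30):
            a, b, c, d = (f"{i}_{j}" for j in range(4))
            g.add_edges_from([(a, c), (a, d), (b, c), (b, d)])
        rng = np.random.default_rng(0)
        nodes = list(g.nodes)
        added = 0
        while added < 25:
            u, v = rng.choice(len(nodes), 2, replace=False)
            if not g.has_edge(nodes[u], nodes[v]):
                g.add_edge(nodes[u], nodes[v])
                added += 1
        records = motif_significance(g, 4, n_random=100, seed=1)
        rec = next(r for r in records if r.motif_id == canonical_id(BIFAN))
        assert rec.significant and rec.z >= 2 and rec.count >= 5


class TestCompose:
    def test_double_star_among_star_compositions(self):
        out = compose_motifs(14, 14)
        # two hubs sharing two of their three targets
        double = np.zeros((6, 6), dtype=int)
        double[0, [2, 3, 4]] = 1
        double[1, [2, 3, 5]] = 1
        target = canonical_id(double)
        assert target in {canonical_id(m) for m in out}

    def test_empty_motif_composes_to_nothing(self):
        assert compose_motifs(0, 14) == []

    def test_outputs_are_canonical(self):
        for m in compose_motifs(14, canonical_id(BIFAN)):
            assert canonical_id(m) == canonical_id(decode_motif_id(canonical_id(m), 6))

    def test_non_canonical_input_rejected(self):
        non_canonical = int("0111" "0000" "0000" "0000", 2)  # star, hub first
        assert canonical_id(decode_motif_id(non_canonical, 4)) == 14
        with pytest.raises(ValueError):
            compose_motifs(non_canonical, 14)
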