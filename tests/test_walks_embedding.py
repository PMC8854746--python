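import networkx as nx
import numpy as np
import pytest

from hetlink.heteronet import HeteroNetwork, assemble_network
from hetlink.io_formats import ValidationError
from hetlink.similarity import NODE_LNC, NODE_PROT
from hetlink.walks_embedding import (
    MetaPathScheme,
    WalkCorpus,
    generate_walks,
    pair_features,
    splice_node_features,
    train_embeddings,
    transition_distribution,
)

LPLPL = MetaPathScheme.from_string("LPLPL")
LLPPLL = MetaPathScheme.from_string("LLPPLL")


def star_network():
    """One lncRNA hub with four protein leaves."""
    return assemble_network([("L0", f"P{i}") for i in range(1, 5)])


class TestMetaPathScheme:
    def test_cycling_uses_first_equals_last(self):
        assert [LPLPL.type_at(i) for i in range(8)] == list("LPLPLPLP")
        assert [LLPPLL.type_at(i) for i in range(11)] == list("LLPPLLLPPLL")

    @pytest.mark.parametrize("bad", ["L", "LP", "LPLX"])
    def test_invalid_schemes_rejected(self, bad):
        with pytest.raises(ValidationError):
            MetaPathScheme.from_string(bad)


class TestTransitionDistribution:
    def test_uniform_over_typed_neighbors(self):
        net = star_network()
        dist = transition_distribution(net, "L0", NODE_PROT)
        assert dist == {f"P{i}": 0.25 for i in range(1, 5)}

    def test_no_admissible_neighbor_gives_empty_map(self):
        net = star_network()
        assert transition_distribution(net, "L0", NODE_LNC) == {}

    def test_unknown_node_rejected(self):
        with pytest.raises(ValidationError):
            transition_distribution(star_network(), "L9", NODE_PROT)

    def test_exhaustive_oracle_on_fixture(self, small_network):
        # independent oracle: scan raw graph edges for same-type endpoints
        g = small_network.graph
        for node in g.nodes:
            for required in (NODE_LNC, NODE_PROT):
                expected_support = sorted(
                    nb for nb in g.neighbors(node) if g.nodes[nb]["ntype"] == required
                )
                dist = transition_distribution(small_network, node, required)
                assert sorted(dist) == expected_support
                if expected_support:
                    assert all(p == 1 / len(expected_support) for p in dist.values())
                    assert sum(dist.values()) == pytest.approx(1.0)


class TestGenerateWalks:
    def test_star_graph_forces_alternation(self):
        corpus = generate_walks(star_network(), LPLPL, walks_per_node=5, walk_length=5, seed=0)
        assert len(corpus) == 5  # one start node of type L
        for walk in corpus.walks:
            assert len(walk) == 5
            assert [t for _, t in walk] == list("LPLPL")
            assert all(node == "L0" for (node, t) in walk if t == NODE_LNC)

    def test_walks_are_scheme_consistent(self, small_network):
        for scheme in (LPLPL, LLPPLL):
            corpus = generate_walks(small_network, scheme, walks_per_node=2, walk_length=20, seed=1)
            for walk in corpus.walks:
                for pos, (_, t) in enumerate(walk):
                    assert t == scheme.type_at(pos)

    def test_consecutive_nodes_are_adjacent(self, small_network):
        corpus = generate_walks(small_network, LLPPLL, walks_per_node=2, walk_length=15, seed=3)
        for walk in corpus.walks:
            for (u, _), (v, _) in zip(walk, walk[1:]):
                assert small_network.graph.has_edge(u, v)

    def test_removed_edge_never_appears_as_bigram(self, small_planted):
        pairs = list(small_planted.positive_pairs)
        held_out, rest = pairs[:3], pairs[3:]
        net = assemble_network(rest)
        corpus = generate_walks(net, LPLPL, walks_per_node=10, walk_length=40, seed=2)
        corpus.assert_excludes(held_out)  # must not raise
        assert not corpus.bigrams() & {frozenset(p) for p in held_out}

    def test_same_seed_reproduces_corpus(self, small_network):
        a = generate_walks(small_network, LPLPL, walks_per_node=3, walk_length=30, seed=8)
        b = generate_walks(small_network, LPLPL, walks_per_node=3, walk_length=30, seed=8)
        assert a.walks == b.walks

    def test_missing_start_type_rejected(self):
        g = nx.Graph()
        g.add_node("P1", ntype=NODE_PROT)
        net = HeteroNetwork(graph=g, variant="KNet")
        with pytest.raises(ValidationError, match="start type"):
            generate_walks(net, LPLPL, walks_per_node=1, walk_length=5, seed=0)

    def test_empirical_frequencies_match_transition_distribution(self, small_network):
        corpus = generate_walks(small_network, LPLPL, walks_per_node=40, walk_length=60, seed=4)
        counts: dict[tuple[str, str], dict[str, int]] = {}
        for walk in corpus.walks:
            for (u, _), (v, tv) in zip(walk, walk[1:]):
                counts.setdefault((u, tv), {}).setdefault(v, 0)
                counts[(u, tv)][v] += 1
        checked = 0
        for (u, tv), obs in counts.items():
            dist = transition_distribution(small_network, u, tv)
            assert set(obs) <= set(dist)  # support never exceeds admissible set
            n = sum(obs.values())
            if n < 300:
                continue
            for v, p in dist.items():
                se = (p * (1 - p) / n) ** 0.5
                assert abs(obs.get(v, 0) / n - p) <= 3 * se + 1e-9
            checked += 1
        assert checked > 0


class TestTrainEmbeddings:
    def test_vector_length_and_coverage(self, small_network):
        corpus = generate_walks(small_network, LPLPL, walks_per_node=3, walk_length=30, seed=0)
        emb = train_embeddings(corpus, dim=16, window=3, epochs=2, seed=0)
        assert all(len(v) == 16 for v in emb.values())
        walked = {n for walk in corpus.walks for n, _ in walk}
        assert set(emb) == walked

    def test_absent_nodes_get_zero_vectors(self, small_network):
        corpus = generate_walks(small_network, LPLPL, walks_per_node=2, walk_length=20, seed=0)
        emb = train_embeddings(corpus, dim=8, window=3, epochs=1, seed=0, all_nodes=["ZZZ"])
        assert np.array_equal(emb["ZZZ"], np.zeros(8, dtype=np.float32))

    def test_empty_corpus_rejected(self):
        empty = WalkCorpus(walks=[], scheme_names=("LPLPL",), walks_per_node=0, walk_length=0, seed=0)
        with pytest.raises(ValidationError):
            train_embeddings(empty, dim=8)

    def test_two_clique_structural_recovery(self):
        # two disjoint bicliques; within-clique cosine similarity should beat
        # between-clique similarity in a majority of seeds
        edges = [(f"La{i}", f"Pa{j}") for i in range(5) for j in range(3)]
        edges += [(f"Lb{i}", f"Pb{j}") for i in range(5) for j in range(3)]
        net = assemble_network(edges)
        wins = 0
        for seed in range(10):
            corpus = generate_walks(net, LPLPL, walks_per_node=10, walk_length=40, seed=seed)
            emb = train_embeddings(corpus, dim=16, window=3, epochs=3, seed=seed)
            names = sorted(emb)
            vecs = np.array([emb[n] for n in names])
            vecs = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
            cos = vecs @ vecs.T
            cliques = np.array([1 if n[1] == "a" else 0 for n in names])
            same = cliques[:, None] == cliques[None, :]
            off_diag = ~np.eye(len(names), dtype=bool)
            within = cos[same & off_diag].mean()
            between = cos[~same].mean()
            wins += within > between
        assert wins >= 6

    def test_fixed_seed_is_bit_reproducible(self, small_network):
        corpus = generate_walks(small_network, LPLPL, walks_per_node=3, walk_length=30, seed=5)
        a = train_embeddings(corpus, dim=16, window=3, epochs=2, seed=5)
        b = train_embeddings(corpus, dim=16, window=3, epochs=2, seed=5)
        assert set(a) == set(b)
        assert all(np.array_equal(a[k], b[k]) for k in a)


class TestSpliceAndPairFeatures:
    def test_splice_concatenates_kjnet_first(self):
        a = {"L1": np.ones(4, dtype=np.float32)}
        b = {"L1": np.full(4, 2.0, dtype=np.float32)}
        out = splice_node_features(a, b)
        assert np.array_equal(out["L1"], np.array([1, 1, 1, 1, 2, 2, 2, 2], dtype=np.float32))

    def test_splice_missing_half_is_zero_block(self):
        a = {"L1": np.ones(3, dtype=np.float32)}
        out = splice_node_features(a, {})
        assert np.array_equal(out["L1"], np.array([1, 1, 1, 0, 0, 0], dtype=np.float32))

    def test_splice_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            splice_node_features({"a": np.ones(3)}, {"b": np.ones(4)})

    def test_splice_doubles_dimension(self):
        a = {f"N{i}": np.random.default_rng(i).normal(size=64).astype(np.float32) for i in range(5)}
        out = splice_node_features(a, a)
        assert all(len(v) == 128 for v in out.values())

    def test_pair_features_hand_concatenation(self):
        feats = {
            "L1": np.array([1.0, 2.0], dtype=np.float32),
            "P1": np.array([3.0, 4.0], dtype=np.float32),
            "P2": np.zeros(2, dtype=np.float32),
        }
        fs = pair_features(feats, [("L1", "P1"), ("L1", "P2")], labels=[1, 0])
        assert fs.dim == 4
        assert np.array_equal(fs.features[0], np.array([1, 2, 3, 4], dtype=np.float32))
        assert np.array_equal(fs.features[1], np.array([1, 2, 0, 0], dtype=np.float32))
        assert fs.labels.tolist() == [1, 0]

    def test_pair_features_unknown_node_names_pair(self):
        with pytest.raises(ValidationError, match=r"\(L1, P9\)"):
            pair_features({"L1": np.zeros(2)}, [("L1", "P9")])


def test_corpus_write_text_and_merge(tmp_path, small_network):
    a = generate_walks(small_network, LPLPL, walks_per_node=1, walk_length=10, seed=0)
    b = generate_walks(small_network, LLPPLL, walks_per_node=1, walk_length=10, seed=0)
    merged = WalkCorpus.merge([a, b])
    assert len(merged) == len(a) + len(b)
    assert merged.scheme_names == ("LPLPL", "LLPPLL")
    path = tmp_path / "walks.txt"
    merged.write_text(path)
    lines = path.read_text().splitlines()
    assert len(lines) == len(merged)
    assert lines[0].split() == [n for n, _ in merged.walks[0]]
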