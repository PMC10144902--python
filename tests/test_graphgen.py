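"""Degree sampling, parity repair, and configuration-model stub matching."""

import collections
import itertools
import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from hetgraph.distribution import HeterogeneityParams, mean_degree, variance_degree
from hetgraph.graphgen import (
    DegreeSequence,
    configuration_model,
    generate_graph,
    largest_component,
    read_degree_sequence,
    read_edgelist,
    read_graphml,
    sample_degree_sequence,
    simplify,
    write_degree_sequence,
    write_edgelist,
    write_graphml,
)


def multigraph_key(g) -> tuple:
    """Canonical edge multiset of a multigraph (sorted unordered pairs)."""
    return tuple(sorted(tuple(sorted(e)) for e in g.edges()))


def enumerate_matchings(degrees):
    """Brute-force oracle: distribution over multigraphs under uniform
    stub matching, by enumerating every perfect matching of labeled stubs."""
    stubs = [i for i, d in enumerate(degrees) for _ in range(d)]

    def match(remaining):
        if not remaining:
            yield ()
            return
        first, rest = remaining[0], remaining[1:]
        for j in range(len(rest)):
            pair = tuple(sorted((stubs[first], stubs[rest[j]])))
            for tail in match(rest[:j] + rest[j + 1 :]):
                yield (pair,) + tail

    counts = collections.Counter(
        tuple(sorted(m)) for m in match(tuple(range(len(stubs))))
    )
    total = sum(counts.values())
    return {key: Fraction(c, total) for key, c in counts.items()}


class TestDegreeSequenceType:
    def test_odd_sum_rejected(self):
        with pytest.raises(ValueError, match="even"):
            DegreeSequence((1, 1, 1))

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            DegreeSequence((2, -1, 1))

    def test_valid_sequence(self):
        seq = DegreeSequence((3, 2, 1))
        assert seq.N == 3
        assert sum(seq.degrees) % 2 == 0


class TestSampleDegreeSequence:
    def test_even_sum_and_length(self, rng):
        seq = sample_degree_sequence(HeterogeneityParams(0.5, 5.0), 101, rng)
        assert seq.N == 101
        assert sum(seq.degrees) % 2 == 0

    def test_deterministic(self, rng_factory):
        p = HeterogeneityParams(0.5, 5.0)
        a = sample_degree_sequence(p, 50, rng_factory(3))
        b = sample_degree_sequence(p, 50, rng_factory(3))
        assert a.degrees == b.degrees

    def test_regular_limit(self, rng):
        """sigma -> 0 yields a lambda-regular degree sequence."""
        seq = sample_degree_sequence(HeterogeneityParams(1e-40, 5.0), 100, rng)
        degs = seq.as_array()
        # parity repair may perturb one node by 1
        assert np.sum(degs == 5) >= 99

    def test_cap_applied(self, rng):
        seq = sample_degree_sequence(HeterogeneityParams(0.9, 5.0), 50, rng, cap=10)
        assert max(seq.degrees) <= 10

    def test_parity_repair_counted_and_preserves_cap(self, rng_factory):
        # scan seeds until a repair triggers; the repaired sum must be even
        p = HeterogeneityParams(0.5, 5.0)
        hit = False
        for seed in range(40):
            seq = sample_degree_sequence(p, 21, rng_factory(seed))
            assert sum(seq.degrees) % 2 == 0
            assert max(seq.degrees) <= 20
            hit = hit or seq.n_parity_repairs == 1
        assert hit, "no odd-sum draw in 40 seeds (p ~ 2^-40)"

    def test_small_N_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_degree_sequence(HeterogeneityParams(0.5, 5.0), 1, rng)

    def test_min_degree_clamp(self, rng):
        seq = sample_degree_sequence(
            HeterogeneityParams(0.9, 5.0), 200, rng, min_degree=1
        )
        assert min(seq.degrees) >= 1


class TestConfigurationModel:
    def test_single_edge(self, rng):
        g = configuration_model(DegreeSequence((1, 1)), rng)
        assert multigraph_key(g) == ((0, 1),)

    def test_forced_self_loop(self, rng):
        g = configuration_model(DegreeSequence((2,)), rng)
        assert multigraph_key(g) == ((0, 0),)

    @pytest.mark.parametrize("sigma", [0.2, 0.5, 0.9])
    def test_degree_preservation_and_handshake(self, rng, sigma):
        seq = sample_degree_sequence(HeterogeneityParams(sigma, 5.0), 300, rng)
        g = configuration_model(seq, rng)
        degs = dict(g.degree())  # networkx counts a self-loop as 2
        assert [degs[i] for i in range(seq.N)] == list(seq.degrees)
        assert 2 * g.number_of_edges() == sum(seq.degrees)

    @pytest.mark.parametrize("degrees", [(1, 1, 1, 1), (2, 1, 1), (2, 2)])
    def test_uniform_matching_against_enumeration(self, rng, degrees):
        """Outcome frequencies over 10^4 runs match the brute-force
        enumeration of stub pairings within 3-sigma multinomial bands."""
        expected = enumerate_matchings(degrees)
        n_runs = 10_000
        counts = collections.Counter(
            multigraph_key(configuration_model(DegreeSequence(degrees), rng))
            for _ in range(n_runs)
        )
        assert set(counts) <= set(expected)
        for key, p in expected.items():
            p = float(p)
            band = 3 * math.sqrt(p * (1 - p) / n_runs)
            assert abs(counts[key] / n_runs - p) <= band, key

    def test_matches_networkx_degree_sequence(self, rng):
        """Cross-check: networkx's configuration model realizes the same
        degree sequence our matcher does."""
        degrees = (4, 3, 3, 2, 1, 1)
        ours = configuration_model(DegreeSequence(degrees), rng)
        theirs = nx.configuration_model(list(degrees), seed=1)
        assert sorted(d for _, d in ours.degree()) == sorted(
            d for _, d in theirs.degree()
        )


class TestSimplifyAndComponents:
    def test_simplify_collapses_and_flags(self, rng):
        g = nx.MultiGraph([(0, 1), (0, 1), (1, 2), (2, 0), (2, 2)])
        s = simplify(g)
        assert sorted(s.edges()) == [(0, 1), (0, 2), (1, 2)]
        assert s.graph["simplified"] is True

    def test_simplify_self_loop_graph_to_isolated_node(self, rng):
        g = configuration_model(DegreeSequence((2,)), rng)
        s = simplify(g)
        assert s.number_of_nodes() == 1 and s.number_of_edges() == 0

    def test_simplify_idempotent_on_simple_graph(self):
        g = nx.MultiGraph([(0, 1), (1, 2)])
        assert sorted(simplify(g).edges()) == sorted(simplify(simplify(g)).edges())

    def test_largest_component_selection(self):
        g = nx.MultiGraph([(0, 1), (0, 2), (3, 4)])
        g.add_node(5)
        sub = largest_component(g)
        assert sorted(sub.nodes()) == [0, 1, 2]
        assert sub.graph["component_nodes"] == (0, 1, 2)

    def test_largest_component_tie_break_smallest_min_id(self):
        g = nx.MultiGraph([(2, 3), (0, 1)])
        assert sorted(largest_component(g).nodes()) == [0, 1]

    def test_connected_graph_is_its_own_component(self):
        g = nx.MultiGraph([(0, 1), (1, 2)])
        assert sorted(largest_component(g).nodes()) == [0, 1, 2]


class TestGenerateGraph:
    def test_regular_limit_graph(self, rng):
        g = generate_graph(HeterogeneityParams(1e-40, 5.0), 200, rng)
        degs = np.array([d for _, d in g.degree()])
        assert np.mean(degs == 5) >= 0.99

    def test_mean_degree_matches_theory(self, rng):
        p = HeterogeneityParams(0.5, 5.0)
        g = generate_graph(p, 1000, rng)
        degs = np.array([d for _, d in g.degree()])
        se = math.sqrt(variance_degree(p) / 1000)
        assert abs(degs.mean() - mean_degree(p)) < 4 * se

    def test_determinism_byte_identical_edge_list(self, rng_factory, tmp_path):
        p = HeterogeneityParams(0.5, 5.0)
        paths = []
        for tag in ("a", "b"):
            g = generate_graph(p, 100, rng_factory(9))
            path = tmp_path / f"{tag}.edges"
            write_edgelist(g, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_provenance_recorded(self, rng):
        g = generate_graph(HeterogeneityParams(0.3, 5.0), 50, rng, simplified=True)
        assert g.graph["sigma"] == 0.3
        assert g.graph["lam"] == 5.0
        assert g.graph["simplified"] is True

    def test_heterogeneity_ordering(self):
        """Empirical degree variance strictly increases with sigma."""
        lam, N = 5.0, 2000
        mean_vars = []
        for i, sigma in enumerate([0.05, 0.3, 0.6, 0.9]):
            p = HeterogeneityParams(sigma, lam)
            vs = []
            for seed in range(10):
                rng = np.random.default_rng(1000 * i + seed)
                seq = sample_degree_sequence(p, N, rng)
                vs.append(seq.as_array().var(ddof=0))
            mean_vars.append(np.mean(vs))
        assert all(a < b for a, b in zip(mean_vars, mean_vars[1:]))


class TestIO:
    def test_edgelist_round_trip(self, rng, tmp_path):
        g = generate_graph(HeterogeneityParams(0.5, 5.0), 60, rng)
        path = tmp_path / "g.edges"
        write_edgelist(g, path)
        h = read_edgelist(path, N=60)
        assert multigraph_key(h) == multigraph_key(g)

    def test_graphml_round_trip(self, rng, tmp_path):
        g = generate_graph(HeterogeneityParams(0.5, 5.0), 30, rng)
        path = tmp_path / "g.graphml"
        write_graphml(g, path)
        h = read_graphml(path)
        assert multigraph_key(h) == multigraph_key(g)
        assert float(h.graph["sigma"]) == pytest.approx(0.5)

    def test_degree_sequence_round_trip(self, rng, tmp_path):
        seq = sample_degree_sequence(HeterogeneityParams(0.5, 5.0), 40, rng)
        path = tmp_path / "degs.txt"
        write_degree_sequence(seq, path)
        assert read_degree_sequence(path).degrees == seq.degrees
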