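"""Configuration-model graph generation at a prescribed heterogeneity.

Pipeline: draw N degrees from the modified Weibull distribution, round to
integers (half-up), clip at a degree cap, repair parity so the stub count
is even, then match stubs uniformly at random.  The result is a
``networkx.MultiGraph`` (self-loops and parallel edges permitted) whose
degree sequence equals the input exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from hetgraph.distribution import HeterogeneityParams, sample

__all__ = [
    "DegreeSequence",
    "sample_degree_sequence",
    "configuration_model",
    "simplify",
    "largest_component",
    "generate_graph",
    "write_edgelist",
    "read_edgelist",
    "write_graphml",
    "read_graphml",
    "write_degree_sequence",
    "read_degree_sequence",
]


@dataclass(frozen=True)
class DegreeSequence:
    """An even-sum sequence of N non-negative integer degrees.

    ``n_parity_repairs`` and ``n_cap_clips`` record the silently applied
    repairs so callers can log them.
    """

    degrees: tuple
    n_parity_repairs: int = 0
    n_cap_clips: int = 0
    N: int = field(init=False)

    def __post_init__(self) -> None:
        degs = tuple(int(d) for d in self.degrees)
        if len(degs) == 0:
            raise ValueError("degree sequence must be non-empty")
        if any(d < 0 for d in degs):
            raise ValueError("degrees must be non-negative")
        if sum(degs) % 2 != 0:
            raise ValueError(
                "sum of degrees must be even (an odd stub count cannot be "
                "fully matched)"
            )
        object.__setattr__(self, "degrees", degs)
        object.__setattr__(self, "N", len(degs))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.degrees, dtype=np.int64)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round is banker's rounding; half-up keeps the rule bit-reproducible
    return np.floor(x + 0.5).astype(np.int64)


def sample_degree_sequence(
    params: HeterogeneityParams,
    N: int,
    rng: np.random.Generator,
    cap: int | None = None,
    min_degree: int = 0,
) -> DegreeSequence:
    """Sample, round, clip, and parity-repair a degree sequence.

    Parameters
    ----------
    params : HeterogeneityParams
    N : int
        Node count, >= 2.
    rng : numpy.random.Generator
    cap : int, optional
        Maximum permitted degree; defaults to ``N - 1`` (a simple graph
        cannot exceed it).  Samples above the cap are clipped and counted.
    min_degree : int, default 0
        Optional floor; zero degrees (isolated nodes) are legal by default.

    Returns
    -------
    DegreeSequence
        Even-sum sequence of length N.  If the rounded degrees summed to an
        odd number, one node chosen uniformly at random has its degree
        incremented by 1 (minimal perturbation).
    """
    if not isinstance(N, (int, np.integer)) or N < 2:
        raise ValueError(f"N must be an integer >= 2, got {N!r}")
    if cap is None:
        cap = int(N) - 1
    if cap < 1:
        raise ValueError(f"degree cap must be >= 1, got {cap!r}")
    raw = sample(params, int(N), rng)
    degs = _round_half_up(raw)
    if min_degree > 0:
        degs = np.maximum(degs, min_degree)
    n_clips = int(np.count_nonzero(degs > cap))
    degs = np.minimum(degs, cap)
    n_repairs = 0
    if int(degs.sum()) % 2 != 0:
        i = int(rng.integers(0, N))
        # stay within the cap: decrement instead if the chosen node is full
        if degs[i] >= cap:
            degs[i] -= 1
        else:
            degs[i] += 1
        n_repairs = 1
    return DegreeSequence(tuple(int(d) for d in degs), n_repairs, n_clips)


def configuration_model(
    seq: DegreeSequence, rng: np.random.Generator
) -> nx.MultiGraph:
    """Uniform stub matching: the plain configuration model.

    Node ``i`` contributes ``seq.degrees[i]`` stubs; the stub multiset is
    shuffled uniformly and consecutive entries are paired, which is
    distributionally identical to repeatedly picking two remaining stubs
    uniformly at random.  Self-loops and parallel edges are kept, so the
    multigraph degree of every node (self-loop counting 2) equals its
    sequence entry exactly.
    """
    degs = seq.as_array()
    if int(degs.sum()) % 2 != 0:  # unreachable through the type, kept defensive
        raise ValueError("requires an even number of stubs (even degree sum)")
    stubs = np.repeat(np.arange(seq.N, dtype=np.int64), degs)
    rng.shuffle(stubs)
    g = nx.MultiGraph()
    g.add_nodes_from(range(seq.N))
    g.add_edges_from(zip(stubs[0::2].tolist(), stubs[1::2].tolist()))
    return g


def simplify(g: nx.MultiGraph) -> nx.Graph:
    """Collapse parallel edges and drop self-loops; flags the result.

    The degree sequence may shrink; the returned simple graph carries
    ``graph['simplified'] = True``.
    """
    sg = nx.Graph(g)
    sg.remove_edges_from(nx.selfloop_edges(sg))
    sg.graph.update(g.graph)
    sg.graph["simplified"] = True
    return sg


def largest_component(g):
    """Induced subgraph on the largest connected component.

    Ties are broken by the smallest minimum node id.  Original node ids are
    preserved and the component's node set is recorded in
    ``graph['component_nodes']``.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    nodes = comps[0]
    sub = g.subgraph(nodes).copy()
    sub.graph.update(g.graph)
    sub.graph["component_nodes"] = tuple(sorted(nodes))
    return sub


def generate_graph(
    params: HeterogeneityParams,
    N: int,
    rng: np.random.Generator,
    *,
    cap: int | None = None,
    min_degree: int = 0,
    simplified: bool = False,
    giant_only: bool = False,
):
    """Full G(sigma, lam, N) pipeline with provenance.

    Composition of :func:`sample_degree_sequence` and
    :func:`configuration_model`, with optional simplification and
    giant-component extraction.  Provenance (sigma, lam, N, options, repair
    counts) is stored in ``graph.graph``.
    """
    seq = sample_degree_sequence(params, N, rng, cap=cap, min_degree=min_degree)
    g = configuration_model(seq, rng)
    g.graph.update(
        sigma=params.sigma,
        lam=params.lam,
        N=int(N),
        simplified=False,
        giant_only=bool(giant_only),
        n_parity_repairs=seq.n_parity_repairs,
        n_cap_clips=seq.n_cap_clips,
    )
    if simplified:
        g = simplify(g)
    if giant_only:
        g = largest_component(g)
    return g


# ---------------------------------------------------------------------------
# plain-text graph I/O


def write_edgelist(g, path) -> None:
    """One 'u v' pair per line; multiplicity by repetition, self-loop as 'v v'."""
    with open(path, "w") as fh:
        for u, v in g.edges():
            fh.write(f"{u} {v}\n")


def read_edgelist(path, N: int | None = None) -> nx.MultiGraph:
    """Read a whitespace-separated edge list into a MultiGraph.

    ``N`` adds isolated nodes 0..N-1 that the edge list cannot represent.
    """
    g = nx.MultiGraph()
    if N is not None:
        g.add_nodes_from(range(int(N)))
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            u, v = int(parts[0]), int(parts[1])
            g.add_edge(u, v)
    return g


def write_graphml(g, path) -> None:
    """GraphML writer; provenance in ``graph.graph`` becomes graph attributes."""
    h = g.copy()
    h.graph = {
        k: (repr(v) if not isinstance(v, (str, int, float, bool)) else v)
        for k, v in g.graph.items()
    }
    nx.write_graphml(h, path)


def read_graphml(path):
    return nx.read_graphml(path, node_type=int)


def write_degree_sequence(seq: DegreeSequence, path) -> None:
    """One integer per line."""
    with open(path, "w") as fh:
        for d in seq.degrees:
            fh.write(f"{d}\n")


def read_degree_sequence(path) -> DegreeSequence:
    with open(path) as fh:
        degs = [int(line) for line in fh if line.strip()]
    return DegreeSequence(tuple(degs))
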