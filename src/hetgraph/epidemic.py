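"""Discrete-time stochastic SIR on generated graphs and the herd immunity
threshold (HIT).

The HIT is the fraction (I + R)/N of the population that has been infected
by the time infections peak — the discrete analogue of reading off I + R at
dI/dt = 0.  On heterogeneous contact networks this quantity is highly
sensitive to the degree distribution, which is the point of sweeping it
against the heterogeneity parameter sigma.

Dynamics per step (synchronous update):

1. every edge joining a currently infected node to a currently susceptible
   node transmits independently with probability tau — parallel edges give
   independent chances, self-loops never transmit;
2. every node infected *before* this step recovers with probability gamma
   (a node cannot recover in the step it is infected).

The per-node infection probability given m infectious edges is
``1 - (1 - tau)^m``, which is how the transmission sweep is vectorized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from hetgraph.distribution import HeterogeneityParams
from hetgraph.graphgen import generate_graph

__all__ = [
    "SIRParams",
    "EpidemicTrace",
    "run_sir",
    "herd_immunity_threshold",
    "sir_sweep",
    "summarize_sweep",
    "child_rng",
]


@dataclass(frozen=True)
class SIRParams:
    """Epidemic parameters.

    Attributes
    ----------
    tau : float
        Transmission probability per infected-susceptible edge per step,
        in [0, 1].
    gamma : float
        Recovery probability per infected node per step, in [0, 1].
        Default 0.2 (mean infectious period of 5 steps).
    epsilon : float
        Initially infected fraction, in (0, 1); ceil(epsilon * N) nodes are
        seeded.  Default 0.01.
    T : int
        Maximum number of steps.  Default ``10 * ceil(1/gamma)``.
    seed : int or None
        RNG seed used when :func:`run_sir` is not handed a generator.
    """

    tau: float
    gamma: float = 0.2
    epsilon: float = 0.01
    T: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau <= 1.0):
            raise ValueError(f"tau must lie in [0, 1], got {self.tau!r}")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma!r}")
        if not (0.0 < self.epsilon < 1.0):
            raise ValueError(f"epsilon must lie in (0, 1), got {self.epsilon!r}")
        if self.T is None:
            horizon = 10 * math.ceil(1.0 / self.gamma) if self.gamma > 0 else 50
            object.__setattr__(self, "T", horizon)
        if not isinstance(self.T, (int, np.integer)) or self.T < 1:
            raise ValueError(f"T must be a positive integer, got {self.T!r}")


@dataclass(frozen=True)
class EpidemicTrace:
    """Per-step (S_t, I_t, R_t) counts for one SIR realization.

    ``counts`` has shape (t_end + 1, 3); row t is the state after t steps
    (row 0 is the initial condition).  Invariants: S + I + R = N at every
    step, S non-increasing, R non-decreasing; the trace ends when I hits 0
    or the horizon T is reached.
    """

    counts: np.ndarray
    N: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 1:
            raise ValueError("counts must be a (t_end+1, 3) array")
        if np.any(c.sum(axis=1) != self.N):
            raise ValueError("S + I + R must equal N at every step")
        object.__setattr__(self, "counts", c)

    @property
    def t_end(self) -> int:
        return self.counts.shape[0] - 1

    @property
    def S(self) -> np.ndarray:
        return self.counts[:, 0]

    @property
    def I(self) -> np.ndarray:
        return self.counts[:, 1]

    @property
    def R(self) -> np.ndarray:
        return self.counts[:, 2]


def _adjacency_no_loops(g) -> "np.ndarray | object":
    """Adjacency with edge multiplicities and zeroed diagonal, as CSR."""
    a = nx.to_scipy_sparse_array(g, nodelist=sorted(g.nodes()), format="csr")
    a.setdiag(0)
    a.eliminate_zeros()
    return a


def run_sir(g, params: SIRParams, rng: np.random.Generator | None = None) -> EpidemicTrace:
    """Run one stochastic SIR realization on a graph.

    ceil(epsilon * N) nodes chosen uniformly without replacement start
    Infected, the rest Susceptible.  Steps are synchronous; the run stops
    as soon as no node is infected or after T steps.  A fixed generator
    state yields an identical trace.
    """
    N = g.number_of_nodes()
    if N == 0:
        raise ValueError("graph is empty")
    n0 = math.ceil(params.epsilon * N)
    if n0 < 1 or n0 > N:
        raise ValueError(
            f"initial infected count ceil(epsilon*N) = {n0} must lie in [1, N={N}]"
        )
    if rng is None:
        rng = np.random.default_rng(params.seed)

    adj = _adjacency_no_loops(g)
    # states: 0 susceptible, 1 infected, 2 recovered
    state = np.zeros(N, dtype=np.int8)
    seeds = rng.choice(N, size=n0, replace=False)
    state[seeds] = 1

    rows = [(N - n0, n0, 0)]
    log1m_tau = math.log1p(-params.tau) if params.tau < 1.0 else -math.inf
    for _ in range(params.T):
        infected = state == 1
        n_inf = int(infected.sum())
        if n_inf == 0:
            break
        susceptible = state == 0
        # infectious pressure: number of edges (with multiplicity) to infected
        m = adj @ infected.astype(np.float64)
        if params.tau >= 1.0:
            p_inf = (m > 0).astype(np.float64)
        else:
            p_inf = -np.expm1(m * log1m_tau)  # 1 - (1-tau)^m
        u = rng.random(N)
        newly_infected = susceptible & (u < p_inf)
        # recoveries apply only to nodes infected before this step
        v = rng.random(N)
        recovers = infected & (v < params.gamma)
        state[newly_infected] = 1
        state[recovers] = 2
        rows.append(
            (
                int((state == 0).sum()),
                int((state == 1).sum()),
                int((state == 2).sum()),
            )
        )
    return EpidemicTrace(np.asarray(rows, dtype=np.int64), N)


def herd_immunity_threshold(trace: EpidemicTrace) -> float:
    """(I + R)/N at the first step where I attains its maximum.

    The earliest maximizer is the discrete stand-in for the dI/dt = 0 peak
    condition; ties break to the earliest step.
    """
    t_star = int(np.argmax(trace.I))  # argmax returns the first maximizer
    return float((trace.I[t_star] + trace.R[t_star]) / trace.N)


def child_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-cell generator derived from a master seed.

    Uses ``SeedSequence(master_seed, spawn_key=key)`` so that extending a
    sweep (more replicates, more grid points) never perturbs the streams of
    cells that already existed.
    """
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=tuple(int(k) for k in key))
    )


def sir_sweep(
    sigma_grid: Sequence[float],
    lam: float,
    tau_grid: Sequence[float],
    N: int,
    n_reps: int,
    master_seed: int,
    *,
    gamma: float = 0.2,
    epsilon: float = 0.01,
    T: int | None = None,
    reuse_graph: bool = False,
    simplified: bool = False,
    giant_only: bool = False,
) -> pd.DataFrame:
    """HIT over a (sigma, tau) grid with n_reps replicates per cell.

    By default a fresh graph is generated per replicate, so replicate
    variance includes graph variance; ``reuse_graph=True`` generates one
    graph per sigma and reuses it across tau and replicates.

    Returns
    -------
    DataFrame with columns ``sigma, tau, replicate, hit``, one row per
    realization.  Use :func:`summarize_sweep` for per-cell means.
    """
    if len(sigma_grid) == 0 or len(tau_grid) == 0:
        raise ValueError("sigma and tau grids must be non-empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    records = []
    for i_s, sigma in enumerate(sigma_grid):
        params = HeterogeneityParams(sigma=sigma, lam=lam)
        fixed_graph = None
        if reuse_graph:
            fixed_graph = generate_graph(
                params,
                N,
                child_rng(master_seed, i_s),
                simplified=simplified,
                giant_only=giant_only,
            )
        for i_t, tau in enumerate(tau_grid):
            sir = SIRParams(tau=tau, gamma=gamma, epsilon=epsilon, T=T)
            for rep in range(n_reps):
                rng = child_rng(master_seed, i_s, i_t, rep)
                if reuse_graph:
                    g = fixed_graph
                else:
                    g = generate_graph(
                        params,
                        N,
                        rng,
                        simplified=simplified,
                        giant_only=giant_only,
                    )
                trace = run_sir(g, sir, rng)
                records.append(
                    {
                        "sigma": float(sigma),
                        "tau": float(tau),
                        "replicate": rep,
                        "hit": herd_immunity_threshold(trace),
                    }
                )
    return pd.DataFrame.from_records(records)


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(sigma, tau) mean HIT with standard error and replicate count."""
    grouped = table.groupby(["sigma", "tau"])["hit"]
    out = grouped.agg(mean_hit="mean", sd="std", n="count").reset_index()
    out["se_hit"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] == 1, "se_hit"] = 0.0
    return out[["sigma", "tau", "mean_hit", "se_hit", "n"]]
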