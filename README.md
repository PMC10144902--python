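# hetgraph

Generate network graphs with a *prescribed, single-parameter* level of
degree-distribution heterogeneity, and study how that heterogeneity drives
epidemic severity and the graph spectrum.

## The idea

The degree distributions of many canonical graphs are special cases of the
two-parameter Weibull density

```
f(x; λ, α) = (α/λ) (x/λ)^(α−1) exp(−(x/λ)^α),   x ≥ 0,  α, λ > 0.
```

Mapping the shape parameter through **σ = exp(−α)** compresses the whole
shape range onto the unit interval, so a single scalar σ ∈ (0, 1)
interpolates the degree distribution between extremes:

| σ | α = −ln σ | distribution / graph |
|---|---|---|
| → 0 | → ∞ | degenerate at λ → λ-regular graph |
| e⁻³·⁴ ≈ 0.033 | 3.4 | ≈ Gaussian → Erdős–Rényi-like |
| e⁻² ≈ 0.135 | 2 | Rayleigh |
| e⁻¹ ≈ 0.368 | 1 | exponential |
| → 1 | < 1 | heavy (subexponential) tails |

Given (σ, λ, N) the generator draws N degrees from the modified Weibull
density, rounds them to integers, repairs parity, and matches stubs
uniformly at random (the configuration model), yielding a multigraph
G(σ, λ, N) whose heterogeneity is controlled by σ alone.

On top of the generator the package provides:

- **moments in closed form** — ⟨k⟩ = λΓ(1 + 1/α) and
  Var(k) = λ²[Γ(1 + 2/α) − Γ(1 + 1/α)²];
- **discrete-time stochastic SIR** on the generated graphs, with the herd
  immunity threshold HIT = (I + R)/N read off at the infection peak
  (the discrete dI/dt = 0);
- **spectral comparison** — the mean-field configuration-model prediction
  of the largest adjacency eigenvalue κ₁ from the Gamma-function moments
  versus the eigenvalue computed from generated graphs.

It is aimed at modellers who want to vary *only* the degree distribution
of a contact or interaction network — epidemiologists doing sensitivity
analyses in σ, and network scientists probing where moment-based
mean-field theory breaks down.

## Worked example

```python
import numpy as np
from hetgraph import (HeterogeneityParams, generate_graph, SIRParams, run_sir,
                      herd_immunity_threshold, kappa1_theory, kappa1_empirical,
                      mean_degree)

params = HeterogeneityParams(sigma=0.5, lam=5.0)
print(f"alpha = {params.alpha:.4f}, analytic mean degree = {mean_degree(params):.3f}")

g = generate_graph(params, N=1000, rng=np.random.default_rng(42))
degs = [d for _, d in g.degree()]
print(f"graph: {g.number_of_nodes()} nodes, {g.number_of_edges()} edges, "
      f"mean degree {np.mean(degs):.3f}")

trace = run_sir(g, SIRParams(tau=0.1, gamma=0.2, epsilon=0.01),
                np.random.default_rng(0))
print(f"HIT = {herd_immunity_threshold(trace):.3f} (peak at t = {int(np.argmax(trace.I))})")
print(f"kappa1: theory <k2>/<k> = {kappa1_theory(params, 'second_moment'):.2f}, "
      f"empirical = {kappa1_empirical(g):.2f}")
```

prints

```
alpha = 0.6931, analytic mean degree = 6.389
graph: 1000 nodes, 3168 edges, mean degree 6.336
HIT = 0.433 (peak at t = 8)
kappa1: theory <k2>/<k> = 20.37, empirical = 20.69
```

At σ = 0.5 the graph is moderately heavy-tailed: the realized mean degree
sits on the Gamma-function prediction, an epidemic with τ = 0.1 has
infected 43% of the population by its peak, and the ⟨k²⟩/⟨k⟩ mean-field
eigenvalue prediction is within 2% of the computed spectral radius.

A command-line interface exposes the same pipeline
(`hetgraph sample-degrees | generate | hit-sweep | spectral-sweep`); every
command echoes its resolved configuration to a sidecar JSON that re-runs
to byte-identical output. See `hetgraph --help`.

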