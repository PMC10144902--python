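# Methods

## The heterogeneity parameterization

The package models a graph's heterogeneity purely through its degree
distribution, taken to be a two-parameter Weibull with shape α and scale
λ. The reparameterization σ = exp(−α) maps the shape range (0, ∞) onto
(0, 1), giving the working density

f(x; λ, σ) = (−ln σ / λ) (x/λ)^(−ln σ − 1) exp(−(x/λ)^(−ln σ)),  x ≥ 0.

σ near 0 concentrates mass at λ (regular graphs); σ near 1 gives
subexponential tails. The boundary values are excluded: σ = 0 is the
degenerate point mass and σ = 1 the α → 0 limit, neither a valid Weibull.
Construction-time validation enforces σ ∈ (0, 1) and λ > 0, so every
downstream operation can assume valid parameters.

Closed-form moments follow from Gamma integrals: ⟨k⟩ = λΓ(1 + 1/α),
Var(k) = λ²[Γ(1 + 2/α) − Γ(1 + 1/α)²], and the raw second moment
⟨k²⟩ = λ²Γ(1 + 2/α) is exposed separately because mean-field spectral
formulas are conventionally written in it. Γ is scipy's implementation;
no bespoke approximation.

Numerical conventions:

- **Density at x = 0.** For α < 1 the density diverges at the origin; the
  pdf returns IEEE `inf` there (and the exact limit 1/λ at α = 1, 0 for
  α > 1). Sampling never produces 0 because the uniform variate is taken
  in the open interval.
- **Sampling** is exact inverse transform, x = λ(−ln u)^(1/α). Exactness
  makes the Kolmogorov–Smirnov comparison against the closed-form CDF a
  clean test oracle.

## Graph generation

Degrees are sampled, rounded **half-up** to the nearest integer (chosen
over banker's rounding for bit-reproducibility of the rule), clipped at a
cap (default N − 1, the simple-graph maximum; clips are counted and
logged), and parity-repaired: if the sum is odd, one node chosen
uniformly at random gains a single degree — or loses one in the corner
case where the chosen node already sits at the cap, so the cap invariant
is never violated. Zero degrees are retained; isolated nodes are legal
(an optional min-degree clamp exists, default off).

Stub matching is the plain configuration model: the stub multiset is
shuffled uniformly and consecutive entries paired, distributionally
identical to repeatedly drawing two remaining stubs uniformly at random.
Self-loops and parallel edges are kept by default, so the multigraph
degree sequence equals the input exactly; simplification (collapse
parallels, drop loops) and giant-component extraction are opt-in flags,
and every experiment records which options were used. Tests check the
matcher against a brute-force enumeration of all labeled stub pairings
on tiny sequences, and against networkx's configuration model as an
independent implementation.

A practical regime note: the λ-regular limit is approached only at very
small σ. At σ = 1e−6 (α ≈ 13.8) about a quarter of the mass still falls
outside [0.9λ, 1.1λ]; the regular-limit tests therefore exercise
σ = 1e−40 (α ≈ 92), where ≥ 99% of rounded degrees equal λ.

## SIR dynamics and the herd immunity threshold

Discrete time, synchronous updates. Initially ⌈εN⌉ nodes chosen uniformly
without replacement are Infected. Each step: (1) every edge joining a
currently infected to a currently susceptible node transmits
independently with probability τ — implemented per susceptible node as
infection probability 1 − (1 − τ)^m with m the number of infectious edges
(multiplicity counted), which is exactly the independent-edges model;
self-loops never transmit; (2) nodes infected *before* the step recover
with probability γ, so transmission precedes recovery and γ = 1 is
non-degenerate. The run stops when I = 0 or at the horizon T.

HIT = (I + R)/N at the **first** step where I attains its maximum (ties
break earliest), the discrete analogue of reading the curve at dI/dt = 0.

Defaults, all configurable and echoed into every output's sidecar config:
ε = 0.01 (a small seeded fraction), γ = 0.2 (mean infectious period of 5
steps), T = 10·⌈1/γ⌉ (long enough that epidemics at these sizes complete).
Sweeps generate a **fresh graph per replicate** so replicate variance
includes graph variance; `reuse_graph` restores the fixed-graph reading.
The τ grid for the epidemic experiment is 10 geometrically spaced values
on [0.01, 1]: geometric spacing resolves the sub-critical/threshold
region at small τ (around γ/⟨k⟩ for near-regular graphs) while still
covering saturation.

Master seeds spawn per-cell child generators via
`SeedSequence(master, spawn_key=(i_sigma, i_tau, rep))`, so enlarging a
grid or adding replicates never perturbs existing cells, and every
pipeline is byte-reproducible under a fixed master seed (the sparse
eigensolver is given a fixed start vector for the same reason).

## Spectral comparison

The mean-field configuration-model prediction for the largest adjacency
eigenvalue is exposed in two modes, because the ratio can be written with
either the variance or the raw second moment in the numerator:

- `as_printed`: κ₁ = Var(k)/⟨k⟩ = λ[Γ(1+2/α) − Γ(1+1/α)²]/Γ(1+1/α);
- `second_moment`: κ₁ = ⟨k²⟩/⟨k⟩ (the conventional mean-field result).

Near the homogeneous limit only the second form tracks the computed
eigenvalue (a d-regular graph has κ₁ = d = ⟨k²⟩/⟨k⟩, while Var/⟨k⟩ → 0);
both forms blow up in the heavy-tailed regime where the finite graph's
eigenvalue is bounded by its capped maximum degree. Experiments record
the mode used. The empirical eigenvalue is computed by a sparse symmetric
Lanczos solve (relative tolerance 1e−8, dense fallback below 5 nodes) on
the adjacency with parallel-edge multiplicities; each self-loop
contributes 1 to the diagonal (while contributing 2 to the node's
degree) — the networkx convention, documented rather than altered.
Percent absolute error uses the empirical value as denominator.

## Study sizes

The packaged experiment defaults are scaled for a single CPU: the
herd-immunity sweep runs λ = 5, N = 500, 20 replicates over
σ ∈ {0.05, 0.5, 0.9} × 10 τ values (about half a minute), and the
spectral sweep N = 2000 with 3 replicates per σ. A `--paper-scale` flag
on the CLI restores the full-size configurations (N = 1000 with 150
replicates for the epidemic sweep; N = 5000 for the spectral sweep).
Moment checks use 10⁵ draws; stub-matching uniformity uses 10⁴ matchings
against the enumerated pairing distribution.

## What the synthetic experiments do and do not show

All inputs are generated internally; there is no empirical network data.
The generator emulates degree heterogeneity *only*: configuration-model
graphs are locally tree-like, with no clustering, modularity, assortative
mixing, or community structure, so passing tests demonstrate the effect
of the degree distribution in isolation, not behaviour on real contact
networks (where those higher-order features matter). In the heavy-tailed
regime a large fraction of nodes is isolated or outside the giant
component, and capped hub degrees (at N − 1) truncate the tail; both are
inherent to finite configuration-model graphs at high σ. Qualitative
claims (absence of a sub-critical regime at high σ, non-monotonic HIT in
τ, monotone growth of κ₁ with σ, breakdown of the mean-field prediction
in the heavy tail) are asserted as inequalities on averaged columns, not
as exact curve reproduction, since the exact experimental constants
(ε, γ, T, τ grid, σ grid) behind the original figures are not part of the
package's contract.

## Known limitations

- No fitting of (σ, λ) to observed degree data; the package generates,
  it does not infer.
- No continuous-time (Gillespie) epidemics, SEIR/SIS variants, or
  interventions.
- Heavy-tailed regimes (σ ≳ 0.9) are dominated by the degree cap and by
  graph fragmentation; moment formulas there describe the uncapped
  distribution, not the realized finite graph.
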