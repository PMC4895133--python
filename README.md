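# connectopo

Topological analysis of large structural connectome graphs: are they
scale-free, and are they small worlds?

Voxel-scale structural brain networks (10^5–10^6 nodes, up to ~10^8
undirected edges, stored as one triangle of the adjacency matrix in plain
edge lists) raise two classic questions that `connectopo` answers with
statistically principled machinery:

1. **What is the degree distribution?**  Candidate models are *hybrid*: the
   low-degree head is fitted freely, `Pr(k) = A_k` for `k ≤ k_c`, and a
   parametric tail takes over above the cutoff, `Pr(k) = c·F(k)` with

   | family | `F(k)` |
   |---|---|
   | EXP | `exp(−αk)` |
   | POW | `α^β (k+α)^{−β}` |
   | LGN | `Φ_c((ln k − μ)/s)` |
   | WBL | `exp(−α k^β)` |
   | TPW | `α^β (k+α)^{−β} e^{−γk}` |
   | GWB | `exp[α(γ^β − (k+γ)^β)]` |

   Heads are maximized in closed form (`A_k = n_k/N`), tails numerically,
   and candidates are ranked by the finite-sample Akaike criterion
   `AICc = −2 ln L + 2K + 2K(K+1)/(N−K−1)` with `K = k_c + 1, 2, 3` extra
   shape parameters per family.  `Δ_j = AICc_j − min AICc` rules a family
   out above 10.  On connectome-like degree data the generalized Weibull
   (stretched-exponential) tail wins and pure power laws lose — the graphs
   are not scale-free.

2. **How "small" is the world?**  The topological (graph) dimension `D`
   comes from BFS ball growth, `N_r ~ r^D`, with the effective exponent
   `D_eff(r+½) = Δln N_r / Δln r` exposing the scaling window.  The
   small-world coefficient compares clustering and path length with an
   Erdős–Rényi null of equal size and density:
   `σ = (C/C_r)/(L/L_r)`, `C_r = ⟨k⟩/N`,
   `L_r = (ln N − γ_E)/ln⟨k⟩ + ½`.  Connectome graphs show `σ ≫ 1` yet
   `D < 4`: small-world by the coefficient, nearly three-dimensional by
   ball growth.

Everything is exercised end-to-end on synthetic graphs with known ground
truth: configuration-model graphs built from any of the six degree
families, periodic lattices, 3D random geometric graphs (whose
Watts–Strogatz clustering approaches 15/32 in the dense limit) and ER
nulls.

## Worked example

Degree-model selection on 50,000 degrees drawn from a generalized-Weibull
tail (`α = 0.358, β = 0.426, γ = 141.72`):

```python
import connectopo as ct

spec = ct.DegreeModelSpec("GWB", 0, [], {"alpha": 0.358, "beta": 0.426,
                                         "gamma": 141.72})
degrees = ct.sample_degree_sequence(spec, 50_000, seed=1)
hist = ct.DegreeHistogram.from_degrees(degrees)
fits = {fam: ct.scan_cutoff(hist, fam, kc_grid=[0, 1, 2, 3, 5, 8])
        for fam in ct.FAMILIES}
table = ct.delta_table(fits)
```

prints (via the loop in `examples` form):

```
GWB:  Delta =     0.00
TPW:  Delta =     4.29
WBL:  Delta =    90.27
POW:  Delta =   108.09
LGN:  Delta =   168.42
EXP:  Delta =  3848.69
support set: ['GWB', 'TPW']
best fit: GWB k_c = 0 {'alpha': 0.279, 'beta': 0.453, 'gamma': 122.441}
```

The generating family wins, the truncated power law is the only plausible
alternative (`Δ < 10`), and the exponential is rejected by thousands of
AICc units — the qualitative fingerprint seen on real connectomes.

Small-world metrics on a spatial graph versus its ER null:

```python
g = ct.random_geometric_graph(5000, ct.radius_for_mean_degree(5000, 30.0),
                              periodic=True, seed=1)
rep = ct.small_world_report(ct.largest_connected_component(g))
```

```
N = 5000, <k> = 30.23
C_W = 0.4686  (dense-limit RGG value 15/32 = 0.4688)
L = 5.637, ER null L_r = 2.829, C_r = 6.05e-03
sigma_W = 38.9
```

The spatial graph is highly clustered (`C_W` at the 15/32 dense-limit
value, 77× the ER expectation) at a modest path-length cost, hence
`σ ≫ 1`.  A 64³ periodic lattice measured the same way gives
`D = 2.81 ± 0.01` over the `r ∈ [5, 16]` window, approaching the embedding
dimension 3 from below (the L1 ball has sizable finite-`r` corrections).

A `connectopo` command-line tool wraps the same stages
(`simulate`, `fit-degrees`, `dimension`, `smallworld`, `analyze`); see
`connectopo --help`.

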