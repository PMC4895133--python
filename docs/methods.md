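# Methods

## The hybrid degree model

All candidate degree distributions share one structure: an empirical head
and a parametric tail split at a cutoff `k_c`,

    Pr(k) = A_k                 k = 1 … k_c
    Pr(k) = c · F(k)            k > k_c ,

with `c = (1 − Σ A_i) / Σ_{k>k_c} F(k)`.  The tail pmf is taken
*proportional to F(k)* evaluated at integer degrees, not as a discrete
difference of a survival function; the two discretizations converge for
slowly varying tails and the proportional reading matches the way the tail
functions are written (`F(k) ∝ k^{−β}` for the power law).  The discrete
log-normal (LGN) tail weight is the complementary normal distribution
function of `(ln k − μ)/s`, i.e. the continuous log-normal survival
evaluated at integer k, in line with treating each family as the "usual
distribution function of its continuous namesake".  The alternative
discretization — reading `F` as a survival function, with
`Pr(k) ∝ F(k) − F(k+1)` and a telescoping closed-form normalizer — is
available as a switch on the pmf/likelihood layer; the two readings
coincide exactly for EXP and converge for slowly varying tails, and the
proportional-F reading stays the fitting default.

For a degree histogram with counts `n_k` (N observations), the
multiplicity-form log-likelihood is `ln L = Σ_k n_k ln Pr(k)` with
`0·ln 0 := 0` for empty head cells.  The head MLE is closed-form,
`A_k = n_k/N`; no model can exceed the saturated value `−N·H` where `H` is
the Shannon entropy of the degree frequencies (Gibbs' inequality).  This
bound is asserted in tests and also enforced as a numerical guard inside
the optimizer (see below).

Family constraints: `α > 0` everywhere it appears; `β > 0`
(`β > 1` for POW, whose tail is otherwise non-summable under the
proportional-F reading); `γ > 0` for TPW; `γ > −(k_c+1)` for GWB so the
tail support keeps `k + γ > 0`; `s > 0` for LGN.  For GWB with `γ ≤ 0`
the `exp(α γ^β)` prefactor of the tail function is undefined in real
arithmetic; because it is a k-independent constant it cancels in the
normalized pmf and is simply dropped on that branch (fitted `γ` values on
real connectome-like data can indeed be negative).

## Infinite tail sums

The normalizer needs `Σ_{k>k_c} F(k)` to high relative accuracy (target
1e−12).  Closed forms are used where exact: geometric series for EXP,
Hurwitz zeta for POW.  The remaining families are summed in log space in
blocks, switching to an Euler–Maclaurin form

    Σ_{k≥K} F(k) ≈ ∫_K^∞ F dx + F(K)/2 − F′(K)/12

once the local log-slope `−d ln F/dk` falls below 0.01 (relative error of
the truncated series is then ≲ slope⁴/720 ≈ 1e−11).  The integral is exact
via upper incomplete gamma functions for WBL/GWB/TPW(β<1) and via a normal
survival identity for LGN.  Two numeric traps are handled explicitly:

- **GWB with `γ ≫ k`**: `γ^β − (k+γ)^β` cancels catastrophically in
  doubles; the exponent is computed as `−α γ^β · expm1(β · log1p(k/γ))`.
  When the incomplete-gamma argument exceeds 600 the closed-form integral
  would pair an underflowing gamma ratio with an overflowing prefactor, so
  the integral of the well-scaled ratio `F(K+t)/F(K)` is evaluated by
  adaptive quadrature instead.
- **Gibbs guard**: any parameter corner whose computed tail likelihood
  exceeds the empirical-tail bound `Σ n_k ln(n_k/n_tail)` is rejected as
  numerically invalid rather than reported as a (spurious) optimum.

The pmf builder extends the support until the truncated mass is below
5e−10, so the returned vector sums to 1 within the documented 1e−9.  When
a `support_max` is given explicitly the vector is renormalized over the
finite support (a conditional distribution, appropriate for sampling
truncation); this matters for families such as POW whose mass converges
too slowly for a 1e−9 auto-support to be practical.

## Tail MLE and model selection

Shape parameters are optimized by L-BFGS-B in transformed unconstrained
coordinates (`ln α`, `ln β` or `ln(β−1)`, `ln γ`, and
`γ = (k_c+1)(e^c − 1)` for GWB so the lower bound maps to `c → −∞`).  The
objective is first evaluated on a fixed 5-point-per-parameter grid
(deterministic; up to 125 points for three-parameter families) and
polished from the best three grid points.  Two further start types are
added: the optimum of the nested subfamily (EXP ⊂ WBL ⊂ GWB, POW ⊂ TPW,
mapped with `γ = 1e−12` or `β = 1`), which makes the nested-likelihood
monotonicity hold up to optimizer tolerance by construction, and any
caller-supplied warm starts — the cutoff scan feeds each `k_c`'s optimum
into the next, which also yields the theoretical monotonicity of the
maximized likelihood in `k_c` (a larger empirical head can always
reproduce the smaller-head optimum exactly).

`AICc = −2 ln L + 2K + 2K(K+1)/(N−K−1)` with `K = k_c + 1` (EXP),
`k_c + 2` (POW, LGN, WBL), `k_c + 3` (TPW, GWB); `BIC = −2 ln L + K ln N`
is available as an alternative criterion and, penalizing harder for
`K ≳ 8`, systematically selects fewer parameters — the Monte Carlo
validation harness quantifies this as selection frequencies and the mean
selected `K` over replicated synthetic datasets.  The default cutoff grid
is dense over 0…100 plus ~20 geometrically spaced points up to `k_max`
with unit-step refinement around the coarse optimum; an exhaustive scan
(`full=True`) is available but refits the tail `k_max` times for
identical optima in practice.  Δ-tables drop non-converged fits (logged)
rather than scoring them, break ties toward fewer parameters, and
annotate both the `Δ < 10` support set and the `Δ ≤ 2` substantial-support
set.

## Synthetic graphs

The generators provide ground-truth inputs for every stage:

- **Degree sampling** is inverse-CDF on the hybrid pmf, then a
  **configuration model** (uniform stub matching; self-loops and
  multi-edges discarded, costing O(1/N) realized degree) turns sequences
  into simple graphs.  The configuration model is plumbing — a standard
  null for a prescribed degree sequence — not a claim about connectome
  geometry.
- **Periodic lattices** supply exact dimension oracles: the 3D L1 ball
  holds `(4r³ + 6r² + 8r + 3)/3` nodes, a closed form asserted directly in
  tests.
- **3D random geometric graphs** (uniform points in the unit cube, edges
  within a radius, periodic boundaries by default to suppress surface
  effects) approach the dense-limit Watts–Strogatz clustering 15/32.
  The radius for a target mean degree comes from the Poisson intensity
  `⟨k⟩ = n·(4/3)πr³`.
- **Erdős–Rényi G(n, m)** graphs with exactly m edges serve as nulls.

What these emulate: the degree structure, spatial embedding and density
regime of voxel connectomes.  What they do not: tractography transitivity
(edges added along entire fibers), hierarchical modularity, or spatial
degree correlations.  Passing tests therefore validate the *measurement
machinery*, not any claim that configuration-model graphs are brains.

## Dimension measurement

The ball-growth curve averages, over BFS seeds, the number of nodes within
distance r (seed included).  The defining scaling counts node *pairs* at
distance ≤ r; averaging per-seed ball sizes differs only by a factor N and
leaves the exponent unchanged, and matches how the measurement is done in
practice.  All seeds are used up to 10^5 nodes; above that a 1,000-seed
uniform sample with per-r standard errors.  BFS is delegated to igraph's C
implementation in chunks of 64 sources; per-seed shell counts are
aggregated with a single scatter-add per chunk.

`D` is the slope of `ln N(r)` vs `ln r`.  The automatic fit window runs
from r = 1 to the last r with `N(r) ≤ N/2` (pre-saturation), never fewer
than three points, with an optional hard cap for graphs whose scaling
window is narrow.  On lattices the L1-ball corrections bias small-r slopes
low (the exact closed form gives slope ≈ 2.6 over r ∈ [2, 10] even though
D = 3), so lattice oracles fit windows like r ∈ [10, 40] where the
effective exponent has approached its asymptote; the effective-exponent
curve `D_eff` is the tool for choosing such windows on real data.

## Small-world metrics

`C^W` averages the local clustering over *all* N nodes, with degree < 2
nodes contributing 0 — this matches the defining equation and weights
low-degree nodes heavily; `C^Δ` is 3·triangles/triples.  `L` is exact
(BFS from every node) up to 2×10^4 nodes and estimated from 1,000 uniform
sources above, with the standard error of per-source means reported.  The
ER null values are `C_r = ⟨k⟩/N` and `L_r = (ln N − γ_E)/ln⟨k⟩ + ½`
(Euler–Mascheroni `γ_E ≈ 0.5772`); the constant ½ and `γ_E` are fixed by
validating the formula against published per-graph tables, which it
reproduces to the printed 2 decimal places.  σ is reported as 0 for
triangle-free graphs (zero clustering) rather than raising, so lattices
produce a well-defined row.

## Scaling fits and robustness

Finite-size series are fitted with `y = a + b·x^c` (x = 1/N) or
`y = A + B·N^C`, by deterministic multi-start over the exponent with the
linear pair solved exactly at each start, then full nonlinear polish;
fits whose power term is indistinguishable from a constant are flagged
degenerate.  A fixed-exponent mode reduces both forms to ordinary linear
regression (used as a cross-check against the closed form).  The
zero-slope test is a two-sided t-test on the simple regression slope
(optionally after log transforms), returning slope 0 with p = 1 for
strictly constant series by convention.

Robustness experiments mirror the analysis defaults: before re-measuring
dimension, 20% of *directed edge views* are removed (each undirected edge
is two arcs, removed independently; the edge survives if either arc does,
and the graph is re-symmetrized — the stored-triangle reading of removing
directed connections while measuring undirected invariants); before
re-measuring small-world metrics, 10% of undirected edges are removed
exactly and uniformly.

## Problem sizes used by the test suite

Closed-form and recovery checks run at the sizes their claims require
(parameter recovery at n = 10^5; RGG clustering at n = 5,000 with five
replicates; lattice dimension on 101³ nodes).  Replicated selection
studies are run at reduced sizes chosen to keep the default suite fast
while leaving the tested inequalities far from marginal: support-set
validity at n = 2×10^4 per family, exponential-rejection over 20
replicates at n = 2×10^4 (the AICc gap is in the thousands), and the
BIC-vs-AICc mean-K comparison over 12 replicates at n = 5,000 on a
three-family nest.  The randomized-spec property suites constrain
parameter ranges so the automatic pmf support stays desk-sized; POW tails
shallower than β ≈ 2.5 are exercised through the explicit-support
(renormalized) path instead.

## Known limitations

- Real OCP-scale graphs (~10^8 edges) are supported by the data
  structures (igraph backend, chunked BFS) but all tests run on synthetic
  graphs ≤ 10^6 nodes; no claim is made about wall-clock time at full
  scale.
- The LGN tail formula and the default ∝F discretization are documented
  choices among defensible alternatives; the survival-difference reading
  is implemented at the pmf/likelihood layer but not wired into the
  fitting path.
- Weighted and directed analyses are out of scope; the robustness modes
  are the only concession to directedness.
- σ recomputed from rounded table inputs agrees with published values
  only to ~1%; exact agreement would require unrounded intermediates.
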