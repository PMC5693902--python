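# Methods

This note records the mathematical model, the numerical choices made in
`landscaper`, and their known limitations.  Every empirical number quoted
here is computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted that the repository does not itself verify.

## Model

The object of study is the Langevin system

```
dx/dt = f(x) + G(x) ζ(t),        ⟨ζ_i(t) ζ_j(t')⟩ = 2 ε δ_ij δ(t − t'),
```

with state `x ∈ R^N`, drift `f`, noise matrix `G`, diffusion
`D = G Gᵀ` (symmetric positive definite) and scalar noise strength `ε`.

**Noise normalization.**  The white-noise covariance carries a factor
`2ε`, so an Euler–Maruyama step adds `G(x)·√(2 ε Δt)·η` with standard-normal
`η`.  This convention fixes the stationary variance of `dx/dt = −x + ζ` to
exactly `ε`; the simulation test suite checks this identity directly.  When
porting formulas from conventions with covariance `ε δ` instead, all `ε`
below rescale by 2.

**Force decomposition.**  A potential function `φ` is defined through

```
f(x) = −(D(x) + Q(x)) ∇φ(x),
```

with `Q` antisymmetric, which implies `(∇φ)ᵀ Q ∇φ = 0`: the curl part does
no work against the gradient.  Under the A-type stochastic interpretation
the steady state is exactly Boltzmann–Gibbs,

```
ρ_ss(x) = exp(−φ(x)/ε) / Z,
```

at **any** noise strength, not only asymptotically as `ε → 0`.

**A-type integration.**  A-type dynamics is realized as an Ito SDE with the
corrected drift `f + ε Δf`, where `Δf_i = Σ_j ∂_j (D_ij + Q_ij)`.  When `D`
and `Q` are both constant the correction vanishes and A-type coincides with
Ito; a nonzero discrepancy between interpretations therefore requires
state-dependent `D` or `Q`.  The package ships the `variable_curl` fixture
(`Q₁₂ = q₀ + c·x₂` with the double-well potential) precisely to expose this
discrepancy: at `ε = 1` the Ito-sampled empirical potential has a minimum
displaced ≈ 2.2 bin widths from the deterministic fixed point, while the
A-type-sampled minima sit exactly on the fixed-point bins.

**Analytic fixtures.**  All oracles used in testing carry closed-form `φ`:

| fixture | potential φ | D | Q | parameters |
|---|---|---|---|---|
| `double_well_1d` | `(x²−1)²/4 + tilt·x` | 1 | 0 | `tilt` (default 0) |
| `double_well_2d` | `(x₁²−1)²/4 + x₂²/2` | I | 0 | — |
| `rotational_ou` | `‖x‖²/2` | I | `[[0,q],[−q,0]]` | `q` (default 1) |
| `gradient_plus_curl` | `(x₁²−1)²/4 + x₂²/2` | I | `[[0,q],[−q,0]]` | `q` (default 1) |
| `variable_curl` | `(x₁²−1)²/4 + x₂²/2` | I | `q(x) = q₀ + c·x₂` | `q₀`, `c` (default 1, 1) |

For `rotational_ou` the action from the origin to `(b, 0)` equals `b²/2`
for every curl strength `q`, which makes it a sharp oracle for the
path-discretization error.

**Hill networks.**  Gene-regulatory models are built from JSON
specifications: per-edge Hill terms `a·xⁿ/(kⁿ + xⁿ)` (activation) or
`a·kⁿ/(kⁿ + xⁿ)` (inhibition) summed per target, plus basal production and
linear degradation, with analytic Jacobians.  `D = I` by default.

## Generator scope

The package computes, for a given system:

- all fixed points of `dx/dt = f(x)` inside a bounding box, with stability
  class from Jacobian eigenvalues (stable: no eigenvalue with real part
  above `1e-6`; saddle: exactly one);
- the two stable states downhill of each saddle and the descent durations;
- uphill potential barriers `Δφ` by least-action minimization;
- an anchored global landscape graph, steady-state probability ratios
  `exp(−Δφ/ε)` and transition-rate exponents `exp(−barrier/ε)`;
- empirical potentials `−ε ln ρ̂` from Euler–Maruyama simulation under the
  Ito, Stratonovich or A-type interpretation.

Out of scope: transition-rate prefactors (only the exponent is computed),
landscapes of limit-cycle or chaotic attractors (fixed points only),
non-white or colored noise, and densities in dimensions too high to
histogram (simulation works in any `N`; the binned Boltzmann reference is
implemented for `N = 2`).

## Numerical choices

**Discretized action.**  The Ito-form action is discretized at pre-points,

```
S = ¼ Σ_k Δt · r_kᵀ D⁻¹(x^{k−1}) r_k,    r_k = (x^k − x^{k−1})/Δt − f(x^{k−1}),
```

and minimized over interior points with both endpoints pinned (L-BFGS-B
with the analytic gradient; the gradient is validated against central
finite differences to relative error below `1e-5`, in practice ~`1e-10`).

**Time convention.**  `T` always denotes the *total* path duration, so the
uniform step is `Δt = T/K`.  The default barrier window is the recorded ODE
descent time from the saddle (the uphill minimizer is the time reverse of
the adjoint downhill relaxation), floored at 1.

**Discretization bias and refinement.**  The discrete minimum lies below
the continuum value by `O(Δt)` (for the rotational OU the relative bias is
`−(1+q²)Δt/2`, verified numerically to be linear in `Δt`).  `refine_action`
therefore doubles `K` repeatedly, warm-starting each level from the
midpoint-inserted previous optimum, and Richardson-extrapolates successive
minima (`R = 2 S_{2K} − S_K`), stopping when two extrapolants agree to
`2e-3` relative.  On the rotational-OU oracle this reduces the worst error
over `b ∈ {0.5, 1, 2} × q ∈ {0, 1, 5}` to `4.5e-5` relative (raw `K = 50`
values err by ~2–5%).

**Fixed-point search.**  Damped Newton iteration (step halving until the
residual decreases, pseudo-inverse fallback for singular Jacobians) from
Latin-hypercube starts; finds are merged within a `1e-4` radius and sorted
lexicographically so results do not depend on start order.

**Landscape assembly.**  Potentials are propagated over a breadth-first
spanning tree from an anchor node; non-tree edges and parallel barriers
measure the cycle inconsistency of the computed landscape (reported, and
logged as a warning above 2%).  Disconnected components are anchored
independently and cross-component ratios raise an error rather than
returning an arbitrary number.

**Empirical potential.**  `−ε ln` of a normalized histogram, shifted so its
minimum is zero; unoccupied bins are NaN (unobserved, not infinite).
Comparisons against an analytic `φ` use *bin-integrated* Boltzmann
probabilities (midpoint rule on an 8× finer grid), because comparing
against `φ` at bin centers introduces an `O(∇φ·h)` binning bias comparable
to the effect under test.  With this reference, A-type simulation of
`gradient_plus_curl` reproduces the Boltzmann potential with mean absolute
deviation 0.0036, 0.023 and 0.112 at `ε = 0.1, 1, 5` (tolerance `0.1·ε`)
over bins with ≥ 200 counts.

**Simulation sizes.**  The acceptance computations use 2000 replicate
trajectories × 25 000 steps at `Δt = 0.002` (40 000 steps at `Δt = 0.001`
for `ε = 5`), 20% burn-in, thinning 10 — about 4–6 × 10⁶ retained samples
per condition, ~10 s each on one CPU.  These sizes are package choices
balancing Monte-Carlo error (~1% of `ε` on the MAD statistic) against run
time.

## Limitations

- The Euler–Maruyama scheme is first order; the empirical potential carries
  an `O(Δt)` bias (e.g. the OU stationary variance is `ε·(1 + Δt/2)` to
  leading order).  `Δt` must respect the stiffest local relaxation rate or
  the integrator diverges (detected and reported).
- The saddle-bin barrier read from a histogram has both binning and
  sampling error; at `ε = 5` the well population contrast is weak and the
  histogram barrier (0.188) deviates visibly from the least-action value
  (0.2500) within its combined tolerance.
- The least-action route reports `Δφ` in the `ε → 0` sense; for finite `ε`
  and state-dependent `D`/`Q` the A-type finite-noise action differs by
  `O(ε)` terms (available via `atype_action`).
- Saddles with more than one unstable direction are classified but not
  descended (no single unstable eigenvector); they do not contribute
  barriers.
- Fixed-point completeness depends on the bounding box and the number of
  Newton starts; there is no guarantee all roots inside the box are found,
  only a stochastic sweep whose census is reproducible under a fixed seed.
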