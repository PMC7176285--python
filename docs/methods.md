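# Methods

## Model and assumptions

`quasiscape` operates on smooth autonomous systems dx/dt = f(x) with n ≥ 2
state variables. The method assumes only local differentiability: around
each grid node x₀ the field is replaced by its linearization
f(x) ≈ f(x₀) + J(x₀)Δx, and the Jacobian is split uniquely into a symmetric
and a skew-symmetric part, J = J_symm + J_skew. The symmetric part defines a
locally gradient field f(x₀) + J_symm(x₀)Δx whose potential difference over
a displacement Δx has the closed form

ΔV(x₀ → x₀+Δx) = −f(x₀)·Δx − ½ Δxᵀ J_symm(x₀) Δx.

The increments are evaluated at the step's **starting** node and accumulated
over the lattice: first along the first axis from the reference corner, then
along each column of the second axis (and so on in higher dimensions — the
sweep is dimension-agnostic, with 2-D as the primary, heavily tested path).
The skew part is discarded from V and instead summarized per node as a
relative error

err = ‖J_skew‖_F / (‖J_symm‖_F + ‖J_skew‖_F) ∈ [0, 1],

0 for locally gradient regions, 1 for purely rotational ones. When both
norms are below 1e−12 the field is locally constant — trivially gradient —
and err is defined as 0.

Two distinct error sources coexist and should not be conflated:

* **Discretization.** The per-step truncation is O(|Δx|³), so V carries an
  O(h²) global error on a grid of spacing h. It vanishes under refinement,
  and is exactly zero for linear fields at any spacing.
* **Rotational neglect.** Independent of h. This is what `err` measures;
  it cannot be reduced by a finer grid.

## Numerical and design choices

* **Norms.** Frobenius, for both parts: cheap, invariant under orthogonal
  changes of basis, and consistent with reading the two norms as the
  "weights" of the gradient and rotational contributions.
* **Sweep path.** The canonical path (`x_first`) is fixed rather than
  averaged over; for non-gradient systems different paths genuinely disagree
  (that is the point), so averaging would only blur the artifact. `y_first`
  and `average` are provided as path-dependence diagnostics. For gradient
  systems all paths agree at O(h²); in fact, for polynomial potentials of
  degree ≤ 4 the per-cell circulation of the accumulated increments cancels
  exactly and the two orders coincide to roundoff.
* **Reference.** V = 0 at the grid's origin node (default: the smallest
  corner). Changing the reference shifts V by a constant only.
* **Jacobians.** All built-in models carry analytic Jacobians, which makes
  the err ≡ 0 / err ≡ 1 landmark results exact rather than tolerance-bound;
  user expression models get theirs by symbolic differentiation. The
  numeric fallback is second-order central differences with per-axis step
  h_i = cbrt(ε)·max(1, |x_i|), the standard truncation/roundoff compromise.
* **Floating point.** The split formulas are exactly closed under their
  symmetries ((J+Jᵀ)/2 is bit-exactly symmetric, (J−Jᵀ)/2 bit-exactly
  skew), but J_symm + J_skew reproduces J only up to one rounding per
  element; tests assert reconstruction at the 4-ulp level.
* **Grids.** Uniform spacing per axis (relative tolerance 1e−12), at least
  2 nodes per axis, at least 2 dimensions; 1-D input is rejected because the
  1-D potential is an exact textbook integral, not an approximation problem.
* **Equilibria.** Deterministic multi-start: every grid node that is a
  local minimum of ‖f‖ over its lattice neighbourhood seeds a damped Newton
  iteration (max 50 steps, step halving on residual increase, convergence at
  ‖f‖ < 1e−11); roots are kept if inside the grid box, deduplicated at
  1e−6, classified by Jacobian eigenvalues (tolerance 1e−8 on real parts:
  all negative → stable, all positive → unstable, mixed → saddle, zero real
  parts with nonzero imaginary → center), and sorted lexicographically.
* **Selkov Hopf points.** The equilibrium is (b, b/(a+b²)); the Hopf pair
  solves trace J = 0 there, which reduces to the quartic
  b⁴ − (1−2a)b² + a + a² = 0 with real positive roots iff a < 1/8. The
  implementation brackets and bisects the trace through the model's own
  Jacobian; the test suite cross-checks against the quartic (at a = 0.1:
  b⁴ − 0.8b² + 0.11 = 0, roots 0.4200 and 0.7897).
* **Trust threshold.** err < 0.2 is exposed as a convenience mask and a
  `trusted` CSV column. It is an explicitly heuristic visualization
  threshold, configurable everywhere it appears.
* **Expressions.** User models are parsed under a whitelisted grammar
  (numbers, state/parameter names, + − * / ^, exp, log, parentheses) into
  sympy and compiled; there is no general code-evaluation path, so configs
  from untrusted sources cannot execute code.

## Test fixtures and what they show

The example systems double as the validation fixtures; they are analytic
equations, not sampled data, so "synthetic" here means constructed systems
with known closed-form answers rather than simulated noisy observations:

* **four_well** (uncoupled): exactly gradient; V must match
  x⁴/4 − x²/2 + y⁴/4 − y²/2 up to a constant and O(h²), and err ≡ 0 exactly.
  At h = 0.05 on [−2,2]² the origin-anchored deviation is ≈ 0.0101 (the
  leading O(h²) constant; ≈ 0.0067 after removing the mean), and halving h
  divides it by ≈ 4.
* **four_well_coupled**: adds the rotational perturbation
  (0.3y, −0.4x)·exp(−((x−1)² + (y−1)²)), confined near (1,1). The error map
  peaks (≈ 0.85) within distance ~0.6 of (1,1).
* **rotation** (−y, x): purely rotational; err ≡ 1 exactly, and the loop
  integral of f around the unit circle is 2π — the witness that no
  potential exists.
* **toggle_switch**: bistable two-gene circuit; the computed landscape has
  exactly two interior wells whose bottoms lie within 0.1 of the stable
  states.
* **lotka_volterra**, **selkov**: cyclic dynamics; the error map flags the
  cyclic regions, and the Selkov error map is independent of b because its
  Jacobian is.

Because the fixtures are noiseless equations, passing tests demonstrate
correctness of the decomposition, accumulation and error calculus — they say
nothing about robustness to measurement noise, model misspecification, or
fields known only at scattered sample points, none of which the method
ingests.

## Known limitations

* **The relative error blows up wherever the gradient part vanishes.** err
  compares *norm ratios*, so in regions where J_symm ≈ 0 even a negligible
  absolute rotational component yields a large err. The coupled four-well
  makes this concrete: on the ring |x| = |y| = 1/√3 the unperturbed Jacobian
  diag(1−3x², 1−3y²) vanishes entirely, and the exponentially small masked
  perturbation drives err to ≈ 0.2 at the ring points far from (1,1) — a
  thin ridge of *relative* error at negligible *absolute* error (the
  `absolute_error_map` surface, ‖J_skew‖·h, is ~1e−2·h there). Read err
  jointly with the field magnitude near degenerate regions.
* V is path-dependent for non-gradient systems; the fixed canonical sweep
  makes the output deterministic, not path-free. Wells of the computed V can
  be slightly displaced from the true stable equilibria (≈ 0.03–0.08 state
  units for the toggle switch at h = 0.03).
* The landscape is only meaningful along trajectories that avoid high-err
  regions; inside limit cycles it is not even locally interpretable.
* Dimensions beyond 3 work in principle (the sweep and decomposition are
  n-dimensional) but node counts grow geometrically; no sparse grids are
  provided.
* Stochastic quasi-potentials (probability-based landscapes), vector
  potentials, trajectory-integration methods and bifurcation continuation
  beyond the Selkov trace condition are out of scope.
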