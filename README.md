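# quasiscape

Approximate **stability landscapes (quasi-potentials)** for deterministic
ODE systems, with a pointwise **error map** that says where the landscape can
be trusted.

## The problem

For a one-dimensional system dx/dt = f(x) the "ball-in-a-landscape" picture
is exact: V(x) = −∫f dx, wells are stable states, peaks are unstable ones.
In two or more dimensions a scalar potential V with f = −∇V exists only for
*gradient* systems, i.e. when the crossed partial derivatives agree
(∂f/∂y = ∂g/∂x, equivalently a symmetric Jacobian everywhere). Most systems
biologists care about — mutually repressing gene circuits, predator–prey
cycles, glycolytic oscillators — are not gradient, and for cyclic dynamics a
potential is outright impossible.

## The method

`quasiscape` linearizes the field at each node of a regular grid and splits
the local Jacobian into its symmetric and skew-symmetric parts,

J = J_symm + J_skew,  J_symm = (J + Jᵀ)/2,  J_skew = (J − Jᵀ)/2.

The symmetric part is a locally gradient field whose potential increment
along a lattice step Δx has the closed form

ΔV = −f(x₀)·Δx − ½ Δxᵀ J_symm(x₀) Δx,

which is accumulated sequentially over the grid (first along x from the
reference corner, then along each column in y) to produce the
quasi-potential V, defined up to an additive constant (V = 0 at the grid
origin). The neglected skew part cannot be represented by any scalar
potential; its relative weight

err = ‖J_skew‖_F / (‖J_symm‖_F + ‖J_skew‖_F) ∈ [0, 1]

is reported per node: 0 where the system is locally gradient, 1 where it is
purely rotational. A rule of thumb: err < 0.2 is small enough for
visualization (the `trusted` column/mask).

Built-in example systems: `four_well` (and its `four_well_coupled`
perturbation), `rotation`, `toggle_switch`, `lotka_volterra`, `selkov` —
all with analytic Jacobians — plus equilibrium finding/classification and
the Selkov Hopf-point solver.

## Worked example

```python
import quasiscape as qs

model = qs.toggle_switch()                      # two mutually repressing genes
grid = qs.RectGrid.from_bounds([[0, 3], [0, 3]], [100, 100])
result = qs.compute(model, grid)                # V landscape + error map

for eq in qs.find_equilibria(model, grid):
    print(f"{eq.stability:>8}  x={eq.location[0]:.3f}  y={eq.location[1]:.3f}")
print(f"max relative error: {result.err.max():.3f}")
print(f"fraction of nodes with err < 0.2: {result.trusted_mask().mean():.3f}")

b_low, b_high = qs.selkov_hopf_points(0.1)
print(f"Selkov limit cycle for b in [{b_low:.4f}, {b_high:.4f}]")
```

prints

```
  stable  x=0.231  y=1.974
  saddle  x=0.540  y=1.040
  stable  x=2.130  y=0.305
max relative error: 0.468
fraction of nodes with err < 0.2: 0.566
Selkov limit cycle for b in [0.4200, 0.7897]
```

The toggle switch is bistable: an x-dominant and a y-dominant expression
state separated by a saddle. The computed landscape has exactly two wells
whose bottoms sit at the stable states, and although the circuit is not a
gradient system, more than half of the region carries a relative error below
the 0.2 threshold — the landscape is a reasonable picture there. The Selkov
model at a = 0.1 destabilizes in a Hopf bifurcation at b ≈ 0.42 and
restabilizes at b ≈ 0.79; inside that interval the dynamics are a limit
cycle and no potential exists on the cycle's region.

## Command line

```sh
quasiscape models
quasiscape run --model selkov --param a=0.1 --param b=0.6 \
    --xlim 0 2.5 --ylim 0 2.5 --nx 100 --ny 100 --out selkov.csv
quasiscape run --config my_run.yaml
```

`run` writes a CSV grid table (`x,y,V,err,trusted`, x varying fastest,
floats at 17 significant digits so a re-read is bit-exact) and a JSON
summary (`<out>.summary.json`) with the model, grid, equilibria, maximum
error and trusted fraction. Config files (YAML or JSON) may name a built-in
model or give per-component expressions in a restricted arithmetic grammar
(`-x*(x^2-1)`, `exp`, `log`; no general code evaluation).

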