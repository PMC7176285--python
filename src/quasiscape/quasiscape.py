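"""Quasi-potential stability landscapes for deterministic ODE systems.

Most multidimensional dynamical systems are not gradient systems: no scalar
potential V exists whose negative gradient reproduces the flow, because the
crossed partial derivatives of the field components differ (equivalently, the
Jacobian is asymmetric somewhere).  This module approximates a landscape
anyway, by linearizing the field on a regular grid, splitting each local
Jacobian into its symmetric (gradient) and skew-symmetric (rotational) parts,
and accumulating the potential increments contributed by the gradient part
along a fixed lattice path.  The ratio of the Frobenius norms of the two
Jacobian parts,

    err = ||J_skew|| / (||J_symm|| + ||J_skew||),

is reported per grid node as a relative-error map: 0 where the system is
locally gradient (the landscape is exact up to discretization), 1 where it is
purely rotational (the landscape is meaningless).

The module is organised in the order the method runs: vector-field
representation and Jacobian decomposition; rectangular grids; potential
accumulation and error maps; the built-in example systems (bistable wells, a
pure rotation, a genetic toggle switch, Lotka-Volterra, Selkov glycolysis)
with equilibrium finding; and finally configuration parsing, CSV/JSON
serialization and the run driver behind the command-line interface.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import sympy
from sympy.parsing.sympy_parser import (
    convert_xor,
    parse_expr,
    standard_transformations,
)

__version__ = "0.1.0"

logger = logging.getLogger("quasiscape")

# --- tunables -------------------------------------------------------------
#: rule-of-thumb ceiling below which the relative error is considered small
#: enough for visualization; heuristic and configurable everywhere it is used
DEFAULT_TRUST_THRESHOLD = 0.2
#: central differences: h_i = _FD_STEP_FACTOR * max(1, |x_i|) balances the
#: O(h^2) truncation error against roundoff for a second-order stencil
_FD_STEP_FACTOR = float(np.cbrt(np.finfo(float).eps))
#: both Jacobian-part norms below this -> field locally constant -> err := 0
_NORM_FLOOR = 1e-12
#: symmetry contract tolerance for matrices callers claim are symmetric
_SYMM_TOL = 1e-12
#: grid axes must be uniform to this relative tolerance
_GRID_UNIFORM_RTOL = 1e-12
_NEWTON_MAX_ITER = 50
_NEWTON_TOL = 1e-11
_NEWTON_DAMPING = 0.5
#: eigenvalue real parts within +-_EIG_TOL of zero count as zero
_EIG_TOL = 1e-8
#: equilibria closer than this (per coordinate) are considered duplicates
_DEDUP_TOL = 1e-6

_SWEEP_MODES = ("x_first", "y_first", "average")


class DomainEvaluationError(ValueError):
    """A model component returned a non-finite value at a requested state."""


# ======================================================================
# Vector fields and Jacobian decomposition
# ======================================================================

@dataclass(frozen=True, eq=False)
class VectorFieldModel:
    """A smooth autonomous dynamical system dx/dt = f(x).

    Parameters
    ----------
    dimension
        Number of state variables, at least 2.
    components
        One scalar callable per state variable; each maps a state vector to
        the corresponding time derivative.
    parameters
        Named parameter values, kept for provenance and serialization; the
        component callables are expected to have them baked in already.
    analytic_jacobian
        Optional callable returning the n-by-n Jacobian at a state vector.
        When present it is preferred over finite differences.
    name
        Label used in outputs and error messages.
    """

    dimension: int
    components: tuple
    parameters: Mapping[str, float] = field(default_factory=dict)
    analytic_jacobian: Callable[[np.ndarray], np.ndarray] | None = None
    name: str = "model"

    def __post_init__(self) -> None:
        if int(self.dimension) < 2 or self.dimension != int(self.dimension):
            raise ValueError(
                f"dimension must be an integer >= 2, got {self.dimension!r}"
            )
        if len(self.components) != self.dimension:
            raise ValueError(
                f"model {self.name!r}: {len(self.components)} components for "
                f"dimension {self.dimension}"
            )

    def __call__(self, state: Sequence[float]) -> np.ndarray:
        """Evaluate the field, raising :class:`DomainEvaluationError` on
        non-finite output (with the offending component and point named)."""
        x = np.asarray(state, dtype=float)
        if x.shape != (self.dimension,):
            raise ValueError(
                f"state of shape {x.shape} for {self.dimension}-dimensional "
                f"model {self.name!r}"
            )
        if not np.all(np.isfinite(x)):
            raise DomainEvaluationError(
                f"model {self.name!r}: non-finite state {x.tolist()}"
            )
        out = np.empty(self.dimension)
        for i, comp in enumerate(self.components):
            value = float(comp(x))
            if not math.isfinite(value):
                raise DomainEvaluationError(
                    f"model {self.name!r}: component {i} returned {value!r} "
                    f"at state {x.tolist()}"
                )
            out[i] = value
        return out

    def jacobian(
        self,
        point: Sequence[float],
        step: float | Sequence[float] | None = None,
        force_numeric: bool = False,
    ) -> np.ndarray:
        """Jacobian at ``point``: analytic when available, else central
        finite differences (see :func:`numeric_jacobian`)."""
        if self.analytic_jacobian is not None and not force_numeric:
            J = np.asarray(self.analytic_jacobian(np.asarray(point, float)),
                           dtype=float)
            if J.shape != (self.dimension, self.dimension):
                raise ValueError(
                    f"model {self.name!r}: analytic Jacobian has shape "
                    f"{J.shape}"
                )
            return J
        return numeric_jacobian(self, point, step=step)


def numeric_jacobian(
    model: VectorFieldModel,
    point: Sequence[float],
    step: float | Sequence[float] | None = None,
) -> np.ndarray:
    """Second-order central-difference Jacobian of ``model`` at ``point``.

    The default per-axis step is ``cbrt(eps) * max(1, |x_i|)``, the classic
    compromise between truncation and roundoff for an O(h^2) stencil.  A
    scalar or per-axis ``step`` overrides it.
    """
    x = np.asarray(point, dtype=float)
    n = model.dimension
    if x.shape != (n,):
        raise ValueError(f"point of shape {x.shape} for dimension {n}")
    if not np.all(np.isfinite(x)):
        raise DomainEvaluationError(f"non-finite point {x.tolist()}")
    if step is None:
        h = _FD_STEP_FACTOR * np.maximum(1.0, np.abs(x))
    else:
        h = np.broadcast_to(np.asarray(step, dtype=float), (n,)).copy()
        if np.any(h <= 0) or not np.all(np.isfinite(h)):
            raise ValueError(f"step must be positive and finite, got {step!r}")
    J = np.empty((n, n))
    for j in range(n):
        offset = np.zeros(n)
        offset[j] = h[j]
        f_plus = model(x + offset)
        f_minus = model(x - offset)
        J[:, j] = (f_plus - f_minus) / (2.0 * h[j])
    return J


@dataclass(frozen=True, eq=False)
class JacobianDecomposition:
    """Split of a Jacobian into symmetric and skew-symmetric parts.

    ``J_symm = (J + J^T)/2`` is the locally-gradient part, ``J_skew =
    (J - J^T)/2`` the rotational remainder; ``norm_symm`` and ``norm_skew``
    are their Frobenius norms (the "weights" of the two parts).
    """

    J: np.ndarray
    J_symm: np.ndarray
    J_skew: np.ndarray
    norm_symm: float
    norm_skew: float
    point: np.ndarray | None = None


def decompose_jacobian(
    J: np.ndarray, point: Sequence[float] | None = None
) -> JacobianDecomposition:
    """Decompose a square matrix into symmetric + skew-symmetric parts.

    The split is the unique one: ``(J + J^T)/2 + (J - J^T)/2 == J``.  Both
    parts inherit their symmetry exactly in floating point; reconstruction is
    exact up to one rounding of each element.
    """
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {J.shape}")
    if not np.all(np.isfinite(J)):
        raise ValueError("Jacobian contains non-finite entries")
    J_symm = (J + J.T) / 2.0
    J_skew = (J - J.T) / 2.0
    return JacobianDecomposition(
        J=J,
        J_symm=J_symm,
        J_skew=J_skew,
        norm_symm=float(np.linalg.norm(J_symm, "fro")),
        norm_skew=float(np.linalg.norm(J_skew, "fro")),
        point=None if point is None else np.asarray(point, dtype=float),
    )


def jacobian_asymmetry(J: np.ndarray) -> np.ndarray:
    """Return ``J - J^T``, the obstruction to a potential existing locally.

    The matrix is identically zero exactly when the crossed partial
    derivatives agree (the gradient condition); algebraically it equals twice
    the skew-symmetric part of ``J``.
    """
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {J.shape}")
    return J - J.T


# ======================================================================
# Rectangular grids
# ======================================================================

@dataclass(frozen=True, eq=False)
class RectGrid:
    """A regular rectangular lattice of evaluation nodes.

    ``axes`` holds one strictly increasing, uniformly spaced coordinate array
    per dimension; ``origin_index`` names the node where the potential is
    pinned to zero (default: the lexicographically smallest corner).
    """

    axes: tuple
    origin_index: tuple = ()

    def __post_init__(self) -> None:
        axes = tuple(np.asarray(a, dtype=float) for a in self.axes)
        object.__setattr__(self, "axes", axes)
        if len(axes) < 2:
            raise ValueError(
                "grids must have at least 2 dimensions; one-dimensional "
                "potentials are an exact textbook integral and unsupported"
            )
        for d, axis in enumerate(axes):
            if axis.ndim != 1 or axis.size < 2:
                raise ValueError(f"axis {d} must be 1-D with >= 2 nodes")
            diffs = np.diff(axis)
            if np.any(diffs <= 0):
                raise ValueError(f"axis {d} must be strictly increasing")
            h = diffs[0]
            if np.any(np.abs(diffs - h) > _GRID_UNIFORM_RTOL * abs(h)):
                raise ValueError(f"axis {d} is not uniformly spaced")
        if not self.origin_index:
            object.__setattr__(self, "origin_index", (0,) * len(axes))
        origin = tuple(int(i) for i in self.origin_index)
        if len(origin) != len(axes) or any(
            not 0 <= i < axes[d].size for d, i in enumerate(origin)
        ):
            raise ValueError(f"origin_index {self.origin_index!r} out of range")
        object.__setattr__(self, "origin_index", origin)

    @classmethod
    def from_bounds(
        cls,
        bounds: Sequence[Sequence[float]],
        resolution: Sequence[int],
        origin_index: Sequence[int] = (),
    ) -> "RectGrid":
        """Build a grid from per-axis ``[lo, hi]`` bounds and node counts."""
        if len(bounds) != len(resolution):
            raise ValueError("bounds and resolution must have equal length")
        axes = []
        for d, ((lo, hi), n) in enumerate(zip(bounds, resolution)):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"axis {d}: bounds must satisfy min < max")
            if int(n) < 2:
                raise ValueError(f"axis {d}: resolution must be >= 2")
            axes.append(np.linspace(float(lo), float(hi), int(n)))
        return cls(axes=tuple(axes), origin_index=tuple(origin_index))

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def shape(self) -> tuple:
        return tuple(a.size for a in self.axes)

    @property
    def spacing(self) -> np.ndarray:
        return np.array([a[1] - a[0] for a in self.axes])

    def node(self, index: Sequence[int]) -> np.ndarray:
        """Coordinates of the node at a multi-index."""
        return np.array(
            [self.axes[d][i] for d, i in enumerate(index)], dtype=float
        )


# ======================================================================
# Quasi-potential accumulation and error maps
# ======================================================================

def delta_V(
    f0: Sequence[float],
    J_symm0: np.ndarray,
    dx: Sequence[float],
) -> float:
    """Potential increment of the linearized gradient part over a step.

    With the field linearized at the step's starting point, the gradient part
    ``f(x0) + J_symm(x0) dx`` integrates in closed form along the straight
    displacement ``dx``::

        dV = -f0 . dx - (1/2) dx^T J_symm0 dx

    Exact for linear fields; O(|dx|^3) local error otherwise.  ``J_symm0``
    must be the symmetric Jacobian part (asymmetry beyond 1e-12 is rejected:
    passing the raw Jacobian here is a caller bug).
    """
    f0 = np.asarray(f0, dtype=float)
    dx = np.asarray(dx, dtype=float)
    J_symm0 = np.asarray(J_symm0, dtype=float)
    n = f0.size
    if dx.shape != (n,) or J_symm0.shape != (n, n):
        raise ValueError(
            f"inconsistent shapes: f0 {f0.shape}, J {J_symm0.shape}, "
            f"dx {dx.shape}"
        )
    scale = max(1.0, float(np.max(np.abs(J_symm0))))
    if np.max(np.abs(J_symm0 - J_symm0.T)) > _SYMM_TOL * scale:
        raise ValueError(
            "J_symm0 is not symmetric; pass the symmetric Jacobian part"
        )
    return float(-f0 @ dx - 0.5 * dx @ J_symm0 @ dx)


def _field_and_symm(model: VectorFieldModel, x: np.ndarray, index: tuple):
    try:
        f = model(x)
        J = model.jacobian(x)
    except DomainEvaluationError as exc:
        raise DomainEvaluationError(
            f"grid node {index} at {x.tolist()}: {exc}"
        ) from exc
    if not np.all(np.isfinite(J)):
        raise DomainEvaluationError(
            f"grid node {index} at {x.tolist()}: non-finite Jacobian"
        )
    return f, (J + J.T) / 2.0


def _sweep_axis_order(model: VectorFieldModel, grid: RectGrid,
                      order: tuple) -> np.ndarray:
    """Accumulate V over the lattice along a fixed sequence of axes.

    Starting from the smallest corner, the first axis in ``order`` is walked
    node by node; each later axis is then walked for every already-filled
    combination of the earlier ones.  In 2-D with order (0, 1) this is
    exactly: first row in +x, then each column in +y, every step using the
    field and symmetric Jacobian at the step's starting node.
    """
    shape = grid.shape
    V = np.full(shape, np.nan)
    V[(0,) * grid.ndim] = 0.0
    for stage, ax in enumerate(order):
        done = set(order[:stage])
        ranges = [
            range(shape[d]) if d in done else range(1)
            for d in range(grid.ndim)
        ]
        for base in itertools.product(*ranges):
            prev_idx = list(base)
            x_prev = grid.node(prev_idx)
            f_prev, Js_prev = _field_and_symm(model, x_prev, tuple(prev_idx))
            for i in range(1, shape[ax]):
                next_idx = list(base)
                next_idx[ax] = i
                x_next = grid.node(next_idx)
                V[tuple(next_idx)] = V[tuple(prev_idx)] + delta_V(
                    f_prev, Js_prev, x_next - x_prev
                )
                prev_idx, x_prev = next_idx, x_next
                if i < shape[ax] - 1:
                    f_prev, Js_prev = _field_and_symm(
                        model, x_prev, tuple(prev_idx)
                    )
    return V


def sweep_grid(
    model: VectorFieldModel, grid: RectGrid, mode: str = "x_first"
) -> np.ndarray:
    """Quasi-potential V over the grid, zero at the grid's origin node.

    ``x_first`` walks the first axis then each later axis in turn (the
    method's canonical path); ``y_first`` reverses the axis order; ``average``
    is the mean of both, useful as a cheap path-dependence diagnostic — for a
    gradient system all three agree up to O(h^2).
    """
    if mode not in _SWEEP_MODES:
        raise ValueError(f"unknown sweep mode {mode!r}; choose {_SWEEP_MODES}")
    forward = tuple(range(grid.ndim))
    if mode == "x_first":
        V = _sweep_axis_order(model, grid, forward)
    elif mode == "y_first":
        V = _sweep_axis_order(model, grid, forward[::-1])
    else:
        V = 0.5 * (
            _sweep_axis_order(model, grid, forward)
            + _sweep_axis_order(model, grid, forward[::-1])
        )
    # re-pin so the chosen reference node is exactly zero
    return V - V[grid.origin_index]


def error_map(model: VectorFieldModel, grid: RectGrid) -> np.ndarray:
    """Relative-error map err = ||J_skew|| / (||J_symm|| + ||J_skew||).

    Frobenius norms; 0 marks locally gradient regions (trustworthy
    landscape), 1 purely rotational ones.  Where both norms vanish (a locally
    constant field) the err is defined as 0: a constant field is trivially
    gradient.
    """
    err = np.empty(grid.shape)
    for index in np.ndindex(*grid.shape):
        x = grid.node(index)
        try:
            J = model.jacobian(x)
        except DomainEvaluationError as exc:
            raise DomainEvaluationError(
                f"grid node {index} at {x.tolist()}: {exc}"
            ) from exc
        dec = decompose_jacobian(J, point=x)
        if dec.norm_symm < _NORM_FLOOR and dec.norm_skew < _NORM_FLOOR:
            err[index] = 0.0
        else:
            err[index] = dec.norm_skew / (dec.norm_symm + dec.norm_skew)
    return err


def absolute_error_map(model: VectorFieldModel, grid: RectGrid) -> np.ndarray:
    """Heuristic local absolute-error scale ``||J_skew||_F * |h|``.

    Approximates the magnitude of the neglected rotational field over one
    grid cell (|f_ng| ~ ||J_skew dx||).  Diagnostic only; the relative map
    :func:`error_map` is the calibrated quantity.
    """
    h = float(np.linalg.norm(grid.spacing))
    out = np.empty(grid.shape)
    for index in np.ndindex(*grid.shape):
        dec = decompose_jacobian(model.jacobian(grid.node(index)))
        out[index] = dec.norm_skew * h
    return out


@dataclass(frozen=True, eq=False)
class QuasiPotentialResult:
    """Bundle of landscape, error map and the grid they live on."""

    grid: RectGrid
    V: np.ndarray
    err: np.ndarray
    reference_value: float
    model_name: str
    sweep_mode: str

    def trusted_mask(
        self, threshold: float = DEFAULT_TRUST_THRESHOLD
    ) -> np.ndarray:
        """Boolean mask of nodes with err below the (heuristic) threshold."""
        if not 0.0 <= threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        return self.err < threshold


def compute(
    model: VectorFieldModel, grid: RectGrid, mode: str = "x_first"
) -> QuasiPotentialResult:
    """Run the full pipeline: sweep the potential, map the relative error."""
    V = sweep_grid(model, grid, mode=mode)
    err = error_map(model, grid)
    return QuasiPotentialResult(
        grid=grid,
        V=V,
        err=err,
        reference_value=float(V[grid.origin_index]),
        model_name=model.name,
        sweep_mode=mode,
    )


def oracle_line_integral(
    model: VectorFieldModel,
    path: Sequence[Sequence[float]],
    refinement: int = 100,
) -> float:
    """Brute-force potential difference ``-∫ f · dr`` along a polyline.

    Composite midpoint quadrature with ``refinement`` subdivisions per
    segment.  For a gradient field this is the exact potential difference
    between the path's endpoints (up to quadrature error) regardless of the
    path, which makes it the independent check for :func:`sweep_grid`; for a
    non-gradient field a closed path yields a non-zero value — the witness
    that no potential exists.
    """
    verts = np.asarray(path, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 2:
        raise ValueError("path must contain at least two vertices")
    if int(refinement) < 1:
        raise ValueError("refinement must be >= 1")
    refinement = int(refinement)
    total = 0.0
    for p, q in zip(verts[:-1], verts[1:]):
        d = (q - p) / refinement
        for s in range(refinement):
            mid = p + (s + 0.5) * d
            try:
                f_mid = model(mid)
            except DomainEvaluationError as exc:
                raise DomainEvaluationError(
                    f"along path at {mid.tolist()}: {exc}"
                ) from exc
            total += float(f_mid @ d)
    return -total


# ======================================================================
# Model zoo: the built-in example systems
# ======================================================================

def four_well(with_interaction: bool = False) -> VectorFieldModel:
    """Two bistable variables: a four-well landscape, optionally perturbed.

    dx/dt = -x(x^2 - 1) + p_x,  dy/dt = -y(y^2 - 1) + p_y.

    Uncoupled (``with_interaction=False``, p = 0) the system is exactly
    gradient with potential x^4/4 - x^2/2 + y^4/4 - y^2/2.  With the
    interaction switched on, p_x = 0.3 y m(x, y), p_y = -0.4 x m(x, y) with
    the Gaussian mask m = exp(-((x-1)^2 + (y-1)^2)) injects a rotational
    component confined to the neighbourhood of (1, 1).
    """
    if with_interaction:

        def mask(x, y):
            return np.exp(-((x - 1.0) ** 2 + (y - 1.0) ** 2))

        def fx(s):
            x, y = s
            return -x * (x * x - 1.0) + 0.3 * y * mask(x, y)

        def fy(s):
            x, y = s
            return -y * (y * y - 1.0) - 0.4 * x * mask(x, y)

        def jac(s):
            x, y = s
            m = mask(x, y)
            dm_dx = -2.0 * (x - 1.0) * m
            dm_dy = -2.0 * (y - 1.0) * m
            return np.array(
                [
                    [1.0 - 3.0 * x * x + 0.3 * y * dm_dx,
                     0.3 * m + 0.3 * y * dm_dy],
                    [-0.4 * m - 0.4 * x * dm_dx,
                     1.0 - 3.0 * y * y - 0.4 * x * dm_dy],
                ]
            )

        return VectorFieldModel(
            dimension=2,
            components=(fx, fy),
            parameters={"px_amp": 0.3, "py_amp": -0.4},
            analytic_jacobian=jac,
            name="four_well_coupled",
        )

    def fx0(s):
        x = s[0]
        return -x * (x * x - 1.0)

    def fy0(s):
        y = s[1]
        return -y * (y * y - 1.0)

    def jac0(s):
        x, y = s
        return np.array(
            [[1.0 - 3.0 * x * x, 0.0], [0.0, 1.0 - 3.0 * y * y]]
        )

    return VectorFieldModel(
        dimension=2,
        components=(fx0, fy0),
        parameters={},
        analytic_jacobian=jac0,
        name="four_well",
    )


def four_well_exact_potential(x, y):
    """Closed-form potential of the uncoupled four-well system."""
    return x**4 / 4.0 - x**2 / 2.0 + y**4 / 4.0 - y**2 / 2.0


def rotation() -> VectorFieldModel:
    """Pure rotation dx/dt = -y, dy/dt = x: zero gradient part everywhere.

    Every trajectory (except the centre at the origin) is a circle, so no
    scalar potential exists anywhere; the relative-error map is 1 at every
    point.  The worst case for any landscape method.
    """

    def jac(s):
        return np.array([[0.0, -1.0], [1.0, 0.0]])

    return VectorFieldModel(
        dimension=2,
        components=(lambda s: -s[1], lambda s: s[0]),
        parameters={},
        analytic_jacobian=jac,
        name="rotation",
    )


#: printed defaults for the mutually repressing two-gene switch
TOGGLE_SWITCH_DEFAULTS: Mapping[str, float] = {
    "ax": 0.4802,
    "ay": 0.109375,
    "bx": 0.2,
    "by": 0.3,
    "kx": 0.2401,
    "ky": 0.0625,
    "rx": 1.0,
    "ry": 1.0,
    "n": 4.0,
}


def _toggle_hill(a: float, k: float, u: float, n: float) -> float:
    # repressive Hill input a / (k + u^n); isolated so the algebraic reading
    # of the production term can be swapped in one place if ever needed
    return a / (k + u**n)


def toggle_switch(
    parameters: Mapping[str, float] | None = None,
) -> VectorFieldModel:
    """Two mutually repressing genes; bistable with the default parameters.

    dx/dt = b_x - r_x x + a_x / (k_x + y^n)
    dy/dt = b_y - r_y y + a_y / (k_y + x^n)

    b is basal production, r linear degradation, a/(k + u^n) a repressive
    Hill term of cooperativity n.  The defaults (fold activations
    a_x/k_x = 2, a_y/k_y = 1.75) give two stable states — x-dominant and
    y-dominant — separated by a saddle.
    """
    p = dict(TOGGLE_SWITCH_DEFAULTS)
    if parameters:
        unknown = set(parameters) - set(p)
        if unknown:
            raise ValueError(f"unknown toggle-switch parameters: {unknown}")
        p.update({k: float(v) for k, v in parameters.items()})
    if any(v <= 0 for v in p.values()):
        raise ValueError("toggle-switch parameters must be positive")

    ax, ay = p["ax"], p["ay"]
    bx, by = p["bx"], p["by"]
    kx, ky = p["kx"], p["ky"]
    rx, ry = p["rx"], p["ry"]
    n = p["n"]

    def fx(s):
        x, y = s
        return bx - rx * x + _toggle_hill(ax, kx, y, n)

    def fy(s):
        x, y = s
        return by - ry * y + _toggle_hill(ay, ky, x, n)

    def jac(s):
        x, y = s
        dfx_dy = -ax * n * y ** (n - 1.0) / (kx + y**n) ** 2
        dfy_dx = -ay * n * x ** (n - 1.0) / (ky + x**n) ** 2
        return np.array([[-rx, dfx_dy], [dfy_dx, -ry]])

    return VectorFieldModel(
        dimension=2,
        components=(fx, fy),
        parameters=p,
        analytic_jacobian=jac,
        name="toggle_switch",
    )


def lotka_volterra(
    a: float = 1.0, b: float = 1.0, c: float = 1.0, d: float = 1.0
) -> VectorFieldModel:
    """Classical predator-prey model: dx/dt = ax - bxy, dy/dt = cxy - dy.

    x is prey and y predator biomass.  The coexistence point (d/c, a/b) is a
    centre surrounded by closed orbits, so the landscape is untrustworthy in
    the cyclic region — which the error map flags.
    """
    if min(a, b, c, d) <= 0:
        raise ValueError("Lotka-Volterra parameters must be positive")

    def jac(s):
        x, y = s
        return np.array([[a - b * y, -b * x], [c * y, c * x - d]])

    return VectorFieldModel(
        dimension=2,
        components=(
            lambda s: a * s[0] - b * s[0] * s[1],
            lambda s: c * s[0] * s[1] - d * s[1],
        ),
        parameters={"a": a, "b": b, "c": c, "d": d},
        analytic_jacobian=jac,
        name="lotka_volterra",
    )


def selkov(a: float = 0.1, b: float = 0.1) -> VectorFieldModel:
    """Selkov glycolysis model: dx/dt = -x + ay + x^2 y, dy/dt = b - ay - x^2 y.

    x, y are the concentrations of two metabolites.  The unique equilibrium
    sits at (b, b/(a + b^2)); at a = 0.1 it loses stability in a Hopf
    bifurcation and a limit cycle exists for b between roughly 0.42 and 0.79.
    The Jacobian — hence the error map — does not depend on b.
    """
    if a <= 0 or b < 0:
        raise ValueError("selkov requires a > 0 and b >= 0")

    def jac(s):
        x, y = s
        return np.array(
            [
                [-1.0 + 2.0 * x * y, a + x * x],
                [-2.0 * x * y, -(a + x * x)],
            ]
        )

    return VectorFieldModel(
        dimension=2,
        components=(
            lambda s: -s[0] + a * s[1] + s[0] ** 2 * s[1],
            lambda s: b - a * s[1] - s[0] ** 2 * s[1],
        ),
        parameters={"a": a, "b": b},
        analytic_jacobian=jac,
        name="selkov",
    )


@dataclass(frozen=True, eq=False)
class Equilibrium:
    """A root of the vector field with its local linear classification."""

    location: np.ndarray
    eigenvalues: np.ndarray
    stability: str  # stable | unstable | saddle | center
    residual: float


def _classify(eigenvalues: np.ndarray, tol: float = _EIG_TOL) -> str:
    re_parts = eigenvalues.real
    if np.all(re_parts < -tol):
        return "stable"
    if np.all(re_parts > tol):
        return "unstable"
    if np.any(re_parts > tol) and np.any(re_parts < -tol):
        return "saddle"
    if np.all(np.abs(re_parts) <= tol) and np.any(
        np.abs(eigenvalues.imag) > tol
    ):
        return "center"
    # non-hyperbolic leftovers: fall back on the imaginary parts
    return "center" if np.any(np.abs(eigenvalues.imag) > tol) else "saddle"


def _newton_root(
    model: VectorFieldModel, seed: np.ndarray
) -> np.ndarray | None:
    """Damped Newton iteration from one seed; None on divergence."""
    x = np.asarray(seed, dtype=float).copy()
    try:
        r = float(np.linalg.norm(model(x)))
    except DomainEvaluationError:
        return None
    for _ in range(_NEWTON_MAX_ITER):
        if r < _NEWTON_TOL:
            return x
        try:
            f = model(x)
            J = model.jacobian(x)
            step = np.linalg.solve(J, -f)
        except (DomainEvaluationError, np.linalg.LinAlgError):
            return None
        lam = 1.0
        accepted = False
        while lam > 1e-10:
            cand = x + lam * step
            try:
                r_cand = float(np.linalg.norm(model(cand)))
            except DomainEvaluationError:
                r_cand = np.inf
            if r_cand < r:
                x, r = cand, r_cand
                accepted = True
                break
            lam *= _NEWTON_DAMPING
        if not accepted:
            return None
    return x if r < _NEWTON_TOL else None


def find_equilibria(
    model: VectorFieldModel, grid: RectGrid
) -> list:
    """Locate and classify the equilibria of ``model`` inside the grid box.

    Deterministic multi-start: every grid node that is a local minimum of
    ``||f||`` over its lattice neighbourhood seeds a damped Newton iteration;
    converged roots inside the grid's bounding box are deduplicated (1e-6)
    and classified by the eigenvalues of the Jacobian.  Sorted
    lexicographically by location.
    """
    shape = grid.shape
    norms = np.empty(shape)
    for index in np.ndindex(*shape):
        norms[index] = np.linalg.norm(model(grid.node(index)))

    neighbour_offsets = [
        off
        for off in itertools.product((-1, 0, 1), repeat=grid.ndim)
        if any(off)
    ]
    seeds = []
    for index in np.ndindex(*shape):
        value = norms[index]
        is_min = True
        for off in neighbour_offsets:
            nb = tuple(i + o for i, o in zip(index, off))
            if all(0 <= i < s for i, s in zip(nb, shape)) and norms[nb] < value:
                is_min = False
                break
        if is_min:
            seeds.append(grid.node(index))

    lo = np.array([a[0] for a in grid.axes])
    hi = np.array([a[-1] for a in grid.axes])
    roots: list[np.ndarray] = []
    for seed in seeds:
        root = _newton_root(model, seed)
        if root is None:
            logger.debug("Newton diverged from seed %s", seed.tolist())
            continue
        if np.any(root < lo - 1e-9) or np.any(root > hi + 1e-9):
            continue
        if any(np.max(np.abs(root - r)) < _DEDUP_TOL for r in roots):
            continue
        roots.append(root)

    equilibria = []
    for root in sorted(roots, key=lambda r: tuple(r)):
        eigs = np.linalg.eigvals(model.jacobian(root))
        equilibria.append(
            Equilibrium(
                location=root,
                eigenvalues=eigs,
                stability=_classify(eigs),
                residual=float(np.linalg.norm(model(root))),
            )
        )
    return equilibria


def selkov_hopf_points(a: float) -> tuple:
    """The two Hopf-bifurcation values of b for the Selkov model at given a.

    At the equilibrium (b, b/(a + b^2)) the Jacobian trace changes sign
    twice as b grows (for 0 < a < 1/8); between the two roots the equilibrium
    is unstable and a limit cycle exists.  The roots satisfy the quartic
    b^4 - (1 - 2a) b^2 + a + a^2 = 0; here they are found by bracketing and
    bisecting the trace itself, evaluated through the model's Jacobian.
    """
    if a <= 0:
        raise ValueError("a must be positive")
    model = selkov(a, 1.0)  # Jacobian independent of b

    def trace_at(b: float) -> float:
        state = np.array([b, b / (a + b * b)])
        J = model.jacobian(state)
        return float(J[0, 0] + J[1, 1])

    bs = np.linspace(1e-9, 2.0, 801)
    values = np.array([trace_at(b) for b in bs])
    brackets = [
        (bs[i], bs[i + 1])
        for i in range(len(bs) - 1)
        if values[i] == 0.0 or (values[i] < 0) != (values[i + 1] < 0)
    ]
    if len(brackets) < 2:
        raise ValueError(f"no Hopf pair for this a ({a!r})")

    def bisect(lo: float, hi: float) -> float:
        flo = trace_at(lo)
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            fmid = trace_at(mid)
            if fmid == 0.0:
                return mid
            if (fmid < 0) == (flo < 0):
                lo, flo = mid, fmid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    b_low = bisect(*brackets[0])
    b_high = bisect(*brackets[1])
    return (b_low, b_high) if b_low <= b_high else (b_high, b_low)


#: built-in models addressable by name from configs and the CLI
MODEL_NAMES = (
    "four_well",
    "four_well_coupled",
    "rotation",
    "toggle_switch",
    "lotka_volterra",
    "selkov",
)


def make_model(
    name: str, parameters: Mapping[str, float] | None = None
) -> VectorFieldModel:
    """Instantiate a built-in model by name with optional parameter overrides."""
    parameters = dict(parameters or {})
    if name == "four_well":
        model = four_well(False)
    elif name == "four_well_coupled":
        model = four_well(True)
    elif name == "rotation":
        model = rotation()
    elif name == "toggle_switch":
        return toggle_switch(parameters or None)
    elif name == "lotka_volterra":
        allowed = {"a", "b", "c", "d"}
        if set(parameters) - allowed:
            raise ValueError(
                f"unknown lotka_volterra parameters: {set(parameters) - allowed}"
            )
        return lotka_volterra(**{k: float(v) for k, v in parameters.items()})
    elif name == "selkov":
        allowed = {"a", "b"}
        if set(parameters) - allowed:
            raise ValueError(
                f"unknown selkov parameters: {set(parameters) - allowed}"
            )
        return selkov(**{k: float(v) for k, v in parameters.items()})
    else:
        raise ValueError(
            f"unknown model {name!r}; built-ins: {', '.join(MODEL_NAMES)}"
        )
    if parameters:
        raise ValueError(f"model {name!r} takes no parameters")
    return model


# ======================================================================
# Configuration, user expressions, serialization, run driver
# ======================================================================

class ConfigError(ValueError):
    """A run configuration failed validation."""


_EXPR_TOKEN_RE = re.compile(r"^[\w\s+\-*/^().]*$")
_ALLOWED_FUNCTIONS = {"exp": sympy.exp, "log": sympy.log}
# minimal namespace for the code parse_expr generates; no builtins
_PARSE_GLOBALS = {
    "Integer": sympy.Integer,
    "Float": sympy.Float,
    "Rational": sympy.Rational,
    "Symbol": sympy.Symbol,
    "Function": sympy.Function,
}


def parse_expression(
    text: str, allowed_symbols: Mapping[str, sympy.Symbol]
) -> sympy.Expr:
    """Parse one component expression under a whitelisted grammar.

    Permitted: numbers, the given symbols, ``+ - * / ^``, parentheses, and
    the functions exp and log.  Anything else — including any other function
    or name — is rejected before evaluation; no general code execution path
    exists.
    """
    if not isinstance(text, str) or not text.strip():
        raise ConfigError("expression must be a non-empty string")
    if not _EXPR_TOKEN_RE.match(text) or "__" in text:
        raise ConfigError(f"expression contains forbidden characters: {text!r}")
    local = dict(allowed_symbols)
    local.update(_ALLOWED_FUNCTIONS)
    try:
        expr = parse_expr(
            text,
            local_dict=local,
            global_dict=dict(_PARSE_GLOBALS),
            transformations=standard_transformations + (convert_xor,),
        )
    except Exception as exc:  # sympy raises a zoo of error types
        raise ConfigError(f"cannot parse expression {text!r}: {exc}") from exc
    unknown = expr.free_symbols - set(allowed_symbols.values())
    if unknown:
        names = sorted(str(s) for s in unknown)
        raise ConfigError(f"unknown names in expression {text!r}: {names}")
    allowed_funcs = tuple(_ALLOWED_FUNCTIONS.values())
    for func in expr.atoms(sympy.Function):
        if not isinstance(func, allowed_funcs):
            raise ConfigError(
                f"function {func.func.__name__!r} not allowed in {text!r}"
            )
    return expr


def model_from_expressions(
    expressions: Sequence[str],
    parameters: Mapping[str, float] | None = None,
    name: str = "custom",
) -> VectorFieldModel:
    """Build a model from per-component expression strings.

    State variables are named x, y (and z in 3-D); parameters are substituted
    numerically before compilation.  The analytic Jacobian is obtained by
    symbolic differentiation, so user models enjoy the same exact error maps
    as the built-ins.
    """
    n = len(expressions)
    if n < 2:
        raise ConfigError("need at least two component expressions")
    if n <= 3:
        state_names = ("x", "y", "z")[:n]
    else:
        state_names = tuple(f"x{i}" for i in range(n))
    state_syms = sympy.symbols(state_names)
    parameters = dict(parameters or {})
    param_syms = {p: sympy.Symbol(p) for p in parameters}
    allowed = {s.name: s for s in state_syms}
    overlap = set(allowed) & set(param_syms)
    if overlap:
        raise ConfigError(f"parameter names shadow state variables: {overlap}")
    allowed.update(param_syms)

    subs = {param_syms[p]: float(v) for p, v in parameters.items()}
    exprs = [parse_expression(text, allowed).subs(subs) for text in expressions]
    for text, expr in zip(expressions, exprs):
        if expr.free_symbols - set(state_syms):
            leftover = sorted(
                str(s) for s in expr.free_symbols - set(state_syms)
            )
            raise ConfigError(
                f"expression {text!r} uses undefined parameters: {leftover}"
            )

    lambdas = [
        sympy.lambdify(state_syms, expr, modules="numpy") for expr in exprs
    ]
    components = tuple(
        (lambda fn: lambda s: float(fn(*s)))(fn) for fn in lambdas
    )
    jac_matrix = sympy.Matrix(exprs).jacobian(sympy.Matrix(state_syms))
    jac_fn = sympy.lambdify(state_syms, jac_matrix, modules="numpy")

    def analytic_jacobian(state: np.ndarray) -> np.ndarray:
        return np.asarray(jac_fn(*state), dtype=float)

    return VectorFieldModel(
        dimension=n,
        components=components,
        parameters=parameters,
        analytic_jacobian=analytic_jacobian,
        name=name,
    )


@dataclass
class RunConfig:
    """Validated description of one landscape computation.

    ``model`` is either a built-in name or a list of component expression
    strings; ``seed`` is reserved for forward compatibility — the pipeline
    itself is deterministic.
    """

    model: str | Sequence[str]
    bounds: Sequence[Sequence[float]]
    resolution: Sequence[int]
    parameters: Mapping[str, float] = field(default_factory=dict)
    sweep_mode: str = "x_first"
    error_threshold: float = DEFAULT_TRUST_THRESHOLD
    output_path: str = "quasiscape.csv"
    summary_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sweep_mode not in _SWEEP_MODES:
            raise ConfigError(
                f"sweep_mode must be one of {_SWEEP_MODES}, "
                f"got {self.sweep_mode!r}"
            )
        if not 0.0 <= float(self.error_threshold) <= 1.0:
            raise ConfigError("error_threshold must lie in [0, 1]")
        if len(self.bounds) != len(self.resolution):
            raise ConfigError("bounds and resolution must have equal length")
        if len(self.bounds) < 2:
            raise ConfigError("need at least two axes (bounds/resolution)")
        for d, pair in enumerate(self.bounds):
            if len(pair) != 2 or not float(pair[0]) < float(pair[1]):
                raise ConfigError(
                    f"axis {d}: bounds must be [min, max] with min < max"
                )
        for d, n in enumerate(self.resolution):
            if int(n) < 2:
                raise ConfigError(f"axis {d}: resolution must be >= 2")
        if self.summary_path is None:
            self.summary_path = str(self.output_path) + ".summary.json"

    def build_model(self) -> VectorFieldModel:
        if isinstance(self.model, str):
            return make_model(self.model, self.parameters)
        return model_from_expressions(list(self.model), self.parameters)

    def build_grid(self) -> RectGrid:
        return RectGrid.from_bounds(self.bounds, self.resolution)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    import yaml

    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    missing = {"model", "bounds", "resolution"} - set(raw)
    if missing:
        raise ConfigError(f"{path}: missing required keys {sorted(missing)}")
    config = RunConfig(**raw)
    # fail fast on model/expression problems, with the file named
    try:
        config.build_model()
    except (ValueError, ConfigError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    logger.info(
        "loaded config: model=%s grid=%s sweep=%s threshold=%s",
        config.model, tuple(config.resolution), config.sweep_mode,
        config.error_threshold,
    )
    return config


def write_grid_table(
    result: QuasiPotentialResult,
    path: str | Path,
    threshold: float = DEFAULT_TRUST_THRESHOLD,
) -> None:
    """Write the landscape as CSV: columns x, y, V, err, trusted.

    Row-major with x varying fastest; floats at 17 significant digits so a
    re-read reproduces the arrays bit-exactly.
    """
    if result.grid.ndim != 2:
        raise ValueError("grid tables are defined for 2-D results")
    if not np.all(np.isfinite(result.V)) or not np.all(np.isfinite(result.err)):
        raise ValueError("result contains non-finite entries")
    ax_x, ax_y = result.grid.axes
    X = np.broadcast_to(ax_x[:, None], result.grid.shape)
    Y = np.broadcast_to(ax_y[None, :], result.grid.shape)
    trusted = (result.err < threshold).astype(int)
    frame = pd.DataFrame(
        {
            "x": X.flatten(order="F"),
            "y": Y.flatten(order="F"),
            "V": result.V.flatten(order="F"),
            "err": result.err.flatten(order="F"),
            "trusted": trusted.flatten(order="F"),
        }
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def read_grid_table(path: str | Path) -> pd.DataFrame:
    """Read back a grid table written by :func:`write_grid_table`."""
    return pd.read_csv(path, float_precision="round_trip")


def run(config: RunConfig) -> int:
    """Execute a configured computation; write CSV grid + JSON summary.

    Returns a process exit status (0 on success).  On a model-evaluation
    failure partial output files are removed and a nonzero status returned.
    """
    out_path = Path(config.output_path)
    summary_path = Path(config.summary_path)
    try:
        model = config.build_model()
        grid = config.build_grid()
        result = compute(model, grid, mode=config.sweep_mode)
        equilibria = find_equilibria(model, grid)
    except (ConfigError, ValueError) as exc:
        logger.error("run failed: %s", exc)
        return 1

    threshold = float(config.error_threshold)
    try:
        write_grid_table(result, out_path, threshold=threshold)
        summary = {
            "model": model.name,
            "parameters": {k: float(v) for k, v in model.parameters.items()},
            "grid": {
                "bounds": [[float(a[0]), float(a[-1])] for a in grid.axes],
                "resolution": list(grid.shape),
                "spacing": [float(h) for h in grid.spacing],
            },
            "sweep_mode": config.sweep_mode,
            "equilibria": [
                {
                    "location": eq.location.tolist(),
                    "stability": eq.stability,
                    "eigenvalues": [
                        [float(ev.real), float(ev.imag)]
                        for ev in eq.eigenvalues
                    ],
                    "residual": eq.residual,
                }
                for eq in equilibria
            ],
            "max_err": float(result.err.max()),
            "trusted_fraction": float(np.mean(result.err < threshold)),
            "error_threshold": threshold,
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    except Exception as exc:
        logger.error("writing outputs failed: %s", exc)
        for p in (out_path, summary_path):
            if p.exists():
                p.unlink()
        return 1
    logger.info(
        "wrote %s and %s (max err %.4g, trusted fraction %.3f)",
        out_path, summary_path, summary["max_err"],
        summary["trusted_fraction"],
    )
    return 0
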