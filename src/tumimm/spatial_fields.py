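"""Spatial discretization on the unit disc and the immune-cell transport solver.

Immune cells live on the two-dimensional unit disc.  They diffuse with a
constant coefficient ``D`` and drift up the gradient of a chemotactic
potential ``phi`` with sensitivity ``chi``; the potential itself solves a
Neumann elliptic problem sourced by a tumor-mass-dependent signal.  All
space-resolved quantities (the antitumor/protumor/exhausted cell
concentrations, the Gaussian form functions and sources) share one
discretization: Cartesian finite volumes on the bounding square ``[-1, 1]^2``
with a masked (staircase) unit disc.

Boundary conditions: homogeneous Dirichlet for cell concentrations (immune
cells far from the tumor are non-activated), zero normal flux for the
potential.  The Neumann problem is only solvable for a zero-mean right-hand
side, so the source is projected onto zero mean before the solve and the
gauge is fixed by a zero-mean potential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "DiscGrid",
    "ScalarField",
    "GaussianSpec",
    "TransportCoefficients",
    "make_disc_grid",
    "gaussian_field",
    "solve_potential",
    "advance_field",
    "advection_cfl_dt",
    "integrate_weighted",
    "advection_matrix",
]


@dataclass(frozen=True)
class TransportCoefficients:
    """Chemotactic sensitivity ``chi``, cell diffusion ``D``, signal diffusion ``K``."""

    chi: float = 0.864
    D: float = 0.05
    K: float = 1.0

    def __post_init__(self):
        if self.chi <= 0 or self.D <= 0 or self.K <= 0:
            raise ValueError("chi, D, K must all be positive")


@dataclass(frozen=True)
class GaussianSpec:
    """Isotropic Gaussian form function ``(A / (2 pi xi2)) exp(-|x-c|^2 / (2 xi2))``."""

    amplitude: float
    xi2: float
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.xi2 <= 0:
            raise ValueError("variance xi2 must be positive")


class DiscGrid:
    """Masked Cartesian grid for the unit disc embedded in ``[-1, 1]^2``.

    Cells whose center lies strictly inside the unit circle are active; all
    fields are stored as flat arrays over the active cells.  The grid owns the
    sparse operators shared by every field: the Neumann Laplacian (for the
    potential), the Dirichlet Laplacian (for cell diffusion), and the interior
    face lists used by the upwind advection scheme.
    """

    def __init__(self, n_axis: int):
        if n_axis < 8:
            raise ValueError("n_axis must be at least 8")
        self.n_axis = int(n_axis)
        self.h = 2.0 / n_axis
        self.cell_area = self.h * self.h
        x1 = -1.0 + self.h * (np.arange(n_axis) + 0.5)
        X, Y = np.meshgrid(x1, x1, indexing="ij")
        self.mask = (X * X + Y * Y) < 1.0
        self.n_active = int(self.mask.sum())
        self.xy = np.column_stack([X[self.mask], Y[self.mask]])
        index = -np.ones((n_axis, n_axis), dtype=np.int64)
        index[self.mask] = np.arange(self.n_active)
        self._index = index
        self._build_faces()
        self._build_operators()
        self._neumann_lu = None
        self._dirichlet_lus: dict[float, object] = {}

    # -- construction ---------------------------------------------------

    def _build_faces(self):
        idx = self._index
        faces = []
        for axis in (0, 1):
            a = idx[:-1, :] if axis == 0 else idx[:, :-1]
            b = idx[1:, :] if axis == 0 else idx[:, 1:]
            both = (a >= 0) & (b >= 0)
            faces.append((a[both], b[both]))
        # interior faces: (left cell, right cell) per axis, left at smaller coord
        self.faces_x = faces[0]
        self.faces_y = faces[1]
        # count of faces from each active cell to masked-out territory
        # (Dirichlet closures for diffusion)
        n_bnd = np.zeros(self.n_active, dtype=np.int64)
        padded = -np.ones((self.n_axis + 2, self.n_axis + 2), dtype=np.int64)
        padded[1:-1, 1:-1] = idx
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb = padded[1 + di:self.n_axis + 1 + di, 1 + dj:self.n_axis + 1 + dj]
            here = (idx >= 0) & (nb < 0)
            np.add.at(n_bnd, idx[here], 1)
        self.n_boundary_faces = n_bnd

    def _build_operators(self):
        n, h2 = self.n_active, self.h * self.h
        rows, cols, vals = [], [], []
        for fa, fb in (self.faces_x, self.faces_y):
            rows += [fa, fb, fa, fb]
            cols += [fb, fa, fa, fb]
            vals += [np.full(fa.size, -1.0 / h2), np.full(fa.size, -1.0 / h2),
                     np.full(fa.size, 1.0 / h2), np.full(fb.size, 1.0 / h2)]
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        # Neumann: interior faces only (zero flux through the staircase boundary)
        self.lap_neumann = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        # Dirichlet: add ghost-cell closure, value 0 at the face (distance h/2)
        bnd = sp.diags(self.n_boundary_faces * 2.0 / h2)
        self.lap_dirichlet = (self.lap_neumann + bnd).tocsc()

    # -- cached factorizations ------------------------------------------

    def neumann_solver(self):
        """LU of the Neumann Laplacian with one cell pinned (gauge)."""
        if self._neumann_lu is None:
            A = self.lap_neumann.tolil(copy=True)
            A[0, :] = 0.0
            A[0, 0] = 1.0
            self._neumann_lu = spla.splu(A.tocsc())
        return self._neumann_lu

    def dirichlet_helmholtz_solver(self, coef: float):
        """LU of ``I + coef * (-Laplacian_Dirichlet)`` cached by coefficient."""
        key = round(float(coef), 15)
        if key not in self._dirichlet_lus:
            A = sp.identity(self.n_active, format="csc") + coef * self.lap_dirichlet
            self._dirichlet_lus[key] = spla.splu(A)
        return self._dirichlet_lus[key]


@dataclass
class ScalarField:
    """A scalar quantity stored on the active cells of a :class:`DiscGrid`."""

    grid: DiscGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_active,):
            raise ValueError("values length does not match the number of active cells")

    @classmethod
    def zeros(cls, grid: DiscGrid) -> "ScalarField":
        return cls(grid, np.zeros(grid.n_active))

    @classmethod
    def constant(cls, grid: DiscGrid, value: float) -> "ScalarField":
        return cls(grid, np.full(grid.n_active, float(value)))

    def integral(self) -> float:
        return float(self.values.sum() * self.grid.cell_area)


def make_disc_grid(n_axis: int) -> DiscGrid:
    """Build the masked unit-disc grid with ``n_axis`` cells per axis."""
    return DiscGrid(n_axis)


def gaussian_field(spec: GaussianSpec, grid: DiscGrid) -> ScalarField:
    """Evaluate a Gaussian form function at the active cell centers."""
    d2 = ((grid.xy[:, 0] - spec.center[0]) ** 2
          + (grid.xy[:, 1] - spec.center[1]) ** 2)
    vals = spec.amplitude / (2.0 * np.pi * spec.xi2) * np.exp(-d2 / (2.0 * spec.xi2))
    return ScalarField(grid, vals)


def solve_potential(sigma: ScalarField, coeffs: TransportCoefficients,
                    strength: float, grid: DiscGrid) -> ScalarField:
    """Chemotactic potential: ``-div(K grad phi) = strength * sigma~``, Neumann.

    ``sigma~`` is the source projected onto zero mean over the disc, the
    compatibility condition for the pure-Neumann problem; the gauge is fixed
    by a zero-mean potential.  ``strength`` is the tumor-mass response
    ``f(mu1) >= 0``.
    """
    if sigma.grid is not grid:
        raise ValueError("sigma lives on a different grid")
    if strength < 0:
        raise ValueError("strength must be nonnegative")
    if strength == 0.0:
        return ScalarField.zeros(grid)
    rhs = strength * sigma.values.copy()
    rhs -= rhs.mean()
    # compatibility must hold exactly before the solve
    if abs(rhs.mean()) > 1e-10 * (np.abs(rhs).max() + 1e-300):
        raise RuntimeError("zero-mean projection of the elliptic source failed")
    rhs = rhs / coeffs.K
    rhs_pinned = rhs.copy()
    rhs_pinned[0] = 0.0  # pinned-cell gauge equation
    phi = grid.neumann_solver().solve(rhs_pinned)
    phi -= phi.mean()
    return ScalarField(grid, phi)


def _face_velocities(phi: ScalarField, chi: float):
    """Face-normal drift ``chi * dphi/dn`` on interior faces (zero on boundary)."""
    g = phi.grid
    v = phi.values
    vx = chi * (v[g.faces_x[1]] - v[g.faces_x[0]]) / g.h
    vy = chi * (v[g.faces_y[1]] - v[g.faces_y[0]]) / g.h
    return vx, vy


def advection_cfl_dt(phi: ScalarField, coeffs: TransportCoefficients) -> float:
    """Largest stable step for the explicit upwind drift substep."""
    g = phi.grid
    vx, vy = _face_velocities(phi, coeffs.chi)
    out = np.zeros(g.n_active)
    # sum of outgoing face speeds per cell
    np.add.at(out, g.faces_x[0], np.maximum(vx, 0.0))
    np.add.at(out, g.faces_x[1], np.maximum(-vx, 0.0))
    np.add.at(out, g.faces_y[0], np.maximum(vy, 0.0))
    np.add.at(out, g.faces_y[1], np.maximum(-vy, 0.0))
    s = float(out.max())
    return 0.9 * g.h / s if s > 0 else np.inf


def advance_field(u: ScalarField, phi: ScalarField, coeffs: TransportCoefficients,
                  gain: ScalarField | np.ndarray, loss_rate: ScalarField | np.ndarray,
                  dt: float) -> ScalarField:
    """One step of ``dt u + div(u chi grad phi - D grad u) = gain - loss_rate u``.

    Operator splitting: explicit upwind advection (positivity under the CFL
    constraint), implicit diffusion with the Dirichlet closure (monotone, so
    unconditionally positivity-preserving), and an implicit linear reaction
    update ``u <- (u + dt gain) / (1 + dt loss)``.  The scheme therefore maps
    nonnegative states with nonnegative gains to nonnegative states.
    """
    g = u.grid
    gain_v = gain.values if isinstance(gain, ScalarField) else np.asarray(gain, float)
    loss_v = (loss_rate.values if isinstance(loss_rate, ScalarField)
              else np.asarray(loss_rate, float))
    if np.any(gain_v < 0) or np.any(loss_v < 0):
        raise ValueError("gain and loss_rate must be nonnegative")
    dt_adv = advection_cfl_dt(phi, coeffs)
    if dt > dt_adv * (1 + 1e-12):
        raise ValueError(
            f"dt={dt:g} violates the advection stability bound; admissible dt <= {dt_adv:g}"
        )
    v = u.values
    vx, vy = _face_velocities(phi, coeffs.chi)
    # upwind advective fluxes on interior faces; Dirichlet (u=0) outside means
    # outgoing boundary flux would need phi outside the disc -- the Neumann
    # condition on phi makes the face-normal drift vanish there, so no term.
    flux_x = np.where(vx > 0, vx * v[g.faces_x[0]], vx * v[g.faces_x[1]])
    flux_y = np.where(vy > 0, vy * v[g.faces_y[0]], vy * v[g.faces_y[1]])
    div = np.zeros(g.n_active)
    np.add.at(div, g.faces_x[0], flux_x)
    np.add.at(div, g.faces_x[1], -flux_x)
    np.add.at(div, g.faces_y[0], flux_y)
    np.add.at(div, g.faces_y[1], -flux_y)
    v1 = v - dt * div / g.h
    v2 = g.dirichlet_helmholtz_solver(dt * coeffs.D).solve(v1)
    v3 = (v2 + dt * gain_v) / (1.0 + dt * loss_v)
    v3 = np.maximum(v3, 0.0)  # clip rounding-level negatives from the LU solve
    return ScalarField(g, v3)


def integrate_weighted(u: ScalarField, w: ScalarField) -> float:
    """Discrete ``∫ w u dx`` over the disc (e.g. the immune kill strength)."""
    if u.grid is not w.grid:
        raise ValueError("fields live on different grids")
    return float(np.sum(u.values * w.values) * u.grid.cell_area)


def advection_matrix(phi: ScalarField, chi: float) -> sp.csr_matrix:
    """Sparse upwind advection operator ``u -> div(u chi grad phi)``.

    Used by the stationary (equilibrium-state) solver; the time stepper keeps
    advection matrix-free.
    """
    g = phi.grid
    n = g.n_active
    vx, vy = _face_velocities(phi, chi)
    rows, cols, vals = [], [], []
    for (fa, fb), vf in ((g.faces_x, vx), (g.faces_y, vy)):
        up = np.where(vf > 0, fa, fb)
        # face flux vf * u_up leaves cell a, enters cell b
        rows += [fa, fb]
        cols += [up, up]
        vals += [vf / g.h, -vf / g.h]
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
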