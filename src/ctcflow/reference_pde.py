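"""Explicit finite-difference oracle for the advection–diffusion equation.

This module exists to *check* the closed-form kernels, not to compete with
them.  It integrates

    dc/dt + u dc/dx = alpha * Laplacian(c)

on a truncated box in the half space, with

* centered second-order diffusion and first-order upwind advection,
  assembled in flux form so interior mass is conserved to round-off;
* an exactly zero wall-normal flux at the wall (the flux on the wall face
  is set to zero, equivalent to a ghost-mirror cell);
* absorbing far boundaries (zero ghost value) whose outflow is tracked as
  "leakage", because the analytic solution lives on an unbounded domain
  and truncation error must be measured rather than hidden.

The propagator test initializes the grid from the analytic kernel at a
small positive time (avoiding any mesh-dependent regularization of the
Dirac initial condition), steps forward, and compares against the kernel
at the later time.  The last grid axis is the wall-normal one (y in 2D, z
in 3D); its lower bound must be the wall itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .kernels import Normalization, Source, greens_2d, greens_3d

__all__ = [
    "PdeGrid",
    "PdeSolution",
    "fd_solve",
    "compare_fields",
    "make_grid",
]


@dataclass(frozen=True)
class PdeGrid:
    """Uniform rectangular grid + time step for the explicit scheme.

    ``bounds`` is one ``(lo, hi)`` pair per axis, ordered (x, y[, z]); the
    last axis is wall-normal and must start at 0 (the wall).  Cells are
    centered: the first cell center sits half a spacing off the wall, so
    the wall coincides with a cell *face* where the zero-flux condition is
    imposed exactly.
    """

    bounds: tuple[tuple[float, float], ...]
    h: tuple[float, ...]
    dt: float
    alpha: float
    u: float = 0.0

    def __post_init__(self) -> None:
        if len(self.bounds) not in (2, 3) or len(self.h) != len(self.bounds):
            raise ValueError("bounds/h must describe 2 or 3 matching axes")
        if self.bounds[-1][0] != 0.0:
            raise ValueError("wall-normal axis must start at the wall (0.0)")
        if self.alpha < 0 or self.u < 0 or self.dt <= 0:
            raise ValueError("alpha, u must be >= 0 and dt > 0")
        if self.alpha > 0:
            diff_number = self.alpha * self.dt * sum(1.0 / hk ** 2 for hk in self.h)
            if diff_number > 0.5 + 1e-12:
                raise ValueError(
                    f"diffusive stability violated: alpha*dt*sum(1/h^2) = "
                    f"{diff_number:.3f} > 1/2"
                )
        if self.u > 0:
            courant = self.u * self.dt / self.h[0]
            if courant > 1.0 + 1e-12:
                raise ValueError(f"Courant number {courant:.3f} > 1")

    @property
    def ndim(self) -> int:
        return len(self.bounds)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(int(round((hi - lo) / hk))
                     for (lo, hi), hk in zip(self.bounds, self.h))

    def centers(self) -> list[np.ndarray]:
        """Cell-center coordinate vector per axis."""
        out = []
        for (lo, _), hk, n in zip(self.bounds, self.h, self.shape):
            out.append(lo + hk * (np.arange(n) + 0.5))
        return out

    def meshgrid(self) -> list[np.ndarray]:
        return np.meshgrid(*self.centers(), indexing="ij")

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.h))


@dataclass
class PdeSolution:
    """Snapshots of the FD solution plus a mass/leakage audit."""

    grid: PdeGrid
    times: np.ndarray
    snapshots: list[np.ndarray]
    leakage: np.ndarray       # cumulative mass lost through far boundaries
    initial_mass: float

    def mass(self, i: int = -1) -> float:
        return float(np.sum(self.snapshots[i]) * self.grid.cell_volume)


def _step(c: np.ndarray, grid: PdeGrid) -> tuple[np.ndarray, float]:
    """One explicit flux-form step; returns (new field, mass leaked out)."""
    alpha, u = grid.alpha, grid.u
    ndim = grid.ndim
    dc = np.zeros_like(c)
    leaked = 0.0
    for axis in range(ndim):
        hk = grid.h[axis]
        # Diffusive flux on interior faces: F = -alpha * (c[i+1]-c[i])/h
        flux_int = -alpha * np.diff(c, axis=axis) / hk
        if axis == 0 and u > 0:
            # Upwind advective flux (u along +x): face carries u*c_left
            flux_int = flux_int + u * c[:-1]
        # Boundary faces. Wall face (last axis, low side): exact zero flux.
        lo_edge = np.take(c, [0], axis=axis)
        hi_edge = np.take(c, [c.shape[axis] - 1], axis=axis)
        if axis == ndim - 1:
            flux_lo = np.zeros_like(lo_edge)
        else:
            flux_lo = -alpha * (lo_edge - 0.0) / hk   # ghost value 0
            if axis == 0 and u > 0:
                flux_lo = flux_lo + u * 0.0           # upwind inflow from ghost
        flux_hi = -alpha * (0.0 - hi_edge) / hk
        if axis == 0 and u > 0:
            flux_hi = flux_hi + u * hi_edge
        flux = np.concatenate([flux_lo, flux_int, flux_hi], axis=axis)
        dc -= np.diff(flux, axis=axis) / hk
        # Outflow bookkeeping: positive flux_hi leaves through the high face,
        # negative flux_lo leaves through the low face.
        face_area = grid.cell_volume / hk
        leaked += float((np.sum(flux_hi) - np.sum(flux_lo)) * face_area)
    return c + grid.dt * dc, leaked * grid.dt


def _analytic_on_grid(grid: PdeGrid, source: Source, t: float,
                      normalization: Normalization) -> np.ndarray:
    mesh = grid.meshgrid()
    if grid.ndim == 2:
        if grid.u != 0:
            raise ValueError("the 2D kernel is defined for the no-flow case")
        return greens_2d(mesh[0], mesh[1], t, x0=source.x0, y0=source.y0,
                         strength=source.strength, alpha=source.alpha)
    return greens_3d(mesh[0], mesh[1], mesh[2], t, x0=source.x0, y0=source.y0,
                     z0=source.z0, u=grid.u, strength=source.strength,
                     alpha=source.alpha, normalization=normalization)


def fd_solve(grid: PdeGrid, source: Source, t_init: float, t_final: float,
             normalization: Normalization = Normalization.TEXTBOOK_PUFF,
             output_times: Sequence[float] | None = None) -> PdeSolution:
    """Propagate the analytic field from ``t_init`` to ``t_final`` numerically.

    The initial condition is the analytic kernel evaluated at ``t_init >
    0``, so the comparison against the kernel at ``t_final`` is a pure
    propagator test with no delta-function regularization involved.
    ``grid.alpha`` must match ``source.alpha`` (the PDE being solved is the
    one the source diffuses under).
    """
    if not t_init > 0:
        raise ValueError("t_init must be > 0 (initialize past the Dirac release)")
    if t_final < t_init:
        raise ValueError("t_final must be >= t_init")
    if grid.alpha != source.alpha:
        raise ValueError("grid.alpha must equal source.alpha")
    c = _analytic_on_grid(grid, source, t_init, normalization)
    initial_mass = float(np.sum(c) * grid.cell_volume)
    wanted = sorted(set(float(t) for t in (output_times or [])) | {float(t_final)})
    if any(t < t_init or t > t_final for t in wanted):
        raise ValueError("output times must lie in [t_init, t_final]")

    times = [t_init]
    snapshots = [c.copy()]
    leak_records = [0.0]
    t = t_init
    leaked_total = 0.0
    for t_out in wanted:
        while t < t_out - 1e-12:
            dt_step = min(grid.dt, t_out - t)
            if dt_step < grid.dt - 1e-15:
                # Final partial step: same flux assembly, shorter dt.
                partial = PdeGrid(bounds=grid.bounds, h=grid.h, dt=dt_step,
                                  alpha=grid.alpha, u=grid.u)
                c, leaked = _step(c, partial)
            else:
                c, leaked = _step(c, grid)
            leaked_total += leaked
            t += dt_step
        times.append(t_out)
        snapshots.append(c.copy())
        leak_records.append(leaked_total)
    return PdeSolution(grid=grid, times=np.asarray(times),
                       snapshots=snapshots,
                       leakage=np.asarray(leak_records),
                       initial_mass=initial_mass)


def compare_fields(analytic: Callable[..., np.ndarray], sol: PdeSolution,
                   time_index: int = -1, norm: str = "l2",
                   margin: int = 0) -> float:
    """Discrepancy between an analytic evaluator and an FD snapshot.

    ``analytic`` is called with the grid's cell-center meshgrid arrays plus
    the snapshot time.  ``margin`` excludes that many cells from every
    boundary (truncation-affected rim).  Norms: ``"l2"`` (relative) or
    ``"linf"``.
    """
    grid = sol.grid
    mesh = grid.meshgrid()
    t = float(sol.times[time_index])
    ref = analytic(*mesh, t)
    num = sol.snapshots[time_index]
    if ref.shape != num.shape:
        raise ValueError("analytic field and FD snapshot shapes differ")
    if margin:
        sl = tuple(slice(margin, -margin) for _ in range(grid.ndim))
        ref, num = ref[sl], num[sl]
    diff = num - ref
    if norm == "l2":
        denom = float(np.linalg.norm(ref.ravel()))
        if denom == 0.0:
            return float(np.linalg.norm(diff.ravel()))
        return float(np.linalg.norm(diff.ravel()) / denom)
    if norm == "linf":
        return float(np.max(np.abs(diff)))
    raise ValueError(f"unknown norm {norm!r}")


def make_grid(bounds: Sequence[tuple[float, float]], h: float | Sequence[float],
              alpha: float, u: float = 0.0, safety: float = 0.8) -> PdeGrid:
    """Build a grid with a stable time step.

    ``dt`` is ``safety`` times the tighter of the diffusive bound
    ``1/2 / (alpha sum 1/h^2)`` and the advective bound ``h_x / u``.
    """
    bounds = tuple((float(lo), float(hi)) for lo, hi in bounds)
    if np.isscalar(h):
        h = (float(h),) * len(bounds)
    else:
        h = tuple(float(v) for v in h)
    limits = []
    if alpha > 0:
        limits.append(0.5 / (alpha * sum(1.0 / hk ** 2 for hk in h)))
    if u > 0:
        limits.append(h[0] / u)
    if not limits:
        limits = [1.0]
    dt = safety * min(limits)
    return PdeGrid(bounds=bounds, h=h, dt=dt, alpha=alpha, u=u)
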