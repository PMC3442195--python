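"""Closed-form concentration kernels for point sources near a no-flux wall.

A circulating tumor cell (CTC) is modeled as a point source of a passive
procoagulant scalar (tissue-factor-dependent activity, e.g. thrombin)
released into the half of space bounded by the vessel wall.  The wall
imposes a no-penetration condition — zero wall-normal concentration
gradient — which is satisfied exactly by the method of images: every
source has a mirror partner reflected across the wall, and the physical
field is the sum of the two free-space kernels.

Two flow regimes are supported:

* **2D, no flow** (:func:`eval_kernel_2d`): the instantaneous Gaussian
  heat kernel in the upper half plane ``y >= 0``, image at ``(x0, -y0)``::

      c = strength / (4 pi alpha t)
          * [exp(-((x-x0)^2 + (y-y0)^2) / (4 alpha t))
             + exp(-((x-x0)^2 + (y+y0)^2) / (4 alpha t))]

* **3D, constant flow** ``u`` along ``+x`` (:func:`eval_kernel_3d`): an
  advected Gaussian kernel in the upper half space ``z >= 0`` with image
  at height ``-H`` (``H = z0``, the release height).  Two normalizations
  are available, see :class:`Normalization`.

All quantities are dimensionless; no unit system is imposed.  Time must be
strictly positive (the ``t = 0`` Dirac initial condition is rejected, not
special-cased).

The module has two layers.  The low-level array functions
(:func:`greens_2d`, :func:`greens_3d`) evaluate the raw formulas anywhere,
including at mirrored (negative wall-normal) coordinates — the image
construction makes the field an even function of the wall-normal
coordinate, and evaluating on both sides is exactly what the wall-flux
diagnostic and the finite-difference oracle need.  The typed layer
(:func:`eval_kernel_2d`, :func:`eval_kernel_3d`, :func:`superpose`)
enforces the half-space domain and the flow-mode contracts.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "FlowMode",
    "Normalization",
    "Source",
    "FlowSpec",
    "EvalPoint",
    "GridSpec",
    "FieldGrid",
    "greens_2d",
    "greens_3d",
    "eval_kernel_2d",
    "eval_kernel_3d",
    "superpose",
    "evaluate_field",
    "eval_field_grid",
    "make_field_evaluator",
]


class FlowMode(enum.Enum):
    """Background flow regime of the run."""

    NO_FLOW_2D = "no_flow_2d"
    CONSTANT_FLOW_3D = "constant_flow_3d"


class Normalization(enum.Enum):
    """Normalization convention for the 3D advected kernel.

    AS_PRINTED
        Prefactor ``strength / (8 pi r^{3/2})`` with the plume-like scaled
        variable ``r = alpha * s / u`` (``s`` the downstream distance from
        the release point) appearing in every Gaussian width.  Undefined
        upstream; the field is set to 0 for ``s <= 0`` (standard plume
        convention).  This is the working kernel used by all reference runs.

    TEXTBOOK_PUFF
        The exact Green's function of the constant-flow advection–diffusion
        equation in the half space: an advected Gaussian puff with widths
        ``4 alpha t`` and prefactor ``(4 pi alpha t)^{3/2}``, defined for
        all ``s``.  This mode satisfies the governing PDE exactly and is
        the one gated against the finite-difference oracle.
    """

    AS_PRINTED = "as_printed"
    TEXTBOOK_PUFF = "textbook_puff"


@dataclass(frozen=True)
class Source:
    """One CTC: release position, emission strength, diffusion coefficient.

    ``strength`` lumps the emitted amount (the Gamma of the 2D kernel and
    the total expressed tissue factor Q_T of the 3D kernel).  ``alpha`` is
    the dimensionless diffusion coefficient of the emitted scalar.  ``z0``
    doubles as the release height ``H`` above the wall in 3D mode and is
    ignored in 2D mode.
    """

    x0: float
    y0: float
    z0: float = 0.0
    strength: float = 1.0
    alpha: float = 1.5

    def __post_init__(self) -> None:
        if not self.strength > 0:
            raise ValueError(f"source strength must be > 0, got {self.strength}")
        if not self.alpha > 0:
            raise ValueError(f"source alpha must be > 0, got {self.alpha}")


@dataclass(frozen=True)
class FlowSpec:
    """Background velocity: zero (2D mode) or constant along +x (3D mode)."""

    mode: FlowMode
    u: float = 0.0

    def __post_init__(self) -> None:
        if self.u < 0:
            raise ValueError("flow speed u must be >= 0")
        if self.mode is FlowMode.NO_FLOW_2D and self.u != 0.0:
            raise ValueError("NO_FLOW_2D requires u = 0")
        if self.mode is FlowMode.CONSTANT_FLOW_3D and not self.u > 0:
            raise ValueError(
                "CONSTANT_FLOW_3D requires u > 0 (r = alpha*s/u is undefined at u = 0)"
            )

    @classmethod
    def no_flow(cls) -> "FlowSpec":
        return cls(mode=FlowMode.NO_FLOW_2D, u=0.0)

    @classmethod
    def constant(cls, u: float) -> "FlowSpec":
        return cls(mode=FlowMode.CONSTANT_FLOW_3D, u=u)

    @property
    def ndim(self) -> int:
        return 2 if self.mode is FlowMode.NO_FLOW_2D else 3

    @property
    def wall_axis(self) -> int:
        """Index of the wall-normal coordinate (y in 2D, z in 3D)."""
        return 1 if self.mode is FlowMode.NO_FLOW_2D else 2


@dataclass(frozen=True)
class EvalPoint:
    """A space-time evaluation point; t must be strictly positive."""

    x: float
    y: float
    t: float
    z: float = 0.0

    def __post_init__(self) -> None:
        if not self.t > 0:
            raise ValueError(f"evaluation time must be > 0, got t={self.t}")


def _check_positive_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("evaluation time must be > 0")
    return t


def greens_2d(x, y, t, *, x0: float, y0: float, strength: float = 1.0,
              alpha: float = 1.5) -> np.ndarray:
    """Vectorized 2D no-flow kernel with wall image (raw formula).

    No half-plane check is applied to ``y``: the image construction makes
    the expression even in ``y``, and both sides are needed by the
    wall-flux diagnostic and the finite-difference oracle.
    """
    t = _check_positive_time(t)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    four_at = 4.0 * alpha * t
    dx2 = (x - x0) ** 2
    direct = np.exp(-(dx2 + (y - y0) ** 2) / four_at)
    image = np.exp(-(dx2 + (y + y0) ** 2) / four_at)
    return strength / (4.0 * math.pi * alpha * t) * (direct + image)


def greens_3d(x, y, z, t, *, x0: float, y0: float, z0: float, u: float,
              strength: float = 1.0, alpha: float = 1.5,
              normalization: Normalization = Normalization.AS_PRINTED) -> np.ndarray:
    """Vectorized 3D constant-flow kernel with wall image (raw formula).

    ``z0`` is the release height H; the image sits at ``-H``.  See
    :class:`Normalization` for the two conventions.  ``z`` is not
    restricted to the half space (evenness across the wall is exploited by
    diagnostics).
    """
    if not u > 0:
        raise ValueError("3D kernel requires u > 0")
    t = _check_positive_time(t)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    H = z0
    if normalization is Normalization.TEXTBOOK_PUFF:
        w = 4.0 * alpha * t  # Gaussian variance scale, all axes
        pref = strength / (math.pi * w) ** 1.5
        planar = np.exp(-(((x - x0) - u * t) ** 2 + (y - y0) ** 2) / w)
        vertical = np.exp(-((z - H) ** 2) / w) + np.exp(-((z + H) ** 2) / w)
        return pref * planar * vertical

    s = x - x0  # downstream distance from the release point
    mask = s > 0
    # Safe r for masked-out entries; results there are overwritten with 0.
    r = alpha * np.where(mask, s, 1.0) / u
    four_r = 4.0 * r
    pref = strength / (8.0 * math.pi * r ** 1.5)
    planar = np.exp(-((s - u * t) ** 2 + (y - y0) ** 2) / four_r)
    vertical = np.exp(-((z - H) ** 2) / four_r) + np.exp(-((z + H) ** 2) / four_r)
    out = pref * planar * vertical
    return np.where(mask, out, 0.0)


def eval_kernel_2d(source: Source, point: EvalPoint) -> float:
    """Single-source 2D no-flow concentration at a half-plane point."""
    if source.y0 < 0:
        raise ValueError("2D source must sit in the upper half plane (y0 >= 0)")
    if point.y < 0:
        raise ValueError("2D evaluation point must satisfy y >= 0")
    return float(greens_2d(point.x, point.y, point.t, x0=source.x0,
                           y0=source.y0, strength=source.strength,
                           alpha=source.alpha))


def eval_kernel_3d(source: Source, flow: FlowSpec, point: EvalPoint,
                   normalization: Normalization = Normalization.AS_PRINTED) -> float:
    """Single-source 3D constant-flow concentration at a half-space point."""
    if flow.mode is not FlowMode.CONSTANT_FLOW_3D:
        raise ValueError("eval_kernel_3d requires CONSTANT_FLOW_3D flow")
    if source.z0 < 0:
        raise ValueError("3D source release height H = z0 must be >= 0")
    if point.z < 0:
        raise ValueError("3D evaluation point must satisfy z >= 0")
    return float(greens_3d(point.x, point.y, point.z, point.t,
                           x0=source.x0, y0=source.y0, z0=source.z0,
                           u=flow.u, strength=source.strength,
                           alpha=source.alpha, normalization=normalization))


def superpose(sources: Sequence[Source], flow: FlowSpec, point: EvalPoint,
              normalization: Normalization = Normalization.AS_PRINTED) -> float:
    """Linear superposition of per-source kernels at one point.

    An empty source list returns 0 (a vessel with no CTCs carries no
    field); this is documented behavior, not an error.
    """
    total = 0.0
    if flow.mode is FlowMode.NO_FLOW_2D:
        for s in sources:
            total += eval_kernel_2d(s, point)
    else:
        for s in sources:
            total += eval_kernel_3d(s, flow, point, normalization)
    return total


def evaluate_field(sources: Sequence[Source], flow: FlowSpec, x, y, z, t,
                   normalization: Normalization = Normalization.AS_PRINTED) -> np.ndarray:
    """Superposed concentration on arrays of coordinates (broadcasting).

    This is the vectorized workhorse behind grids, peak scans and tracker
    polling.  Per-source contributions are accumulated in source order, so
    the result is bit-identical to a pointwise :func:`superpose` loop over
    the same sources (which accumulates in the same order).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    shape = np.broadcast_shapes(np.shape(x), np.shape(y),
                                np.shape(z) if z is not None else (),
                                np.shape(t))
    total = np.zeros(shape)
    if flow.mode is FlowMode.NO_FLOW_2D:
        for s in sources:
            total += greens_2d(x, y, t, x0=s.x0, y0=s.y0, strength=s.strength,
                               alpha=s.alpha)
    else:
        for s in sources:
            total += greens_3d(x, y, z, t, x0=s.x0, y0=s.y0, z0=s.z0, u=flow.u,
                               strength=s.strength, alpha=s.alpha,
                               normalization=normalization)
    return total


def make_field_evaluator(sources: Sequence[Source], flow: FlowSpec,
                         normalization: Normalization = Normalization.AS_PRINTED,
                         ) -> Callable[..., np.ndarray]:
    """Bind sources/flow into an ``f(x, y, z, t) -> concentration`` callable."""

    def field_at(x, y, z, t):
        return evaluate_field(sources, flow, x, y, z, t, normalization)

    return field_at


@dataclass(frozen=True)
class GridSpec:
    """Rectilinear sample coordinates for a slice or volume.

    ``x`` and ``y`` are 1D coordinate vectors; ``z`` is ``None`` in 2D
    mode and a 1D vector (possibly length 1, i.e. a z-slice) in 3D mode.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.atleast_1d(np.asarray(self.x, float)))
        object.__setattr__(self, "y", np.atleast_1d(np.asarray(self.y, float)))
        if self.z is not None:
            object.__setattr__(self, "z", np.atleast_1d(np.asarray(self.z, float)))

    @classmethod
    def from_bounds(cls, window: dict, resolution: int) -> "GridSpec":
        """Build a uniform grid from ``{"x": (lo, hi), "y": ..., ["z": ...]}``."""
        axes = {}
        for name, bounds in window.items():
            lo, hi = float(bounds[0]), float(bounds[1])
            axes[name] = np.linspace(lo, hi, resolution) if hi > lo else np.array([lo])
        return cls(x=axes["x"], y=axes["y"], z=axes.get("z"))


@dataclass
class FieldGrid:
    """Concentration sampled on a rectilinear grid at one time."""

    values: np.ndarray
    x: np.ndarray
    y: np.ndarray
    t: float
    z: np.ndarray | None = None
    attrs: dict = field(default_factory=dict)

    def to_xarray(self):
        """Self-describing container view (``xarray.DataArray``)."""
        import xarray as xr

        coords = {"x": self.x, "y": self.y}
        dims = ["x", "y"]
        if self.z is not None:
            coords["z"] = self.z
            dims.append("z")
        attrs = {"t": self.t, **{k: str(v) for k, v in self.attrs.items()}}
        return xr.DataArray(self.values, coords=coords, dims=dims, attrs=attrs)


def eval_field_grid(sources: Sequence[Source], flow: FlowSpec, grid: GridSpec,
                    t: float,
                    normalization: Normalization = Normalization.AS_PRINTED,
                    ) -> FieldGrid:
    """Superposed field on every cell of a grid (wall-respecting).

    The grid must lie entirely in the closed half space: ``y >= 0`` in 2D,
    ``z >= 0`` in 3D.  Values are identical (bitwise) to calling
    :func:`superpose` cell by cell.
    """
    if not t > 0:
        raise ValueError("t must be > 0")
    if flow.mode is FlowMode.NO_FLOW_2D:
        if np.any(grid.y < 0):
            raise ValueError("2D grid crosses the wall: all y must be >= 0")
        X, Y = np.meshgrid(grid.x, grid.y, indexing="ij")
        values = evaluate_field(sources, flow, X, Y, None, t, normalization)
        return FieldGrid(values=values, x=grid.x, y=grid.y, t=t)
    if grid.z is None:
        raise ValueError("3D mode requires a z coordinate vector")
    if np.any(grid.z < 0):
        raise ValueError("3D grid crosses the wall: all z must be >= 0")
    X, Y, Z = np.meshgrid(grid.x, grid.y, grid.z, indexing="ij")
    values = evaluate_field(sources, flow, X, Y, Z, t, normalization)
    return FieldGrid(values=values, x=grid.x, y=grid.y, z=grid.z, t=t)
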