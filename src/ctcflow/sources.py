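"""Construction, seeded random placement, and advection of CTC source sets.

CTCs enter the vessel at random positions; each run either lists its
sources explicitly or describes them with a :class:`PlacementRecipe`
(count + axis-aligned placement box + seed + shared emission parameters).
Placement is reproducible: the random bit generator is pinned by name
(PCG64) so a ``(recipe, seed)`` pair yields the same source set on every
platform and process.

Advection: in constant flow every cell drifts downstream at the flow
speed, ``x0(t) = x0(0) + u t``.  The 3D field kernel already carries this
drift through its ``(x - u t)`` traveling term, so field evaluation must
use *release* positions; :func:`advect_sources` exists for trajectory
output and for co-plotting cell positions with trackers, never for
feeding the kernels (doing so would double-apply the advection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .kernels import FlowMode, FlowSpec, Source

__all__ = [
    "Box",
    "PlacementRecipe",
    "SourceSet",
    "place_random",
    "four_ctc_sources",
    "advect_sources",
]

#: Explicit 3D release positions (x, y, z) of the four-CTC reference run.
FOUR_CTC_POSITIONS = ((300.0, 300.0, 45.0), (180.0, 400.0, 30.0),
                      (300.0, 100.0, 30.0), (275.0, 200.0, 60.0))

#: Dimensionless per-cell diffusion coefficient used in all reference runs.
DEFAULT_ALPHA = 1.5


@dataclass(frozen=True)
class Box:
    """Axis-aligned placement bounds; ``z`` is None for 2D (no-flow) runs.

    The wall-normal axis (y when ``z is None``, else z) must not dip below
    the wall.
    """

    x: tuple[float, float]
    y: tuple[float, float]
    z: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name, bounds in self.items():
            lo, hi = bounds
            if not hi > lo:
                raise ValueError(f"degenerate box along {name}: {bounds}")
        wall_name, (wall_lo, _) = ("y", self.y) if self.z is None else ("z", self.z)
        if wall_lo < 0:
            raise ValueError(
                f"placement box crosses the wall: {wall_name} lower bound "
                f"{wall_lo} < 0"
            )

    def items(self):
        axes = [("x", self.x), ("y", self.y)]
        if self.z is not None:
            axes.append(("z", self.z))
        return axes

    @property
    def ndim(self) -> int:
        return 2 if self.z is None else 3


@dataclass(frozen=True)
class PlacementRecipe:
    """Seeded i.i.d.-uniform placement of ``count`` identical-parameter CTCs."""

    count: int
    box: Box
    seed: int
    strength: float = 1.0
    alpha: float = DEFAULT_ALPHA
    #: Bit generator pinned by name so seeds are portable across platforms.
    bit_generator: str = "PCG64"

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("recipe count must be >= 1")
        if self.bit_generator != "PCG64":
            raise ValueError("only the PCG64 bit generator is supported")


@dataclass(frozen=True)
class SourceSet:
    """Ordered, deterministic collection of sources plus creation metadata."""

    sources: tuple[Source, ...]
    meta: dict = field(default_factory=dict, compare=False)

    def __iter__(self) -> Iterator[Source]:
        return iter(self.sources)

    def __len__(self) -> int:
        return len(self.sources)

    def __getitem__(self, i: int) -> Source:
        return self.sources[i]

    def to_frame(self) -> pd.DataFrame:
        """One row per source: id, x0, y0, z0, strength, alpha."""
        return pd.DataFrame(
            {
                "id": np.arange(len(self.sources)),
                "x0": [s.x0 for s in self.sources],
                "y0": [s.y0 for s in self.sources],
                "z0": [s.z0 for s in self.sources],
                "strength": [s.strength for s in self.sources],
                "alpha": [s.alpha for s in self.sources],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, meta: dict | None = None) -> "SourceSet":
        frame = frame.sort_values("id") if "id" in frame else frame
        sources = tuple(
            Source(x0=row.x0, y0=row.y0, z0=row.z0, strength=row.strength,
                   alpha=row.alpha)
            for row in frame.itertuples()
        )
        return cls(sources=sources, meta=meta or {"created": "from_frame"})

    def to_csv(self, path) -> None:
        # %.17g + round_trip parsing keeps coordinates bit-exact through disk
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "SourceSet":
        frame = pd.read_csv(path, float_precision="round_trip")
        return cls.from_frame(frame, meta={"created": str(path)})


def place_random(recipe: PlacementRecipe) -> SourceSet:
    """Draw ``count`` sources i.i.d. uniform over the recipe's box.

    Coordinates are drawn axis by axis in the fixed order x, y, z so the
    stream of variates — and hence the source set — is fully determined by
    ``(recipe, seed)``.
    """
    rng = np.random.Generator(np.random.PCG64(recipe.seed))
    coords = {}
    for name, (lo, hi) in recipe.box.items():
        coords[name] = rng.uniform(lo, hi, size=recipe.count)
    z = coords.get("z", np.zeros(recipe.count))
    sources = tuple(
        Source(x0=float(coords["x"][i]), y0=float(coords["y"][i]),
               z0=float(z[i]), strength=recipe.strength, alpha=recipe.alpha)
        for i in range(recipe.count)
    )
    return SourceSet(sources=sources, meta={"recipe": recipe})


def four_ctc_sources(strength: float = 1.0, alpha: float = DEFAULT_ALPHA) -> SourceSet:
    """The explicit four-CTC 3D reference configuration.

    Release positions (300, 300, 45), (180, 400, 30), (300, 100, 30),
    (275, 200, 60), all with the same diffusion coefficient (1.5 by
    default).
    """
    sources = tuple(
        Source(x0=x, y0=y, z0=z, strength=strength, alpha=alpha)
        for x, y, z in FOUR_CTC_POSITIONS
    )
    return SourceSet(sources=sources, meta={"created": "four_ctc_sources"})


def advect_sources(sset: SourceSet, flow: FlowSpec, dt: float) -> SourceSet:
    """Drift every source downstream by ``u * dt`` (identity in 2D mode).

    Only ``x0`` changes; wall-normal and cross-stream coordinates are
    untouched.  For display/trajectory use only — the 3D kernel evaluates
    from release positions and carries advection itself.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if flow.mode is FlowMode.NO_FLOW_2D or dt == 0.0:
        return SourceSet(sources=sset.sources, meta=dict(sset.meta))
    shift = flow.u * dt
    sources = tuple(
        Source(x0=s.x0 + shift, y0=s.y0, z0=s.z0, strength=s.strength,
               alpha=s.alpha)
        for s in sset.sources
    )
    meta = dict(sset.meta)
    meta["advected_by"] = meta.get("advected_by", 0.0) + shift
    return SourceSet(sources=sources, meta=meta)
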