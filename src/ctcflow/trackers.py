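"""Passive gradient trackers: the six-point polling diagnostic.

A tracker is a massless diagnostic particle that does not perturb the
field.  At each tick it polls the concentration at the axis neighbors a
probe distance ``eps`` away — ``(+x, -x, +y, -y, +z, -z)``, the z pair
omitted in 2D — and hops by ``eps`` to the neighbor with the largest
concentration *increase* (HIGH_SEEKING, drawn red) or largest *decrease*
(LOW_SEEKING, drawn blue).  If no neighbor improves beyond an absolute
tolerance the tracker stays put.  As ``eps`` shrinks the hop direction
approaches the dominant component of the true concentration gradient; the
probe scale also sets the tracking timescale.

Conventions (the published algorithm leaves these open; they are fixed
here for determinism):

* ties between equally good neighbors break by polling order, first
  winner takes it;
* probe points and moves that would leave the half space are clamped to
  the wall plane, where the field remains defined;
* probe distance equals step distance (one ``eps``), each independently
  configurable in :class:`Tracker`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .kernels import FlowSpec, Normalization, make_field_evaluator
from .sources import Box, SourceSet

__all__ = [
    "Polarity",
    "Tracker",
    "TrackerTrajectory",
    "poll_neighbors",
    "step_tracker",
    "evolve_trackers",
    "place_trackers",
    "trajectories_to_frame",
]

#: Polling order: +x, -x, +y, -y, +z, -z (first four used in 2D).
DIRECTIONS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=float,
)

#: Differences below this absolute size count as "no improvement".
DEFAULT_TOL = 1e-15


class Polarity(enum.Enum):
    HIGH_SEEKING = "red"
    LOW_SEEKING = "blue"


@dataclass(frozen=True)
class Tracker:
    """Position + polarity + probe/step distance of one gradient tracker."""

    position: tuple[float, float, float]
    polarity: Polarity
    eps: float
    step: float | None = None  # defaults to eps (probe distance = hop distance)
    tol: float = DEFAULT_TOL

    def __post_init__(self) -> None:
        if not self.eps > 0:
            raise ValueError("tracker eps must be > 0")
        if self.step is not None and not self.step > 0:
            raise ValueError("tracker step must be > 0")
        object.__setattr__(self, "position", tuple(float(c) for c in self.position))
        if len(self.position) != 3:
            raise ValueError("tracker position must have 3 components (z=0 in 2D)")

    @property
    def hop(self) -> float:
        return self.eps if self.step is None else self.step


@dataclass
class TrackerTrajectory:
    """Sampled (time, position) history of one tracker."""

    tracker_id: int
    polarity: Polarity
    times: np.ndarray
    positions: np.ndarray  # shape (n_samples, 3)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.positions = np.asarray(self.positions, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")


def _clamp_wall(points: np.ndarray, wall_axis: int) -> np.ndarray:
    out = np.array(points, dtype=float, copy=True)
    out[..., wall_axis] = np.maximum(out[..., wall_axis], 0.0)
    return out


def _probe_points(positions: np.ndarray, eps: float, ndim: int,
                  wall_axis: int) -> np.ndarray:
    """Probe coordinates, shape (n, k, 3) with k = 2*ndim, wall-clamped."""
    dirs = DIRECTIONS[: 2 * ndim]
    probes = positions[:, None, :] + eps * dirs[None, :, :]
    return _clamp_wall(probes, wall_axis)


def poll_neighbors(tracker: Tracker, field_at: Callable[..., np.ndarray],
                   t: float, flow: FlowSpec) -> np.ndarray:
    """Signed differences ``c(p) - c(p +/- eps e_k)`` in polling order.

    Returns four values in 2D mode, six in 3D mode.  A positive entry
    means the neighbor is *lower* than the tracker's own concentration.
    """
    if not t > 0:
        raise ValueError("t must be > 0")
    pos = np.asarray([tracker.position], float)
    pos = _clamp_wall(pos, flow.wall_axis)
    probes = _probe_points(pos, tracker.eps, flow.ndim, flow.wall_axis)[0]
    c0 = field_at(pos[0, 0], pos[0, 1], pos[0, 2], t)
    cn = field_at(probes[:, 0], probes[:, 1], probes[:, 2], t)
    return np.asarray(c0 - cn, dtype=float)


def _step_batch(positions: np.ndarray, polarities: Sequence[Polarity],
                eps: float, hop: float, tol: float,
                field_at: Callable[..., np.ndarray], t: float,
                flow: FlowSpec) -> np.ndarray:
    """Advance a batch of trackers one tick (vectorized over trackers)."""
    n = positions.shape[0]
    k = 2 * flow.ndim
    pos = _clamp_wall(positions, flow.wall_axis)
    probes = _probe_points(pos, eps, flow.ndim, flow.wall_axis)
    c0 = field_at(pos[:, 0], pos[:, 1], pos[:, 2], t)
    flat = probes.reshape(-1, 3)
    cn = field_at(flat[:, 0], flat[:, 1], flat[:, 2], t).reshape(n, k)
    gains = cn - np.asarray(c0)[:, None]  # concentration change toward neighbor
    high = np.array([p is Polarity.HIGH_SEEKING for p in polarities])
    score = np.where(high[:, None], gains, -gains)
    best = np.argmax(score, axis=1)  # first maximum wins (fixed polling order)
    improve = score[np.arange(n), best] > tol
    moves = DIRECTIONS[best] * hop
    new = pos + np.where(improve[:, None], moves, 0.0)
    return _clamp_wall(new, flow.wall_axis)


def step_tracker(tracker: Tracker, field_at: Callable[..., np.ndarray],
                 t: float, flow: FlowSpec) -> Tracker:
    """Advance one tracker one tick; position unchanged if nothing improves."""
    if not t > 0:
        raise ValueError("t must be > 0")
    new = _step_batch(np.asarray([tracker.position], float), [tracker.polarity],
                      tracker.eps, tracker.hop, tracker.tol, field_at, t, flow)
    return replace(tracker, position=tuple(new[0]))


def evolve_trackers(trackers: Sequence[Tracker], sources: SourceSet | Sequence,
                    flow: FlowSpec, t0: float, t1: float, cadence: float,
                    normalization: Normalization = Normalization.AS_PRINTED,
                    ) -> list[TrackerTrajectory]:
    """Step every tracker once per cadence tick against the evolving field.

    The field is the analytic superposition over the *release* source
    positions (the 3D kernel carries its own advection); trackers never
    feed back on it.  Trajectories record the initial position at ``t0``
    and the position after the step taken at each subsequent tick.
    """
    if not t0 > 0:
        raise ValueError("t0 must be > 0")
    if not cadence > 0:
        raise ValueError("cadence must be > 0")
    if t1 < t0:
        raise ValueError("t1 must be >= t0")
    trackers = list(trackers)
    field_at = make_field_evaluator(list(sources), flow, normalization)
    n_ticks = int(np.floor((t1 - t0) / cadence + 1e-12))
    times = t0 + cadence * np.arange(n_ticks + 1)

    if not trackers:
        return []
    eps_set = {tr.eps for tr in trackers}
    hop_set = {tr.hop for tr in trackers}
    tol_set = {tr.tol for tr in trackers}
    if len(eps_set) > 1 or len(hop_set) > 1 or len(tol_set) > 1:
        raise ValueError("evolve_trackers requires a shared eps/step/tol per batch")
    eps, hop, tol = eps_set.pop(), hop_set.pop(), tol_set.pop()
    polarities = [tr.polarity for tr in trackers]
    pos = _clamp_wall(np.asarray([tr.position for tr in trackers], float),
                      flow.wall_axis)
    history = [pos.copy()]
    for t in times[1:]:
        pos = _step_batch(pos, polarities, eps, hop, tol, field_at, float(t), flow)
        history.append(pos.copy())
    stacked = np.stack(history)  # (n_times, n_trackers, 3)
    return [
        TrackerTrajectory(tracker_id=i, polarity=trackers[i].polarity,
                          times=times, positions=stacked[:, i, :])
        for i in range(len(trackers))
    ]


def place_trackers(count: int, box: Box, seed: int, polarity: Polarity,
                   eps: float, tol: float = DEFAULT_TOL) -> list[Tracker]:
    """Seeded uniform initial scatter of trackers over a sub-box."""
    rng = np.random.Generator(np.random.PCG64(seed))
    coords = {name: rng.uniform(lo, hi, size=count) for name, (lo, hi) in box.items()}
    z = coords.get("z", np.zeros(count))
    return [
        Tracker(position=(coords["x"][i], coords["y"][i], z[i]),
                polarity=polarity, eps=eps, tol=tol)
        for i in range(count)
    ]


def trajectories_to_frame(trajectories: Sequence[TrackerTrajectory]) -> pd.DataFrame:
    """Long-format export: tracker_id, polarity, t, x, y, z."""
    rows = []
    for traj in trajectories:
        for t, p in zip(traj.times, traj.positions):
            rows.append((traj.tracker_id, traj.polarity.value, float(t),
                         float(p[0]), float(p[1]), float(p[2])))
    return pd.DataFrame(rows, columns=["tracker_id", "polarity", "t", "x", "y", "z"])
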