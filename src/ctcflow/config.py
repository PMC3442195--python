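"""Structured-text run configuration: schema, validation, round-trip.

A run is described by one YAML document.  Unknown keys anywhere are a hard
error (nothing is silently ignored); invariant violations are raised
before any computation.  The same dictionary form is what the archive
stores, so ``write -> read -> normalize`` is the identity.

Schema (top level)::

    mode: no_flow_2d | constant_flow_3d
    u: <float>                  # 0 in 2D mode, > 0 in 3D mode
    normalization: as_printed | textbook_puff
    seed: <int>
    sources:
      kind: recipe | explicit | four_ctc
      # recipe: count, box, strength, alpha, seed (defaults to top seed)
      # explicit: list of {x0, y0, z0, strength, alpha}
      # four_ctc: strength, alpha
    times: [t1, t2, ...]        # strictly increasing, > 0
    peak_times: [..] | {start, stop, num, spacing: log|linear}   # optional
    slices: [{axis: y|z, offset: <float>}, ...]
    window: {x: [lo, hi], y: [lo, hi], z: [lo, hi]}   # z only in 3D
    resolution: <int>
    trackers:                   # optional block
      count_high, count_low, box, eps, cadence, t0, t1, seed, tol,
      frame_times

Packaged fixtures (the reference runs) live under ``ctcflow/fixtures`` and
are accessed with :func:`fixture_names` / :func:`load_fixture`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .engine import RunConfig, SliceDef, TrackerBlock
from .kernels import FlowMode, FlowSpec, Normalization, Source
from .sources import Box, PlacementRecipe, SourceSet

__all__ = [
    "ConfigError",
    "config_from_dict",
    "config_to_dict",
    "load_config",
    "save_config",
    "fixture_names",
    "load_fixture",
    "fixture_path",
]


class ConfigError(ValueError):
    """Schema or invariant violation in a run configuration."""


_TOP_KEYS = {"mode", "u", "normalization", "seed", "sources", "times",
             "peak_times", "slices", "window", "resolution", "trackers"}
_SOURCE_KEYS = {"kind", "count", "box", "strength", "alpha", "seed", "list"}
_TRACKER_KEYS = {"count_high", "count_low", "box", "eps", "cadence", "t0",
                 "t1", "seed", "tol", "frame_times"}
_SLICE_KEYS = {"axis", "offset"}
_EXPLICIT_KEYS = {"x0", "y0", "z0", "strength", "alpha"}
_PEAK_KEYS = {"start", "stop", "num", "spacing"}


def _check_keys(d: dict, allowed: set, where: str) -> None:
    if not isinstance(d, dict):
        raise ConfigError(f"{where} must be a mapping, got {type(d).__name__}")
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _parse_box(d: dict, where: str, require_z: bool) -> Box:
    _check_keys(d, {"x", "y", "z"}, where)
    for axis in ("x", "y") + (("z",) if require_z else ()):
        if axis not in d:
            raise ConfigError(f"{where} missing axis {axis!r}")
    def pair(axis):
        v = d[axis]
        if not (isinstance(v, (list, tuple)) and len(v) == 2):
            raise ConfigError(f"{where}.{axis} must be [lo, hi]")
        return (float(v[0]), float(v[1]))
    try:
        return Box(x=pair("x"), y=pair("y"),
                   z=pair("z") if "z" in d and d["z"] is not None else None)
    except ValueError as e:
        raise ConfigError(f"{where}: {e}") from e


def _parse_peak_times(v, where: str):
    if v is None:
        return None
    if isinstance(v, dict):
        _check_keys(v, _PEAK_KEYS, where)
        start, stop = float(v["start"]), float(v["stop"])
        num = int(v["num"])
        spacing = v.get("spacing", "log")
        if spacing == "log":
            if start <= 0:
                raise ConfigError(f"{where}: log spacing requires start > 0")
            return tuple(np.geomspace(start, stop, num))
        if spacing == "linear":
            return tuple(np.linspace(start, stop, num))
        raise ConfigError(f"{where}: spacing must be 'log' or 'linear'")
    return tuple(float(t) for t in v)


def config_from_dict(d: dict) -> RunConfig:
    """Validate a plain dictionary and build a :class:`RunConfig`."""
    _check_keys(d, _TOP_KEYS, "config")
    for key in ("mode", "sources", "times", "slices", "window"):
        if key not in d:
            raise ConfigError(f"config missing required key {key!r}")
    try:
        mode = FlowMode(d["mode"])
    except ValueError as e:
        raise ConfigError(f"unknown mode {d['mode']!r}") from e
    u = float(d.get("u", 0.0))
    try:
        flow = FlowSpec(mode=mode, u=u)
        normalization = Normalization(d.get("normalization", "as_printed"))
    except ValueError as e:
        raise ConfigError(str(e)) from e
    seed = int(d.get("seed", 0))
    is_3d = mode is FlowMode.CONSTANT_FLOW_3D

    sd = d["sources"]
    _check_keys(sd, _SOURCE_KEYS, "sources")
    kind = sd.get("kind")
    try:
        if kind == "recipe":
            box = _parse_box(sd["box"], "sources.box", require_z=is_3d)
            sources: SourceSet | PlacementRecipe = PlacementRecipe(
                count=int(sd["count"]), box=box,
                seed=int(sd.get("seed", seed)),
                strength=float(sd.get("strength", 1.0)),
                alpha=float(sd.get("alpha", 1.5)))
        elif kind == "explicit":
            entries = sd.get("list")
            if not entries:
                raise ConfigError("sources.kind=explicit requires a 'list'")
            items = []
            for i, entry in enumerate(entries):
                _check_keys(entry, _EXPLICIT_KEYS, f"sources.list[{i}]")
                items.append(Source(x0=float(entry["x0"]),
                                    y0=float(entry["y0"]),
                                    z0=float(entry.get("z0", 0.0)),
                                    strength=float(entry.get("strength", 1.0)),
                                    alpha=float(entry.get("alpha", 1.5))))
            sources = SourceSet(tuple(items), meta={"created": "explicit"})
        elif kind == "four_ctc":
            from .sources import four_ctc_sources

            sources = four_ctc_sources(strength=float(sd.get("strength", 1.0)),
                                       alpha=float(sd.get("alpha", 1.5)))
        else:
            raise ConfigError(
                f"sources.kind must be recipe|explicit|four_ctc, got {kind!r}")
    except (KeyError, TypeError) as e:
        raise ConfigError(f"sources block malformed: {e}") from e

    slices = []
    for i, sl in enumerate(d["slices"]):
        _check_keys(sl, _SLICE_KEYS, f"slices[{i}]")
        slices.append(SliceDef(axis=str(sl["axis"]), offset=float(sl["offset"])))

    window = d["window"]
    _check_keys(window, {"x", "y", "z"}, "window")
    window = {k: (float(v[0]), float(v[1])) for k, v in window.items()
              if v is not None}

    trackers = None
    if d.get("trackers") is not None:
        td = d["trackers"]
        _check_keys(td, _TRACKER_KEYS, "trackers")
        try:
            trackers = TrackerBlock(
                count_high=int(td.get("count_high", 0)),
                count_low=int(td.get("count_low", 0)),
                box=_parse_box(td["box"], "trackers.box", require_z=is_3d),
                eps=float(td["eps"]), cadence=float(td["cadence"]),
                t0=float(td["t0"]), t1=float(td["t1"]),
                seed=int(td.get("seed", seed)),
                tol=float(td.get("tol", 1e-15)),
                frame_times=tuple(float(t) for t in td["frame_times"])
                if td.get("frame_times") else None)
        except (KeyError, TypeError) as e:
            raise ConfigError(f"trackers block malformed: {e}") from e

    try:
        return RunConfig(
            flow=flow, sources=sources, times=tuple(float(t) for t in d["times"]),
            slices=tuple(slices), window=window,
            resolution=int(d.get("resolution", 256)),
            peak_times=_parse_peak_times(d.get("peak_times"), "peak_times"),
            trackers=trackers, normalization=normalization, seed=seed)
    except ValueError as e:
        raise ConfigError(str(e)) from e


def config_to_dict(config: RunConfig) -> dict:
    """Normalized plain-dict form of a config (YAML- and JSON-safe)."""
    d: dict = {
        "mode": config.flow.mode.value,
        "u": config.flow.u,
        "normalization": config.normalization.value,
        "seed": config.seed,
        "times": list(config.times),
        "slices": [{"axis": sl.axis, "offset": sl.offset}
                   for sl in config.slices],
        "window": {k: [v[0], v[1]] for k, v in config.window.items()},
        "resolution": config.resolution,
    }
    if config.peak_times is not None:
        d["peak_times"] = list(config.peak_times)
    src = config.sources
    if isinstance(src, PlacementRecipe):
        d["sources"] = {
            "kind": "recipe", "count": src.count, "seed": src.seed,
            "strength": src.strength, "alpha": src.alpha,
            "box": {name: [lo, hi] for name, (lo, hi) in src.box.items()},
        }
    else:
        d["sources"] = {
            "kind": "explicit",
            "list": [{"x0": s.x0, "y0": s.y0, "z0": s.z0,
                      "strength": s.strength, "alpha": s.alpha} for s in src],
        }
    if config.trackers is not None:
        tb = config.trackers
        d["trackers"] = {
            "count_high": tb.count_high, "count_low": tb.count_low,
            "box": {name: [lo, hi] for name, (lo, hi) in tb.box.items()},
            "eps": tb.eps, "cadence": tb.cadence, "t0": tb.t0, "t1": tb.t1,
            "seed": tb.seed, "tol": tb.tol,
        }
        if tb.frame_times is not None:
            d["trackers"]["frame_times"] = list(tb.frame_times)
    return d


def load_config(path) -> RunConfig:
    with open(path, "r") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} does not hold a mapping")
    return config_from_dict(data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def fixture_names() -> list[str]:
    """Names of the packaged reference-run configurations."""
    root = resources.files("ctcflow") / "fixtures"
    return sorted(p.name[:-len(".yaml")] for p in root.iterdir()
                  if p.name.endswith(".yaml"))


def fixture_path(name: str) -> Path:
    p = resources.files("ctcflow") / "fixtures" / f"{name}.yaml"
    if not p.is_file():
        raise ConfigError(
            f"unknown fixture {name!r}; available: {fixture_names()}")
    return Path(str(p))


def load_fixture(name: str) -> RunConfig:
    return load_config(fixture_path(name))
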