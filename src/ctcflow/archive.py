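"""Run archives: self-describing on-disk bundles of one run's outputs.

An archive is a directory::

    manifest.json       config digest, version, seeds, wall times, artifact
                        checksums (sha256 of every emitted file)
    config.yaml         normalized configuration (round-trips exactly)
    sources.csv         one row per source
    fields.nc           every sampled FieldGrid as a netCDF variable with
                        coordinate vectors and (t, slice) metadata
    peaks.csv           per-slice peak series
    profiles.csv        exact slice profiles (2D runs)
    trajectories.csv    tracker trajectories (when trackers ran)

All numeric artifacts are deterministic for a fixed (config, seed); the
manifest's wall-clock timestamps are the only fields that vary between
identical runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import load_config, save_config
from .engine import RunConfig, RunResult
from .sources import SourceSet

__all__ = ["write_archive", "read_archive", "ArchiveData", "sha256_file"]


def sha256_file(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _fields_to_dataset(result: RunResult):
    import xarray as xr

    data_vars = {}
    for i, ((t, label), fg) in enumerate(sorted(result.fields.items())):
        name = f"field_{i:03d}"
        dims = [f"x_{i:03d}", f"y_{i:03d}"]
        coords = {dims[0]: fg.x, dims[1]: fg.y}
        values = fg.values
        if fg.z is not None and values.ndim == 3 and values.shape[2] == 1:
            values = values[:, :, 0]  # stored z-slice
        attrs = {"t": float(t), "slice": label}
        if fg.z is not None:
            attrs["z_offset"] = float(fg.z[0])
        data_vars[name] = xr.DataArray(values, dims=dims, coords=coords,
                                       attrs=attrs)
    return xr.Dataset(data_vars)


def write_archive(result: RunResult, outdir, flat_fields: bool = False,
                  manifest_extra: dict | None = None) -> Path:
    """Write a run's outputs; returns the archive directory path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()

    save_config(result.config, outdir / "config.yaml")
    result.sources.to_csv(outdir / "sources.csv")
    result.peaks.frame.to_csv(outdir / "peaks.csv", index=False)

    ds = _fields_to_dataset(result)
    ds.to_netcdf(outdir / "fields.nc", engine="scipy")

    if result.profiles:
        rows = []
        for (t, label), frame in sorted(result.profiles.items()):
            coord_col = [c for c in frame.columns if c != "c"][0]
            for coord, c in zip(frame[coord_col], frame["c"]):
                rows.append((t, label, coord_col, coord, c))
        pd.DataFrame(rows, columns=["t", "slice", "coord_axis", "coord", "c"]
                     ).to_csv(outdir / "profiles.csv", index=False)

    if result.trajectories:
        from .trackers import trajectories_to_frame

        trajectories_to_frame(result.trajectories).to_csv(
            outdir / "trajectories.csv", index=False)

    if flat_fields:
        rows = []
        for (t, label), fg in sorted(result.fields.items()):
            X, Y = np.meshgrid(fg.x, fg.y, indexing="ij")
            vals = fg.values[:, :, 0] if fg.values.ndim == 3 else fg.values
            for xi, yi, ci in zip(X.ravel(), Y.ravel(), vals.ravel()):
                rows.append((t, label, xi, yi, ci))
        pd.DataFrame(rows, columns=["t", "slice", "x", "y", "c"]).to_csv(
            outdir / "fields_flat.csv", index=False)

    artifacts = {
        p.name: sha256_file(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "tool": "ctcflow",
        "version": __version__,
        "config_digest": result.config.digest(),
        "seed": result.config.seed,
        "tracker_seed": (result.config.trackers.seed
                         if result.config.trackers else None),
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
        "artifacts": artifacts,
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


@dataclass
class ArchiveData:
    """In-memory view of an archive directory."""

    path: Path
    manifest: dict
    config: RunConfig
    sources: SourceSet
    fields: list  # (t, label, 2D ndarray, x, y, attrs)
    peaks: pd.DataFrame
    profiles: pd.DataFrame | None
    trajectories: pd.DataFrame | None


def read_archive(path) -> ArchiveData:
    import xarray as xr

    path = Path(path)
    if not (path / "manifest.json").is_file():
        raise FileNotFoundError(f"{path} is not a run archive (no manifest.json)")
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    if manifest.get("tool") != "ctcflow":
        raise ValueError(f"{path} was not produced by this tool")
    config = load_config(path / "config.yaml")
    sources = SourceSet.from_csv(path / "sources.csv")
    peaks = pd.read_csv(path / "peaks.csv")
    profiles = None
    if (path / "profiles.csv").is_file():
        profiles = pd.read_csv(path / "profiles.csv")
    trajectories = None
    if (path / "trajectories.csv").is_file():
        trajectories = pd.read_csv(path / "trajectories.csv")
    fields = []
    with xr.open_dataset(path / "fields.nc", engine="scipy") as ds:
        for name in sorted(ds.data_vars):
            da = ds[name]
            dims = list(da.dims)
            fields.append((float(da.attrs["t"]), str(da.attrs["slice"]),
                           np.asarray(da.values),
                           np.asarray(da[dims[0]].values),
                           np.asarray(da[dims[1]].values),
                           dict(da.attrs)))
    return ArchiveData(path=path, manifest=manifest, config=config,
                       sources=sources, fields=fields, peaks=peaks,
                       profiles=profiles, trajectories=trajectories)
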