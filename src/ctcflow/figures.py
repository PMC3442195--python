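"""Figure layouts for run archives.

Layouts operate purely on an :class:`~ctcflow.archive.ArchiveData`, so the
numerics never depend on plotting; a missing diagnostic raises an error
that names what to re-run.

Available layouts (``ctcflow figures --layout ...``):

``fields2d``
    3x3 grid for a 2D run: field heatmaps, slice profiles, and surface
    plots at the first three archived times.
``peaks``
    Two panels for a 2D run: slice profiles at the latest time, and the
    per-slice peak series on log-log axes with the fitted two-regime
    breakpoint marked.
``slices3d``
    Heatmap grid for a 3D run: one row per z-slice, one column per time.
``trackers``
    One 3D scatter frame per tracker display time: red high-seeking and
    blue low-seeking trackers plus the advected cell positions.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .archive import ArchiveData
from .engine import regime_split
from .kernels import FlowMode

__all__ = ["LAYOUTS", "render"]


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


def fields2d(archive: ArchiveData, outdir: Path) -> list[Path]:
    _require(archive.config.flow.mode is FlowMode.NO_FLOW_2D,
             "layout fields2d needs a 2D (no-flow) archive")
    _require(archive.profiles is not None,
             "archive has no profiles.csv; re-run the 2D configuration")
    times = sorted({t for t, *_ in archive.fields})[:3]
    fig = plt.figure(figsize=(12, 11))
    for col, t in enumerate(times):
        t_, label, values, x, y, attrs = next(
            f for f in archive.fields if f[0] == t)
        ax = fig.add_subplot(3, 3, col + 1)
        im = ax.pcolormesh(x, y, values.T, shading="auto", cmap="inferno")
        ax.set_title(f"T = {t:g}")
        ax.set_xlabel("x"); ax.set_ylabel("y")
        fig.colorbar(im, ax=ax, shrink=0.8)

        ax = fig.add_subplot(3, 3, 3 + col + 1)
        prof_t = archive.profiles[np.isclose(archive.profiles["t"], t)]
        for slab in sorted(prof_t["slice"].unique()):
            sel = prof_t[prof_t["slice"] == slab]
            ax.plot(sel["coord"], sel["c"], label=slab)
        ax.set_xlabel("x"); ax.set_ylabel("c")
        if col == 0:
            ax.legend(fontsize=7)

        ax = fig.add_subplot(3, 3, 6 + col + 1, projection="3d")
        X, Y = np.meshgrid(x, y, indexing="ij")
        stride = max(1, len(x) // 64)
        ax.plot_surface(X[::stride, ::stride], Y[::stride, ::stride],
                        values[::stride, ::stride], cmap="inferno",
                        linewidth=0)
        ax.set_xlabel("x"); ax.set_ylabel("y")
    fig.tight_layout()
    out = outdir / "fields2d.png"
    fig.savefig(out, dpi=130)
    plt.close(fig)
    return [out]


def peaks(archive: ArchiveData, outdir: Path) -> list[Path]:
    _require(archive.profiles is not None,
             "archive has no profiles.csv; re-run the 2D configuration")
    _require(len(archive.peaks) > 0, "archive has an empty peak series")
    fig, (ax_a, ax_b) = plt.subplots(1, 2, figsize=(11, 4.5))
    t_last = archive.profiles["t"].max()
    prof = archive.profiles[np.isclose(archive.profiles["t"], t_last)]
    for slab in sorted(prof["slice"].unique()):
        sel = prof[prof["slice"] == slab]
        ax_a.plot(sel["coord"], sel["c"], label=slab)
    ax_a.set_title(f"profiles at T = {t_last:g}")
    ax_a.set_xlabel("x"); ax_a.set_ylabel("c"); ax_a.legend(fontsize=8)

    wall_axis = "y" if archive.config.flow.mode is FlowMode.NO_FLOW_2D else "z"
    for (axis, offset), sel in archive.peaks.groupby(["axis", "offset"]):
        sel = sel.sort_values("t")
        ax_b.loglog(sel["t"], sel["peak"], label=f"{axis}={offset:g}")
        if axis == wall_axis and offset == 0.0 and len(sel) >= 10:
            fit = regime_split(sel["t"].to_numpy(), sel["peak"].to_numpy())
            ax_b.axvline(fit.t_split, color="k", ls="--", lw=0.8)
    ax_b.set_title("peak concentration vs time")
    ax_b.set_xlabel("T"); ax_b.set_ylabel("max c"); ax_b.legend(fontsize=8)
    fig.tight_layout()
    out = outdir / "peaks.png"
    fig.savefig(out, dpi=130)
    plt.close(fig)
    return [out]


def slices3d(archive: ArchiveData, outdir: Path) -> list[Path]:
    _require(archive.config.flow.mode is FlowMode.CONSTANT_FLOW_3D,
             "layout slices3d needs a 3D (constant-flow) archive")
    times = sorted({t for t, *_ in archive.fields})
    labels = sorted({f[1] for f in archive.fields})
    fig, axes = plt.subplots(len(labels), len(times),
                             figsize=(3.2 * len(times), 2.8 * len(labels)),
                             squeeze=False)
    for i, label in enumerate(labels):
        for j, t in enumerate(times):
            entry = next(f for f in archive.fields
                         if f[0] == t and f[1] == label)
            _, _, values, x, y, attrs = entry
            ax = axes[i][j]
            ax.pcolormesh(x, y, values.T, shading="auto", cmap="inferno")
            if i == 0:
                ax.set_title(f"T = {t:g}")
            if j == 0:
                ax.set_ylabel(label)
    fig.tight_layout()
    out = outdir / "slices3d.png"
    fig.savefig(out, dpi=130)
    plt.close(fig)
    return [out]


def trackers(archive: ArchiveData, outdir: Path) -> list[Path]:
    _require(archive.trajectories is not None and len(archive.trajectories) > 0,
             "archive has no trajectories.csv; re-run with a trackers block")
    tb = archive.config.trackers
    frame_times = (tb.frame_times if tb and tb.frame_times
                   else archive.config.times)
    traj = archive.trajectories
    ticks = np.sort(traj["t"].unique())
    u = archive.config.flow.u
    src = archive.sources.to_frame()
    outputs = []
    for k, t_req in enumerate(frame_times):
        t = float(ticks[np.argmin(np.abs(ticks - t_req))])
        sel = traj[np.isclose(traj["t"], t)]
        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(111, projection="3d")
        for polarity, color in (("red", "tab:red"), ("blue", "tab:blue")):
            pts = sel[sel["polarity"] == polarity]
            if len(pts):
                ax.scatter(pts["x"], pts["y"], pts["z"], s=5, c=color,
                           depthshade=False)
        ax.scatter(src["x0"] + u * t, src["y0"], src["z0"], s=25, c="k",
                   marker="^", depthshade=False)
        ax.set_title(f"T = {t:g}")
        ax.set_xlabel("x"); ax.set_ylabel("y"); ax.set_zlabel("z")
        out = outdir / f"trackers_{k:02d}_t{t:g}.png"
        fig.savefig(out, dpi=130)
        plt.close(fig)
        outputs.append(out)
    return outputs


LAYOUTS = {
    "fields2d": fields2d,
    "peaks": peaks,
    "slices3d": slices3d,
    "trackers": trackers,
}


def render(archive: ArchiveData, layout: str, outdir) -> list[Path]:
    """Render one layout into ``outdir``; returns the written image paths."""
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; available: "
                         f"{sorted(LAYOUTS)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return LAYOUTS[layout](archive, outdir)
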