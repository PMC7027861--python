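"""Figure rendering for all analytics.

Every renderer is a pure function of (data, style): it writes a figure file
and returns the exact table of what was drawn, so tests and downstream
analyses work on the numbers rather than on rendered pixels. Default color
choices are colorblind-safe: the viridis sequential map for heatmaps and the
Okabe-Ito palette for categorical lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.figure import Figure

from .core import ImageStack
from .errors import SpecError
from .profiles import ClusterResult, Demograph, Kymograph
from .projections import DensityGrid
from .timelapse import LineageTree

__all__ = ["PlotSpec", "render_overlay", "render_plot", "OKABE_ITO"]

#: categorical colorblind-safe palette
OKABE_ITO = [
    "#E69F00", "#56B4E9", "#009E73", "#F0E442",
    "#0072B2", "#D55E00", "#CC79A7", "#000000",
]

KINDS = (
    "overlay", "tower", "demograph", "kymograph", "tracks",
    "trajectory_xy", "tree", "histogram", "movie_strip", "cluster_summary",
)


@dataclass
class PlotSpec:
    """What to draw and how.

    ``data`` carries kind-specific inputs (see :func:`render_plot`);
    ``pixel_size`` (micrometers/pixel), when given, adds a scale bar to
    image-like plots.
    """

    kind: str
    data: dict = field(default_factory=dict)
    cmap: str = "viridis"
    out_format: str = "png"
    pixel_size: float | None = None
    title: str = ""


def _save(fig: Figure, out: Path, fmt: str) -> Path:
    out = Path(out)
    if out.suffix[1:] != fmt:
        out = out.with_suffix(f".{fmt}")
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=120)
    return out


def render_overlay(
    image: np.ndarray,
    records,
    spots: pd.DataFrame | None = None,
    out="overlay.png",
    cmap: str = "viridis",
    out_format: str = "png",
) -> tuple[Path, pd.DataFrame]:
    """Raw image with cell outlines and (optionally) detected spots on top.

    Returns the written path and the drawn-coordinate table: one row per
    drawn vertex/point with its layer ('mesh' or 'spot') and identifier,
    exactly the coordinates handed to the plotting backend.
    """
    fig = Figure(figsize=(6, 6))
    ax = fig.add_subplot(111)
    ax.imshow(image, cmap=cmap, origin="upper")
    rows = []
    for rec in records:
        v = np.vstack([rec.vertices, rec.vertices[:1]])
        ax.plot(v[:, 0], v[:, 1], color=OKABE_ITO[0], lw=1)
        for x, y in rec.vertices:
            rows.append({"layer": "mesh", "id": rec.cell_id, "x": x, "y": y})
    if spots is not None and len(spots):
        ax.scatter(spots["x"], spots["y"], s=12, color=OKABE_ITO[1], marker="o")
        for _, s in spots.iterrows():
            rows.append({"layer": "spot", "id": s["spot_id"], "x": s["x"], "y": s["y"]})
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    path = _save(fig, Path(out), out_format)
    return path, pd.DataFrame(rows, columns=["layer", "id", "x", "y"])


def _render_tower(spec: PlotSpec, fig: Figure) -> pd.DataFrame:
    grids: list[DensityGrid] = spec.data["grids"]
    n = len(grids)
    tables = []
    for i, g in enumerate(grids):
        ax = fig.add_subplot(1, n, i + 1)
        ax.pcolormesh(g.x_edges, g.y_edges, g.values, cmap=spec.cmap)
        ax.set_title(f"group {g.group} (n={g.n_spots})", fontsize=8)
        ax.set_aspect("equal")
        tables.append(g.to_table())
    return pd.concat(tables, ignore_index=True)


def _render_matrix(matrix: np.ndarray, fig: Figure, spec: PlotSpec, ylabel: str) -> None:
    ax = fig.add_subplot(111)
    ax.imshow(matrix, aspect="auto", cmap=spec.cmap, origin="upper")
    ax.set_xlabel("length-axis bin")
    ax.set_ylabel(ylabel)


def _render_tree(tree: LineageTree, fig: Figure) -> pd.DataFrame:
    ax = fig.add_subplot(111)
    rows = []
    y_next = [0.0]

    def layout(node, x0):
        children = sorted(tree.graph.successors(node))
        dur = tree.graph.nodes[node].get("duration", 0.0)
        x1 = x0 + dur
        if not children:
            y = y_next[0]
            y_next[0] += 1.0
        else:
            ys = [layout(c, x1) for c in children]
            y = float(np.mean(ys))
            for c, cy in zip(children, ys):
                ax.plot([x1, x1], [y, cy], color="0.3", lw=1)
        ax.plot([x0, x1], [y, y], color="0.3", lw=1)
        ax.annotate(node, (x1, y), fontsize=7)
        rows.append(
            {"node": node, "x0": x0, "x1": x1, "y": y, "leaf": not children}
        )
        return y

    for root in tree.roots():
        layout(root, 0.0)
    ax.set_xlabel("time (s)")
    ax.set_yticks([])
    return pd.DataFrame(rows, columns=["node", "x0", "x1", "y", "leaf"])


def render_plot(spec: PlotSpec, out="plot.png") -> tuple[Path, pd.DataFrame]:
    """Render any supported plot kind; returns (path, plotted table).

    Data expected per kind:

    - ``overlay``: image, records, spots?
    - ``tower``: grids (list of DensityGrid)
    - ``demograph``: demograph (Demograph)
    - ``kymograph``: kymograph (Kymograph)
    - ``tracks``: tracks (tidy DataFrame with track_id/time/length)
    - ``trajectory_xy``: spots (DataFrame with trajectory/x/y), records?
    - ``tree``: tree (LineageTree)
    - ``histogram``: values (array), label?
    - ``movie_strip``: stack (ImageStack), frames (list of frame ids)
    - ``cluster_summary``: result (ClusterResult), profiles? (DataFrame)
    """
    if spec.kind not in KINDS:
        raise SpecError(f"unknown plot kind {spec.kind!r}; known: {KINDS}")
    try:
        if spec.kind == "overlay":
            return render_overlay(
                spec.data["image"],
                spec.data["records"],
                spec.data.get("spots"),
                out=out,
                cmap=spec.cmap,
                out_format=spec.out_format,
            )
        fig = Figure(figsize=(7, 4))
        if spec.kind == "tower":
            table = _render_tower(spec, fig)
        elif spec.kind == "demograph":
            demo: Demograph = spec.data["demograph"]
            _render_matrix(demo.matrix, fig, spec, "cell (short to long)")
            r, c = demo.matrix.shape
            table = pd.DataFrame(
                {
                    "cell_id": np.repeat(demo.cell_ids, c),
                    "bin": np.tile(np.arange(c), r),
                    "value": demo.matrix.ravel(),
                }
            )
        elif spec.kind == "kymograph":
            kymo: Kymograph = spec.data["kymograph"]
            _render_matrix(kymo.matrix, fig, spec, "time")
            table = kymo.to_table()
        elif spec.kind == "tracks":
            tracks = spec.data["tracks"]
            ax = fig.add_subplot(111)
            for i, (tid, sub) in enumerate(tracks.groupby("track_id")):
                ax.plot(sub["time"], sub["length"], lw=0.8,
                        color=OKABE_ITO[i % len(OKABE_ITO)])
            ax.set_xlabel("time (s)")
            ax.set_ylabel("length (px)")
            table = tracks[["track_id", "time", "length"]].reset_index(drop=True)
        elif spec.kind == "trajectory_xy":
            spots = spec.data["spots"]
            ax = fig.add_subplot(111)
            for rec in spec.data.get("records", []):
                v = np.vstack([rec.vertices, rec.vertices[:1]])
                ax.plot(v[:, 0], v[:, 1], color="0.6", lw=1)
            key = "trajectory" if "trajectory" in spots else "spot_id"
            for i, (_, sub) in enumerate(spots.groupby(key)):
                ax.plot(sub["x"], sub["y"], marker="o", ms=2, lw=0.8,
                        color=OKABE_ITO[i % len(OKABE_ITO)])
            ax.set_aspect("equal")
            table = spots[[key, "x", "y"]].reset_index(drop=True)
        elif spec.kind == "tree":
            table = _render_tree(spec.data["tree"], fig)
        elif spec.kind == "histogram":
            values = np.asarray(spec.data["values"], float)
            ax = fig.add_subplot(111)
            counts, edges, _ = ax.hist(values, bins=spec.data.get("bins", 30),
                                       color=OKABE_ITO[0])
            ax.set_xlabel(spec.data.get("label", "value"))
            table = pd.DataFrame(
                {"lo": edges[:-1], "hi": edges[1:], "count": counts.astype(int)}
            )
        elif spec.kind == "movie_strip":
            stack: ImageStack = spec.data["stack"]
            frames = list(spec.data.get("frames", range(len(stack.frames))))
            rows = []
            for i, f in enumerate(frames):
                ax = fig.add_subplot(1, len(frames), i + 1)
                ax.imshow(stack.frames[f], cmap=spec.cmap)
                ax.set_xticks([])
                ax.set_yticks([])
                t = f * (stack.time_interval or 1.0)
                ax.set_title(f"{t:g}s", fontsize=7)
                rows.append({"panel": i, "frame_id": f, "time": t})
            table = pd.DataFrame(rows, columns=["panel", "frame_id", "time"])
        elif spec.kind == "cluster_summary":
            result: ClusterResult = spec.data["result"]
            profiles = spec.data.get("profiles")
            ks = sorted(result.summary["cluster"])
            for i, c in enumerate(ks):
                ax = fig.add_subplot(len(ks), 1, i + 1)
                sub = result.mean_profiles[result.mean_profiles["cluster"] == c]
                if profiles is not None:
                    members = result.labels[result.labels == c].index
                    for m in members:
                        ax.plot(np.asarray(profiles.columns, float),
                                profiles.loc[m], color="0.8", lw=0.5)
                ax.fill_between(sub["grid"], sub["mean"] - sub["sd"],
                                sub["mean"] + sub["sd"], alpha=0.3,
                                color=OKABE_ITO[i % len(OKABE_ITO)])
                ax.plot(sub["grid"], sub["mean"], color=OKABE_ITO[i % len(OKABE_ITO)])
                n = int(result.summary.set_index("cluster").loc[c, "n"])
                frac = result.summary.set_index("cluster").loc[c, "fraction"]
                ax.set_ylabel(f"C{c} n={n} ({100 * frac:.0f}%)", fontsize=8)
            table = result.mean_profiles.copy()
        else:  # pragma: no cover - guarded by KINDS check
            raise SpecError(spec.kind)
    except KeyError as exc:
        raise SpecError(f"plot kind {spec.kind!r} is missing required data {exc}") from exc
    if spec.title:
        fig.suptitle(spec.title)
    path = _save(fig, Path(out), spec.out_format)
    return path, table
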