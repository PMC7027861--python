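"""Population-level localization summaries.

Snapshots of many cells are pooled into: equal-count cell-length groups,
2-D spot-density heatmaps per group ("cell towers"), and a projection of all
spot positions on the length axis with cells ordered by cell length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GroupingError

__all__ = [
    "LengthGrouping",
    "GridSpec",
    "DensityGrid",
    "length_groups",
    "density_projection",
    "length_axis_projection",
]

log = logging.getLogger(__name__)


@dataclass
class LengthGrouping:
    """Assignment of cells into ``n_groups`` contiguous length classes.

    ``table`` has one row per cell (``cell_id``, ``length``, ``group`` with
    groups 1..n ordered short to long); ``summary`` one row per group with
    its size and mean length/width.
    """

    n_groups: int
    table: pd.DataFrame
    summary: pd.DataFrame


def length_groups(cells: pd.DataFrame, n_groups: int = 5) -> LengthGrouping:
    """Split cells into groups of (near-)equal count by ascending length.

    Cells are sorted by ``(length, cell_id)`` — the id breaks ties so the
    split is deterministic — and cut into ``n_groups`` contiguous blocks.
    When the count does not divide evenly, the remainder r is distributed as
    one extra cell to each of the r shortest-length groups, so group sizes
    never differ by more than one.

    Parameters
    ----------
    cells : DataFrame
        Needs ``cell_id`` and ``length``; ``width`` is used for the summary
        when present.
    """
    n = len(cells)
    if n_groups < 1 or n_groups > n:
        raise GroupingError(f"cannot split {n} cells into {n_groups} groups")
    tab = cells.sort_values(["length", "cell_id"], kind="mergesort").reset_index(drop=True)
    base, rem = divmod(n, n_groups)
    sizes = [base + 1 if g < rem else base for g in range(n_groups)]
    tab["group"] = np.repeat(np.arange(1, n_groups + 1), sizes)
    agg = {"n": ("cell_id", "size"), "mean_length": ("length", "mean")}
    if "width" in tab:
        agg["mean_width"] = ("width", "mean")
    summary = tab.groupby("group").agg(**agg).reset_index()
    return LengthGrouping(n_groups=n_groups, table=tab, summary=summary)


@dataclass
class GridSpec:
    """Binning specification for 2-D density maps.

    Defaults cover relative coordinates with margin for spots detected just
    outside the bounding box. ``bandwidth`` (kernel mode) defaults to one
    bin width.
    """

    nx: int = 25
    ny: int = 25
    extent: tuple[float, float, float, float] = (-0.6, 0.6, -0.6, 0.6)
    bandwidth: float | None = None

    @property
    def x_edges(self) -> np.ndarray:
        return np.linspace(self.extent[0], self.extent[1], self.nx + 1)

    @property
    def y_edges(self) -> np.ndarray:
        return np.linspace(self.extent[2], self.extent[3], self.ny + 1)


@dataclass
class DensityGrid:
    """A binned 2-D localization density for one length group."""

    group: int
    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray  # shape (ny, nx), rows indexed by y
    mode: str
    n_spots: int

    def to_table(self) -> pd.DataFrame:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        X, Y = np.meshgrid(xc, yc)
        return pd.DataFrame(
            {"group": self.group, "x": X.ravel(), "y": Y.ravel(), "value": self.values.ravel()}
        )


def _kernel_density(x, y, spec: GridSpec) -> np.ndarray:
    bw = spec.bandwidth
    if bw is None:
        bw = (spec.extent[1] - spec.extent[0]) / spec.nx
    xc = 0.5 * (spec.x_edges[:-1] + spec.x_edges[1:])
    yc = 0.5 * (spec.y_edges[:-1] + spec.y_edges[1:])
    # product Gaussian kernel, averaged over spots -> integrates to ~1
    gx = np.exp(-0.5 * ((xc[None, :] - x[:, None]) / bw) ** 2) / (bw * np.sqrt(2 * np.pi))
    gy = np.exp(-0.5 * ((yc[None, :] - y[:, None]) / bw) ** 2) / (bw * np.sqrt(2 * np.pi))
    return (gy[:, :, None] * gx[:, None, :]).mean(axis=0)


def density_projection(
    spots: pd.DataFrame,
    grouping: LengthGrouping | None = None,
    spec: GridSpec | None = None,
    mode: str = "histogram",
    coords: tuple[str, str] = ("l_rel", "d_rel"),
) -> list[DensityGrid]:
    """Per-length-group 2-D density of relativized spot positions.

    In ``histogram`` mode the grid holds counts (their sum equals the number
    of contributing spots); in ``kernel`` mode a product-Gaussian kernel
    density whose numeric integral over the grid is ~1. Spots are grouped by
    joining ``cell_id`` against the grouping table; with no grouping all
    spots form a single group 1. A group without spots yields an all-zero
    grid and is logged.
    """
    if mode not in ("histogram", "kernel"):
        raise ValueError(f"unknown density mode {mode!r}")
    spec = spec or GridSpec()
    cx, cy = coords
    if grouping is None:
        labeled = spots.assign(group=1)
        groups = [1]
    else:
        labeled = spots.merge(grouping.table[["cell_id", "group"]], on="cell_id", how="inner")
        groups = list(grouping.summary["group"])
    out = []
    for g in groups:
        sub = labeled[labeled["group"] == g]
        x = sub[cx].to_numpy(float)
        y = sub[cy].to_numpy(float)
        if len(sub) == 0:
            log.warning("length group %s has no spots; emitting empty grid", g)
            values = np.zeros((spec.ny, spec.nx))
        elif mode == "histogram":
            values, _, _ = np.histogram2d(y, x, bins=[spec.y_edges, spec.x_edges])
        else:
            values = _kernel_density(x, y, spec)
        out.append(
            DensityGrid(
                group=int(g),
                x_edges=spec.x_edges,
                y_edges=spec.y_edges,
                values=values,
                mode=mode,
                n_spots=len(sub),
            )
        )
    return out


def length_axis_projection(spots: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
    """All spots on the cell length axis, cells ordered by ascending length.

    Returns one row per spot: the owning cell's length rank (1 = shortest;
    ties broken by ``cell_id``), the spot's along-axis coordinate ``l`` and
    the cell's ``half_length`` envelope for plotting. The output is sorted
    by (rank, spot_id) and therefore invariant to input row order.
    """
    ranked = cells.sort_values(["length", "cell_id"], kind="mergesort").reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    ranked["half_length"] = ranked["length"] / 2.0
    out = spots.merge(
        ranked[["cell_id", "rank", "length", "half_length"]], on="cell_id", how="inner"
    )
    cols = ["cell_id", "rank", "length", "half_length", "spot_id", "l"]
    return out[cols].sort_values(["rank", "spot_id"], kind="mergesort").reset_index(drop=True)
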