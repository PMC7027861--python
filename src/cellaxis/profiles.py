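"""Intensity analytics on the cell length axis.

The building block is the *axis profile*: mean pixel intensity in equal bins
of the normalized along-axis coordinate ``l_rel`` in [-0.5, 0.5]. Profiles
stack into kymographs (one cell over time), demographs (one population
ordered by cell length) and, for time-lapse cohorts, into a cells x
percentage-of-division matrix whose rows can be clustered hierarchically to
separate different fluorescence dynamics over the cell cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .core import ImageStack, MeshRecord
from .errors import ClusterError, DissimilarityError, EmptyCell, MissingFrame
from .geometry import pixels_in_mesh

__all__ = [
    "AxisProfile",
    "axis_profile",
    "Kymograph",
    "kymograph",
    "Demograph",
    "demograph",
    "ProfileMatrix",
    "profile_matrix",
    "bin_profiles_by_percent",
    "dissimilarity_matrix",
    "ClusterResult",
    "cluster_profiles",
]

log = logging.getLogger(__name__)


@dataclass
class AxisProfile:
    """Binned mean intensity along the normalized length axis of one cell."""

    values: np.ndarray
    interpolated: np.ndarray  # True where an empty bin was filled from neighbors
    cell_id: str | None = None
    frame_id: int | None = None


def axis_profile(pixels: pd.DataFrame, length: float, n_bins: int = 25) -> AxisProfile:
    """Mean intensity per length-axis bin for one cell.

    ``pixels`` comes from :func:`cellaxis.geometry.pixels_in_mesh` (columns
    ``l`` and ``intensity``); ``length`` is the cell's box-fit length used to
    normalize ``l`` into [-0.5, 0.5]. Bins left empty by the pixel grid are
    linearly interpolated from their populated neighbors (edge bins take the
    nearest populated value) and flagged.

    Raises
    ------
    EmptyCell
        When there are no pixels at all.
    """
    if len(pixels) == 0:
        raise EmptyCell("no pixels to profile")
    l_rel = pixels["l"].to_numpy(float) / float(length)
    inten = pixels["intensity"].to_numpy(float)
    edges = np.linspace(-0.5, 0.5, n_bins + 1)
    idx = np.clip(np.digitize(l_rel, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=inten, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    values = np.full(n_bins, np.nan)
    np.divide(sums, counts, out=values, where=counts > 0)
    empty = counts == 0
    if empty.all():
        raise EmptyCell("no pixels fall in any length-axis bin")
    if empty.any():
        centers = 0.5 * (edges[:-1] + edges[1:])
        values[empty] = np.interp(centers[empty], centers[~empty], values[~empty])
    return AxisProfile(values=values, interpolated=empty)


@dataclass
class Kymograph:
    """Length-axis profiles of one cell stacked over time.

    ``matrix`` rows are frames in ascending time; ``flipped`` records which
    rows were mirrored to keep pole orientation consistent.
    """

    track_id: str
    matrix: np.ndarray
    times: np.ndarray
    flipped: np.ndarray

    def to_table(self) -> pd.DataFrame:
        rows, cols = self.matrix.shape
        t = np.repeat(self.times, cols)
        b = np.tile(np.arange(cols), rows)
        return pd.DataFrame({"time": t, "bin": b, "intensity": self.matrix.ravel()})


def kymograph(
    records: list[MeshRecord],
    stack: ImageStack,
    n_bins: int = 25,
    track_id: str = "",
) -> Kymograph:
    """Build a kymograph for one tracked cell from its meshes and a movie.

    Each record's ``frame_id`` indexes a frame of ``stack``; the row is the
    cell's axis profile on that frame. The bounding-box frame gives no pole
    identity, so orientation is held consistent across frames by choosing,
    per row, the orientation (as-is or mirrored) whose profile is closer in
    L2 distance to the previous row.

    Raises
    ------
    MissingFrame
        When a record references a frame the stack does not contain.
    """
    records = sorted(records, key=lambda r: r.frame_id)
    n_frames = len(stack.frames)
    rows, times, flips = [], [], []
    prev = None
    for rec in records:
        if rec.frame_id >= n_frames:
            raise MissingFrame(
                f"track {track_id!r} references frame {rec.frame_id}, stack has {n_frames}"
            )
        pix = pixels_in_mesh(rec.vertices, stack.frames[rec.frame_id], rec.fit)
        prof = axis_profile(pix, rec.fit.length, n_bins=n_bins).values
        if prev is not None:
            keep = float(np.linalg.norm(prof - prev))
            flip = float(np.linalg.norm(prof[::-1] - prev))
            if flip < keep:
                prof = prof[::-1]
                flips.append(True)
            else:
                flips.append(False)
        else:
            flips.append(False)
        prev = prof
        rows.append(prof)
        dt = stack.time_interval if stack.time_interval is not None else 1.0
        times.append(rec.frame_id * dt)
    return Kymograph(
        track_id=track_id,
        matrix=np.vstack(rows),
        times=np.asarray(times, float),
        flipped=np.asarray(flips, bool),
    )


@dataclass
class Demograph:
    """Population profile matrix with rows ordered by ascending cell length."""

    matrix: np.ndarray
    cell_ids: list[str]
    lengths: np.ndarray


def demograph(
    profiles: pd.DataFrame,
    lengths: pd.DataFrame,
    normalize: bool = False,
) -> Demograph:
    """Stack one profile per cell, shortest cell first.

    ``profiles`` holds one row per cell (index = cell_id, columns = length
    bins); ``lengths`` maps ``cell_id`` to ``length``. Ties in length are
    broken by cell_id so the matrix is invariant to input row order. With
    ``normalize`` each row is divided by its own maximum (nonzero rows).
    """
    order = lengths.sort_values(["length", "cell_id"], kind="mergesort")["cell_id"].tolist()
    mat = profiles.loc[order].to_numpy(float)
    if normalize:
        peaks = mat.max(axis=1, keepdims=True)
        np.divide(mat, peaks, out=mat, where=peaks != 0)
    lens = lengths.set_index("cell_id").loc[order, "length"].to_numpy(float)
    return Demograph(matrix=mat, cell_ids=order, lengths=lens)


@dataclass
class ProfileMatrix:
    """Cells x percentage-of-division grid of mean cellular fluorescence.

    Each cell's (percentage, fluorescence) observations from its first
    complete cycle are linearly interpolated to a common grid; grid points
    outside a cell's observed percentage range take the nearest observed
    value and are flagged in ``extrapolated``.
    """

    values: pd.DataFrame  # rows = cells, columns = grid points
    grid: np.ndarray
    extrapolated: pd.DataFrame
    excluded: list = field(default_factory=list)

    def znormalized(self) -> pd.DataFrame:
        """Rows scaled to mean 0, sd 1 (raises for zero-variance rows)."""
        v = self.values.to_numpy(float)
        sd = v.std(axis=1, ddof=0)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            raise DissimilarityError(
                f"zero-variance profile for cell {self.values.index[flat[0]]!r}"
            )
        return pd.DataFrame(
            (v - v.mean(axis=1, keepdims=True)) / sd[:, None],
            index=self.values.index,
            columns=self.values.columns,
        )


def profile_matrix(
    tracks: pd.DataFrame,
    grid: np.ndarray | None = None,
    value: str = "fluor",
) -> ProfileMatrix:
    """Interpolate per-cell fluorescence-vs-percentage onto a common grid.

    ``tracks`` must be division-annotated (``percentage``/``cycle``
    columns). Tracks with fewer than 2 annotated frames are excluded and
    logged. The default grid is 0..100 in steps of 1 (101 points).
    """
    grid = np.arange(0.0, 101.0) if grid is None else np.asarray(grid, float)
    rows, masks, excluded = {}, {}, []
    for tid, sub in tracks.groupby("track_id", sort=False):
        obs = sub[sub["cycle"] >= 0]
        if len(obs) and "cycle" in obs:
            obs = obs[obs["cycle"] == obs["cycle"].min()]
        obs = obs.sort_values("percentage", kind="mergesort")
        if len(obs) < 2:
            excluded.append(tid)
            log.warning("track %r excluded from profile matrix (<2 annotated frames)", tid)
            continue
        p = obs["percentage"].to_numpy(float)
        f = obs[value].to_numpy(float)
        rows[tid] = np.interp(grid, p, f)
        masks[tid] = (grid < p.min()) | (grid > p.max())
    values = pd.DataFrame.from_dict(rows, orient="index", columns=grid)
    extrap = pd.DataFrame.from_dict(masks, orient="index", columns=grid)
    return ProfileMatrix(values=values, grid=grid, extrapolated=extrap, excluded=excluded)


def bin_profiles_by_percent(
    profiles: np.ndarray,
    percentages: np.ndarray,
    n_bins: int = 10,
) -> np.ndarray:
    """Average length-axis profiles into percentage-of-division bins.

    ``profiles`` has one row per observation (frame) and ``percentages`` the
    matching percentage-of-division values; returns an ``n_bins`` x
    ``profiles.shape[1]`` matrix (NaN rows for empty bins).
    """
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    idx = np.minimum(np.digitize(np.asarray(percentages, float), edges) - 1, n_bins - 1)
    out = np.full((n_bins, profiles.shape[1]), np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            out[b] = profiles[sel].mean(axis=0)
    return out


def dissimilarity_matrix(values: pd.DataFrame | np.ndarray, method: str = "euclidean") -> np.ndarray:
    """Pairwise dissimilarity of profile rows.

    ``euclidean`` is the L2 distance between rows; ``correlation`` is
    1 - Pearson r (so perfectly anticorrelated rows are 2 apart). The result
    is symmetric with a zero diagonal.

    Raises
    ------
    DissimilarityError
        Under ``correlation`` when a row has zero variance (names the cell).
    """
    v = values.to_numpy(float) if isinstance(values, pd.DataFrame) else np.asarray(values, float)
    if v.shape[0] < 2:
        raise DissimilarityError("need at least 2 profiles")
    if method == "euclidean":
        diff = v[:, None, :] - v[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    if method == "correlation":
        sd = v.std(axis=1)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            name = values.index[flat[0]] if isinstance(values, pd.DataFrame) else flat[0]
            raise DissimilarityError(f"zero-variance profile for cell {name!r}")
        r = np.corrcoef(v)
        d = 1.0 - r
        np.fill_diagonal(d, 0.0)
        return d
    raise ValueError(f"unknown dissimilarity method {method!r}")


@dataclass
class ClusterResult:
    """Hierarchical clustering of fluorescence-vs-division profiles.

    Labels are 1..k, renumbered so cluster 1 is the largest; ``summary``
    holds per-cluster size and fraction, ``mean_profiles`` the per-cluster
    mean and sd over the grid when profiles were supplied.
    """

    labels: pd.Series
    k: int
    summary: pd.DataFrame
    mean_profiles: pd.DataFrame | None = None


def cluster_profiles(
    D: np.ndarray,
    k: int,
    profiles: pd.DataFrame | None = None,
    linkage: str = "average",
    index: pd.Index | None = None,
) -> ClusterResult:
    """Agglomerative clustering of a dissimilarity matrix, cut at k clusters.

    Parameters
    ----------
    D : square symmetric dissimilarity matrix (zero diagonal)
    k : number of clusters, 1 <= k <= n
    profiles : optional DataFrame aligned with D's rows, used for the
        per-cluster mean/sd summaries
    linkage : {'average', 'complete', 'ward'}
    """
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ClusterError(f"k={k} outside 1..{n}")
    if linkage not in ("average", "complete", "ward"):
        raise ClusterError(f"unsupported linkage {linkage!r}")
    if index is None:
        index = profiles.index if profiles is not None else pd.RangeIndex(n)
    Z = scipy_linkage(squareform(D, checks=False), method=linkage)
    raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel in decreasing cluster size (ties by first appearance)
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=index, name="cluster")
    sizes_by_label = labels.value_counts().sort_index()
    summary = pd.DataFrame(
        {"cluster": sizes_by_label.index.to_numpy(), "n": sizes_by_label.to_numpy()}
    )
    summary["fraction"] = summary["n"] / n
    mean_profiles = None
    if profiles is not None:
        parts = []
        for c in summary["cluster"]:
            sub = profiles.loc[labels[labels == c].index].to_numpy(float)
            parts.append(
                pd.DataFrame(
                    {
                        "cluster": c,
                        "grid": np.asarray(profiles.columns, float),
                        "mean": sub.mean(axis=0),
                        "sd": sub.std(axis=0, ddof=1) if sub.shape[0] > 1 else 0.0,
                    }
                )
            )
        mean_profiles = pd.concat(parts, ignore_index=True)
    return ClusterResult(labels=labels, k=k, summary=summary, mean_profiles=mean_profiles)
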