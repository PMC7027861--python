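"""Coordinate mathematics for cell-relative analyses.

All geometry lives in pixel units with the image convention: 0-based
coordinates, pixel centers at integer positions, x along columns and y along
rows (y increases downward). A cell's internal frame is defined by its
minimum-area enclosing rectangle: the *length axis* is the long side of that
rectangle, the *width axis* the short side, and the box center is the origin.
Along-axis coordinates are written ``l`` (0 at mid-cell) and across-axis
coordinates ``d`` (0 on the central axis, positive toward rotated +y; no
biological polarity is implied).

Angles are reported in degrees in [-90, 90), measured from the image x-axis
to the length axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon as ShapelyPolygon

from .errors import DegenerateGeometry, EmptyCell

__all__ = [
    "BoxFit",
    "min_bounding_box",
    "orient_mesh",
    "points_in_polygon",
    "assign_spots",
    "spot_relative",
    "spot_absolute",
    "pixels_in_mesh",
    "relativize_objects",
    "signed_area",
    "ensure_ccw",
]

#: area ratio below which two candidate boxes are considered tied
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class BoxFit:
    """Minimum-area enclosing rectangle of a cell outline.

    Attributes
    ----------
    length, width : float
        Long and short side of the rectangle, pixels; ``length >= width > 0``.
    angle : float
        Orientation of the length axis relative to the image x-axis,
        degrees in ``[-90, 90)``.
    center : tuple of float
        Rectangle center ``(x, y)`` in image pixels.
    """

    length: float
    width: float
    angle: float
    center: tuple[float, float]


def signed_area(vertices: np.ndarray) -> float:
    """Shoelace signed area; positive for counterclockwise vertex order."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def ensure_ccw(vertices: np.ndarray) -> np.ndarray:
    """Return the vertex array in counterclockwise order (positive shoelace)."""
    v = np.asarray(vertices, dtype=float)
    if signed_area(v) < 0:
        return v[::-1].copy()
    return v


def _rotation(angle_deg: float) -> np.ndarray:
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s], [s, c]])


def min_bounding_box(vertices: Sequence | np.ndarray) -> BoxFit:
    """Minimum-area enclosing rectangle of a polygon.

    The rectangle is found by the rotating-calipers property: the minimum-area
    enclosing rectangle shares an edge direction with the convex hull, so only
    hull-edge orientations need to be scanned. Ties in area are broken first
    toward the largest length (a rotation-invariant choice — for a triangle
    every edge-aligned box has the same area), then toward the length-axis
    angle of smallest absolute value (so an axis-aligned square reports
    angle 0, not -90).

    Raises
    ------
    DegenerateGeometry
        For fewer than 3 vertices or collinear input.
    """
    pts = np.asarray(vertices, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise DegenerateGeometry("need at least 3 (x, y) vertices")
    if not np.all(np.isfinite(pts)):
        raise DegenerateGeometry("non-finite vertex coordinates")
    try:
        hull = pts[ConvexHull(pts).vertices]
    except QhullError as exc:
        raise DegenerateGeometry(f"degenerate polygon: {exc}") from exc

    edges = np.roll(hull, -1, axis=0) - hull
    theta = np.arctan2(edges[:, 1], edges[:, 0])  # radians

    c, s = np.cos(theta), np.sin(theta)
    # rotate hull by -theta for every edge orientation: (n_edges, n_pts)
    xr = c[:, None] * hull[None, :, 0] + s[:, None] * hull[None, :, 1]
    yr = -s[:, None] * hull[None, :, 0] + c[:, None] * hull[None, :, 1]
    xmin, xmax = xr.min(axis=1), xr.max(axis=1)
    ymin, ymax = yr.min(axis=1), yr.max(axis=1)
    w, h = xmax - xmin, ymax - ymin
    area = w * h

    best = area.min()
    tied = np.flatnonzero(area <= best * (1.0 + _TIE_RTOL))

    # axis angle of each tied candidate, normalized to [-90, 90)
    cand = []
    for i in tied:
        if w[i] >= h[i]:
            axis = math.degrees(theta[i])
            length, width = float(w[i]), float(h[i])
        else:
            axis = math.degrees(theta[i]) + 90.0
            length, width = float(h[i]), float(w[i])
        axis = (axis + 90.0) % 180.0 - 90.0
        cand.append((axis, i, length, width))
    longest = max(c[2] for c in cand)
    cand = [c for c in cand if c[2] >= longest * (1.0 - _TIE_RTOL)]
    cand.sort(key=lambda t: (abs(t[0]), t[0]))
    axis, i, length, width = cand[0]

    if width <= 0:
        raise DegenerateGeometry("polygon has zero width (collinear vertices)")

    cx_r = 0.5 * (xmin[i] + xmax[i])
    cy_r = 0.5 * (ymin[i] + ymax[i])
    # rotate the center back by +theta[i]
    cx = c[i] * cx_r - s[i] * cy_r
    cy = s[i] * cx_r + c[i] * cy_r
    return BoxFit(length=length, width=width, angle=float(axis), center=(float(cx), float(cy)))


def orient_mesh(vertices: np.ndarray, fit: BoxFit) -> np.ndarray:
    """Turn a cell onto its length axis with the box center at the origin.

    Vertices are rotated by ``-fit.angle`` about ``fit.center`` and
    translated so the center maps to (0, 0). The x-extent of the result
    equals ``fit.length`` and the y-extent equals ``fit.width``; the polygon
    area is preserved (rigid motion).
    """
    v = np.asarray(vertices, dtype=float) - np.asarray(fit.center)
    return v @ _rotation(-fit.angle).T


def points_in_polygon(vertices: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Boundary-inclusive containment test of points against a polygon.

    Uses the even-odd rule with the boundary counting as inside (a closed
    polygon), so spots detected on the membrane are kept.
    """
    poly = ShapelyPolygon(np.asarray(vertices, dtype=float))
    return shapely.intersects_xy(poly, np.asarray(x, float), np.asarray(y, float))


def spot_relative(x, y, fit: BoxFit):
    """Transform image coordinates into the cell's internal frame.

    Returns ``(l, d, l_rel, d_rel)`` where ``(l, d)`` is the rotation of
    ``(x, y) - center`` by ``-angle`` and the ``_rel`` values are normalized
    by cell length and width. Accepts scalars or arrays.

    Raises
    ------
    DegenerateGeometry
        If the fit has zero length or width.
    """
    if fit.length <= 0 or fit.width <= 0:
        raise DegenerateGeometry("cannot relativize against a zero-size cell")
    dx = np.asarray(x, dtype=float) - fit.center[0]
    dy = np.asarray(y, dtype=float) - fit.center[1]
    t = math.radians(fit.angle)
    c, s = math.cos(t), math.sin(t)
    l = c * dx + s * dy
    d = -s * dx + c * dy
    return l, d, l / fit.length, d / fit.width


def spot_absolute(l, d, fit: BoxFit):
    """Inverse of :func:`spot_relative`: internal ``(l, d)`` back to image ``(x, y)``."""
    t = math.radians(fit.angle)
    c, s = math.cos(t), math.sin(t)
    l = np.asarray(l, dtype=float)
    d = np.asarray(d, dtype=float)
    x = c * l - s * d + fit.center[0]
    y = s * l + c * d + fit.center[1]
    return x, y


def assign_spots(spots: pd.DataFrame, cells: Iterable) -> pd.DataFrame:
    """Connect detected spots to the cells whose outlines contain them.

    Parameters
    ----------
    spots : DataFrame
        Must carry ``spot_id``, ``frame_id``, ``x``, ``y``.
    cells : iterable
        Objects exposing ``cell_id``, ``frame_id``, ``vertices`` and ``fit``
        (e.g. :class:`cellaxis.core.MeshRecord`).

    Returns
    -------
    DataFrame with one row per input spot: ``spot_id``, ``frame_id``,
    ``cell_id`` (None when the spot lies in no outline) and ``ambiguous``
    (True when several outlines contain the spot; the spot then goes to the
    cell with the nearest box center — relevant for touching cells in chains).
    """
    by_frame: dict[int, list] = {}
    for rec in cells:
        by_frame.setdefault(int(rec.frame_id), []).append(rec)

    out = {"spot_id": [], "frame_id": [], "cell_id": [], "ambiguous": []}
    for frame_id, sub in spots.groupby("frame_id", sort=False):
        recs = by_frame.get(int(frame_id), [])
        xs = sub["x"].to_numpy(float)
        ys = sub["y"].to_numpy(float)
        masks = [points_in_polygon(r.vertices, xs, ys) for r in recs]
        hits = np.vstack(masks) if masks else np.zeros((0, len(sub)), bool)
        for j, (sid, x, y) in enumerate(zip(sub["spot_id"], xs, ys)):
            owners = np.flatnonzero(hits[:, j]) if hits.size else np.array([], int)
            out["spot_id"].append(sid)
            out["frame_id"].append(int(frame_id))
            if owners.size == 0:
                out["cell_id"].append(None)
                out["ambiguous"].append(False)
            elif owners.size == 1:
                out["cell_id"].append(recs[owners[0]].cell_id)
                out["ambiguous"].append(False)
            else:
                d2 = [
                    (x - recs[i].fit.center[0]) ** 2 + (y - recs[i].fit.center[1]) ** 2
                    for i in owners
                ]
                out["cell_id"].append(recs[owners[int(np.argmin(d2))]].cell_id)
                out["ambiguous"].append(True)
    return pd.DataFrame(out)


def pixels_in_mesh(
    vertices: np.ndarray,
    image: np.ndarray,
    fit: BoxFit | None = None,
) -> pd.DataFrame:
    """Extract every image pixel whose center lies inside a cell outline.

    Pixel centers sit at integer coordinates (x = column, y = row); the
    containment test is boundary-inclusive. Pixels outside the image bounds
    are clipped. Returns a DataFrame with ``row``, ``col``, ``intensity``
    and the center's along/across-axis coordinates ``l``, ``d``.

    Raises
    ------
    EmptyCell
        When, after clipping, no pixel center falls inside the polygon.
    """
    v = np.asarray(vertices, dtype=float)
    img = np.asarray(image)
    if fit is None:
        fit = min_bounding_box(v)
    h, w = img.shape[:2]
    c0 = max(int(math.floor(v[:, 0].min())), 0)
    c1 = min(int(math.ceil(v[:, 0].max())), w - 1)
    r0 = max(int(math.floor(v[:, 1].min())), 0)
    r1 = min(int(math.ceil(v[:, 1].max())), h - 1)
    if c1 < c0 or r1 < r0:
        raise EmptyCell("cell outline lies outside the image")
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    cols, rows = cols.ravel(), rows.ravel()
    inside = points_in_polygon(v, cols.astype(float), rows.astype(float))
    if not inside.any():
        raise EmptyCell("no pixel center inside the cell outline")
    cols, rows = cols[inside], rows[inside]
    l, d, _, _ = spot_relative(cols.astype(float), rows.astype(float), fit)
    return pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "intensity": img[rows, cols].astype(float),
            "l": l,
            "d": d,
        }
    )


def relativize_objects(objects: pd.DataFrame, cells: Iterable) -> pd.DataFrame:
    """Attach fluorescent-object outlines to host cells and relativize them.

    ``objects`` is a per-vertex table (``object_id``, ``frame_id``, ``x``,
    ``y``). The host cell is the one containing the object's centroid, with
    the same nearest-center tie rule as :func:`assign_spots`. Vertices of
    hosted objects get cell-internal coordinates ``l``/``d`` (the same
    transform as :func:`spot_relative`, applied vertex-wise); objects whose
    centroid lies in no cell keep their outline unchanged with
    ``cell_id = None``.
    """
    cells = list(cells)
    frames = []
    for (obj_id, frame_id), sub in objects.groupby(["object_id", "frame_id"], sort=False):
        v = sub[["x", "y"]].to_numpy(float)
        cent = ShapelyPolygon(v).centroid
        probe = pd.DataFrame(
            {"spot_id": [obj_id], "frame_id": [frame_id], "x": [cent.x], "y": [cent.y]}
        )
        hit = assign_spots(probe, cells).iloc[0]
        sub = sub.copy()
        sub["cell_id"] = hit["cell_id"]
        sub["ambiguous"] = hit["ambiguous"]
        if hit["cell_id"] is not None:
            host = next(
                r for r in cells if r.cell_id == hit["cell_id"] and int(r.frame_id) == int(frame_id)
            )
            l, d, _, _ = spot_relative(v[:, 0], v[:, 1], host.fit)
            sub["l"], sub["d"] = l, d
        else:
            sub["l"] = np.nan
            sub["d"] = np.nan
        frames.append(sub)
    if not frames:
        out = objects.copy()
        for col in ("cell_id", "ambiguous", "l", "d"):
            out[col] = pd.Series(dtype=object if col == "cell_id" else float)
        return out
    return pd.concat(frames, ignore_index=True)
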