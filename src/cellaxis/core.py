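"""Standard data model shared by all importers and analytics.

Heterogeneous segmentation/detection outputs are funneled into one set of
containers:

* ``MeshFrame`` — per-cell outline polygons with their minimum-bounding-box
  fit and length-axis-oriented coordinates,
* ``spotframe`` — detected fluorescent foci in image coordinates,
* ``spots_relative`` — the same foci in cell-internal coordinates,
* ``objectframe`` — outlines of larger fluorescent objects,
* ``tracks`` — per-cell time series for time-lapse data,
* ``cell_list`` — the original input tables, preserved verbatim per source.

Coordinate convention throughout: 0-based pixels, pixel centers at integer
coordinates, y increasing downward. Importers converting 1-based sources
subtract 1 before data enter this module. All geometry stays in pixel
units; micrometers appear only through the optional ``pixel_size`` metadata
at presentation time.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon as ShapelyPolygon

from . import geometry
from .errors import ConventionMismatch, CorruptDataset, DegenerateGeometry, DuplicateCell
from .geometry import BoxFit

__all__ = [
    "Mesh",
    "MeshRecord",
    "MeshFrame",
    "BoxFit",
    "ImageStack",
    "Dataset",
    "build_dataset",
    "save_dataset",
    "load_dataset",
    "SPOT_COLUMNS",
    "compose_cell_id",
]

#: standard spotframe columns, in on-disk order
SPOT_COLUMNS = ["spot_id", "frame_id", "channel", "x", "y", "intensity", "time"]

_RELATIVE_COLUMNS = [
    "spot_id", "cell_id", "frame_id", "channel",
    "l", "d", "l_rel", "d_rel", "ambiguous",
]

_TRACK_COLUMNS = ["track_id", "frame_id", "time", "length", "width", "fluor", "parent"]


def compose_cell_id(source: str, frame_id: int, native_id) -> str:
    """Compose a globally unique cell id from (source, frame, native id).

    Used when merging inputs from several programs, whose native ids may
    collide.
    """
    return f"{source}.f{int(frame_id)}.{native_id}"


@dataclass
class Mesh:
    """A single cell outline polygon on one frame.

    Vertices are normalized to counterclockwise order on construction; the
    polygon must be simple with strictly positive area.
    """

    cell_id: str
    frame_id: int
    vertices: np.ndarray
    source: str = "generic"

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
            raise DegenerateGeometry(
                f"cell {self.cell_id!r}: a mesh needs >= 3 (x, y) vertices"
            )
        poly = ShapelyPolygon(v)
        if not poly.is_valid or poly.area <= 0:
            raise DegenerateGeometry(
                f"cell {self.cell_id!r}: outline is self-intersecting or has no area"
            )
        self.vertices = geometry.ensure_ccw(v)
        self.frame_id = int(self.frame_id)
        if self.frame_id < 0:
            raise ValueError("frame_id must be >= 0")


@dataclass
class MeshRecord:
    """A mesh together with its box fit and length-axis-oriented vertices."""

    mesh: Mesh
    fit: BoxFit
    rotated: np.ndarray

    @property
    def cell_id(self) -> str:
        return self.mesh.cell_id

    @property
    def frame_id(self) -> int:
        return self.mesh.frame_id

    @property
    def vertices(self) -> np.ndarray:
        return self.mesh.vertices

    @property
    def source(self) -> str:
        return self.mesh.source


class MeshFrame:
    """Collection of :class:`MeshRecord`, indexed by (cell_id, frame_id)."""

    def __init__(self, records: Iterable[MeshRecord] = ()):
        self.records: list[MeshRecord] = []
        self._index: dict[tuple[str, int], MeshRecord] = {}
        for rec in records:
            self._add(rec)

    def _add(self, rec: MeshRecord) -> None:
        key = (rec.cell_id, rec.frame_id)
        if key in self._index:
            raise DuplicateCell(f"duplicate mesh for cell {key[0]!r} on frame {key[1]}")
        self._index[key] = rec
        self.records.append(rec)

    @classmethod
    def from_meshes(cls, meshes: Iterable[Mesh]) -> "MeshFrame":
        """Fit every mesh's bounding box and orient it onto its length axis."""
        records = []
        for m in meshes:
            fit = geometry.min_bounding_box(m.vertices)
            records.append(MeshRecord(mesh=m, fit=fit, rotated=geometry.orient_mesh(m.vertices, fit)))
        return cls(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, cell_id: str, frame_id: int | None = None) -> MeshRecord:
        if frame_id is not None:
            return self._index[(cell_id, int(frame_id))]
        hits = [r for r in self.records if r.cell_id == cell_id]
        if not hits:
            raise KeyError(cell_id)
        return hits[0]

    def cell_ids(self) -> set[str]:
        return {r.cell_id for r in self.records}

    def cells_table(self) -> pd.DataFrame:
        """One row per cell: box-fit length/width/angle/center and source."""
        rows = [
            {
                "cell_id": r.cell_id,
                "frame_id": r.frame_id,
                "source": r.source,
                "length": r.fit.length,
                "width": r.fit.width,
                "angle": r.fit.angle,
                "center_x": r.fit.center[0],
                "center_y": r.fit.center[1],
            }
            for r in self.records
        ]
        cols = ["cell_id", "frame_id", "source", "length", "width",
                "angle", "center_x", "center_y"]
        return pd.DataFrame(rows, columns=cols)

    def vertices_table(self) -> pd.DataFrame:
        """One row per vertex: raw and length-axis-oriented coordinates."""
        parts = []
        for r in self.records:
            n = len(r.vertices)
            parts.append(
                pd.DataFrame(
                    {
                        "cell_id": [r.cell_id] * n,
                        "frame_id": [r.frame_id] * n,
                        "vertex": np.arange(n),
                        "x": r.vertices[:, 0],
                        "y": r.vertices[:, 1],
                        "x_rot": r.rotated[:, 0],
                        "y_rot": r.rotated[:, 1],
                    }
                )
            )
        cols = ["cell_id", "frame_id", "vertex", "x", "y", "x_rot", "y_rot"]
        if not parts:
            return pd.DataFrame(columns=cols)
        return pd.concat(parts, ignore_index=True)[cols]


@dataclass
class ImageStack:
    """A single-channel image time series.

    ``pixel_size`` (micrometers per pixel) and ``time_interval`` (seconds)
    are optional metadata; pixel data stay in native intensity units.
    """

    frames: list[np.ndarray]
    channel: str = "ch1"
    pixel_size: float | None = None
    time_interval: float | None = None

    def __post_init__(self):
        if not self.frames:
            raise ValueError("an ImageStack needs at least one frame")
        shape = np.asarray(self.frames[0]).shape
        frames = []
        for f in self.frames:
            a = np.asarray(f, dtype=float)
            if a.shape != shape:
                raise ValueError("all frames in a stack must share dimensions")
            if not np.all(np.isfinite(a)) or a.min() < 0:
                raise ValueError("intensities must be finite and >= 0")
            frames.append(a)
        self.frames = frames

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @classmethod
    def from_tiff(cls, path, channel: str = "ch1", pixel_size=None, time_interval=None):
        data = tifffile.imread(path)
        if data.ndim == 2:
            frames = [data]
        else:
            frames = [data[i] for i in range(data.shape[0])]
        return cls(frames=frames, channel=channel, pixel_size=pixel_size,
                   time_interval=time_interval)

    def to_tiff(self, path) -> None:
        tifffile.imwrite(
            path, np.stack(self.frames).astype(np.float32), photometric="minisblack"
        )


@dataclass
class Dataset:
    """The standardized bundle all analytics consume.

    ``cell_list`` keeps the original input tables with as little change as
    possible, keyed by source name, so nothing from upstream programs is
    ever lost in standardization.
    """

    meshframe: MeshFrame = field(default_factory=MeshFrame)
    spotframe: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=SPOT_COLUMNS))
    spots_relative: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_RELATIVE_COLUMNS))
    objectframe: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["object_id", "frame_id", "x", "y"])
    )
    tracks: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_TRACK_COLUMNS))
    images: dict[str, ImageStack] = field(default_factory=dict)
    cell_list: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_spots_unassigned: int = 0

    def validate(self) -> None:
        """Check referential integrity: every referenced cell_id must exist."""
        known = self.meshframe.cell_ids()
        if not self.tracks.empty and "track_id" in self.tracks:
            known |= set(self.tracks["track_id"].astype(str))
        for name, table in (("spots_relative", self.spots_relative),
                            ("objectframe", self.objectframe)):
            if table.empty or "cell_id" not in table:
                continue
            refs = set(table["cell_id"].dropna().astype(str))
            missing = refs - known
            if missing:
                raise CorruptDataset(f"{name} references unknown cells: {sorted(missing)[:5]}")


def _check_convention(table: pd.DataFrame | None, what: str) -> None:
    if table is None:
        return
    base = table.attrs.get("coordinate_base", 0)
    if int(base) != 0:
        raise ConventionMismatch(
            f"{what} declares coordinate base {base}; importers must convert to 0-based"
        )


def _normalize_spots(spots: pd.DataFrame) -> pd.DataFrame:
    df = spots.copy()
    if "spot_id" not in df:
        df["spot_id"] = [f"s{i}" for i in range(len(df))]
    df["spot_id"] = df["spot_id"].astype(str)
    df["frame_id"] = df["frame_id"].astype(int)
    if "channel" not in df:
        df["channel"] = "ch1"
    for opt in ("intensity", "time"):
        if opt not in df:
            df[opt] = np.nan
    if not np.all(np.isfinite(df[["x", "y"]].to_numpy(float))):
        raise ValueError("spot coordinates must be finite")
    if (df["frame_id"] < 0).any():
        raise ValueError("spot frame_id must be >= 0")
    extra = [c for c in df.columns if c not in SPOT_COLUMNS]
    return df[SPOT_COLUMNS + extra]


def build_dataset(
    meshes: Iterable[Mesh],
    spots: pd.DataFrame | None = None,
    objects: pd.DataFrame | None = None,
    images: Mapping[str, ImageStack] | None = None,
    tracks: pd.DataFrame | None = None,
    cell_list: Mapping[str, pd.DataFrame] | None = None,
) -> Dataset:
    """Assemble a :class:`Dataset` from standardized inputs.

    Box fits and oriented outlines are computed for every mesh; if spots are
    given they are connected to cells and relativized (spot count is
    conserved: assigned + unassigned = input). Original input tables passed
    via ``cell_list`` are stored verbatim.
    """
    _check_convention(spots, "spotframe")
    _check_convention(objects, "objectframe")
    mf = MeshFrame.from_meshes(meshes)
    ds = Dataset(meshframe=mf)

    if tracks is not None and len(tracks):
        ds.tracks = tracks.copy()

    if spots is not None and len(spots):
        sf = _normalize_spots(spots)
        ds.spotframe = sf
        assignment = geometry.assign_spots(sf, mf.records)
        merged = sf.merge(assignment, on=["spot_id", "frame_id"], how="left")
        rows = []
        for _, r in merged.iterrows():
            if r["cell_id"] is None or (isinstance(r["cell_id"], float) and np.isnan(r["cell_id"])):
                continue
            rec = mf.get(r["cell_id"], r["frame_id"])
            l, d, lr, dr = geometry.spot_relative(r["x"], r["y"], rec.fit)
            rows.append(
                {
                    "spot_id": r["spot_id"],
                    "cell_id": r["cell_id"],
                    "frame_id": int(r["frame_id"]),
                    "channel": r["channel"],
                    "l": float(l),
                    "d": float(d),
                    "l_rel": float(lr),
                    "d_rel": float(dr),
                    "ambiguous": bool(r["ambiguous"]),
                }
            )
        ds.spots_relative = pd.DataFrame(rows, columns=_RELATIVE_COLUMNS)
        ds.n_spots_unassigned = len(sf) - len(rows)

    if objects is not None and len(objects):
        ds.objectframe = geometry.relativize_objects(objects, mf.records)

    if images:
        ds.images = dict(images)
    if cell_list:
        ds.cell_list = {k: v.copy() for k, v in cell_list.items()}
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# persistence: one delimited UTF-8 table per frame type + plain-text manifest

_MANIFEST = "manifest.txt"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # 17 significant digits make the float round-trip exact
    df.to_csv(path, index=False, float_format="%.17g")


def save_dataset(ds: Dataset, directory) -> Path:
    """Persist a dataset as delimited tables plus a checksummed manifest.

    Returns the manifest path. ``load_dataset(save_dataset(ds))`` reproduces
    every numeric field (floats are written in round-tripping precision) and
    every identifier exactly.
    """
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "cells.csv": ds.meshframe.cells_table(),
        "mesh_vertices.csv": ds.meshframe.vertices_table(),
        "spots.csv": ds.spotframe,
        "spots_relative.csv": ds.spots_relative,
        "objects.csv": ds.objectframe,
        "tracks.csv": ds.tracks,
    }
    for source, table in ds.cell_list.items():
        tables[f"cell_list_{source}.csv"] = table

    lines = ["format: cellaxis-dataset/1", f"unassigned_spots: {ds.n_spots_unassigned}"]
    for name, df in tables.items():
        _write_csv(df, out / name)
        lines.append(f"table: {name} sha256={_sha256(out / name)}")
    for channel, stack in ds.images.items():
        name = f"images_{channel}.tif"
        stack.to_tiff(out / name)
        meta = []
        if stack.pixel_size is not None:
            meta.append(f"pixel_size={stack.pixel_size!r}")
        if stack.time_interval is not None:
            meta.append(f"time_interval={stack.time_interval!r}")
        lines.append(
            f"image: {name} channel={channel} sha256={_sha256(out / name)}"
            + ("".join(" " + m for m in meta))
        )
    (out / _MANIFEST).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out / _MANIFEST


def _read_csv(path: Path, str_cols=(), int_cols=()) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={c: str for c in str_cols}, float_precision="round_trip")
    for c in int_cols:
        if c in df and len(df):
            df[c] = df[c].astype(int)
    return df


def load_dataset(directory) -> Dataset:
    """Load a dataset saved by :func:`save_dataset`, verifying checksums."""
    root = Path(directory)
    manifest = root / _MANIFEST
    if not manifest.exists():
        raise CorruptDataset(f"no {_MANIFEST} in {root}")
    tables: dict[str, Path] = {}
    images: list[tuple[str, str, str]] = []
    unassigned = 0
    for line in manifest.read_text(encoding="utf-8").splitlines():
        if line.startswith("unassigned_spots:"):
            unassigned = int(line.split(":", 1)[1])
        elif line.startswith("table:"):
            _, rest = line.split(":", 1)
            name, checksum = rest.split()[:2]
            tables[name] = checksum.removeprefix("sha256=")
        elif line.startswith("image:"):
            parts = line.split()
            name = parts[1]
            channel = next(p.split("=", 1)[1] for p in parts if p.startswith("channel="))
            checksum = next(p.split("=", 1)[1] for p in parts if p.startswith("sha256="))
            images.append((name, channel, checksum))

    loaded: dict[str, pd.DataFrame] = {}
    for name, checksum in tables.items():
        path = root / name
        if not path.exists():
            raise CorruptDataset(f"missing table file {name}")
        if _sha256(path) != checksum:
            raise CorruptDataset(f"checksum mismatch for {name}")
        try:
            loaded[name] = pd.read_csv(path, float_precision="round_trip")
        except pd.errors.EmptyDataError:
            loaded[name] = pd.DataFrame()

    cells = _read_csv(root / "cells.csv", str_cols=("cell_id", "source"), int_cols=("frame_id",))
    verts = _read_csv(root / "mesh_vertices.csv", str_cols=("cell_id",), int_cols=("frame_id", "vertex"))
    records = []
    for _, row in cells.iterrows():
        sub = verts[(verts["cell_id"] == row["cell_id"]) & (verts["frame_id"] == row["frame_id"])]
        sub = sub.sort_values("vertex")
        mesh = Mesh(
            cell_id=row["cell_id"],
            frame_id=int(row["frame_id"]),
            vertices=sub[["x", "y"]].to_numpy(float),
            source=row["source"],
        )
        fit = BoxFit(
            length=float(row["length"]),
            width=float(row["width"]),
            angle=float(row["angle"]),
            center=(float(row["center_x"]), float(row["center_y"])),
        )
        records.append(MeshRecord(mesh=mesh, fit=fit, rotated=sub[["x_rot", "y_rot"]].to_numpy(float)))

    ds = Dataset(meshframe=MeshFrame(records), n_spots_unassigned=unassigned)
    ds.spotframe = _read_csv(root / "spots.csv", str_cols=("spot_id", "channel"), int_cols=("frame_id",))
    ds.spots_relative = _read_csv(
        root / "spots_relative.csv", str_cols=("spot_id", "cell_id", "channel"), int_cols=("frame_id",)
    )
    ds.objectframe = loaded["objects.csv"]
    ds.tracks = _read_csv(root / "tracks.csv", str_cols=("track_id", "parent"), int_cols=("frame_id",)) \
        if "tracks.csv" in loaded else pd.DataFrame(columns=_TRACK_COLUMNS)
    for name in tables:
        if name.startswith("cell_list_"):
            ds.cell_list[name[len("cell_list_"):-len(".csv")]] = loaded[name]
    for name, channel, checksum in images:
        path = root / name
        if not path.exists() or _sha256(path) != checksum:
            raise CorruptDataset(f"missing or corrupt image stack {name}")
        ds.images[channel] = ImageStack.from_tiff(path, channel=channel)
    return ds
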