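"""Parsers that funnel upstream segmentation/detection outputs into the
standard data model.

One generic delimited-table importer covers any program that can export a
table; shipped column-mapping presets document the dialects of MicrobeJ,
SuperSegger, Morphometrics and ObjectJ exports. Two bespoke importers handle
structured formats: MAT v5 cell lists with paired left/right contour meshes
(the Oufti layout) and single-molecule spot/trajectory tables (the iSBatch
layout).

Importing never mutates coordinates beyond the declared base shift
(1-based sources are converted to the package-wide 0-based convention), and
the unmodified source table is always preserved so it can enter the
dataset's ``cell_list``.
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io

from .core import Mesh
from .errors import DegenerateGeometry, ParseError, SchemaError

__all__ = [
    "ColumnMapping",
    "Imported",
    "import_generic",
    "import_oufti_mat",
    "import_isbatch_spots",
    "PRESETS",
]

log = logging.getLogger(__name__)

PRESETS = ("generic", "microbej", "supersegger", "morphometrics", "objectj")

_REQUIRED = {
    "mesh": ("cell_id", "frame_id", "x", "y"),
    "spot": ("frame_id", "x", "y"),
    "object": ("object_id", "frame_id", "x", "y"),
    "track": ("track_id", "frame_id", "time", "length"),
}

_NUMERIC = {"x", "y", "time", "length", "width", "fluor", "intensity"}
_INTEGER = {"frame_id"}


@dataclass
class ColumnMapping:
    """Mapping from standard fields to source column names for one dialect.

    ``fields[kind][standard_field] -> source column``; ``base`` is the
    coordinate base of the source (0 or 1). 1-based sources have ``base``
    subtracted from x, y and frame_id on import.
    """

    name: str
    fields: dict[str, dict[str, str]]
    base: int = 0

    @classmethod
    def preset(cls, name: str) -> "ColumnMapping":
        if name not in PRESETS:
            raise SchemaError(f"unknown preset {name!r}; available: {PRESETS}")
        text = resources.files("cellaxis.presets").joinpath(f"{name}.cfg").read_text()
        return cls.from_text(text, name=name)

    @classmethod
    def from_text(cls, text: str, name: str = "custom") -> "ColumnMapping":
        cp = configparser.ConfigParser()
        cp.optionxform = str  # keep case of standard field names
        cp.read_string(text)
        base = cp.getint("meta", "base", fallback=0)
        fields = {
            kind: dict(cp[kind]) for kind in ("mesh", "spot", "object", "track") if cp.has_section(kind)
        }
        return cls(name=name, fields=fields, base=base)

    @classmethod
    def from_file(cls, path) -> "ColumnMapping":
        return cls.from_text(Path(path).read_text(), name=Path(path).stem)

    def for_kind(self, kind: str) -> dict[str, str]:
        if kind not in _REQUIRED:
            raise SchemaError(f"unknown import kind {kind!r}")
        mapping = self.fields.get(kind)
        if mapping is None:
            raise SchemaError(f"preset {self.name!r} has no mapping for kind {kind!r}")
        missing = [f for f in _REQUIRED[kind] if f not in mapping]
        if missing:
            raise SchemaError(
                f"preset {self.name!r} does not map required fields {missing} for {kind!r}"
            )
        return mapping


@dataclass
class Imported:
    """Result of one import: standardized records plus the untouched source.

    ``raw`` is the source table exactly as read (for ``Dataset.cell_list``);
    ``skipped`` counts cells dropped for degenerate geometry.
    """

    kind: str
    source: str
    table: pd.DataFrame
    raw: pd.DataFrame
    meshes: list[Mesh] | None = None
    tracks: pd.DataFrame | None = None
    skipped: int = 0
    messages: list[str] = field(default_factory=list)


def _coerce_numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: non-numeric value {raw.iloc[row]!r} in column {col!r} at data row {row}"
        )
    return out


def import_generic(
    path,
    mapping: ColumnMapping | str = "generic",
    kind: str = "spot",
    source: str | None = None,
) -> Imported:
    """Import any delimited table through a column mapping.

    Parameters
    ----------
    path : file path
        Comma-separated table with a header row.
    mapping : ColumnMapping or preset name
    kind : {'mesh', 'spot', 'object', 'track'}
    source : str
        Source label recorded on every record; defaults to the mapping name.

    Unmapped source columns are not dropped: the full source table is kept in
    ``Imported.raw``. Coordinates (and frame ids) of 1-based sources are
    shifted to 0-based.
    """
    if isinstance(mapping, str):
        mapping = ColumnMapping.preset(mapping)
    source = source or mapping.name
    cols = mapping.for_kind(kind)
    raw = pd.read_csv(path)
    present = {std: src for std, src in cols.items() if src in raw.columns}
    missing = [std for std in _REQUIRED[kind] if std not in present]
    if missing:
        raise SchemaError(
            f"{path}: missing mapped column(s) "
            + ", ".join(f"{std!r} (source column {cols[std]!r})" for std in missing)
        )

    std = pd.DataFrame(index=raw.index)
    for field_name, src_col in present.items():
        if field_name in _NUMERIC:
            std[field_name] = _coerce_numeric(raw, src_col, path)
        elif field_name in _INTEGER:
            std[field_name] = _coerce_numeric(raw, src_col, path).astype(int)
        else:
            std[field_name] = raw[src_col].astype(str)
    for c in ("x", "y"):
        if c in std:
            std[c] = std[c] - mapping.base
    if "frame_id" in std:
        std["frame_id"] = std["frame_id"] - mapping.base
    std.attrs["coordinate_base"] = 0

    result = Imported(kind=kind, source=source, table=std, raw=raw)
    if kind == "mesh":
        meshes, skipped = [], 0
        for (cid, fid), sub in std.groupby(["cell_id", "frame_id"], sort=False):
            try:
                meshes.append(
                    Mesh(
                        cell_id=str(cid),
                        frame_id=int(fid),
                        vertices=sub[["x", "y"]].to_numpy(float),
                        source=source,
                    )
                )
            except DegenerateGeometry as exc:
                skipped += 1
                msg = f"skipped degenerate cell {cid!r} frame {fid}: {exc}"
                result.messages.append(msg)
                log.warning(msg)
        result.meshes = meshes
        result.skipped = skipped
    elif kind == "track":
        result.tracks = std
    return result


# ---------------------------------------------------------------------------
# MAT v5 cell lists with paired left/right contours (Oufti layout)


def _as_list(obj) -> list:
    """Flatten a MATLAB cell-array level into a Python list."""
    if obj is None:
        return []
    if isinstance(obj, np.ndarray):
        if obj.size == 0:
            return []
        return list(np.ravel(obj))
    if isinstance(obj, (list, tuple)):
        return list(obj)
    return [obj]


def _unwrap(obj):
    """Peel (1, 1) object-array wrappers that MAT v5 nesting produces."""
    while isinstance(obj, np.ndarray) and obj.dtype == object and obj.size == 1:
        obj = obj.ravel()[0]
    return obj


def import_oufti_mat(path, varname: str = "cellList", source: str = "oufti") -> Imported:
    """Import a MAT v5 cell list whose per-cell mesh pairs left/right contours.

    The expected layout is a struct with ``meshData`` (per-frame cell arrays
    of cell structs carrying an N x 4 ``mesh`` of (x_left, y_left, x_right,
    y_right) rows) and ``cellId`` (per-frame native ids); a bare per-frame
    cell array is also accepted. Each mesh is converted to a single simple
    polygon by walking the left contour and returning along the reversed
    right contour, dropping the duplicated pole points (2N - 2 vertices).
    Genealogy fields (``ancestors``/``birthframe``), when present, are
    forwarded as a lineage table. MATLAB's 1-based coordinates and frame
    numbers become 0-based.
    """
    mat = scipy.io.loadmat(path, squeeze_me=False, struct_as_record=False)
    if varname not in mat:
        raise SchemaError(f"{path}: no variable {varname!r} in MAT file")
    var = _unwrap(mat[varname])

    if hasattr(var, "meshData"):
        frames = [[_unwrap(c) for c in _as_list(f)] for f in _as_list(var.meshData)]
        ids = [
            [np.ravel(_unwrap(i)) for i in _as_list(f)]
            for f in _as_list(getattr(var, "cellId", None))
        ]
        ids = [[i.item() if isinstance(i, np.ndarray) and i.size == 1 else i for i in f] for f in ids]
    else:
        frames = [[_unwrap(c) for c in _as_list(f)] for f in _as_list(var)]
        ids = []

    meshes: list[Mesh] = []
    lineage_rows = []
    raw_rows = []
    skipped = 0
    messages: list[str] = []
    for fidx, cells in enumerate(frames):
        frame_ids = ids[fidx] if fidx < len(ids) else [i + 1 for i in range(len(cells))]
        for cidx, cellstruct in enumerate(cells):
            native = frame_ids[cidx] if cidx < len(frame_ids) else cidx + 1
            cid = str(int(native)) if isinstance(native, (int, np.integer, float)) else str(native)
            mesh_arr = np.atleast_2d(np.asarray(getattr(cellstruct, "mesh", np.empty((0, 4)))))
            raw_rows.append(
                {"frame": fidx + 1, "cell": cid, "n_mesh_rows": int(mesh_arr.shape[0])}
            )
            if mesh_arr.shape[0] < 2 or mesh_arr.shape[1] != 4:
                skipped += 1
                messages.append(f"skipped cell {cid} frame {fidx}: mesh has < 2 rows")
                continue
            left = mesh_arr[:, :2]
            right = mesh_arr[:, 2:]
            poly = np.vstack([left, right[::-1][1:-1]]) - 1.0  # 1-based -> 0-based
            try:
                meshes.append(Mesh(cell_id=cid, frame_id=fidx, vertices=poly, source=source))
            except DegenerateGeometry as exc:
                skipped += 1
                messages.append(f"skipped cell {cid} frame {fidx}: {exc}")
                continue
            if hasattr(cellstruct, "ancestors") or hasattr(cellstruct, "birthframe"):
                anc = _as_list(getattr(cellstruct, "ancestors", []))
                lineage_rows.append(
                    {
                        "track_id": cid,
                        "frame_id": fidx,
                        "parent": str(int(anc[-1])) if anc else "",
                        "birthframe": int(getattr(cellstruct, "birthframe", fidx + 1)) - 1,
                    }
                )
    for m in messages:
        log.warning(m)
    table_cols = ["cell_id", "frame_id"]
    table = pd.DataFrame(
        [{"cell_id": m.cell_id, "frame_id": m.frame_id} for m in meshes], columns=table_cols
    )
    return Imported(
        kind="mesh",
        source=source,
        table=table,
        raw=pd.DataFrame(raw_rows, columns=["frame", "cell", "n_mesh_rows"]),
        meshes=meshes,
        tracks=pd.DataFrame(lineage_rows) if lineage_rows else None,
        skipped=skipped,
        messages=messages,
    )


# ---------------------------------------------------------------------------
# single-molecule spot/trajectory tables (iSBatch layout)

_ISBATCH_REQUIRED = ("x", "y", "slice")


def import_isbatch_spots(path, source: str = "isbatch") -> Imported:
    """Import a single-molecule spot table with trajectory ids.

    Expected columns: ``x``, ``y`` (0-based pixels), ``slice`` (1-based
    frame number), and optionally ``trajectory``, ``intensity``, ``channel``.
    The trajectory id is preserved so spots can be followed over time.
    Duplicated spot ids within a frame are accepted and flagged in the log.
    """
    raw = pd.read_csv(path)
    missing = [c for c in _ISBATCH_REQUIRED if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    std = pd.DataFrame(index=raw.index)
    for c in ("x", "y"):
        std[c] = _coerce_numeric(raw, c, path)
    std["frame_id"] = _coerce_numeric(raw, "slice", path).astype(int) - 1
    if "spot" in raw.columns:
        std["spot_id"] = raw["spot"].astype(str)
    else:
        std["spot_id"] = [f"{source}-{i}" for i in range(len(raw))]
    if "trajectory" in raw.columns:
        std["trajectory"] = raw["trajectory"].astype(str)
    if "intensity" in raw.columns:
        std["intensity"] = _coerce_numeric(raw, "intensity", path)
    if "channel" in raw.columns:
        std["channel"] = raw["channel"].astype(str)
    std.attrs["coordinate_base"] = 0

    messages = []
    dup = std.duplicated(subset=["spot_id", "frame_id"])
    if dup.any():
        msg = f"{int(dup.sum())} duplicated spot ids within a frame (kept)"
        messages.append(msg)
        log.warning("%s: %s", path, msg)
    return Imported(kind="spot", source=source, table=std, raw=raw, messages=messages)
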