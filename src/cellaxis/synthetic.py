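"""Synthetic data with known ground truth.

Everything the toolbox can ingest is also generated here, so every pipeline
can be exercised end-to-end without external downloads: cell outlines for
the three morphologies of common Gram-positive model organisms (rods,
cocci, ovococci), fluorescent-spot images with Gaussian point-spread and
optional Poisson noise, exponentially growing and dividing time-lapse
tracks, planted fluorescence-dynamics archetypes for clustering, and
dialect files that close the importer round-trip loop.

All randomness flows through ``numpy.random.default_rng(seed)`` (PCG64), so
regeneration is bit-identical per seed across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io

from .core import ImageStack, Mesh, MeshFrame
from .errors import DialectError, GeometryError
from .geometry import BoxFit, ensure_ccw, spot_absolute

__all__ = [
    "make_mesh",
    "make_population",
    "place_spots",
    "simulate_timelapse",
    "simulate_profile_cohort",
    "ARCHETYPES",
    "render_image",
    "sweeping_band_movie",
    "write_fixture",
    "SimulationTruth",
    "DIALECTS",
]

DIALECTS = ("generic-csv", "oufti-mat", "isbatch-csv", "microbej-csv")


@dataclass
class SimulationTruth:
    """Ground truth of a synthetic dataset, fully determined by (params, seed)."""

    seed: int
    params: dict = field(default_factory=dict)
    cells: pd.DataFrame | None = None
    spots: pd.DataFrame | None = None
    divisions: pd.DataFrame | None = None
    track_flags: pd.DataFrame | None = None
    labels: pd.Series | None = None


def make_mesh(
    shape: str,
    length: float,
    width: float,
    center: tuple[float, float] = (0.0, 0.0),
    angle: float = 0.0,
    n_vertices: int = 32,
) -> np.ndarray:
    """Polygon outline of an idealized cell.

    ``rod`` is a rectangle with semicircular caps, ``coccus`` a circle
    (diameter = length) and ``ovococcus`` an ellipse. The outline is simple,
    counterclockwise, and rotated/translated to (angle, center).

    Raises
    ------
    GeometryError
        When width exceeds length or sizes are not positive.
    """
    if width > length:
        raise GeometryError("width must not exceed length")
    if width <= 0 or length <= 0:
        raise GeometryError("length and width must be positive")
    if n_vertices < 8:
        raise GeometryError("need at least 8 vertices")
    if shape == "rod":
        r = width / 2.0
        cap = length / 2.0 - r
        n_half = max(n_vertices // 2, 5)
        if n_half % 2 == 0:
            n_half += 1  # odd count puts a vertex exactly on the pole
        t_right = np.linspace(-np.pi / 2, np.pi / 2, n_half)
        t_left = np.linspace(np.pi / 2, 3 * np.pi / 2, n_half)
        right = np.column_stack([cap + r * np.cos(t_right), r * np.sin(t_right)])
        left = np.column_stack([-cap + r * np.cos(t_left), r * np.sin(t_left)])
        v = np.vstack([right, left])
    elif shape == "coccus":
        t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        r = length / 2.0
        v = np.column_stack([r * np.cos(t), r * np.sin(t)])
    elif shape == "ovococcus":
        t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        v = np.column_stack([length / 2.0 * np.cos(t), width / 2.0 * np.sin(t)])
    else:
        raise GeometryError(f"unknown shape {shape!r}")
    th = np.radians(angle)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return ensure_ccw(v @ rot.T + np.asarray(center))


def make_population(
    n_cells: int,
    shape: str = "rod",
    seed: int = 0,
    length_range: tuple[float, float] = (15.0, 35.0),
    aspect: float = 0.35,
    n_vertices: int = 32,
    frame_id: int = 0,
    source: str = "synthetic",
) -> tuple[list[Mesh], SimulationTruth]:
    """Snapshot population of non-overlapping cells on a regular grid.

    Lengths draw uniformly from ``length_range``; widths are
    ``aspect * length`` (equal to length for cocci); orientations are
    uniform in [-90, 90). Cells sit on a grid whose pitch exceeds the
    maximum length so outlines cannot overlap. Truth records per-cell
    length, width, angle and center.
    """
    rng = np.random.default_rng(seed)
    pitch = length_range[1] + 6.0
    per_row = int(np.ceil(np.sqrt(n_cells)))
    meshes, rows = [], []
    for i in range(n_cells):
        length = rng.uniform(*length_range)
        width = length if shape == "coccus" else aspect * length
        angle = rng.uniform(-90.0, 90.0)
        cx = (i % per_row + 0.5) * pitch + rng.uniform(-1, 1)
        cy = (i // per_row + 0.5) * pitch + rng.uniform(-1, 1)
        cid = f"c{i:03d}"
        meshes.append(
            Mesh(
                cell_id=cid,
                frame_id=frame_id,
                vertices=make_mesh(shape, length, width, (cx, cy), angle, n_vertices),
                source=source,
            )
        )
        rows.append(
            {
                "cell_id": cid,
                "frame_id": frame_id,
                "shape": shape,
                "length": length,
                "width": width,
                "angle": angle,
                "center_x": cx,
                "center_y": cy,
            }
        )
    truth = SimulationTruth(
        seed=seed,
        params={"shape": shape, "n_cells": n_cells, "length_range": length_range},
        cells=pd.DataFrame(rows),
    )
    return meshes, truth


def place_spots(
    truth: SimulationTruth,
    pattern: str = "uniform",
    spots_per_cell: int = 2,
    jitter: float = 0.03,
    seed: int = 0,
    channel: str = "ch1",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant fluorescent spots inside the cells of a synthetic population.

    Patterns (in relative coordinates): ``midcell`` at (0, 0), ``quarter``
    alternating (-0.25, 0)/(+0.25, 0) — the positions a divisome or
    replisome marker occupies late in the cycle — and ``uniform`` anywhere
    safely inside the outline. ``jitter`` is Gaussian noise on the relative
    position. Returns the spotframe and a truth table mapping each spot to
    its cell.
    """
    rng = np.random.default_rng(seed)
    spot_rows, truth_rows = [], []
    k = 0
    for _, cell in truth.cells.iterrows():
        fit = BoxFit(
            length=cell["length"],
            width=cell["width"],
            angle=cell["angle"],
            center=(cell["center_x"], cell["center_y"]),
        )
        for j in range(spots_per_cell):
            if pattern == "midcell":
                lr, dr = 0.0, 0.0
            elif pattern == "quarter":
                lr, dr = (-0.25 if j % 2 == 0 else 0.25), 0.0
            elif pattern == "uniform":
                lr, dr = rng.uniform(-0.3, 0.3), rng.uniform(-0.2, 0.2)
            else:
                raise ValueError(f"unknown spot pattern {pattern!r}")
            lr += rng.normal(0.0, jitter)
            dr += rng.normal(0.0, jitter)
            x, y = spot_absolute(lr * fit.length, dr * fit.width, fit)
            sid = f"s{k:04d}"
            k += 1
            spot_rows.append(
                {
                    "spot_id": sid,
                    "frame_id": int(cell["frame_id"]),
                    "channel": channel,
                    "x": float(x),
                    "y": float(y),
                    "intensity": float(rng.uniform(100, 300)),
                    "time": np.nan,
                }
            )
            truth_rows.append(
                {"spot_id": sid, "cell_id": cell["cell_id"], "l_rel": lr, "d_rel": dr}
            )
    return pd.DataFrame(spot_rows), pd.DataFrame(truth_rows)


def simulate_timelapse(
    n_tracks: int = 200,
    growth_rate: float = 0.01,
    division_length: float = 40.0,
    length_noise: float = 0.03,
    frame_interval: float = 120.0,
    n_frames: int = 120,
    non_grower_fraction: float = 0.1,
    fluor_mean: float = 100.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Exponentially growing, dividing single-cell tracks.

    Each track follows one cell line from birth: true length grows as
    ``L(t) = L_birth * exp(growth_rate * t_min)`` (rate per minute) and
    halves into equal daughters whenever it reaches ``division_length``;
    the observed length carries multiplicative noise
    ``exp(length_noise * N(0,1))`` per observation. A planted fraction of
    non-growers holds constant true length. Mean cellular fluorescence is
    ``fluor_mean`` with 5% multiplicative noise.

    Returns the tidy tracks table and truth (division boundaries per track:
    the frame index t with the division between t and t+1; plus the
    non-grower flags).

    Defaults mirror a slow-growth time-lapse: 2-min frames over 4 h,
    doubling time ~69 min, 3% length noise, 10% non-growers.
    """
    rng = np.random.default_rng(seed)
    non_growers = set(rng.choice(n_tracks, size=round(non_grower_fraction * n_tracks), replace=False))
    dt_min = frame_interval / 60.0
    rows, div_rows, flag_rows = [], [], []
    for i in range(n_tracks):
        tid = f"t{i:03d}"
        grower = i not in non_growers
        L = division_length / 2.0 * rng.uniform(0.9, 1.1)
        width = 0.35 * division_length / 2.0
        for f in range(n_frames):
            obs = L * np.exp(length_noise * rng.normal())
            rows.append(
                {
                    "track_id": tid,
                    "frame_id": f,
                    "time": f * frame_interval,
                    "length": obs,
                    "width": width,
                    "fluor": fluor_mean * np.exp(0.05 * rng.normal()),
                    "parent": "",
                }
            )
            if grower and f < n_frames - 1:
                L *= np.exp(growth_rate * dt_min)
                if L >= division_length:
                    L /= 2.0
                    div_rows.append({"track_id": tid, "frame": f})
        flag_rows.append({"track_id": tid, "non_grower": not grower})
    truth = SimulationTruth(
        seed=seed,
        params={
            "n_tracks": n_tracks,
            "growth_rate": growth_rate,
            "division_length": division_length,
            "length_noise": length_noise,
            "frame_interval": frame_interval,
            "n_frames": n_frames,
            "non_grower_fraction": non_grower_fraction,
        },
        divisions=pd.DataFrame(div_rows, columns=["track_id", "frame"]),
        track_flags=pd.DataFrame(flag_rows),
    )
    return pd.DataFrame(rows), truth


#: planted fluorescence-over-cycle archetypes (functions of percentage 0-100):
#: a dip just before division that recovers, a gradual decline, and a late
#: drop — the qualitative dynamics a replisome marker can show over division.
ARCHETYPES = {
    "dip_recover": lambda p: 1.0 - 0.8 * np.exp(-0.5 * ((p - 70.0) / 10.0) ** 2),
    "gradual": lambda p: 1.0 - 0.006 * p,
    "late_drop": lambda p: 1.0 / (1.0 + np.exp((p - 85.0) / 4.0)),
}


def simulate_profile_cohort(
    n_cells: int = 150,
    noise_sd: float | None = None,
    points_per_cell: int = 21,
    seed: int = 0,
    archetypes: dict | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Cohort of fluorescence-vs-percentage observations with planted classes.

    Cells split evenly over the archetypes; each cell observes its archetype
    at ``points_per_cell`` percentages with additive Gaussian noise. The
    default ``noise_sd`` is 10% of the minimum L2 separation between
    archetype curves. Returns an annotated-track-like table (``track_id``,
    ``percentage``, ``fluor``, ``cycle``, ``complete``) and truth labels.
    """
    rng = np.random.default_rng(seed)
    archetypes = archetypes or ARCHETYPES
    names = list(archetypes)
    grid = np.linspace(0.0, 100.0, points_per_cell)
    if noise_sd is None:
        curves = [archetypes[n](grid) for n in names]
        seps = [
            np.linalg.norm(curves[a] - curves[b]) / np.sqrt(len(grid))
            for a in range(len(curves))
            for b in range(a + 1, len(curves))
        ]
        noise_sd = 0.1 * min(seps)
    rows, labels = [], {}
    for i in range(n_cells):
        name = names[i % len(names)]
        tid = f"p{i:03d}"
        labels[tid] = name
        f = archetypes[name](grid) + rng.normal(0.0, noise_sd, size=grid.size)
        for p, v in zip(grid, f):
            rows.append(
                {"track_id": tid, "percentage": p, "fluor": v, "cycle": 0, "complete": True}
            )
    truth = SimulationTruth(
        seed=seed,
        params={"n_cells": n_cells, "noise_sd": noise_sd, "archetypes": names},
        labels=pd.Series(labels, name="archetype"),
    )
    return pd.DataFrame(rows), truth


def render_image(
    shape: tuple[int, int] = (64, 64),
    spots: pd.DataFrame | None = None,
    psf_sigma: float = 1.5,
    background: float = 100.0,
    amplitude: float = 200.0,
    poisson: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Render one fluorescence frame: background + Gaussian spot images.

    Each spot contributes ``amplitude * exp(-r^2 / (2 psf_sigma^2))``
    centered on its (x, y); with ``poisson`` the expected image is sampled
    pixel-wise from a Poisson distribution (shot noise), deterministically
    per seed.
    """
    h, w = shape
    img = np.full((h, w), float(background))
    if spots is not None and len(spots):
        cols, rows_ = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        for _, s in spots.iterrows():
            amp = float(s["amplitude"]) if "amplitude" in s else amplitude
            img += amp * np.exp(
                -(((cols - s["x"]) ** 2 + (rows_ - s["y"]) ** 2) / (2 * psf_sigma**2))
            )
    if poisson:
        img = np.random.default_rng(seed).poisson(img).astype(float)
    return img


def sweeping_band_movie(
    n_frames: int = 20,
    length: float = 40.0,
    width: float = 12.0,
    image_shape: tuple[int, int] = (32, 64),
    band_sigma: float = 2.0,
    start_l_rel: float = 0.0,
    end_l_rel: float = 0.25,
    background: float = 10.0,
    amplitude: float = 100.0,
) -> tuple[MeshFrame, ImageStack, np.ndarray]:
    """Movie of one static cell with a fluorescent band sweeping along it.

    The band is Gaussian in the along-axis coordinate and flat across the
    cell; its center moves linearly from ``start_l_rel`` to ``end_l_rel``
    (mid-cell to the quarter position by default, the motion a divisome
    or replisome marker shows between divisions). Returns the per-frame
    meshes, the noise-free image stack and the true band center (relative
    units) per frame.
    """
    h, w = image_shape
    center = (w / 2.0, h / 2.0)
    meshes = [
        Mesh(
            cell_id="band",
            frame_id=f,
            vertices=make_mesh("rod", length, width, center, 0.0, 40),
            source="synthetic",
        )
        for f in range(n_frames)
    ]
    centers_rel = np.linspace(start_l_rel, end_l_rel, n_frames)
    frames = []
    cols = np.arange(w, dtype=float)
    for f in range(n_frames):
        xc = center[0] + centers_rel[f] * length
        row = background + amplitude * np.exp(-((cols - xc) ** 2) / (2 * band_sigma**2))
        frames.append(np.tile(row, (h, 1)))
    stack = ImageStack(frames=frames, channel="ch1", time_interval=20.0)
    return MeshFrame.from_meshes(meshes), stack, centers_rel


# ---------------------------------------------------------------------------
# dialect writers (close the importer round-trip loop)


def _write_generic(outdir: Path, meshes, spots) -> dict:
    paths = {}
    if meshes is not None:
        rows = []
        for m in meshes:
            for x, y in m.vertices:
                rows.append({"cell": m.cell_id, "frame": m.frame_id, "x": x, "y": y})
        p = outdir / "meshes.csv"
        pd.DataFrame(rows, columns=["cell", "frame", "x", "y"]).to_csv(p, index=False)
        paths["mesh"] = p
    if spots is not None:
        df = pd.DataFrame(
            {
                "spot": spots["spot_id"],
                "frame": spots["frame_id"],
                "x": spots["x"],
                "y": spots["y"],
            }
        )
        for opt in ("channel", "intensity", "time"):
            if opt in spots:
                df[opt] = spots[opt]
        p = outdir / "spots.csv"
        df.to_csv(p, index=False)
        paths["spot"] = p
    return paths


def _write_oufti(outdir: Path, meshes, spots) -> dict:
    frames = sorted({m.frame_id for m in meshes}) if meshes else []
    mesh_data = np.empty(len(frames), dtype=object)
    cell_ids = np.empty(len(frames), dtype=object)
    for k, f in enumerate(frames):
        cells = [m for m in meshes if m.frame_id == f]
        arr = np.empty(len(cells), dtype=object)
        ids = np.empty(len(cells), dtype=object)
        for j, m in enumerate(cells):
            v = m.vertices
            if len(v) % 2 != 0:
                raise DialectError(
                    "paired-contour MAT meshes need an even vertex count"
                )
            n = (len(v) + 2) // 2
            left = v[:n]
            right = np.empty_like(left)
            right[0], right[-1] = v[0], v[n - 1]
            for i in range(1, n - 1):
                right[i] = v[2 * n - 2 - i]
            mesh_arr = np.hstack([left, right]) + 1.0  # back to 1-based
            arr[j] = {"mesh": mesh_arr}
            ids[j] = m.cell_id
        mesh_data[k] = arr
        cell_ids[k] = ids
    p = outdir / "cells.mat"
    scipy.io.savemat(p, {"cellList": {"meshData": mesh_data, "cellId": cell_ids}})
    return {"mesh": p}


def _write_isbatch(outdir: Path, meshes, spots) -> dict:
    df = pd.DataFrame(
        {
            "spot": spots["spot_id"],
            "x": spots["x"],
            "y": spots["y"],
            "slice": spots["frame_id"] + 1,
        }
    )
    if "trajectory" in spots:
        df["trajectory"] = spots["trajectory"]
    if "intensity" in spots:
        df["intensity"] = spots["intensity"]
    if "channel" in spots:
        df["channel"] = spots["channel"]
    p = outdir / "isbatch_spots.csv"
    df.to_csv(p, index=False)
    return {"spot": p}


def _write_microbej(outdir: Path, meshes, spots) -> dict:
    paths = {}
    if meshes is not None:
        rows = []
        for m in meshes:
            for x, y in m.vertices:
                rows.append(
                    {"NAME": m.cell_id, "POSITION": m.frame_id, "SHAPE.x": x, "SHAPE.y": y}
                )
        p = outdir / "microbej_contours.csv"
        pd.DataFrame(rows, columns=["NAME", "POSITION", "SHAPE.x", "SHAPE.y"]).to_csv(p, index=False)
        paths["mesh"] = p
    if spots is not None:
        df = pd.DataFrame(
            {
                "NAME": spots["spot_id"],
                "POSITION": spots["frame_id"],
                "LOCATION.x": spots["x"],
                "LOCATION.y": spots["y"],
            }
        )
        if "intensity" in spots:
            df["INTENSITY.ch1"] = spots["intensity"]
        p = outdir / "microbej_maxima.csv"
        df.to_csv(p, index=False)
        paths["spot"] = p
    return paths


def write_fixture(
    outdir,
    dialect: str,
    meshes: list[Mesh] | None = None,
    spots: pd.DataFrame | None = None,
) -> dict:
    """Write a synthetic dataset in one of the supported import dialects.

    Returns a dict mapping kind ('mesh'/'spot') to the written path. The
    files are structurally valid for the matching importer, so
    ``import(write(X))`` equals X on all standard fields.

    Raises
    ------
    DialectError
        For an unsupported dialect name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    writers = {
        "generic-csv": _write_generic,
        "oufti-mat": _write_oufti,
        "isbatch-csv": _write_isbatch,
        "microbej-csv": _write_microbej,
    }
    if dialect not in writers:
        raise DialectError(f"unsupported dialect {dialect!r}; supported: {DIALECTS}")
    return writers[dialect](outdir, meshes, spots)
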