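"""Time-lapse analytics: division detection, cell-cycle alignment, track
filtering and lineage trees.

Cell length is used as a proxy for division: a sudden drop in length between
consecutive frames marks a division, unless the upstream tracker already
supplied genealogy. Once divisions are known, every frame of a complete
cycle (birth and division both observed) gets a percentage-of-division in
[0, 100] by linear interpolation in wall-clock time, which makes cells with
different cycle lengths comparable and lets cohorts be binned by cell-cycle
progress.

Tracks are tidy DataFrames with one row per (track, frame):
``track_id, frame_id, time, length, width, fluor, parent`` (time in seconds,
lengths in pixels, fluorescence in arbitrary units).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import LineageError

__all__ = [
    "detect_divisions",
    "percent_division",
    "annotate_tracks",
    "filter_tracks",
    "FilterResult",
    "bin_by_percent",
    "LineageTree",
    "build_lineage",
]

log = logging.getLogger(__name__)

#: default relative length drop that calls a division: a division halves the
#: length, so requiring a 25% drop tolerates observation noise while staying
#: far above ordinary growth fluctuations.
DEFAULT_DROP_FRACTION = 0.25


def detect_divisions(
    track: pd.DataFrame | np.ndarray,
    drop_fraction: float = DEFAULT_DROP_FRACTION,
    explicit: np.ndarray | None = None,
) -> np.ndarray:
    """Find division events in a single track's length trajectory.

    A division is called between frames t and t+1 when
    ``length[t+1] <= (1 - drop_fraction) * length[t]``. The returned array
    holds the 0-based indices t of the last frame of each mother cycle.
    When ``explicit`` division indices are given (genealogy from the
    segmentation software), they override length-based detection.
    """
    if explicit is not None:
        return np.asarray(sorted(int(i) for i in explicit), dtype=int)
    lengths = track["length"].to_numpy(float) if isinstance(track, pd.DataFrame) else np.asarray(track, float)
    if lengths.size < 2:
        return np.array([], dtype=int)
    drops = lengths[1:] <= (1.0 - drop_fraction) * lengths[:-1]
    return np.flatnonzero(drops)


def percent_division(
    track: pd.DataFrame,
    divisions: np.ndarray,
    first_frame_is_birth: bool = False,
) -> pd.DataFrame:
    """Percentage-of-division for every frame of one track.

    Within each complete cycle the percentage interpolates linearly in
    wall-clock time from 0 at the birth frame to 100 at the division frame
    (the last frame of the mother). A cycle is complete when its birth was
    observed (the frame follows a detected division, or the track starts at
    birth and ``first_frame_is_birth`` is set) and its division was
    observed. Frames outside complete cycles get NaN and ``complete=False``.

    Returns a DataFrame aligned with ``track`` carrying ``percentage``,
    ``cycle`` (0-based cycle counter, -1 outside complete cycles) and
    ``complete``.
    """
    times = track["time"].to_numpy(float)
    n = len(times)
    divisions = np.asarray(divisions, dtype=int)
    pct = np.full(n, np.nan)
    cyc = np.full(n, -1, dtype=int)
    starts = np.concatenate([[0], divisions + 1])
    k = 0
    for s in starts:
        later = divisions[divisions >= s]
        if later.size == 0:
            break  # trailing frames: division never observed
        e = int(later[0])
        birth_observed = s > 0 or first_frame_is_birth
        if not birth_observed or e == s:
            continue
        sl = slice(s, e + 1)
        pct[sl] = 100.0 * (times[sl] - times[s]) / (times[e] - times[s])
        cyc[sl] = k
        k += 1
    return pd.DataFrame({"percentage": pct, "cycle": cyc, "complete": cyc >= 0}, index=track.index)


def annotate_tracks(
    tracks: pd.DataFrame,
    drop_fraction: float = DEFAULT_DROP_FRACTION,
    first_frame_is_birth: bool = False,
) -> pd.DataFrame:
    """Division-annotate every track of a tidy tracks table.

    Adds ``division`` (True on the last frame of a mother cycle),
    ``percentage``, ``cycle`` and ``complete`` columns. If the table carries
    an explicit boolean ``division`` column from the importer (genealogy),
    it overrides length-based detection.
    """
    out = []
    has_explicit = "division" in tracks.columns
    for _, sub in tracks.groupby("track_id", sort=False):
        sub = sub.sort_values("time", kind="mergesort")
        explicit = np.flatnonzero(sub["division"].to_numpy(bool)) if has_explicit else None
        div = detect_divisions(sub, drop_fraction, explicit=explicit)
        ann = percent_division(sub, div, first_frame_is_birth=first_frame_is_birth)
        sub = sub.copy()
        marker = np.zeros(len(sub), dtype=bool)
        marker[div] = True
        sub["division"] = marker
        for c in ("percentage", "cycle", "complete"):
            sub[c] = ann[c].to_numpy()
        out.append(sub)
    return pd.concat(out, ignore_index=True) if out else tracks.copy()


@dataclass
class FilterResult:
    """Outcome of track quality filtering, with per-track discard reasons."""

    kept: pd.DataFrame
    reasons: pd.DataFrame  # track_id, reason ('' for kept tracks)
    counts: dict


def filter_tracks(
    tracks: pd.DataFrame,
    min_growth_ratio: float = 1.2,
    min_fluor: float | None = None,
    require_complete: bool = True,
) -> FilterResult:
    """Discard non-growing, incomplete or dim tracks.

    A track is discarded when its growth ratio (maximum length over the
    cycle divided by length at birth; over the whole track when no complete
    cycle exists) falls below ``min_growth_ratio``, when it has no complete
    cycle (if ``require_complete``), or when its mean fluorescence is below
    ``min_fluor``. The first matching reason is recorded per track.
    """
    rows = []
    kept_parts = []
    for tid, sub in tracks.groupby("track_id", sort=False):
        sub = sub.sort_values("time", kind="mergesort")
        lengths = sub["length"].to_numpy(float)
        complete = sub["complete"].to_numpy(bool) if "complete" in sub else np.zeros(len(sub), bool)
        ratios = []
        if "cycle" in sub:
            for c in np.unique(sub.loc[sub["cycle"] >= 0, "cycle"]):
                seg = lengths[(sub["cycle"] == c).to_numpy()]
                ratios.append(seg.max() / seg[0])
        ratio = max(ratios) if ratios else lengths.max() / lengths[0]
        reason = ""
        if ratio < min_growth_ratio:
            reason = "no growth"
        elif require_complete and not complete.any():
            reason = "incomplete cycle"
        elif min_fluor is not None and "fluor" in sub and np.nanmean(sub["fluor"]) < min_fluor:
            reason = "low fluorescence"
        rows.append({"track_id": tid, "reason": reason, "growth_ratio": ratio})
        if reason == "":
            kept_parts.append(sub)
    reasons = pd.DataFrame(rows, columns=["track_id", "reason", "growth_ratio"])
    counts = reasons[reasons["reason"] != ""]["reason"].value_counts().to_dict()
    counts["kept"] = int((reasons["reason"] == "").sum())
    kept = pd.concat(kept_parts, ignore_index=True) if kept_parts else tracks.iloc[0:0].copy()
    return FilterResult(kept=kept, reasons=reasons, counts=counts)


def bin_by_percent(
    tracks: pd.DataFrame,
    quantity: str = "fluor",
    n_bins: int = 10,
) -> pd.DataFrame:
    """Aggregate a per-frame quantity into percentage-of-division bins.

    Bins are [0,10), [10,20), ..., [90,100] for the default ``n_bins=10``;
    the aggregate pools all complete-cycle frames of all tracks. Empty bins
    are reported with n=0 and NaN aggregates (and logged).
    """
    df = tracks[tracks["percentage"].notna()]
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    idx = np.minimum(np.digitize(df["percentage"].to_numpy(float), edges) - 1, n_bins - 1)
    vals = df[quantity].to_numpy(float)
    rows = []
    for b in range(n_bins):
        v = vals[idx == b]
        if v.size == 0:
            log.warning("percentage bin %d (%g-%g%%) is empty", b + 1, edges[b], edges[b + 1])
        rows.append(
            {
                "bin": b + 1,
                "lo": edges[b],
                "hi": edges[b + 1],
                "n": int(v.size),
                "mean": float(np.mean(v)) if v.size else np.nan,
                "sd": float(np.std(v, ddof=1)) if v.size > 1 else (0.0 if v.size == 1 else np.nan),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class LineageTree:
    """Genealogy forest: nodes are track ids, branch lengths cycle durations."""

    graph: nx.DiGraph

    def roots(self) -> list[str]:
        return sorted(n for n in self.graph if self.graph.in_degree(n) == 0)

    def newick(self) -> str:
        """One Newick string per tree (branch lengths in seconds)."""

        def emit(node: str) -> str:
            children = sorted(self.graph.successors(node))
            dur = self.graph.nodes[node].get("duration", 0.0)
            inner = f"({','.join(emit(c) for c in children)})" if children else ""
            return f"{inner}{node}:{dur:g}"

        return "\n".join(emit(r) + ";" for r in self.roots())


def build_lineage(tracks: pd.DataFrame) -> LineageTree:
    """Build the genealogy forest from parent references.

    ``tracks`` is either a tidy per-frame table (durations derived as last
    minus first observed time per track) or a per-track table with
    ``track_id``, ``parent`` and optional ``duration`` columns. Empty/NaN
    parents mark roots.

    Raises
    ------
    LineageError
        On cyclic parent references or more than two daughters per cell.
    """
    if "time" in tracks.columns:
        per = tracks.groupby("track_id").agg(
            parent=("parent", "first"), t0=("time", "min"), t1=("time", "max")
        )
        per["duration"] = per["t1"] - per["t0"]
        per = per.reset_index()
    else:
        per = tracks.copy()
        if "duration" not in per:
            per["duration"] = 0.0

    g = nx.DiGraph()
    for _, r in per.iterrows():
        tid = str(r["track_id"])
        g.add_node(tid, duration=float(r["duration"]))
    for _, r in per.iterrows():
        parent = r.get("parent")
        if parent is None or (isinstance(parent, float) and np.isnan(parent)) or str(parent) == "":
            continue
        g.add_edge(str(parent), str(r["track_id"]))
    if not nx.is_directed_acyclic_graph(g):
        raise LineageError("cyclic parent references")
    bad = [n for n in g if g.out_degree(n) > 2]
    if bad:
        raise LineageError(f"cells with more than two daughters: {bad}")
    return LineageTree(graph=g)
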