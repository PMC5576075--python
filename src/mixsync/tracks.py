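"""Data model and I/O for 3D single-cell trajectories.

The common currency of the package is :class:`CellTrackSet`: a tidy table of
nuclear (or cell-center) positions, one row per tracked cell per time frame,
with a single uniform frame interval ``dt_frame`` (minutes).  There is no
community standard on-disk format for 3D tracks, so the canonical dialect is
a CSV with header ``track_id,frame,t_min,x_um,y_um,z_um``; a column-mapping
dialect accommodates other exports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "CellTrackSet",
    "RegionBox",
    "TrackFormatError",
    "TrackIntegrityError",
    "read_tracks",
    "write_tracks",
    "clip_to_box",
    "link_detections",
    "CANONICAL_COLUMNS",
]

CANONICAL_COLUMNS = ["track_id", "frame", "t_min", "x_um", "y_um", "z_um"]


class TrackFormatError(ValueError):
    """The file does not expose the required columns."""


class TrackIntegrityError(ValueError):
    """The table violates a track-set invariant (e.g. duplicate rows)."""


@dataclass(frozen=True)
class RegionBox:
    """Axis-aligned region of interest, micrometers."""

    origin: np.ndarray
    extent: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "extent", np.asarray(self.extent, dtype=float))
        if self.origin.shape != (3,) or self.extent.shape != (3,):
            raise ValueError("origin and extent must be 3-vectors")
        if not np.all(self.extent > 0):
            raise ValueError("box extent must be strictly positive componentwise")

    @property
    def volume(self) -> float:
        return float(np.prod(self.extent))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the closed box."""
        p = np.atleast_2d(points)
        lo = self.origin
        hi = self.origin + self.extent
        return np.all((p >= lo) & (p <= hi), axis=1)


@dataclass
class CellTrackSet:
    """Validated set of 3D trajectories with uniform frame spacing.

    Parameters
    ----------
    data
        Tidy table with the canonical columns.  ``t_min`` must equal
        ``frame * dt_frame`` (up to float tolerance); it is recomputed if
        absent.
    dt_frame
        Frame interval in minutes.  Always user-supplied: the package never
        guesses the acquisition cadence.
    """

    data: pd.DataFrame
    dt_frame: float = field(default=1.0)

    def __post_init__(self) -> None:
        df = self.data.copy()
        if "t_min" not in df.columns:
            df["t_min"] = df["frame"] * self.dt_frame
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise TrackFormatError(f"missing columns: {missing}")
        df = df[CANONICAL_COLUMNS].astype(
            {"track_id": np.int64, "frame": np.int64, "t_min": float,
             "x_um": float, "y_um": float, "z_um": float}
        )
        if self.dt_frame <= 0:
            raise ValueError("dt_frame must be positive")
        if (df["frame"] < 0).any():
            raise TrackIntegrityError("negative frame index")
        if df.duplicated(subset=["track_id", "frame"]).any():
            dup = df[df.duplicated(subset=["track_id", "frame"], keep=False)]
            raise TrackIntegrityError(
                f"duplicate (track_id, frame) rows, e.g. {dup.iloc[0][['track_id', 'frame']].tolist()}"
            )
        pos = df[["x_um", "y_um", "z_um"]].to_numpy()
        if not np.all(np.isfinite(pos)):
            raise TrackIntegrityError("non-finite positions")
        if not np.allclose(df["t_min"], df["frame"] * self.dt_frame, atol=1e-6):
            raise TrackIntegrityError("t_min inconsistent with frame * dt_frame")
        df = df.sort_values(["track_id", "frame"], kind="mergesort").reset_index(drop=True)
        self.data = df

    # -- basic introspection -------------------------------------------------

    @property
    def track_ids(self) -> np.ndarray:
        return self.data["track_id"].unique()

    @property
    def n_tracks(self) -> int:
        return len(self.track_ids)

    @property
    def n_frames(self) -> int:
        return int(self.data["frame"].nunique())

    @property
    def frames(self) -> np.ndarray:
        return np.sort(self.data["frame"].unique())

    def gaps(self) -> dict[int, list[tuple[int, int]]]:
        """Missing-frame runs per track: {track_id: [(after, before), ...]}.

        Gaps are recorded, never interpolated; displacement computations
        across a gap are discarded downstream.
        """
        out: dict[int, list[tuple[int, int]]] = {}
        for tid, grp in self.data.groupby("track_id"):
            f = grp["frame"].to_numpy()
            jumps = np.where(np.diff(f) > 1)[0]
            if jumps.size:
                out[int(tid)] = [(int(f[j]), int(f[j + 1])) for j in jumps]
        return out

    def positions_at(self, frame: int) -> tuple[np.ndarray, np.ndarray]:
        """(track_ids, positions (n,3)) present at a frame."""
        sel = self.data[self.data["frame"] == frame]
        return sel["track_id"].to_numpy(), sel[["x_um", "y_um", "z_um"]].to_numpy()

    def positions(self) -> np.ndarray:
        return self.data[["x_um", "y_um", "z_um"]].to_numpy()

    def translated(self, drift: np.ndarray) -> "CellTrackSet":
        """Copy with a per-frame global translation added.

        ``drift`` maps frame index -> 3-vector; shape (n_frames_max+1, 3)
        or a callable ``drift(frame_array) -> (n, 3)``.  Used to express the
        frame-independence property of the mixing statistics.
        """
        df = self.data.copy()
        if callable(drift):
            d = np.asarray(drift(df["frame"].to_numpy()), dtype=float)
        else:
            d = np.asarray(drift, dtype=float)[df["frame"].to_numpy()]
        df[["x_um", "y_um", "z_um"]] = df[["x_um", "y_um", "z_um"]].to_numpy() + d
        return CellTrackSet(df, dt_frame=self.dt_frame)

    def summary(self) -> dict:
        return {
            "n_tracks": self.n_tracks,
            "n_frames": self.n_frames,
            "n_rows": len(self.data),
            "n_gapped_tracks": len(self.gaps()),
        }


# -- I/O ----------------------------------------------------------------------

def read_tracks(path, dt_frame: float = 1.0, dialect: dict[str, str] | None = None,
                sep: str = ",") -> CellTrackSet:
    """Read a trajectory table from CSV/TSV.

    ``dialect`` maps canonical column names to the file's column names, e.g.
    ``{"track_id": "TrackID", "x_um": "Position X"}``; unmapped canonical
    names are looked up verbatim.  ``t_min`` may be absent and is then
    derived from ``frame * dt_frame``.
    """
    raw = pd.read_csv(path, sep=sep)
    dialect = dialect or {}
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = dialect.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
        elif canon != "t_min":
            raise TrackFormatError(f"column {src!r} (for {canon}) not found in {path}")
    df = raw.rename(columns=rename)
    return CellTrackSet(df, dt_frame=dt_frame)


def write_tracks(ts: CellTrackSet, path, sep: str = ",") -> None:
    """Write the canonical CSV dialect (lossless round trip at float repr)."""
    ts.data.to_csv(path, sep=sep, index=False)


# -- region selection ---------------------------------------------------------

def clip_to_box(ts: CellTrackSet, box: RegionBox, mode: str = "whole-track") -> CellTrackSet:
    """Restrict a track set to a region of interest.

    mode="whole-track": keep every track with at least one frame inside the
    box, retaining *all* its frames (the convention used when pooling cells
    within a measurement box over the whole imaging period).
    mode="per-frame": keep only rows whose position is inside the box.
    """
    inside = box.contains(ts.positions())
    if mode == "whole-track":
        keep_ids = ts.data.loc[inside, "track_id"].unique()
        df = ts.data[ts.data["track_id"].isin(keep_ids)]
    elif mode == "per-frame":
        df = ts.data[inside]
    else:
        raise ValueError(f"unknown clip mode {mode!r}")
    if df.empty:
        warnings.warn("clip_to_box produced an empty track set", stacklevel=2)
    return CellTrackSet(df.reset_index(drop=True), dt_frame=ts.dt_frame)


# -- frame-to-frame linking ---------------------------------------------------

def link_detections(detections: list[np.ndarray], max_link_distance: float,
                    dt_frame: float = 1.0) -> CellTrackSet:
    """Greedy mutual-nearest-neighbor linking of per-frame point sets.

    Each detection in frame t is linked to its nearest neighbor in frame
    t+1 iff the relation is mutual and the distance does not exceed
    ``max_link_distance``.  Unlinked detections start new tracks.

    This is a convenience linker, not a validated tracker: a pair of points
    crossing paths closer than their frame-to-frame displacement will swap
    identities (nearest-neighbor ambiguity).
    """
    if len(detections) < 2:
        raise ValueError("need at least two frames of detections")
    rows: list[tuple[int, int, float, float, float]] = []
    next_id = 0
    prev_pts = np.atleast_2d(np.asarray(detections[0], dtype=float))
    prev_ids = list(range(next_id, next_id + len(prev_pts)))
    next_id += len(prev_pts)
    for i, p in zip(prev_ids, prev_pts):
        rows.append((i, 0, *p))
    for f in range(1, len(detections)):
        cur_pts = np.atleast_2d(np.asarray(detections[f], dtype=float))
        cur_ids = [-1] * len(cur_pts)
        if len(prev_pts) and len(cur_pts):
            fwd_d, fwd = cKDTree(cur_pts).query(prev_pts)  # prev -> nearest cur
            _, bwd = cKDTree(prev_pts).query(cur_pts)      # cur -> nearest prev
            for ip, (ic, d) in enumerate(zip(fwd, fwd_d)):
                if bwd[ic] == ip and d <= max_link_distance:
                    cur_ids[ic] = prev_ids[ip]
        for ic in range(len(cur_pts)):
            if cur_ids[ic] == -1:
                cur_ids[ic] = next_id
                next_id += 1
            rows.append((cur_ids[ic], f, *cur_pts[ic]))
        prev_pts, prev_ids = cur_pts, cur_ids
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um", "z_um"])
    return CellTrackSet(df, dt_frame=dt_frame)
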