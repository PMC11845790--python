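"""Reading, writing and spatial subsetting of 3D cell-track tables.

The universal input of the package is a delimited-text table with one row per
cell per frame — the shape of an Imaris/TrackMate spot export. Columns (header
required): ``track_id, frame, t_min, x_um, y_um, z_um[, tissue]``. Units are
fixed at micrometres and minutes at this boundary; anything in other units is
converted on the way in via ``column_map`` scale factors.

Coordinate convention: x = medial-lateral, y = anterior-posterior,
z = dorsal-ventral, unless a different ``axes_convention`` is recorded on the
:class:`TrackSet`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tailflow")

#: canonical column order of the track-table format
TRACK_COLUMNS = ["track_id", "frame", "t_min", "x_um", "y_um", "z_um", "tissue"]

DEFAULT_AXES = {"x": "medial-lateral", "y": "anterior-posterior", "z": "dorsal-ventral"}


class TrackFormatError(ValueError):
    """A track table is malformed (missing columns, unreadable values)."""


class TrackIntegrityError(ValueError):
    """A track table violates integrity (duplicate (track, frame) keys)."""


@dataclass(frozen=True)
class LoadReport:
    """Row accounting for one :func:`read_tracks` call."""

    n_rows_input: int
    n_rows_kept: int
    n_rows_dropped_nonfinite: int

    def __post_init__(self) -> None:
        assert self.n_rows_kept + self.n_rows_dropped_nonfinite == self.n_rows_input


@dataclass(frozen=True)
class Track:
    """One cell trajectory: frames, times [min] and positions [µm].

    Frames are strictly increasing; gaps (missing frames) are allowed and
    simply absent from ``frames``.
    """

    track_id: int
    frames: np.ndarray  # (n,) int
    t: np.ndarray  # (n,) float, minutes
    pos: np.ndarray  # (n, 3) float, µm
    tissue_label: str | None = None

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def has_gaps(self) -> bool:
        return bool(np.any(np.diff(self.frames) > 1))


@dataclass(frozen=True)
class CuboidROI:
    """Axis-aligned cuboid with half-open inclusion [min_corner, max_corner).

    ``membership_time`` decides which sample of a track is tested by
    :func:`crop_roi`: ``"start"`` (the default, mirroring slice construction
    from the track start position) or an explicit frame index.
    """

    min_corner: tuple[float, float, float]
    max_corner: tuple[float, float, float]
    membership_time: str | int = "start"

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.min_corner, float), np.asarray(self.max_corner, float)
        if not np.all(lo < hi):
            raise ValueError(f"ROI min_corner must be < max_corner componentwise, got {lo} vs {hi}")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Half-open membership test for an (n, 3) array of points."""
        p = np.atleast_2d(np.asarray(points, float))
        lo = np.asarray(self.min_corner, float)
        hi = np.asarray(self.max_corner, float)
        return np.all((p >= lo) & (p < hi), axis=1)

    @property
    def volume(self) -> float:
        lo = np.asarray(self.min_corner, float)
        hi = np.asarray(self.max_corner, float)
        return float(np.prod(hi - lo))


@dataclass(frozen=True)
class TrackSet:
    """A collection of tracks sharing one frame interval [min].

    Internally a tidy DataFrame in canonical column order; :meth:`tracks`
    iterates typed :class:`Track` views, and :meth:`frame_positions` gives the
    per-frame point cloud used by neighbor queries.
    """

    data: pd.DataFrame
    frame_interval: float
    embryo_id: str = ""
    axes_convention: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_AXES))

    def __post_init__(self) -> None:
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    @property
    def track_ids(self) -> np.ndarray:
        return self.data["track_id"].unique()

    def __len__(self) -> int:
        return len(self.data)

    def tracks(self) -> Iterator[Track]:
        for tid, g in self.data.groupby("track_id", sort=True):
            tissue = g["tissue"].iloc[0] if "tissue" in g and pd.notna(g["tissue"].iloc[0]) else None
            yield Track(
                track_id=tid,
                frames=g["frame"].to_numpy(int),
                t=g["t_min"].to_numpy(float),
                pos=g[["x_um", "y_um", "z_um"]].to_numpy(float),
                tissue_label=tissue,
            )

    def get_track(self, track_id: int) -> Track:
        g = self.data[self.data["track_id"] == track_id]
        if g.empty:
            raise KeyError(f"no track with id {track_id}")
        tissue = g["tissue"].iloc[0] if pd.notna(g["tissue"].iloc[0]) else None
        return Track(track_id, g["frame"].to_numpy(int), g["t_min"].to_numpy(float),
                     g[["x_um", "y_um", "z_um"]].to_numpy(float), tissue)

    def frame_positions(self, frame: int) -> tuple[np.ndarray, np.ndarray]:
        """(track_ids, (n,3) positions) of all cells sampled at ``frame``."""
        g = self.data[self.data["frame"] == frame]
        return g["track_id"].to_numpy(), g[["x_um", "y_um", "z_um"]].to_numpy(float)

    @property
    def frames(self) -> np.ndarray:
        return np.sort(self.data["frame"].unique())

    def select_tissue(self, label: str) -> "TrackSet":
        keep = self.data[self.data["tissue"] == label]
        return replace(self, data=keep.reset_index(drop=True))

    def with_positions(self, pos: np.ndarray) -> "TrackSet":
        """Copy with all coordinates replaced (row order preserved)."""
        d = self.data.copy()
        d[["x_um", "y_um", "z_um"]] = np.asarray(pos, float)
        return replace(self, data=d)


def tracks_from_arrays(
    track_ids: Sequence[int],
    frames: Sequence[int],
    positions: np.ndarray,
    frame_interval: float,
    tissue: Sequence[str] | None = None,
    embryo_id: str = "",
) -> TrackSet:
    """Assemble a TrackSet from flat per-row arrays (the generator path)."""
    df = pd.DataFrame(
        {
            "track_id": np.asarray(track_ids),
            "frame": np.asarray(frames, int),
            "t_min": np.asarray(frames, float) * frame_interval,
            "x_um": np.asarray(positions, float)[:, 0],
            "y_um": np.asarray(positions, float)[:, 1],
            "z_um": np.asarray(positions, float)[:, 2],
            "tissue": tissue if tissue is not None else pd.NA,
        }
    )
    df = df.sort_values(["track_id", "frame"]).reset_index(drop=True)
    _check_integrity(df)
    return TrackSet(df, frame_interval=frame_interval, embryo_id=embryo_id)


def _check_integrity(df: pd.DataFrame) -> None:
    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        offenders = df.loc[dup, ["track_id", "frame"]].drop_duplicates()
        pairs = ", ".join(f"(track {r.track_id}, frame {r.frame})" for r in offenders.itertuples())
        raise TrackIntegrityError(f"duplicate (track, frame) rows: {pairs}")


def read_tracks(
    path,
    column_map: Mapping[str, str] | None = None,
    frame_interval: float | None = None,
    scale_xyz: float = 1.0,
    scale_t: float = 1.0,
    embryo_id: str = "",
    sep: str | None = None,
) -> tuple[TrackSet, LoadReport]:
    """Read a delimited track table into a validated :class:`TrackSet`.

    Parameters
    ----------
    column_map
        Maps canonical names (``track_id``, ``frame`` or ``t_min``, ``x_um``,
        ``y_um``, ``z_um``, optionally ``tissue``) to the file's column names.
        Defaults to the identity mapping on the canonical names.
    frame_interval
        Frame interval in minutes. If omitted it is inferred from the ``t_min``
        column (smallest positive within-track time step).
    scale_xyz, scale_t
        Multiplicative unit conversions applied to coordinates and times
        (e.g. ``scale_xyz=1e-3`` for nanometre input).

    Returns the TrackSet and a :class:`LoadReport`; rows with non-finite
    coordinates are dropped and counted.
    """
    cmap = dict(column_map or {})
    raw = pd.read_csv(path, sep=sep, engine="python")
    raw.columns = [c.strip() for c in raw.columns]

    def col(name: str) -> str:
        return cmap.get(name, name)

    required = ["track_id", "x_um", "y_um", "z_um"]
    missing = [n for n in required if col(n) not in raw.columns]
    has_frame = col("frame") in raw.columns
    has_time = col("t_min") in raw.columns
    if not (has_frame or has_time):
        missing.append("frame|t_min")
    if missing:
        raise TrackFormatError(
            f"missing required column(s) {missing}; file has {list(raw.columns)}"
        )

    df = pd.DataFrame({"track_id": raw[col("track_id")]})
    for axis in ("x_um", "y_um", "z_um"):
        df[axis] = pd.to_numeric(raw[col(axis)], errors="coerce") * scale_xyz
    if has_time:
        df["t_min"] = pd.to_numeric(raw[col("t_min")], errors="coerce") * scale_t
    if has_frame:
        df["frame"] = raw[col("frame")].astype(int)

    if frame_interval is None:
        if not has_time:
            raise TrackFormatError("frame_interval must be given when the file has no time column")
        steps = df.groupby("track_id")["t_min"].diff().dropna()
        steps = steps[steps > 0]
        if steps.empty:
            raise TrackFormatError("cannot infer frame_interval: no positive time steps")
        frame_interval = float(steps.min())
    if not has_frame:
        df["frame"] = np.rint(df["t_min"] / frame_interval).astype(int)
    if not has_time:
        df["t_min"] = df["frame"] * frame_interval

    df["tissue"] = raw[col("tissue")] if col("tissue") in raw.columns else pd.NA

    n_in = len(df)
    finite = np.isfinite(df[["x_um", "y_um", "z_um", "t_min"]].to_numpy(float)).all(axis=1)
    n_drop = int((~finite).sum())
    if n_drop:
        logger.warning("read_tracks: dropped %d row(s) with non-finite coordinates", n_drop)
    df = df[finite]

    df = df[TRACK_COLUMNS].sort_values(["track_id", "frame"]).reset_index(drop=True)
    _check_integrity(df)

    # time/frame consistency within half a frame interval
    t_err = np.abs(df["t_min"] - df["frame"] * frame_interval)
    if (t_err > 0.5 * frame_interval + 1e-9).any():
        logger.warning("read_tracks: %d sample(s) with t deviating from frame*interval",
                       int((t_err > 0.5 * frame_interval + 1e-9).sum()))

    report = LoadReport(n_in, len(df), n_drop)
    logger.info("read_tracks: %d rows in, %d kept, %d dropped (%d tracks)",
                n_in, len(df), n_drop, df["track_id"].nunique())
    return TrackSet(df, frame_interval=frame_interval, embryo_id=embryo_id), report


def write_tracks(ts: TrackSet, path) -> None:
    """Write a TrackSet in canonical column order at full float precision."""
    out = ts.data[TRACK_COLUMNS].copy()
    out.to_csv(path, index=False, float_format="%.17g")


def crop_roi(ts: TrackSet, roi: CuboidROI) -> TrackSet:
    """Keep whole tracks whose reference position lies inside ``roi``.

    The reference position is the first sample (``membership_time="start"``,
    the track-start-position rule used to cut tissue slices) or the sample at
    an explicit frame index; tracks not sampled at that frame are excluded.
    Samples of retained tracks are never truncated — a track that later exits
    the ROI is kept whole. Half-open inclusion; idempotent.
    """
    if roi.membership_time == "start":
        ref = ts.data.groupby("track_id", sort=True).head(1)
    else:
        f = int(roi.membership_time)
        ref = ts.data[ts.data["frame"] == f]
    inside = roi.contains(ref[["x_um", "y_um", "z_um"]].to_numpy(float))
    keep_ids = set(ref.loc[inside, "track_id"])
    out = ts.data[ts.data["track_id"].isin(keep_ids)].reset_index(drop=True)
    if out.empty:
        logger.warning("crop_roi: no tracks retained by ROI %s-%s", roi.min_corner, roi.max_corner)
    return replace(ts, data=out)
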