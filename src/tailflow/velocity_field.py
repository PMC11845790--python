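"""Coarse-grained morphogenetic velocity fields from cell tracks.

The pipeline: (1) per-track smoothing B-spline over time per coordinate, to
remove high-frequency nuclear jiggle; (2) central-difference velocities on the
spline-discretized positions at the native frame grid; (3) centered temporal
boxcar average (default 12 min); (4) spatial average over all cells within a
sphere (default radius 35 µm, focal cell included, unweighted); (5) projection
onto a 2D plane.

Defaults: cubic splines, smoothing set by the classical residual-targeting
condition s = n·σ² with σ the expected localization noise (default 0.5 µm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate
from scipy.spatial import cKDTree

from .trajectory_io import Track, TrackSet

logger = logging.getLogger("tailflow")

__all__ = [
    "SmoothedTrack", "VelocityField", "smooth_track", "smooth_tracks",
    "field_velocities", "temporal_average", "spatial_average", "project_2d",
    "velocity_field_pipeline", "find_stagnation_point",
]

_PLANE_AXES = {"xy": (0, 1), "yz": (1, 2), "xz": (0, 2)}


@dataclass(frozen=True)
class SmoothedTrack:
    """Per-axis smoothing splines of one trajectory over time."""

    track_id: int
    tck: tuple            # per-axis (t, c, k) triples, one per coordinate
    t_min: float
    t_max: float
    frames: np.ndarray
    residual_rms: float   # µm, RMS distance of samples to the curve

    def __call__(self, t) -> np.ndarray:
        """Evaluate the smoothed position at times t (minutes) -> (n, 3)."""
        t = np.atleast_1d(np.asarray(t, float))
        return np.stack([interpolate.splev(t, tck) for tck in self.tck], axis=-1)


@dataclass(frozen=True)
class VelocityField:
    """Per-cell velocities through the averaging cascade, as a tidy table.

    Columns: track_id, frame, t_min, x/y/z (smoothed positions, µm),
    v_raw_*, v_tavg_*, v_savg_* (µm/min) and, after projection, vx2d/vy2d.
    """

    data: pd.DataFrame
    frame_interval: float
    window: float
    radius: float
    plane: str | None = None

    @property
    def points(self) -> np.ndarray:
        return self.data[["x", "y", "z"]].to_numpy()


def smooth_track(track: Track, degree: int = 3, noise_sd: float = 0.5,
                 smoothing: float | None = None) -> SmoothedTrack:
    """Least-squares smoothing B-spline per coordinate over time.

    ``smoothing`` is the splrep residual budget s (µm²); if None it defaults
    to n·noise_sd², the classical choice that absorbs i.i.d. localization
    noise of the given SD while following the real motion. ``smoothing=0``
    interpolates every sample.
    """
    n = len(track)
    if n < degree + 1:
        raise ValueError(
            f"track {track.track_id}: {n} samples < degree+1={degree + 1} needed for smoothing")
    s = n * noise_sd**2 if smoothing is None else float(smoothing)
    tcks = []
    for ax in range(3):
        tcks.append(interpolate.splrep(track.t, track.pos[:, ax], k=degree, s=s))
    st = SmoothedTrack(track.track_id, tuple(tcks), float(track.t[0]),
                       float(track.t[-1]), track.frames.copy(), 0.0)
    resid = st(track.t) - track.pos
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return SmoothedTrack(st.track_id, st.tck, st.t_min, st.t_max, st.frames, rms)


def smooth_tracks(ts: TrackSet, degree: int = 3, noise_sd: float = 0.5,
                  smoothing: float | None = None) -> list[SmoothedTrack]:
    """Smooth every track with enough samples; short tracks are skipped with a note."""
    out, skipped = [], 0
    for tr in ts.tracks():
        if len(tr) < degree + 1:
            skipped += 1
            continue
        out.append(smooth_track(tr, degree, noise_sd, smoothing))
    if skipped:
        logger.info("smooth_tracks: skipped %d track(s) shorter than degree+1", skipped)
    return out


def field_velocities(smoothed: Sequence[SmoothedTrack], frame_interval: float) -> pd.DataFrame:
    """Central-difference velocities on spline-discretized positions.

    Positions are the spline evaluated on the native frame grid across each
    track's time span (the spline bridges interior gaps); endpoints use
    one-sided differences.
    """
    recs = []
    for st in smoothed:
        f0 = int(round(st.t_min / frame_interval))
        f1 = int(round(st.t_max / frame_interval))
        frames = np.arange(f0, f1 + 1)
        t = frames * frame_interval
        pos = st(t)
        v = np.full_like(pos, np.nan)
        if len(t) >= 2:
            v[1:-1] = (pos[2:] - pos[:-2]) / (2 * frame_interval)
            v[0] = (pos[1] - pos[0]) / frame_interval
            v[-1] = (pos[-1] - pos[-2]) / frame_interval
        recs.append(pd.DataFrame({
            "track_id": st.track_id, "frame": frames, "t_min": t,
            "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
            "v_raw_x": v[:, 0], "v_raw_y": v[:, 1], "v_raw_z": v[:, 2],
        }))
    if not recs:
        return pd.DataFrame(columns=["track_id", "frame", "t_min", "x", "y", "z",
                                     "v_raw_x", "v_raw_y", "v_raw_z"])
    return pd.concat(recs, ignore_index=True)


def temporal_average(df: pd.DataFrame, window: float = 12.0,
                     frame_interval: float = 2.0) -> pd.DataFrame:
    """Centered boxcar mean of v_raw over ±window/2 per cell.

    Near track ends the window shrinks to the symmetric span that fits.
    Adds v_tavg_{x,y,z} columns.
    """
    if window < frame_interval:
        raise ValueError("window must be at least one frame interval")
    half = int(np.floor(window / 2 / frame_interval + 1e-9))
    out = df.copy()
    for ax in "xyz":
        out[f"v_tavg_{ax}"] = np.nan
    cols = [f"v_raw_{ax}" for ax in "xyz"]
    tcols = [f"v_tavg_{ax}" for ax in "xyz"]
    for _, g in out.groupby("track_id", sort=False):
        v = g[cols].to_numpy()
        n = len(g)
        avg = np.empty_like(v)
        for i in range(n):
            h = min(half, i, n - 1 - i)  # symmetric shrink at ends
            avg[i] = np.nanmean(v[i - h: i + h + 1], axis=0)
        out.loc[g.index, tcols] = avg
    return out


def spatial_average(df: pd.DataFrame, radius: float = 35.0) -> pd.DataFrame:
    """Sphere average of v_tavg over neighbors at each time.

    Per cell and frame: unweighted mean of v_tavg over all cells (self
    included) within ``radius`` µm. An isolated cell averages with itself.
    Adds v_savg_{x,y,z} columns.
    """
    out = df.copy()
    tcols = [f"v_tavg_{ax}" for ax in "xyz"]
    scols = [f"v_savg_{ax}" for ax in "xyz"]
    for c in scols:
        out[c] = np.nan
    for _, g in out.groupby("frame", sort=False):
        X = g[["x", "y", "z"]].to_numpy()
        V = g[tcols].to_numpy()
        tree = cKDTree(X)
        neigh = tree.query_ball_point(X, r=radius)
        avg = np.empty_like(V)
        for i, nb in enumerate(neigh):
            avg[i] = np.nanmean(V[nb], axis=0)
        out.loc[g.index, scols] = avg
    return out


def project_2d(df: pd.DataFrame, plane: Literal["xy", "yz", "xz"] = "xy",
               source: str = "v_savg") -> pd.DataFrame:
    """Drop the out-of-plane component of positions and velocities.

    Adds px2d/py2d (in-plane position) and vx2d/vy2d from the chosen velocity
    stage (default the fully averaged one).
    """
    if plane not in _PLANE_AXES:
        raise ValueError(f"plane must be one of {sorted(_PLANE_AXES)}")
    a, b = _PLANE_AXES[plane]
    axes = "xyz"
    out = df.copy()
    out["px2d"] = df[axes[a]]
    out["py2d"] = df[axes[b]]
    out["vx2d"] = df[f"{source}_{axes[a]}"]
    out["vy2d"] = df[f"{source}_{axes[b]}"]
    return out


def velocity_field_pipeline(
    ts: TrackSet,
    degree: int = 3,
    noise_sd: float = 0.5,
    smoothing: float | None = None,
    window: float = 12.0,
    radius: float = 35.0,
    plane: str = "xy",
) -> VelocityField:
    """Full cascade: smooth → differentiate → 12-min → 35-µm → project."""
    st = smooth_tracks(ts, degree, noise_sd, smoothing)
    df = field_velocities(st, ts.frame_interval)
    df = temporal_average(df, window, ts.frame_interval)
    df = spatial_average(df, radius)
    df = project_2d(df, plane)
    return VelocityField(df, ts.frame_interval, window, radius, plane)


def find_stagnation_point(vf: VelocityField, frame: int | None = None,
                          grid_step: float = 2.0) -> tuple[float, float]:
    """Locate the in-plane speed minimum of the averaged field.

    Convenience utility: linear interpolation of (vx2d, vy2d) onto a regular
    grid over the convex hull of cell positions, then the argmin of |v|.
    Uses all frames pooled unless ``frame`` is given.
    """
    d = vf.data if frame is None else vf.data[vf.data["frame"] == frame]
    d = d.dropna(subset=["vx2d", "vy2d"])
    pts = d[["px2d", "py2d"]].to_numpy()
    v = d[["vx2d", "vy2d"]].to_numpy()
    gx = np.arange(pts[:, 0].min(), pts[:, 0].max() + grid_step, grid_step)
    gy = np.arange(pts[:, 1].min(), pts[:, 1].max() + grid_step, grid_step)
    GX, GY = np.meshgrid(gx, gy)
    VX = interpolate.griddata(pts, v[:, 0], (GX, GY), method="linear")
    VY = interpolate.griddata(pts, v[:, 1], (GX, GY), method="linear")
    speed = np.hypot(VX, VY)
    speed[~np.isfinite(speed)] = np.inf
    iy, ix = np.unravel_index(np.argmin(speed), speed.shape)
    return float(GX[iy, ix]), float(GY[iy, ix])
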