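"""Trajectory-mechanics measures over a TrackSet or ROI.

Five ensemble statistics quantify how cells move relative to their
neighborhood:

* mean squared relative displacement (MSRD) of initially neighboring pairs,
  normalized per pair by the initial squared separation, so a value of 1 marks
  a rearrangement on the scale of the pair's own spacing;
* velocity temporal autocorrelation;
* velocity spatial correlation (absolute and relative, i.e. after removing
  the scope-mean flow at each time);
* averaged normalized speed.

Velocities are central differences on raw positions; smoothing belongs to
:mod:`tailflow.velocity_field`. Undefined statistics are reported as NaN and
never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajectory_io import TrackSet

logger = logging.getLogger("tailflow")

__all__ = [
    "PairEnsemble", "MsrdCurve", "CorrelationCurve", "SpeedSeries",
    "track_velocities", "build_pairs", "msrd_curve",
    "velocity_temporal_autocorrelation", "velocity_spatial_correlation",
    "average_normalized_speed", "position_tensor", "velocity_tensor",
]


# ---------------------------------------------------------------- containers

@dataclass(frozen=True)
class PairEnsemble:
    """Cell pairs with reference frame and initial separation.

    ``pairs`` has columns ``i, j`` (integer row indices into ``track_ids``),
    ``t0`` (reference frame) and ``d0`` (initial separation, µm). Directed
    ensembles keep (i, j) per focal cell i (the fluidity-index construction);
    undirected ensembles are deduplicated with i < j.
    """

    pairs: pd.DataFrame
    track_ids: np.ndarray
    selection_rule: str
    directed: bool

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class MsrdCurve:
    lags: np.ndarray          # minutes
    msrd: np.ndarray          # dimensionless (or µm² if normalization="none")
    se: np.ndarray
    n_pairs: np.ndarray
    normalization: str = "per_pair"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_min": self.lags, "msrd": self.msrd,
                             "se": self.se, "n": self.n_pairs})


@dataclass(frozen=True)
class CorrelationCurve:
    abscissa: np.ndarray      # lag [min] or distance bin center [µm]
    value: np.ndarray
    se: np.ndarray
    n: np.ndarray
    mode: Literal["temporal", "spatial_absolute", "spatial_relative"] = "temporal"

    def to_frame(self) -> pd.DataFrame:
        name = "lag_min" if self.mode == "temporal" else "r_um"
        return pd.DataFrame({name: self.abscissa, "value": self.value,
                             "se": self.se, "n": self.n})


@dataclass(frozen=True)
class SpeedSeries:
    t: np.ndarray             # minutes
    mean_norm_speed: np.ndarray
    se: np.ndarray
    n_tracks: np.ndarray
    normalizer: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_min": self.t, "mean_norm_speed": self.mean_norm_speed,
                             "se": self.se, "n": self.n_tracks})


# --------------------------------------------------------------- dense views

def position_tensor(ts: TrackSet) -> tuple[np.ndarray, np.ndarray, int]:
    """Dense (n_tracks, n_frames, 3) position array, NaN where unsampled.

    Returns (track_ids, P, frame0) with frame axis covering
    [frame0, frame0 + n_frames).
    """
    ids = np.sort(ts.data["track_id"].unique())
    id_index = {tid: k for k, tid in enumerate(ids)}
    frames = ts.data["frame"].to_numpy(int)
    f0 = int(frames.min()) if len(frames) else 0
    n_f = int(frames.max()) - f0 + 1 if len(frames) else 0
    P = np.full((len(ids), n_f, 3), np.nan)
    rows = ts.data["track_id"].map(id_index).to_numpy()
    P[rows, frames - f0] = ts.data[["x_um", "y_um", "z_um"]].to_numpy(float)
    return ids, P, f0


def velocity_tensor(ts: TrackSet, scheme: str = "central") -> tuple[np.ndarray, np.ndarray, int]:
    """Dense (n_tracks, n_frames, 3) velocity array [µm/min], NaN where undefined."""
    ids, P, f0 = position_tensor(ts)
    dt = ts.frame_interval
    V = np.full_like(P, np.nan)
    has = np.isfinite(P[..., 0])
    if scheme == "forward":
        ok = has[:, :-1] & has[:, 1:]
        V[:, :-1][ok] = (P[:, 1:][ok] - P[:, :-1][ok]) / dt
        return ids, V, f0
    if scheme != "central":
        raise ValueError(f"unknown scheme {scheme!r}")
    # central where the sample itself and both neighbors are sampled
    mid = has[:, 1:-1] & has[:, :-2] & has[:, 2:]
    V[:, 1:-1][mid] = (P[:, 2:][mid] - P[:, :-2][mid]) / (2 * dt)
    # one-sided differences at track endpoints only (not at interior gaps)
    nf = P.shape[1]
    for r in range(len(ids)):
        idx = np.flatnonzero(has[r])
        if len(idx) < 2:
            continue
        first, last = idx[0], idx[-1]
        if first + 1 < nf and has[r, first + 1]:
            V[r, first] = (P[r, first + 1] - P[r, first]) / dt
        if has[r, last - 1]:
            V[r, last] = (P[r, last] - P[r, last - 1]) / dt
    return ids, V, f0


def track_velocities(ts: TrackSet, scheme: str = "central") -> pd.DataFrame:
    """Per-sample 3-velocities [µm/min] as a tidy table.

    Central differences, v(t) = [x(t+Δ) − x(t−Δ)]/(2Δ), where both neighboring
    frames are sampled; track endpoints fall back to one-sided differences;
    samples flanking gaps get no velocity. Tracks too short for the scheme
    simply contribute nothing.
    """
    ids, V, f0 = velocity_tensor(ts, scheme)
    r, f = np.nonzero(np.isfinite(V[..., 0]))
    return pd.DataFrame({
        "track_id": ids[r],
        "frame": f + f0,
        "t_min": (f + f0) * ts.frame_interval,
        "vx": V[r, f, 0], "vy": V[r, f, 1], "vz": V[r, f, 2],
    })


# ------------------------------------------------------------ pair selection

def build_pairs(
    ts: TrackSet,
    rule: Literal["knn", "cutoff"] = "knn",
    k: int = 8,
    d_max: float = 15.0,
    t0_policy: Literal["sliding", "fixed"] = "sliding",
    t0_frame: int | None = None,
    directed: bool = False,
) -> PairEnsemble:
    """Select initially neighboring cell pairs at one or many reference frames.

    ``knn``: for each cell at each admissible t0, its ``k`` nearest co-sampled
    cells by Euclidean distance (all available, with a log note, when fewer
    than ``k`` exist). ``cutoff``: all pairs with initial separation
    ≤ ``d_max`` µm. ``sliding`` uses every frame as t0; ``fixed`` uses
    ``t0_frame`` only. Directed ensembles keep per-focal-cell pairs (for the
    fluidity index); undirected ones are deduplicated.
    """
    ids, P, f0 = position_tensor(ts)
    if t0_policy == "fixed":
        if t0_frame is None:
            raise ValueError("t0_policy='fixed' requires t0_frame")
        frames = [int(t0_frame) - f0]
    else:
        frames = range(P.shape[1])

    out_i, out_j, out_t0, out_d0 = [], [], [], []
    short_noted = False
    for fi in frames:
        present = np.flatnonzero(np.isfinite(P[:, fi, 0]))
        if len(present) < 2:
            continue
        X = P[present, fi]
        if rule == "knn":
            kk = min(k, len(present) - 1)
            if kk < k and not short_noted:
                logger.info("build_pairs: only %d neighbors available (k=%d requested)", kk, k)
                short_noted = True
            tree = cKDTree(X)
            d, nb = tree.query(X, k=kk + 1)
            for c in range(len(present)):
                # skip self (distance 0 at first position)
                out_i.extend([present[c]] * kk)
                out_j.extend(present[nb[c, 1:]])
                out_t0.extend([fi + f0] * kk)
                out_d0.extend(d[c, 1:])
        elif rule == "cutoff":
            tree = cKDTree(X)
            prs = np.array(sorted(tree.query_pairs(d_max)), dtype=int)
            if len(prs) == 0:
                continue
            d = np.linalg.norm(X[prs[:, 0]] - X[prs[:, 1]], axis=1)
            out_i.extend(present[prs[:, 0]])
            out_j.extend(present[prs[:, 1]])
            out_t0.extend([fi + f0] * len(prs))
            out_d0.extend(d)
        else:
            raise ValueError(f"unknown pair rule {rule!r}")

    pairs = pd.DataFrame({"i": np.array(out_i, int), "j": np.array(out_j, int),
                          "t0": np.array(out_t0, int), "d0": np.array(out_d0, float)})
    pairs = pairs[pairs["d0"] > 0].reset_index(drop=True)
    if not directed:
        lo = np.minimum(pairs["i"], pairs["j"])
        hi = np.maximum(pairs["i"], pairs["j"])
        pairs = pairs.assign(i=lo, j=hi).drop_duplicates(["i", "j", "t0"]).reset_index(drop=True)
    return PairEnsemble(pairs, ids, selection_rule=rule, directed=directed)


# -------------------------------------------------------------------- curves

def _lag_to_frames(lags: Sequence[float], dt: float) -> np.ndarray:
    lags = np.asarray(lags, float)
    dl = np.rint(lags / dt).astype(int)
    off = np.abs(dl * dt - lags)
    if np.any(off > 1e-9):
        logger.warning("lags %s not multiples of frame interval %g; rounded to nearest frame",
                       lags[off > 1e-9], dt)
    return dl


def pair_msrd_values(P: np.ndarray, pairs: pd.DataFrame, dl: int,
                     normalization: str = "per_pair") -> np.ndarray:
    """Per-pair (normalized) squared change of the separation vector at a lag.

    NaN where either track is unsampled at t0 or t0+lag.
    """
    i = pairs["i"].to_numpy()
    j = pairs["j"].to_numpy()
    f0 = pairs["t0"].to_numpy()
    f1 = f0 + dl
    valid = f1 < P.shape[1]
    m = np.full(len(pairs), np.nan)
    if not valid.any():
        return m
    r0 = P[i[valid], f0[valid]] - P[j[valid], f0[valid]]
    r1 = P[i[valid], f1[valid]] - P[j[valid], f1[valid]]
    sq = np.sum((r1 - r0) ** 2, axis=1)
    if normalization == "per_pair":
        sq = sq / np.sum(r0 ** 2, axis=1)
    elif normalization == "ensemble":
        d0sq = np.sum(r0 ** 2, axis=1)
        sq = sq / np.nanmean(np.where(np.isfinite(sq), d0sq, np.nan))
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    m[valid] = sq
    return m


def msrd_curve(ts: TrackSet, pe: PairEnsemble, lags: Sequence[float],
               normalization: str = "per_pair") -> MsrdCurve:
    """Ensemble MSRD curve over a pair ensemble.

    For pair p with separation vector r_ij and lag τ:
    m_p(τ) = |r_ij(t0+τ) − r_ij(t0)|² / |r_ij(t0)|² (per-pair normalization,
    the default: m_p > 1 means the pair moved apart by more than its own
    initial spacing). ``normalization="ensemble"`` divides by the ensemble
    mean d0² instead; ``"none"`` leaves µm². Mean over all pairs (and sliding
    reference times, if the ensemble holds them) with standard error and
    per-lag pair count.
    """
    _, P, f0 = position_tensor(ts)
    pairs = pe.pairs.assign(t0=pe.pairs["t0"] - f0)
    dls = _lag_to_frames(lags, ts.frame_interval)
    msrd = np.full(len(dls), np.nan)
    se = np.full(len(dls), np.nan)
    n = np.zeros(len(dls), int)
    for a, dl in enumerate(dls):
        m = pair_msrd_values(P, pairs, dl, normalization)
        good = np.isfinite(m)
        n[a] = good.sum()
        if n[a]:
            msrd[a] = m[good].mean()
            se[a] = m[good].std(ddof=1) / np.sqrt(n[a]) if n[a] > 1 else 0.0
    return MsrdCurve(np.asarray(lags, float), msrd, se, n, normalization)


def velocity_temporal_autocorrelation(ts: TrackSet, lags: Sequence[float],
                                      scheme: str = "central") -> CorrelationCurve:
    """C(τ) = ⟨v_i(t)·v_i(t+τ)⟩ / ⟨|v_i(t)|²⟩, pooled over cells and times.

    Pooled normalization makes C(0) = 1 by construction. All-zero velocities
    leave the curve undefined (NaN, with a warning).
    """
    _, V, _ = velocity_tensor(ts, scheme)
    den = np.nanmean(np.nansum(V**2, axis=-1)[np.isfinite(V[..., 0])])
    if not np.isfinite(den) or den == 0:
        logger.warning("temporal autocorrelation undefined: zero or no velocities")
        den = np.nan
    dls = _lag_to_frames(lags, ts.frame_interval)
    val = np.full(len(dls), np.nan)
    se = np.full(len(dls), np.nan)
    n = np.zeros(len(dls), int)
    for a, dl in enumerate(dls):
        if dl >= V.shape[1]:
            continue
        v0 = V[:, : V.shape[1] - dl] if dl else V
        v1 = V[:, dl:]
        dot = np.sum(v0 * v1, axis=-1)
        good = np.isfinite(dot)
        n[a] = good.sum()
        if n[a]:
            val[a] = dot[good].mean() / den
            se[a] = dot[good].std(ddof=1) / (den * np.sqrt(n[a])) if n[a] > 1 else 0.0
    return CorrelationCurve(np.asarray(lags, float), val, se, n, "temporal")


def velocity_spatial_correlation(
    ts: TrackSet,
    bins: Sequence[float],
    mode: Literal["absolute", "relative"] = "absolute",
    scheme: str = "central",
) -> CorrelationCurve:
    """Equal-time velocity correlation binned by cell-pair distance.

    absolute: C(R) = ⟨v_i·v_j⟩_{|x_i−x_j|∈bin} / ⟨|v|²⟩ over same-frame pairs.
    relative: the same on u_i = v_i − V̄(t), the fluctuation about the
    scope-mean velocity at each time — uniform translation then has u ≡ 0 and
    the curve is NaN with counts still reported (documented degenerate case).
    """
    ids, V, f0 = velocity_tensor(ts, scheme)
    _, P, _ = position_tensor(ts)
    edges = np.asarray(bins, float)
    dots: list[np.ndarray] = []
    dists: list[np.ndarray] = []
    sq_all: list[np.ndarray] = []
    for fi in range(V.shape[1]):
        present = np.flatnonzero(np.isfinite(V[:, fi, 0]))
        if len(present) < 2:
            continue
        v = V[present, fi]
        if mode == "relative":
            v = v - v.mean(axis=0)
        sq_all.append(np.sum(v**2, axis=1))
        X = P[present, fi]
        tree = cKDTree(X)
        prs = np.array(sorted(tree.query_pairs(float(edges[-1]))), dtype=int)
        if len(prs) == 0:
            continue
        dists.append(np.linalg.norm(X[prs[:, 0]] - X[prs[:, 1]], axis=1))
        dots.append(np.sum(v[prs[:, 0]] * v[prs[:, 1]], axis=1))
    centers = 0.5 * (edges[:-1] + edges[1:])
    val = np.full(len(centers), np.nan)
    se = np.full(len(centers), np.nan)
    n = np.zeros(len(centers), int)
    den = float(np.mean(np.concatenate(sq_all))) if sq_all else np.nan
    if mode == "relative":
        # degenerate when fluctuations vanish relative to the absolute scale
        # (uniform translation): the correlation of pure rounding residue
        # carries no signal
        abs_scale = float(np.nanmean(np.nansum(V**2, axis=-1)[np.isfinite(V[..., 0])]))
        if abs_scale > 0 and den < 1e-12 * abs_scale:
            den = 0.0
    if den == 0:
        logger.warning("spatial correlation undefined: zero velocity fluctuations")
        den = np.nan
    if dots:
        d = np.concatenate(dists)
        c = np.concatenate(dots)
        which = np.digitize(d, edges) - 1
        for b in range(len(centers)):
            sel = c[which == b]
            n[b] = len(sel)
            if n[b]:
                val[b] = sel.mean() / den
                se[b] = sel.std(ddof=1) / (den * np.sqrt(n[b])) if n[b] > 1 else 0.0
    return CorrelationCurve(centers, val, se, n, f"spatial_{mode}")


def average_normalized_speed(
    ts: TrackSet,
    scope_ids: Sequence[int] | None = None,
    normalizer: float | str = "global_mean_speed",
    scheme: str = "central",
) -> SpeedSeries:
    """Mean speed of the scope cells at each time, divided by a normalizer.

    Default normalizer: the mean speed over the entire TrackSet and movie, so
    a homogeneous ensemble hovers at 1 and a scope moving twice as fast reads
    2. The normalizer actually used is stamped on the result.
    """
    ids, V, f0 = velocity_tensor(ts, scheme)
    speed = np.linalg.norm(V, axis=-1)  # NaN propagates
    if normalizer == "global_mean_speed":
        norm = float(np.nanmean(speed))
    else:
        norm = float(normalizer)
    if not norm > 0:
        raise ValueError(f"normalizer must be > 0, got {norm}")
    if scope_ids is not None:
        keep = np.isin(ids, np.asarray(scope_ids))
        speed = speed[keep]
    fin = np.isfinite(speed)
    nt = fin.sum(axis=0)
    s = np.where(fin, speed, 0.0)
    mean = np.divide(s.sum(axis=0), nt, out=np.full(speed.shape[1], np.nan), where=nt > 0)
    dev2 = np.where(fin, (s - np.where(np.isfinite(mean), mean, 0.0)[None, :]) ** 2, 0.0)
    var = np.divide(dev2.sum(axis=0), np.maximum(nt - 1, 1),
                    out=np.zeros(speed.shape[1]), where=nt > 1)
    sd = np.sqrt(var)
    t = (np.arange(speed.shape[1]) + f0) * ts.frame_interval
    return SpeedSeries(t, mean / norm, sd / (norm * np.sqrt(np.maximum(nt, 1))), nt, norm)
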