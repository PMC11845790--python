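"""Junction-length fluctuation analysis of labeled epithelium movies.

Input is a time series of 2D integer label images: 0 is background (outside
the tissue), positive values are cell ids, stable across frames (label
tracking is input, not computed here), with cells touching directly. From
each frame the cell/junction graph is extracted: cell areas, the interface
point chain of every adjacent cell pair, and the vertices where three or more
regions meet.

Junction lengths come from a least-squares B-spline through the ordered
interface points, which suppresses the pixel-staircase bias of summing raw
pixel steps. Junctions whose adjacent cells change cross-sectional area by
more than 30% over the analyzed movie are excluded, so the remaining length
fluctuations reflect junctional tension dynamics rather than area change.
Retained lengths are normalized per junction by their own time mean and
pooled into a probability distribution; its low-length tail is where
rearrangement-prone, transiently short contacts show up.

Pixel convention: interface points are midpoints between 4-adjacent pixel
centers of differing labels; vertices are pixel-corner points whose four
surrounding pixels carry ≥3 distinct values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, interpolate
from scipy.spatial import cKDTree

logger = logging.getLogger("tailflow")

__all__ = [
    "LabeledFrameSeries", "JunctionGraph", "FluctuationDistribution",
    "AreaFilterReport", "build_junction_graph", "junction_length",
    "area_variation_filter", "fluctuation_distribution",
]

DEFAULT_MAX_REL_VARIATION = 0.30
DEFAULT_DEGREE_CAP = 5
#: interface points further apart than this (pixels) belong to different segments
_CHAIN_LINK_RADIUS = 1.2


@dataclass(frozen=True)
class LabeledFrameSeries:
    frames: np.ndarray        # (T, H, W) integer labels
    pixel_size: float         # µm per pixel
    frame_interval: float     # seconds

    def __post_init__(self) -> None:
        if np.asarray(self.frames).ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class JunctionGraph:
    """Cells, junctions and vertices of a labeled movie.

    ``areas``: cell_id, frame, area_um2.
    ``junctions``: junction_id, cell_a, cell_b, frame, length_um, n_points —
    one row per junction per frame where it exists; junction identity across
    frames is the adjacent cell-id pair (disconnected interfaces get
    ``#k``-suffixed segment ids).
    ``chains`` maps (junction_id, frame) to the ordered interface points [µm].
    ``vertices`` maps frame to (n, 2) corner points [µm] where ≥3 regions meet.
    """

    areas: pd.DataFrame
    junctions: pd.DataFrame
    chains: dict = field(repr=False, default_factory=dict)
    vertices: dict = field(repr=False, default_factory=dict)
    pixel_size: float = 1.0

    def junction_ids(self) -> np.ndarray:
        return self.junctions["junction_id"].unique()

    def area_series(self, cell_id: int) -> pd.DataFrame:
        return self.areas[self.areas["cell_id"] == cell_id]


@dataclass(frozen=True)
class AreaFilterReport:
    retained: list
    excluded_variation: list
    excluded_missing: list


@dataclass(frozen=True)
class FluctuationDistribution:
    normalized_lengths: np.ndarray
    edges: np.ndarray
    probabilities: np.ndarray       # sum to 1 over in-range samples
    n_samples: int
    n_junctions_retained: int
    n_junctions_excluded: int
    tail_threshold: float
    tail_mass: float                # fraction of samples below tail_threshold


# ------------------------------------------------------------- graph build

def _interface_points(img: np.ndarray) -> dict[tuple[int, int], np.ndarray]:
    """Midpoints between 4-adjacent differing positive labels, per cell pair.

    Points are (row, col) in pixel units; pixel centers sit at integers.
    """
    out: dict[tuple[int, int], list] = {}
    # horizontal neighbors: (r, c) vs (r, c+1) -> midpoint (r, c+0.5)
    a, b = img[:, :-1], img[:, 1:]
    m = (a != b) & (a > 0) & (b > 0)
    rr, cc = np.nonzero(m)
    for r, c in zip(rr, cc):
        key = (min(a[r, c], b[r, c]), max(a[r, c], b[r, c]))
        out.setdefault(key, []).append((float(r), c + 0.5))
    # vertical neighbors: (r, c) vs (r+1, c) -> midpoint (r+0.5, c)
    a, b = img[:-1, :], img[1:, :]
    m = (a != b) & (a > 0) & (b > 0)
    rr, cc = np.nonzero(m)
    for r, c in zip(rr, cc):
        key = (min(a[r, c], b[r, c]), max(a[r, c], b[r, c]))
        out.setdefault(key, []).append((r + 0.5, float(c)))
    return {k: np.array(v) for k, v in out.items()}


def _vertices(img: np.ndarray) -> np.ndarray:
    """Pixel-corner points whose 2x2 neighborhood holds >=3 distinct labels."""
    q = np.stack([img[:-1, :-1], img[:-1, 1:], img[1:, :-1], img[1:, 1:]])
    s = np.sort(q.reshape(4, -1), axis=0)
    distinct = 1 + (np.diff(s, axis=0) != 0).sum(axis=0)
    rr, cc = np.nonzero(distinct.reshape(img.shape[0] - 1, img.shape[1] - 1) >= 3)
    return np.column_stack([rr + 0.5, cc + 0.5]).astype(float)


def _connected_segments(points: np.ndarray, radius: float = _CHAIN_LINK_RADIUS) -> list[np.ndarray]:
    """Split interface points into connected segments (graph components)."""
    if len(points) == 1:
        return [np.array([0])]
    tree = cKDTree(points)
    n = len(points)
    parent = np.arange(n)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in tree.query_pairs(radius):
        parent[find(i)] = find(j)
    roots = np.array([find(i) for i in range(n)])
    return [np.flatnonzero(roots == r) for r in np.unique(roots)]


def order_chain(points: np.ndarray) -> np.ndarray:
    """Order interface points along the curve by a nearest-neighbor walk.

    Starts from the point farthest from the centroid (an endpoint for
    non-closed chains) and greedily visits the nearest unvisited point.
    """
    n = len(points)
    if n <= 2:
        return points
    start = int(np.argmax(np.linalg.norm(points - points.mean(axis=0), axis=1)))
    visited = np.zeros(n, bool)
    order = [start]
    visited[start] = True
    tree = cKDTree(points)
    for _ in range(n - 1):
        cur = points[order[-1]]
        # expand candidate ring until an unvisited point is found
        for k in (4, 16, n):
            d, idx = tree.query(cur, k=min(k, n))
            idx = np.atleast_1d(idx)
            cand = [i for i in idx if not visited[i]]
            if cand:
                order.append(cand[0])
                visited[cand[0]] = True
                break
    return points[order]


def build_junction_graph(lfs: LabeledFrameSeries) -> JunctionGraph:
    """Extract cells, junctions and vertices from every frame.

    Junction identity across frames is the adjacent cell-id pair; an
    interface that is disconnected within a frame is split into segments with
    suffixed ids and logged. Junctions appearing or disappearing (e.g. T1
    events) simply contribute the frames where they exist.
    """
    area_rows, junc_rows = [], []
    chains: dict = {}
    vertices: dict = {}
    px = lfs.pixel_size
    for f, img in enumerate(np.asarray(lfs.frames)):
        img = np.asarray(img)
        labs, cnt = np.unique(img, return_counts=True)
        for lab, c in zip(labs, cnt):
            if lab > 0:
                area_rows.append((int(lab), f, float(c) * px**2))
        vertices[f] = _vertices(img) * px
        for (ca, cb), pts in _interface_points(img).items():
            segs = _connected_segments(pts)
            if len(segs) > 1:
                logger.info("frame %d: interface %d-%d disconnected into %d segments",
                            f, ca, cb, len(segs))
                # deterministic segment order: by first-point position
                segs = sorted(segs, key=lambda s: tuple(pts[s].min(axis=0)))
            for si, seg in enumerate(segs):
                jid = f"{ca}-{cb}" if len(segs) == 1 else f"{ca}-{cb}#{si}"
                chain = order_chain(pts[seg]) * px
                chains[(jid, f)] = chain
                junc_rows.append((jid, int(ca), int(cb), f,
                                  junction_length(chain), len(chain)))
    areas = pd.DataFrame(area_rows, columns=["cell_id", "frame", "area_um2"])
    junctions = pd.DataFrame(
        junc_rows, columns=["junction_id", "cell_a", "cell_b", "frame",
                            "length_um", "n_points"])
    return JunctionGraph(areas, junctions, chains, vertices, px)


# ------------------------------------------------------------------ lengths

def junction_length(chain: np.ndarray, degree_cap: int = DEFAULT_DEGREE_CAP,
                    smoothing: float | None = None) -> float:
    """Arc length of a least-squares B-spline through an ordered point chain.

    The spline degree is min(degree_cap, n−1). The default smoothing budget,
    s = n·(0.35·h)² with h the median point spacing, absorbs rasterization
    error of a fraction of a pixel while leaving collinear chains exact; a
    2-point chain degenerates to the Euclidean distance. Chains whose point
    order is inconsistent (a step much longer than typical) are re-ordered by
    a nearest-neighbor walk before fitting.
    """
    pts = np.asarray(chain, float)
    if len(pts) < 2:
        raise ValueError("junction chain needs at least 2 points")
    if len(pts) == 2:
        return float(np.linalg.norm(pts[1] - pts[0]))
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    # repair inconsistent ordering: a correct order is the shortest walk
    reordered = order_chain(pts)
    r_steps = np.linalg.norm(np.diff(reordered, axis=0), axis=1)
    if r_steps.sum() < steps.sum() * (1.0 - 1e-9):
        pts, steps = reordered, r_steps
    h = float(np.median(steps))
    if np.max(steps) > 5.0 * h + 1e-9:
        raise ValueError("junction chain could not be ordered into a simple curve")
    deg = int(min(degree_cap, len(pts) - 1))
    u = np.concatenate([[0.0], np.cumsum(steps)])
    u = u / u[-1]
    s = len(pts) * (0.35 * h) ** 2 if smoothing is None else float(smoothing)
    # least-squares parametric spline; fall back to interpolation if the
    # smoothing system is degenerate for very short chains
    try:
        (t, c, k), _ = interpolate.splprep(pts.T, u=u, k=deg, s=s)
    except (TypeError, ValueError):
        (t, c, k), _ = interpolate.splprep(pts.T, u=u, k=deg, s=0)
    uu = np.linspace(0.0, 1.0, max(20 * len(pts), 200))
    der = np.stack(interpolate.splev(uu, (t, c, k), der=1), axis=-1)
    speed = np.linalg.norm(der, axis=1)
    return float(integrate.simpson(speed, x=uu))


# ---------------------------------------------------------------- filtering

def area_variation_filter(
    jg: JunctionGraph,
    max_rel_variation: float = DEFAULT_MAX_REL_VARIATION,
    frames: Sequence[int] | None = None,
    method: str = "range",
) -> AreaFilterReport:
    """Keep junctions whose BOTH adjacent cells hold their area steady.

    A cell passes if (A_max − A_min)/A_mean ≤ ``max_rel_variation`` (default
    0.30) over the analyzed frames (``method="sd"`` uses SD/mean instead). A
    junction is retained only if both its cells pass; junctions of cells
    absent in some analyzed frame are excluded and counted separately.
    """
    if frames is None:
        frames = sorted(jg.areas["frame"].unique())
    frames = list(frames)
    wide = jg.areas.pivot(index="cell_id", columns="frame", values="area_um2")
    wide = wide.reindex(columns=frames)

    def cell_status(cid: int) -> str:
        if cid not in wide.index:
            return "missing"
        a = wide.loc[cid].to_numpy(float)
        if not np.isfinite(a).all():
            return "missing"
        rel = ((a.max() - a.min()) / a.mean()) if method == "range" else (a.std(ddof=1) / a.mean())
        return "ok" if rel <= max_rel_variation else "varies"

    retained, excl_var, excl_missing = [], [], []
    pairs = jg.junctions[["junction_id", "cell_a", "cell_b"]].drop_duplicates("junction_id")
    for row in pairs.itertuples(index=False):
        sa, sb = cell_status(row.cell_a), cell_status(row.cell_b)
        if "missing" in (sa, sb):
            excl_missing.append(row.junction_id)
        elif "varies" in (sa, sb):
            excl_var.append(row.junction_id)
        else:
            retained.append(row.junction_id)
    logger.info("area_variation_filter: %d retained, %d excluded (area), %d excluded (missing)",
                len(retained), len(excl_var), len(excl_missing))
    return AreaFilterReport(retained, excl_var, excl_missing)


def fluctuation_distribution(
    jg: JunctionGraph,
    retained_ids: Sequence[str],
    bin_edges: np.ndarray | None = None,
    tail_threshold: float = 0.8,
) -> FluctuationDistribution:
    """Pooled probability distribution of per-junction-normalized lengths.

    Each retained junction with ≥2 measured frames contributes l_t / ⟨l⟩_t,
    normalized by its own time mean, so the pool has mean exactly 1. The
    histogram is probability-normalized over the pooled samples, and the mass
    below ``tail_threshold`` — transiently short contacts — is reported.
    """
    if bin_edges is None:
        bin_edges = np.arange(0.0, 2.0 + 1e-9, 0.05)
    pool = []
    n_used = 0
    for jid in retained_ids:
        ls = jg.junctions.loc[jg.junctions["junction_id"] == jid, "length_um"].to_numpy(float)
        if len(ls) < 2:
            continue
        pool.append(ls / ls.mean())
        n_used += 1
    if not pool:
        raise ValueError("no retained junction has >=2 measured frames")
    pooled = np.concatenate(pool)
    counts, edges = np.histogram(pooled, bins=bin_edges)
    probs = counts / len(pooled)
    return FluctuationDistribution(
        pooled, edges, probs, len(pooled), n_used,
        len(jg.junction_ids()) - n_used, tail_threshold,
        float((pooled < tail_threshold).mean()),
    )
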