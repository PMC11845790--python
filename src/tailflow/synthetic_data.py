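"""Ground-truth-labeled synthetic inputs for every analysis stage.

Kinematic fixtures only — no forces, no divisions. Each generator is
deterministic given its seed and attaches the ground truth a test needs:

* caged cells: Ornstein-Uhlenbeck (OU) jiggle about fixed (optionally
  advected) anchors, so the MSRD plateau is set by a stationary variance.
  ``sigma_c`` is the 3D RMS excursion from the anchor (per-axis SD is
  sigma_c/√3); the long-lag normalized MSRD plateau of a pair at initial
  separation d0 is then 4·sigma_c²/d0².
* Brownian cells: independent 3D random walks with diffusivity D, so the
  un-normalized pair MSRD grows as 12·D·τ.
* flow tracers: RK4 integration through analytic planar flows (uniform,
  shear, Gaussian vortices, hyperbolic stagnation flow and their
  superposition), extruded in z, with the true velocity recorded per sample.
* mixed tissue: a fluid posterior region of Brownian cells abutting a caged
  anterior region, with landmarks, for fluidity-map testing.
* fluctuating tessellations, porous masks with exactly known component
  volumes, and homogeneous Poisson clouds for the image-based modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import fsolve
from scipy.spatial import cKDTree

from .fluidity import LandmarkSet
from .junction_fluctuations import LabeledFrameSeries
from .tissue_structure import BinaryMask3D, PointCloud3D
from .trajectory_io import TrackSet, tracks_from_arrays

__all__ = [
    "gen_caged_tracks", "gen_brownian_tracks", "gen_flow_tracks",
    "gen_mixed_tissue", "gen_tessellation", "gen_porous_mask",
    "gen_poisson_cloud", "FlowField", "uniform_flow", "shear_flow",
    "gaussian_vortex", "hyperbolic_flow", "superpose",
    "vortex_pair_hyperbolic_field",
]


# ------------------------------------------------------------------ tracks

def _ou_exact(rng: np.random.Generator, n_steps: int, dt: float, tau: float,
              sd: np.ndarray) -> np.ndarray:
    """Exact stationary OU sample paths, shape (*sd.shape, n_steps+1)."""
    a = np.exp(-dt / tau)
    x = np.empty(sd.shape + (n_steps + 1,))
    x[..., 0] = rng.standard_normal(sd.shape) * sd
    noise_sd = sd * np.sqrt(1.0 - a * a)
    for s in range(n_steps):
        x[..., s + 1] = a * x[..., s] + rng.standard_normal(sd.shape) * noise_sd
    return x


def gen_caged_tracks(
    n_cells: int = 100,
    n_frames: int = 61,
    frame_interval: float = 2.0,
    sigma_c: float = 1.0,
    tau_relax: float = 10.0,
    box: Sequence[float] = (100.0, 100.0, 50.0),
    drift: Sequence[float] = (0.0, 0.0, 0.0),
    seed: int = 0,
    label: str = "solid",
) -> TrackSet:
    """Cells jiggling about anchors — the caged, solid-like regime.

    OU jiggle with 3D stationary RMS ``sigma_c`` [µm] and relaxation time
    ``tau_relax`` [min]; anchors drawn uniformly in ``box`` and advected by
    the constant ``drift`` [µm/min]. ``sigma_c=0`` gives rigid motion.
    """
    rng = np.random.default_rng(seed)
    anchors = rng.uniform(0.0, 1.0, (n_cells, 3)) * np.asarray(box, float)
    t = np.arange(n_frames) * frame_interval
    pos = anchors[:, :, None] + np.asarray(drift, float)[None, :, None] * t[None, None, :]
    if sigma_c > 0:
        sd = np.full((n_cells, 3), sigma_c / np.sqrt(3.0))
        pos = pos + _ou_exact(rng, n_frames - 1, frame_interval, tau_relax, sd)
    ids = np.repeat(np.arange(n_cells), n_frames)
    frames = np.tile(np.arange(n_frames), n_cells)
    flat = pos.transpose(0, 2, 1).reshape(-1, 3)
    return tracks_from_arrays(ids, frames, flat, frame_interval,
                              tissue=[label] * len(ids), embryo_id=f"caged-{seed}")


def gen_brownian_tracks(
    n_cells: int = 100,
    n_frames: int = 61,
    frame_interval: float = 2.0,
    D: float = 1.0,
    box: Sequence[float] = (100.0, 100.0, 50.0),
    drift: Sequence[float] = (0.0, 0.0, 0.0),
    seed: int = 0,
    label: str = "fluid",
) -> TrackSet:
    """Independent 3D random walks — the uncaged, fluid regime.

    Per-axis increments N(drift·Δt, 2·D·Δt) with D in µm²/min. D=0 with zero
    drift gives static cells.
    """
    rng = np.random.default_rng(seed)
    start = rng.uniform(0.0, 1.0, (n_cells, 1, 3)) * np.asarray(box, float)
    steps = rng.standard_normal((n_cells, n_frames - 1, 3)) * np.sqrt(2.0 * D * frame_interval)
    steps = steps + np.asarray(drift, float) * frame_interval
    pos = np.concatenate([start, start + np.cumsum(steps, axis=1)], axis=1)
    ids = np.repeat(np.arange(n_cells), n_frames)
    frames = np.tile(np.arange(n_frames), n_cells)
    return tracks_from_arrays(ids, frames, pos.reshape(-1, 3), frame_interval,
                              tissue=[label] * len(ids), embryo_id=f"brownian-{seed}")


# ---------------------------------------------------------------- flow fields

@dataclass(frozen=True)
class FlowField:
    """Analytic planar velocity field v(x, y) [µm/min], extruded in z."""

    fn: Callable[[np.ndarray], np.ndarray]
    name: str = "flow"

    def __call__(self, xy: np.ndarray) -> np.ndarray:
        return self.fn(np.atleast_2d(np.asarray(xy, float)))

    def velocity3d(self, pos: np.ndarray) -> np.ndarray:
        v = self(np.atleast_2d(pos)[:, :2])
        return np.column_stack([v, np.zeros(len(v))])

    def stagnation_point(self, guess: Sequence[float]) -> np.ndarray:
        """Root of the field near ``guess`` (the true stagnation point)."""
        sol = fsolve(lambda p: self(p[None, :])[0], np.asarray(guess, float), full_output=False)
        return np.asarray(sol, float)


def uniform_flow(v: Sequence[float]) -> FlowField:
    v = np.asarray(v, float)
    return FlowField(lambda xy: np.broadcast_to(v, (len(xy), 2)).copy(), "uniform")


def shear_flow(gamma: float) -> FlowField:
    """v_x = γ·y, v_y = 0."""
    return FlowField(lambda xy: np.column_stack([gamma * xy[:, 1], np.zeros(len(xy))]), "shear")


def gaussian_vortex(center: Sequence[float], omega: float, core: float) -> FlowField:
    """Solid-body core with Gaussian decay: v_θ = ω·r·exp(−r²/(2·core²))."""
    c = np.asarray(center, float)

    def fn(xy):
        d = xy - c
        w = omega * np.exp(-np.sum(d**2, axis=1) / (2.0 * core**2))
        return np.column_stack([-w * d[:, 1], w * d[:, 0]])

    return FlowField(fn, "vortex")


def hyperbolic_flow(center: Sequence[float], strain: float) -> FlowField:
    """Stagnation flow v = (k·(x−x0), −k·(y−y0)); stagnation point at center."""
    c = np.asarray(center, float)
    return FlowField(lambda xy: strain * np.column_stack([xy[:, 0] - c[0], -(xy[:, 1] - c[1])]),
                     "hyperbolic")


def superpose(*fields: FlowField, name: str = "superposition") -> FlowField:
    return FlowField(lambda xy: sum(f(xy) for f in fields), name)


def vortex_pair_hyperbolic_field(
    vortex_centers: Sequence[Sequence[float]] = ((30.0, 75.0), (70.0, 75.0)),
    omega: float = 0.15,
    core: float = 12.0,
    hyperbolic_center: Sequence[float] = (50.0, 25.0),
    strain: float = 0.05,
) -> FlowField:
    """Counter-rotating Gaussian vortex pair plus a hyperbolic stagnation flow.

    The vortices are localized (Gaussian cores), so the flow near the
    hyperbolic center is dominated by the straining term and the true
    stagnation point sits close to it; :meth:`FlowField.stagnation_point`
    locates it exactly from the analytic field.
    """
    f = superpose(
        gaussian_vortex(vortex_centers[0], +omega, core),
        gaussian_vortex(vortex_centers[1], -omega, core),
        hyperbolic_flow(hyperbolic_center, strain),
        name="vortex_pair_hyperbolic",
    )
    return f


def gen_flow_tracks(
    field: FlowField,
    n_tracers: int = 200,
    n_frames: int = 31,
    frame_interval: float = 2.0,
    box: Sequence[float] = (100.0, 100.0, 30.0),
    jiggle_sd: float = 0.0,
    seed: int = 0,
    rk4_substeps: int = 10,
) -> tuple[TrackSet, pd.DataFrame]:
    """Advect tracers through an analytic flow; RK4 at Δt/substeps.

    Positions get i.i.d. Gaussian jiggle of SD ``jiggle_sd`` [µm] per axis
    (localization noise) after integration. Returns the TrackSet and a truth
    table ``track_id, frame, x, y, z, vx, vy, vz`` with the noise-free
    positions and the analytic velocity there.
    """
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, 1.0, (n_tracers, 3)) * np.asarray(box, float)
    h = frame_interval / rk4_substeps
    traj = np.empty((n_tracers, n_frames, 3))
    traj[:, 0] = pos
    for f in range(1, n_frames):
        p = traj[:, f - 1].copy()
        for _ in range(rk4_substeps):
            k1 = field.velocity3d(p)
            k2 = field.velocity3d(p + 0.5 * h * k1)
            k3 = field.velocity3d(p + 0.5 * h * k2)
            k4 = field.velocity3d(p + h * k3)
            p = p + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        traj[:, f] = p
    ids = np.repeat(np.arange(n_tracers), n_frames)
    frames = np.tile(np.arange(n_frames), n_tracers)
    flat_true = traj.reshape(-1, 3)
    v_true = field.velocity3d(flat_true)
    truth = pd.DataFrame({
        "track_id": ids, "frame": frames,
        "x": flat_true[:, 0], "y": flat_true[:, 1], "z": flat_true[:, 2],
        "vx": v_true[:, 0], "vy": v_true[:, 1], "vz": v_true[:, 2],
    })
    noisy = flat_true + rng.standard_normal(flat_true.shape) * jiggle_sd
    ts = tracks_from_arrays(ids, frames, noisy, frame_interval,
                            embryo_id=f"{field.name}-{seed}")
    return ts, truth


def gen_mixed_tissue(
    n_cells: int = 300,
    n_frames: int = 20,
    frame_interval: float = 2.0,
    box: Sequence[float] = (100.0, 200.0, 40.0),
    y_fluid_max: float = 100.0,
    D: float = 1.0,
    sigma_c: float = 1.0,
    tau_relax: float = 10.0,
    seed: int = 0,
) -> tuple[TrackSet, LandmarkSet]:
    """Posterior fluid region + anterior caged region, with landmarks.

    Cells starting at y < ``y_fluid_max`` are Brownian (label "fluid"), the
    rest are caged OU jigglers (label "solid"). Landmarks: tail width = box x
    extent; y of the posterior MPZ end = 0; y of the notochord = box y
    extent. A zero-width fluid region (``y_fluid_max=0``) gives a uniformly
    solid tissue.
    """
    rng = np.random.default_rng(seed)
    start = rng.uniform(0.0, 1.0, (n_cells, 3)) * np.asarray(box, float)
    fluid = start[:, 1] < y_fluid_max
    t = np.arange(n_frames) * frame_interval
    pos = np.repeat(start[:, None, :], n_frames, axis=1)
    n_fluid = int(fluid.sum())
    if n_fluid:
        steps = rng.standard_normal((n_fluid, n_frames - 1, 3)) * np.sqrt(2.0 * D * frame_interval)
        pos[fluid, 1:] = pos[fluid, :1] + np.cumsum(steps, axis=1)
    n_solid = n_cells - n_fluid
    if n_solid and sigma_c > 0:
        sd = np.full((n_solid, 3), sigma_c / np.sqrt(3.0))
        jig = _ou_exact(rng, n_frames - 1, frame_interval, tau_relax, sd)
        pos[~fluid] = pos[~fluid] + jig.transpose(0, 2, 1)
    ids = np.repeat(np.arange(n_cells), n_frames)
    frames = np.tile(np.arange(n_frames), n_cells)
    tissue = np.repeat(np.where(fluid, "fluid", "solid"), n_frames)
    ts = tracks_from_arrays(ids, frames, pos.reshape(-1, 3), frame_interval,
                            tissue=list(tissue), embryo_id=f"mixed-{seed}")
    lm = LandmarkSet(tail_width=float(box[0]), y_mpz_posterior=0.0,
                     y_notochord=float(box[1]))
    return ts, lm


# ------------------------------------------------------------ image fixtures

def gen_tessellation(
    n_rows: int = 6,
    n_cols: int = 6,
    cell_size_px: float = 20.0,
    n_frames: int = 1,
    n_label_rings: int = 1,
    vertex_jiggle_sd: float = 0.0,
    jiggle_tau_frames: float = 5.0,
    pixel_size: float = 0.5,
    frame_interval: float = 10.0,
    seed: int = 0,
) -> tuple[LabeledFrameSeries, dict]:
    """Voronoi tessellation of a (jittered) hexagonal seed lattice.

    Seeds within ``n_label_rings`` lattice spacings of the central seed get
    stable labels 1..n (ring 1 → the classic 7-cell honeycomb); everything
    else is background 0. With ``vertex_jiggle_sd`` > 0 the seeds follow an
    OU process over frames (per-axis stationary SD in pixels), so junction
    lengths fluctuate while labels stay fixed. Returns the label movie and a
    truth dict (seed trajectories, label ids, lattice spacing).
    """
    rng = np.random.default_rng(seed)
    a = cell_size_px
    seeds = []
    for i in range(n_rows):
        for j in range(n_cols):
            seeds.append((i * a * np.sqrt(3) / 2.0, j * a + (i % 2) * a / 2.0))
    seeds = np.array(seeds)
    center = seeds[np.argmin(np.sum((seeds - seeds.mean(axis=0)) ** 2, axis=1))]
    dist = np.linalg.norm(seeds - center, axis=1)
    labeled = np.flatnonzero(dist < (n_label_rings + 0.5) * a)
    labels = np.zeros(len(seeds), int)
    labels[labeled] = np.arange(1, len(labeled) + 1)

    H = int(np.ceil(seeds[:, 0].max()))
    W = int(np.ceil(seeds[:, 1].max()))
    rrows, ccols = np.mgrid[0:H, 0:W]
    pix = np.column_stack([rrows.ravel(), ccols.ravel()]).astype(float)

    if vertex_jiggle_sd > 0:
        sd = np.full((len(seeds), 2), vertex_jiggle_sd)
        jig = _ou_exact(rng, n_frames - 1, 1.0, jiggle_tau_frames, sd)
        seed_traj = seeds[:, :, None] + jig
    else:
        seed_traj = np.repeat(seeds[:, :, None], n_frames, axis=2)

    movie = np.empty((n_frames, H, W), int)
    for f in range(n_frames):
        tree = cKDTree(seed_traj[:, :, f])
        _, nearest = tree.query(pix)
        movie[f] = labels[nearest].reshape(H, W)
    lfs = LabeledFrameSeries(movie, pixel_size, frame_interval)
    truth = {"seed_traj_px": seed_traj, "labels": labels, "lattice_spacing_px": a}
    return lfs, truth


def gen_porous_mask(
    component_volumes_um3: Sequence[float] = (5.0, 0.8),
    shape: Sequence[int] = (40, 40, 40),
    voxel_size: Sequence[float] = (0.5, 0.5, 0.5),
) -> tuple[BinaryMask3D, dict]:
    """Binary mask of isolated components with exactly known volumes.

    Each requested volume is rounded to a whole voxel count and laid down as
    a raster-order prefix of a z-slab (always face-connected), slabs
    separated by ≥2 empty voxels so components never merge even at
    26-connectivity. Truth: per-component voxel volumes and the exact
    fraction retained under a given minimum-volume threshold.
    """
    vox = np.zeros(tuple(shape), bool)
    vv = float(np.prod(voxel_size))
    ny, nx = shape[1] - 2, shape[2] - 2
    placed = []
    z = 1
    for target in component_volumes_um3:
        n = max(1, int(round(target / vv)))
        depth = -(-n // (ny * nx))  # z-slices needed
        if z + depth >= shape[0] - 1:
            raise ValueError("mask shape too small for requested components")
        flat = np.zeros(depth * ny * nx, bool)
        flat[:n] = True
        vox[z:z + depth, 1:1 + ny, 1:1 + nx] = flat.reshape(depth, ny, nx)
        placed.append(n * vv)
        z += depth + 2
    mask = BinaryMask3D(vox, tuple(voxel_size))
    total = vox.size * vv

    def true_fraction(min_volume: float) -> float:
        return sum(v for v in placed if v >= min_volume) / total

    truth = {"component_volumes_um3": placed, "true_fraction": true_fraction,
             "total_volume_um3": total}
    return mask, truth


def gen_poisson_cloud(
    intensity: float = 0.002,
    region_min: Sequence[float] = (0.0, 0.0, 0.0),
    region_max: Sequence[float] = (80.0, 80.0, 40.0),
    seed: int = 0,
) -> PointCloud3D:
    """Homogeneous Poisson point cloud of the given intensity [µm⁻³]."""
    rng = np.random.default_rng(seed)
    lo = np.asarray(region_min, float)
    hi = np.asarray(region_max, float)
    n = rng.poisson(intensity * np.prod(hi - lo))
    pts = lo + rng.uniform(0.0, 1.0, (n, 3)) * (hi - lo)
    return PointCloud3D(pts, tuple(lo), tuple(hi))
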