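"""Nuclear number density and extracellular volume fraction.

Density is estimated by randomly placing a cubic box of side L fully inside a
cropped homogeneous region, counting the points it contains (half-open
inclusion) and averaging count/L³ over many placements; sweeping L probes
length-scale effects, and the value at L = 15 µm serves as the asymptotic
density of a sample.

Volume fraction starts from a binary 3D mask of segmented extracellular
space: connected components (26-connected by default) below a minimum volume
(default 1 µm³, discarding puncta-like objects) are dropped, and the retained
foreground volume is divided by the ROI volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .trajectory_io import CuboidROI

logger = logging.getLogger("tailflow")

__all__ = ["PointCloud3D", "DensityProfile", "BinaryMask3D",
           "density_profile", "volume_fraction"]

DEFAULT_N_PLACEMENTS = 10_000
DEFAULT_L_REPORT = 15.0
DEFAULT_MIN_COMPONENT_VOLUME = 1.0


@dataclass(frozen=True)
class PointCloud3D:
    """3D point set [µm] inside an axis-aligned bounding region."""

    positions: np.ndarray           # (n, 3)
    region_min: tuple[float, float, float]
    region_max: tuple[float, float, float]

    def __post_init__(self) -> None:
        p = np.atleast_2d(self.positions)
        lo = np.asarray(self.region_min, float)
        hi = np.asarray(self.region_max, float)
        if len(p) and not np.all((p >= lo) & (p <= hi)):
            raise ValueError("points outside the stated bounding region")

    def __len__(self) -> int:
        return len(np.atleast_2d(self.positions)) if np.size(self.positions) else 0


@dataclass(frozen=True)
class DensityProfile:
    L: np.ndarray              # box sides [µm]
    density: np.ndarray        # mean local density [µm⁻³]
    se: np.ndarray             # SE over placements
    n_placements: int
    asymptote: float           # density at L_report
    L_report: float = DEFAULT_L_REPORT


@dataclass(frozen=True)
class BinaryMask3D:
    """Voxelized {0,1} volume with anisotropic voxel size [µm]."""

    voxels: np.ndarray                      # (nz, ny, nx) or any 3D order, bool
    voxel_size: tuple[float, float, float]  # along the three array axes

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be > 0")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


def density_profile(
    pc: PointCloud3D,
    L_values=None,
    n_placements: int = DEFAULT_N_PLACEMENTS,
    seed: int | None = None,
    L_report: float = DEFAULT_L_REPORT,
) -> DensityProfile:
    """Random-box density estimator over a range of box sizes.

    For each side length L, ``n_placements`` cubic boxes are placed uniformly
    with the box fully inside the region (no edge bias); local density is the
    half-open point count divided by L³, and the profile is the mean with its
    SE over placements. L values exceeding the region are skipped with a
    warning. The ``asymptote`` is the profile value at the L closest to
    ``L_report`` (interpolated onto the grid if absent). Same seed, same
    profile, bit for bit.
    """
    if L_values is None:
        L_values = np.arange(0.2, 30.0 + 1e-9, 0.2)  # 0.2..30 µm in 0.2 steps
    L_values = np.asarray(L_values, float)
    rng = np.random.default_rng(seed)
    lo = np.asarray(pc.region_min, float)
    hi = np.asarray(pc.region_max, float)
    span = hi - lo
    pts = np.atleast_2d(np.asarray(pc.positions, float)) if len(pc) else np.empty((0, 3))

    dens = np.full(len(L_values), np.nan)
    se = np.full(len(L_values), np.nan)
    for a, L in enumerate(L_values):
        if L > span.min() + 1e-12:
            logger.warning("density_profile: box side %.3g exceeds region span; skipped", L)
            continue
        low = lo + rng.uniform(0.0, 1.0, size=(n_placements, 3)) * (span - L)
        counts = np.zeros(n_placements)
        if len(pts):
            # chunked half-open counting: point in [low, low+L)
            chunk = max(1, int(2_000_000 // max(len(pts), 1)))
            for s in range(0, n_placements, chunk):
                b = low[s:s + chunk]
                inside = (pts[None, :, :] >= b[:, None, :]) & (pts[None, :, :] < (b + L)[:, None, :])
                counts[s:s + chunk] = inside.all(axis=2).sum(axis=1)
        local = counts / L**3
        dens[a] = local.mean()
        se[a] = local.std(ddof=1) / np.sqrt(n_placements) if n_placements > 1 else 0.0

    finite = np.isfinite(dens)
    if finite.any():
        idx = np.argmin(np.abs(L_values[finite] - L_report))
        asym = float(dens[finite][idx])
    else:
        asym = float("nan")
    return DensityProfile(L_values, dens, se, n_placements, asym, L_report)


def volume_fraction(
    mask: BinaryMask3D,
    roi: CuboidROI | None = None,
    min_component_volume: float = DEFAULT_MIN_COMPONENT_VOLUME,
    connectivity: int = 26,
) -> float:
    """Retained-foreground fraction of a cuboid ROI of a binary mask.

    Foreground components are labeled at the requested connectivity (26 or 6)
    within the ROI; components smaller than ``min_component_volume`` µm³ are
    discarded; the fraction is retained foreground volume over ROI volume.
    The ROI is given in µm in array-axis order and snapped to whole voxels
    (half-open); omitted, the whole mask is used.
    """
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    vox = np.asarray(mask.voxels).astype(bool)
    vs = np.asarray(mask.voxel_size, float)
    if roi is not None:
        lo = np.floor(np.asarray(roi.min_corner, float) / vs).astype(int)
        hi = np.ceil(np.asarray(roi.max_corner, float) / vs).astype(int)
        lo = np.clip(lo, 0, vox.shape)
        hi = np.clip(hi, 0, vox.shape)
        if np.any(hi <= lo):
            raise ValueError("ROI has zero volume within the mask extent")
        vox = vox[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    if vox.size == 0:
        raise ValueError("empty ROI")
    lab = measure.label(vox, connectivity=3 if connectivity == 26 else 1)
    if lab.max() == 0:
        return 0.0
    sizes = np.bincount(lab.ravel())[1:] * mask.voxel_volume
    retained = sizes[sizes >= min_component_volume].sum()
    return float(retained / (vox.size * mask.voxel_volume))
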