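"""Per-cell Fluidity Index and landmark-rescaled ensemble maps.

The Fluidity Index (FI) of a cell is the probability, between 0 and 1, that
the normalized MSRD of a pair formed with one of its k nearest neighbors
(default k = 8) exceeds 1 after a horizon Δt (default 30 min, on the order of
the tissue relaxation time). A value of 1 marks a rearrangement: the pair has
separated by more than its initial spacing. Under a normal model for the k
pair values with sample mean μ and SD σ,

    FI = P(MSRD > 1) = 1 − Φ((1 − μ) / σ),

with Φ the standard normal CDF. The degenerate σ = 0 takes the limit: FI = 1
if μ > 1, else 0 (so rigid motion, where every pair MSRD is 0, gives FI = 0).

For maps, cell positions are projected on the medial-lateral × anterior-
posterior plane, rescaled to landmark coordinates (x by tail width, y by the
posterior-MPZ-to-notochord span), binned, and averaged with equal weight per
embryo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import norm

from .movement_metrics import pair_msrd_values, position_tensor
from .trajectory_io import TrackSet

logger = logging.getLogger("tailflow")

__all__ = [
    "LandmarkSet", "FluidityMap2D", "fluidity_index", "fi_from_moments",
    "rescale_coordinates", "fluidity_map",
]

DEFAULT_HORIZON_MIN = 30.0
DEFAULT_K_NEIGHBORS = 8


@dataclass(frozen=True)
class LandmarkSet:
    """Per-embryo anatomical landmarks for cross-embryo rescaling [µm]."""

    tail_width: float
    y_mpz_posterior: float
    y_notochord: float

    def __post_init__(self) -> None:
        if not self.tail_width > 0:
            raise ValueError("tail_width must be > 0")
        if self.y_notochord == self.y_mpz_posterior:
            raise ValueError("landmarks span zero: y_notochord == y_mpz_posterior")


@dataclass(frozen=True)
class FluidityMap2D:
    """Binned mean FI on the rescaled (x', y') plane."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    mean_fi: np.ndarray   # (nx, ny); NaN where no data
    counts: np.ndarray    # (nx, ny) cells pooled over embryos
    n_embryos: np.ndarray  # (nx, ny) embryos contributing per bin


def fi_from_moments(mu: float, sigma: float) -> float:
    """FI = 1 − Φ((1 − μ)/σ); step limit at μ = 1 when σ = 0."""
    if sigma > 0:
        return float(1.0 - norm.cdf((1.0 - mu) / sigma))
    return 1.0 if mu > 1.0 else 0.0


def fluidity_index(
    ts: TrackSet,
    t0: float | None = None,
    horizon: float = DEFAULT_HORIZON_MIN,
    k: int = DEFAULT_K_NEIGHBORS,
    sliding: bool = False,
) -> pd.DataFrame:
    """Per-cell Fluidity Index records.

    For each focal cell sampled at both t0 and t0+Δt, its k nearest co-sampled
    neighbors (also valid at the horizon) are found at t0 by Euclidean
    distance; the per-pair normalized MSRD at Δt gives μ and σ (sample SD,
    n−1), and FI through the normal model. Cells with fewer than 2 valid
    neighbors are skipped and counted in the log.

    ``t0`` defaults to the first frame; ``sliding=True`` instead evaluates
    every admissible reference time and averages records per cell.

    Returns columns ``track_id, t0_min, mu, sigma, fi, k_effective, x, y, z``
    (position at t0; with sliding, the per-cell means over reference times).
    """
    ids, P, f0 = position_tensor(ts)
    dt = ts.frame_interval
    dl = int(round(horizon / dt))
    if abs(dl * dt - horizon) > 1e-9:
        logger.warning("horizon %g min rounded to %d frames", horizon, dl)
    n_frames = P.shape[1]
    if sliding:
        t0_frames = range(max(n_frames - dl, 0))
    else:
        f_t0 = int(round(t0 / dt)) - f0 if t0 is not None else 0
        t0_frames = [f_t0]

    rows = []
    n_skipped = 0
    for fi_ in t0_frames:
        if fi_ + dl >= n_frames:
            logger.warning("t0 + horizon beyond movie end; no records for t0 frame %d", fi_ + f0)
            continue
        ok = np.isfinite(P[:, fi_, 0]) & np.isfinite(P[:, fi_ + dl, 0])
        present = np.flatnonzero(ok)
        if len(present) < 3:
            n_skipped += len(present)
            continue
        X = P[present, fi_]
        kk = min(k, len(present) - 1)
        tree = cKDTree(X)
        d, nb = tree.query(X, k=kk + 1)
        for c in range(len(present)):
            dd = d[c, 1:]
            valid = dd > 0
            if valid.sum() < 2:
                n_skipped += 1
                continue
            pairs = pd.DataFrame({
                "i": np.repeat(present[c], valid.sum()),
                "j": present[nb[c, 1:][valid]],
                "t0": fi_,
                "d0": dd[valid],
            })
            m = pair_msrd_values(P, pairs, dl)
            m = m[np.isfinite(m)]
            if len(m) < 2:
                n_skipped += 1
                continue
            mu = float(m.mean())
            sigma = float(m.std(ddof=1))
            rows.append({
                "track_id": ids[present[c]],
                "t0_min": (fi_ + f0) * dt,
                "mu": mu, "sigma": sigma,
                "fi": fi_from_moments(mu, sigma),
                "k_effective": len(m),
                "x": X[c, 0], "y": X[c, 1], "z": X[c, 2],
            })
    if n_skipped:
        logger.info("fluidity_index: skipped %d cell(s) with <2 valid neighbor pairs", n_skipped)
    rec = pd.DataFrame(rows)
    if sliding and not rec.empty:
        rec = (rec.groupby("track_id", as_index=False)
                  .agg({"t0_min": "mean", "mu": "mean", "sigma": "mean", "fi": "mean",
                        "k_effective": "min", "x": "mean", "y": "mean", "z": "mean"}))
    return rec


def rescale_coordinates(points: np.ndarray, lm: LandmarkSet) -> np.ndarray:
    """Map (x, y) µm positions to landmark coordinates (x', y').

    x' = x / tail_width;
    y' = (y − y_mpz_posterior) / (y_notochord − y_mpz_posterior),
    so y' = 0 at the posterior end of the MPZ and y' = 1 at the notochord.
    Accepts (n, 2) or (n, 3) input; any z column is dropped (the map lives in
    the medial-lateral × anterior-posterior plane).
    """
    p = np.atleast_2d(np.asarray(points, float))
    out = np.empty((len(p), 2))
    out[:, 0] = p[:, 0] / lm.tail_width
    out[:, 1] = (p[:, 1] - lm.y_mpz_posterior) / (lm.y_notochord - lm.y_mpz_posterior)
    return out


def attach_rescaled(records: pd.DataFrame, lm: LandmarkSet,
                    embryo_id: str = "") -> pd.DataFrame:
    """Add xr/yr (rescaled) and embryo_id columns to FI records."""
    out = records.copy()
    xy = rescale_coordinates(out[["x", "y"]].to_numpy(), lm)
    out["xr"] = xy[:, 0]
    out["yr"] = xy[:, 1]
    out["embryo_id"] = embryo_id
    return out


def fluidity_map(
    records: pd.DataFrame,
    bin_width: float | tuple[float, float] = 0.1,
    x_range: tuple[float, float] | None = None,
    y_range: tuple[float, float] | None = None,
) -> FluidityMap2D:
    """Bin FI records on the rescaled plane, averaging embryos with equal weight.

    ``records`` needs columns xr, yr, fi and (for multi-embryo input)
    embryo_id. Each embryo's per-bin mean FI is computed first; the map is the
    mean of those per-embryo means, so every embryo counts equally regardless
    of cell number. Bin edges snap to multiples of the bin width so that maps
    from different record sets share a grid.
    """
    bw = (bin_width, bin_width) if np.isscalar(bin_width) else tuple(bin_width)
    xr = records["xr"].to_numpy(float)
    yr = records["yr"].to_numpy(float)
    if x_range is None:
        x_range = (np.floor(xr.min() / bw[0]) * bw[0], np.ceil(xr.max() / bw[0]) * bw[0])
    if y_range is None:
        y_range = (np.floor(yr.min() / bw[1]) * bw[1], np.ceil(yr.max() / bw[1]) * bw[1])
    x_edges = np.arange(x_range[0], x_range[1] + bw[0] / 2, bw[0])
    y_edges = np.arange(y_range[0], y_range[1] + bw[1] / 2, bw[1])
    nx, ny = len(x_edges) - 1, len(y_edges) - 1

    if "embryo_id" not in records:
        records = records.assign(embryo_id="")
    sum_means = np.zeros((nx, ny))
    n_emb = np.zeros((nx, ny), int)
    counts = np.zeros((nx, ny), int)
    for _, g in records.groupby("embryo_id", sort=True):
        cnt, _, _ = np.histogram2d(g["xr"], g["yr"], bins=(x_edges, y_edges))
        tot, _, _ = np.histogram2d(g["xr"], g["yr"], bins=(x_edges, y_edges),
                                   weights=g["fi"].to_numpy(float))
        occ = cnt > 0
        sum_means[occ] += tot[occ] / cnt[occ]
        n_emb += occ
        counts += cnt.astype(int)
    mean_fi = np.divide(sum_means, n_emb, out=np.full((nx, ny), np.nan), where=n_emb > 0)
    return FluidityMap2D(x_edges, y_edges, mean_fi, counts, n_emb)
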