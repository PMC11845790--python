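# Methods

This note records the models implemented in `tailflow`, the conventions and
defaults they rest on, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Coordinates, units, and track ingestion

All positions are micrometres and all times minutes at the library boundary;
readers convert other units via scale factors. The axis convention is
x = medial-lateral, y = anterior-posterior, z = dorsal-ventral unless a
TrackSet records otherwise. Spatial inclusion (ROIs, density boxes) is
half-open, [min, max), so tiled regions partition points exactly.

ROI cropping keeps or drops *whole* tracks by the position of one reference
sample — by default the first sample of the track, which is how 30-µm tissue
slices are cut from full-tailbud tracking data ("track start position"); a
frame-index option supports cropping at an arbitrary reference time. Samples
are never truncated: a retained track that later leaves the ROI stays whole.
Tracks may have frame gaps; every lag- or difference-based statistic uses
only sample pairs where both frames exist, and exported track ids are taken
as-is (no merging of split tracks).

## Movement metrics

Velocities are central differences on raw positions, v(t) = [x(t+Δ) −
x(t−Δ)]/(2Δ); track endpoints fall back to one-sided differences; samples
flanking interior gaps get no velocity. Smoothing is deliberately confined
to the velocity-field pipeline — the ensemble statistics operate on raw
kinematics. A consequence worth knowing: on noisy tracks the central
stencil's noise variance is one quarter of the forward stencil's (2σ²/(2Δ)²
vs 2σ²/Δ²).

MSRD is normalized per pair by |r_ij(t0)|², so the rearrangement criterion
MSRD > 1 is scale-free pair by pair; ensemble normalization (divide by the
ensemble-mean d0²) and no normalization (µm², for slope fits — a diffusing
pair's un-normalized MSRD grows as 12·D·τ) are available. The vector-based
definition is anchored by the identity that a neighbor at d0 displaced
perpendicular by exactly d0 gives MSRD = 1. It is exactly zero under rigid
translation but *not* under rigid rotation, which rotates separation
vectors; the rotating-solid MSRD is small (second order in the rotation
angle per lag) but nonzero. Users analyzing strongly rotating tissue should
read MSRD plateaus accordingly.

Pair selection defaults to each cell's k = 8 nearest co-sampled neighbors at
the reference time, the same construction the fluidity index uses; a
distance cutoff (default 15 µm, one to two cell diameters) is the
alternative. Reference times slide over the movie by default — curves far
shorter than the movie imply pooling over t0 — with a fixed-t0 mode exposed.
Pairs are directed per focal cell for the fluidity index and deduplicated
for ensemble curves.

Autocorrelations use pooled normalization (one ⟨|v|²⟩ over the scope), which
makes C(0) = 1 by construction; the |C| ≤ 1 bound is asserted to 1e-9. The
relative spatial correlation subtracts the scope-mean velocity at each
frame; when the fluctuation energy is below 1e-12 of the absolute energy
(uniform translation), the statistic is reported as NaN with counts intact.
NaN is the uniform signal for undefined values everywhere in the package;
undefined entries are never silently dropped. The normalizer of the averaged
normalized speed is not uniquely determined by the analysis it supports; the
default is the mean speed over the entire TrackSet and movie (so a
homogeneous ensemble reads 1), and the normalizer used is stamped on the
output.

## Velocity fields

Per-coordinate smoothing B-splines over time remove high-frequency nuclear
jiggle before differentiation. Degree defaults to cubic. The smoothing
budget follows the classical residual-targeting rule s = n·σ² with σ the
expected localization noise, default 0.5 µm — with that choice the spline
absorbs i.i.d. jiggle of that amplitude while tracking the real motion
(verified on synthetic tracks: ≥ 5× reduction of high-frequency velocity
variance). σ and all other parameters are recorded in run provenance.

The cascade is: spline positions evaluated on the native frame grid (no
temporal resampling) → central differences → centered 12-min boxcar per cell
(window shrinks symmetrically at track ends) → unweighted mean over all
cells, focal cell included, within a 35-µm sphere at each time → projection
onto a coordinate plane by dropping the orthogonal component. 12 min and
35 µm are the analysis constants the pipeline was designed around; both are
configurable. The stagnation-point finder (linear interpolation of the
projected field on a 2-µm grid, argmin of speed) is a convenience utility;
because tracers advect out of straining regions, it is most reliable on
early frames or a frame chosen near the time of interest, not on frames
pooled across a long movie.

## Fluidity index and maps

For each focal cell sampled at both t0 and t0+Δt, its k nearest co-sampled
neighbors (restricted to cells also valid at the horizon, which maximizes
usable pairs) give k per-pair MSRDs at Δt; with sample mean μ and SD σ
(n−1 formula), FI = 1 − Φ((1−μ)/σ). Defaults: Δt = 30 min — the order of
the tissue relaxation time — and k = 8. Degenerate σ = 0 takes the limit of
the normal model: FI = 1 if μ > 1 else 0, so rigid motion scores exactly 0.
Cells with fewer than two valid neighbor pairs are skipped and counted.
Per-cell FI uses a single reference time by default; a sliding mode
averages records per cell over all admissible t0.

Two properties of the normal model worth keeping in mind. FI is monotone in
μ at fixed σ, and σ pulls FI toward ½ from either side of the threshold.
And because both μ and σ of the k pair MSRDs scale linearly with diffusivity
(the per-pair MSRD is chi-square-like, σ/μ roughly constant), FI saturates
in the fast-diffusion limit at Φ(μ/σ) ≈ 0.83–0.9 rather than exactly 1; the
index separates regimes, it is not a calibrated probability at the extremes.

Maps: records are projected on the medial-lateral × anterior-posterior
plane and rescaled to landmark coordinates, x′ = x / tail width and
y′ = (y − y_posterior-MPZ)/(y_notochord − y_posterior-MPZ), so embryos of
different sizes share a frame (y′ = 0 at the posterior end of the progenitor
zone, 1 at the notochord). Binning uses edges snapped to multiples of the
bin width (default 0.1 in rescaled units, ≈ 10–20 µm for a typical tailbud)
so maps from different runs share a grid; per-embryo bin means are averaged
with equal embryo weight, making the map invariant to embryo order and to
unequal cell counts. Dorsal/ventral assignment is consumed as input labels
(or an interpolated boundary-point surface); the package does not segment
tissue.

## Tissue structure

Density: cubic boxes of side L are placed uniformly with the box entirely
inside the cropped region (no edge bias); local density is the half-open
point count over L³; the profile over L (default 0.2–30 µm in 0.2-µm steps,
10,000 placements per L) shows length-scale effects and the value at
L = 15 µm is reported as the asymptote. The placement RNG is the only
stochastic element: the same seed reproduces the profile bit for bit. When L
is commensurate with a lattice of points, the half-open convention makes
every placement count identical — a property the tests exploit as an exact
oracle.

Volume fraction: foreground components of the binary mask within the ROI are
labeled 26-connected (configurable to 6; the convention of the original
surface segmentation is unknown), components below 1 µm³ are discarded as
puncta, and the retained volume is divided by the ROI volume. ROIs are
snapped outward to whole voxels.

## Junction fluctuations

Input label movies have cells touching directly: interfaces are defined
between 4-adjacent pixels of differing positive labels, with interface
points at the midpoints between pixel centers — the convention that makes
the two-half-plane case a straight chain. A 0 label is background (outside
the tissue), not a membrane skeleton. Vertices are pixel-corner points whose
2×2 neighborhood holds ≥ 3 distinct labels (background counts, so boundary
tripoints are represented). Junction identity across frames is the adjacent
cell-id pair; a disconnected interface is split into segments with suffixed
ids and logged; junctions appearing or disappearing (T1 events) contribute
only the frames where they exist.

Junction length is the arc length of a least-squares parametric B-spline
through the ordered chain, degree min(5, n−1) — the degree grows with chain
length up to a cap of 5, since unbounded-degree fits through long noisy
chains are ill-conditioned. The default smoothing budget s = n·(0.35·h)²,
with h the median point spacing, absorbs sub-pixel rasterization error while
leaving collinear chains exact; a 2-point chain is the Euclidean distance.
Chains whose given order is not the shortest walk are re-ordered by a greedy
nearest-neighbor walk from the farthest-from-centroid point; if a step
longer than 5× the median spacing survives reordering, the chain is rejected
as not a simple curve. On a rasterized quarter circle this spline length is
within 0.2% of the analytic arc, where the raw pixel-step sum overestimates
by several percent.

The area-variation filter retains a junction only if *both* adjacent cells
satisfy (A_max − A_min)/A_mean ≤ 0.30 over the analyzed frames (SD/mean
available behind a flag); junctions of cells missing from some frame are
excluded and counted separately. Retained junctions are normalized by their
own time-mean length and pooled — the pool then has mean exactly 1 — and
histogrammed with probability normalization (default bin width 0.05 in
normalized units); the mass below a threshold (default 0.8) summarizes the
short-contact tail that promotes rearrangement.

## Synthetic data: what it emulates, and what it does not

The generators are kinematic fixtures with attached ground truth, not tissue
simulations — no forces, no vertex-model mechanics, no divisions, no
tracking errors.

* **Caged cells**: exact-discretization Ornstein-Uhlenbeck jiggle about
  anchors (optionally advected by a uniform drift). σ_c is the 3D stationary
  RMS excursion (per-axis SD σ_c/√3), chosen so the long-lag normalized MSRD
  plateau of a pair at separation d0 is 4σ_c²/d0²; the relaxation time
  (default 10 min) sets how fast the plateau is reached. Defaults σ_c = 1 µm
  at ~10 µm spacing put the plateau near 0.04 — deeply solid.
* **Brownian cells**: independent 3D random walks, default D = 1 µm²/min,
  giving un-normalized pair-MSRD slope 12D.
* **Flow tracers**: RK4 integration (step = frame interval/10) through
  analytic planar fields — uniform, shear, Gaussian-core vortices,
  hyperbolic stagnation flow, and their superposition — extruded in z, with
  the analytic velocity recorded at every sample and the true stagnation
  point available by root finding on the field. The standard test field is a
  counter-rotating vortex pair (ω = 0.15 min⁻¹, 12-µm cores) plus a
  hyperbolic flow (strain 0.05 min⁻¹), giving cell-scale speeds of
  ~1 µm/min. Positions optionally get i.i.d. Gaussian localization noise
  (0.5 µm in the standard conditions).
* **Mixed tissue**: a 100×200×40 µm block, posterior half Brownian
  (labelled "fluid"), anterior half caged ("solid"), with landmarks (tail
  width = x extent; y′ spans the block). Movies default to 2-min frames, the
  standard acquisition interval.
* **Tessellations**: Voronoi rasterization of a hexagonal seed lattice (the
  7-cell honeycomb as the labeled core), with optional OU jitter of seeds
  over frames so junction lengths fluctuate under stable labels.
* **Porous masks**: raster-prefix-filled blocks with exact voxel counts,
  separated so components never merge; the retained fraction under any
  volume threshold is known exactly. **Poisson clouds**: homogeneous, known
  intensity.

Passing tests on these fixtures establishes that the estimators recover
known kinematic and geometric ground truth at realistic scales and noise
levels. It does not establish robustness to what real microscopy adds:
tracking errors and identity swaps, anisotropic and depth-dependent
localization noise, segmentation errors at membranes, uneven cell density,
or tissue-scale deformation modes absent from the fixtures.

## Problem sizes and determinism

The test suite and the verification script run everything at desk scale,
chosen as the smallest ensembles at which the targeted statistics are
well-resolved: ~10³ independent pairs for closed-form MSRD checks, 250–300
cells for fluid/solid discrimination and maps, 250 tracers × 31 frames for
field reconstruction, 10,000 box placements for density. Every stochastic
step takes an explicit seed (numpy Generator); identical seeds give
bit-identical outputs, which the tests assert. The command-line tool writes
a provenance record (resolved parameters, input checksums, package version,
seed) next to every output.

## Known limitations

* MSRD and FI are kinematic proxies for the tissue's mechanical state; FI is
  not a measured viscosity, and its absolute value depends on k, Δt, and the
  normal-model assumption (see the saturation note above).
* The MSRD is not invariant under rigid rotation of the whole tissue.
* The junction pipeline assumes tracked (stable) labels and does not call T1
  events or infer tension.
* The stagnation-point utility reports the speed minimum of an interpolated
  field; it does not classify defect topology.
* Density and volume-fraction estimators start from detected points and
  segmented masks; detection and segmentation quality are upstream of the
  package.
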