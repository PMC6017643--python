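# Methods

This note documents the models, parameters, numerical choices and known
limitations of `bundletrac`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and data conventions

Volumes are `(x, y, z)`-indexed grids with the bundle axis along `+y`;
cross-sections are X–Z planes. Voxel coordinates are 0-based and continuous
(voxel centers at integers), because the tracing targets sub-voxel accuracy.
Density polarity is "higher = more filament mass"; maps with dark filaments
are negated on read (`--invert`). MRC2014 I/O is implemented directly
(1024-byte header + raw data, modes 0/1/2/6 read, mode 2 written); the
on-disk axis permutation (`MAPC/MAPR/MAPS`) is undone on read so internal
axis 1 is always the header's Y. Filament models are CSV
(`filament_id,x,y,z`, voxel units) or Chimera CMM marker-set XML, one marker
set per filament; coordinates in both are voxels, with the voxel size
carried separately by the volume.

## Phantom generator

The generator emulates the statistics of a stereocilium-shaft tomogram, not
its biology:

* hexagonal lattice of `1 + 3n(n+1)` filaments, nearest-neighbour spacing
  `spacing_voxels` (default 12; the physical range is ~11–13 voxels at
  ~0.95 nm/voxel);
* radially Gaussian filament cross-sections, `filament_sigma_voxels = 2.0`
  by default, which after the PSF gives the ~8–10-voxel apparent thickness
  of actin filaments;
* a single smooth displacement field shared by all filaments — a global tilt
  plus a sinusoid whose *maximum direction deviation* is
  `bend_amplitude_deg` — so filaments stay parallel and the ground-truth
  spacing is conserved exactly. This isolates the regime the tracer is
  designed for (collective, gradual direction change);
* missing-wedge anisotropy as a Z-elongated Gaussian PSF
  (`sigma_z = z_elongation_factor * sigma_xy`, default factor 2, default
  `sigma_xy = 1.5`). Fourier wedge masking is deliberately not simulated:
  the denoiser itself models the PSF as a Gaussian, and a Gaussian blur
  keeps every phantom moment analytically checkable;
* i.i.d. additive Gaussian noise with standard deviation `noise_sigma`
  relative to the unit pre-PSF peak filament amplitude (default 1.0 — noise
  as large as the signal peak), seeded and bit-reproducible.

What the phantom does **not** emulate: membranes, cross-linkers, CTF,
correlated noise, the tip/taper region, and "irregular" filaments that jump
to a neighbour. Passing tests therefore demonstrate correctness of the
algorithms under the bundle model's own assumptions, not performance on any
particular real tomogram.

The default fixture (3 shells = 37 filaments, length 400, noise 1.0) is the
problem size used throughout the acceptance path; it keeps the full
five-variant ablation near one minute on one CPU while still containing
two interior shells and a rim.

## Axis detection

Consecutive thickness-averaged sections (defaults: 30-slice slabs every 55
slices — the slab thickness that resolves the hexagonal pattern, and a
sampling interval short enough for gradual direction change) are
cross-correlated after mean subtraction, with zero padding (linear, not
circular, correlation). The integer peak is refined by a least-squares 2D
quadratic fit to its 3×3 neighbourhood; shifts larger than
`step·tan(30°)` are treated as correlation failures and dropped with a
warning, since the bundle is roughly parallel to Y by assumption. Directions
are assigned to the midpoint between section centers and interpolated
linearly (then renormalized) between samples, constant beyond the ends.

## Longitudinal averaging

`out(p) = mean_k Φ(p + k·v(p_y))`, `k = −h…h`, trilinear sampling, `h = 15`
voxels by default. Samples falling outside the volume are dropped from the
mean rather than padded, which keeps the estimator unbiased at the borders.
The half-window unit is voxels (15 voxels ≈ 14 nm at 0.947 nm/voxel). The
optional isotropic Gaussian pre-filter defaults to σ = 1.0 voxel — kept mild
because its measured benefit in the five-way comparison is small.

## Tracing

The placement score is the inner product of a rendered kernel (sum of
unit-amplitude Gaussians at the peak centers, then mean-subtracted and
scaled to unit norm) with the slab patch sampled bilinearly at the candidate
position. Zero mean makes the score invariant to constant density offsets;
unit norm makes scores commensurable across kernels and across slabs at
different step distances, which is what lets "best peak value" arbitrate
between the four candidate steps without an intensity bias.

Numerical design of the optimizer:

* Because the kernel lives on integer offsets and the patch is bilinear, the
  score at a continuous position is *exactly* the bilinear interpolation of
  the integer-lag correlation map of slab and kernel. The search therefore
  anchors its half-voxel position grid to the global half-integer lattice
  (at most 0.25 voxel from a grid anchored at the prediction), computes the
  correlation maps for the whole kernel bank (9 spacings × 12 orientations
  for seven peaks) once per slab with batched FFTs, and shares them across
  all filaments. This is an exact algebraic factorization of the grid
  search, not an approximation.
* Sub-voxel refinement fits a 2D quadratic to the winning kernel's direct
  scores on a 3×3 stencil of **unit** spacing. Unit spacing matters:
  bilinear sampling slightly attenuates scores at fractional positions, and
  a stencil with uniform fractional parts cancels that attenuation out of
  the fit instead of biasing the peak toward integer positions.
* Ties (relative score within 1e-9) break to the smallest displacement from
  the prediction, then smallest hexagon spacing, then smallest orientation;
  remaining ties fall to a fixed scan order, so tracing is fully
  deterministic.
* The next-marker search advances the current marker along the interpolated
  axis direction to predict the in-plane position at each candidate step,
  then searches a disc of radius `search_radius_voxels · d/10` around the
  prediction, **capped at `search_radius_voxels` (3 voxels by default)**.
  The cap is a deliberate design choice: the axis-field prediction already
  compensates collective direction change, so the residual displacement of
  one filament per step does not grow with step distance — while an
  uncapped, linearly growing disc would reach a neighbouring filament's
  score basin, which genuinely out-scores a rim filament's own position
  under the seven-peak kernel and drags the rim toward the bundle interior.
  The cap also enforces the gradual-change premise as a hard guarantee.

Known limitations, both visible in the test suite: (i) rim filaments carry a
few tenths of a voxel of placement bias/scatter — their matched ring peaks
all lie on one side, so a small outward shift combined with a larger hexagon
spacing leaves the score nearly unchanged (a near-degenerate mode of the
spacing–position optimization), and Z-elongation pulls merged densities
toward the bundle; (ii) for very small bundles (e.g. a single shell of 7
filaments) under strong Z-elongation plus extra blur, diagonal rim filaments
can lose their local score maximum entirely and walk to the interior — the
method is built for bundles of hundreds of filaments, where the rim is a
small fraction.

## Cross-distance

The test filament is interpolated at ≤0.1-voxel arc steps with the original
vertices always included (so chords never cut corners); each reference
marker inside the common y-range is matched to its nearest interpolated
point (KD-tree) and the distance refined by exact projection onto the two
adjacent polyline segments. `D_f` is the mean over those markers — the
printed formula of the metric omits the `1/n`, but the quantity is an
average by construction and is implemented as one. Nearest points are 3D
Euclidean by default; a per-section X–Z variant (`mode="planar"`) exists for
sensitivity analysis. Filament correspondence is by id (seeds carry ids);
no proximity matching.

## Polynomial kernel regression

`W` is Gaussian with covariance `H = H_S + H_R` (the convolution of two
Gaussians is Gaussian with summed covariances). `H_S` has variance
`sigma_long²` along the filament direction and `sigma_thick²` across it;
because the cross-filament variance is isotropic, `H_S` is built directly as
`sigma_thick²·I + (sigma_long² − sigma_thick²)·ddᵀ` without an explicit
rotation matrix. `H_R = diag(σ_r², σ_r², (2σ_r)²)`. Defaults
`sigma_thick = 2`, `sigma_long = 8`, `sigma_r = 1` voxels (filament radius,
a length over which filaments are straight, and a mild resolution model).
Support is truncated at 3 standard deviations of `H` per axis and weights
below `exp(−9/2)` of the maximum are zeroed.

Because the weighted design matrix depends only on `W`, the fitted value is
a fixed linear stencil ("equivalent kernel") per direction; `denoise`
applies it as a filter bank, one distinct direction per y. Voxels whose full
support box does not fit inside the volume are copied from the input with a
logged count; `local_fit` remains the direct per-voxel weighted
least-squares solve and doubles as the oracle the fast path is tested
against (they coincide on interior voxels). The fit reproduces every
polynomial of total degree ≤ 2 exactly and is linear in the data — both are
tested. The per-voxel direction comes from the axis field (one shared
direction per y), matching the information available before tracing.

## Ablation

The five variants combine the longitudinal average (L), the Gaussian
pre-filter (G, applied to the original map before L) and the kernel peak
count (7/1): `Trace_L_G_7`, `Trace_L_7`, `Trace_G_7`, `Trace_L_1`,
`Trace_L_G_1`. The axis field is estimated once on the raw volume and shared.
The two summary percentages are `improvement(Trace_L_G_1, Trace_L_G_7)`
(seven-peak benefit) and `improvement(Trace_G_7, Trace_L_G_7)` (longitudinal
averaging benefit), with `improvement(base, new) = (base − new)/base·100`.

## Error handling and degenerate inputs

Constant cross-sections make the correlation peak undefined and raise a
dedicated error (dropped with a warning inside `estimate_axis`); fewer than
10 voxels of regression support raise a rank-deficiency error; malformed MRC
headers name the offending field; the CLI maps validation errors to exit
code 2 and I/O errors to 3.
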