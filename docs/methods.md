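# Methods

## Model

A fiber is the path of a discrete three-dimensional fractional Brownian
motion confined to a brain-shaped domain. The walker obeys
r_{n+1} = r_n + ξ_n with steps ξ_n drawn, per Cartesian component, from
stationary fractional Gaussian noise (FGN) with autocovariance

    γ(n) = (σ²/2) (|n+1|^{2H} − 2|n|^{2H} + |n−1|^{2H}),

the unique second difference of the FBM variance function σ²|n|^{2H}. The
three components are independent (the δ_ij in the covariance). Assumptions
worth making explicit: tissue is treated as homogeneous (no chemotaxis,
fasciculation or region-dependent motility — H and σ are global constants);
fibers do not interact or branch; the geometry is static; and a trajectory
is a line of occupancy, not a growing structure with an energetic cost.

Confinement uses the rejection rule: a step whose endpoint leaves the
allowed region is not carried out, but still consumes a time step, so every
trajectory has exactly n_steps + 1 recorded positions. Reflection-rule
details are known to affect reflected FBM only within a few steps of the
wall, which justifies this simplest choice. The rostral and caudal stack
faces are handled by the same rule (outside-z is "not inside"). Only the
step endpoint is tested — no swept-segment intersection — which is sound
while σ is below one cell; `WalkConfig` warns if σ > 1 is configured.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| H | 0.8 | — | Hurst index; >0.5 persistent/superdiffusive, the regime measured for serotonergic fibers |
| σ | 0.4 | grid units (6.6 µm each, so ≈2.6 µm) | RMS step per component |
| length | 2^18 (desk) / 2^25 (full) | steps | walk length per fiber |
| n_fibers | 960 | — | cohort size of the full-scale study |
| bin_cells | 2 | cells | pooling bins of 2×2×2 cells (13.2 µm edge) |
| k | 10^8.3 | — | optical-density transform gain |
| start cuboid | 680×1200×400 µm³ | µm | raphe-like start region (≈103×182×61 cells) |
| subdivisions | 12 | slices/section | virtual slices per 80 µm physical section |

The full-scale walk length (2^25) needs ~0.8 GB of increments per fiber
(three float64 components); the desk default 2^18 keeps the whole test
suite and the acceptance computations in seconds-to-minutes on one CPU.
Tests use cohorts of 8–32 fibers and 2^9–2^18 steps; these sizes were
chosen once as the smallest at which each statistical effect is resolved
against its Monte-Carlo error.

## Noise generation

Whole increment sequences are generated up front — FGN is non-Markovian
and cannot be extended step by step. Two independent constructions:

- **Fourier filtering** (`generate_fgn_fourier`, the production path):
  real white Gaussian noise of length 2L is filtered in the frequency
  domain by the square root of the discrete spectral density, taken as the
  DFT of the circular even extension of γ on the 2L grid; the first L
  values are returned. With this discretization the population covariance
  equals γ exactly up to circular wrap-around, which the 2× embedding
  pushes beyond any usable lag.
- **Circulant embedding / Davies–Harte** (`generate_fgn_exact`, the
  oracle): Hermitian complex Gaussian Fourier coefficients with variances
  equal to the circulant eigenvalues, transformed back. For 0 < H < 1 the
  embedding is provably nonnegative-definite; eigenvalues are clipped at
  −10⁻⁸ relative only to absorb round-off, and anything below that raises.

Both are validated against the closed form and against each other
(dual-route tests), using Bartlett's formula for the standard error of
sample autocovariances — essential here, because long-range dependence
makes the naive 1/√n error wrong by an order of magnitude (for H = 0.8 the
variance of the lag-0 sample autocovariance decays as n^{4H−4} = n^{−0.8},
not n^{−1}).

Seeding: each fiber and component derives its stream from
`SeedSequence(master_seed, spawn_key=(fiber, component))` (component 3 is
the start-position stream), so cohorts are bit-reproducible regardless of
execution order; serial and shuffled execution are asserted identical.

## Geometry

Coordinates are a 0-based integer grid; cell (i,j,k) owns the half-open
box [i,i+1)×[j,j+1)×[k,k+1); x is mediolateral, y dorsoventral (increasing
ventral), z rostrocaudal (increasing caudal). A section is a set of
contours, each a run of consecutive-y rows (y, x_left, x_right); forbidden
contours subtract from the union of allowed ones (multiple allowed
contours per slice are permitted).

Interpolation (missing physical sections, and the 12 virtual slices per
section) matches contours by (kind, rank order) and rows by y; x-bounds
interpolate linearly and round to nearest integer. A row or contour that
exists on only one side is kept iff the interpolation fraction lies nearer
that side (<0.5), avoiding topology jumps; if exclusions split a contour's
y-run, the longest run is kept. Unequal contour counts are handled by the
same nearness rule rather than raising, since real section series gain and
lose ventricle contours along the stack. Virtual slice 12·i + j
interpolates section i toward i+1 at fraction j/12; the caudal-most
section extrudes. A forbidden contour that would protrude beyond the
allowed extent after interpolation is clipped to it with a warning
(semantics are unchanged — forbidden regions only subtract).

`is_inside` is the direct contour-row test; `VolumeModel.rasterize()`
paints an independent boolean mask used by the numba walk kernel, and a
test asserts the two routes agree cell-for-cell on a full phantom grid.

## Density mapping

Pooling into 2×2×2 bins happens on raw counts *before* normalization;
trailing partial bins are kept. A position is assigned by its floor cell
(segment-endpoint counting; at σ = 0.4 < 1 cell the distinction from
segment-crossing counting is negligible). Rejected steps are tallied (the
position repeats); `count_rejected=False` exposes the alternative for
sensitivity analysis. d_s = counts / total, so Σd_s = 1 exactly up to
float summation; d_o = 1 − exp(−k·d_s) ∈ [0,1), though float64 saturates
to exactly 1.0 once k·d_s ≳ 37 — range tests therefore assert ≤ 1. Because
k = 10^8.3 was tuned for a full-scale bin count, small desk-scale volumes
drive most bins into saturation; `auto_k` instead sets k = ln 2 / median
nonzero d_s so the median bin maps to 0.5. NIfTI exports record the
13.2 µm bin size (in mm) in the header.

## Phantoms

The synthetic geometries emulate the structure, not the anatomy, of an
embryonic mouse brain stack: an elongated stack of tapering ellipses with
two lateral forbidden voids ("ventricles"), a dorsomedial forbidden notch
(surface concavity), and a start cuboid in the caudal third, ventral of
center (the raphe sits under the aqueduct). They are deterministic,
validated by the same reader as external stacks, and round-trip through
stack.json bit-identically. What they deliberately lack: real contour
irregularity, hippocampal folding, bilateral asymmetries, tissue
heterogeneity. Passing tests on phantoms therefore demonstrates the
correctness of the machinery (covariance, confinement, normalization,
border effects), not anatomical prediction on real brains; a loader for
externally produced contour stacks is provided but only phantom-backed in
the test suite.

## Validation statistics

- Sample autocovariance uses the unbiased 1/(n−lag) normalization with
  sample-mean removal.
- MSD is ensemble- and time-origin-averaged over free-space trajectories
  (reflected trajectories are refused unless explicitly allowed); the
  Hurst estimate is half the log-log least-squares slope, default fit
  window lags 8–512 — an estimator chosen for validation, exact on power
  laws to numerical precision.
- Border profiles group pooling bins by Chebyshev distance (chessboard
  distance transform, domain padded so the array edge counts as border) to
  the nearest non-allowed bin; a bin counts as allowed if any of its cells
  is. Chebyshev is cheap and rotation-agnostic at this resolution.
- Convergence toward the density steady state is monitored by the L1
  distance between normalized fields of two run segments; no universal
  threshold is imposed — for the slab fixture the mirror asymmetry and
  split-half L1 both shrink with run length but remain ~0.1–0.3 at desk
  scale, which the tests budget for explicitly.

## Known limitations

Constant H and σ everywhere (no multifractional FBM); no deterministic
bundle routing (e.g. the medial forebrain bundle), branching or
fiber–fiber interaction; static geometry; endpoint-only boundary testing;
phantom geometries only in CI. The acceptance computations run at desk
scale (2^16–2^20-step noise, ≤32-fiber cohorts), which recovers parameters
and effect directions, not the full-scale density maps.
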