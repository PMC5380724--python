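# Methods

`meghubs` implements an expressive-language MEG analysis chain — sensor
cleaning, LCMV beamformer source estimation, differential low-beta power
mapping with permutation/FDR inference, broadband phase-locking-value
(PLV) connectivity, and graph-theoretic hub/laterality analysis — and a
synthetic-data generator whose ground truth (active sources, coupling
topology, hub placement, hemispheric asymmetry) is known by
construction, so every stage is testable without any recorded data.

## Forward model

The conductor is a homogeneous sphere. The magnetic field of a current
dipole at `r0` with moment `q` observed at `r` (sphere center at the
origin) is the closed-form Sarvas expression

    B(r) = μ0 / (4π F²) · [ F (q × r0) − ((q × r0) · r) ∇F ],
    F = a (r a + r² − r0·r),   a = |r − r0|,

projected onto each magnetometer's radially-inward sensitive axis. Two
exact properties matter downstream and are asserted in tests: a radially
oriented dipole is silent at every sensor, and the mapping is linear in
the dipole moment. A realistic one-shell model fitted to segmented
anatomy shares the radial-silence property; the analytic sphere is used
here because it is dependency-free and desk-testable. Sensors are a
Fibonacci lattice on the upper hemisphere of a shell (quasi-uniform,
deterministic per seed); the source grid is an axis-aligned lattice
clipped to 95 % of the head radius and offset half a spacing along the
left–right axis, so the grid is mirror-symmetric with no midline voxels
and hemisphere splits are unambiguous.

## Synthetic source dynamics

* **Event-related desynchrony (ERD).** Designated voxels carry
  band-limited stochastic oscillations (spectrally masked white noise,
  13–23 Hz by default) whose envelope drops to `√(1 − erd_depth)`
  inside the active window, so active-window band power is
  `(1 − erd_depth)` × baseline power in expectation. A stochastic
  carrier (rather than a deterministic sinusoid) gives realistic
  trial-to-trial variability, which is what makes the permutation test
  meaningful.
* **Phase coupling.** Each coupled pair shares a per-trial random phase
  at a set of active-window DFT bins; each member adds independent
  jitter uniform on `(1 − c)·(−π, π)`, so the expected PLV rises
  monotonically from the null level to 1 as the coupling strength `c`
  goes 0 → 1. Two deliberate design choices:
  * the second pair member lags by a constant 90°. PLV is invariant to
    a constant lag, but quadrature signals have zero zero-lag
    correlation, so the minimum-variance beamformer does not cancel
    the planted pair the way it cancels coherent sources. Without this,
    the filter at one pair member acquires large negative gain on the
    other (measured ≈ −0.7) and the planted coupling is destroyed in
    source space.
  * when a voxel participates in several pairs, the pairs are
    multiplexed onto disjoint frequency bins, so pairwise couplings do
    not interfere through phase mixing in the shared voxel.
* **Background.** All remaining voxels carry independent 1/f-like
  noise; sensors add i.i.d. Gaussian noise. The defaults (10 nAm
  planted components, 3–5 nAm background, tens of fT sensor noise)
  keep planted effects roughly an order of magnitude above the
  incoherent floor. This sandwich matters for voxel-level PLV: if the
  floor is far below the beamformer's spatial leakage, every voxel
  near a planted source phase-locks to every other ("leakage
  cliques" spanning the volume); if the floor drowns the direct
  signal, nothing is recovered. Real recordings sit in between, which
  is the regime the generator emulates.

What the generator does **not** emulate: realistic anatomy and source
orientation geometry, correlated sensor noise (no empty-room model),
heartbeat/eye/muscle artifacts, head movement, or volume-conduction
differences between tissues. Passing tests therefore show the analysis
chain is correct and well calibrated on data obeying its model
assumptions — not that those assumptions hold for any particular
recording.

## Preprocessing

Epoching is endpoint-inclusive over −900…1800 ms around stimulus onset
with baseline correction over −900…0 ms; all later window selection is
half-open `[t0, t1)`, so the −400–0 ms baseline and 600–1000 ms active
windows always contain equal sample counts. Line components at 60, 120
and 180 Hz are removed per epoch by least-squares projection onto the
exact sine/cosine pair at each frequency plus zeroing of the nearest
DFT bin and its two neighbors — sharp regardless of whether the line
frequency falls on the epoch's DFT grid. The 0.1–100 Hz bandpass is a
symmetric Hamming windowed-sinc FIR applied centered via FFT
convolution, which is exactly zero-phase in one pass (phase distortion
would corrupt PLV downstream); the default order gives a ≈ 4 Hz
transition band, and the sub-hertz high-pass edge is necessarily
gentle at epoch length. Jump-artifact rejection scores each
trial/channel by the maximum absolute first difference of the
median-filtered (9-sample kernel) trace: the median filter suppresses
noise and transient spikes while faithfully tracking a sensor jump,
whose step then dominates the derivative. (The deviation of the raw
trace from its median-filtered version is *not* used: a median filter
tracks a clean step exactly, so that residual is blind to the artifact
it is meant to find.) Scores become robust z-values across trials per
channel, scaled by the 90th percentile of the pooled derivative
distribution — the per-trial maxima concentrate and the median of the
piecewise-constant filter's derivative degenerates to ≈ 0, so neither
is a usable scale. The default threshold (z > 20) rejects only gross
steps.

## Source inversion

The covariance is the "common filter": pooled over the concatenated
baseline and active windows of all kept trials, per-window per-channel
mean removed (the pooled matrix is then exactly the sample-weighted
combination of the window covariances). One set of weights computed
from it serves both windows, so power contrasts are not biased by
window-specific filters. Regularization is `C + λ·mean(diag C)·I` with
λ = 0.001 (the conventional reading of "0.1 %" regularization).

The scalar LCMV filter for a voxel with orientation-resolved leadfield
column `l` is `w = C⁻¹l / (lᵀC⁻¹l)` (unit gain, minimum variance). The
orientation is chosen in the tangential plane — the radial direction is
silent in the spherical model — as the eigenvector of the 2 × 2 matrix
`LᵀC_reg⁻¹L` with the **smallest** eigenvalue, i.e. the orientation
maximizing unit-gain output power. This is the standard source-bearing
orientation of the scalar beamformer; the opposite choice (minimizing
output power across orientations) selects the direction orthogonal to
the source and destroys localization (verified empirically: ~40 mm
median error versus 0 mm). Voxels whose tangential leadfield is
numerically zero (a grid point at the sphere center) are flagged silent
and get zero weights. Band power uses a Hann-tapered periodogram with
bins inside 13–23 Hz summed; the ERD map is `(P_act − P_base)/P_base`
per voxel with NaN where baseline power is zero.

## Statistics

The paired active-vs-baseline contrast uses trial-level sign flips as
the exchangeability unit: each of `n_rand` randomizations flips the
window assignment in a random subset of trials and recomputes the
paired t. Two-sided p-values use the add-one rule
`p = (1 + #{|t*| ≥ |t|}) / (1 + n_rand)`, which cannot return zero and
is valid at any `n_rand`. Benjamini–Hochberg step-up FDR at q = 0.05
corrects across voxels (and, at group level, across parcels); NaN
statistics (zero-variance parcels) are excluded from the family. Group
contrasts use Welch's t by default (pooled-variance selectable).

## Connectivity

Per trial and voxel, a Hann-tapered DFT of each 400 ms analysis window
yields one phase per retained bin; the PLV of a pair at bin ω is the
magnitude of the trial-averaged unit phasor of the phase difference.
The broadband summary is the unweighted mean over retained bins, and
the task-related adjacency is active-window PLV minus baseline-window
PLV. With 400 ms windows the bin spacing is 2.5 Hz, and bins must
complete ≥ 2 cycles in the window, retaining 5, 7.5, …, 30 Hz: the
3–5 Hz edge of the nominal 3–30 Hz band is not resolvable at this
window length and is excluded by default (configurable). For
independent phases the expected PLV is ≈ √(π/4N) (≈ 0.089 at N = 100
trials), the floor against which planted coupling is judged.

## Network analysis

The adjacency is binarized at 70 % of its maximum positive entry; only
positive (task-increased) coupling forms edges — task-related decreases
are not hubs (`edge_sign: absolute` is available). Degree is the row
sum; eigenvector centrality is the non-negative leading eigenvector of
the adjacency computed on the largest connected component (ties broken
toward the component containing the lowest-index node), zero elsewhere,
scaled to max 1; betweenness is unnormalized Brandes shortest-path
betweenness with undirected pairs counted once. Voxel metrics are
averaged per atlas parcel; group-level maps are rescaled to [0, 1] by
their maximum after aggregation. The laterality index is
`LI = (L − R)/(L + R)` of EVC summed over frontal and temporal parcels
per hemisphere (sum and mean agree when hemispheres contribute equal
parcel counts, as in the mirrored synthetic atlas); strictly LI > 0.25
classifies left, LI < −0.25 right, otherwise bilateral.

The synthetic atlas splits voxels by hemisphere, seeds parcels with
k-means on left-hemisphere coordinates mirrored to the right, and grows
parcels by multi-source breadth-first search on the 6-neighbor lattice,
so each parcel is one connected component and parcel pairs are
mirror-matched with shared frontal/temporal annotations.

## Validation studies and problem sizes

The end-to-end studies in `meghubs.studies` use a desk-scale setup: a
5 cm spherical head (so a 10–12 mm lattice stays at a few hundred
voxels), 120 sensors, 30–100 trials at 600 Hz, and reduced permutation
counts (500) where full counts add nothing at these effect sizes.
These sizes are the package's own choice of test conditions; all
stage defaults (windows, bands, λ, thresholds, q) are the study values
listed in `PipelineConfig`.

Planted-hub scenarios put the hub and two of its three partners in one
parcel (the third in another parcel of the same hemisphere), all at
cortical depth (≥ 60 % of the maximum voxel radius) and away from parcel
boundaries. The placement reflects how such hubs present in source
space: parcel-mean EVC rewards *regions* of concentrated centrality,
and beamformer point spread must land inside the hub's parcel for the
parcel-level readout to be meaningful. With random deep placement the
hub's weak sensor footprint lets a superficial partner's point-spread
neighborhood out-score it — a depth-bias limitation of the method
itself, not of the implementation, and the reason hub recovery is
specified at cortical depth.

## Numerical choices and degenerate inputs

* Permutation p-values are deterministic per seed; pipeline stage seeds
  derive from the master seed by hashing the stage name, so adding a
  stage never perturbs later stages' randomness.
* Zero-variance paired differences give t = ±inf (sign of the mean) and
  p = 1 where 0/0; empty graphs give all-zero centralities with a
  warning; L + R = 0 gives an undefined LI reported as bilateral with a
  warning; baseline power 0 gives NaN ERD excluded from inference.
* The unit-gain constraint `w·(G·u) = 1` is asserted to 1e−9 for every
  non-silent voxel; PLV is asserted ≤ 1 + 1e−9 before differencing.

## Known limitations

* Voxel-level PLV between beamformed estimates inherits spatial
  leakage: point-spread neighborhoods of a genuinely coupled source
  phase-lock with it and with each other. No leakage correction
  (orthogonalization, imaginary coherence) is applied — the method
  under study uses raw PLV — so voxel-level edges near planted sources
  must be interpreted regionally; parcel aggregation is what makes the
  hub readout stable.
* The beamformer assumes sources are uncorrelated; strongly zero-lag
  coherent sources partially cancel. The generator's quadrature
  coupling sidesteps this; real co-oscillating sources with near-zero
  lag would be attenuated.
* The 3–5 Hz corner of the broadband range is unmeasurable in 400 ms
  windows; conclusions about theta-range coupling would need longer
  windows.
* The spherical forward model has no preferred cortical orientation
  structure; depth sensitivity falls toward the sphere center faster
  than for a realistic head.
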