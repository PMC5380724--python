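"""Ground-truth MEG simulation: geometry, forward model, source dynamics.

Everything downstream (beamforming, phase-locking connectivity, hub
mapping) is validated against datasets generated here, whose active
sources, coupling topology, hub placement and hemispheric asymmetry are
known by construction.

Forward model
-------------
The conductor is a homogeneous sphere; the magnetic field of a current
dipole is evaluated with the closed-form Sarvas expression

    B(r) = μ0 / (4π F²) · (F (q × r0) − ((q × r0) · r) ∇F)

with the sphere center at the origin, source position r0, sensor
position r, a = r − r0, F = a (r a + r² − r0 · r). This analytic model
shares the property MEG beamforming relies on: a radially oriented
dipole produces exactly zero external field, so only the tangential
dipole subspace is observable.

Source dynamics
---------------
* Event-related desynchrony (ERD) voxels carry band-limited stochastic
  oscillations (spectrally masked white noise) whose envelope drops to
  ``sqrt(1 − erd_depth)`` inside the active window, so active-window
  band power is ``(1 − erd_depth)`` × baseline power in expectation.
* Coupled voxel pairs share a common random phase per trial at a set of
  DFT bins of the active window; each member adds independent phase
  jitter uniform on ``(1 − coupling_strength)·(−π, π)``, making the
  expected phase-locking value monotone in coupling strength. When a
  voxel participates in several pairs, pairs are multiplexed onto
  disjoint frequency bins so pairwise couplings do not interfere.
* All remaining voxels carry independent 1/f-like background noise.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.cluster.vq import kmeans2

from .containers import GeometryError, SensorEpochs

__all__ = [
    "MU0",
    "HeadModel",
    "SensorArray",
    "SourceGrid",
    "Leadfield",
    "SimulationScenario",
    "ParcelAtlas",
    "build_head_and_sensors",
    "build_source_grid",
    "compute_leadfield",
    "draw_tangential_orientations",
    "simulate_trial_sources",
    "project_and_add_noise",
    "build_synthetic_atlas",
    "coupling_bin_frequencies",
]

MU0 = 4e-7 * np.pi  # vacuum permeability, T·m/A


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class HeadModel:
    """Spherical homogeneous conductor: center (m) and radius (m)."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.center.shape != (3,):
            raise GeometryError("head center must be a 3-vector")
        if not self.radius > 0:
            raise GeometryError("head radius must be positive")


@dataclass
class SensorArray:
    """Magnetometer positions (m) and unit sensitive axes."""

    positions: np.ndarray
    orientations: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        if self.positions.shape != self.orientations.shape or self.positions.ndim != 2:
            raise GeometryError("positions/orientations must both be n_chan × 3")
        if self.positions.shape[0] < 16:
            raise GeometryError("need at least 16 channels")
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise GeometryError("orientation rows must have unit norm")

    @property
    def n_chan(self) -> int:
        return self.positions.shape[0]


@dataclass
class SourceGrid:
    """Axis-aligned dipole lattice clipped strictly inside the head.

    ``ijk`` holds the integer lattice coordinates of each retained point
    (used for 6-neighbor adjacency when building parcels). The lattice
    is offset by half a spacing along x so no point sits exactly on the
    midsagittal plane and the grid is mirror-symmetric about it.
    """

    points: np.ndarray
    spacing: float
    ijk: np.ndarray
    inside_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.ijk = np.asarray(self.ijk, dtype=int)
        if self.inside_mask is None:
            self.inside_mask = np.ones(len(self.points), dtype=bool)
        if not self.spacing > 0:
            raise GeometryError("grid spacing must be positive")

    @property
    def n_vox(self) -> int:
        return self.points.shape[0]


@dataclass
class Leadfield:
    """Gain matrix: ``gain[c, v, k]`` is the field at channel c (T) per
    unit dipole moment (A·m) along axis k at voxel v."""

    gain: np.ndarray

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 3 or self.gain.shape[2] != 3:
            raise ValueError("gain must be n_chan × n_vox × 3")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("leadfield contains non-finite values")

    @property
    def n_chan(self) -> int:
        return self.gain.shape[0]

    @property
    def n_vox(self) -> int:
        return self.gain.shape[1]


def build_head_and_sensors(
    n_chan: int = 275,
    head_radius: float = 0.09,
    sensor_shell_radius: float = 0.12,
    seed: int = 0,
) -> Tuple[HeadModel, SensorArray]:
    """Spherical head plus a quasi-uniform helmet of radial magnetometers.

    Sensors are placed on the upper hemisphere of a shell of radius
    ``sensor_shell_radius`` using a Fibonacci lattice (deterministic for
    a fixed seed; the seed only rotates the whole layout in azimuth).
    Sensitive axes point radially inward, mimicking an axial-gradiometer
    helmet read out as magnetometers.
    """
    if not (sensor_shell_radius > head_radius > 0):
        raise GeometryError("need sensor_shell_radius > head_radius > 0")
    head = HeadModel(center=np.zeros(3), radius=head_radius)
    rng = np.random.default_rng(seed)
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    i = np.arange(n_chan)
    # z in (0, 1]: upper hemisphere, denser sampling handled by lattice
    z = (i + 0.5) / n_chan
    golden = np.pi * (3.0 - math.sqrt(5.0))
    theta = phi0 + i * golden
    rho = np.sqrt(1.0 - z**2)
    unit = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    positions = head.center + sensor_shell_radius * unit
    orientations = -unit  # radially inward
    return head, SensorArray(positions=positions, orientations=orientations)


def build_source_grid(head: HeadModel, spacing: float) -> SourceGrid:
    """Axis-aligned lattice clipped to ‖p − center‖ < 0.95 · radius.

    The x axis (left–right) is offset by spacing/2 so the lattice is
    mirror-symmetric about the midsagittal plane with no midline voxels,
    giving clean left/right hemisphere splits downstream.
    """
    if not (0 < spacing < head.radius):
        raise GeometryError("spacing must lie in (0, head radius)")
    rmax = 0.95 * head.radius
    nhalf = int(math.ceil(rmax / spacing)) + 1
    ks = np.arange(-nhalf, nhalf + 1)
    xs = (ks[:-1] + 0.5) * spacing  # half-offset, symmetric about 0
    ys = ks * spacing
    zs = ks * spacing
    gx, gy, gz = np.meshgrid(np.arange(len(xs)), np.arange(len(ys)), np.arange(len(zs)), indexing="ij")
    pts = np.column_stack(
        [xs[gx.ravel()], ys[gy.ravel()], zs[gz.ravel()]]
    ) + head.center
    ijk = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = np.linalg.norm(pts - head.center, axis=1) < rmax
    if not inside.any():
        raise GeometryError("spacing too coarse: no grid point falls inside the head")
    return SourceGrid(points=pts[inside], spacing=spacing, ijk=ijk[inside])


# ---------------------------------------------------------------------------
# forward model


def _dipole_gain(r0: np.ndarray, sensors: SensorArray, head: HeadModel) -> np.ndarray:
    """Sarvas field at every sensor for the three unit dipole moments.

    Returns an (n_chan, 3) array of projections onto the sensor axes.
    """
    r = sensors.positions - head.center  # (n, 3)
    p0 = r0 - head.center  # (3,)
    a_vec = r - p0
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    r0dotr = r @ p0
    adotr = np.einsum("ij,ij->i", a_vec, r)
    F = a * (rn * a + rn**2 - r0dotr)
    c1 = a**2 / rn + adotr / a + 2.0 * a + 2.0 * rn
    c2 = a + 2.0 * rn + adotr / a
    gradF = c1[:, None] * r - c2[:, None] * p0
    out = np.empty((sensors.n_chan, 3))
    pref = MU0 / (4.0 * np.pi * F**2)
    for k in range(3):
        q = np.zeros(3)
        q[k] = 1.0
        qxr0 = np.cross(q, p0)
        if not np.any(qxr0):
            out[:, k] = 0.0
            continue
        B = pref[:, None] * (F[:, None] * qxr0[None, :] - (r @ qxr0)[:, None] * gradF)
        out[:, k] = np.einsum("ij,ij->i", B, sensors.orientations)
    return out


def compute_leadfield(grid: SourceGrid, sensors: SensorArray, head: HeadModel) -> Leadfield:
    """Leadfield for every grid point under the spherical-conductor model.

    The gain of a radially oriented dipole is exactly zero at every
    sensor (q × r0 vanishes for q ∥ r0), and a source at the sphere
    center is silent by symmetry — both returned as zero columns, not
    errors.
    """
    dist_sens = np.linalg.norm(sensors.positions - head.center, axis=1)
    if np.any(dist_sens <= head.radius):
        raise GeometryError("all sensors must lie outside the conductor sphere")
    dist_src = np.linalg.norm(grid.points - head.center, axis=1)
    if np.any(dist_src >= head.radius):
        raise GeometryError("all grid points must lie inside the conductor sphere")
    gain = np.empty((sensors.n_chan, grid.n_vox, 3))
    for v in range(grid.n_vox):
        gain[:, v, :] = _dipole_gain(grid.points[v], sensors, head)
    return Leadfield(gain=gain)


def draw_tangential_orientations(grid: SourceGrid, head: HeadModel, seed: int = 0) -> np.ndarray:
    """One fixed tangential unit orientation per voxel.

    Tangential (⊥ to the radial direction) orientations guarantee that
    no source is silent under the spherical conductor model. The
    in-plane angle is drawn once per scenario.
    """
    rng = np.random.default_rng(seed)
    radial = grid.points - head.center
    nrm = np.linalg.norm(radial, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    radial = radial / nrm
    # build an orthonormal tangent basis per voxel
    helper = np.tile(np.array([1.0, 0.0, 0.0]), (grid.n_vox, 1))
    near_x = np.abs(radial[:, 0]) > 0.9
    helper[near_x] = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(radial, helper)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(radial, t1)
    ang = rng.uniform(0.0, 2.0 * np.pi, size=grid.n_vox)
    ori = np.cos(ang)[:, None] * t1 + np.sin(ang)[:, None] * t2
    return ori / np.linalg.norm(ori, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# scenario and source dynamics


@dataclass
class SimulationScenario:
    """Ground-truth description of one simulated recording session.

    Defaults follow the emulated acquisition: 71 target trials, 1200 Hz
    sampling, epochs −900–1800 ms around stimulus onset, ERD in the
    13–23 Hz low-beta band, a −400–0 ms baseline and a 600–1000 ms
    active window. Amplitudes are in ampere·meter (10 nAm-scale
    sources); ``noise_sd`` is the per-sample sensor noise in tesla.
    """

    n_trials: int = 71
    sfreq: float = 1200.0
    epoch_window: Tuple[float, float] = (-0.9, 1.8)
    erd_voxels: Tuple[int, ...] = ()
    erd_band: Tuple[float, float] = (13.0, 23.0)
    erd_depth: float = 0.0
    coupled_pairs: Tuple[Tuple[int, int, float], ...] = ()
    noise_sd: float = 1e-14
    seed: int = 0
    source_amp: float = 1e-8
    background_amp: float = 5e-9
    coupling_amp: float = 1e-8
    active_window: Tuple[float, float] = (0.6, 1.0)
    baseline_window: Tuple[float, float] = (-0.4, 0.0)
    latency_jitter: float = 0.0  # s; stimulus-locked response jitter, default none

    def __post_init__(self) -> None:
        t0, t1 = self.epoch_window
        if not (t0 < 0.0 < t1):
            raise ValueError("epoch window must straddle stimulus onset")
        if not (0.0 <= self.erd_depth <= 1.0):
            raise ValueError("erd_depth must be in [0, 1]")
        lo, hi = self.erd_band
        if not (0.0 < lo < hi < self.sfreq / 2.0):
            raise ValueError("erd_band must lie inside (0, Nyquist)")
        for pair in self.coupled_pairs:
            i, j, c = pair
            if i == j:
                raise ValueError("coupled pair must join two distinct voxels")
            if not (0.0 <= c <= 1.0):
                raise ValueError("coupling_strength must be in [0, 1]")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")

    def validate_against(self, grid: SourceGrid) -> None:
        idx = list(self.erd_voxels) + [i for p in self.coupled_pairs for i in p[:2]]
        for v in idx:
            if not (0 <= int(v) < grid.n_vox):
                raise ValueError(f"voxel index {v} outside grid of {grid.n_vox}")

    def times(self) -> np.ndarray:
        t0, t1 = self.epoch_window
        n = int(round((t1 - t0) * self.sfreq)) + 1  # inclusive endpoints
        return t0 + np.arange(n) / self.sfreq


def coupling_bin_frequencies(scenario: SimulationScenario, min_cycles: float = 2.0) -> np.ndarray:
    """DFT bin frequencies of the active window usable for planted coupling.

    Bins are multiples of 1/T (T the active-window duration) within
    3–30 Hz that complete at least ``min_cycles`` cycles in the window;
    for the default 400 ms window this is 5, 7.5, …, 30 Hz — the same
    bins the connectivity stage retains by default.
    """
    a0, a1 = scenario.active_window
    T = a1 - a0
    df = 1.0 / T
    f = np.arange(1, int(math.floor(30.0 * T)) + 1) * df
    return f[(f >= max(3.0, min_cycles / T)) & (f <= 30.0)]


def _one_over_f_noise(rng: np.random.Generator, shape: Tuple[int, ...], n: int, sfreq: float) -> np.ndarray:
    """Unit-variance 1/f-like noise along the last axis."""
    white = rng.standard_normal(shape + (n,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / sfreq)
    scale = 1.0 / np.sqrt(np.maximum(f, 1.0))
    spec *= scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _narrowband_noise(
    rng: np.random.Generator, shape: Tuple[int, ...], n: int, sfreq: float, band: Tuple[float, float]
) -> np.ndarray:
    """Unit-variance band-limited stochastic oscillation."""
    white = rng.standard_normal(shape + (n,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / sfreq)
    mask = (f >= band[0]) & (f <= band[1])
    spec *= mask
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_trial_sources(scenario: SimulationScenario, grid: SourceGrid) -> np.ndarray:
    """Generate per-trial voxel time courses (trials × n_vox × samples).

    ERD voxels carry a band-limited oscillation whose envelope power in
    the active window is (1 − erd_depth) × the baseline power; coupled
    pairs share trial-wise phases at multiplexed active-window DFT bins;
    all other voxels carry independent 1/f-like background noise.
    Deterministic for a fixed scenario seed.
    """
    scenario.validate_against(grid)
    lo, hi = scenario.erd_band
    if hi >= scenario.sfreq / 2.0:
        raise ValueError("erd_band exceeds Nyquist")
    rng = np.random.default_rng(scenario.seed)
    times = scenario.times()
    n = times.size
    n_vox = grid.n_vox
    src = np.zeros((scenario.n_trials, n_vox, n))

    erd_set = sorted(set(int(v) for v in scenario.erd_voxels))
    coupled_set = sorted(
        set(int(v) for p in scenario.coupled_pairs for v in p[:2]) - set(erd_set)
    )
    bg_vox = [v for v in range(n_vox) if v not in erd_set]

    # background 1/f noise on every non-ERD voxel (chunked to bound memory)
    if bg_vox and scenario.background_amp > 0:
        for start in range(0, len(bg_vox), 64):
            chunk = bg_vox[start : start + 64]
            src[:, chunk, :] += scenario.background_amp * _one_over_f_noise(
                rng, (scenario.n_trials, len(chunk)), n, scenario.sfreq
            )

    # ERD voxels: narrowband oscillation × envelope
    if erd_set:
        a0, a1 = scenario.active_window
        jit = (
            rng.uniform(-scenario.latency_jitter, scenario.latency_jitter, scenario.n_trials)
            if scenario.latency_jitter > 0
            else np.zeros(scenario.n_trials)
        )
        osc = scenario.source_amp * _narrowband_noise(
            rng, (scenario.n_trials, len(erd_set)), n, scenario.sfreq, scenario.erd_band
        )
        gain = math.sqrt(1.0 - scenario.erd_depth)
        for t in range(scenario.n_trials):
            env = np.ones(n)
            active = (times >= a0 + jit[t]) & (times < a1 + jit[t])
            env[active] = gain
            src[t, erd_set, :] += osc[t] * env[None, :]

    # coupled pairs: shared phases at disjoint active-window DFT bins
    if scenario.coupled_pairs:
        freqs = coupling_bin_frequencies(scenario)
        n_pairs = len(scenario.coupled_pairs)
        if n_pairs > freqs.size:
            raise ValueError(
                f"cannot multiplex {n_pairs} coupled pairs onto {freqs.size} bins"
            )
        k = freqs.size // n_pairs
        a0, a1 = scenario.active_window
        active_env = ((times >= a0) & (times < a1)).astype(float)
        tau = times - a0
        for p, (vi, vj, c) in enumerate(scenario.coupled_pairs):
            fset = freqs[p * k : (p + 1) * k]
            for f in fset:
                theta = rng.uniform(0.0, 2.0 * np.pi, scenario.n_trials)
                jit_i = (1.0 - c) * rng.uniform(-np.pi, np.pi, scenario.n_trials)
                jit_j = (1.0 - c) * rng.uniform(-np.pi, np.pi, scenario.n_trials)
                carrier = 2.0 * np.pi * f * tau
                # the second member lags by 90°: PLV is invariant to a
                # constant lag, but quadrature signals have zero
                # zero-lag correlation, so minimum-variance filters do
                # not cancel the planted pair as coherent sources
                src[:, int(vi), :] += (
                    scenario.coupling_amp
                    * np.cos(carrier[None, :] + (theta + jit_i)[:, None])
                    * active_env[None, :]
                )
                src[:, int(vj), :] += (
                    scenario.coupling_amp
                    * np.cos(carrier[None, :] + np.pi / 2.0 + (theta + jit_j)[:, None])
                    * active_env[None, :]
                )
    return src


def project_and_add_noise(
    sources: np.ndarray,
    leadfield: Leadfield,
    orientations: np.ndarray,
    noise_sd: float,
    seed: int,
    sfreq: float,
    times: np.ndarray,
    chan_pos: Optional[np.ndarray] = None,
    chan_ori: Optional[np.ndarray] = None,
) -> SensorEpochs:
    """Project source time courses to sensors and add i.i.d. Gaussian noise.

    ``data = Σ_vox gain · orientation · timecourse + N(0, noise_sd²)``;
    the projection is linear in source amplitude.
    """
    sources = np.asarray(sources, dtype=float)
    orientations = np.asarray(orientations, dtype=float)
    if sources.ndim != 3 or sources.shape[1] != leadfield.n_vox:
        raise ValueError("sources must be trials × n_vox × samples")
    norms = np.linalg.norm(orientations, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("orientation rows must have unit norm")
    gain_eff = np.einsum("cvk,vk->cv", leadfield.gain, orientations)  # chan × vox
    data = np.einsum("cv,tvs->tcs", gain_eff, sources)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return SensorEpochs(
        data=data, sfreq=sfreq, times=np.asarray(times, dtype=float),
        chan_pos=chan_pos, chan_ori=chan_ori,
    )


# ---------------------------------------------------------------------------
# parcel atlas


@dataclass
class ParcelAtlas:
    """Voxel → parcel label table with hemisphere and lobe annotations."""

    labels: np.ndarray  # n_vox ints
    names: Dict[int, str]
    hemisphere: Dict[int, str]  # L / R / midline
    lobe: Dict[int, str]  # frontal / temporal / other

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        for lab in np.unique(self.labels):
            if int(lab) not in self.names or int(lab) not in self.hemisphere or int(lab) not in self.lobe:
                raise ValueError(f"parcel {lab} is missing annotations")

    @property
    def parcel_ids(self) -> np.ndarray:
        return np.array(sorted(self.names.keys()))


def _lattice_neighbors(ijk: np.ndarray) -> Dict[int, list]:
    """6-neighbor adjacency among retained lattice points."""
    index = {tuple(p): i for i, p in enumerate(ijk)}
    nbrs: Dict[int, list] = {i: [] for i in range(len(ijk))}
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for i, p in enumerate(ijk):
        for d in offsets:
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            j = index.get(q)
            if j is not None:
                nbrs[i].append(j)
    return nbrs


def build_synthetic_atlas(
    grid: SourceGrid, n_parcels_per_hemisphere: int, seed: int = 0
) -> ParcelAtlas:
    """Partition the grid into mirrored, spatially contiguous parcels.

    Voxels are split into left (x < 0) and right hemispheres, the left
    hemisphere is clustered with k-means on coordinates, cluster seeds
    are mirrored to the right, and parcels are grown by multi-source
    breadth-first search on the 6-neighbor lattice so each parcel is one
    connected component. Mirrored parcel pairs receive matched
    frontal/temporal lobe annotations (split on the y coordinate of the
    seed).
    """
    k = int(n_parcels_per_hemisphere)
    if k < 2:
        raise ValueError("need at least 2 parcels per hemisphere")
    x = grid.points[:, 0]
    left = np.nonzero(x < 0)[0]
    right = np.nonzero(x >= 0)[0]
    if len(left) < k or len(right) < k:
        raise ValueError("fewer voxels than parcels in a hemisphere")

    rng = np.random.default_rng(seed)
    centers, _ = kmeans2(grid.points[left], k, seed=rng, minit="++")
    mirror = centers * np.array([-1.0, 1.0, 1.0])

    nbrs = _lattice_neighbors(grid.ijk)
    labels = np.full(grid.n_vox, -1, dtype=int)

    def grow(vox_idx: np.ndarray, seeds_xyz: np.ndarray, label_offset: int) -> None:
        member = set(int(v) for v in vox_idx)
        # seed voxel: nearest member voxel to each cluster center
        q: deque = deque()
        for c, ctr in enumerate(seeds_xyz):
            d = np.linalg.norm(grid.points[vox_idx] - ctr, axis=1)
            order = np.argsort(d)
            for o in order:
                v = int(vox_idx[o])
                if labels[v] == -1:
                    labels[v] = label_offset + c
                    q.append(v)
                    break
        while q:
            v = q.popleft()
            for w in nbrs[v]:
                if w in member and labels[w] == -1:
                    labels[w] = labels[v]
                    q.append(w)
        # voxels unreachable on the lattice (isolated islands): nearest seed
        for v in vox_idx:
            v = int(v)
            if labels[v] == -1:
                d = np.linalg.norm(seeds_xyz - grid.points[v], axis=1)
                labels[v] = label_offset + int(np.argmin(d))

    grow(left, centers, 0)
    grow(right, mirror, k)

    names: Dict[int, str] = {}
    hemis: Dict[int, str] = {}
    lobes: Dict[int, str] = {}
    for c in range(k):
        lobe = "frontal" if centers[c, 1] > 0 else "temporal"
        for lab, hemi in ((c, "L"), (k + c, "R")):
            names[lab] = f"{lobe.capitalize()}_{hemi}_{c:02d}"
            hemis[lab] = hemi
            lobes[lab] = lobe
    return ParcelAtlas(labels=labels, names=names, hemisphere=hemis, lobe=lobes)
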