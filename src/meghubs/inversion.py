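"""LCMV beamformer source estimation and differential band-power mapping.

The spatial filter is the classic linearly constrained minimum-variance
beamformer: for a voxel with (orientation-resolved) leadfield column l,

    w = C⁻¹ l / (lᵀ C⁻¹ l),

which passes the target source with unit gain while minimizing total
output variance. The covariance C is the "common filter" covariance,
pooled over the baseline and active windows of all kept trials, so one
set of weights serves both windows and power contrasts are not biased
by window-specific filters. C is regularized as
C + λ·mean(diag(C))·I with λ = 0.001 (the conventional reading of
"0.1% regularization").

A scalar beamformer is used: for each voxel the dipole orientation is
chosen in the tangential plane (the radial direction is silent under
the spherical conductor model) as the orientation maximizing unit-gain
output power — the eigenvector of the 2 × 2 matrix Lᵀ C⁻¹ L (over the
tangential basis) with the smallest eigenvalue, the standard
source-bearing orientation of the scalar beamformer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import linalg, signal

from .containers import SensorEpochs, SourceEstimate
from .synthetic import HeadModel, Leadfield, SourceGrid

logger = logging.getLogger(__name__)

__all__ = [
    "Covariance",
    "BeamformerWeights",
    "ERDMap",
    "common_covariance",
    "lcmv_weights",
    "project_sources",
    "trial_band_power",
    "differential_band_power",
    "localize_erd_peak",
]


@dataclass
class Covariance:
    """Sensor covariance (tesla²) with provenance."""

    matrix: np.ndarray
    window_spec: str = ""
    n_samples_used: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        C = self.matrix
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(C, C.T, atol=1e-12 * max(1.0, np.abs(C).max())):
            raise ValueError("covariance must be symmetric")
        w = np.linalg.eigvalsh(C)
        if w.min() < -1e-10 * max(w.max(), 1e-300):
            raise ValueError("covariance must be positive semi-definite")


@dataclass
class BeamformerWeights:
    """Per-voxel scalar spatial filters and selected orientations."""

    weights: np.ndarray  # n_vox × n_chan
    orientation: np.ndarray  # n_vox × 3 unit vectors (zero rows for silent voxels)
    regularization_lambda: float
    silent_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.silent_mask is None:
            self.silent_mask = np.zeros(self.weights.shape[0], dtype=bool)


@dataclass
class ERDMap:
    """Relative band-power change per voxel, with optional statistics.

    ``rel_power_change = (P_active − P_baseline) / P_baseline`` in the
    given band; negative values are event-related desynchrony. Voxels
    with zero baseline power carry NaN and are excluded from inference.
    """

    rel_power_change: np.ndarray
    band: Tuple[float, float]
    baseline_power: np.ndarray  # trials × n_vox
    active_power: np.ndarray  # trials × n_vox
    t_stat: Optional[np.ndarray] = None
    p_value: Optional[np.ndarray] = None
    significant_mask: Optional[np.ndarray] = None


def common_covariance(
    baseline_epochs: SensorEpochs, active_epochs: SensorEpochs
) -> Covariance:
    """Covariance pooled over the concatenated baseline and active windows.

    The per-window, per-channel mean (over all kept trials and samples)
    is removed before pooling, so the result is exactly the
    sample-count-weighted combination of the two within-window
    covariances.
    """
    if baseline_epochs.n_channels != active_epochs.n_channels:
        raise ValueError("window epochs must share the channel set")
    if baseline_epochs.n_trials < 2 or active_epochs.n_trials < 2:
        raise ValueError("need at least 2 trials per window")
    segs = []
    n_used = 0
    for ep in (baseline_epochs, active_epochs):
        d = ep.kept_data()  # trials × chan × samples
        x = np.moveaxis(d, 1, 0).reshape(d.shape[1], -1)  # chan × (trials·samples)
        x = x - x.mean(axis=1, keepdims=True)
        segs.append(x)
        n_used += x.shape[1]
    X = np.concatenate(segs, axis=1)
    C = (X @ X.T) / (X.shape[1] - 1)
    n_chan = C.shape[0]
    if np.linalg.matrix_rank(C) < n_chan:
        logger.info("common covariance is rank deficient (%d channels)", n_chan)
    return Covariance(matrix=C, window_spec="baseline+active common filter", n_samples_used=n_used)


def _tangential_basis(points: np.ndarray, center: np.ndarray) -> np.ndarray:
    """(n_vox, 3, 2) orthonormal bases of the plane ⊥ the radial direction."""
    radial = points - center
    nrm = np.linalg.norm(radial, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    u = radial / nrm
    helper = np.tile(np.array([1.0, 0.0, 0.0]), (len(points), 1))
    helper[np.abs(u[:, 0]) > 0.9] = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(u, helper)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(u, t1)
    return np.stack([t1, t2], axis=2)


def lcmv_weights(
    leadfield: Leadfield,
    cov: Covariance,
    lam: float = 0.001,
    grid: Optional[SourceGrid] = None,
    head: Optional[HeadModel] = None,
) -> BeamformerWeights:
    """Regularized scalar LCMV weights with per-voxel optimal orientation.

    ``grid`` and ``head`` supply the geometry for the tangential-plane
    orientation search; when omitted the basis is derived from the
    leadfield's own null direction per voxel via SVD.

    Voxels whose tangential leadfield is numerically zero (e.g. a grid
    point at the sphere center) are flagged silent and receive
    all-zero weights rather than an error.
    """
    C = cov.matrix
    n_chan = C.shape[0]
    if leadfield.n_chan != n_chan:
        raise ValueError("leadfield and covariance disagree on channel count")
    scale = float(np.mean(np.diag(C)))
    if scale <= 0:
        raise np.linalg.LinAlgError("covariance diagonal is not positive")
    C_reg = C + lam * scale * np.eye(n_chan)
    try:
        cho = linalg.cho_factor(C_reg)
    except linalg.LinAlgError as exc:  # pragma: no cover - diagnostic path
        raise np.linalg.LinAlgError(f"regularized covariance not SPD: {exc}")

    G = leadfield.gain  # chan × vox × 3
    n_vox = leadfield.n_vox
    if grid is not None and head is not None:
        T = _tangential_basis(grid.points, head.center)  # vox × 3 × 2
    else:
        # per-voxel dominant 2D subspace of the 3-column leadfield
        T = np.empty((n_vox, 3, 2))
        for v in range(n_vox):
            _, _, vt = np.linalg.svd(G[:, v, :], full_matrices=False)
            T[v] = vt[:2].T

    # C⁻¹ G for all voxels/orientations at once
    CiG = linalg.cho_solve(cho, G.reshape(n_chan, -1)).reshape(n_chan, n_vox, 3)
    A = np.einsum("cvi,cvj->vij", G, CiG)  # vox × 3 × 3, = GᵀC⁻¹G
    M = np.einsum("vik,vij,vjl->vkl", T, A, T)  # vox × 2 × 2

    weights = np.zeros((n_vox, n_chan))
    orientation = np.zeros((n_vox, 3))
    silent = np.zeros(n_vox, dtype=bool)
    lf_scale = np.median(np.sqrt(np.einsum("vii->v", A)))
    evals, evecs = np.linalg.eigh(M)  # ascending
    for v in range(n_vox):
        if not np.isfinite(M[v]).all() or np.sqrt(max(evals[v, -1], 0.0)) < 1e-8 * lf_scale:
            silent[v] = True
            continue
        # orientation solving the generalized problem on Lᵀ C_reg⁻¹ L:
        # the eigenvector with the smallest eigenvalue maximizes the
        # unit-gain output power 1/(lᵀC⁻¹l) — the source-bearing
        # orientation of the scalar beamformer
        u2 = evecs[v][:, 0]
        ori = T[v] @ u2
        ori = ori / np.linalg.norm(ori)
        l = G[:, v, :] @ ori
        Cil = CiG[:, v, :] @ ori
        denom = float(l @ Cil)
        weights[v] = Cil / denom
        orientation[v] = ori
    if silent.any():
        logger.info("flagged %d silent voxels", int(silent.sum()))
    return BeamformerWeights(
        weights=weights, orientation=orientation,
        regularization_lambda=lam, silent_mask=silent,
    )


def project_sources(weights: BeamformerWeights, epochs: SensorEpochs) -> SourceEstimate:
    """Apply the spatial filters: ``source[t, v, s] = w_v · data[t, :, s]``.

    Linear in the sensor data; silent voxels yield all-zero time courses.
    """
    if weights.weights.shape[1] != epochs.n_channels:
        raise ValueError("weights and epochs disagree on channel count")
    data = np.einsum("vc,tcs->tvs", weights.weights, epochs.kept_data())
    return SourceEstimate(data=data, sfreq=epochs.sfreq, times=epochs.times)


def trial_band_power(
    source_data: np.ndarray, sfreq: float, band: Tuple[float, float]
) -> np.ndarray:
    """Per-trial, per-voxel band power from a Hann-tapered periodogram.

    Bins whose center frequency lies inside ``[lo, hi]`` are summed.
    Returns trials × n_vox.
    """
    freqs, psd = signal.periodogram(
        source_data, fs=sfreq, window="hann", detrend=False, axis=-1
    )
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError(f"no periodogram bin inside band {band}")
    return psd[..., sel].sum(axis=-1)


def differential_band_power(
    sources_baseline: SourceEstimate,
    sources_active: SourceEstimate,
    band: Tuple[float, float] = (13.0, 23.0),
) -> ERDMap:
    """Relative active-vs-baseline band power change per voxel.

    Band power is averaged over trials in each window before forming
    ``(P_act − P_base) / P_base``. Voxels with zero baseline power get
    NaN (excluded from statistics).
    """
    if sources_baseline.n_trials != sources_active.n_trials:
        raise ValueError("windows must contain the same trials")
    if sources_baseline.data.shape[2] != sources_active.data.shape[2]:
        raise ValueError("windows must have equal sample counts")
    pb = trial_band_power(sources_baseline.data, sources_baseline.sfreq, band)
    pa = trial_band_power(sources_active.data, sources_active.sfreq, band)
    mb = pb.mean(axis=0)
    ma = pa.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (ma - mb) / mb
    rel[mb == 0] = np.nan
    return ERDMap(
        rel_power_change=rel, band=band, baseline_power=pb, active_power=pa
    )


def output_variance_map(weights: BeamformerWeights, cov: Covariance) -> np.ndarray:
    """Beamformer output variance per voxel, ``w_vᵀ C w_v``.

    The argmax localizes a dominant source; silent voxels report zero.
    """
    var = np.einsum("vc,cd,vd->v", weights.weights, cov.matrix, weights.weights)
    var[weights.silent_mask] = 0.0
    return var


def localize_erd_peak(erdmap: ERDMap) -> int:
    """Voxel with the strongest relative power change (largest |rel|)."""
    rel = np.where(np.isfinite(erdmap.rel_power_change), np.abs(erdmap.rel_power_change), -np.inf)
    return int(np.argmax(rel))
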