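"""Voxel-pair phase-locking connectivity on broadband source estimates.

For every trial and voxel, a Hann-tapered DFT of the analysis window
yields one phase per retained frequency bin. The phase-locking value of
a voxel pair (a, b) at bin ω is

    PLV(ω) = | (1/N) Σ_trials exp(j (φ_a(ω) − φ_b(ω))) |,

1 for perfect trial-wise locking, ≈ √(π/4N) in expectation for
independent phases. The broadband summary is the unweighted mean of the
bin-wise PLV over retained bins, and the task-related adjacency is the
active-window PLV minus the baseline-window PLV per pair.

With the default 400 ms windows the DFT bin spacing is 2.5 Hz and bins
must complete ≥ 2 cycles in the window, retaining 5, 7.5, …, 30 Hz;
the 3–5 Hz edge of the nominal 3–30 Hz band is not resolvable at this
window length and is excluded by default (``min_cycles`` overrides).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .containers import SourceEstimate

__all__ = ["PhaseTensor", "AdjacencyMatrix", "trial_spectral_phases", "plv_adjacency"]


@dataclass
class PhaseTensor:
    """Per-trial spectral phases: trials × n_vox × n_bins, radians."""

    phases: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.phases.ndim != 3 or self.phases.shape[2] != self.freqs.size:
            raise ValueError("phases must be trials × voxels × bins matching freqs")
        if not np.all(np.isfinite(self.phases)):
            raise ValueError("phases must be finite")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")


@dataclass
class AdjacencyMatrix:
    """Symmetric voxel × voxel task-related PLV difference in [−1, 1]."""

    values: np.ndarray
    window_spec: str = "active-minus-baseline"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        V = self.values
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(V, V.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.abs(np.diag(V)) > 1e-12):
            raise ValueError("adjacency diagonal must be zero")

    @property
    def n_vox(self) -> int:
        return self.values.shape[0]


def trial_spectral_phases(
    sources: SourceEstimate,
    band: Tuple[float, float] = (3.0, 30.0),
    min_cycles: float = 2.0,
) -> PhaseTensor:
    """Hann-tapered DFT phases per trial, voxel and retained bin.

    Retained bins lie inside ``band`` and complete at least
    ``min_cycles`` cycles in the window.
    """
    n = sources.data.shape[2]
    sfreq = sources.sfreq
    T = n / sfreq
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    f_lo = max(band[0], min_cycles / T)
    sel = (freqs >= f_lo - 1e-9) & (freqs <= band[1] + 1e-9)
    sel[0] = False  # DC carries no phase information
    if not sel.any():
        raise ValueError(
            f"window of {T:.3f}s too short for any bin in {band} at ≥{min_cycles} cycles"
        )
    taper = np.hanning(n)
    spec = np.fft.rfft(sources.data * taper[None, None, :], axis=2)
    return PhaseTensor(phases=np.angle(spec[:, :, sel]), freqs=freqs[sel])


def _plv_matrix(phases: np.ndarray) -> np.ndarray:
    """Bin-averaged PLV matrix from a trials × vox × bins phase array."""
    n_trials, n_vox, n_bins = phases.shape
    Z = np.exp(1j * phases)
    acc = np.zeros((n_vox, n_vox))
    for b in range(n_bins):
        Zb = Z[:, :, b]  # trials × vox
        M = (Zb.conj().T @ Zb) / n_trials  # vox × vox trial-averaged phasor
        plv_b = np.abs(M)
        assert plv_b.max() <= 1.0 + 1e-9, "PLV must not exceed 1"
        acc += plv_b
    return acc / n_bins


def plv_adjacency(
    phases_active: PhaseTensor, phases_baseline: PhaseTensor
) -> AdjacencyMatrix:
    """Task-related adjacency: active-window PLV minus baseline-window PLV.

    Within-window PLV is computed per bin and averaged over retained
    bins; the difference isolates task-related coupling. Symmetric with
    zero diagonal; entries in [−1, 1].
    """
    if phases_active.phases.shape != phases_baseline.phases.shape:
        raise ValueError("phase tensors must share trials, voxels and bins")
    if not np.allclose(phases_active.freqs, phases_baseline.freqs):
        raise ValueError("phase tensors must share frequency bins")
    if phases_active.phases.shape[0] < 2:
        raise ValueError("PLV is degenerate with fewer than 2 trials")
    diff = _plv_matrix(phases_active.phases) - _plv_matrix(phases_baseline.phases)
    diff = 0.5 * (diff + diff.T)
    np.fill_diagonal(diff, 0.0)
    return AdjacencyMatrix(values=diff)
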