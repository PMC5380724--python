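"""Shared in-memory containers for the sensor → source → network pipeline.

Conventions used throughout the package:

* SI units everywhere: positions in meters, magnetic field in tesla,
  dipole moments in ampere·meter, time in seconds.
* Time axes are relative to stimulus onset (t = 0 at onset).
* Epoched data are ``trials × channels × samples`` arrays.
* Analysis windows are half-open ``[t0, t1)`` in sample selection, so a
  400 ms baseline and a 400 ms active window always contain the same
  number of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "GeometryError",
    "SensorEpochs",
    "SourceEstimate",
    "WindowPair",
    "window_slice",
]


class GeometryError(ValueError):
    """Raised for invalid head/sensor/grid geometry."""


@dataclass
class SensorEpochs:
    """Epoched multichannel magnetometer data.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Magnetic field in tesla.
    sfreq : float
        Sampling rate in Hz.
    times : ndarray, shape (n_samples,)
        Seconds relative to stimulus onset; strictly increasing,
        uniformly spaced at 1/sfreq.
    chan_pos, chan_ori : ndarray, shape (n_channels, 3) or None
        Sensor positions (m) and unit sensitive axes.
    events : ndarray or None
        Event onset times (s) in the original continuous recording.
    trial_keep_mask : ndarray of bool, shape (n_trials,)
        Trials surviving artifact rejection. All stages preserve trial
        identity; rejection only flips this mask.
    """

    data: np.ndarray
    sfreq: float
    times: np.ndarray
    chan_pos: Optional[np.ndarray] = None
    chan_ori: Optional[np.ndarray] = None
    events: Optional[np.ndarray] = None
    trial_keep_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials × channels × samples")
        if self.times.shape != (self.data.shape[2],):
            raise ValueError("times length must match the sample axis")
        dt = np.diff(self.times)
        if dt.size and not np.allclose(dt, 1.0 / self.sfreq, rtol=0, atol=1e-9):
            raise ValueError("times must be uniformly spaced at 1/sfreq")
        if self.trial_keep_mask is None:
            self.trial_keep_mask = np.ones(self.data.shape[0], dtype=bool)
        self.trial_keep_mask = np.asarray(self.trial_keep_mask, dtype=bool)
        if self.trial_keep_mask.shape != (self.data.shape[0],):
            raise ValueError("trial_keep_mask must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def kept_data(self) -> np.ndarray:
        """Data restricted to trials with ``trial_keep_mask`` true."""
        return self.data[self.trial_keep_mask]

    def copy_with(self, **changes) -> "SensorEpochs":
        out = replace(self, **changes)
        return out


@dataclass
class SourceEstimate:
    """Per-trial voxel time courses produced by a spatial filter.

    ``data`` is trials × n_voxels × samples in nominal ampere·meter.
    """

    data: np.ndarray
    sfreq: float
    times: np.ndarray
    grid_points: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials × voxels × samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("source estimate contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class WindowPair:
    """Baseline and active analysis windows (seconds, half-open).

    Defaults follow the verb-generation design: a −400–0 ms pre-stimulus
    baseline and a 600–1000 ms active window capturing the delayed
    response to auditory stimuli. The two windows must have equal
    duration so paired power comparisons use equal sample counts.
    """

    baseline: tuple = (-0.400, 0.000)
    active: tuple = (0.600, 1.000)

    def __post_init__(self) -> None:
        b0, b1 = self.baseline
        a0, a1 = self.active
        if not (b0 < b1 <= 0.0 < a0 < a1):
            raise ValueError("baseline must end at/before 0 and active start after 0")
        if abs((b1 - b0) - (a1 - a0)) > 1e-12:
            raise ValueError("baseline and active windows must have equal duration")


def window_slice(times: np.ndarray, window: tuple, sfreq: float) -> slice:
    """Half-open sample slice covering ``[t0, t1)``.

    Sample i is included iff t0 − ε ≤ times[i] < t1 − ε with ε a half
    sample tolerance, so windows whose edges fall exactly on the sample
    grid select exactly ``round((t1 − t0)·sfreq)`` samples.
    """
    t0, t1 = window
    tol = 0.5 / sfreq
    if t0 < times[0] - tol or t1 > times[-1] + 1.0 / sfreq + tol:
        raise ValueError(f"window {window} outside epoch extent")
    eps = 1e-3 / sfreq
    idx = np.nonzero((times >= t0 - eps) & (times < t1 - eps))[0]
    if idx.size == 0:
        raise ValueError(f"window {window} selects no samples")
    return slice(int(idx[0]), int(idx[-1]) + 1)
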