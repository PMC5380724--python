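"""Permutation inference for paired window contrasts and BH-FDR control.

The exchangeability unit for the paired active-vs-baseline contrast is
the trial: under the null the window labels within a trial are
exchangeable, so each Monte-Carlo randomization flips the
active/baseline assignment in a random subset of trials (a sign flip of
the per-trial difference) and recomputes the paired t statistic.
P-values use the add-one rule p = (1 + #{|t*| ≥ |t|}) / (1 + n_rand),
which never returns zero and keeps the test valid at any n_rand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["PermutationResult", "paired_t", "permutation_erd_test", "fdr_bh"]


@dataclass
class PermutationResult:
    observed_t: np.ndarray
    p_values: np.ndarray
    n_randomizations: int
    seed: int


def paired_t(active_power: np.ndarray, baseline_power: np.ndarray) -> np.ndarray:
    """Classical paired t on per-trial differences, per voxel.

    ``t = mean(d) / (sd(d) / √n)`` with d = active − baseline. Voxels
    whose differences have zero variance get ``±inf`` with the sign of
    the mean (0/0 gives NaN).
    """
    a = np.asarray(active_power, dtype=float)
    b = np.asarray(baseline_power, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have identical shape")
    n = a.shape[0]
    if n < 3:
        raise ValueError("paired t needs at least 3 trials")
    d = a - b
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    zero_var = sd == 0
    if np.any(zero_var):
        t = np.where(zero_var, np.sign(m) * np.inf, t)
        t = np.where(zero_var & (m == 0), np.nan, t)
    return t


def permutation_erd_test(
    active_power: np.ndarray,
    baseline_power: np.ndarray,
    n_rand: int = 5000,
    seed: int = 0,
) -> PermutationResult:
    """Monte-Carlo sign-flip test of the paired window contrast.

    Each randomization flips the active/baseline assignment within a
    random subset of trials; two-sided p per voxel via the add-one rule.
    Deterministic for a fixed seed.
    """
    a = np.asarray(active_power, dtype=float)
    b = np.asarray(baseline_power, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have identical shape")
    if n_rand < 100:
        warnings.warn("n_rand < 100 gives an unstable p-value floor", stacklevel=2)
    n_trials = a.shape[0]
    d = a - b  # trials × vox
    t_obs = paired_t(a, b)
    rng = np.random.default_rng(seed)
    flips = rng.integers(0, 2, size=(n_rand, n_trials)) * 2 - 1  # ±1
    # sum(d²) is flip-invariant, so t* needs only the flipped mean
    sum_d2 = np.sum(d * d, axis=0)  # (vox,)
    m_star = (flips @ d) / n_trials  # n_rand × vox
    var_star = (sum_d2[None, :] - n_trials * m_star**2) / (n_trials - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_star = m_star / np.sqrt(var_star / n_trials)
    abs_obs = np.abs(t_obs)
    exceed = np.sum(np.abs(t_star) >= abs_obs[None, :], axis=0)
    # voxels with NaN t (e.g. all-zero differences) get p = 1
    p = (1.0 + exceed) / (1.0 + n_rand)
    p = np.where(np.isnan(t_obs), 1.0, p)
    return PermutationResult(observed_t=t_obs, p_values=p, n_randomizations=n_rand, seed=seed)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up false-discovery-rate control.

    Rejects all hypotheses with p(i) ≤ i·q/m for the largest such i
    (sorted ascending). NaN entries are excluded from the family and
    never rejected. Returns a boolean mask aligned with the input.
    """
    p = np.asarray(p_values, dtype=float)
    mask = np.zeros(p.shape, dtype=bool)
    valid = np.isfinite(p)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return mask
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(pv, kind="stable")
    thresh = (np.arange(1, m + 1) * q) / m
    below = pv[order] <= thresh
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        rej = np.zeros(m, dtype=bool)
        rej[order[: k + 1]] = True
        mask[valid] = rej
    return mask
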