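"""Circular and permutation statistics for the evaluation stack.

The Rayleigh test checks whether heartbeats are phase-locked to the stimulus
train (each stimulus is assigned the angle 2*pi * elapsed fraction of the RR
interval it falls into). The max-T sign-flip permutation t-test compares
paired per-participant metric values across methods with family-wise error
control.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)


def rayleigh_test(angles: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Returns (mean resultant length R-bar, p-value) using the standard
    closed-form approximation p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n))
    with Rn = n * R-bar.
    """
    angles = np.asarray(angles, float)
    n = len(angles)
    if n == 0:
        raise ValueError("no angles")
    rbar = float(np.abs(np.mean(np.exp(1j * angles))))
    rn = n * rbar
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n ** 2 - rn ** 2)) - (1 + 2 * n))
    return rbar, float(min(p, 1.0))


def stimulus_cardiac_angles(stim_samples: np.ndarray, r_peaks: np.ndarray,
                            srate: float) -> np.ndarray:
    """Angle of each stimulus within its current RR interval.

    angle = 2*pi * (t_stim - t_lastR) / RR_current. Stimuli before the first
    or after the last R-peak have no enclosing interval and are dropped.
    """
    stim = np.asarray(stim_samples, float)
    r = np.asarray(r_peaks, float)
    if len(r) < 2:
        raise ValueError("need at least 2 R-peaks")
    idx = np.searchsorted(r, stim, side="right") - 1
    ok = (idx >= 0) & (idx < len(r) - 1)
    if (~ok).sum():
        logger.info("%d stimuli outside the R-peak span dropped", int((~ok).sum()))
    last_r = r[idx[ok]]
    rr = r[idx[ok] + 1] - last_r
    return 2 * np.pi * (stim[ok] - last_r) / rr


def rayleigh_locking(stim_samples, r_peaks, srate: float) -> tuple[float, float]:
    """Rayleigh test of cardiac-cycle locking to the stimulus train."""
    angles = stimulus_cardiac_angles(stim_samples, r_peaks, srate)
    return rayleigh_test(angles)


def _t_stats(diffs: np.ndarray) -> np.ndarray:
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def maxt_permutation_tests(diffs: np.ndarray, n_perm: int = 10000,
                           seed: int = 0) -> dict:
    """One-sample, two-tailed sign-flip permutation t-tests with max-T FWE.

    ``diffs`` is (n_comparisons, n_subjects) of paired differences. Returns a
    dict with observed t statistics, raw permutation p-values, and max-T
    adjusted p-values (adjusted >= raw always).
    """
    diffs = np.atleast_2d(np.asarray(diffs, float))
    n_cmp, n_sub = diffs.shape
    if n_sub < 5:
        raise ValueError("need at least 5 paired observations per comparison")
    if n_perm < 100:
        logger.warning("n_perm=%d gives a very coarse p-value resolution", n_perm)
    rng = np.random.default_rng(seed)
    t_obs = _t_stats(diffs)
    abs_obs = np.abs(t_obs)
    count_raw = np.zeros(n_cmp)
    count_max = np.zeros(n_cmp)
    block = 500   # permutations per vectorised block, keeps memory flat
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        signs = rng.choice((-1.0, 1.0), size=(b, 1, n_sub))
        t_perm = np.abs(_t_stats_3d(diffs[None] * signs))
        count_raw += (t_perm >= abs_obs[None]).sum(axis=0)
        count_max += (t_perm.max(axis=1, keepdims=True) >= abs_obs[None]).sum(axis=0)
        done += b
    p_raw = (count_raw + 1) / (n_perm + 1)
    p_adj = (count_max + 1) / (n_perm + 1)
    return {"t": t_obs, "p_raw": np.minimum(p_raw, 1.0),
            "p_adjusted": np.minimum(p_adj, 1.0)}


def _t_stats_3d(diffs: np.ndarray) -> np.ndarray:
    n = diffs.shape[2]
    mean = diffs.mean(axis=2)
    sd = diffs.std(axis=2, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
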