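"""Spatial-subspace cardiac cleaning: SSP, CCA average regression, DSS.

All three methods assume the cardiac artefact occupies a low-dimensional,
temporally stable spatial subspace of the multichannel data:

* SSP extracts orthonormal projection vectors from the SVD of the R-peak-locked
  average and removes their span with the projector I - U_k U_k^T.
* CCA average regression finds spatial filters maximising the correlation
  between concatenated single-beat epochs (X) and the repeated beat average
  (Y); components ranked by canonical correlation are zeroed and the data
  back-projected.
* DSS jointly diagonalises the covariance C0 of the raw data and the
  covariance C1 of the beat-averaged (bias-filtered) data; components are
  ranked by the power ratio (generalized eigenvalue), the first being the most
  beat-repeatable linear combination of sensors.

The number of components to remove is chosen by the weighted elbow rule
(0.5 idxRI + 0.5 idxINPSR + 1 idxSNR) / 2, where idxRI/idxINPSR are Kneedle
elbows of the metric-versus-k curves and idxSNR the SNR argmax.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .recording import EpochSet, Recording

logger = logging.getLogger(__name__)


@dataclass
class SpatialFilterSet:
    """Unmixing filters, mixing patterns, and per-component ranking scores.

    ``filters`` W is (n_components, n_channels); components = W @ data.
    ``patterns`` A is (n_channels, n_components); data ~ A @ components.
    ``scores`` are non-increasing: singular values (SSP), canonical
    correlations (CCA) or power ratios (DSS). ``channels`` records which
    recording channels the filters act on.
    """

    filters: np.ndarray
    patterns: np.ndarray
    scores: np.ndarray
    method: str
    channels: list[str]

    @property
    def n_components(self) -> int:
        return self.filters.shape[0]


@dataclass
class CountSelection:
    """Outcome of the weighted projector/component-count rule."""

    idx_ri: int
    idx_inpsr: int
    idx_snr: int

    @property
    def chosen(self) -> int:
        x = (0.5 * self.idx_ri + 0.5 * self.idx_inpsr + 1.0 * self.idx_snr) / 2.0
        return int(math.floor(x + 0.5))   # ties (x.5) round up


def _sym_inv_sqrt(C: np.ndarray, shrinkage: float = 1e-9) -> np.ndarray:
    """Inverse matrix square root with relative shrinkage regularisation."""
    n = C.shape[0]
    C = C + shrinkage * np.trace(C) / n * np.eye(n)
    w, V = np.linalg.eigh(C)
    w = np.clip(w, np.finfo(float).tiny, None)
    return (V / np.sqrt(w)) @ V.T


# ---------------------------------------------------------------- SSP

def compute_ssp(epochs: EpochSet, n_proj: int = 5,
                ssp_source: str = "evoked") -> SpatialFilterSet:
    """Projection vectors from R-peak-locked epochs.

    'evoked' (default) takes the top left singular vectors of the epoch
    average (channels x time); 'covariance' uses the epoch covariance instead.
    """
    n_ch = epochs.data.shape[1]
    if n_proj >= n_ch:
        raise ValueError(f"n_proj={n_proj} must be < n_channels={n_ch}")
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 epochs")
    if ssp_source == "evoked":
        evoked = epochs.average()
        U, s, _ = np.linalg.svd(evoked - evoked.mean(axis=1, keepdims=True),
                                full_matrices=False)
    elif ssp_source == "covariance":
        X = epochs.data.transpose(1, 0, 2).reshape(n_ch, -1)
        X = X - X.mean(axis=1, keepdims=True)
        w, V = np.linalg.eigh(X @ X.T / X.shape[1])
        U, s = V[:, ::-1], np.sqrt(np.clip(w[::-1], 0, None))
    else:
        raise ValueError("ssp_source must be 'evoked' or 'covariance'")
    U = U[:, :n_proj]
    return SpatialFilterSet(filters=U.T, patterns=U, scores=s[:n_proj],
                            method="ssp", channels=list(epochs.labels))


def apply_projection(rec: Recording, filters: SpatialFilterSet, k: int) -> Recording:
    """Remove span(U_k) from the data: x <- (I - U_k U_k^T) x. ECG untouched."""
    if k > filters.n_components:
        raise IndexError(f"k={k} > {filters.n_components} available projectors")
    out = rec.copy()
    if k == 0:
        return out
    idx = rec.picks(labels=filters.channels)
    U, _ = np.linalg.qr(filters.filters[:k].T)   # orthonormalise first k vectors
    X = out.data[idx]
    out.data[idx] = X - U @ (U.T @ X)
    return out


# ---------------------------------------------------------------- CCA

def cca_average_regression(X: np.ndarray, Y: np.ndarray,
                           shrinkage: float = 1e-9,
                           channels: list[str] | None = None,
                           method: str = "cca") -> SpatialFilterSet:
    """Canonical correlation between single-trial data and its repeated average.

    X and Y are (n_channels, n_samples) with identical shapes. Solved by SVD
    of the whitened cross-covariance; filters satisfy W Cxx W^T = I, patterns
    are Cxx W^T (which equals inv(W) for square full-rank W).
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape:
        raise ValueError("X and Y must have identical shapes")
    n_ch, n = X.shape
    if n < n_ch:
        raise ValueError("need at least as many samples as channels")
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Cxx = Xc @ Xc.T / n
    Cyy = Yc @ Yc.T / n
    Cxy = Xc @ Yc.T / n
    Wx_half = _sym_inv_sqrt(Cxx, shrinkage)
    Wy_half = _sym_inv_sqrt(Cyy, shrinkage)
    U, s, _ = np.linalg.svd(Wx_half @ Cxy @ Wy_half)
    W = (Wx_half @ U).T                       # (n_comp, n_ch), W Cxx W^T = I
    A = Cxx @ W.T                             # Haufe-style patterns
    scores = np.clip(s, 0.0, 1.0)
    if channels is None:
        channels = [f"ch{i}" for i in range(n_ch)]
    return SpatialFilterSet(filters=W, patterns=A, scores=scores,
                            method=method, channels=list(channels))


def beat_cca(rec: Recording, tmin: float = -0.4, tmax: float = 0.6) -> SpatialFilterSet:
    """CCA-cardiac: single-beat concatenation vs repeated beat average."""
    from .recording import epoch
    ep = epoch(rec, "r_peak", tmin, tmax, picks=rec.esg_picks)
    n_tr, n_ch, n_t = ep.data.shape
    X = ep.data.transpose(1, 0, 2).reshape(n_ch, n_tr * n_t)
    avg = ep.average()
    Y = np.tile(avg, (1, n_tr))
    return cca_average_regression(X, Y, channels=ep.labels, method="cca")


def remove_components(rec: Recording, filters: SpatialFilterSet, k: int) -> Recording:
    """Zero the top-k components on continuous data and back-project."""
    if k > filters.n_components:
        raise IndexError(f"k={k} > {filters.n_components} components")
    out = rec.copy()
    idx = rec.picks(labels=filters.channels)
    W, A = filters.filters, filters.patterns
    if W.shape[0] != W.shape[1]:
        raise np.linalg.LinAlgError("component removal needs a square filter matrix")
    comps = W @ out.data[idx]
    comps[:k] = 0.0
    out.data[idx] = A @ comps
    return out


# ---------------------------------------------------------------- DSS

def dss_from_covariances(C0: np.ndarray, C1: np.ndarray,
                         shrinkage: float = 1e-9,
                         channels: list[str] | None = None) -> SpatialFilterSet:
    """Joint diagonalisation of (C1, C0): whiten by C0, eigendecompose C1.

    Scores are the power ratios (biased power / raw power), descending.
    Filters satisfy w_i^T C0 w_j = delta_ij.
    """
    W0 = _sym_inv_sqrt(C0, shrinkage)
    M = W0 @ C1 @ W0
    w, V = np.linalg.eigh((M + M.T) / 2)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    W = (W0 @ V).T
    A = C0 @ W.T
    if channels is None:
        channels = [f"ch{i}" for i in range(C0.shape[0])]
    return SpatialFilterSet(filters=W, patterns=A, scores=np.clip(w, 0, None),
                            method="dss", channels=list(channels))


def dss(rec: Recording, bias_epochs: EpochSet,
        shrinkage: float = 1e-9) -> SpatialFilterSet:
    """DSS-cardiac: C0 from the continuous data, C1 from the beat average."""
    idx = rec.picks(labels=bias_epochs.labels)
    X = rec.data[idx]
    Xc = X - X.mean(axis=1, keepdims=True)
    C0 = Xc @ Xc.T / X.shape[1]
    avg = bias_epochs.average()
    if np.allclose(avg, 0):
        raise ValueError("bias average is zero; DSS undefined")
    B = avg - avg.mean(axis=1, keepdims=True)
    C1 = B @ B.T / B.shape[1]
    return dss_from_covariances(C0, C1, shrinkage, channels=bias_epochs.labels)


# --------------------------------------------- component-count selection

def kneedle_elbow(k: np.ndarray, y: np.ndarray, name: str = "metric") -> int:
    """Discrete elbow: max perpendicular distance to the chord on normalised axes.

    The curve is normalised to [0, 1] on both axes and flipped to increasing
    if needed; equals the point of maximum curvature for convex monotone
    curves.
    """
    k = np.asarray(k, float)
    y = np.asarray(y, float)
    if np.ptp(y) == 0:
        raise ValueError(f"elbow undefined: {name} curve is constant")
    x = (k - k[0]) / (k[-1] - k[0])
    yn = (y - y.min()) / np.ptp(y)
    if yn[-1] < yn[0]:
        yn = 1.0 - yn
    # distance from each point to the chord joining the endpoints
    p0, p1 = np.array([x[0], yn[0]]), np.array([x[-1], yn[-1]])
    d = p1 - p0
    d /= np.linalg.norm(d)
    rel = np.stack([x - p0[0], yn - p0[1]], axis=1)
    dist = np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0])
    return int(k[int(np.argmax(dist))])


def select_component_count(k_grid, ri_curve, inpsr_curve, snr_curve) -> CountSelection:
    """Weighted projector-count rule over RI(k), INPSR(k), SNR(k) curves."""
    k_grid = np.asarray(k_grid)
    for c in (ri_curve, inpsr_curve, snr_curve):
        if len(c) != len(k_grid):
            raise ValueError("curves must share the k grid")
    idx_ri = kneedle_elbow(k_grid, np.asarray(ri_curve), "RI")
    idx_inpsr = kneedle_elbow(k_grid, np.asarray(inpsr_curve), "INPSR")
    idx_snr = int(k_grid[int(np.argmax(snr_curve))])
    return CountSelection(idx_ri=idx_ri, idx_inpsr=idx_inpsr, idx_snr=idx_snr)
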