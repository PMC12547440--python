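"""Per-channel cardiac artefact subtraction with optimal basis sets (PCA-OBS).

Each channel is treated independently. A window of +/- half the median RR
interval is extracted around every R-peak; PCA across these beat occurrences
yields the leading principal components, which together with the mean artefact
("mean effect") form the optimal basis set. The basis is least-squares fitted
to every occurrence and the fitted artefact subtracted. An optional Tukey
taper (alpha = 0.25) on the fitted artefact suppresses the sharp edges the
subtraction otherwise leaves at window boundaries. PCHIP interpolation maps
the fitted window onto clipped or irregular sample grids at the recording
edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal.windows import tukey

from .recording import EventList, Recording

logger = logging.getLogger(__name__)

DEFAULT_N_PCS = 4
TUKEY_ALPHA = 0.25


@dataclass
class ObsBasis:
    """Optimal basis set: mean effect + leading PCs over one beat window."""

    window: tuple[int, int]            # (pre, post) samples relative to R-peak
    regressors: np.ndarray             # (window_len, 1 + n_pcs)
    n_pcs: int
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def window_len(self) -> int:
        return self.regressors.shape[0]


@dataclass
class FittedBeat:
    beat_sample: int
    coefficients: np.ndarray           # length 1 + n_pcs
    fitted: np.ndarray                 # over the (possibly clipped) window
    start: int                         # first sample index covered
    clipped: bool


def _window_half(r_peaks: np.ndarray, srate: float, fraction: float) -> int:
    if len(r_peaks) < 2:
        raise ValueError("need at least 2 R-peaks to define the median RR interval")
    median_rr = np.median(np.diff(r_peaks)) / srate
    return int(round(fraction * median_rr * srate))


def build_beat_matrix(channel: np.ndarray, r_peaks: EventList | np.ndarray,
                      srate: float, window_fraction: float = 0.5
                      ) -> tuple[np.ndarray, np.ndarray, int]:
    """Stack one row per beat occurrence over +/- window_fraction * medianRR.

    Returns ``(beats, full, half)``: the (n_beats, 2*half+1) matrix (clipped
    beats zero-padded), a boolean mask of rows whose window fit entirely inside
    the recording, and the half-window in samples.
    """
    peaks = r_peaks.r_peaks if isinstance(r_peaks, EventList) else np.asarray(r_peaks)
    channel = np.asarray(channel, dtype=np.float64).ravel()
    half = _window_half(peaks, srate, window_fraction)
    n = len(channel)
    beats = np.zeros((len(peaks), 2 * half + 1))
    full = np.ones(len(peaks), dtype=bool)
    for i, p in enumerate(peaks):
        a, b = p - half, p + half + 1
        ca, cb = max(a, 0), min(b, n)
        beats[i, ca - a:(ca - a) + (cb - ca)] = channel[ca:cb]
        full[i] = (a >= 0) and (b <= n)
    if not full.all():
        logger.info("%d of %d beat windows clipped at recording edges",
                    (~full).sum(), len(peaks))
    return beats, full, half


def compute_obs(beats: np.ndarray, n_pcs: int = DEFAULT_N_PCS,
                half: int | None = None) -> ObsBasis:
    """Mean effect + first ``n_pcs`` principal components of the occurrences.

    PCA runs on mean-removed occurrences; components are ordered by descending
    explained variance.
    """
    beats = np.asarray(beats, dtype=np.float64)
    n_beats, win = beats.shape
    if n_beats <= n_pcs:
        raise ValueError(f"{n_beats} beats cannot support {n_pcs} PCs")
    mean = beats.mean(axis=0)
    centred = beats - mean
    # SVD of the occurrence matrix == eigendecomposition of its covariance
    _, sv, vt = np.linalg.svd(centred, full_matrices=False)
    var = sv ** 2 / max(n_beats - 1, 1)
    evr = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    regressors = np.column_stack([mean, vt[:n_pcs].T])
    if half is None:
        half = (win - 1) // 2
    return ObsBasis(window=(half, half), regressors=regressors, n_pcs=n_pcs,
                    explained_variance=var, explained_variance_ratio=evr)


def clean_channel(channel: np.ndarray, r_peaks: EventList | np.ndarray,
                  srate: float, n_pcs: int = DEFAULT_N_PCS,
                  taper: str = "none", window_fraction: float = 0.5,
                  tukey_alpha: float = TUKEY_ALPHA,
                  bridge_gaps: bool = True
                  ) -> tuple[np.ndarray, list[FittedBeat]]:
    """Fit and subtract the OBS artefact estimate beat by beat.

    The fitted artefacts are accumulated into a continuous artefact estimate
    (overlapping windows from short RR intervals add both fits) and gaps
    between consecutive beat windows (long RR intervals) are filled by PCHIP
    interpolation anchored on the neighbouring fits, so the subtraction leaves
    no raw-artefact islands between windows. taper 'tukey' multiplies each
    fitted window with a Tukey window (alpha = 0.25) before accumulation to
    soften subtraction edges; 'none' (default) subtracts the plain OLS fit.
    Samples before the first window and after the last are untouched.
    """
    if taper not in ("none", "tukey"):
        raise ValueError("taper must be 'none' or 'tukey'")
    peaks = r_peaks.r_peaks if isinstance(r_peaks, EventList) else np.asarray(r_peaks)
    channel = np.asarray(channel, dtype=np.float64).ravel()
    beats, full, half = build_beat_matrix(channel, peaks, srate, window_fraction)
    basis = compute_obs(beats[full] if full.sum() > n_pcs else beats, n_pcs, half)
    R = basis.regressors
    win = R.shape[0]
    w = tukey(win, tukey_alpha) if taper == "tukey" else np.ones(win)
    # OLS solution operator for the common full-window case
    pinv_full = np.linalg.pinv(R)
    grid = np.arange(-half, half + 1)

    n = len(channel)
    fitted_art = np.zeros(n)
    fits: list[FittedBeat] = []
    overlaps = int(np.sum(np.diff(peaks) < win)) if len(peaks) > 1 else 0
    if overlaps:
        logger.info("%d beat windows overlap their neighbour; overlap region "
                    "receives both fits", overlaps)
    for i, p in enumerate(peaks):
        a, b = p - half, p + half + 1
        if full[i]:
            occ = channel[a:b]
            coef = pinv_full @ occ
            fitted = (R @ coef) * w
            fitted_art[a:b] += fitted
            fits.append(FittedBeat(int(p), coef, fitted, int(a), False))
        else:
            ca, cb = max(a, 0), min(b, n)
            sub_grid = np.arange(ca, cb) - p
            keep = np.isin(grid, sub_grid)
            coef, *_ = np.linalg.lstsq(R[keep], channel[ca:cb], rcond=None)
            # PCHIP maps the full fitted window onto the clipped sample grid
            fitted_full = (R @ coef) * w
            fitted = PchipInterpolator(grid, fitted_full)(sub_grid)
            fitted_art[ca:cb] += fitted
            fits.append(FittedBeat(int(p), coef, fitted, int(ca), True))

    if bridge_gaps and len(peaks) > 1:
        n_anchor = max(half // 8, 2)
        for p0, p1 in zip(peaks[:-1], peaks[1:]):
            gap0, gap1 = p0 + half + 1, p1 - half   # [gap0, gap1) uncovered
            if gap1 <= gap0:
                continue
            x_fit = np.concatenate([np.arange(gap0 - n_anchor, gap0),
                                    np.arange(gap1, gap1 + n_anchor)])
            x_fit = x_fit[(x_fit >= 0) & (x_fit < n)]
            if len(x_fit) < 2:
                continue
            interp = PchipInterpolator(x_fit, fitted_art[x_fit])
            fitted_art[gap0:gap1] = interp(np.arange(gap0, gap1))

    return channel - fitted_art, fits


def clean_recording(rec: Recording, n_pcs: int = DEFAULT_N_PCS,
                    taper: str = "none", window_fraction: float = 0.5,
                    tukey_alpha: float = TUKEY_ALPHA) -> Recording:
    """Apply PCA-OBS to every ESG channel of a recording (ECG untouched)."""
    out = rec.copy()
    peaks = rec.events.r_peaks
    for i in rec.esg_picks:
        out.data[i], _ = clean_channel(rec.data[i], peaks, rec.srate,
                                       n_pcs=n_pcs, taper=taper,
                                       window_fraction=window_fraction,
                                       tukey_alpha=tukey_alpha)
    return out
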