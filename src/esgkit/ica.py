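"""ICA cleaning with automatic cardiac-component selection by CTPS.

FastICA decomposes the ESG channels into as many components as there are ESG
channels. Components whose analytic-signal phase is locked to the heartbeat
are detected with cross-trial phase statistics (CTPS): phases are epoched in a
1-s window centred on each R-peak and, per time point, tested against phase
uniformity with the Kuiper statistic; the statistic is converted to a
normalised significance score in [0, 1] (Stephens' approximation) and the
maximum over time points is the component score. Components scoring above the
threshold (default 0.25) are zeroed and the data inverse-transformed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.fft
import scipy.signal
import scipy.special
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .recording import EventList, Recording

logger = logging.getLogger(__name__)

CTPS_THRESHOLD = 0.25


@dataclass
class IcaModel:
    unmixing: np.ndarray     # (n_components, n_channels), applied to centred data
    mixing: np.ndarray       # (n_channels, n_components)
    mean: np.ndarray         # per-channel mean removed before unmixing
    channels: list[str]
    seed: int
    converged: bool = True

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def sources(self, data: np.ndarray) -> np.ndarray:
        return self.unmixing @ (data - self.mean[:, None])


@dataclass
class CtpsResult:
    scores: np.ndarray       # per-component max normalised Kuiper score, [0, 1]
    threshold: float
    low_confidence: bool = False

    @property
    def flagged(self) -> np.ndarray:
        return np.flatnonzero(self.scores > self.threshold)


def fit_ica(rec: Recording, seed: int = 0, max_iter: int = 200,
            tol: float = 1e-6) -> IcaModel:
    """FastICA (parallel updates, logcosh contrast) on the ESG channels.

    The default iteration cap of 200 is deliberate: the symmetric FastICA
    rotation rarely meets tol on long quasi-Gaussian recordings, but the
    cardiac components are already well separated long before formal
    convergence, and the score-based CTPS selection is insensitive to the
    residual rotation of the remaining components.
    """
    idx = rec.esg_picks
    X = rec.data[idx]
    n_ch, n_samples = X.shape
    if n_samples < 10 * n_ch:
        raise ValueError("too few samples for a stable ICA fit")
    ica = FastICA(n_components=n_ch, algorithm="parallel", fun="logcosh",
                  whiten="unit-variance", max_iter=max_iter, tol=tol,
                  random_state=seed)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("always", ConvergenceWarning)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            ica.fit(X.T)
            if any(issubclass(c.category, ConvergenceWarning) for c in caught):
                converged = False
                logger.warning("FastICA did not converge in %d iterations "
                               "(data may be too Gaussian)", max_iter)
    return IcaModel(unmixing=ica.components_, mixing=ica.mixing_,
                    mean=ica.mean_, channels=[rec.labels[i] for i in idx],
                    seed=seed, converged=converged)


def kuiper_score(phases: np.ndarray) -> np.ndarray:
    """Normalised Kuiper significance of phase non-uniformity, per column.

    ``phases`` is (n_trials, ...) with values in [0, 1). Returns the Kuiper
    statistic V = D+ + D- transformed through Stephens' tail approximation and
    normalised as -log(P) / (2 n), clipped to [0, 1].
    """
    x = np.sort(np.asarray(phases, float), axis=0)
    n = x.shape[0]
    j1 = (np.arange(n) + 1.0) / n
    j2 = np.arange(n) / float(n)
    shape = (n,) + (1,) * (x.ndim - 1)
    d_plus = (j1.reshape(shape) - x).max(axis=0)
    d_minus = (x - j2.reshape(shape)).max(axis=0)
    v = d_plus + d_minus
    en = np.sqrt(n)
    lam = (en + 0.155 + 0.24 / en) * v
    l2 = lam ** 2
    j = np.arange(1, 101).reshape((100,) + (1,) * v.ndim)
    terms_log = -2.0 * j ** 2 * l2[None]
    weights = 2.0 * (4.0 * j ** 2 * l2[None] - 1.0)
    score = -scipy.special.logsumexp(terms_log, b=weights, axis=0) / (2.0 * n)
    score = np.where(lam < 0.4, 0.0, score)
    return np.clip(score, 0.0, 1.0)


def ctps_score_from_signal(signal: np.ndarray, srate: float,
                           peaks: np.ndarray, window: float = 1.0) -> float:
    """Max-over-time CTPS score of one component signal around given R-peaks."""
    signal = np.asarray(signal, float).ravel()
    n = len(signal)
    analytic = scipy.signal.hilbert(signal, N=scipy.fft.next_fast_len(n))[:n]
    phase = (np.angle(analytic) + np.pi) / (2 * np.pi)
    half = int(round(window / 2 * srate))
    peaks = np.asarray(peaks)
    peaks = peaks[(peaks - half >= 0) & (peaks + half < n)]
    if len(peaks) < 2:
        raise ValueError("need at least 2 usable R-peak events")
    trials = phase[peaks[:, None] + np.arange(-half, half + 1)[None, :]]
    return float(kuiper_score(trials).max())


def ctps_scores(model: IcaModel, rec: Recording, r_peaks: EventList | None = None,
                threshold: float = CTPS_THRESHOLD,
                window: float = 1.0) -> CtpsResult:
    """Max-over-time CTPS score per independent component.

    Phases come from the analytic signal of each broadband component, epoched
    in a ``window``-second window centred on each R-peak.
    """
    if r_peaks is None:
        r_peaks = rec.events
    peaks = r_peaks.r_peaks if isinstance(r_peaks, EventList) else np.asarray(r_peaks)
    idx = rec.picks(labels=model.channels)
    sources = model.sources(rec.data[idx])
    n_comp, n_samples = sources.shape

    nfast = scipy.fft.next_fast_len(n_samples)
    analytic = scipy.signal.hilbert(sources, N=nfast)[:, :n_samples]
    phase = (np.angle(analytic) + np.pi) / (2 * np.pi)   # normalised to [0, 1)

    half = int(round(window / 2 * rec.srate))
    peaks = peaks[(peaks - half >= 0) & (peaks + half < n_samples)]
    low_conf = len(peaks) < 20
    if low_conf:
        logger.warning("only %d usable R-peak events; CTPS scores are "
                       "low-confidence", len(peaks))
    if len(peaks) < 2:
        raise ValueError("need at least 2 R-peak events inside the recording")
    offs = np.arange(-half, half + 1)
    trials = phase[:, peaks[:, None] + offs[None, :]]    # (n_comp, n_trials, n_win)
    scores = np.empty(n_comp)
    for c in range(n_comp):
        scores[c] = kuiper_score(trials[c]).max()
    return CtpsResult(scores=scores, threshold=threshold, low_confidence=low_conf)


def clean_ica(rec: Recording, model: IcaModel,
              flagged: np.ndarray | list) -> Recording:
    """Zero the flagged components and inverse-transform. Non-ESG untouched."""
    flagged = np.asarray(flagged, dtype=int)
    if len(flagged) and (flagged.min() < 0 or flagged.max() >= model.n_components):
        raise IndexError("flagged component index out of range")
    out = rec.copy()
    idx = rec.picks(labels=model.channels)
    S = model.sources(rec.data[idx])
    S[flagged] = 0.0
    out.data[idx] = model.mixing @ S + model.mean[:, None]
    return out


def clean_recording(rec: Recording, seed: int = 0,
                    threshold: float = CTPS_THRESHOLD
                    ) -> tuple[Recording, IcaModel, CtpsResult]:
    """Fit ICA, score components with CTPS, and reconstruct without them."""
    model = fit_ica(rec, seed=seed)
    result = ctps_scores(model, rec, threshold=threshold)
    return clean_ica(rec, model, result.flagged), model, result
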