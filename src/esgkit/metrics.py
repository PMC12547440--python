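"""Evaluation metrics: RI, INPSR, SEP SNR, single-trial CoV, and ranking.

* Residual intensity (RI): 100 x RMS of the R-peak-locked residual evoked
  response after cleaning over the same RMS before cleaning, averaged over the
  three midline channels of interest. Lower is better.
* Improved normalised power spectrum ratio (INPSR): band power of the
  uncleaned over the cleaned data in 0.2 Hz bands centred at the cardiac
  fundamental frequency and its first four harmonics; log10-transformed per
  channel, then averaged. Higher is better.
* SEP SNR: strongest negative deflection of the trial average within the
  expected-latency window (13 +/- 5 ms median, 22 +/- 10 ms tibial), taken
  across channels of interest, divided by the baseline standard deviation of
  the winning channel's average.
* Single-trial CoV: sample std over mean of per-trial peak-to-peak amplitude
  in a condition-specific crop (8-18 ms median, 12-32 ms tibial).

Methods are ranked per metric (1 = best; ties share the mean rank) and
combined as overall = (0.5 rankRI + 0.5 rankINPSR + 1 rankSNR) / 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats

from .enhance import LATENCY_WINDOW, EnhancedSep
from .recording import EpochSet, Recording, epoch

logger = logging.getLogger(__name__)

RI_WINDOW = (-0.3, 0.4)
RI_BASELINE = (-0.3, -0.2)
SNR_BASELINE = (-0.1, -0.01)
COV_WINDOW = {"median": (0.008, 0.018), "tibial": (0.012, 0.032)}
RANK_WEIGHTS = {"ri": 0.5, "inpsr": 0.5, "snr": 1.0}


@dataclass
class MetricReport:
    method: str
    condition: str
    ri: float | None = None
    inpsr_log: float | None = None
    snr: float | None = None
    cov: float | None = None
    channels_used: tuple = field(default_factory=tuple)


def _residual_evoked(rec: Recording, channels) -> np.ndarray:
    ep = epoch(rec, "r_peak", *RI_WINDOW, baseline=RI_BASELINE,
               picks=rec.picks(labels=channels))
    return ep.average()


def residual_intensity(cleaned: Recording, uncleaned: Recording,
                       channels) -> float:
    """Percentage RMS of the cleaned vs uncleaned residual evoked response."""
    if not np.array_equal(cleaned.events.r_peaks, uncleaned.events.r_peaks):
        raise ValueError("cleaned and uncleaned recordings must share R-peaks")
    ev_c = _residual_evoked(cleaned, channels)
    ev_u = _residual_evoked(uncleaned, channels)
    rms_c = np.sqrt(np.mean(ev_c ** 2, axis=1))
    rms_u = np.sqrt(np.mean(ev_u ** 2, axis=1))
    if np.any(rms_u == 0):
        raise ZeroDivisionError("uncleaned residual evoked RMS is zero")
    return float(np.mean(100.0 * rms_c / rms_u))


def harmonic_band_power(data: np.ndarray, srate: float, f0: float,
                        n_harmonics: int = 5, half_band: float = 0.1,
                        nperseg_seconds: float = 10.0) -> np.ndarray:
    """Summed Welch band power at m*f0 +/- half_band, m = 1..n_harmonics.

    Returns one value per channel. Bands above Nyquist are dropped with a
    warning.
    """
    data = np.atleast_2d(data)
    nperseg = int(round(nperseg_seconds * srate))
    freqs, psd = scipy.signal.welch(data, fs=srate, window="hann",
                                    nperseg=nperseg, noverlap=nperseg // 2,
                                    axis=-1)
    total = np.zeros(data.shape[0])
    for m in range(1, n_harmonics + 1):
        fc = m * f0
        if fc + half_band > srate / 2:
            logger.warning("harmonic band %.2f Hz above Nyquist; dropped", fc)
            continue
        band = (freqs >= fc - half_band) & (freqs <= fc + half_band)
        total += psd[:, band].sum(axis=1)
    return total


def inpsr(cleaned: Recording, uncleaned: Recording, channels,
          mean_hr: float | None = None, log_base: float = 10.0) -> float:
    """Mean over channels of log(band-power ratio uncleaned / cleaned).

    ``mean_hr`` (Hz) defaults to 1 / mean RR over the uncleaned recording.
    """
    if uncleaned.duration < 60:
        logger.warning("recording shorter than 60 s; INPSR spectral "
                       "resolution is degraded")
    if mean_hr is None:
        rr = np.diff(uncleaned.events.r_peaks) / uncleaned.srate
        if len(rr) == 0:
            raise ValueError("no R-peaks to estimate the mean heart rate")
        mean_hr = 1.0 / float(np.mean(rr))
    idx_c = cleaned.picks(labels=channels)
    idx_u = uncleaned.picks(labels=channels)
    p_c = harmonic_band_power(cleaned.data[idx_c], cleaned.srate, mean_hr)
    p_u = harmonic_band_power(uncleaned.data[idx_u], uncleaned.srate, mean_hr)
    ratio = p_u / p_c
    return float(np.mean(np.log(ratio) / np.log(log_base)))


def sep_snr(epochs: EpochSet | EnhancedSep, condition: str,
            channels=None) -> float:
    """Evoked peak amplitude over baseline standard deviation.

    For an EpochSet the trial average is searched in the expected-latency
    window across the channels of interest and the largest-magnitude negative
    peak wins; its channel's baseline std is the noise term. For an
    EnhancedSep the single component plays the role of the channel.
    """
    t0, t1 = LATENCY_WINDOW[condition]
    b0, b1 = SNR_BASELINE
    if isinstance(epochs, EnhancedSep):
        avg = epochs.average[None, :]
        tmin, srate = epochs.tmin, epochs.srate
    else:
        ep = epochs.pick(channels) if channels is not None else epochs
        avg = ep.average()
        tmin, srate = ep.tmin, ep.srate
    i0 = int(round((t0 - tmin) * srate))
    i1 = int(round((t1 - tmin) * srate)) + 1
    j0 = int(round((b0 - tmin) * srate))
    j1 = int(round((b1 - tmin) * srate)) + 1
    seg = avg[:, i0:i1]
    neg_min = seg.min(axis=1)
    if np.all(neg_min >= 0):
        logger.warning("no negative deflection in the %s latency window; "
                       "using the window minimum", condition)
    ch = int(np.argmin(neg_min))
    peak = abs(float(seg[ch].min()))
    noise = float(avg[ch, j0:j1].std(ddof=1))
    if noise == 0:
        raise ZeroDivisionError("baseline standard deviation is zero")
    return peak / noise


def single_trial_peak_to_peak(trials: np.ndarray, tmin: float, srate: float,
                              condition: str) -> np.ndarray:
    """Per-trial max-minus-min within the condition-specific crop window."""
    t0, t1 = COV_WINDOW[condition]
    i0 = int(round((t0 - tmin) * srate))
    i1 = int(round((t1 - tmin) * srate)) + 1
    seg = trials[:, i0:i1]
    return seg.max(axis=1) - seg.min(axis=1)


def single_trial_cov(trials: EnhancedSep | EpochSet | np.ndarray,
                     condition: str, channel: str | None = None,
                     tmin: float | None = None,
                     srate: float | None = None) -> float:
    """Coefficient of variation of single-trial peak-to-peak amplitudes.

    Accepts an EnhancedSep (component trials), an EpochSet (specify the
    ``channel`` of interest), or a raw (n_trials, n_samples) array with
    explicit ``tmin``/``srate``.
    """
    if isinstance(trials, EnhancedSep):
        x, tmin, srate = trials.component_timecourses, trials.tmin, trials.srate
    elif isinstance(trials, EpochSet):
        ch = channel if channel is not None else trials.labels[len(trials.labels) // 2]
        x = trials.data[:, trials.labels.index(ch), :]
        tmin, srate = trials.tmin, trials.srate
    else:
        if tmin is None or srate is None:
            raise ValueError("raw trial arrays need explicit tmin and srate")
        x = np.asarray(trials, float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    p2p = single_trial_peak_to_peak(x, tmin, srate, condition)
    mean = p2p.mean()
    if mean <= 0:
        raise ValueError("mean peak-to-peak amplitude is not positive")
    return float(p2p.std(ddof=1) / mean)


@dataclass
class RankTable:
    """Per-method ranks and the weighted overall score (lower = better)."""

    table: pd.DataFrame

    def best(self) -> str:
        return str(self.table.sort_values("overall").index[0])


def rank_methods(reports: list[MetricReport]) -> RankTable:
    """Rank methods on RI (ascending), INPSR and SNR (descending)."""
    conds = {r.condition for r in reports}
    if len(conds) > 1:
        raise ValueError("all reports must share one condition")
    for r in reports:
        for m in ("ri", "inpsr_log", "snr"):
            if getattr(r, m) is None:
                raise ValueError(f"method {r.method!r} is missing metric {m!r}")
    df = pd.DataFrame({"method": [r.method for r in reports],
                       "ri": [r.ri for r in reports],
                       "inpsr_log": [r.inpsr_log for r in reports],
                       "snr": [r.snr for r in reports]}).set_index("method")
    df["rank_ri"] = scipy.stats.rankdata(df["ri"])
    df["rank_inpsr"] = scipy.stats.rankdata(-df["inpsr_log"])
    df["rank_snr"] = scipy.stats.rankdata(-df["snr"])
    w = RANK_WEIGHTS
    df["overall"] = (w["ri"] * df["rank_ri"] + w["inpsr"] * df["rank_inpsr"]
                     + w["snr"] * df["rank_snr"]) / sum(w.values())
    return RankTable(df)
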