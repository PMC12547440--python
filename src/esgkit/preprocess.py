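"""Fixed preprocessing chain producing "Uncleaned" data, plus R-peak detection.

The chain is: linear interpolation of the electrical stimulation artefact
(-7 to +7 ms around stimulus onset), polyphase downsampling to 1000 Hz, a
zero-phase FIR notch at 50 Hz, and a zero-phase 2nd-order Butterworth bandpass
1-400 Hz. Data after this stage are the reference point ("Uncleaned") against
which every cleaning method is evaluated.
"""

from __future__ import annotations

import fractions
import logging

import numpy as np
import scipy.signal

import mne.filter

from .recording import EventList, Recording

logger = logging.getLogger(__name__)

TARGET_SRATE = 1000.0
STIM_INTERP_WINDOW = (-0.007, 0.007)
NOTCH_FREQ = 50.0
BAND = (1.0, 400.0)


def interpolate_stimulus_artefact(rec: Recording,
                                  window: tuple[float, float] = STIM_INTERP_WINDOW
                                  ) -> Recording:
    """Replace samples around each stimulus with a straight line.

    Samples strictly inside ``window`` (seconds, stimulus-relative) are replaced
    by the line joining the two boundary samples; windows that spill over the
    recording edge are clipped to valid samples.
    """
    out = rec.copy()
    stim = rec.events.select(kind="stimulus")
    if len(stim) == 0:
        logger.info("no stimulus events: stimulation-artefact interpolation skipped")
        return out
    w0 = int(round(window[0] * rec.srate))
    w1 = int(round(window[1] * rec.srate))
    n = rec.n_samples
    for s in stim:
        a = max(s + w0, 0)
        b = min(s + w1, n - 1)
        if b - a < 2:
            continue
        inner = np.arange(a + 1, b)
        frac = (inner - a) / (b - a)
        out.data[:, inner] = (out.data[:, [a]] * (1 - frac)
                              + out.data[:, [b]] * frac)
    return out


def _resample(rec: Recording, target: float) -> Recording:
    if rec.srate == target:
        return rec.copy()
    if rec.srate < target:
        raise ValueError(f"srate {rec.srate} below target {target}; refusing to upsample")
    ratio = fractions.Fraction(target / rec.srate).limit_denominator(10000)
    data = scipy.signal.resample_poly(rec.data, ratio.numerator, ratio.denominator,
                                      axis=1)
    events = rec.events.resampled(target / rec.srate)
    return Recording(data, target, list(rec.labels), list(rec.roles), events)


def notch_filter(data: np.ndarray, srate: float, freq: float = NOTCH_FREQ) -> np.ndarray:
    """Zero-phase FIR notch (MNE design)."""
    return mne.filter.notch_filter(np.ascontiguousarray(data), srate, freqs=freq,
                                   verbose="error")


def bandpass_filter(data: np.ndarray, srate: float,
                    band: tuple[float, float] = BAND) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth bandpass (forward-backward)."""
    sos = scipy.signal.butter(2, band, btype="bandpass", fs=srate, output="sos")
    return scipy.signal.sosfiltfilt(sos, data, axis=-1)


def preprocess_uncleaned(rec: Recording, notch_stage: str = "pre",
                         interpolate_stim: bool = True) -> Recording:
    """Apply the full preprocessing chain.

    notch_stage 'pre' (default) notches here; 'post' defers the notch so the
    caller can apply :func:`notch_filter` after cardiac cleaning instead.
    """
    if notch_stage not in ("pre", "post"):
        raise ValueError("notch_stage must be 'pre' or 'post'")
    if rec.srate < TARGET_SRATE:
        raise ValueError(f"srate {rec.srate} Hz < {TARGET_SRATE} Hz")
    out = interpolate_stimulus_artefact(rec) if interpolate_stim and \
        len(rec.events.select(kind="stimulus")) else rec.copy()
    out = _resample(out, TARGET_SRATE)
    if notch_stage == "pre":
        out.data = notch_filter(out.data, out.srate)
    out.data = bandpass_filter(out.data, out.srate)
    out.validate()
    return out


def detect_r_peaks(ecg: np.ndarray, srate: float,
                   refractory: float = 0.3) -> EventList:
    """Automatic R-peak detection on a single ECG channel.

    Bandpasses 5-30 Hz, squares, thresholds at 0.5x a blockwise 95th
    percentile, and enforces a refractory period. Polarity-insensitive. The
    apex is refined on the raw signal (largest absolute deviation from the
    local median) within +/-40 ms of each squared-signal peak.
    """
    ecg = np.asarray(ecg, dtype=np.float64).ravel()
    if len(ecg) < 2 * srate:
        raise ValueError("need at least 2 s of ECG")
    if np.ptp(ecg) == 0:
        raise ValueError("flat ECG signal: no peaks detectable")
    sos = scipy.signal.butter(4, (5.0, 30.0), btype="bandpass", fs=srate, output="sos")
    bp = scipy.signal.sosfiltfilt(sos, ecg)
    sq = bp ** 2

    # blockwise 95th percentile (2 s blocks) as a cheap rolling threshold
    block = max(int(2 * srate), 1)
    n_blocks = max(len(sq) // block, 1)
    edges = np.linspace(0, len(sq), n_blocks + 1).astype(int)
    centers = (edges[:-1] + edges[1:]) / 2
    p95 = np.array([np.percentile(sq[a:b], 95) for a, b in zip(edges[:-1], edges[1:])])
    thresh = 0.5 * np.interp(np.arange(len(sq)), centers, p95)

    peaks, _ = scipy.signal.find_peaks(sq, distance=int(refractory * srate))
    peaks = peaks[sq[peaks] > thresh[peaks]]
    if len(peaks) == 0:
        raise ValueError("no R-peaks found above threshold")

    # refine apex on the raw trace, polarity-insensitive
    half = int(round(0.04 * srate))
    med = np.median(ecg)
    refined = []
    for p in peaks:
        a, b = max(p - half, 0), min(p + half + 1, len(ecg))
        refined.append(a + int(np.argmax(np.abs(ecg[a:b] - med))))
    refined = np.array(sorted(set(refined)), dtype=np.int64)
    keep = [0]
    for i in range(1, len(refined)):
        if refined[i] - refined[keep[-1]] >= int(refractory * srate):
            keep.append(i)
    return EventList.from_arrays(refined[keep], "r_peak")
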