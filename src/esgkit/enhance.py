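"""Evoked-response enhancement: CCA-SEP and DSS-SEP.

Rather than removing the cardiac artefact, these methods build a single
spatial filter that concentrates the stimulus-locked response:

* CCA-SEP trains canonical correlation between concatenated single-trial
  segments shortly after stimulus delivery (7-37 ms for median-nerve trials,
  7-47 ms for tibial) and the repeated trial average of the same segments; the
  top-ranked filter is then applied to the full epoch window.
* DSS-SEP biases DSS with the stimulus-locked average over the whole epoch
  (-0.2 to 0.7 s) and retains the first component.

Both operate on the relevant patch only (median -> cervical, tibial -> lumbar)
and are polarity-normalised: the expected spinal potentials (N13/N22) are
negative deflections, so if the trial-average of the chosen component shows a
positive peak at the expected latency the component is inverted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import EpochSet, Recording
from .subspace import SpatialFilterSet, cca_average_regression, dss_from_covariances

#: CCA training windows, seconds after stimulus.
TRAIN_WINDOW = {"median": (0.007, 0.037), "tibial": (0.007, 0.047)}
#: Expected-latency windows used for the polarity check (and for SNR peaks).
LATENCY_WINDOW = {"median": (0.008, 0.018), "tibial": (0.012, 0.032)}


@dataclass
class EnhancedSep:
    """Single enhanced-component output of CCA-SEP or DSS-SEP."""

    component_timecourses: np.ndarray   # (n_trials, n_window_samples)
    filter: np.ndarray                  # (n_channels,)
    pattern: np.ndarray
    score: float                        # canonical correlation or power ratio
    polarity_inverted: bool
    train_window: tuple[float, float]
    tmin: float
    srate: float
    condition: str
    method: str
    filter_set: SpatialFilterSet | None = None   # full ranked set, for export

    @property
    def average(self) -> np.ndarray:
        return self.component_timecourses.mean(axis=0)

    def time_index(self, t: float) -> int:
        return int(round((t - self.tmin) * self.srate))


def _normalise_polarity(comps: np.ndarray, tmin: float, srate: float,
                        condition: str) -> tuple[np.ndarray, bool]:
    """Invert so the expected-latency deflection of the average is negative."""
    t0, t1 = LATENCY_WINDOW[condition]
    i0 = int(round((t0 - tmin) * srate))
    i1 = int(round((t1 - tmin) * srate)) + 1
    seg = comps.mean(axis=0)[i0:i1]
    extremum = seg[np.argmax(np.abs(seg))]
    if extremum > 0:
        return -comps, True
    return comps, False


def cca_sep(epochs: EpochSet, condition: str) -> EnhancedSep:
    """CCA average regression trained on short post-stimulus segments."""
    if condition not in TRAIN_WINDOW:
        raise ValueError(f"unknown condition {condition!r}")
    t0, t1 = TRAIN_WINDOW[condition]
    if not (epochs.tmin <= t0 and t1 <= epochs.tmax):
        raise ValueError("training window lies outside the epoch window")
    n_tr, n_ch, _ = epochs.data.shape
    if n_tr < n_ch:
        raise ValueError("need at least as many trials as channels")
    sl = epochs.window_slice(t0, t1)
    seg = epochs.data[:, :, sl]                       # (n_tr, n_ch, n_seg)
    X = seg.transpose(1, 0, 2).reshape(n_ch, -1)
    Y = np.tile(seg.mean(axis=0), (1, n_tr))
    fs = cca_average_regression(X, Y, channels=epochs.labels, method="cca_sep")
    w = fs.filters[0]
    comps = np.einsum("c,tcs->ts", w, epochs.data)
    comps, inverted = _normalise_polarity(comps, epochs.tmin, epochs.srate, condition)
    return EnhancedSep(component_timecourses=comps,
                       filter=-w if inverted else w,
                       pattern=-fs.patterns[:, 0] if inverted else fs.patterns[:, 0],
                       score=float(fs.scores[0]), polarity_inverted=inverted,
                       train_window=(t0, t1), tmin=epochs.tmin, srate=epochs.srate,
                       condition=condition, method="cca_sep", filter_set=fs)


def dss_sep(epochs: EpochSet, rec: Recording, condition: str,
            shrinkage: float = 1e-9) -> EnhancedSep:
    """DSS biased by the stimulus-locked average over the entire epoch."""
    if condition not in TRAIN_WINDOW:
        raise ValueError(f"unknown condition {condition!r}")
    idx = rec.picks(labels=epochs.labels)
    X = rec.data[idx]
    Xc = X - X.mean(axis=1, keepdims=True)
    C0 = Xc @ Xc.T / X.shape[1]
    avg = epochs.average()
    B = avg - avg.mean(axis=1, keepdims=True)
    C1 = B @ B.T / B.shape[1]
    fs = dss_from_covariances(C0, C1, shrinkage, channels=epochs.labels)
    fs.method = "dss_sep"
    w = fs.filters[0]
    comps = np.einsum("c,tcs->ts", w, epochs.data)
    comps, inverted = _normalise_polarity(comps, epochs.tmin, epochs.srate, condition)
    return EnhancedSep(component_timecourses=comps,
                       filter=-w if inverted else w,
                       pattern=-fs.patterns[:, 0] if inverted else fs.patterns[:, 0],
                       score=float(fs.scores[0]), polarity_inverted=inverted,
                       train_window=(epochs.tmin, epochs.tmax),
                       tmin=epochs.tmin, srate=epochs.srate,
                       condition=condition, method="dss_sep", filter_set=fs)
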