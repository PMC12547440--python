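"""Core in-memory containers for multichannel ESG recordings.

A :class:`Recording` is a plain channels-by-samples matrix in microvolts with a
sampling rate, per-channel labels and roles, and an attached :class:`EventList`.
Epoching produces an :class:`EpochSet` (trials x channels x window samples).

Channel roles distinguish the two spinal electrode patches (cervical, centred
on SC6; lumbar, centred on L1) from the ECG channel used to anchor heartbeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ROLE_CERVICAL = "esg_cervical"
ROLE_LUMBAR = "esg_lumbar"
ROLE_ECG = "ecg"
ROLE_OTHER = "other"

#: Midline channels with the strongest SEPs, per patch.
CERVICAL_CHANNELS_OF_INTEREST = ("S6", "SC6", "S14")
LUMBAR_CHANNELS_OF_INTEREST = ("S23", "L1", "S31")

EVENT_COLUMNS = ("sample", "kind", "condition")


class EventList:
    """Typed event latencies (R-peaks, stimuli) in samples.

    Thin wrapper around a DataFrame with columns ``sample`` (int, 0-based),
    ``kind`` (``r_peak`` | ``stimulus``) and ``condition``
    (``median`` | ``tibial`` | ``none``). Kept sorted by sample.
    """

    def __init__(self, frame: pd.DataFrame | None = None):
        if frame is None:
            frame = pd.DataFrame({c: [] for c in EVENT_COLUMNS})
        frame = frame[list(EVENT_COLUMNS)].copy()
        frame["sample"] = frame["sample"].astype(np.int64)
        frame = frame.sort_values("sample", kind="stable").reset_index(drop=True)
        r = frame.loc[frame["kind"] == "r_peak", "sample"].to_numpy()
        if len(r) > 1 and not np.all(np.diff(r) > 0):
            raise ValueError("r_peak events must be strictly increasing")
        self.frame = frame

    @classmethod
    def from_arrays(cls, samples, kinds, conditions=None) -> "EventList":
        samples = np.asarray(samples, dtype=np.int64)
        if isinstance(kinds, str):
            kinds = [kinds] * len(samples)
        if conditions is None:
            conditions = ["none"] * len(samples)
        elif isinstance(conditions, str):
            conditions = [conditions] * len(samples)
        return cls(pd.DataFrame(
            {"sample": samples, "kind": list(kinds), "condition": list(conditions)}
        ))

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventList) and self.frame.equals(other.frame)

    def select(self, kind: str | None = None, condition: str | None = None) -> np.ndarray:
        """Return event samples matching the given kind/condition."""
        mask = np.ones(len(self.frame), dtype=bool)
        if kind is not None:
            mask &= (self.frame["kind"] == kind).to_numpy()
        if condition is not None:
            mask &= (self.frame["condition"] == condition).to_numpy()
        return self.frame.loc[mask, "sample"].to_numpy()

    @property
    def r_peaks(self) -> np.ndarray:
        return self.select(kind="r_peak")

    def stimuli(self, condition: str | None = None) -> np.ndarray:
        return self.select(kind="stimulus", condition=condition)

    def resampled(self, ratio: float) -> "EventList":
        """Map event samples to a new rate by nearest sample (order-preserving)."""
        frame = self.frame.copy()
        frame["sample"] = np.round(frame["sample"].to_numpy() * ratio).astype(np.int64)
        # nearest-sample mapping may collide for r-peaks at extreme ratios;
        # enforce strict monotonicity by bumping duplicates
        for kind in ("r_peak",):
            idx = frame.index[frame["kind"] == kind]
            s = frame.loc[idx, "sample"].to_numpy()
            for i in range(1, len(s)):
                if s[i] <= s[i - 1]:
                    s[i] = s[i - 1] + 1
            frame.loc[idx, "sample"] = s
        return EventList(frame)

    def concat(self, other: "EventList") -> "EventList":
        return EventList(pd.concat([self.frame, other.frame], ignore_index=True))


@dataclass
class Recording:
    """Multichannel recording: ``data`` is (n_channels, n_samples) in microvolts."""

    data: np.ndarray
    srate: float
    labels: list[str]
    roles: list[str]
    events: EventList = field(default_factory=EventList)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if self.data.shape[0] != len(self.labels) or len(self.labels) != len(self.roles):
            raise ValueError("data/labels/roles channel counts disagree")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.srate

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy(),
                       labels=list(self.labels), roles=list(self.roles),
                       events=EventList(self.events.frame))

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def picks(self, roles=None, labels=None) -> np.ndarray:
        """Channel indices by role set and/or explicit labels."""
        if labels is not None:
            return np.array([self.channel_index(l) for l in labels], dtype=int)
        roles = set(roles) if roles is not None else None
        return np.array([i for i, r in enumerate(self.roles)
                         if roles is None or r in roles], dtype=int)

    @property
    def esg_picks(self) -> np.ndarray:
        return self.picks(roles={ROLE_CERVICAL, ROLE_LUMBAR})

    def patch_picks(self, condition: str) -> np.ndarray:
        """Relevant patch for a stimulation condition (median->cervical, tibial->lumbar)."""
        role = {"median": ROLE_CERVICAL, "tibial": ROLE_LUMBAR}[condition]
        return self.picks(roles={role})

    def channels_of_interest(self, condition: str) -> tuple[str, ...]:
        coi = {"median": CERVICAL_CHANNELS_OF_INTEREST,
               "tibial": LUMBAR_CHANNELS_OF_INTEREST}[condition]
        missing = [c for c in coi if c not in self.labels]
        if missing:
            raise KeyError(f"channels of interest {missing} not present")
        return coi

    def validate(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        s = self.events.frame["sample"].to_numpy()
        if len(s) and (s.min() < 0 or s.max() >= self.n_samples):
            raise ValueError("event sample index outside recording")


@dataclass
class EpochSet:
    """Event-locked trials: ``data`` is (n_trials, n_channels, n_window_samples).

    The window is inclusive of both endpoints: length = round((tmax-tmin)*srate)+1.
    ``baseline`` records the interval (in seconds, event-relative) whose per-trial,
    per-channel mean was subtracted, or None.
    """

    data: np.ndarray
    tmin: float
    tmax: float
    srate: float
    labels: list[str]
    baseline: tuple[float, float] | None = None
    event_samples: np.ndarray | None = None
    condition: str = "none"

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.tmin + np.arange(n) / self.srate

    def time_index(self, t: float) -> int:
        """Sample index within the window closest to event-relative time t."""
        i = int(round((t - self.tmin) * self.srate))
        return min(max(i, 0), self.data.shape[2] - 1)

    def window_slice(self, t0: float, t1: float) -> slice:
        return slice(self.time_index(t0), self.time_index(t1) + 1)

    def average(self) -> np.ndarray:
        """Trial average, (n_channels, n_window_samples)."""
        return self.data.mean(axis=0)

    def pick(self, labels) -> "EpochSet":
        idx = [self.labels.index(l) for l in labels]
        return EpochSet(self.data[:, idx, :], self.tmin, self.tmax, self.srate,
                        list(labels), self.baseline, self.event_samples, self.condition)


def epoch(rec: Recording, kind: str, tmin: float, tmax: float,
          baseline: tuple[float, float] | None = None,
          condition: str | None = None, picks=None) -> EpochSet:
    """Slice event-locked trials out of a recording.

    Only events whose full window lies inside the recording become trials;
    trials are kept in event order. With ``baseline`` given, the mean of each
    trial/channel over the baseline interval is subtracted.
    """
    if tmin >= tmax:
        raise ValueError("tmin must be < tmax")
    if baseline is not None and not (tmin <= baseline[0] < baseline[1] <= tmax):
        raise ValueError("baseline must lie within [tmin, tmax]")
    samples = rec.events.select(kind=kind, condition=condition)
    if picks is None:
        picks = np.arange(rec.n_channels)
    picks = np.asarray(picks, dtype=int)
    i0 = int(round(tmin * rec.srate))
    n_win = int(round((tmax - tmin) * rec.srate)) + 1
    starts = samples + i0
    ok = (starts >= 0) & (starts + n_win <= rec.n_samples)
    starts = starts[ok]
    if len(starts) == 0:
        raise ValueError(f"no usable events of kind {kind!r} "
                         f"(condition {condition!r}) for window ({tmin}, {tmax})")
    data = np.stack([rec.data[np.ix_(picks, np.arange(s, s + n_win))] for s in starts])
    if baseline is not None:
        b0 = int(round((baseline[0] - tmin) * rec.srate))
        b1 = int(round((baseline[1] - tmin) * rec.srate)) + 1
        data = data - data[:, :, b0:b1].mean(axis=2, keepdims=True)
    return EpochSet(data, tmin, tmax, rec.srate,
                    [rec.labels[i] for i in picks], baseline,
                    event_samples=samples[ok],
                    condition=condition if condition is not None else "none")
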