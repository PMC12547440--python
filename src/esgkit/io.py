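"""Reading and writing recordings and event lists.

Readers: BrainVision (.vhdr/.vmrk/.eeg) and EDF through MNE; a portable HDF5
container for lossless internal round-tripping; BIDS-style tab-separated
event files (columns onset_sample, kind, condition).

The BrainVision writer emits an IEEE float32 multiplexed .eeg with text
.vhdr/.vmrk sidecars; markers encode the event kind and condition so they
survive a round trip through the MNE reader.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

import mne

from .recording import (EventList, Recording, ROLE_CERVICAL, ROLE_ECG,
                        ROLE_LUMBAR, ROLE_OTHER,
                        CERVICAL_CHANNELS_OF_INTEREST,
                        LUMBAR_CHANNELS_OF_INTEREST)

logger = logging.getLogger(__name__)


def infer_roles(labels: list[str]) -> list[str]:
    """Heuristic channel roles from the montage naming convention."""
    roles = []
    for lab in labels:
        if lab.upper().startswith("ECG"):
            roles.append(ROLE_ECG)
        elif lab in CERVICAL_CHANNELS_OF_INTEREST or lab.startswith("CV"):
            roles.append(ROLE_CERVICAL)
        elif lab in LUMBAR_CHANNELS_OF_INTEREST or lab.startswith("LU"):
            roles.append(ROLE_LUMBAR)
        else:
            roles.append(ROLE_OTHER)
    return roles


def _events_from_annotations(raw) -> EventList:
    rows = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        parts = desc.split("/")
        kind = parts[-2] if len(parts) >= 2 else parts[0]
        cond = parts[-1] if len(parts) >= 2 else "none"
        if kind not in ("r_peak", "stimulus"):
            # foreign marker stream: keep stimulus-looking markers, drop rest
            continue
        rows.append({"sample": int(round(onset * raw.info["sfreq"])),
                     "kind": kind, "condition": cond})
    if not rows:
        return EventList()
    return EventList(pd.DataFrame(rows))


def read_recording(path, fmt: str | None = None,
                   roles: list[str] | None = None) -> Recording:
    """Read a BrainVision, EDF or HDF5 recording into microvolts."""
    path = Path(path)
    if fmt is None:
        fmt = {".vhdr": "brainvision", ".edf": "edf",
               ".h5": "hdf5", ".hdf5": "hdf5"}.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format of {path.name}")
    if fmt == "hdf5":
        return read_hdf5(path)
    try:
        if fmt == "brainvision":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        elif fmt == "edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (OSError, ValueError, RuntimeError) as err:
        raise OSError(f"unreadable {fmt} file {path}: {err}") from err
    data = raw.get_data() * 1e6      # MNE works in volts
    labels = list(raw.ch_names)
    if roles is None:
        roles = infer_roles(labels)
    events = _events_from_annotations(raw)
    if len(events) == 0:
        logger.info("no marker track found in %s; empty event list", path.name)
    return Recording(data, float(raw.info["sfreq"]), labels, roles, events)


def write_recording(rec: Recording, path, fmt: str | None = None) -> Path:
    """Write a recording as BrainVision (.vhdr + .vmrk + .eeg) or HDF5."""
    path = Path(path)
    if fmt is None:
        fmt = {".vhdr": "brainvision", ".h5": "hdf5",
               ".hdf5": "hdf5"}.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format of {path.name}")
    if fmt == "hdf5":
        return write_hdf5(rec, path)
    if fmt != "brainvision":
        raise NotImplementedError(f"writing format {fmt!r} is not supported")
    stem = path.with_suffix("")
    eeg, vmrk, vhdr = stem.with_suffix(".eeg"), stem.with_suffix(".vmrk"), path
    n_ch = rec.n_channels
    rec.data.astype("<f4").T.ravel().tofile(eeg)   # multiplexed float32
    res_us = 1e6 / rec.srate
    lines = ["BrainVision Data Exchange Header File Version 1.0", "",
             "[Common Infos]", "Codepage=UTF-8",
             f"DataFile={eeg.name}", f"MarkerFile={vmrk.name}",
             "DataFormat=BINARY", "DataOrientation=MULTIPLEXED",
             f"NumberOfChannels={n_ch}",
             f"SamplingInterval={res_us:.6f}", "",
             "[Binary Infos]", "BinaryFormat=IEEE_FLOAT_32", "",
             "[Channel Infos]"]
    for i, lab in enumerate(rec.labels, start=1):
        lines.append(f"Ch{i}={lab},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")
    mlines = ["BrainVision Data Exchange Marker File, Version 1.0", "",
              "[Common Infos]", "Codepage=UTF-8", f"DataFile={eeg.name}", "",
              "[Marker Infos]",
              "Mk1=New Segment,,1,1,0"]
    for i, (_, ev) in enumerate(rec.events.frame.iterrows(), start=2):
        mlines.append(f"Mk{i}={ev['kind']},{ev['condition']},"
                      f"{int(ev['sample']) + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")
    return vhdr


def write_hdf5(rec: Recording, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip")
        f.attrs["srate"] = rec.srate
        f.create_dataset("labels", data=np.array(rec.labels, dtype="S"))
        f.create_dataset("roles", data=np.array(rec.roles, dtype="S"))
        g = f.create_group("events")
        g.create_dataset("sample", data=rec.events.frame["sample"].to_numpy())
        g.create_dataset("kind",
                         data=rec.events.frame["kind"].to_numpy().astype("S"))
        g.create_dataset("condition",
                         data=rec.events.frame["condition"].to_numpy().astype("S"))
    return path


def read_hdf5(path) -> Recording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        srate = float(f.attrs["srate"])
        labels = [s.decode() for s in f["labels"][()]]
        roles = [s.decode() for s in f["roles"][()]]
        ev = EventList(pd.DataFrame({
            "sample": f["events/sample"][()],
            "kind": [s.decode() for s in f["events/kind"][()]],
            "condition": [s.decode() for s in f["events/condition"][()]]}))
    return Recording(data, srate, labels, roles, ev)


def read_events_tsv(path) -> EventList:
    """Events from a tab-separated file with onset_sample, kind, condition."""
    df = pd.read_csv(path, sep="\t")
    if "onset_sample" not in df.columns or "kind" not in df.columns:
        raise ValueError("events file needs onset_sample and kind columns")
    if "condition" not in df.columns:
        df["condition"] = "none"
    return EventList(df.rename(columns={"onset_sample": "sample"}))


def write_events_tsv(events: EventList, path) -> Path:
    path = Path(path)
    events.frame.rename(columns={"sample": "onset_sample"}).to_csv(
        path, sep="\t", index=False)
    return path
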