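"""File input/output.

EEG: BrainVision triplets (.vhdr/.vmrk/.eeg) are written natively in the
IEEE_FLOAT_32 multiplexed dialect (the dialect is stated in the header) and
read back through mne's BrainVision reader; EDF files are read through
mne's built-in EDF reader.  Epoched data are stored as a .npy array plus a
JSON sidecar carrying rates, labels, metadata and the rejection mask.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd

from .preproc import EEGRecording, EpochSet

__all__ = [
    "write_brainvision",
    "read_brainvision",
    "read_edf",
    "write_epochs",
    "read_epochs",
    "write_cohort",
]

_VHDR_TEMPLATE = """Brain Vision Data Exchange Header File Version 1.0
; Written by entrainflow (IEEE_FLOAT_32 multiplexed dialect)

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_channels}
SamplingInterval={sampling_interval_us}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
{channel_lines}
"""

_VMRK_TEMPLATE = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg

[Marker Infos]
{marker_lines}
"""


def write_brainvision(rec: EEGRecording, path: str | pathlib.Path) -> None:
    """Write a recording as a BrainVision triplet next to ``path``.

    ``path`` names the .vhdr file; the .vmrk and .eeg siblings are derived
    from its stem.  Data are float32 microvolts, multiplexed; stimulus
    events become ``Stimulus,S<code>`` markers (1-based sample positions
    per the format convention).
    """
    path = pathlib.Path(path).with_suffix(".vhdr")
    stem = path.stem
    channel_lines = "\n".join(
        f"Ch{i + 1}={label},,1,µV"
        for i, label in enumerate(rec.channel_labels))
    vhdr = _VHDR_TEMPLATE.format(
        stem=stem, n_channels=len(rec.channel_labels),
        sampling_interval_us=int(round(1e6 / rec.rate_hz)),
        channel_lines=channel_lines)
    markers = ["Mk1=New Segment,,1,1,0,00000000000000000000"]
    for i, (sample, code) in enumerate(rec.events, start=2):
        markers.append(f"Mk{i}=Stimulus,S{code:>3},{sample + 1},1,0")
    vmrk = _VMRK_TEMPLATE.format(stem=stem, marker_lines="\n".join(markers))
    path.write_text(vhdr, encoding="utf-8")
    path.with_suffix(".vmrk").write_text(vmrk, encoding="utf-8")
    rec.data.T.astype("<f4").tofile(path.with_suffix(".eeg"))


def _from_mne_raw(raw, stim_prefix: str = "Stimulus") -> EEGRecording:
    import mne

    data = raw.get_data() * 1e6  # mne works in volts
    events = []
    ann = raw.annotations
    for onset, desc in zip(ann.onset, ann.description):
        if desc.startswith(stim_prefix):
            code_txt = "".join(ch for ch in desc if ch.isdigit())
            code = int(code_txt) if code_txt else 0
            events.append((int(round(onset * raw.info["sfreq"])), code))
    return EEGRecording(data, raw.info["sfreq"], list(raw.ch_names),
                        events=events)


def read_brainvision(path: str | pathlib.Path) -> EEGRecording:
    """Read a BrainVision triplet (header parsed for binary format,
    resolution and channel order by mne)."""
    import mne

    raw = mne.io.read_raw_brainvision(str(path), preload=True,
                                      verbose="error")
    return _from_mne_raw(raw)


def read_edf(path: str | pathlib.Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return _from_mne_raw(raw)


def write_epochs(epochs: EpochSet, directory: str | pathlib.Path,
                 stem: str = "epochs") -> None:
    """Binary array + JSON sidecar layout for epoched data."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / f"{stem}.npy", epochs.data)
    sidecar = {
        "rate_hz": epochs.rate_hz,
        "channel_labels": epochs.channel_labels,
        "window_s": list(epochs.window_s),
        "rejection_mask": epochs.rejection_mask.tolist(),
        "metadata": epochs.metadata.to_dict(orient="records"),
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))


def read_epochs(directory: str | pathlib.Path,
                stem: str = "epochs") -> EpochSet:
    directory = pathlib.Path(directory)
    data = np.load(directory / f"{stem}.npy")
    sidecar = json.loads((directory / f"{stem}.json").read_text())
    return EpochSet(data, sidecar["rate_hz"], sidecar["channel_labels"],
                    pd.DataFrame(sidecar["metadata"]),
                    np.array(sidecar["rejection_mask"], dtype=bool),
                    window_s=tuple(sidecar["window_s"]))


def write_cohort(cohort, directory: str | pathlib.Path) -> None:
    """Persist a synthetic cohort: BrainVision EEG per trial, flow CSVs."""
    from .flow import write_flow_csv

    directory = pathlib.Path(directory)
    (directory / "flow").mkdir(parents=True, exist_ok=True)
    (directory / "eeg").mkdir(exist_ok=True)
    for fl in cohort.flows:
        write_flow_csv(fl, directory / "flow" / f"{fl.source_id}.csv")
    for inst in cohort.instances:
        for fl, rec in inst.trials:
            name = (f"{inst.participant}_{inst.condition}_"
                    f"{fl.source_id.replace('-reversed', '')}")
            write_brainvision(rec, directory / "eeg" / f"{name}.vhdr")
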