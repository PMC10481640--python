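"""Plain-text session fixtures and EDF import.

A session on disk is a directory of small text files:

    <id>_samples.csv   one column per channel, microvolts, header = labels
    <id>_events.csv    onset_s, offset_s, kind
    <id>_meta.json     fs, state, ids, generator parameters, phase flag
    <id>_phase.csv     phase_deg, valid (only when true phase is known)

EDF recordings can be imported when MNE is available; the true phase is
then unknown and only Hilbert ground truth applies.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import EEGRecording, EventList, PhaseTrace, ValidationError


def save_session(directory, recording: EEGRecording, events: EventList,
                 phase: PhaseTrace | None = None, extra_meta: dict | None = None):
    """Write one session in the CSV/JSON fixture dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rid = recording.recording_id
    pd.DataFrame(recording.data, columns=list(recording.channel_labels)).to_csv(
        directory / f"{rid}_samples.csv", index=False, float_format="%.6g")
    events.to_frame().to_csv(directory / f"{rid}_events.csv", index=False)
    meta = {
        "fs": recording.fs,
        "state": recording.state,
        "dataset_id": recording.dataset_id,
        "individual_id": recording.individual_id,
        "recording_id": rid,
        "has_true_phase": phase is not None,
    }
    if extra_meta:
        meta.update(extra_meta)
    (directory / f"{rid}_meta.json").write_text(json.dumps(meta, indent=1))
    if phase is not None:
        pd.DataFrame({"phase_deg": phase.phase_deg,
                      "valid": phase.valid_mask.astype(int)}).to_csv(
            directory / f"{rid}_phase.csv", index=False, float_format="%.4f")
    return directory


def load_session(directory, recording_id: str):
    """Read a session back; returns (recording, events, phase_or_None)."""
    directory = Path(directory)
    meta = json.loads((directory / f"{recording_id}_meta.json").read_text())
    samples = pd.read_csv(directory / f"{recording_id}_samples.csv")
    rec = EEGRecording(
        data=samples.to_numpy(dtype=float), fs=float(meta["fs"]),
        channel_labels=tuple(samples.columns), state=meta["state"],
        dataset_id=meta["dataset_id"], individual_id=meta["individual_id"],
        recording_id=meta["recording_id"])
    ev_path = directory / f"{recording_id}_events.csv"
    ev_df = pd.read_csv(ev_path)
    events = EventList.from_frame(ev_df) if len(ev_df) else EventList([])
    phase = None
    if meta.get("has_true_phase"):
        ph = pd.read_csv(directory / f"{recording_id}_phase.csv")
        phase = PhaseTrace(ph["phase_deg"].to_numpy(dtype=float), fs=rec.fs,
                           valid_mask=ph["valid"].to_numpy(dtype=bool))
    return rec, events, phase


def load_edf(path, state: str = "EC", dataset_id: str = "edf",
             individual_id: str = "s01", recording_id: str | None = None) -> EEGRecording:
    """Import a European Data Format recording via MNE (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ValidationError("EDF import requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data().T * 1e6  # volts -> microvolts
    return EEGRecording(
        data=data, fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names), state=state,
        dataset_id=dataset_id, individual_id=individual_id,
        recording_id=recording_id or Path(path).stem)
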