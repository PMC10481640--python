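"""Shared in-memory containers and exceptions.

The pipeline passes multichannel recordings, per-sample phase traces and
event lists between stages.  All voltages are in microvolts, all times in
seconds, all phases in degrees with the cosine convention (a local maximum
of the oscillation sits at 0 degrees).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Default alpha band (Hz).  Its midpoint, 10.5 Hz, is the fixed peak
#: frequency implicitly assumed when no individual alpha frequency is used.
DEFAULT_ALPHA_BAND: tuple[float, float] = (8.0, 13.0)

#: The 32 standard 10-20 electrode labels used throughout.
STANDARD_1020_32: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
)

VALID_STATES = ("EC", "EO", "task")


class ValidationError(ValueError):
    """Raised when an input or configuration violates a precondition."""


class RecordingExcludedError(RuntimeError):
    """Raised when a recording cannot proceed through the pipeline
    (e.g. all channels rejected, Laplacian montage unavailable)."""


class TrainingFailedError(RuntimeError):
    """Raised when too few interpeak intervals are available to train."""


def wrap_degrees(deg):
    """Wrap angles to the half-open interval (-180, 180]."""
    w = np.asarray(deg, dtype=float)
    w = (w + 180.0) % 360.0 - 180.0
    w = np.where(w == -180.0, 180.0, w)
    if np.ndim(deg) == 0:
        return float(w)
    return w


def circular_abs_diff_deg(a, b):
    """Absolute circular difference of two angles in degrees, in [0, 180]."""
    return np.abs(wrap_degrees(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))


@dataclass
class EEGRecording:
    """Multichannel EEG samples (samples x channels, microvolts)."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    state: str = "EC"
    dataset_id: str = "synthetic"
    individual_id: str = "s01"
    recording_id: str = "r01"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be 2-D (samples x channels)")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValidationError("channel_labels length must match data columns")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError("channel labels must be unique")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.state not in VALID_STATES:
            raise ValidationError(f"state must be one of {VALID_STATES}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None
        return self.data[:, idx]

    def copy(self) -> "EEGRecording":
        return replace(self, data=self.data.copy())


@dataclass
class PhaseTrace:
    """Per-sample instantaneous phase in degrees, peak = 0 degrees.

    ``valid_mask`` marks samples whose phase is trustworthy (filter and
    Hilbert edge effects are masked out for estimated traces; generator
    truth is valid everywhere).
    """

    phase_deg: np.ndarray
    fs: float
    valid_mask: np.ndarray = None

    def __post_init__(self):
        self.phase_deg = np.asarray(self.phase_deg, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones_like(self.phase_deg, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.phase_deg.shape:
            raise ValidationError("valid_mask shape must match phase_deg")

    def at_time(self, t_s: float) -> float:
        idx = int(round(t_s * self.fs))
        if idx < 0 or idx >= self.phase_deg.size:
            raise ValidationError(f"time {t_s} s outside phase trace")
        return float(self.phase_deg[idx])

    def is_valid_at(self, t_s: float) -> bool:
        idx = int(round(t_s * self.fs))
        if idx < 0 or idx >= self.phase_deg.size:
            return False
        return bool(self.valid_mask[idx])


@dataclass(frozen=True)
class Event:
    onset_s: float
    offset_s: float
    kind: str  # "trial" | "iti"


@dataclass
class EventList:
    """Chronological, non-overlapping trial / intertrial interval markers."""

    events: list = field(default_factory=list)

    def __post_init__(self):
        evs = [e if isinstance(e, Event) else Event(*e) for e in self.events]
        self.events = evs
        last_off = -np.inf
        last_kind = None
        for e in evs:
            if e.kind not in ("trial", "iti"):
                raise ValidationError(f"unknown event kind {e.kind!r}")
            if not (e.onset_s < e.offset_s):
                raise ValidationError("event onset must precede offset")
            if e.onset_s < last_off:
                raise ValidationError("events overlap or are out of order")
            if last_kind is not None and e.kind == last_kind:
                raise ValidationError("trial and iti events must alternate")
            last_off = e.offset_s
            last_kind = e.kind

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.onset_s, e.offset_s, e.kind) for e in self.events],
            columns=["onset_s", "offset_s", "kind"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventList":
        return cls([Event(float(r.onset_s), float(r.offset_s), str(r.kind))
                    for r in df.itertuples()])
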