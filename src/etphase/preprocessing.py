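"""Harmonization, channel/artifact rejection, Laplacian, epoching.

Recordings from heterogeneous sources are brought to a common footing:
resampled to 250 Hz, bandpassed 0.15-60 Hz with a zero-phase Hamming FIR,
stripped of bad channels, re-referenced to a Pz-centered surface
Laplacian, and cut into training / test epochs.  Epochs containing
amplitudes beyond three standard deviations of the Laplacian signal are
rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import (
    EEGRecording,
    EventList,
    RecordingExcludedError,
    ValidationError,
)
from .filters import fir_bandpass_taps, highpass_residual, zero_phase_filter

WIDEBAND = (0.15, 60.0)
TARGET_FS = 250.0


@dataclass(frozen=True)
class Epoch:
    start_s: float
    end_s: float
    role: str  # "train" | "test"
    kind: str  # "rest" | "iti" | "on_task"
    kept: bool = True


@dataclass
class EpochSet:
    """Train/test epochs of one recording, with rejection flags."""

    epochs: list
    fs: float

    def __iter__(self):
        return iter(self.epochs)

    def __len__(self):
        return len(self.epochs)

    def select(self, role: str | None = None, kept_only: bool = True):
        out = [e for e in self.epochs
               if (role is None or e.role == role) and (not kept_only or e.kept)]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.start_s, e.end_s, e.role, e.kind, e.kept) for e in self.epochs],
            columns=["start_s", "end_s", "role", "kind", "kept"],
        )


def resample(recording: EEGRecording, target_fs: float = TARGET_FS) -> EEGRecording:
    """Polyphase downsampling to ``target_fs`` (upsampling is refused)."""
    if target_fs > recording.fs:
        raise ValidationError("upsampling is not supported")
    if target_fs == recording.fs:
        return recording.copy()
    frac = Fraction(int(round(target_fs * 1000)), int(round(recording.fs * 1000)))
    data = sps.resample_poly(recording.data, frac.numerator, frac.denominator, axis=0)
    return replace(recording, data=data, fs=float(target_fs))


def wideband_filter(recording: EEGRecording,
                    band: tuple[float, float] = WIDEBAND) -> EEGRecording:
    """Zero-phase Hamming FIR bandpass 0.15-60 Hz; removes DC drift."""
    taps = fir_bandpass_taps(band[0], band[1], recording.fs)
    return replace(recording, data=zero_phase_filter(taps, recording.data))


# ---------------------------------------------------------------------------
# bad channels

def _flat_flag(x: np.ndarray, fs: float, min_s: float, tol: float = 1e-8) -> bool:
    """True when the channel holds a constant value for more than ``min_s``."""
    const = np.abs(np.diff(x)) <= tol
    if not const.any():
        return False
    # longest run of consecutive constant differences
    edges = np.diff(np.concatenate([[0], const.astype(int), [0]]))
    starts = np.where(edges == 1)[0]
    ends = np.where(edges == -1)[0]
    longest = int((ends - starts).max()) + 1  # samples in the flat stretch
    return longest / fs > min_s


def _reconstruction_correlations(data: np.ndarray, fs: float, window_s: float,
                                 max_windows: int, ridge: float) -> np.ndarray:
    """Median windowed correlation of each channel with its ridge-regression
    reconstruction from all other channels."""
    n, n_ch = data.shape
    win = int(round(window_s * fs))
    n_win = max(1, n // win)
    use = np.linspace(0, n_win - 1, min(max_windows, n_win)).astype(int)
    corrs = np.full((len(use), n_ch), np.nan)
    for wi, w in enumerate(use):
        seg = data[w * win:(w + 1) * win]
        seg = seg - seg.mean(axis=0)
        cov = seg.T @ seg / seg.shape[0]
        lam = ridge * np.trace(cov) / n_ch
        for ch in range(n_ch):
            others = np.delete(np.arange(n_ch), ch)
            a = cov[np.ix_(others, others)] + lam * np.eye(n_ch - 1)
            b = cov[others, ch]
            coef = np.linalg.solve(a, b)
            pred = seg[:, others] @ coef
            denom = np.std(pred) * np.std(seg[:, ch])
            corrs[wi, ch] = 0.0 if denom < 1e-20 else float(
                np.mean(pred * seg[:, ch]) / denom)
    return np.nanmedian(corrs, axis=0)


def reject_bad_channels(recording: EEGRecording, corr_threshold: float = 0.85,
                        hf_sd_threshold: float = 4.0, flat_min_s: float = 5.0,
                        window_s: float = 5.0, max_windows: int = 12,
                        ridge: float = 1e-3):
    """Flag and drop bad channels.

    Criteria: (1) correlation below ``corr_threshold`` with a ridge
    reconstruction of the channel from all other channels over 5 s
    windows; (2) high-frequency (>45 Hz) noise more than
    ``hf_sd_threshold`` standard deviations above the channel population
    mean; (3) flat data for more than ``flat_min_s`` seconds.

    Returns ``(cleaned_recording, report)`` where ``report`` is a
    DataFrame indexed by channel with boolean columns ``low_correlation``,
    ``hf_noise``, ``flat`` and ``rejected``.
    """
    if recording.data.shape[1] < 8:
        raise ValidationError("bad-channel rejection needs at least 8 channels")
    data, fs = recording.data, recording.fs

    flat = np.array([_flat_flag(data[:, c], fs, flat_min_s)
                     for c in range(data.shape[1])])

    hf = highpass_residual(data, fs)
    hf_sd = hf.std(axis=0)
    hf_flag = hf_sd > hf_sd.mean() + hf_sd_threshold * hf_sd.std()

    corr = _reconstruction_correlations(data, fs, window_s, max_windows, ridge)
    low_corr = corr < corr_threshold

    rejected = flat | hf_flag | low_corr
    report = pd.DataFrame({
        "low_correlation": low_corr,
        "hf_noise": hf_flag,
        "flat": flat,
        "rejected": rejected,
        "reconstruction_corr": corr,
    }, index=list(recording.channel_labels))
    if rejected.all():
        raise RecordingExcludedError("all channels rejected")
    keep = ~rejected
    cleaned = replace(recording, data=data[:, keep],
                      channel_labels=tuple(np.array(recording.channel_labels)[keep]))
    return cleaned, report


def laplacian(recording: EEGRecording, center: str = "Pz",
              surround=("Oz", "Cz", "P3", "P4")) -> np.ndarray:
    """Surface Laplacian: center channel minus the mean of the available
    surround channels (at least two required)."""
    if center not in recording.channel_labels:
        raise RecordingExcludedError(f"Laplacian center {center!r} unavailable")
    present = [s for s in surround if s in recording.channel_labels]
    if len(present) < 2:
        raise RecordingExcludedError(
            f"only {len(present)} surround channels available for the Laplacian")
    surround_mean = np.mean([recording.channel(s) for s in present], axis=0)
    return recording.channel(center) - surround_mean


# ---------------------------------------------------------------------------
# epochs

def extract_epochs(recording: EEGRecording, events: EventList,
                   epoch_len_s: float = 2.0) -> EpochSet:
    """Cut a recording into training and test epochs.

    Rest recordings (empty event list): first half -> training, second
    half -> test, each tiled with non-overlapping ``epoch_len_s`` epochs.
    Task recordings: intertrial intervals become training epochs and
    trials become test epochs; an intertrial interval not followed by a
    trial is dropped (its end is not bounded by a trial onset), so the
    two sets have equal counts before rejection when every interval is
    trial-bounded.
    """
    epochs: list[Epoch] = []
    if len(events) == 0:
        half = recording.duration_s / 2.0
        for role, lo, hi in (("train", 0.0, half), ("test", half, recording.duration_s)):
            t = lo
            while t + epoch_len_s <= hi + 1e-9:
                epochs.append(Epoch(t, t + epoch_len_s, role, "rest"))
                t += epoch_len_s
    else:
        evs = list(events)
        if sum(e.kind == "trial" for e in evs) < 2:
            raise ValidationError("task recordings need at least 2 trials")
        for i, e in enumerate(evs):
            if e.offset_s > recording.duration_s + 1e-9:
                raise ValidationError("event extends beyond the recording")
            if e.kind == "trial":
                epochs.append(Epoch(e.onset_s, e.offset_s, "test", "on_task"))
            else:
                followed = i + 1 < len(evs) and evs[i + 1].kind == "trial"
                if followed:
                    epochs.append(Epoch(e.onset_s, e.offset_s, "train", "iti"))
    return EpochSet(epochs, fs=recording.fs)


def reject_epochs(epoch_set: EpochSet, signal: np.ndarray,
                  sd_multiple: float = 3.0) -> EpochSet:
    """Reject epochs whose peak amplitude exceeds ``sd_multiple`` times the
    standard deviation of the (Laplacian) signal over the whole recording.

    Already-rejected epochs stay rejected; the operation is idempotent
    because the threshold depends only on the full recording.
    """
    fs = epoch_set.fs
    threshold = sd_multiple * float(np.std(signal))
    out = []
    for e in epoch_set.epochs:
        i0, i1 = int(round(e.start_s * fs)), int(round(e.end_s * fs))
        seg = signal[i0:i1]
        kept = e.kept and (seg.size > 0) and (np.max(np.abs(seg)) <= threshold)
        out.append(replace(e, kept=bool(kept)))
    return EpochSet(out, fs=fs)
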