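"""Educated Temporal Prediction (ETP) of alpha peaks.

ETP is a parameter-free forecaster: a training pass learns the mean
interval between consecutive peaks of the alpha-band filtered signal,
and at test time the next peak is predicted as the time of the last seen
peak plus that mean interval.  Test-time peak detection runs causally on
500 ms sliding windows filtered with an ideal ("brickwall") FFT bandpass;
peaks near window edges are ignored because the ideal filter rings there.

The band defaults to 8-13 Hz but is normally individualized to
IAF +/- 2.5 Hz, preserving the 5 Hz width of the default band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .containers import DEFAULT_ALPHA_BAND, TrainingFailedError, ValidationError
from .filters import bandpass

#: Half-width of the individualized band around the IAF (Hz).
IAF_HALF_WIDTH = 2.5


def individualized_band(iaf_hz: float, half_width: float = IAF_HALF_WIDTH):
    return (iaf_hz - half_width, iaf_hz + half_width)


@dataclass
class ETPModel:
    """Learned mean interpeak interval for one recording."""

    mean_ipi_ms: float
    mean_ipi_samples: int
    band: tuple[float, float]
    n_intervals_used: int
    fs: float


@dataclass(frozen=True)
class PredictionRecord:
    """One forecast: the last seen peak plus the mean interpeak interval."""

    predicted_time_s: float
    source_peak_time_s: float
    window_end_s: float
    epoch_id: int


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict-left / non-strict-right local maxima."""
    if x.size < 3:
        return np.array([], dtype=int)
    core = (x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])
    return np.where(core)[0] + 1


def train_etp(signal: np.ndarray, fs: float, train_epochs,
              band: tuple[float, float] = DEFAULT_ALPHA_BAND,
              min_intervals: int = 10) -> ETPModel:
    """Learn the mean interpeak interval from training epochs.

    The continuous signal is bandpassed once with a zero-phase Hamming
    FIR; peaks are local maxima of the filtered signal inside each
    training epoch, and intervals between consecutive peaks of the same
    epoch are kept when they fall inside the plausible alpha range
    ``[1000/hi, 1000/lo]`` ms (a guard against double-peak artifacts).
    """
    epochs = list(train_epochs)
    total_s = sum(e.end_s - e.start_s for e in epochs)
    if total_s < 30.0:
        raise TrainingFailedError(
            f"only {total_s:.1f} s of training data (need >= 30 s)")
    filt = bandpass(np.asarray(signal, dtype=float), fs, band)
    lo_ms, hi_ms = 1000.0 / band[1], 1000.0 / band[0]
    intervals_ms = []
    for e in epochs:
        i0, i1 = int(round(e.start_s * fs)), int(round(e.end_s * fs))
        peaks = _local_maxima(filt[i0:i1])
        ipis = np.diff(peaks) * 1000.0 / fs
        intervals_ms.extend(ipis[(ipis >= lo_ms) & (ipis <= hi_ms)])
    if len(intervals_ms) < min_intervals:
        raise TrainingFailedError(
            f"{len(intervals_ms)} usable interpeak intervals (need >= {min_intervals})")
    mean_ms = float(np.mean(intervals_ms))
    return ETPModel(mean_ipi_ms=mean_ms,
                    mean_ipi_samples=int(round(mean_ms * fs / 1000.0)),
                    band=tuple(band), n_intervals_used=len(intervals_ms), fs=fs)


def brickwall(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Ideal bandpass: zero FFT coefficients outside ``band``, inverse
    transform, real part.  Operates on the last axis."""
    n = x.shape[-1]
    spec = np.fft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[..., (f < band[0]) | (f > band[1])] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def predict_peaks(signal: np.ndarray, fs: float, epoch, model: ETPModel,
                  epoch_id: int = 0, window_s: float = 0.5,
                  edge_margin_s: float = 0.06) -> list[PredictionRecord]:
    """Slide a 500 ms window sample by sample over a test epoch and emit
    peak forecasts.

    Per window the data are brickwall-filtered to the model band and local
    maxima away from the window edges are designated peaks; with no peak
    the window is skipped.  The forecast is the last seen peak plus the
    learned mean interpeak interval.  Each distinct last-seen peak emits
    one prediction, from the first window whose forecast lands strictly
    beyond the window end (a genuine forecast, never a postdiction);
    forecasts beyond the epoch end are dropped.
    """
    if epoch.end_s <= epoch.start_s:
        raise ValidationError("empty epoch")
    i0 = int(round(epoch.start_s * fs))
    i1 = int(round(epoch.end_s * fs))
    x = np.asarray(signal, dtype=float)[i0:i1]
    w = int(round(window_s * fs))
    if x.size < w:
        return []
    margin = int(round(edge_margin_s * fs))
    wins = sliding_window_view(x, w)                    # (n_win, w)
    filt = brickwall(wins, fs, model.band)
    is_peak = np.zeros_like(filt, dtype=bool)
    is_peak[:, 1:-1] = (filt[:, 1:-1] > filt[:, :-2]) & (filt[:, 1:-1] >= filt[:, 2:])
    if margin > 0:
        is_peak[:, :margin] = False
        is_peak[:, w - margin:] = False
    has_peak = is_peak.any(axis=1)
    if not has_peak.any():
        return []
    # index of the last peak inside each window
    rev_arg = np.argmax(is_peak[:, ::-1], axis=1)
    last_rel = (w - 1) - rev_arg
    win_idx = np.where(has_peak)[0]
    source_abs = win_idx + last_rel[win_idx]            # samples within epoch
    predicted_abs = source_abs + model.mean_ipi_samples
    window_end_abs = win_idx + (w - 1)
    ok = predicted_abs > window_end_abs                 # forecast, not postdiction
    ok &= predicted_abs < x.size                        # inside the epoch
    win_idx, source_abs, predicted_abs, window_end_abs = (
        a[ok] for a in (win_idx, source_abs, predicted_abs, window_end_abs))
    # first emitting window per distinct source peak
    _, first = np.unique(source_abs, return_index=True)
    records = []
    for j in np.sort(first):
        records.append(PredictionRecord(
            predicted_time_s=(i0 + predicted_abs[j]) / fs,
            source_peak_time_s=(i0 + source_abs[j]) / fs,
            window_end_s=(i0 + window_end_abs[j]) / fs,
            epoch_id=epoch_id,
        ))
    return records


def predict_epochs(signal: np.ndarray, fs: float, test_epochs,
                   model: ETPModel, **kwargs) -> list[PredictionRecord]:
    """Run :func:`predict_peaks` over a sequence of test epochs."""
    records: list[PredictionRecord] = []
    for k, e in enumerate(test_epochs):
        records.extend(predict_peaks(signal, fs, e, model, epoch_id=k, **kwargs))
    return records
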