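"""Ground-truth phase, prediction scoring and circular summaries.

Ground truth is the instantaneous phase of the alpha-band filtered
signal obtained from the analytic (Hilbert) signal, with the cosine
convention: a local maximum of the oscillation is 0 degrees.  Each
forecast is scored with

    accuracy = 1 - |theta_i - theta_t|_circ / 180

where ``theta_i`` is the ground-truth phase at the predicted time,
``theta_t`` the targeted phase (0 degrees, a peak), and the difference
is circular.  Accuracy 1 means the prediction landed exactly on the
targeted phase; accuracy 0 means the opposite phase.

The instantaneous-power covariate is the Hilbert envelope amplitude (uV)
of the band-filtered signal at the moment of prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import (
    DEFAULT_ALPHA_BAND,
    PhaseTrace,
    ValidationError,
    circular_abs_diff_deg,
    wrap_degrees,
)
from .filters import fir_bandpass_taps, zero_phase_filter


@dataclass
class CircularSummary:
    mean_error_deg: float
    circular_sd_deg: float
    mean_accuracy: float
    sd_accuracy: float
    n: int


def _analytic(signal: np.ndarray, fs: float, band) -> tuple[np.ndarray, np.ndarray, int]:
    taps = fir_bandpass_taps(band[0], band[1], fs)
    filt = zero_phase_filter(taps, np.asarray(signal, dtype=float))
    analytic = sps.hilbert(filt)
    edge = taps.size // 2
    return analytic, filt, edge


def ground_truth_phase(signal: np.ndarray, fs: float,
                       band=DEFAULT_ALPHA_BAND) -> PhaseTrace:
    """Hilbert instantaneous phase of the zero-phase band-filtered signal.

    Samples within half a filter length of either end are marked invalid
    (filter and Hilbert edge effects).
    """
    analytic, _, edge = _analytic(signal, fs, band)
    phase = wrap_degrees(np.degrees(np.angle(analytic)))
    valid = np.ones(phase.size, dtype=bool)
    valid[:edge] = False
    valid[phase.size - edge:] = False
    return PhaseTrace(phase, fs=fs, valid_mask=valid)


def hilbert_envelope(signal: np.ndarray, fs: float,
                     band=DEFAULT_ALPHA_BAND) -> np.ndarray:
    """Instantaneous amplitude (uV) of the band-filtered signal."""
    analytic, _, _ = _analytic(signal, fs, band)
    return np.abs(analytic)


def instantaneous_power(signal: np.ndarray, fs: float, band, t_s: float) -> float:
    """Hilbert envelope of the band-filtered signal at time ``t_s``."""
    env = hilbert_envelope(signal, fs, band)
    idx = int(round(t_s * fs))
    if not (0 <= idx < env.size):
        raise ValidationError("time outside signal")
    return float(env[idx])


def accuracy_from_phase(theta_i_deg, theta_t_deg: float = 0.0):
    """The accuracy statistic: 1 - circular|theta_i - theta_t| / 180."""
    d = circular_abs_diff_deg(theta_i_deg, theta_t_deg)
    return 1.0 - d / 180.0


def score(prediction, phase_trace: PhaseTrace, theta_t_deg: float = 0.0) -> dict:
    """Score one prediction against the ground-truth phase trace."""
    if not phase_trace.is_valid_at(prediction.predicted_time_s):
        raise ValidationError("predicted time outside the valid phase region")
    theta_i = phase_trace.at_time(prediction.predicted_time_s)
    return {
        "theta_i_deg": theta_i,
        "accuracy": float(accuracy_from_phase(theta_i, theta_t_deg)),
        "predicted_time_s": prediction.predicted_time_s,
        "source_peak_time_s": prediction.source_peak_time_s,
        "epoch_id": prediction.epoch_id,
    }


def score_predictions(predictions, signal: np.ndarray, fs: float,
                      band=DEFAULT_ALPHA_BAND, phase_trace: PhaseTrace | None = None,
                      theta_t_deg: float = 0.0, state: str = "EC",
                      dataset_id: str = "synthetic", individual_id: str = "s01",
                      snr_db: float = np.nan) -> pd.DataFrame:
    """Long-format accuracy table for a recording's predictions.

    ``phase_trace`` defaults to the Hilbert ground truth computed from
    ``signal``; pass the generator's trace to score against exact truth.
    The instantaneous-power covariate always comes from the Hilbert
    envelope of ``signal`` (the quantity available in practice).
    Predictions landing in invalid phase regions are silently dropped.
    """
    if phase_trace is None:
        phase_trace = ground_truth_phase(signal, fs, band)
    env = hilbert_envelope(signal, fs, band)
    rows = []
    for p in predictions:
        if not phase_trace.is_valid_at(p.predicted_time_s):
            continue
        rec = score(p, phase_trace, theta_t_deg)
        rec["inst_power"] = float(env[int(round(p.predicted_time_s * fs))])
        rec.update(state=state, dataset_id=dataset_id, individual_id=individual_id,
                   snr_db=snr_db)
        rows.append(rec)
    cols = ["dataset_id", "individual_id", "state", "epoch_id",
            "predicted_time_s", "source_peak_time_s", "theta_i_deg",
            "accuracy", "inst_power", "snr_db"]
    return pd.DataFrame(rows, columns=cols)


def summarize(records: pd.DataFrame) -> CircularSummary:
    """Circular mean/SD of the phase errors plus accuracy moments."""
    theta = np.radians(records["theta_i_deg"].to_numpy(dtype=float))
    n = theta.size
    if n == 0:
        return CircularSummary(np.nan, np.nan, np.nan, np.nan, 0)
    z = np.exp(1j * theta).mean()
    mean_err = wrap_degrees(np.degrees(np.angle(z)))
    r = np.abs(z)
    circ_sd = np.degrees(np.sqrt(-2.0 * np.log(max(r, 1e-12))))
    acc = records["accuracy"].to_numpy(dtype=float)
    return CircularSummary(float(mean_err), float(circ_sd),
                           float(acc.mean()), float(acc.std(ddof=1)) if n > 1 else 0.0,
                           int(n))


def deg_to_ms(deg: float, freq_hz: float) -> float:
    """Angular offset to time for an oscillation at ``freq_hz``: a full
    360-degree cycle spans one period (1000/freq ms)."""
    return deg / 360.0 * 1000.0 / freq_hz


def acc_diff_to_deg(pct: float) -> float:
    """Accuracy difference (percentage points) to phase angle: 100% of
    accuracy spans the 180-degree half cycle."""
    return pct / 100.0 * 180.0
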