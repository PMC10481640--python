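"""FIR filter design and zero-phase application.

All offline filtering uses Hamming-windowed FIR designs applied
forward-backward, so the filters contribute no group delay and cannot
skew the phase traces the analysis is built around.  The forward-backward
pass is implemented with FFT convolution, which is orders of magnitude
faster than direct convolution for the long high-pass kernels needed at
a 0.15 Hz band edge.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .containers import ValidationError


def fir_bandpass_taps(lo_hz: float, hi_hz: float, fs: float,
                      transition_hz: float | None = None) -> np.ndarray:
    """Design a Hamming-window FIR bandpass.

    The transition bandwidth defaults to ``min(max(lo/4, 2), lo)`` Hz, the
    usual rule for keeping the kernel short while still resolving a low
    band edge; kernel length follows the Hamming approximation
    ``N = 3.3 * fs / transition``.
    """
    nyq = fs / 2.0
    if not (0 < lo_hz < hi_hz < nyq):
        raise ValidationError(f"band ({lo_hz}, {hi_hz}) invalid for fs={fs}")
    if transition_hz is None:
        transition_hz = min(max(lo_hz / 4.0, 2.0), lo_hz)
    numtaps = int(np.ceil(3.3 * fs / transition_hz))
    numtaps += (numtaps + 1) % 2  # odd length -> integer group delay
    return sps.firwin(numtaps, [lo_hz, hi_hz], pass_zero=False,
                      window="hamming", fs=fs)


def _zero_phase_1d(taps: np.ndarray, x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    pad = min(3 * taps.size, n - 1)
    # odd reflection padding, as in filtfilt, to suppress edge transients
    left = 2.0 * x[0] - x[pad:0:-1]
    right = 2.0 * x[-1] - x[-2:-pad - 2:-1]
    xp = np.concatenate([left, x, right])
    fwd = sps.fftconvolve(xp, taps, mode="same")
    bwd = sps.fftconvolve(fwd[::-1], taps, mode="same")[::-1]
    return bwd[pad:pad + n]


def zero_phase_filter(taps: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Apply an odd-length FIR forward and backward (zero net phase).

    Accepts a 1-D signal or a samples x channels matrix.
    """
    taps = np.asarray(taps, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.shape[0] <= taps.size // 4:
        raise ValidationError("signal too short for the requested filter")
    if x.ndim == 1:
        return _zero_phase_1d(taps, x)
    out = np.empty_like(x)
    for c in range(x.shape[1]):
        out[:, c] = _zero_phase_1d(taps, x[:, c])
    return out


def bandpass(x: np.ndarray, fs: float, band: tuple[float, float],
             transition_hz: float | None = None) -> np.ndarray:
    """Zero-phase Hamming FIR bandpass of ``x`` to ``band`` Hz."""
    taps = fir_bandpass_taps(band[0], band[1], fs, transition_hz)
    return zero_phase_filter(taps, x)


def highpass_residual(x: np.ndarray, fs: float, cutoff_hz: float = 45.0) -> np.ndarray:
    """High-frequency residual of ``x`` above ``cutoff_hz`` (zero phase)."""
    taps = sps.firwin(int(np.ceil(3.3 * fs / 10.0)) | 1, cutoff_hz,
                      pass_zero=False, window="hamming", fs=fs)
    return zero_phase_filter(taps, x)
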