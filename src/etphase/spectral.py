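"""Spectral characterization: Welch PSD, aperiodic 1/f fit, IAF and SNR.

The signal-to-noise ratio of an alpha oscillation is defined here as the
elevation, in decibels, of the Welch power spectrum at the individual
alpha frequency (IAF) above a straight line fitted to the spectrum in
log-log coordinates over frequencies away from the alpha band.  Both the
IAF and the SNR feed quality control (recordings without a detectable
alpha peak, or with negative SNR, are excluded) and later serve as
covariates in the accuracy models.

dB convention: power is expressed as 10*log10(power); one power decade at
the peak therefore equals 10 dB of SNR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import DEFAULT_ALPHA_BAND, ValidationError

#: Frequency intervals (Hz) used for the aperiodic line fit.  The upper
#: interval stops at 60 Hz because the wideband prefilter removes content
#: above that frequency.
DEFAULT_FIT_RANGES: tuple[tuple[float, float], ...] = ((0.5, 7.0), (35.0, 60.0))


def db(power):
    """Power in decibels, 10*log10(power)."""
    return 10.0 * np.log10(np.maximum(np.asarray(power, dtype=float), 1e-30))


@dataclass
class PowerSpectrum:
    freqs: np.ndarray  # Hz, uniform grid
    power: np.ndarray  # uV^2/Hz, non-negative

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValidationError("freqs and power must have equal shape")
        if np.any(self.power < 0):
            raise ValidationError("power must be non-negative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def power_at(self, f_hz: float) -> float:
        """Power at the grid bin nearest ``f_hz``."""
        return float(self.power[int(np.argmin(np.abs(self.freqs - f_hz)))])


@dataclass
class AperiodicFit:
    """Straight line fitted to the PSD in (log10 f, dB power) coordinates."""

    slope: float       # dB per decade of frequency
    intercept: float   # dB at 1 Hz
    fit_ranges: tuple = DEFAULT_FIT_RANGES

    def predict_db(self, f_hz):
        return self.intercept + self.slope * np.log10(np.asarray(f_hz, dtype=float))

    def predict_power(self, f_hz):
        return 10.0 ** (self.predict_db(f_hz) / 10.0)


@dataclass
class SpectralSummary:
    iaf: float
    snr_db: float
    peak_found: bool
    excluded: bool
    slope: float = np.nan
    intercept: float = np.nan


def welch_psd(x: np.ndarray, fs: float, seg_s: float = 2.0) -> PowerSpectrum:
    """Welch periodogram: 50% overlapping segments of ``seg_s`` seconds,
    linearly detrended, Hann windowed and averaged.  With 2 s segments the
    frequency resolution is 0.5 Hz."""
    x = np.asarray(x, dtype=float)
    nperseg = int(round(seg_s * fs))
    if x.size < 2 * nperseg:
        raise ValidationError(
            f"signal of {x.size / fs:.2f} s too short for {seg_s} s Welch segments")
    f, p = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, detrend="linear")
    return PowerSpectrum(f, p)


def fit_aperiodic(spectrum: PowerSpectrum,
                  fit_ranges=DEFAULT_FIT_RANGES) -> AperiodicFit:
    """Ordinary least squares line through (log10 f, dB power), restricted
    to the declared frequency ranges (the alpha band lies outside them, so
    an oscillatory peak does not bias the fit)."""
    f, p = spectrum.freqs, spectrum.power
    mask = np.zeros_like(f, dtype=bool)
    for lo, hi in fit_ranges:
        mask |= (f >= lo) & (f <= hi)
    mask &= f > 0
    if mask.sum() < 10:
        raise ValidationError("fewer than 10 spectral points in the fit ranges")
    slope, intercept = np.polyfit(np.log10(f[mask]), db(p[mask]), 1)
    return AperiodicFit(float(slope), float(intercept), tuple(fit_ranges))


def find_iaf(spectrum: PowerSpectrum, fit: AperiodicFit,
             band: tuple[float, float] = DEFAULT_ALPHA_BAND,
             min_elevation_db: float = 1.0) -> tuple[float, bool]:
    """Individual alpha frequency from the Welch spectrum.

    Peaks are local maxima of the PSD inside ``band`` that rise above the
    aperiodic fit by more than ``min_elevation_db`` — roughly two standard
    errors of the Welch estimate at the segment counts used here, so that
    sampling wiggles of the background do not register as oscillatory
    peaks.  A single peak gives its bin frequency directly; several peaks
    give the mean of their frequencies weighted by their alpha power in
    excess of the background fit.  Returns ``(nan, False)`` when no peak
    is found.  No sub-bin interpolation is applied; the 0.5 Hz bin center
    is reported.
    """
    f, p = spectrum.freqs, spectrum.power
    in_band = np.where((f >= band[0]) & (f <= band[1]))[0]
    if in_band.size < 3:
        raise ValidationError("spectrum does not cover the alpha band")
    peaks = []
    for i in in_band:
        left = p[i - 1] if i > 0 else -np.inf
        right = p[i + 1] if i < p.size - 1 else -np.inf
        elevated = db(p[i]) - fit.predict_db(f[i]) > min_elevation_db
        if p[i] > left and p[i] >= right and elevated:
            peaks.append(i)
    if not peaks:
        return float("nan"), False
    if len(peaks) == 1:
        return float(f[peaks[0]]), True
    w = p[peaks] - fit.predict_power(f[peaks])
    return float(np.sum(f[peaks] * w) / np.sum(w)), True


def compute_snr(spectrum: PowerSpectrum, fit: AperiodicFit, iaf: float,
                band: tuple[float, float] = DEFAULT_ALPHA_BAND) -> float:
    """SNR in dB: spectral power at the alpha peak minus the aperiodic fit
    at that frequency, both on the dB scale.

    The power is taken at the dominant alpha peak — the bin of highest
    in-band power.  With a single spectral peak this is the IAF itself;
    with several peaks the IAF is a power-weighted mean that generally
    falls between peaks, where evaluating the amplitude would understate
    the oscillation, so the dominant peak is used instead.
    """
    if not np.isfinite(iaf):
        raise ValidationError("SNR requires a detected alpha peak")
    f, p = spectrum.freqs, spectrum.power
    in_band = np.where((f >= band[0]) & (f <= band[1]))[0]
    i_pk = in_band[np.argmax(p[in_band])]
    return float(db(p[i_pk]) - fit.predict_db(f[i_pk]))


def summarize_signal(x: np.ndarray, fs: float,
                     band: tuple[float, float] = DEFAULT_ALPHA_BAND,
                     fit_ranges=DEFAULT_FIT_RANGES) -> SpectralSummary:
    """Convenience wrapper: Welch -> aperiodic fit -> IAF -> SNR -> QC flag."""
    spec = welch_psd(x, fs)
    fit = fit_aperiodic(spec, fit_ranges)
    iaf, found = find_iaf(spec, fit, band)
    snr = compute_snr(spec, fit, iaf) if found else float("nan")
    excluded = (not found) or (snr < 0)
    return SpectralSummary(iaf=iaf, snr_db=snr, peak_found=found,
                           excluded=excluded, slope=fit.slope,
                           intercept=fit.intercept)


def qc_exclude(summaries: pd.DataFrame) -> pd.DataFrame:
    """Recording- and participant-level exclusion decisions.

    ``summaries`` must have columns ``individual_id``, ``snr_db`` and
    ``peak_found`` (one row per recording).  A recording is excluded when
    its SNR is negative or no alpha peak was found; a participant is
    excluded when none of their recordings survive.
    """
    out = summaries.copy()
    out["excluded"] = (~out["peak_found"].astype(bool)) | (out["snr_db"] < 0)
    surviving = out.loc[~out["excluded"], "individual_id"].unique()
    out["individual_excluded"] = ~out["individual_id"].isin(surviving)
    return out
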