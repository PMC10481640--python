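# Methods

`etphase` studies how well upcoming peaks of the parieto-occipital alpha
rhythm (8–13 Hz) can be forecast from running EEG, and how forecast
accuracy depends on cognitive state (eyes-closed rest, eyes-open rest,
task), instantaneous alpha power, and the recording's signal-to-noise
ratio (SNR). Real EEG never reveals the true instantaneous phase of an
oscillation, so the package is built around a synthetic generator whose
alpha component has a recorded, exact phase; every downstream stage is
validated against that ground truth.

## Synthetic EEG

A session is `envelope(t)·cos(φ(t))` alpha plus 1/f^χ aperiodic noise on
32 channels of the 10–20 system at 250 Hz.

**Aperiodic background.** White Gaussian noise is shaped in the frequency
domain by `f^(−χ/2)` (amplitudes), giving an exact `offset·f^(−χ)` power
spectrum for any seed (default χ = 1, offset 1 μV²/Hz at 1 Hz). Channels
mix a shared common-mode component (80% of noise variance) with an
independent component. The common mode mimics the strong spatial
correlation of referential scalp EEG — without it, a
correlation-to-neighbours bad-channel criterion would reject every
channel of the montage — and it cancels exactly in the surface Laplacian,
which is precisely what that montage is for.

**Alpha component.** The phase ramp is `φ0 + 2π f t` with `f ∈ [8, 13]`
Hz; `φ0` is drawn uniformly per seed (it can be pinned for oracle tests
that need peaks aligned to the sample grid). The bursty envelope —
low-pass-filtered Gaussian noise (timescale 1 s), standardized, scaled by
depth 0.75 and clamped above 0.05 — reproduces the waxing and waning of
alpha power needed to study the power→accuracy relation. A constant
envelope is available for analytic checks.

**Spatial projection and SNR calibration.** Alpha projects with weight
1.0 at Pz/Oz, 0.5 at P3/P4/Cz, 0.1 elsewhere. The alpha amplitude is
calibrated so that the package's own spectral estimator, applied to the
Pz-centred Laplacian signal, reports the target SNR: one analytic rescale
from the measured band powers (`a² = (r−1)·N(f_peak)/P_α(f_peak)`, with
`r` the linear SNR target) followed by a single verification pass that
re-measures the elevation at the injected peak bin. Measured calibration
error is ≲0.2 dB for targets of 3–15 dB. Targets at or below 0 dB cannot
be represented by *adding* signal (a peak cannot sit below the aperiodic
fit), so the generator instead emits an alpha-free recording with the
alpha band of the noise suppressed — the kind of recording quality
control is meant to exclude.

**Sessions.** Task sessions alternate intertrial intervals (drawn
uniformly from 0.25–2 s) and trials (1–7.1 s), beginning with an
intertrial interval and ending with a trial so that intertrial and trial
epochs are equally numerous before artifact rejection. Rest sessions
(EC/EO) carry no events. Identical spec + seed gives bit-identical
output. Artifact injection (spikes, flatlined stretches, high-frequency
channel noise) leaves untouched samples bit-identical.

## Preprocessing

Recordings are downsampled (polyphase) to 250 Hz when needed and
bandpassed 0.15–60 Hz with a Hamming-window FIR applied
forward-backward (zero phase — forecasting error must not be confounded
by filter delay). Bad channels are detected *before* filtering (a
flatline is only exactly constant in raw data) with three criteria:
reconstruction correlation below 0.85 against a ridge regression on all
other channels over 5 s windows, high-frequency (>45 Hz) noise more than
4 SD above the channel population, and flat data for more than 5 s. The
analysis signal is the surface Laplacian, Pz minus the mean of the
available surround channels (Oz, Cz, P3, P4; at least two required,
reweighting over the remainder when some are rejected).

Rest recordings are split in half — first half training, second half
test — and tiled with 2 s epochs; task recordings use intertrial
intervals as training and trials as test. Epochs whose peak Laplacian
amplitude exceeds 3× the whole-recording Laplacian SD are rejected. On
Gaussian synthetic data this is a conservative criterion (Gaussian tails
put ~30–40% of 2 s epochs over the threshold; real EEG has heavier tails
*and* artifact-inflated SDs, making rejection rarer), so default session
durations are chosen to leave ≥30 s of training data after rejection.
Rejection depends only on the full recording, hence is idempotent.

## Spectral characterization

Welch spectra use 2 s Hann segments, 50% overlap, linear detrending
(0.5 Hz resolution). The aperiodic background is an ordinary
least-squares line through (log10 f, 10·log10 P) restricted to 0.5–7 and
35–60 Hz — outside the alpha band, so the fit ignores the oscillation;
the upper limit is 60 Hz because the wideband prefilter removes content
above it. All decibel quantities use the power convention 10·log10.

The individual alpha frequency (IAF) is the 8–13 Hz bin of highest power
when the spectrum has one peak there. A peak must exceed the aperiodic
fit by more than 1 dB — roughly two standard errors of the Welch
estimate at these segment counts — so that sampling wiggles of the
background are not mistaken for oscillations. With several peaks the IAF
is their mean weighted by power *in excess of* the fit. SNR is the dB
elevation of the dominant in-band peak above the fit at that frequency
(identical to "power at the IAF" in the single-peak case; when the IAF
is a multi-peak weighted mean it falls between peaks, where evaluating
the spectrum would understate the oscillation). Recordings with negative
SNR or no detectable peak are excluded; participants are excluded when
none of their recordings survive. Injected IAFs of 8.5/10/12.5 Hz are
recovered exactly (bin-resolution) at ≥6 dB, and injected SNRs of
3–15 dB within ~0.5 dB on 10-seed means.

## Peak forecasting (ETP)

Training bandpasses the continuous Laplacian signal to the alpha band
(default 8–13 Hz; normally individualized to IAF ± 2.5 Hz, preserving the
5 Hz default width) with a zero-phase Hamming FIR, finds local maxima
inside each training epoch, and averages the intervals between
consecutive peaks, keeping only intervals inside the band-plausible
range `[1000/f_hi, 1000/f_lo]` ms (a guard against double peaks). At
least 30 s of training data and 10 usable intervals are required.

At test time a 500 ms window slides sample by sample. Each window is
filtered with an ideal FFT bandpass ("brickwall": coefficients outside
the band zeroed); local maxima more than 60 ms from either window edge
(where the ideal filter rings) are peaks; windows without peaks are
skipped. The forecast is the last seen peak plus the learned mean
interval. Each distinct last-seen peak emits exactly one prediction,
from the first window whose forecast lands strictly beyond the window
end — a causal forecast, never a postdiction — and forecasts beyond the
epoch end are dropped. The implementation batches all windows through a
single vectorized FFT; causality is asserted by tests, not just by
construction.

On noiseless, sample-aligned 10 Hz alpha the learned interval is
100.0 ms and every forecast lands within one sample of a true peak
(accuracy ≈ 1.0). With a random initial phase, sample-grid quantization
alone (14.4°/sample at 10 Hz / 250 Hz) bounds expected accuracy near
0.98 — a useful reminder that part of any measured inaccuracy is the
sampling grid, not the algorithm.

## Scoring and ground truth

Ground truth is the Hilbert instantaneous phase of the zero-phase
alpha-filtered signal, cosine convention (0° at peaks), with samples
within half a filter length of the recording edges masked invalid.
Against the generator's exact phase this estimate is accurate to well
under 5° RMSE wherever the envelope is non-negligible (phase is
undefined in deep envelope troughs). Each forecast is scored

    accuracy = 1 − |θ_i − θ_t|_circ / 180,

with θ_i the ground-truth phase at the predicted time and θ_t = 0°. The
difference is circular (the raw formula is undefined at the ±180° wrap).
The instantaneous-power covariate is the Hilbert envelope amplitude (μV)
at the moment of prediction — "power" in the amplitude sense; the
squared convention would only rescale the covariate. Circular summaries
report the circular mean and SD of θ_i; degrees convert to milliseconds
via the full 360° cycle (47.34° at 10 Hz ↦ 13.15 ms) and accuracy
percentage points to degrees via the 180° half cycle (5.75 % ↦ 10.35°).

## Multilevel accuracy models

Forecast records nest within individuals within datasets. Accuracy
(scaled to 0–100 so coefficients read in percentage points) is modelled
with linear mixed-effects models fitted by maximum likelihood
(statsmodels MixedLM), with presets:

* null: intercept + (1 | dataset) + (1 | dataset:individual)
* base: + state (EC reference)
* intermediate: state×power fixed effects, random power slopes
* full: state×power×SNR (12 fixed terms), random power·SNR slopes

The dataset level carries an unstructured random-effects covariance;
individual-within-dataset effects enter as independent variance
components. On non-convergence the dataset slopes fall back to
independent components, recorded on the result. Wald t tests use
residual degrees of freedom; 95% CIs are ±1.96 SE. Nested models are
compared by likelihood-ratio tests (χ² = 2Δll, df = parameter
difference). Because optimizers occasionally stall the larger model
below the smaller one's likelihood — impossible at the true ML optimum —
the LRT re-optimizes the larger model from the smaller model's solution
whenever the nesting property is violated and the two share their random
structure.

Simulation checks use hierarchical data with known effects (state
effects −2.03 / −2.78 points, unit-mean gamma power). Coverage of the
95% CI is checked at 15 datasets × 6 individuals × 25 records; LRT power
at 45 datasets (state is a between-dataset effect, so power is governed
by cluster count — the full-scale analysis this emulates pooled ~1.5
million records, which desk-scale simulation replaces with more
clusters); type-I calibration at 30 datasets, where the ML-LRT p-values
are uniform under the null (KS test).

## Pipeline

`run_pipeline(config)` chains simulate → preprocess → spectral QC →
train → predict → evaluate → model from a single master seed
(`SeedSequence` substreams per recording), writing every interface as
CSV/JSON into the run directory; identical config + seed reproduce
byte-identical outputs, and QC-excluded recordings contribute no
predictions and no model rows. The `etphase` CLI exposes each stage and
`run-all`; thresholds (0.85 correlation, 4 SD, 5 s flat, 3 SD epochs,
500 ms window, 2 s epochs) are configurable with the defaults above.

Default session durations (240 s rest, 300 s task in examples; 120–160 s
in tests) are chosen so that training data survive epoch rejection with
margin while keeping full runs fast.

## Known limitations

* The generator is stationary in frequency (no IAF drift), uses Gaussian
  noise (real EEG is leptokurtic), and has no biophysical head model or
  blink/EMG morphology; passing tests demonstrate algorithmic
  correctness and directional effects, not clinical realism.
* Task instantaneous power and SNR are independent knobs; the generator
  does not model why task states can show higher power at lower SNR.
* SNR below ~3 dB is represented but not precisely calibrated; at and
  below 0 dB the recording is alpha-free by construction.
* The eBOSC-style robust-regression SNR variant is out of scope.
* Individual-level random slopes are independent (diagonal), not
  unstructured — a statsmodels constraint.
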