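# etphase

Forecasting the phase of parieto-occipital alpha waves in EEG — and
quantifying how forecast accuracy depends on cognitive state,
instantaneous alpha power, and signal-to-noise ratio (SNR).

Closed-loop EEG experiments and brain–computer interfaces need to hit a
target phase of an ongoing oscillation *before* it happens. `etphase`
implements the Educated Temporal Prediction (ETP) approach: learn an
individual's mean interval between consecutive alpha peaks from training
data, then forecast the next peak as *last seen peak + mean interpeak
interval*, detecting peaks causally in 500 ms sliding windows with an
ideal ("brickwall") bandpass. Forecasts are scored against Hilbert
ground-truth phase with the linear accuracy statistic

    accuracy = 1 − |θ_i − θ_t|_circ / 180°,

which is 1 when the forecast lands on the targeted phase (0°, a peak)
and 0 at the opposite phase. Accuracy records are then modelled with
nested linear mixed-effects models,

    accuracy ~ state + (1 | dataset) + (1 | dataset:individual)

up to the maximal `state × power × SNR` model with random slopes,
compared by likelihood-ratio tests.

Because real EEG never reveals an oscillation's true phase, the package
ships a synthetic EEG generator: a known-phase alpha component (bursty
or constant envelope) over 1/f aperiodic noise on 32 channels of the
10–20 system at 250 Hz, with the alpha amplitude calibrated so the
package's own spectral estimator measures a requested SNR on the
Pz-centred surface Laplacian. Every pipeline stage — 0.15–60 Hz
zero-phase FIR filtering, bad-channel rejection, Laplacian referencing,
epoch extraction and 3 SD artifact rejection, Welch spectra with a
log-log aperiodic line fit, individual alpha frequency (IAF) and SNR
estimation with QC exclusions, ETP training/prediction, scoring, and
the multilevel models — is validated against that ground truth.

## Worked example

```python
from etphase import SyntheticSpec, generate_session
from etphase.preprocessing import extract_epochs, laplacian, reject_epochs, wideband_filter
from etphase.spectral import summarize_signal
from etphase.etp import individualized_band, predict_epochs, train_etp
from etphase.evaluation import score_predictions, summarize

spec = SyntheticSpec(duration_s=160.0, state="EC", target_snr_db=10.0, seed=5)
rec, events, true_phase = generate_session(spec)

lap = laplacian(wideband_filter(rec))          # Pz − mean(Oz, Cz, P3, P4)
summ = summarize_signal(lap, rec.fs)           # Welch + 1/f fit + IAF + SNR
band = individualized_band(summ.iaf)           # IAF ± 2.5 Hz
epochs = reject_epochs(extract_epochs(rec, events), lap)

model = train_etp(lap, rec.fs, epochs.select("train"), band)
preds = predict_epochs(lap, rec.fs, epochs.select("test"), model)
records = score_predictions(preds, lap, rec.fs, band=band)
s = summarize(records)
print(f"IAF {summ.iaf:.1f} Hz, SNR {summ.snr_db:.2f} dB, "
      f"mean IPI {model.mean_ipi_ms:.1f} ms")
print(f"{s.n} forecasts, mean accuracy {100 * s.mean_accuracy:.1f}%, "
      f"circular SD {s.circular_sd_deg:.1f} deg")
```

prints

```
IAF 10.0 Hz, SNR 10.03 dB, mean IPI 99.9 ms
821 forecasts, mean accuracy 70.6%, circular SD 67.9 deg
```

i.e. at a 10 dB alpha SNR the forecasts average about three-quarters of
the way from the opposite phase to a perfect peak hit; accuracy falls
toward chance (~0.5) as the injected SNR drops to 0 dB and rises with
instantaneous alpha power.

The same flow runs end to end from the command line:

```bash
etphase run-all --config config.yaml --seed 1
etphase report  --config config.yaml
```

where `config.yaml` declares datasets (state, individuals, duration,
target SNR), the band policy, and QC thresholds; `simulate`,
`preprocess`, `spectral`, `predict`, `evaluate` and `model` run the
stages individually over the run directory's CSV/JSON artifacts.

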