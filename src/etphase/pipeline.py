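"""End-to-end orchestration: simulate -> preprocess -> spectral -> predict
-> evaluate -> model, fully reproducible from (config, master seed).

The pipeline generates synthetic sessions per configured dataset, runs
each recording through preprocessing and spectral QC, trains ETP on the
training epochs, scores forecasts against Hilbert ground truth, pools
the long-format accuracy records, and fits the nested multilevel models.
Every stage communicates through plain CSV/JSON artifacts written to the
run directory; recordings excluded by QC contribute no predictions and
no model rows.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import etp, evaluation, mixed_models, preprocessing, spectral
from .containers import DEFAULT_ALPHA_BAND, ValidationError
from .io import save_session
from .synthetic import SyntheticSpec, generate_session

_REQUIRED_TOP = ("master_seed", "datasets")
_REQUIRED_DS = ("dataset_id", "state", "n_individuals", "duration_s")
_BAND_POLICIES = ("fixed_8_13", "iaf_pm_2.5")


@dataclass
class DatasetSpec:
    dataset_id: str
    state: str
    n_individuals: int
    duration_s: float
    target_snr_db: float = 10.0
    alpha_freq: float | None = None  # None -> drawn per individual


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (plain-text YAML on disk)."""

    master_seed: int
    datasets: list
    out_dir: str = "runs/etphase"
    band_policy: str = "iaf_pm_2.5"
    fs: float = 250.0
    epoch_len_s: float = 2.0
    window_ms: float = 500.0
    edge_margin_ms: float = 60.0
    channel_corr: float = 0.85
    hf_sd: float = 4.0
    flat_s: float = 5.0
    epoch_sd: float = 3.0
    reject_channels: bool = True
    reject_epoch_artifacts: bool = True
    spectral_exclusion: bool = True
    fit_models: tuple = ("null", "base", "intermediate", "full")
    save_sessions: bool = False

    def __post_init__(self):
        if self.band_policy not in _BAND_POLICIES:
            raise ValidationError(f"band_policy must be one of {_BAND_POLICIES}")
        if not self.datasets:
            raise ValidationError("config declares no datasets")
        self.datasets = [d if isinstance(d, DatasetSpec) else DatasetSpec(**d)
                         for d in self.datasets]
        # YAML reads a bare `null` list entry as None; map it back
        self.fit_models = tuple("null" if m is None else str(m)
                                for m in self.fit_models)
        known = {"null", "base", "intermediate", "full"}
        bad = set(self.fit_models) - known
        if bad:
            raise ValidationError(f"unknown model presets {sorted(bad)}")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        for key in _REQUIRED_TOP:
            if key not in raw:
                raise ValidationError(f"config missing required key {key!r}")
        for ds in raw["datasets"]:
            for key in _REQUIRED_DS:
                if key not in ds:
                    raise ValidationError(f"dataset entry missing key {key!r}")
        fields_ = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - fields_
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        raw = dict(raw)
        if "fit_models" in raw:
            raw["fit_models"] = tuple(raw["fit_models"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["datasets"] = [dict(ds.__dict__) for ds in self.datasets]
        d["fit_models"] = list(self.fit_models)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _recording_band(config: PipelineConfig, summary) -> tuple[float, float]:
    if config.band_policy == "fixed_8_13":
        return DEFAULT_ALPHA_BAND
    return etp.individualized_band(summary.iaf)


def process_recording(recording, events, config: PipelineConfig):
    """One recording through preprocess -> spectral -> train -> predict.

    Returns ``(status, payload)`` where payload carries the Laplacian
    signal, spectral summary, epoch set, model and predictions for
    successful recordings, and a reason string otherwise.
    """
    # channel rejection runs on the unfiltered data (a flatlined stretch
    # stays exactly constant only before filtering)
    rec = recording
    report = None
    if config.reject_channels:
        try:
            rec, report = preprocessing.reject_bad_channels(
                rec, corr_threshold=config.channel_corr,
                hf_sd_threshold=config.hf_sd, flat_min_s=config.flat_s)
        except preprocessing.RecordingExcludedError as exc:
            return "excluded_channels", {"reason": str(exc)}
    rec = preprocessing.wideband_filter(rec)
    try:
        lap = preprocessing.laplacian(rec)
    except preprocessing.RecordingExcludedError as exc:
        return "excluded_montage", {"reason": str(exc)}

    summary = spectral.summarize_signal(lap, rec.fs)
    if config.spectral_exclusion and summary.excluded:
        return "excluded_qc", {"reason": "negative SNR or no alpha peak",
                               "summary": summary, "channel_report": report}

    epochs = preprocessing.extract_epochs(rec, events, config.epoch_len_s)
    if config.reject_epoch_artifacts:
        epochs = preprocessing.reject_epochs(epochs, lap, config.epoch_sd)

    band = _recording_band(config, summary)
    try:
        model = etp.train_etp(lap, rec.fs, epochs.select("train"), band)
    except etp.TrainingFailedError as exc:
        return "training_failed", {"reason": str(exc), "summary": summary}
    predictions = etp.predict_epochs(
        lap, rec.fs, epochs.select("test"), model,
        window_s=config.window_ms / 1000.0,
        edge_margin_s=config.edge_margin_ms / 1000.0)
    return "trained", {"laplacian": lap, "summary": summary, "epochs": epochs,
                       "model": model, "predictions": predictions,
                       "channel_report": report, "band": band, "fs": rec.fs}


def run_pipeline(config: PipelineConfig, write: bool = True):
    """Execute the full pipeline; returns ``(manifest, tables)``.

    ``tables`` maps artifact names to DataFrames (``accuracy``,
    ``spectral``, ``predictions``, ``coefficients``) plus the fitted
    models under ``fits`` and the text report under ``report``.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    manifest = {"config_hash": config.config_hash(), "recordings": {},
                "timings_s": {}}
    ss = np.random.SeedSequence(config.master_seed)
    n_recordings = sum(ds.n_individuals for ds in config.datasets)
    children = ss.spawn(n_recordings)

    accuracy_rows, spectral_rows, prediction_rows = [], [], []
    idx = 0
    for ds in config.datasets:
        for i in range(ds.n_individuals):
            child = children[idx]
            idx += 1
            rng = np.random.default_rng(child)
            seed = int(child.generate_state(1)[0] % (2 ** 31))
            alpha = (ds.alpha_freq if ds.alpha_freq is not None
                     else float(rng.uniform(8.5, 12.0)))
            spec = SyntheticSpec(
                duration_s=ds.duration_s, fs=config.fs, state=ds.state,
                alpha_freq=alpha, target_snr_db=ds.target_snr_db, seed=seed)
            recording, events, phase = generate_session(spec)
            recording.dataset_id = ds.dataset_id
            recording.individual_id = f"s{i:02d}"
            recording.recording_id = f"{ds.dataset_id}_s{i:02d}"
            if config.save_sessions and write:
                save_session(out / "sessions", recording, events, phase,
                             extra_meta={"alpha_freq": alpha,
                                         "target_snr_db": ds.target_snr_db})
            status, payload = process_recording(recording, events, config)
            entry = {"status": status, "dataset_id": ds.dataset_id,
                     "individual_id": recording.individual_id,
                     "state": ds.state, "n_predictions": 0}
            summary = payload.get("summary")
            if summary is not None:
                spectral_rows.append({
                    "recording_id": recording.recording_id,
                    "dataset_id": ds.dataset_id,
                    "individual_id": recording.individual_id,
                    "state": ds.state, "iaf_hz": summary.iaf,
                    "snr_db": summary.snr_db,
                    "peak_found": summary.peak_found,
                    "excluded": summary.excluded})
            if status == "trained":
                records = evaluation.score_predictions(
                    payload["predictions"], payload["laplacian"], payload["fs"],
                    band=payload["band"], state=ds.state,
                    dataset_id=ds.dataset_id,
                    individual_id=recording.individual_id,
                    snr_db=summary.snr_db)
                records.insert(0, "recording_id", recording.recording_id)
                accuracy_rows.append(records)
                entry["n_predictions"] = len(records)
                for p in payload["predictions"]:
                    prediction_rows.append({
                        "recording_id": recording.recording_id,
                        "epoch_id": p.epoch_id,
                        "predicted_time_s": p.predicted_time_s,
                        "source_peak_time_s": p.source_peak_time_s})
            else:
                entry["reason"] = payload.get("reason", "")
            manifest["recordings"][recording.recording_id] = entry
    manifest["timings_s"]["simulate_to_evaluate"] = round(time.time() - t0, 3)

    accuracy = (pd.concat(accuracy_rows, ignore_index=True) if accuracy_rows
                else pd.DataFrame())
    spectral_df = pd.DataFrame(spectral_rows)
    predictions_df = pd.DataFrame(prediction_rows)

    t1 = time.time()
    fits, lrts, coef_rows = {}, {}, []
    if len(accuracy) and accuracy["dataset_id"].nunique() >= 2:
        presets = {"null": mixed_models.null_model,
                   "base": mixed_models.base_model,
                   "intermediate": mixed_models.intermediate_model,
                   "full": mixed_models.full_model}
        for name in config.fit_models:
            try:
                fits[name] = mixed_models.fit_model(accuracy, presets[name]())
            except Exception as exc:  # keep the run alive; flag the failure
                fits[name] = None
                manifest.setdefault("model_errors", {})[name] = str(exc)
        order = ["null", "base", "intermediate", "full"]
        chain = [n for n in order if fits.get(n) is not None]
        for small, big in zip(chain[:-1], chain[1:]):
            lrts[f"{small}_vs_{big}"] = mixed_models.likelihood_ratio_test(
                fits[small], fits[big])
        for name, fit in fits.items():
            if fit is None:
                continue
            tab = mixed_models.significance_report(fit)
            tab.insert(0, "model", name)
            coef_rows.append(tab)
    coefficients = (pd.concat(coef_rows, ignore_index=True) if coef_rows
                    else pd.DataFrame())
    manifest["timings_s"]["models"] = round(time.time() - t1, 3)
    manifest["lrt"] = {k: {"chi2": v.chi2, "df": v.df, "p": v.p}
                       for k, v in lrts.items()}

    text = report(manifest, accuracy, spectral_df, fits)
    tables = {"accuracy": accuracy, "spectral": spectral_df,
              "predictions": predictions_df, "coefficients": coefficients,
              "fits": fits, "lrts": lrts, "report": text}
    if write:
        out.mkdir(parents=True, exist_ok=True)
        accuracy.to_csv(out / "accuracy.csv", index=False)
        spectral_df.to_csv(out / "spectral.csv", index=False)
        predictions_df.to_csv(out / "predictions.csv", index=False)
        coefficients.to_csv(out / "coefficients.csv", index=False)
        (out / "report.txt").write_text(text)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
        lines = [mixed_models.render_report(f) for f in fits.values()
                 if f is not None]
        (out / "model_report.txt").write_text("\n\n".join(lines))
    return manifest, tables


def report(manifest: dict, accuracy: pd.DataFrame, spectral_df: pd.DataFrame,
           fits: dict | None = None) -> str:
    """Descriptive summary of a run: overall accuracy, circular error with
    its millisecond equivalent at 10 Hz, and per-state power/SNR means."""
    lines = ["etphase pipeline report",
             f"config hash: {manifest.get('config_hash', '?')}"]
    statuses = pd.Series(
        [r["status"] for r in manifest.get("recordings", {}).values()])
    for status, count in statuses.value_counts().items():
        lines.append(f"  recordings {status}: {count}")
    if len(accuracy):
        summ = evaluation.summarize(accuracy)
        ms = evaluation.deg_to_ms(summ.circular_sd_deg, 10.0)
        lines += [
            f"predictions: {summ.n}",
            f"mean accuracy: {100 * summ.mean_accuracy:.2f}% "
            f"(SD = {100 * summ.sd_accuracy:.2f}%)",
            f"circular mean error: {summ.mean_error_deg:+.2f} deg "
            f"(SD = {summ.circular_sd_deg:.2f} deg)",
            f"at 10 Hz the angular SD corresponds to {ms:.2f} ms",
        ]
        for state, grp in accuracy.groupby("state"):
            lines.append(
                f"  state {state}: n={len(grp)}, "
                f"accuracy {100 * grp['accuracy'].mean():.2f}%, "
                f"power {grp['inst_power'].mean():.2f} uV "
                f"(SD {grp['inst_power'].std():.2f}), "
                f"SNR {grp['snr_db'].mean():.2f} dB")
    if fits:
        for name, fit in fits.items():
            if fit is not None:
                lines.append(f"model {name}: logLik={fit.loglik:.1f} "
                             f"({fit.df_params} params, converged={fit.converged})")
    return "\n".join(lines) + "\n"
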