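"""Resampling, filtering, channel rejection, Laplacian and epoching."""

import numpy as np
import pytest

from etphase import spectral
from etphase.containers import (
    EEGRecording,
    Event,
    EventList,
    RecordingExcludedError,
    ValidationError,
)
from etphase.preprocessing import (
    extract_epochs,
    laplacian,
    reject_bad_channels,
    reject_epochs,
    resample,
    wideband_filter,
)
from etphase.synthetic import inject_artifacts

FS = 250.0


def _recording(data, fs=FS, labels=None):
    n_ch = data.shape[1]
    labels = labels or tuple(f"ch{i}" for i in range(n_ch))
    return EEGRecording(data=data, fs=fs, channel_labels=labels)


class TestResample:
    def test_length_scales_with_rate_ratio(self, rng):
        rec = _recording(rng.standard_normal((1001, 2)), fs=500.0)
        out = resample(rec, 250.0)
        assert abs(out.n_samples - 1001 // 2) <= 1
        assert out.fs == 250.0

    def test_same_rate_is_identity(self, rng):
        rec = _recording(rng.standard_normal((100, 2)))
        out = resample(rec, FS)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_upsampling_refused(self, rng):
        rec = _recording(rng.standard_normal((100, 2)))
        with pytest.raises(ValidationError):
            resample(rec, 500.0)

    def test_spectral_peak_survives_downsampling(self):
        t = np.arange(0, 40.0, 1 / 1000.0)
        rec = _recording(np.sin(2 * np.pi * 10.0 * t)[:, None], fs=1000.0)
        out = resample(rec, 250.0)
        ps = spectral.welch_psd(out.data[:, 0], out.fs)
        assert ps.freqs[np.argmax(ps.power)] == pytest.approx(10.0, abs=0.25)


class TestWidebandFilter:
    def test_dc_offset_removed(self, rng):
        rec = _recording(np.full((30 * int(FS), 1), 5.0)
                         + 0.01 * rng.standard_normal((30 * int(FS), 1)))
        out = wideband_filter(rec)
        assert abs(out.data.mean()) < 5 * 1e-2  # < 1e-2 per unit offset

    def test_alpha_band_amplitude_preserved(self):
        t = np.arange(0, 60.0, 1 / FS)
        rec = _recording(np.sin(2 * np.pi * 10.0 * t)[:, None])
        out = wideband_filter(rec)
        mid = slice(2000, -2000)
        ratio = out.data[mid, 0].std() / rec.data[mid, 0].std()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_above_band_attenuated_20db(self):
        t = np.arange(0, 60.0, 1 / FS)
        rec = _recording(np.sin(2 * np.pi * 80.0 * t)[:, None])
        out = wideband_filter(rec)
        mid = slice(2000, -2000)
        atten = 20 * np.log10(rec.data[mid, 0].std() / out.data[mid, 0].std())
        assert atten > 20.0


class TestBadChannels:
    def test_clean_correlated_channels_not_rejected(self, ec_session):
        _, rec, _, _ = ec_session
        _, report = reject_bad_channels(rec)
        assert not report["rejected"].any()

    def test_six_second_flat_stretch_flagged(self, ec_session):
        _, rec, _, _ = ec_session
        bad = inject_artifacts(rec, flats=[("F7", 20.0, 6.0)])
        cleaned, report = reject_bad_channels(bad)
        assert report.loc["F7", "flat"] and report.loc["F7", "rejected"]
        assert "F7" not in cleaned.channel_labels

    def test_short_flat_stretch_not_flagged(self, ec_session):
        _, rec, _, _ = ec_session
        ok = inject_artifacts(rec, flats=[("F7", 20.0, 3.0)])
        _, report = reject_bad_channels(ok)
        assert not report.loc["F7", "flat"]

    def test_high_frequency_noise_flagged(self, ec_session):
        _, rec, _, _ = ec_session
        bad = inject_artifacts(rec, hf_noise=[("C3", 10.0)])
        _, report = reject_bad_channels(bad)
        assert report.loc["C3", "hf_noise"] and report.loc["C3", "rejected"]

    def test_needs_at_least_eight_channels(self, rng):
        rec = _recording(rng.standard_normal((2500, 4)))
        with pytest.raises(ValidationError):
            reject_bad_channels(rec)


class TestLaplacian:
    labels = ("Pz", "Oz", "Cz", "P3", "P4", "F3")

    def test_uniform_activity_maps_to_zero(self, rng):
        x = rng.standard_normal(1000)
        rec = _recording(np.tile(x[:, None], (1, 6)), labels=self.labels)
        np.testing.assert_allclose(laplacian(rec), 0.0, atol=1e-12)

    def test_pz_only_component_recovered_exactly(self, rng):
        base = rng.standard_normal(1000)
        s = np.sin(np.linspace(0, 20 * np.pi, 1000))
        data = np.tile(base[:, None], (1, 6))
        data[:, 0] += s
        rec = _recording(data, labels=self.labels)
        np.testing.assert_allclose(laplacian(rec), s, atol=1e-12)

    def test_missing_surround_reweights_over_remainder(self, rng):
        data = rng.standard_normal((500, 4))
        rec = _recording(data, labels=("Pz", "Oz", "Cz", "P3"))
        out = laplacian(rec)
        np.testing.assert_allclose(out, data[:, 0] - data[:, 1:].mean(axis=1))

    def test_fewer_than_two_surrounds_excludes_recording(self, rng):
        rec = _recording(rng.standard_normal((500, 2)), labels=("Pz", "Oz"))
        with pytest.raises(RecordingExcludedError):
            laplacian(rec)

    def test_missing_center_excludes_recording(self, rng):
        rec = _recording(rng.standard_normal((500, 4)),
                         labels=("Oz", "Cz", "P3", "P4"))
        with pytest.raises(RecordingExcludedError):
            laplacian(rec)


class TestEpochs:
    def test_four_minute_rest_gives_60_train_60_test(self, rng):
        rec = _recording(rng.standard_normal((int(240 * FS), 2)))
        eps = extract_epochs(rec, EventList([]))
        assert len(eps.select("train")) == 60
        assert len(eps.select("test")) == 60
        assert all(e.end_s - e.start_s == pytest.approx(2.0) for e in eps)

    def test_epoch_partition_covers_halves_without_overlap(self, rng):
        rec = _recording(rng.standard_normal((int(60 * FS), 2)))
        eps = extract_epochs(rec, EventList([]))
        bounds = sorted((e.start_s, e.end_s) for e in eps)
        for (s1, e1), (s2, _) in zip(bounds[:-1], bounds[1:]):
            assert s2 >= e1 - 1e-9

    def test_task_trials_and_itis_have_equal_counts(self, task_session):
        _, rec, events, _ = task_session
        eps = extract_epochs(rec, events)
        assert len(eps.select("train")) == len(eps.select("test")) > 0
        assert all(e.kind == "iti" for e in eps.select("train"))
        assert all(e.kind == "on_task" for e in eps.select("test"))

    def test_trailing_iti_without_next_trial_omitted(self, rng):
        rec = _recording(rng.standard_normal((int(20 * FS), 2)))
        events = EventList([Event(0.0, 1.0, "iti"), Event(1.0, 3.0, "trial"),
                            Event(3.0, 4.0, "iti"), Event(4.0, 6.0, "trial"),
                            Event(6.0, 7.0, "iti")])
        eps = extract_epochs(rec, events)
        assert len(eps.select("test")) == 2
        assert len(eps.select("train")) == 2  # trailing iti dropped

    def test_single_trial_task_rejected(self, rng):
        rec = _recording(rng.standard_normal((int(20 * FS), 2)))
        events = EventList([Event(0.0, 1.0, "iti"), Event(1.0, 3.0, "trial")])
        with pytest.raises(ValidationError):
            extract_epochs(rec, events)


class TestEpochRejection:
    def test_bounded_signal_keeps_all_epochs(self):
        t = np.arange(0, 60.0, 1 / FS)
        sig = np.sin(2 * np.pi * 10 * t)  # max amplitude exactly 1, SD ~0.707
        rec = _recording(np.tile(sig[:, None], (1, 2)))
        eps = extract_epochs(rec, EventList([]))
        out = reject_epochs(eps, sig)
        assert all(e.kept for e in out)

    def test_spiked_epoch_is_the_one_removed(self):
        t = np.arange(0, 60.0, 1 / FS)
        sig = np.sin(2 * np.pi * 10 * t)
        sig[int(11.0 * FS)] += 10 * sig.std()
        rec = _recording(np.tile(sig[:, None], (1, 2)))
        out = reject_epochs(extract_epochs(rec, EventList([])), sig)
        dropped = [e for e in out.epochs if not e.kept]
        assert len(dropped) == 1
        assert dropped[0].start_s <= 11.0 < dropped[0].end_s

    def test_rejection_is_idempotent(self, ec_session):
        _, rec, events, _ = ec_session
        lap = laplacian(wideband_filter(rec))
        once = reject_epochs(extract_epochs(rec, events), lap)
        twice = reject_epochs(once, lap)
        assert [e.kept for e in once] == [e.kept for e in twice]

    def test_rejection_deterministic_on_rerun(self, ec_session):
        _, rec, events, _ = ec_session
        lap = laplacian(wideband_filter(rec))
        a = reject_epochs(extract_epochs(rec, events), lap)
        b = reject_epochs(extract_epochs(rec, events), lap)
        assert [e.kept for e in a] == [e.kept for e in b]
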