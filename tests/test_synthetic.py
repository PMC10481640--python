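"""Generator contracts: spectra, phase bookkeeping, sessions, artifacts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from etphase import spectral
from etphase.containers import EventList, ValidationError, wrap_degrees
from etphase.preprocessing import extract_epochs, laplacian, reject_epochs, wideband_filter
from etphase.synthetic import (
    SyntheticSpec,
    compose_recording,
    generate_alpha,
    generate_aperiodic,
    generate_aperiodic_channels,
    generate_session,
    inject_artifacts,
)

FS = 250.0


class TestAperiodic:
    @pytest.mark.parametrize("chi,tol", [(0.0, 0.1), (1.0, 0.15)])
    def test_fitted_loglog_slope_matches_exponent(self, chi, tol):
        spec = SyntheticSpec(duration_s=120.0, aperiodic_exponent=chi)
        slopes = []
        for seed in range(20):
            x = generate_aperiodic(spec, seed=seed)
            fit = spectral.fit_aperiodic(spectral.welch_psd(x, FS))
            slopes.append(fit.slope / 10.0)  # dB/decade -> exponent
        assert np.mean(slopes) == pytest.approx(-chi, abs=tol)

    def test_same_seed_gives_identical_samples(self):
        spec = SyntheticSpec(duration_s=10.0)
        a = generate_aperiodic(spec, seed=7)
        b = generate_aperiodic(spec, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticSpec(duration_s=2.0)


class TestAlpha:
    def test_signal_is_envelope_times_cos_phase(self):
        spec = SyntheticSpec(duration_s=20.0, alpha_envelope="bursty", seed=3)
        sig, phase, env = generate_alpha(spec)
        np.testing.assert_allclose(
            sig, env * np.cos(np.radians(phase.phase_deg)), atol=1e-12)
        assert np.all(env > 0)

    def test_phase_zero_at_local_maxima(self):
        spec = SyntheticSpec(duration_s=20.0, alpha_envelope="constant",
                             alpha_freq=10.0, seed=2)
        sig, phase, _ = generate_alpha(spec)
        peaks = np.where((sig[1:-1] > sig[:-2]) & (sig[1:-1] >= sig[2:]))[0] + 1
        # half-sample quantization at 250 Hz / 10 Hz = 7.2 degrees
        assert np.max(np.abs(phase.phase_deg[peaks])) <= 7.2 + 1e-9

    def test_spectral_module_recovers_alpha_frequency(self):
        spec = SyntheticSpec(duration_s=60.0, alpha_envelope="constant",
                             alpha_freq=10.0, seed=4)
        sig, _, _ = generate_alpha(spec)
        ps = spectral.welch_psd(sig, FS)
        assert ps.freqs[np.argmax(ps.power)] == pytest.approx(10.0, abs=0.25)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(freq=st.floats(8.0, 13.0), seed=st.integers(0, 100))
    def test_unwrapped_phase_slope_is_360f(self, freq, seed):
        spec = SyntheticSpec(duration_s=8.0, alpha_freq=freq, seed=seed)
        _, phase, _ = generate_alpha(spec)
        unwrapped = np.unwrap(np.radians(phase.phase_deg))
        assert np.all(np.diff(unwrapped) > 0)
        slope = np.degrees(unwrapped[-1] - unwrapped[0]) / (spec.duration_s - 1 / FS)
        assert slope == pytest.approx(360.0 * freq, rel=1e-6)


class TestCompose:
    def test_snr_calibration_hits_target(self):
        vals = []
        for seed in range(3):
            spec = SyntheticSpec(duration_s=120.0, target_snr_db=10.0,
                                 seed=50 + seed)
            rec, _, _ = generate_session(spec)
            vals.append(spectral.summarize_signal(laplacian(rec), FS).snr_db)
        assert np.mean(vals) == pytest.approx(10.0, abs=1.5)

    def test_doubling_alpha_amplitude_adds_six_db(self):
        spec = SyntheticSpec(duration_s=120.0, target_snr_db=15.0, seed=11)
        rng = np.random.default_rng(spec.seed)
        alpha, phase, _ = generate_alpha(spec, rng=rng)
        noise = generate_aperiodic_channels(spec, rng)
        rec, _ = compose_recording(alpha, phase, noise, FS, 15.0)
        snr1 = spectral.summarize_signal(laplacian(rec), FS).snr_db
        rec2 = rec.copy()
        rec2.data = noise + 2.0 * (rec.data - noise)  # alpha part doubled
        snr2 = spectral.summarize_signal(laplacian(rec2), FS).snr_db
        assert snr2 - snr1 == pytest.approx(6.02, abs=0.5)

    def test_negative_target_marked_excluded_by_qc(self):
        spec = SyntheticSpec(duration_s=120.0, target_snr_db=-5.0, seed=2)
        rec, _, _ = generate_session(spec)
        summ = spectral.summarize_signal(laplacian(rec), FS)
        assert summ.excluded

    def test_phase_trace_passes_through_unchanged(self):
        spec = SyntheticSpec(duration_s=30.0, seed=8)
        rng = np.random.default_rng(0)
        alpha, phase, _ = generate_alpha(spec, rng=rng)
        noise = generate_aperiodic_channels(spec, rng)
        _, phase_out = compose_recording(alpha, phase, noise, FS, 10.0)
        np.testing.assert_array_equal(phase_out.phase_deg, phase.phase_deg)


class TestSession:
    def test_identical_spec_and_seed_bitwise_reproducible(self):
        spec = SyntheticSpec(duration_s=30.0, state="task", seed=21)
        rec1, ev1, ph1 = generate_session(spec)
        rec2, ev2, ph2 = generate_session(spec)
        np.testing.assert_array_equal(rec1.data, rec2.data)
        np.testing.assert_array_equal(ph1.phase_deg, ph2.phase_deg)
        assert ev1.to_frame().equals(ev2.to_frame())

    def test_task_event_lengths_inside_configured_ranges(self, task_session):
        spec, _, events, _ = task_session
        for e in events:
            length = e.offset_s - e.onset_s
            lo, hi = (spec.trial_len_range_s if e.kind == "trial"
                      else spec.iti_range_s)
            assert lo - 1e-9 <= length <= hi + 1e-9

    def test_events_alternate_and_stay_inside_session(self, task_session):
        spec, _, events, _ = task_session
        kinds = [e.kind for e in events]
        assert kinds[::2] == ["iti"] * len(kinds[::2])
        assert kinds[1::2] == ["trial"] * len(kinds[1::2])
        assert events.events[-1].offset_s <= spec.duration_s

    def test_rest_sessions_have_no_events(self, ec_session):
        _, _, events, _ = ec_session
        assert len(events) == 0

    def test_zero_trials_is_a_validation_error(self):
        with pytest.raises(ValidationError):
            SyntheticSpec(duration_s=60.0, state="task", n_trials=0)

    def test_trials_not_fitting_duration_is_an_error(self):
        spec = SyntheticSpec(duration_s=30.0, state="task", n_trials=50, seed=0)
        with pytest.raises(ValidationError):
            generate_session(spec)


class TestArtifacts:
    def test_empty_artifact_spec_is_identity(self, ec_session):
        _, rec, _, _ = ec_session
        out = inject_artifacts(rec)
        np.testing.assert_array_equal(out.data, rec.data)
        assert out is not rec

    def test_untouched_samples_bit_identical(self, ec_session):
        _, rec, _, _ = ec_session
        out = inject_artifacts(rec, spikes=[(10.0, "Pz", 500.0)])
        idx = int(round(10.0 * rec.fs))
        mask = np.ones(rec.n_samples, dtype=bool)
        mask[idx] = False
        np.testing.assert_array_equal(out.data[mask], rec.data[mask])
        assert out.data[idx, rec.channel_labels.index("Pz")] != rec.data[
            idx, rec.channel_labels.index("Pz")]

    def test_large_spike_causes_epoch_rejection(self, ec_session):
        _, rec, events, _ = ec_session
        lap0 = laplacian(wideband_filter(rec))
        spike_t = 70.1  # inside a test-half epoch
        rec_a = inject_artifacts(rec, spikes=[(spike_t, "Pz", 10 * np.std(lap0))])
        lap = laplacian(wideband_filter(rec_a))
        epochs = reject_epochs(extract_epochs(rec_a, events), lap)
        hit = [e for e in epochs.epochs if e.start_s <= spike_t < e.end_s]
        assert len(hit) == 1 and not hit[0].kept
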