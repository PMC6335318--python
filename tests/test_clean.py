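import numpy as np
import pytest

import eegfmriqc as q
from eegfmriqc import clean, spectral

from conftest import match_rate


def _periodic_artifact_recording(montage, n_epochs=30, d=200, fs=500.0,
                                 drift=0.0, seed=0):
    """TR-locked artifact with zero neural signal; optional linear drift."""
    rng = np.random.default_rng(seed)
    template = rng.normal(0, 100, (3, d))
    m = montage.subset(["C3", "C4", "Cz"])
    data = np.zeros((3, n_epochs * d + 50))
    events = []
    for i in range(n_epochs):
        s = i * d
        data[:, s:s + d] = template * (1.0 + drift * i)
        events.append(q.Event(s, "tr_onset"))
    return q.EEGRecording(data=data, fs=fs, events=events, montage=m)


class TestAAS:
    def test_identical_epochs_leave_zero_residual(self, montage):
        rec = _periodic_artifact_recording(montage)
        out = clean.aas_correct(rec)
        interior = out.data[:, 5 * 200:25 * 200]
        assert np.abs(interior).max() < 1e-9

    def test_samples_outside_tr_epochs_unchanged(self, montage):
        rec = _periodic_artifact_recording(montage)
        rec.data[:, -50:] = 7.0  # tail beyond the last TR epoch
        out = clean.aas_correct(rec)
        assert np.array_equal(out.data[:, -50:], rec.data[:, -50:])

    def test_sliding_window_beats_global_template_under_drift(self, montage):
        """1%/epoch amplitude drift favors a local over a global template."""
        rec = _periodic_artifact_recording(montage, n_epochs=100, drift=0.01)
        sliding = clean.aas_correct(rec).data[:, :100 * 200]
        onsets = rec.event_latencies("tr_onset")
        epochs = np.stack([rec.data[:, s:s + 200] for s in onsets])
        global_template = epochs.mean(axis=0)
        global_resid = (epochs - global_template).std()
        assert sliding.std() < global_resid

    def test_attenuation_on_synthetic_session(self, simultaneous_session):
        """Slice-harmonic band power drops by >= 40 dB after AAS."""
        rec, _ = simultaneous_session
        out = clean.aas_correct(rec)

        def harmonic_power(data):
            spec = spectral.fft_sq_amplitude(data[:8], rec.fs, fmax=400)
            sel = np.zeros(spec.freqs.size, bool)
            for k in range(1, 22):
                sel |= np.abs(spec.freqs - 18.0 * k) < 0.6
            return spec.a2[:, sel].sum()

        before = harmonic_power(rec.data)
        after = harmonic_power(out.data)
        assert 10 * np.log10(before / after) >= 40.0

    def test_irregular_tr_onsets_rejected(self, montage):
        rec = _periodic_artifact_recording(montage)
        events = [q.Event(e.latency + (5 if i == 10 else 0), e.label)
                  for i, e in enumerate(rec.events)]
        bad = rec.copy_with(events=events)
        with pytest.raises(clean.AlignmentError):
            clean.aas_correct(bad)

    def test_few_epochs_shrink_window_with_warning(self, montage):
        rec = _periodic_artifact_recording(montage, n_epochs=10)
        with pytest.warns(UserWarning, match="window shrinks"):
            out = clean.aas_correct(rec, epochs_per_average=25)
        assert np.abs(out.data[:, :10 * 200]).max() < 1e-9


class TestQRSDetection:
    def test_ecg_channel_sensitivity_precision(self, pre_acquisition_session):
        rec, gt = pre_acquisition_session
        det = clean.detect_qrs(clean.bandpass(rec), ecg="ECG")
        sens, prec = match_rate(det.times(rec.fs), gt.r_peak_times)
        assert sens >= 0.99 and prec >= 0.99

    def test_min_distance_rule(self, small_montage):
        fs = 500.0
        x = np.zeros(int(fs * 3))
        x[500] = 5.0
        x[650] = 10.0  # 0.30 s later: closer than 60/110 s -> larger wins
        rec = q.EEGRecording(data=np.zeros((3, x.size)), fs=fs,
                             montage=small_montage, aux={"ECG": x})
        det = clean.detect_qrs(rec, ecg="ECG", prominence=1.0)
        assert 650 in det.peak_latencies
        assert 500 not in det.peak_latencies

    def test_ica_agrees_with_ecg_channel(self, pre_acquisition_session):
        rec, _ = pre_acquisition_session
        rec_b = clean.bandpass(rec)
        det_ecg = clean.detect_qrs(rec_b, ecg="ECG")
        det_ica = clean.detect_qrs(rec_b, ecg=None)
        assert det_ica.source == "ica"
        assert det_ica.component_scores.max() > 0.1
        agree, _ = match_rate(det_ica.times(rec.fs), det_ecg.times(rec.fs),
                              tol=0.025)
        assert agree >= 0.99

    def test_no_cardiac_component_raises(self, small_montage):
        rng = np.random.default_rng(0)
        rec = q.EEGRecording(data=rng.normal(size=(3, 2000)), fs=500.0,
                             montage=small_montage)
        with pytest.raises(clean.DetectionError):
            clean.detect_qrs(rec, ecg=None, n_components=3)


class TestPulseSubtract:
    def test_identical_epochs_removed_exactly(self, small_montage):
        fs = 500.0
        rr = int(0.9 * fs)
        template = np.outer([1.0, 2.0, 0.5],
                            np.hanning(int(0.5 * fs)))
        data = np.zeros((3, 20 * rr))
        peaks = []
        for i in range(2, 18):
            s = i * rr
            data[:, s:s + template.shape[1]] += template
            peaks.append(s + int(0.1 * fs))  # peak inside the bump
        rec = q.EEGRecording(data=data, fs=fs, montage=small_montage)
        out = clean.pulse_subtract(rec, np.array(peaks))
        locked = [out.data[:, p - 50:p + 200] for p in peaks[1:-1]]
        assert np.abs(np.stack(locked)).max() < 1e-9

    def test_variance_reduction_on_synthetic_session(self,
                                                     pre_acquisition_session):
        rec, gt = pre_acquisition_session
        rec_b = clean.bandpass(rec)
        det = clean.detect_qrs(rec_b, ecg="ECG")
        sub = clean.pulse_subtract(rec_b, det)
        clean_b = clean.bandpass(rec.copy_with(data=gt.clean_data))
        win = int(0.5 * rec.fs)
        before = after = 0.0
        for t_r in gt.r_peak_times:
            s = int(t_r * rec.fs)
            if s + win > rec.n_samples:
                continue
            before += ((rec_b.data[:, s:s + win]
                        - clean_b.data[:, s:s + win]) ** 2).mean()
            after += ((sub.data[:, s:s + win]
                       - clean_b.data[:, s:s + win]) ** 2).mean()
        assert 1 - after / before >= 0.80

    def test_infinite_sd_limit_is_plain_moving_mean(self, small_montage):
        fs = 500.0
        rng = np.random.default_rng(1)
        data = rng.normal(size=(3, 6000))
        peaks = np.arange(400, 5500, 450)
        rec = q.EEGRecording(data=data, fs=fs, montage=small_montage)
        out = clean.pulse_subtract(rec, peaks, n_neighbors=5,
                                   gaussian_sd_epochs=1e9)
        rr = int(np.median(np.diff(peaks)))
        pre, post = int(round(0.25 * rr)), int(round(0.75 * rr))
        # middle epoch: template should equal the unweighted 5-epoch mean
        k = 5
        s = peaks[k] - pre
        neigh = [data[:, p - pre:p - pre + pre + post]
                 for p in peaks[k - 2:k + 3]]
        expected = data[:, s:s + pre + post] - np.mean(neigh, axis=0)
        assert np.allclose(out.data[:, s:s + pre + post], expected, atol=1e-9)


class TestEndToEnd:
    def test_pipeline_removes_artifacts_with_bounded_distortion(
            self, simultaneous_session):
        """Full chain on a scanning session: artifact band power collapses
        while neural distortion stays at the mean-template noise floor
        (~sqrt(1/25) from AAS plus ~sqrt(1/17) inside pulse windows)."""
        from scipy import signal as ssig

        rec, gt = simultaneous_session
        cleaned = clean.clean_pipeline(rec, seed=0)
        ref = rec.copy_with(data=gt.clean_data.copy(),
                            events=list(rec.events))
        ref = clean.rereference_average(
            clean.bandpass(clean.resample(ref, 500)))
        raw = clean.rereference_average(
            clean.bandpass(clean.resample(rec, 500)))

        # residual artifact band power (slice harmonics + QRS-locked)
        art_before = raw.data - ref.data
        art_after = cleaned.data - ref.data

        def artifact_power(art):
            spec = spectral.fft_sq_amplitude(art, 500.0, fmax=30)
            sel = np.abs(spec.freqs - 18.0) < 0.6  # in-band slice harmonic
            total = spec.a2[:, sel].sum()
            win = int(0.5 * 500)
            for t_r in gt.r_peak_times:
                s = int(t_r * 500)
                if s + win <= art.shape[1]:
                    total += (art[:, s:s + win] ** 2).mean()
            return total

        assert artifact_power(art_after) <= 0.05 * artifact_power(art_before)

        # neural distortion in 1-30 Hz, relative to the clean reference
        sos = ssig.butter(4, [1, 30], btype="bandpass", fs=500, output="sos")
        err = ssig.sosfiltfilt(sos, art_after, axis=1)[:, 1000:-1000]
        sig = ssig.sosfiltfilt(sos, ref.data, axis=1)[:, 1000:-1000]
        assert err.std() / sig.std() <= 0.35

    def test_condition_without_artifacts_passes_through(self, montage):
        """Stages whose artifact is absent simply do not apply."""
        params = q.condition_params("separate", seed=6, fs=500, duration=10)
        rec, _ = q.generate_eeg_session(params)
        out = clean.clean_pipeline(rec)
        assert out.fs == 500.0
        assert out.reference == "average"


class TestResampleFilter:
    def test_sinusoid_amplitude_preserved(self, small_montage):
        fs = 5000.0
        t = np.arange(int(fs * 4)) / fs
        x = np.sin(2 * np.pi * 10 * t)
        rec = q.EEGRecording(data=np.tile(x, (3, 1)), fs=fs,
                             montage=small_montage,
                             events=[q.Event(5000, "stimulus")])
        out = clean.resample(rec, 500.0)
        assert out.fs == 500.0
        mid = out.data[0, 200:-200]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.01)
        assert out.events[0].latency == 500

    def test_identity_resample(self, small_montage):
        rec = q.EEGRecording(data=np.ones((3, 100)), fs=500.0,
                             montage=small_montage)
        out = clean.resample(rec, 500.0)
        assert np.array_equal(out.data, rec.data)

    def test_bandpass_gains(self, small_montage):
        fs = 500.0
        t = np.arange(int(fs * 10)) / fs
        for freq, lo, hi in [(10, 0.95, 1.0), (60, 0.0, 0.5)]:
            x = np.sin(2 * np.pi * freq * t)
            rec = q.EEGRecording(data=np.tile(x, (3, 1)), fs=fs,
                                 montage=small_montage)
            out = clean.bandpass(rec)
            mid = slice(2000, -2000)
            gain = (np.sqrt(np.mean(out.data[0, mid] ** 2))
                    / np.sqrt(np.mean(x[mid] ** 2)))
            assert lo <= gain <= hi + 1e-6, freq

    def test_dc_removed(self, small_montage):
        rec = q.EEGRecording(data=np.full((3, 5000), 3.3), fs=500.0,
                             montage=small_montage)
        out = clean.bandpass(rec)
        assert np.abs(out.data[:, 1000:-1000]).max() < 1e-6

    def test_invalid_band_rejected(self, small_montage):
        rec = q.EEGRecording(data=np.zeros((3, 100)), fs=500.0,
                             montage=small_montage)
        with pytest.raises(ValueError):
            clean.bandpass(rec, low=30.0, high=0.5)


class TestInterpolation:
    def test_identical_good_channels_reproduced(self, montage):
        n = 500
        s = np.sin(np.linspace(0, 10, n))
        rec = q.EEGRecording(data=np.tile(s, (60, 1)), fs=500.0,
                             montage=montage)
        rec.data[montage.index("Cz")] = 99.0
        out = clean.interpolate_bad_channels(rec, ["Cz"])
        assert np.allclose(out.data[montage.index("Cz")], s, atol=1e-9)

    def test_leave_one_out_smooth_field(self, montage):
        # smooth topography: value depends on position only
        pos = montage.positions
        field = 1.0 + pos[:, 1] + 0.5 * pos[:, 2]
        data = np.outer(field, np.ones(100))
        rec = q.EEGRecording(data=data, fs=500.0, montage=montage)
        errs = []
        for label in ["Cz", "C3", "PO4"]:
            out = clean.interpolate_bad_channels(rec, [label])
            i = montage.index(label)
            errs.append(out.data[i, 0] - field[i])
        recon = np.array([field[montage.index(l)] + e
                          for l, e in zip(["Cz", "C3", "PO4"], errs)])
        truth = np.array([field[montage.index(l)]
                          for l in ["Cz", "C3", "PO4"]])
        assert np.corrcoef(recon, truth)[0, 1] >= 0.95

    def test_all_bad_rejected(self, small_montage):
        rec = q.EEGRecording(data=np.zeros((3, 10)), fs=10.0,
                             montage=small_montage)
        with pytest.raises(ValueError):
            clean.interpolate_bad_channels(rec, ["C3", "C4", "Cz"])


class TestReference:
    def test_subset_mean_zero_and_idempotent(self, montage):
        rng = np.random.default_rng(2)
        rec = q.EEGRecording(data=rng.normal(size=(60, 200)), fs=500.0,
                             montage=montage)
        subset = montage.labels[:30]
        once = clean.rereference_average(rec, subset)
        idx = [montage.index(l) for l in subset]
        assert np.abs(once.data[idx].mean(axis=0)).max() < 1e-9
        twice = clean.rereference_average(once, subset)
        assert np.allclose(once.data, twice.data, atol=1e-12)
        assert once.reference == "average"

    def test_subset_choice_shifts_by_constant_per_sample(self, montage):
        rng = np.random.default_rng(3)
        rec = q.EEGRecording(data=rng.normal(size=(60, 100)), fs=500.0,
                             montage=montage)
        full = clean.rereference_average(rec, montage.labels)
        part = clean.rereference_average(rec, montage.labels[:20])
        diff = full.data - part.data
        assert np.abs(diff - diff[0:1, :]).max() < 1e-9


class TestEpoching:
    def _rec(self, montage, offset=0.0):
        fs = 500.0
        rng = np.random.default_rng(4)
        data = rng.normal(size=(3, int(fs * 10))) + offset
        events = [q.Event(int(fs * t), "stimulus") for t in (2, 4, 6)]
        return q.EEGRecording(data=data, fs=fs, montage=montage,
                              events=events)

    def test_window_length_and_baseline_zero(self, small_montage):
        ep = clean.epoch_and_baseline(self._rec(small_montage))
        assert ep.data.shape == (3, 3, 1300)  # [-0.8, 1.8) s at 500 Hz
        bl = ep.data[:, :, ep.baseline_slice()]
        assert np.abs(bl.mean(axis=2)).max() < 1e-9

    def test_constant_offset_epochs_are_zero(self, small_montage):
        rec = self._rec(small_montage)
        rec.data[:] = 42.0
        ep = clean.epoch_and_baseline(rec)
        assert np.abs(ep.data).max() < 1e-9

    def test_out_of_bounds_epochs_dropped(self, small_montage):
        rec = self._rec(small_montage)
        rec.events.append(q.Event(10, "stimulus"))  # window starts before 0
        ep = clean.epoch_and_baseline(rec)
        assert ep.n_epochs == 3
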