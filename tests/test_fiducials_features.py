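"""Fiducial detection against generator ground truth, and feature assembly."""

import numpy as np
import pytest

import cardiocs as cc
from cardiocs.errors import DataError, DetectionError
from cardiocs.fiducials import ECG_ORDER


def _match(detected, truth, name, tol):
    """Every ground-truth index must have a detected index within tol samples."""
    d = detected.indices(name)
    for beat in truth:
        if not any(abs(beat[name] - i) <= tol for i in d):
            return False
    return True


class TestEcgDetection:
    def test_r_peaks_within_two_samples_of_ground_truth(self, clean_ecg):
        sig, truth = clean_ecg
        fid = cc.detect_ecg_fiducials(sig)
        assert len(fid) == len(truth)
        for det, gt in zip(fid.beats, truth):
            assert abs(det["R"] - gt["R"]) <= 2

    def test_ordering_invariant_on_every_beat(self, clean_ecg):
        sig, _ = clean_ecg
        fid = cc.detect_ecg_fiducials(sig)
        for beat in fid.beats:
            seq = [beat[k] for k in ECG_ORDER]
            assert seq == sorted(seq)

    def test_amplitude_scaling_leaves_indices_unchanged(self, clean_ecg):
        sig, _ = clean_ecg
        fid1 = cc.detect_ecg_fiducials(sig)
        fid2 = cc.detect_ecg_fiducials(sig.with_samples(2.0 * sig.samples))
        assert fid1.beats == fid2.beats

    def test_detection_survives_mild_noise(self):
        sig, truth = cc.make_ecg(duration=10.0, noise=cc.NoiseSpec(white_sd=0.02, seed=5))
        den = cc.denoise(sig)
        fid = cc.detect_ecg_fiducials(den)
        assert _match(fid, truth, "R", tol=3)

    def test_flat_signal_raises_detection_error(self):
        with pytest.raises(DetectionError):
            cc.detect_ecg_fiducials(cc.Signal(np.zeros(2048), 500.0))


class TestPpgDetection:
    def test_systolic_peaks_within_two_samples_of_ground_truth(self, clean_ppg):
        sig, truth = clean_ppg
        fid = cc.detect_ppg_fiducials(sig)
        assert _match(fid, truth[: len(fid)], "P", tol=2)

    def test_valley_strictly_between_consecutive_peaks(self, clean_ppg):
        sig, _ = clean_ppg
        fid = cc.detect_ppg_fiducials(sig)
        peaks = fid.indices("P")
        for i, beat in enumerate(fid.beats[:-1]):
            assert peaks[i] < beat["V"] < peaks[i + 1]

    def test_amplitude_scaling_leaves_indices_unchanged(self, clean_ppg):
        sig, _ = clean_ppg
        fid1 = cc.detect_ppg_fiducials(sig)
        fid2 = cc.detect_ppg_fiducials(sig.with_samples(3.0 * sig.samples))
        assert fid1.beats == fid2.beats


class TestFeatureExtraction:
    def test_ecg_vector_has_21_named_entries(self, clean_ecg):
        sig, _ = clean_ecg
        vecs = cc.extract_features(cc.detect_ecg_fiducials(sig), sig)
        for v in vecs:
            assert v.values.size == 21
            assert len(v.names) == 21

    def test_ppg_vector_has_12_named_entries(self, clean_ppg):
        sig, _ = clean_ppg
        vecs = cc.extract_features(cc.detect_ppg_fiducials(sig), sig)
        for v in vecs:
            assert v.values.size == 12

    def test_q_r_amplitude_is_signed_difference(self, clean_ecg):
        # template Q amplitude -0.12 mV, R amplitude 1.0 mV  ->  Q - R ~ -1.12
        sig, _ = clean_ecg
        vecs = cc.extract_features(cc.detect_ecg_fiducials(sig), sig)
        idx = vecs[0].names.index("a_Q-R")
        for v in vecs:
            assert v.values[idx] == pytest.approx(-1.12, abs=0.02)

    def test_distance_features_invariant_amplitudes_linear_under_scaling(self, clean_ecg):
        sig, _ = clean_ecg
        fid = cc.detect_ecg_fiducials(sig)
        v1 = cc.extract_features(fid, sig)[0]
        scaled = sig.with_samples(2.0 * sig.samples)
        v2 = cc.extract_features(cc.detect_ecg_fiducials(scaled), scaled)[0]
        np.testing.assert_allclose(v2.values[:15], v1.values[:15], atol=1e-12)
        np.testing.assert_allclose(v2.values[15:], 2.0 * v1.values[15:], atol=1e-12)

    def test_rr_normalization_absorbs_uniform_time_stretch(self):
        # the same morphology at a slower heart rate gives matching distance
        # features once divided by the mean RR
        t60 = cc.default_ecg_template(60.0)
        t50 = cc.BeatTemplate(
            waves={n: cc.Wave(w.center * 1.2, w.width * 1.2, w.amplitude)
                   for n, w in t60.waves.items()},
            heart_rate=50.0,
        )
        s1, _ = cc.make_ecg(t60, duration=10.0)
        s2, _ = cc.make_ecg(t50, duration=12.0)
        v1 = cc.extract_features(cc.detect_ecg_fiducials(s1), s1, aggregate="mean")[0]
        v2 = cc.extract_features(cc.detect_ecg_fiducials(s2), s2, aggregate="mean")[0]
        # within ~2 sample-equivalents of the (RR-normalized) unit
        np.testing.assert_allclose(v2.values[:15], v1.values[:15], atol=2 / 500.0)

    def test_mean_aggregation_returns_single_vector(self, clean_ecg):
        sig, _ = clean_ecg
        vecs = cc.extract_features(cc.detect_ecg_fiducials(sig), sig, aggregate="mean")
        assert len(vecs) == 1

    def test_features_agree_before_and_after_high_quality_reconstruction(self):
        # on clean beats, a reconstruction with MR > 0.99 must leave every
        # feature within 5% (relative to the feature's scale)
        sig, _ = cc.make_ecg(duration=4.0, fs=500.0)
        n = len(sig)
        domain = cc.dct_domain(n)
        ensemble = cc.gaussian_ensemble(n, 0.7, seed=21)
        obs = cc.sense(ensemble, sig.samples, domain=domain)
        a, norms = cc.effective_matrix(ensemble, domain)
        res = cc.swamp(obs.y, a, cc.SwampConfig(eps1=1e-4, eps_relative=True))
        x_hat = cc.reconstruct_signal(res, domain, column_norms=norms)
        assert cc.matching_rate(sig.samples, x_hat) > 0.99
        rec = sig.with_samples(x_hat)
        v_before = cc.extract_features(cc.detect_ecg_fiducials(sig), sig, aggregate="mean")[0]
        v_after = cc.extract_features(cc.detect_ecg_fiducials(rec), rec, aggregate="mean")[0]
        scale = np.maximum(np.abs(v_before.values), 0.05)
        np.testing.assert_array_less(
            np.abs(v_after.values - v_before.values) / scale, 0.05
        )

    def test_too_few_beats_for_rr_raises(self):
        sig, _ = cc.make_ecg(duration=10.0)
        fid = cc.detect_ecg_fiducials(sig)
        single = cc.FiducialSet(beats=fid.beats[:1], fs=fid.fs, kind="ecg")
        with pytest.raises(DataError):
            cc.extract_features(single, sig)


class TestFiducialIO:
    def test_fiducial_file_round_trip(self, tmp_path, clean_ecg):
        sig, _ = clean_ecg
        fid = cc.detect_ecg_fiducials(sig)
        path = tmp_path / "fid.csv"
        cc.write_fiducials(fid, path)
        loaded = cc.read_fiducials(path)
        assert loaded.beats == fid.beats
        assert loaded.kind == "ecg"
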