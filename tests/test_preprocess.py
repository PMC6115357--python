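"""Cleaning chain: filtering, resampling, sensor and epoch rejection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sweepvep as sv
from sweepvep.harmonics import dft_coefficients
from sweepvep.preprocess import PreprocessingError
from sweepvep.synth import ArtifactSpec


FS = 420.0


def _tone(freq, fs=FS, dur=10.0, amp=1.0, phase=0.0):
    t = np.arange(int(fs * dur)) / fs
    return amp * np.cos(2 * np.pi * freq * t + phase)


class TestBandpass:
    def test_dc_removed(self):
        x = np.full(int(FS * 10), 5.0)
        y = sv.bandpass_filter(x, FS)
        assert np.sqrt(np.mean(y**2)) < 0.05  # < 1% of input amplitude

    def test_passband_gain_near_unity(self):
        y = sv.bandpass_filter(_tone(10.0), FS)
        # sinusoid regression on the central region (away from edges)
        c = dft_coefficients(y[1260:1260 + 1680], FS, [10.0])[0]
        assert abs(abs(c) - 1.0) < 0.02

    def test_stopband_attenuation(self):
        # long tone with generous edge trim so the steady-state response,
        # not the filter's start-up transient, is measured
        y = sv.bandpass_filter(_tone(100.0, dur=60.0), FS)
        rms_in = 1 / np.sqrt(2)
        rms_out = np.sqrt(np.mean(y[int(10 * FS) : -int(10 * FS)] ** 2))
        assert 20 * np.log10(rms_in / max(rms_out, 1e-300)) > 40

    def test_low_rate_rejected(self):
        with pytest.raises(PreprocessingError):
            sv.bandpass_filter(np.zeros(100), fs=90.0)


class TestResample:
    def test_length_500_to_420(self):
        x = np.zeros(5000)  # 10 s at 500 Hz
        y = sv.resample_to_420(x, 500.0)
        assert y.shape[-1] == 4200

    def test_identity_at_420(self):
        x = np.random.default_rng(0).standard_normal(4200)
        assert np.array_equal(sv.resample_to_420(x, 420.0), x)

    def test_inband_amplitude_preserved(self):
        t = np.arange(5000) / 500.0
        x = np.cos(2 * np.pi * 4.0 * t)
        y = sv.resample_to_420(x, 500.0)
        c = dft_coefficients(y, 420.0, [4.0])[0]
        assert abs(abs(c) - 1.0) < 1e-3  # within 0.1%

    def test_unusual_rate_warns(self):
        with pytest.warns(UserWarning):
            sv.resample_to_420(np.zeros(1000), 250.0)


class TestBadSensors:
    def test_sixteen_percent_flagged(self):
        x = np.zeros((4, 200))
        x[2, :32] = 35.0  # 16% of samples above 30 uV
        assert sv.detect_bad_sensors(x, 30.0) == [2]

    def test_all_zero_clean(self):
        assert sv.detect_bad_sensors(np.zeros((4, 100)), 30.0) == []

    def test_boundary_exactly_fifteen_percent_not_flagged(self):
        x = np.zeros((1, 200))
        x[0, :30] = 35.0  # exactly 15.0%: strict inequality, not flagged
        assert sv.detect_bad_sensors(x, 30.0) == []
        x[0, 30] = 35.0  # 15.5% now
        assert sv.detect_bad_sensors(x, 30.0) == [0]


class TestInterpolation:
    def test_constant_neighbors_reproduced(self, montage32):
        x = np.full((32, 50), 7.0)
        x[4] = 100.0
        repaired, nbmap = sv.interpolate_sensors(x, [4], montage32)
        assert np.allclose(repaired[4], 7.0)
        assert len(nbmap[4]) == 6

    def test_neighbor_choice_matches_bruteforce(self, montage32):
        x = np.random.default_rng(1).standard_normal((32, 20))
        _, nbmap = sv.interpolate_sensors(x, [10], montage32)
        d = np.linalg.norm(montage32.positions - montage32.positions[10], axis=1)
        d[10] = np.inf
        brute = set(np.argsort(d, kind="stable")[:6])
        assert set(nbmap[10]) == brute

    def test_bad_sensors_excluded_from_each_other(self, montage32):
        x = np.random.default_rng(2).standard_normal((32, 20))
        bad = [0, montage32.neighbors[0][0]]  # two adjacent bad sensors
        _, nbmap = sv.interpolate_sensors(x, bad, montage32)
        assert bad[1] not in nbmap[bad[0]]
        assert bad[0] not in nbmap[bad[1]]

    def test_too_few_good_neighbors_raises(self, montage32):
        x = np.zeros((32, 10))
        with pytest.raises(PreprocessingError, match="sensor"):
            sv.interpolate_sensors(x, list(range(28)), montage32)


class TestRereference:
    def test_channel_means_vanish(self):
        x = np.random.default_rng(3).standard_normal((16, 100)) + 2.0
        y = sv.rereference_common_average(x)
        assert np.abs(y.mean(axis=0)).max() < 1e-12

    def test_zero_mean_data_unchanged(self):
        x = np.random.default_rng(4).standard_normal((8, 50))
        x -= x.mean(axis=0, keepdims=True)
        assert np.allclose(sv.rereference_common_average(x), x, atol=1e-14)

    @given(offset=st.floats(-100, 100, allow_nan=False))
    def test_common_offset_invariance(self, offset):
        x = np.random.default_rng(5).standard_normal((8, 30))
        assert np.allclose(
            sv.rereference_common_average(x + offset), sv.rereference_common_average(x), atol=1e-10
        )

    def test_idempotent(self):
        x = np.random.default_rng(6).standard_normal((8, 40))
        once = sv.rereference_common_average(x)
        assert np.allclose(sv.rereference_common_average(once), once, atol=1e-13)


class TestSegmentation:
    def test_adult_sweep_gives_ten_epochs(self, noiseless_trial):
        epochs = sv.segment_epochs(noiseless_trial.samples, FS)
        assert epochs.shape == (10, 32, 420)

    def test_half_second_epochs(self):
        x = np.random.default_rng(7).standard_normal((4, 420))
        assert sv.segment_epochs(x, FS, epoch_ms=500).shape[0] == 2

    def test_roundtrip_concatenation(self, noiseless_trial):
        epochs = sv.segment_epochs(noiseless_trial.samples, FS)
        rebuilt = np.concatenate(list(epochs), axis=-1)
        assert np.array_equal(rebuilt, noiseless_trial.samples)

    def test_non_multiple_length_raises(self):
        with pytest.raises(PreprocessingError):
            sv.segment_epochs(np.zeros((2, 1000)), FS)


class TestRejection:
    def test_clean_data_all_valid(self, noiseless_trial):
        epochs = sv.segment_epochs(noiseless_trial.samples, FS)
        valid, report = sv.reject_epochs(epochs)
        assert valid.all()
        assert report.rejected_epochs == []

    def test_noisy_channel_epoch_only(self):
        epochs = np.zeros((4, 8, 420))
        n_bad = int(np.ceil(0.11 * 420))  # 11% of samples above threshold
        epochs[2, 5, :n_bad] = 31.0
        valid, report = sv.reject_epochs(epochs)
        assert not valid[5, 2]
        valid[5, 2] = True
        assert valid.all()
        assert report.rejected_channel_epochs == {5: [2]}

    def test_eight_peaking_sensors_reject_whole_epoch(self):
        epochs = np.zeros((5, 16, 420))
        epochs[3, :8, 7] = 70.0
        valid, report = sv.reject_epochs(epochs)
        assert report.rejected_epochs == [3]
        assert not valid[:, 3].any()
        # seven peaking sensors: only those channel-epochs go
        epochs = np.zeros((5, 16, 420))
        epochs[3, :7, 7] = 70.0
        valid, report = sv.reject_epochs(epochs)
        assert report.rejected_epochs == []
        assert not valid[:7, 3].any()
        assert valid[7:, 3].all()


class TestFullChain:
    def test_ledger_predicts_rejections_exactly(self, adult_protocol, montage32, inphase_cond):
        truth = sv.default_ground_truth(inphase_cond, montage32, adult_protocol)
        rec = sv.synthesize_trial(
            inphase_cond, adult_protocol, truth, montage32, noise=sv.NoiseSpec.silent(), seed=21
        )
        # amplitudes chosen to survive common-average re-referencing: an
        # 8-of-32-channel spike loses a quarter of its amplitude to the CAR
        spec = ArtifactSpec(
            bad_channels=((6, 40.0, 0.20),),
            spikes=(
                (int(2 * FS) + 50, 121.0, tuple(range(8, 16))),  # whole-epoch blowout, epoch 2
                (int(7 * FS) + 11, 75.0, (20,)),  # single-channel peak in epoch 7
            ),
        )
        dirty = sv.inject_artifacts(rec, spec, seed=5)
        pre = sv.preprocess_trial(dirty.samples, FS, montage32, apply_filter=False)
        assert pre.report.excluded_sensors == [6]
        assert 6 in pre.report.interpolated_sensors
        assert pre.report.rejected_epochs == [2]
        assert not pre.epochs.valid[:, 2].any()
        assert not pre.epochs.valid[20, 7]
        other = np.ones_like(pre.epochs.valid)
        other[:, 2] = False
        other[20, 7] = False
        assert np.array_equal(pre.epochs.valid, other.astype(bool))

    def test_report_interpolated_subset_of_excluded(self, montage32):
        report = sv.CleaningReport(excluded_sensors=[1], interpolated_sensors={2: (0, 3, 4, 5, 6, 7)})
        with pytest.raises(ValueError):
            report.validate()
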