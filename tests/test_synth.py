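"""Synthetic recordings: planted harmonic structure, artifacts, cohorts."""

import numpy as np
import pytest

import sweepvep as sv
from sweepvep.harmonics import dft_coefficients
from sweepvep.synth import ArtifactSpec, GroundTruthResponse, HarmonicTruth

from conftest import flat_truth


class TestSynthesizeTrial:
    def test_zero_truth_zero_noise_gives_zero_samples(self, adult_protocol, montage32, inphase_cond):
        params = sv.NakaRushtonParams(rmax=0.0, d50=2.0, n=1.5, b=0.0)
        truth = flat_truth(inphase_cond, montage32, params)
        rec = sv.synthesize_trial(
            inphase_cond, adult_protocol, truth, montage32, noise=sv.NoiseSpec.silent(), seed=0
        )
        assert np.all(rec.samples == 0)

    def test_trial_length_is_ten_seconds(self, noiseless_trial, adult_protocol):
        n = noiseless_trial.samples.shape[1]
        assert n == adult_protocol.n_samples
        assert n / noiseless_trial.fs == pytest.approx(10.0)

    def test_bin_coefficient_matches_response_function(self, adult_protocol, montage32, inphase_cond):
        # single 2F component, flat topography, saturated regime: the DFT
        # coefficient of every bin must equal the planted amplitude curve
        params = sv.NakaRushtonParams(rmax=1.0, d50=0.01, n=2.0, b=0.0)
        truth = flat_truth(inphase_cond, montage32, params, harmonic=2, phase=0.0)
        rec = sv.synthesize_trial(
            inphase_cond, adult_protocol, truth, montage32, noise=sv.NoiseSpec.silent(), seed=0
        )
        grid = sv.make_sweep_grid(adult_protocol)
        for k, sl in enumerate(adult_protocol.bin_slices()):
            c = dft_coefficients(rec.samples[0, sl], adult_protocol.fs, [4.0])[0]
            assert abs(c - sv.nr_eval(grid[k], params)) < 1e-9

    def test_spectral_purity_no_offgrid_energy(self, noiseless_trial, adult_protocol):
        # noiseless generation with integer cycles per bin: every
        # non-planted integer frequency must be empty
        planted = {h * adult_protocol.f_stim for h in (1, 2, 4)}
        sl = adult_protocol.bin_slices()[4]
        freqs = [f for f in range(1, 30) if f not in planted]
        c = dft_coefficients(noiseless_trial.samples[:, sl], adult_protocol.fs, freqs)
        assert np.abs(c).max() < 1e-9

    def test_symmetric_condition_plants_no_odd_harmonics(self, adult_protocol, montage32):
        cond = sv.ConditionSpec(interocular_phase="anti_phase", trajectory="straddle_zero")
        truth = sv.default_ground_truth(cond, montage32, adult_protocol)
        assert truth.components[1].params.rmax == 0.0
        with pytest.raises(ValueError):
            GroundTruthResponse(
                components={
                    1: HarmonicTruth(
                        params=sv.NakaRushtonParams(rmax=1.0, d50=2.0, n=1.5),
                        phase=0.0,
                        topography=np.ones(montage32.n_channels),
                    )
                },
                condition=cond,
            )

    def test_phase_locking_across_trials(self, adult_protocol, montage32, antiphase_cond):
        # planted phase identical across trials: circular variance of the
        # noiseless 2F coefficients over repeated trials is ~0
        truth = sv.default_ground_truth(antiphase_cond, montage32, adult_protocol)
        phases = []
        for seed in range(5):
            rec = sv.synthesize_trial(
                antiphase_cond, adult_protocol, truth, montage32,
                noise=sv.NoiseSpec.silent(), seed=seed,
            )
            sl = adult_protocol.bin_slices()[8]
            c = dft_coefficients(rec.samples[0, sl], adult_protocol.fs, [4.0])[0]
            phases.append(np.angle(c))
        z = np.mean(np.exp(1j * np.array(phases)))
        assert 1 - abs(z) < 1e-12

    def test_montage_mismatch_raises(self, adult_protocol, montage32, montage128, inphase_cond):
        truth = sv.default_ground_truth(inphase_cond, montage128, adult_protocol)
        with pytest.raises(ValueError):
            sv.synthesize_trial(inphase_cond, adult_protocol, truth, montage32, seed=0)

    def test_determinism_per_seed(self, adult_protocol, montage32, inphase_cond):
        truth = sv.default_ground_truth(inphase_cond, montage32, adult_protocol)
        a = sv.synthesize_trial(inphase_cond, adult_protocol, truth, montage32, seed=5)
        b = sv.synthesize_trial(inphase_cond, adult_protocol, truth, montage32, seed=5)
        assert np.array_equal(a.samples, b.samples)


class TestDefaultTruth:
    def test_antiphase_d50_doubled(self, adult_protocol, montage32, inphase_cond, antiphase_cond):
        t_in = sv.default_ground_truth(inphase_cond, montage32, adult_protocol)
        t_anti = sv.default_ground_truth(antiphase_cond, montage32, adult_protocol)
        assert t_anti.components[2].params.d50 == pytest.approx(
            2.0 * t_in.components[2].params.d50
        )

    def test_reference_removal_reduces_rmax(self, adult_protocol, montage32):
        full = sv.default_ground_truth(sv.ConditionSpec(), montage32, adult_protocol)
        noise_ref = sv.default_ground_truth(
            sv.ConditionSpec(reference_type="noise"), montage32, adult_protocol
        )
        assert noise_ref.components[2].params.rmax == pytest.approx(
            0.5 * full.components[2].params.rmax
        )

    def test_infant_preset_reversal_and_reference_insensitivity(self, montage32):
        p = sv.SweepProtocol.infant()
        base = sv.ConditionSpec(population="infant")
        t_in = sv.default_ground_truth(base, montage32, p)
        t_anti = sv.default_ground_truth(
            base.replace(interocular_phase="anti_phase"), montage32, p
        )
        t_noref = sv.default_ground_truth(base.replace(reference_type="none"), montage32, p)
        # anti-phase responses larger, no d50 shift, reference has no effect
        assert t_anti.components[2].params.rmax > t_in.components[2].params.rmax
        assert t_anti.components[2].params.d50 == pytest.approx(t_in.components[2].params.d50)
        assert t_noref.components[2].params.rmax == pytest.approx(t_in.components[2].params.rmax)


class TestArtifacts:
    def test_empty_spec_is_identity(self, noiseless_trial):
        out = sv.inject_artifacts(noiseless_trial, ArtifactSpec(), seed=0)
        assert np.array_equal(out.samples, noiseless_trial.samples)
        assert out.artifact_ledger.entries == []

    def test_bad_channel_flagged_downstream(self, noiseless_trial):
        spec = ArtifactSpec(bad_channels=((3, 35.0, 0.16),))
        out = sv.inject_artifacts(noiseless_trial, spec, seed=1)
        flagged = sv.detect_bad_sensors(out.samples, amp_thresh_uv=30.0, frac=0.15)
        assert 3 in flagged
        # ledger records the exact injected samples
        entry = out.artifact_ledger.entries[0]
        assert len(entry["samples"]) == round(0.16 * noiseless_trial.samples.shape[1])

    def test_spike_triggers_whole_epoch_rejection(self, noiseless_trial, adult_protocol):
        epoch, fs = 3, adult_protocol.fs
        sample = int(epoch * fs) + 100
        spec = ArtifactSpec(spikes=((sample, 70.0, tuple(range(8))),))
        out = sv.inject_artifacts(noiseless_trial, spec, seed=0)
        epochs = sv.segment_epochs(out.samples, fs)
        valid, report = sv.reject_epochs(epochs)
        assert report.rejected_epochs == [epoch]
        assert not valid[:, epoch].any()

    def test_out_of_bounds_artifact_raises(self, noiseless_trial):
        with pytest.raises(IndexError):
            sv.inject_artifacts(
                noiseless_trial, ArtifactSpec(spikes=((10**6, 70.0, (0,)),)), seed=0
            )


class TestCohort:
    def test_cohort_determinism(self, adult_protocol, montage32, inphase_cond):
        kw = dict(
            montage=montage32, noise=sv.NoiseSpec(pink_rms=1.0, white_rms=0.5),
            cohort=sv.CohortSpec(n_participants=2, n_trials=2),
        )
        a = sv.generate_cohort(2, [inphase_cond], adult_protocol, seed=9, **kw)
        b = sv.generate_cohort(2, [inphase_cond], adult_protocol, seed=9, **kw)
        assert len(a) == len(b) == 4
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.samples, rb.samples)

    def test_zero_spread_gives_identical_truth(self, adult_protocol, montage32, inphase_cond):
        recs = sv.generate_cohort(
            3, [inphase_cond], adult_protocol, seed=2, montage=montage32,
            noise=sv.NoiseSpec.silent(),
            cohort=sv.CohortSpec(n_participants=3, n_trials=1, amp_spread=0.0, topo_jitter=0.0),
        )
        rmaxes = {r.ground_truth.components[2].params.rmax for r in recs}
        assert len(rmaxes) == 1

    def test_planted_rmax_spread_mean(self, adult_protocol, montage32, inphase_cond):
        # 10% lognormal spread: the cohort mean of planted Rmax stays within
        # 3 SEM of the nominal value
        recs = sv.generate_cohort(
            15, [inphase_cond], adult_protocol, seed=3, montage=montage32,
            noise=sv.NoiseSpec.silent(),
            cohort=sv.CohortSpec(n_participants=15, n_trials=1, amp_spread=0.10, topo_jitter=0.0),
        )
        rmaxes = np.array([r.ground_truth.components[2].params.rmax for r in recs])
        nominal = 3.0
        sem = nominal * 0.10 / np.sqrt(15)
        assert abs(rmaxes.mean() - nominal) < 3 * sem
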