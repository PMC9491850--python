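"""Synthetic sEMG generator: determinism, envelopes, spectra, SNR, force."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import signal as sps

from emgforce.synth import (SynthConfig, Recording, TASKS, DEFAULT_LABELS,
                            generate_activation, generate_recording,
                            generate_task_suite, task_weights)
from emgforce.metrics import spectrum


class TestActivation:
    def test_seeded_determinism(self):
        a = generate_activation("flexion", 10.0, 1000.0, seed=1)
        b = generate_activation("flexion", 10.0, 1000.0, seed=1)
        np.testing.assert_array_equal(a, b)

    def test_range_and_rest_zero(self):
        env = generate_activation("flexion", 12.0, 1000.0, seed=3)
        assert env.min() >= 0.0 and env.max() <= 1.0
        # schedule starts with a 2 s rest bout: exactly zero there
        assert np.all(env[:2000] == 0.0)

    def test_unknown_task_lists_valid(self):
        with pytest.raises(ValueError, match="flexion"):
            generate_activation("wiggle", 10.0, 1000.0, seed=0)

    @pytest.mark.parametrize("task", TASKS)
    def test_dominant_channel_has_largest_weighted_activation(self, task):
        w = np.asarray(task_weights(task))
        env = generate_activation(task, 30.0, 1000.0, seed=5)
        product = env.mean(axis=0) * w
        assert int(np.argmax(product)) == int(np.argmax(w))

    def test_envelope_band_limited(self):
        env = generate_activation("extension", 30.0, 1000.0, seed=2)[:, 1]
        f, p = sps.periodogram(env - env.mean(), fs=1000.0)
        assert p[f <= 5.0].sum() / p.sum() > 0.99

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError, match="bout"):
            generate_activation("flexion", 1.0, 1000.0, seed=0)


class TestRecording:
    def test_seeded_determinism(self):
        cfg = SynthConfig(duration=8.0, seed=11)
        r1, r2 = generate_recording(cfg), generate_recording(cfg)
        np.testing.assert_array_equal(r1.signals, r2.signals)
        np.testing.assert_array_equal(r1.force, r2.force)

    def test_truth_provenance_and_shapes(self, short_recording):
        rec = short_recording
        assert rec.truth is not None and rec.truth.seed == 7
        assert rec.signals.shape == (12000, 4)
        assert rec.force.shape == (12000,)
        assert rec.labels == DEFAULT_LABELS

    def test_powerline_peak_detected(self, short_recording):
        spec = spectrum(short_recording.signals[:, 0], fs=1000.0)
        f, p = spec.frequencies, spec.power
        i = np.argmin(np.abs(f - 50.0))
        assert p[i] > p[i - 2] and p[i] > p[i + 2]

    def test_band_power_concentrated_below_150hz(self):
        cfg = SynthConfig(duration=20.0, seed=3,
                          powerline_amplitude=0.0, ecg_amplitude=0.0)
        rec = generate_recording(cfg)
        for c in range(rec.n_channels):
            spec = spectrum(rec.signals[:, c], fs=rec.fs)
            frac = spec.power[spec.frequencies <= 150.0].sum() / spec.power.sum()
            assert frac >= 0.70

    def test_measured_snr_within_1db(self):
        snr_db = 12.0
        cfg = SynthConfig(duration=30.0, seed=9, snr_db=snr_db)
        noisy = generate_recording(cfg)
        clean = generate_recording(replace(cfg, snr_db=200.0))
        for c in range(4):
            noise = noisy.signals[:, c] - clean.signals[:, c]
            measured = 10 * np.log10(np.mean(clean.signals[:, c] ** 2)
                                     / np.mean(noise ** 2))
            assert abs(measured - snr_db) < 1.0

    def test_force_invariant_to_joint_channel_permutation(self):
        cfg = SynthConfig(duration=8.0, seed=21)
        perm = (2, 0, 3, 1)
        cfg_p = replace(cfg,
                        channel_labels=tuple(cfg.channel_labels[i] for i in perm),
                        weight_vector=tuple(cfg.weights[i] for i in perm))
        rec, rec_p = generate_recording(cfg), generate_recording(cfg_p)
        np.testing.assert_allclose(rec_p.force, rec.force)
        np.testing.assert_allclose(rec_p.signals, rec.signals[:, perm])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(duration=-1.0)
        with pytest.raises(ValueError):
            SynthConfig(fs=250.0)          # below twice the max frequency
        with pytest.raises(ValueError):
            SynthConfig(weight_vector=(1.0, 1.0, 0.5, 0.5))  # two maxima


class TestTaskSuite:
    def test_four_tasks_planted_dominants(self):
        suite = generate_task_suite(SynthConfig(duration=8.0, seed=42))
        assert set(suite) == set(TASKS)
        flex = suite["flexion"].truth
        assert int(np.argmax(flex.weights)) == DEFAULT_LABELS.index("BB")
        assert int(np.argmax(suite["extension"].truth.weights)) == DEFAULT_LABELS.index("TB")
        assert int(np.argmax(suite["pronation"].truth.weights)) == DEFAULT_LABELS.index("BRD")
        assert int(np.argmax(suite["supination"].truth.weights)) == DEFAULT_LABELS.index("BR")

    def test_shared_fs_duration_distinct_signals(self):
        suite = generate_task_suite(SynthConfig(duration=8.0, seed=1))
        recs = list(suite.values())
        assert len({r.fs for r in recs}) == 1
        assert len({r.n_samples for r in recs}) == 1
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                assert not np.array_equal(recs[i].signals, recs[j].signals)
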