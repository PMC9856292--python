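"""Synthetic-EEG generator: planted structure, determinism, convergence."""

import dataclasses

import numpy as np
import pytest

from msdoc import (
    GroundTruth,
    Montage,
    default_montage,
    make_templates,
    simulate_label_sequence,
    stationary_coverage,
    synthesize_eeg,
)
from msdoc.synth import embedded_stationary, expected_syntax, uniform_offdiagonal


class TestMakeTemplates:
    def test_postconditions(self, montage):
        T = make_templates(montage, 4, seed=1)
        assert T.shape == (4, 19)
        assert np.abs(T.mean(axis=1)).max() < 1e-12
        assert np.abs(np.linalg.norm(T, axis=1) - 1).max() < 1e-12
        corr = T @ T.T
        off = corr[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() <= 0.7

    def test_two_channel_single_map_is_antisymmetric(self):
        # average reference leaves a single zero-mean direction in 2 channels
        T = make_templates(Montage(("a", "b")), 1, seed=0)
        expected = np.array([1.0, -1.0]) / np.sqrt(2)
        assert np.allclose(np.abs(T[0]), np.abs(expected))
        assert abs(abs(float(T[0] @ expected)) - 1.0) < 1e-12

    def test_seed_determinism(self, montage):
        assert np.array_equal(
            make_templates(montage, 4, seed=9), make_templates(montage, 4, seed=9)
        )

    def test_k_too_large_rejected(self, montage):
        with pytest.raises(ValueError):
            make_templates(montage, 19, seed=0)


class TestLabelSequence:
    def test_fixed_dwell_forced_alternation(self):
        T = make_templates(Montage(("a", "b", "c")), 2, seed=0)
        truth = GroundTruth(
            templates=T,
            transition_probs=np.array([[0.0, 1.0], [1.0, 0.0]]),
            mean_dwell_ms=100.0,  # 20 samples at 200 Hz
            dwell_dist="fixed",
        )
        lab = simulate_label_sequence(truth, 2.0, 200.0, seed=1)
        assert len(lab) == 400
        blocks = np.split(lab, np.flatnonzero(np.diff(lab)) + 1)
        assert all(len(b) == 20 for b in blocks)
        starts = [b[0] for b in blocks]
        assert all(a != b for a, b in zip(starts[:-1], starts[1:]))

    def test_mean_dwell_converges(self, truth):
        uniform = dataclasses.replace(truth, mean_dwell_ms=np.full(4, 80.0))
        lab = simulate_label_sequence(uniform, 600.0, 200.0, seed=2)
        bounds = np.flatnonzero(np.diff(lab)) + 1
        lens = np.diff(np.concatenate([[0], bounds, [len(lab)]]))
        assert abs(lens.mean() * 5.0 - 80.0) / 80.0 < 0.05

    def test_transition_frequencies_converge(self, templates):
        P = np.array(
            [
                [0.0, 0.5, 0.3, 0.2],
                [0.4, 0.0, 0.4, 0.2],
                [0.1, 0.3, 0.0, 0.6],
                [0.3, 0.3, 0.4, 0.0],
            ]
        )
        truth = GroundTruth(
            templates=templates, transition_probs=P, mean_dwell_ms=40.0
        )
        lab = simulate_label_sequence(truth, 600.0, 200.0, seed=4)
        bounds = np.flatnonzero(np.diff(lab)) + 1
        src, dst = lab[bounds - 1], lab[bounds]
        assert len(src) > 1000
        for i in range(4):
            sel = src == i
            for j in range(4):
                if i != j:
                    emp = np.mean(dst[sel] == j)
                    assert abs(emp - P[i, j]) < 0.05

    def test_non_stochastic_rows_rejected(self, templates):
        bad = np.full((4, 4), 0.2)
        with pytest.raises(ValueError):
            GroundTruth(templates=templates, transition_probs=bad, mean_dwell_ms=80.0)


class TestSynthesizeEEG:
    def test_default_shape(self, truth):
        rec, _ = synthesize_eeg(truth, 360.0, 200.0, seed=0)
        assert rec.data.shape == (72000, 19)
        assert rec.fs == 200.0

    def test_noise_free_topography_matches_template(self, clean_recording):
        rec, realized = clean_recording
        data = rec.data - rec.data.mean(axis=1, keepdims=True)
        unit = data / np.linalg.norm(data, axis=1, keepdims=True)
        r = np.einsum("tc,tc->t", unit, realized.templates[realized.label_sequence])
        assert np.allclose(np.abs(r), 1.0, atol=1e-9)

    def test_noise_free_channel_mean_zero(self, clean_recording):
        rec, _ = clean_recording
        assert np.abs(rec.data.mean(axis=1)).max() < 1e-9

    def test_snr_realised(self, truth):
        rec, realized = synthesize_eeg(truth, 60.0, 200.0, seed=5)
        clean, _ = synthesize_eeg(
            dataclasses.replace(truth, snr=np.inf), 60.0, 200.0, seed=5
        )
        noise = rec.data - clean.data
        gfp = lambda d: np.sqrt(
            np.mean((d - d.mean(axis=1, keepdims=True)) ** 2, axis=1)
        )
        realized_snr = gfp(clean.data).mean() / gfp(noise).mean()
        assert abs(realized_snr - 5.0) / 5.0 < 0.01

    def test_seed_determinism(self, truth):
        a, ta = synthesize_eeg(truth, 5.0, 200.0, seed=11)
        b, tb = synthesize_eeg(truth, 5.0, 200.0, seed=11)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(ta.label_sequence, tb.label_sequence)

    def test_invalid_snr_rejected(self, truth):
        bad = dataclasses.replace(truth, snr=-1.0)
        with pytest.raises(ValueError):
            synthesize_eeg(bad, 1.0, 200.0, seed=0)


class TestStationary:
    def test_embedded_uniform(self):
        nu = embedded_stationary(uniform_offdiagonal(4))
        assert np.allclose(nu, 0.25)

    def test_coverage_weights_by_dwell(self, templates):
        truth = GroundTruth(
            templates=templates,
            transition_probs=uniform_offdiagonal(4),
            mean_dwell_ms=(85.0, 85.0, 73.0, 95.0),
        )
        cov = stationary_coverage(truth)
        assert np.allclose(cov, np.array([85, 85, 73, 95]) / 338.0)

    def test_realised_coverage_converges(self, truth):
        lab = simulate_label_sequence(truth, 600.0, 200.0, seed=6)
        cov = stationary_coverage(truth)
        emp = np.array([np.mean(lab == k) for k in range(4)])
        assert np.abs(emp - cov).max() < 0.03

    def test_expected_syntax_normalised(self, truth):
        syn = expected_syntax(truth)
        assert abs(syn.sum() - 1.0) < 1e-12
        assert np.abs(np.diag(syn)).max() == 0.0
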