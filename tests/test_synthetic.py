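"""Synthetic targets, oddball paradigm, binning rule, epoching."""

import numpy as np
import pytest

from aancolumn import ConfigError
from aancolumn.synthetic import (ERFComponent, ERFComponentSet,
                                 OddballTimeline, bin_tones, epoch,
                                 generate_oddball, generate_targets)


class TestTargets:
    def test_null_aan_makes_conditions_identical(self):
        spec = ERFComponentSet(aan=ERFComponent("AAN", 180, 65, 0.0),
                               noise_nAm=0.0)
        und, det = generate_targets(spec)
        np.testing.assert_array_equal(und.amplitude_nAm, det.amplitude_nAm)

    def test_difference_recovers_aan_exactly(self):
        spec = ERFComponentSet(noise_nAm=0.0)
        und, det = generate_targets(spec)
        diff = det.amplitude_nAm - und.amplitude_nAm
        np.testing.assert_allclose(diff, spec.aan.waveform(und.times_ms),
                                   atol=1e-12)

    def test_difference_extremum_at_aan_peak(self):
        spec = ERFComponentSet(noise_nAm=0.0)
        und, det = generate_targets(spec)
        diff = det.amplitude_nAm - und.amplitude_nAm
        t_ext = und.times_ms[np.argmin(diff)]
        assert diff.min() < 0
        assert abs(t_ext - spec.aan.peak_ms) <= 4.0  # within two samples

    def test_undetected_morphology(self):
        und, _ = generate_targets(ERFComponentSet(noise_nAm=0.0))
        t = und.times_ms
        early = und.amplitude_nAm[(t >= 40) & (t <= 60)]
        n1 = und.amplitude_nAm[(t >= 90) & (t <= 110)]
        assert early[np.argmax(np.abs(early))] > 0
        assert n1[np.argmin(n1)] < 0

    def test_epoch_grid(self):
        und, _ = generate_targets()
        assert und.times_ms[0] == -50.0
        assert und.times_ms.size == 250  # 500 ms at 500 Hz
        assert und.times_ms[1] - und.times_ms[0] == pytest.approx(2.0)

    def test_reproducible_given_seed(self):
        a, _ = generate_targets(ERFComponentSet(seed=5))
        b, _ = generate_targets(ERFComponentSet(seed=5))
        np.testing.assert_array_equal(a.amplitude_nAm, b.amplitude_nAm)
        c, _ = generate_targets(ERFComponentSet(seed=6))
        assert not np.array_equal(a.amplitude_nAm, c.amplitude_nAm)

    def test_aan_support_is_broad(self):
        spec = ERFComponentSet()
        aan = spec.aan
        for t_edge in (60.0, 360.0):
            assert abs(aan.waveform(np.array([t_edge]))[0]) \
                >= 0.01 * abs(aan.amplitude_nAm)


class TestOddball:
    def test_sequence_geometry(self):
        (tl,) = generate_oddball(seed=0, n_sequences=1)
        assert len(tl.onsets_s) == 10
        assert np.allclose(np.diff(tl.onsets_s), 0.5)
        assert tl.tone_duration_ms == 100.0
        assert len(tl.standard_onsets_s) == 9

    def test_deterministic(self):
        a = generate_oddball(seed=3, n_sequences=5)
        b = generate_oddball(seed=3, n_sequences=5)
        assert [(x.deviant_index, x.press_time_s) for x in a] == \
               [(x.deviant_index, x.press_time_s) for x in b]

    def test_deviant_positions_roughly_uniform(self):
        tls = generate_oddball(seed=1, n_sequences=400)
        counts = np.bincount([tl.deviant_index for tl in tls], minlength=10)
        chi2 = ((counts - 40.0) ** 2 / 40.0).sum()
        assert chi2 < 27.9  # chi-square 9 dof, p ~ 0.001

    def test_uneven_spacing_rejected(self):
        with pytest.raises(ConfigError):
            OddballTimeline(onsets_s=tuple(np.linspace(0, 4.4, 10)),
                            deviant_index=0)


class TestBinning:
    def test_worked_example(self):
        tl = OddballTimeline(onsets_s=tuple(np.arange(10) * 0.5),
                             deviant_index=4, press_time_s=2.7)
        detected, undetected = bin_tones(tl)
        assert detected == [1.5, 2.5, 3.0, 3.5, 4.0, 4.5]
        assert undetected == [0.0, 0.5, 1.0]

    def test_no_press_all_undetected(self):
        tl = OddballTimeline(onsets_s=tuple(np.arange(10) * 0.5),
                             deviant_index=0, press_time_s=None)
        detected, undetected = bin_tones(tl)
        assert detected == []
        assert len(undetected) == 9

    def test_immediate_press_all_detected(self):
        tl = OddballTimeline(onsets_s=tuple(np.arange(10) * 0.5),
                             deviant_index=9, press_time_s=0.1)
        detected, undetected = bin_tones(tl)
        assert undetected == []
        assert len(detected) == 9

    def test_partition_invariants_random_timelines(self):
        """detected and undetected partition the standards; the deviant
        belongs to neither."""
        rng = np.random.default_rng(12)
        onsets = tuple(np.arange(10) * 0.5)
        for _ in range(1000):
            tl = OddballTimeline(
                onsets_s=onsets,
                deviant_index=int(rng.integers(0, 10)),
                press_time_s=(float(rng.uniform(-0.5, 5.5))
                              if rng.random() < 0.8 else None))
            detected, undetected = bin_tones(tl)
            standards = set(tl.standard_onsets_s)
            assert set(detected) | set(undetected) == standards
            assert set(detected) & set(undetected) == set()
            assert onsets[tl.deviant_index] not in set(detected) | set(
                undetected)


class TestEpoch:
    def test_single_onset_sample_count(self):
        fs = 500.0
        t = np.arange(0, 6.0, 1 / fs)
        x = np.sin(t)
        epochs, kept = epoch(t, x, [1.0])
        assert len(epochs) == 1 and kept == [1.0]
        assert epochs[0].size == 250

    def test_no_onsets(self):
        t = np.arange(0, 2.0, 0.002)
        assert epoch(t, np.zeros_like(t), [])[0] == []

    def test_edge_onset_dropped(self):
        t = np.arange(0, 1.0, 0.002)
        epochs, kept = epoch(t, np.zeros_like(t), [0.9])
        assert epochs == [] and kept == []

    def test_translation_between_onsets(self):
        fs = 500.0
        t = np.arange(0, 6.0, 1 / fs)
        x = t.copy()  # ramp: epoch values encode absolute time
        epochs, _ = epoch(t, x, [2.0, 2.5])
        np.testing.assert_allclose(epochs[1] - epochs[0], 0.5, atol=1e-9)
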