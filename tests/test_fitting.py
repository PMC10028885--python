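"""RMSE, variant construction, optimisation contracts, comparison."""

import copy

import numpy as np
import pytest

from aancolumn import ConfigError, SimulationConfig
from aancolumn.fitting import (DEFAULT_SCALE, ModelVariant, build_variant,
                               difference_waveform, optimize_drives, rmse,
                               simulate_condition)
from aancolumn.observables import DipoleTrace
from aancolumn.synthetic import TargetWaveform


def _trace(values, t0=0.0, dt=2.0):
    v = np.asarray(values, dtype=float)
    t = t0 + dt * np.arange(v.size)
    return DipoleTrace(t, np.stack([v / 2, v / 2]))


def _target(values, t0=0.0, dt=2.0, condition="undetected"):
    v = np.asarray(values, dtype=float)
    return TargetWaveform(t0 + dt * np.arange(v.size), v, condition)


class TestRmse:
    def test_identity_zero(self):
        v = np.sin(np.linspace(0, 5, 50))
        assert rmse(_trace(v), _target(v), (0, 98)) == pytest.approx(0.0)

    def test_constant_offset(self):
        v = np.linspace(-1, 1, 40)
        assert rmse(_trace(v + 0.37), _target(v), (0, 78)) \
            == pytest.approx(0.37)

    def test_hand_computed_three_samples(self):
        sim = _trace([3.0, 4.0, 0.0])
        tgt = _target([0.0, 0.0, 0.0])
        assert rmse(sim, tgt, (0, 4)) == pytest.approx(np.sqrt(25.0 / 3.0))

    def test_disjoint_support_rejected(self):
        sim = _trace([1.0, 2.0], t0=0.0)
        tgt = _target([1.0, 2.0], t0=500.0)
        with pytest.raises(ConfigError):
            rmse(sim, tgt, (0.0, 4.0))


class TestVariants:
    def test_preferred_drive_sequence(self):
        v = build_variant("preferred")
        und = v.drives["undetected"]
        det = v.drives["detected"]
        assert [(d.kind, d.mean_time_ms, d.sd_time_ms) for d in und] == [
            ("proximal", 47.8, 13.2), ("distal", 84.3, 15.1)]
        assert det[-1].kind == "distal"
        assert (det[-1].mean_time_ms, det[-1].sd_time_ms) == (169.3, 50.4)
        assert v.frozen["detected"] == (True, True, False)

    def test_perisomatic_variant(self):
        v = build_variant("perisomatic_inhibition")
        assert v.perisomatic_factor == 2.0
        conn = v.connectivity()
        assert conn.find("L5_basket", "L5_PN", "soma",
                         "GABA_B").weight_uS == pytest.approx(0.05)
        drives = v.drives["detected"]
        assert [(d.kind, d.mean_time_ms) for d in drives] == [
            ("proximal", 36.0), ("distal", 84.3), ("proximal", 169.3)]

    def test_reduced_variant(self):
        v = build_variant("reduced")
        assert len(v.drives["undetected"]) == 1
        assert v.drives["undetected"][0].kind == "proximal"
        assert v.drives["undetected"][0].sd_time_ms == 13.3
        assert (v.drives["detected"][1].mean_time_ms,
                v.drives["detected"][1].sd_time_ms) == (154.0, 55.1)

    def test_prox_dist_prox_variant(self):
        v = build_variant("prox_dist_prox")
        last = v.drives["detected"][-1]
        assert last.kind == "proximal"
        assert (last.mean_time_ms, last.sd_time_ms) == (395.4, 20.0)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigError):
            build_variant("jones2009")


class TestDifferenceWaveform:
    def test_identical_inputs_zero(self):
        v = np.sin(np.linspace(0, 3, 30))
        d = difference_waveform(_trace(v), _trace(v))
        assert d.condition == "difference"
        np.testing.assert_allclose(d.amplitude_nAm, 0.0, atol=1e-15)

    def test_linearity_recovers_added_component(self):
        base = np.sin(np.linspace(0, 3, 30))
        extra = -0.8 * np.exp(-np.linspace(-2, 2, 30) ** 2)
        d = difference_waveform(_trace(base + extra), _trace(base))
        np.testing.assert_allclose(d.amplitude_nAm, extra, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            difference_waveform(_trace(np.zeros(10)),
                                _trace(np.zeros(10), t0=1.0))


class TestOptimizerContracts:
    """Cheap contracts (budget 0); the full parameter-recovery check
    lives in the acceptance suite."""

    def _quick_target(self):
        t = np.arange(-50.0, 450.0, 2.0)
        return TargetWaveform(t, np.zeros_like(t), "undetected")

    def test_budget_zero_returns_initial_evaluation(self):
        v = build_variant("reduced")
        res = optimize_drives(v, "undetected", self._quick_target(),
                              budget=0, seed=1, n_trials=1)
        assert res.n_evaluations == 1
        assert res.rmse_nAm == res.initial_rmse_nAm
        assert [d.mean_time_ms for d in res.drives] == [47.8]

    def test_negative_budget_rejected(self):
        v = build_variant("reduced")
        with pytest.raises(ConfigError):
            optimize_drives(v, "undetected", self._quick_target(), budget=-1)

    def test_frozen_drives_bit_identical(self):
        v = build_variant("preferred")
        originals = copy.deepcopy(v.drives["detected"][:2])
        res = optimize_drives(v, "detected", self._quick_target(),
                              budget=4, seed=1, n_trials=1)
        for orig, fitted in zip(originals, res.drives[:2]):
            assert fitted.mean_time_ms == orig.mean_time_ms
            assert fitted.sd_time_ms == orig.sd_time_ms
            assert fitted.weights == orig.weights

    def test_best_so_far_trace_monotone(self):
        v = build_variant("reduced")
        res = optimize_drives(v, "undetected", self._quick_target(),
                              budget=6, seed=1, n_trials=1)
        assert all(a >= b for a, b in zip(res.trace, res.trace[1:]))
        assert res.rmse_nAm <= res.initial_rmse_nAm
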