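"""Integration engine: determinism, accuracy, bookkeeping, batching."""

import numpy as np
import pytest

from aancolumn import (ConfigError, EvokedDrive, SimulationConfig,
                       attach_drive, build_default_column,
                       default_connectivity, integrate, run_batch,
                       set_connectivity)
import aancolumn._kernel as kernel_mod


def _driven_network(sd=5.0, seed_net=0):
    net = build_default_column(seed_net, 1)
    set_connectivity(net, default_connectivity())
    attach_drive(net, EvokedDrive("p", "proximal", 40.0, sd,
                                  {("L23_PN", "AMPA"): 4e-3,
                                   ("L5_PN", "AMPA"): 1e-3,
                                   ("L23_basket", "AMPA"): 2e-4}))
    return net


class TestDeterminismAndBatching:
    def test_resting_network_flat(self, column):
        cfg = SimulationConfig(tstart_ms=0, duration_ms=100, n_trials=1)
        res = integrate(column, [], cfg, 0)
        assert res.spike_times.size == 0
        assert np.allclose(res.dipole_layers_nAm, 0.0, atol=1e-12)

    def test_bitwise_reproducible(self):
        cfg = SimulationConfig(tstart_ms=0, duration_ms=150, n_trials=1)
        res = [integrate(_driven_network(), None, cfg, 5) for _ in range(2)]
        assert np.array_equal(res[0].spike_times, res[1].spike_times)
        assert np.array_equal(res[0].dipole_layers_nAm,
                              res[1].dipole_layers_nAm)

    def test_batch_seeds_and_variability(self):
        cfg = SimulationConfig(tstart_ms=0, duration_ms=150, n_trials=5,
                               base_seed=3)
        trials = run_batch(_driven_network(), None, cfg)
        assert len(trials) == 5
        assert [t.trial_seed for t in trials] == [3, 4, 5, 6, 7]
        rasters = {tuple(np.round(t.spike_times, 3)) for t in trials}
        assert len(rasters) > 1  # Gaussian jitter differs across trials

    def test_degenerate_sd_trials_identical(self):
        cfg = SimulationConfig(tstart_ms=0, duration_ms=120, n_trials=3)
        trials = run_batch(_driven_network(sd=0.0), None, cfg)
        for t in trials[1:]:
            assert np.array_equal(t.spike_times, trials[0].spike_times)
            assert np.array_equal(t.dipole_layers_nAm,
                                  trials[0].dipole_layers_nAm)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(dt_ms=0.0)
        with pytest.raises(ConfigError):
            SimulationConfig(n_trials=0)

    def test_voltage_blowup_aborts_with_diagnostic(self, column):
        from aancolumn import SimulationError

        cfg = SimulationConfig(tstart_ms=0, duration_ms=50, n_trials=1)
        with pytest.raises(SimulationError, match="blow-up"):
            integrate(column, [], cfg, 0,
                      injections=[(0, "soma", 1e5, 10.0, 40.0)])


class TestNumericalAccuracy:
    def test_single_neuron_spike_count_matches_fine_step(self, column):
        """Current-step spike count is unchanged under a 10x finer step."""
        inj = [(0, "soma", 0.2, 50.0, 150.0)]
        counts = {}
        for dt in (0.025, 0.0025):
            cfg = SimulationConfig(dt_ms=dt, tstart_ms=0, duration_ms=200,
                                   n_trials=1)
            res = integrate(column, [], cfg, 0, injections=inj)
            counts[dt] = int((res.spike_cells == 0).sum())
        assert counts[0.025] == counts[0.0025]

    def test_step_halving_convergence(self):
        """The preferred model's averaged dipole changes by <1% of its
        peak-to-peak range when the integration step is halved."""
        from aancolumn.fitting import build_variant, simulate_condition

        out = {}
        for dt in (0.025, 0.0125):
            cfg = SimulationConfig(dt_ms=dt, n_trials=3, base_seed=1)
            avg = simulate_condition(build_variant("preferred"), "detected",
                                     cfg)
            out[dt] = (avg.times_ms, avg.total_nAm)
        t1, a = out[0.025]
        t2, b = out[0.0125]
        bi = np.interp(t1, t2, b)
        rms = np.sqrt(np.mean((a - bi) ** 2))
        assert rms < 0.01 * (a.max() - a.min())

    def test_charge_bookkeeping(self):
        """Capacitive current balances ionic + synaptic + axial + injected
        currents at every step (subthreshold regime)."""
        net = build_default_column(0, 1)
        attach_drive(net, EvokedDrive("p", "proximal", 20.0, 0.0,
                                      {("L23_PN", "AMPA"): 2e-4}))
        cfg = SimulationConfig(tstart_ms=0, duration_ms=60, n_trials=1,
                               record_currents=True)
        res = integrate(net, None, cfg, 0)
        b = res.bookkeeping
        residual = b["i_cap"] + b["i_ion"] + b["i_syn"] - b["i_ax"] - b["i_inj"]
        scale = np.abs(b["i_cap"]).max()
        assert np.abs(residual).max() < 0.02 * max(scale, 1e-9)

    def test_accelerated_path_matches_reference(self, monkeypatch):
        """The fused kernel and the plain-numpy path agree closely.

        Compared in the subthreshold regime, where floating-point
        reassociation cannot be amplified through spike thresholding.
        """
        def weak_net():
            net = build_default_column(0, 1)
            set_connectivity(net, default_connectivity())
            attach_drive(net, EvokedDrive("p", "proximal", 40.0, 5.0,
                                          {("L23_PN", "AMPA"): 1e-4,
                                           ("L5_PN", "AMPA"): 1e-4}))
            return net

        cfg = SimulationConfig(tstart_ms=0, duration_ms=120, n_trials=1)
        fast = integrate(weak_net(), None, cfg, 2)
        monkeypatch.setattr(kernel_mod, "HAVE_NUMBA", False)
        slow = integrate(weak_net(), None, cfg, 2)
        assert fast.spike_times.size == 0 and slow.spike_times.size == 0
        np.testing.assert_allclose(fast.dipole_layers_nAm,
                                   slow.dipole_layers_nAm,
                                   rtol=1e-6, atol=1e-12)
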