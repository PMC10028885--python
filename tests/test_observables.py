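"""Dipole, laminar decomposition, LFP forward model, spike statistics."""

import numpy as np
import pytest

from aancolumn import (ConfigError, EvokedDrive, SimulationConfig,
                       attach_drive, average_scale_smooth, baseline_correct,
                       build_default_column, build_raster, compute_dipole,
                       compute_lfp, decompose_by_layer, integrate,
                       spike_stats)
from aancolumn.observables import (DipoleTrace, ElectrodeConfig, SpikeRaster)


def _sim(kind, weights, duration=150.0, seed=0, net=None):
    net = net or build_default_column(0, 1)
    attach_drive(net, EvokedDrive("d", kind, 50.0, 0.0, weights))
    cfg = SimulationConfig(tstart_ms=0.0, duration_ms=duration, n_trials=1)
    return integrate(net, None, cfg, seed), net


class TestDipole:
    def test_resting_trial_zero(self, column):
        cfg = SimulationConfig(tstart_ms=0, duration_ms=50, n_trials=1)
        res = integrate(column, [], cfg, 0)
        d = compute_dipole(res, column)
        assert np.allclose(d.total_nAm, 0.0, atol=1e-12)

    @pytest.mark.parametrize("kind,sign", [("proximal", +1), ("distal", -1)])
    def test_sign_convention_initial_deflection(self, kind, sign):
        """Excitatory proximal input drives current up the dendrites
        (positive dipole onset); excitatory distal input drives it down
        (negative onset).  Local connectivity is left unattached so only
        the direct effect is measured."""
        res, net = _sim(kind, {("L23_PN", "AMPA"): 5e-4,
                               ("L5_PN", "AMPA"): 5e-4})
        d = compute_dipole(res, net)
        tot = d.total_nAm
        thr = 0.02 * np.abs(tot).max()
        first = tot[np.abs(tot) > thr][0]
        assert np.sign(first) == sign

    def test_laminar_partition_identity(self):
        res, net = _sim("proximal", {("L23_PN", "AMPA"): 4e-3,
                                     ("L5_PN", "AMPA"): 2e-3})
        l23, l5 = decompose_by_layer(res, net)
        total = compute_dipole(res, net).total_nAm
        np.testing.assert_allclose(l23 + l5, total, rtol=1e-9, atol=1e-15)

    def test_resting_decomposition_zero(self, column):
        cfg = SimulationConfig(tstart_ms=0, duration_ms=50, n_trials=1)
        l23, l5 = decompose_by_layer(integrate(column, [], cfg, 0), column)
        assert np.allclose(l23, 0.0, atol=1e-12)
        assert np.allclose(l5, 0.0, atol=1e-12)


class TestAverageScaleSmooth:
    def _trace(self, values):
        v = np.asarray(values, dtype=float)
        return DipoleTrace(np.arange(v.size, dtype=float),
                           np.stack([v / 2, v / 2]))

    def test_identity_settings(self):
        tr = self._trace(np.sin(np.linspace(0, 3, 40)))
        out = average_scale_smooth([tr], scale=1, smoothing_ms=0.0)
        np.testing.assert_allclose(out.total_nAm, tr.total_nAm)

    def test_identical_traces_average_to_input_scaled(self):
        tr = self._trace(np.linspace(-1, 1, 30))
        out = average_scale_smooth([tr, tr, tr], scale=300, smoothing_ms=0.0)
        np.testing.assert_allclose(out.total_nAm, 300 * tr.total_nAm)

    def test_dc_preserved_by_smoothing(self):
        tr = self._trace(np.full(60, 0.7))
        out = average_scale_smooth([tr], scale=2, smoothing_ms=10.0)
        np.testing.assert_allclose(out.total_nAm, 1.4, rtol=1e-9)

    def test_empty_list_rejected(self):
        with pytest.raises(ConfigError):
            average_scale_smooth([], scale=1)

    def test_baseline_correction(self):
        t = np.arange(-50.0, 50.0, 2.0)
        layers = np.stack([np.full(t.size, 3.0), np.full(t.size, 1.0)])
        tr = DipoleTrace(t, layers)
        out = baseline_correct(tr)
        np.testing.assert_allclose(out.total_nAm, 0.0, atol=1e-12)


class TestLFP:
    def test_resting_lfp_zero(self, column):
        cfg = SimulationConfig(tstart_ms=0, duration_ms=50, n_trials=1)
        res = integrate(column, [], cfg, 0)
        lfp = compute_lfp(res, column)
        assert lfp.potentials_mV.shape[0] == 50
        assert np.allclose(lfp.potentials_mV, 0.0, atol=1e-9)

    def test_point_source_closed_form(self, column):
        """phi = I / (4 pi sigma r) for a single point source."""
        cfg = SimulationConfig(tstart_ms=0, duration_ms=10, n_trials=1)
        res = integrate(column, [], cfg, 0)
        res.membrane_currents_nA = np.zeros_like(res.membrane_currents_nA)
        src = 0  # first compartment of cell 0
        res.membrane_currents_nA[:, src] = 2.5
        el = ElectrodeConfig()
        lfp = compute_lfp(res, column, el)
        f = column.fabric
        for contact in (0, 25, 49):
            r = np.sqrt((f.x_um[src] - el.x_um) ** 2
                        + (f.y_um[src] - el.y_um) ** 2
                        + (f.z_um[src] - el.depths_um[contact]) ** 2)
            r = max(r, el.min_distance_um)
            expected = 2.5 / (4 * np.pi * el.conductivity_S_per_m * r)
            assert lfp.potentials_mV[contact, 0] == pytest.approx(expected)

    def test_conductivity_scaling(self, column):
        cfg = SimulationConfig(tstart_ms=0, duration_ms=10, n_trials=1)
        res = integrate(column, [], cfg, 0)
        res.membrane_currents_nA[:, :] = np.random.default_rng(0).normal(
            size=res.membrane_currents_nA.shape)
        a = compute_lfp(res, column, ElectrodeConfig(conductivity_S_per_m=0.3))
        b = compute_lfp(res, column, ElectrodeConfig(conductivity_S_per_m=0.6))
        np.testing.assert_allclose(a.potentials_mV, 2 * b.potentials_mV,
                                   rtol=1e-12)

    def test_linearity_in_sources(self, column):
        cfg = SimulationConfig(tstart_ms=0, duration_ms=10, n_trials=1)
        res = integrate(column, [], cfg, 0)
        base = np.zeros_like(res.membrane_currents_nA)
        ia, ib = base.copy(), base.copy()
        ia[:, 10] = 1.0
        ib[:, 500] = -2.0
        out = {}
        for key, cur in (("a", ia), ("b", ib), ("ab", ia + ib)):
            res.membrane_currents_nA = cur
            out[key] = compute_lfp(res, column).potentials_mV
        np.testing.assert_allclose(out["ab"], out["a"] + out["b"],
                                   rtol=1e-12, atol=1e-15)


class TestSpikeStats:
    def _raster(self, rows):
        cid, cls, t = zip(*rows) if rows else ((), (), ())
        return SpikeRaster(np.array(cid, dtype=int),
                           np.array(cls, dtype=int),
                           np.array(t, dtype=float))

    def test_empty_raster_all_zero(self):
        st = spike_stats(self._raster([]), (100, 300))
        assert all(v == 0 for v in st["counts"].values())
        assert all(v == 0 for v in st["bursts"].values())

    def test_single_l5_burst_example(self):
        # one L5 PN (class code 1) spiking at 180, 190, 200 ms
        r = self._raster([(7, 1, 180.0), (7, 1, 190.0), (7, 1, 200.0)])
        st = spike_stats(r, (100, 300))
        assert st["counts"]["L5_PN"] == 3
        assert st["bursts"]["L5_PN"] == 1

    def test_window_exclusion(self):
        r = self._raster([(7, 1, 180.0), (7, 1, 190.0), (7, 1, 200.0)])
        st = spike_stats(r, (0, 100))
        assert st["counts"]["L5_PN"] == 0

    def test_sparse_spikes_are_not_bursts(self):
        r = self._raster([(7, 1, 100.0), (7, 1, 200.0), (7, 1, 299.0)])
        st = spike_stats(r, (100, 300))
        assert st["counts"]["L5_PN"] == 3
        assert st["bursts"]["L5_PN"] == 0
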