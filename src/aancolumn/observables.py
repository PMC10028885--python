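"""Forward models from simulated currents to measurable quantities.

* Primary current dipole: net longitudinal current in PN apical axes
  (positive = current toward the pia), with its laminar decomposition into
  layer-II/III and layer-V PN contributions.  This is the quantity
  compared against source-localised MEG waveforms (units nAm after the
  population scaling factor).
* Laminar LFP: extracellular potentials on a vertical multielectrode
  array via the point-source forward model phi = I / (4 pi sigma r).
* Spike rasters and burst statistics per cell class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import TrialResult
from .errors import ConfigError
from .network import CELL_CLASSES, ColumnNetwork

__all__ = [
    "DipoleTrace",
    "LFPGrid",
    "SpikeRaster",
    "ElectrodeConfig",
    "compute_dipole",
    "decompose_by_layer",
    "average_scale_smooth",
    "baseline_correct",
    "compute_lfp",
    "build_raster",
    "spike_stats",
    "BURST_WINDOW_MS",
]

BURST_WINDOW_MS = 30.0  # >= 2 spikes of one cell within this span = burst


@dataclass
class DipoleTrace:
    """Primary current dipole time series (nAm).

    ``layers`` holds the L2/3-PN and L5-PN components; their sum is the
    total at every sample.  ``scale`` is the population scaling factor
    already applied (1 for raw single-column output).
    """

    times_ms: np.ndarray
    layers_nAm: np.ndarray       # shape (2, n): [L2/3, L5]
    scale: int = 1
    smoothing_ms: float = 0.0

    @property
    def total_nAm(self) -> np.ndarray:
        return self.layers_nAm.sum(axis=0)

    @property
    def l23_nAm(self) -> np.ndarray:
        return self.layers_nAm[0]

    @property
    def l5_nAm(self) -> np.ndarray:
        return self.layers_nAm[1]

    def to_table(self) -> np.ndarray:
        """(n, 2) array of time_ms, total amplitude (plain-text export)."""
        return np.column_stack([self.times_ms, self.total_nAm])


@dataclass(frozen=True)
class ElectrodeConfig:
    """Vertical laminar probe geometry (depth along z, um)."""

    n_contacts: int = 50
    spacing_um: float = 100.0
    x_um: float = 450.0
    y_um: float = 450.0
    z_top_um: float = 1200.0
    conductivity_S_per_m: float = 0.3
    min_distance_um: float = 10.0

    @property
    def depths_um(self) -> np.ndarray:
        return self.z_top_um - self.spacing_um * np.arange(self.n_contacts)


@dataclass
class LFPGrid:
    """Laminar local field potentials, one row per electrode contact."""

    times_ms: np.ndarray
    depths_um: np.ndarray
    potentials_mV: np.ndarray    # (n_contacts, n_times)
    conductivity_S_per_m: float
    trial_seed: int


@dataclass
class SpikeRaster:
    """Spike events with class labels and per-class tallies."""

    cell_ids: np.ndarray
    cell_classes: np.ndarray     # int codes into CELL_CLASSES
    times_ms: np.ndarray

    @property
    def counts(self) -> dict:
        return {cls: int((self.cell_classes == k).sum())
                for k, cls in enumerate(CELL_CLASSES)}

    def binned_rates(self, bin_ms: float, t0: float, t1: float) -> dict:
        edges = np.arange(t0, t1 + bin_ms, bin_ms)
        out = {}
        for k, cls in enumerate(CELL_CLASSES):
            out[cls] = np.histogram(
                self.times_ms[self.cell_classes == k], edges)[0] / (bin_ms / 1e3)
        return out


def _decimate(x: np.ndarray, stride: int) -> np.ndarray:
    """Anti-aliased decimation by boxcar-averaging each stride block."""
    n = (x.shape[-1] // stride) * stride
    return x[..., :n].reshape(*x.shape[:-1], -1, stride).mean(axis=-1)


def compute_dipole(trial: TrialResult, network: ColumnNetwork,
                   target_hz: float = 500.0) -> DipoleTrace:
    """Per-trial unscaled dipole, decimated to the output sampling rate.

    The dipole is accumulated at every integration step as the sum over
    PN axial segments of (axial current x signed vertical extent); basket
    cells contribute nothing.  Decimation bin-averages full-resolution
    samples onto the coarser grid, preserving the DC component.
    """
    if trial.dipole_layers_nAm.size == 0:
        raise ConfigError("trial carries no recorded dipole")
    stride = max(1, int(round(1000.0 / target_hz / trial.dt_ms)))
    layers = _decimate(trial.dipole_layers_nAm, stride)
    n = layers.shape[1]
    times = trial.tstart_ms + (np.arange(n) + 0.5) * stride * trial.dt_ms
    return DipoleTrace(times_ms=times, layers_nAm=layers, scale=1)


def decompose_by_layer(trial: TrialResult, network: ColumnNetwork):
    """(L2/3 component, L5 component) of the per-trial dipole; they sum
    to the total by construction."""
    d = compute_dipole(trial, network)
    return d.l23_nAm, d.l5_nAm


def average_scale_smooth(traces: list, scale: int,
                         smoothing_ms: float = 30.0) -> DipoleTrace:
    """Trial average, population scaling, and Hamming-window smoothing.

    The normalised window preserves constants (DC); window length 0
    disables smoothing.  All traces must share one time grid.
    """
    if not traces:
        raise ConfigError("need at least one dipole trace")
    t0 = traces[0].times_ms
    for tr in traces[1:]:
        if tr.times_ms.shape != t0.shape or not np.allclose(tr.times_ms, t0):
            raise ConfigError("traces do not share a time grid")
    layers = np.mean([tr.layers_nAm for tr in traces], axis=0) * scale
    if smoothing_ms > 0:
        dt = float(t0[1] - t0[0]) if t0.size > 1 else 1.0
        nwin = max(1, int(round(smoothing_ms / dt)))
        if nwin > 1:
            win = np.hamming(nwin)
            win /= win.sum()
            norm = np.convolve(np.ones(t0.size), win, mode="same")
            layers = np.stack([
                np.convolve(row, win, mode="same") / norm for row in layers])
    return DipoleTrace(times_ms=t0.copy(), layers_nAm=layers, scale=scale,
                       smoothing_ms=smoothing_ms)


def baseline_correct(trace: DipoleTrace,
                     window_ms=(-50.0, 0.0)) -> DipoleTrace:
    """Subtract the mean over the pre-stimulus window from each layer."""
    m = (trace.times_ms >= window_ms[0]) & (trace.times_ms < window_ms[1])
    if not m.any():
        return trace
    layers = trace.layers_nAm - trace.layers_nAm[:, m].mean(axis=1,
                                                            keepdims=True)
    return DipoleTrace(trace.times_ms.copy(), layers, trace.scale,
                       trace.smoothing_ms)


def compute_lfp(trial: TrialResult, network: ColumnNetwork,
                electrodes: ElectrodeConfig | None = None) -> LFPGrid:
    """Extracellular potentials across cortical depth, point-source model.

    phi_e(t) = 1/(4 pi sigma) * sum_i I_i(t) / r_ei with the net
    transmembrane current I_i of every compartment (pyramidal and basket)
    treated as a point source at its centre; r is floored at
    ``min_distance_um`` to guard electrode/source coincidence.
    With I in nA, r in um and sigma in S/m the result is in mV.
    """
    if trial.membrane_currents_nA.size == 0:
        raise ConfigError("trial carries no recorded membrane currents")
    el = electrodes or ElectrodeConfig()
    f = network.fabric
    dx = f.x_um - el.x_um
    dy = f.y_um - el.y_um
    dz = f.z_um[None, :] - el.depths_um[:, None]
    r = np.sqrt(dx[None, :] ** 2 + dy[None, :] ** 2 + dz ** 2)
    np.maximum(r, el.min_distance_um, out=r)
    weights = 1.0 / (4.0 * np.pi * el.conductivity_S_per_m * r)
    phi = weights @ trial.membrane_currents_nA.T
    return LFPGrid(times_ms=trial.rec_times.copy(),
                   depths_um=el.depths_um,
                   potentials_mV=phi,
                   conductivity_S_per_m=el.conductivity_S_per_m,
                   trial_seed=trial.trial_seed)


def build_raster(trial: TrialResult) -> SpikeRaster:
    return SpikeRaster(cell_ids=trial.spike_cells.copy(),
                       cell_classes=trial.spike_classes.copy(),
                       times_ms=trial.spike_times.copy())


def spike_stats(raster: SpikeRaster, window_ms=(100.0, 300.0)) -> dict:
    """Per-class spike counts and burst tallies inside a time window.

    A burst is >=2 spikes of one cell whose consecutive intervals stay
    within ``BURST_WINDOW_MS``; each such cluster counts once.
    """
    t0, t1 = window_ms
    sel = (raster.times_ms >= t0) & (raster.times_ms <= t1)
    counts = {}
    bursts = {}
    for k, cls in enumerate(CELL_CLASSES):
        m = sel & (raster.cell_classes == k)
        counts[cls] = int(m.sum())
        nb = 0
        for cid in np.unique(raster.cell_ids[m]):
            st = np.sort(raster.times_ms[m & (raster.cell_ids == cid)])
            run = 1
            for gap in np.diff(st):
                if gap <= BURST_WINDOW_MS:
                    run += 1
                    if run == 2:
                        nb += 1
                else:
                    run = 1
        bursts[cls] = nb
    return {"counts": counts, "bursts": bursts, "window_ms": (t0, t1)}
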