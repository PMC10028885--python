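"""Voltage- and calcium-gated channel kinetics.

All compartments carry Hodgkin-Huxley-style transient sodium (``na``),
delayed-rectifier potassium (``kdr``) and leak (``leak``) conductances.
Apical compartments of layer-V pyramidal neurons additionally carry a
high-voltage-activated calcium channel (``ca_hva``), a calcium-dependent
potassium channel (``kca``) and a first-order intracellular calcium pool.
The calcium machinery is what lets a strong apical (tuft) input evoke a
plateau that drives somatic burst firing in layer V but not in layer II/III.

Units: voltage mV, time ms, conductance density S/cm^2, calcium uM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "ChannelKinetics",
    "CHANNELS",
    "gate_steady_states",
    "na_rates",
    "kdr_rates",
    "ca_hva_gate",
    "kca_open_fraction",
]

E_NA = 50.0
E_K = -90.0
E_CA = 120.0

# calcium pool defaults
CA_BASELINE_UM = 0.05     # resting free-calcium concentration, uM
CA_DECAY_TAU_MS = 40.0    # first-order removal time constant
CA_INFLUX_UM_PER_NA_MS = 0.2  # pool increment per unit inward Ca current

KCA_KD_UM = 10.0           # half-activation of the Ca-dependent K channel


def _vtrap(x: np.ndarray, y: float) -> np.ndarray:
    """x / (1 - exp(-x/y)) with the removable singularity at x=0 handled."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-6
    safe = np.where(small, 1.0, x)
    out = safe / -np.expm1(-safe / y)
    return np.where(small, y * (1.0 + x / (2.0 * y)), out)


def na_rates(v):
    """Traub-style transient-Na alpha/beta rates (am, bm, ah, bh), 1/ms."""
    v = np.asarray(v, dtype=float)
    am = 0.32 * _vtrap(v + 54.0, 4.0)
    bm = 0.28 * _vtrap(-(v + 27.0), 5.0)
    ah = 0.128 * np.exp(-(v + 50.0) / 18.0)
    bh = 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))
    return am, bm, ah, bh


def kdr_rates(v):
    """Delayed-rectifier K alpha/beta rates (an, bn), 1/ms."""
    v = np.asarray(v, dtype=float)
    an = 0.032 * _vtrap(v + 52.0, 5.0)
    bn = 0.5 * np.exp(-(v + 57.0) / 40.0)
    return an, bn


def ca_hva_gate(v):
    """High-voltage-activated Ca channel: (q_inf, tau_q ms).

    Sigmoidal steady-state activation centred at -35 mV; the channel opens
    only on strong depolarisation, giving the regenerative apical plateau.
    """
    v = np.asarray(v, dtype=float)
    q_inf = 1.0 / (1.0 + np.exp(-(v + 35.0) / 4.5))
    tau_q = np.full_like(q_inf, 5.0)
    return q_inf, tau_q


def kca_open_fraction(ca_um):
    """Instantaneous Ca-dependent K open fraction, Michaelis in [Ca]."""
    ca_um = np.asarray(ca_um, dtype=float)
    return ca_um / (ca_um + KCA_KD_UM)


@dataclass(frozen=True)
class ChannelKinetics:
    """A named conductance with its reversal potential and gating rule.

    ``gates`` maps gate names to exponents in the open-probability product;
    ``rates`` returns per-gate (alpha, beta) or (x_inf, tau) pairs.
    """

    name: str
    reversal_mV: float
    gates: dict = field(default_factory=dict)
    rates: Callable | None = None
    ca_dependent: bool = False
    decay_tau_ms: float | None = None

    def steady_gates(self, v: np.ndarray) -> dict:
        if not self.gates:
            return {}
        if self.name == "na":
            am, bm, ah, bh = na_rates(v)
            return {"m": am / (am + bm), "h": ah / (ah + bh)}
        if self.name == "kdr":
            an, bn = kdr_rates(v)
            return {"n": an / (an + bn)}
        if self.name == "ca_hva":
            q_inf, _ = ca_hva_gate(v)
            return {"q": q_inf}
        raise KeyError(self.name)


CHANNELS: dict[str, ChannelKinetics] = {
    "na": ChannelKinetics("na", E_NA, gates={"m": 3, "h": 1}, rates=na_rates),
    "kdr": ChannelKinetics("kdr", E_K, gates={"n": 4}, rates=kdr_rates),
    "leak": ChannelKinetics("leak", -65.0),
    "ca_hva": ChannelKinetics("ca_hva", E_CA, gates={"q": 2}, rates=ca_hva_gate,
                              decay_tau_ms=CA_DECAY_TAU_MS),
    "kca": ChannelKinetics("kca", E_K, ca_dependent=True),
}


def gate_steady_states(v: float) -> dict:
    """All gating variables at their steady state for voltage ``v`` (mV)."""
    va = np.asarray(v, dtype=float)
    am, bm, ah, bh = na_rates(va)
    an, bn = kdr_rates(va)
    q_inf, _ = ca_hva_gate(va)
    return {
        "m": am / (am + bm),
        "h": ah / (ah + bh),
        "n": an / (an + bn),
        "q": q_inf,
    }
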