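"""Exogenous evoked drives: the proximal/distal inputs that activate the column.

A *proximal* drive stands for feedforward (lemniscal thalamic) input: it
targets the basal and oblique dendrites of PNs in both layers and the
somata of basket cells in both layers.  A *distal* drive stands for
cortico-cortical feedback or non-lemniscal thalamic input: it targets the
apical tufts of PNs in both layers and the somata of layer-II/III basket
cells only.  Each drive delivers ``n_spikes`` input spikes to every target
synapse, with times drawn i.i.d. from Normal(mean_time, sd_time) per
synapse per trial (truncated at 0 ms); a weight of 0 uS means no synapse.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .network import ColumnNetwork
from .synapses import RECEPTORS, RECEPTOR_ORDER

__all__ = [
    "EvokedDrive",
    "DriveSynapses",
    "drive_target_map",
    "sample_drive_spikes",
    "attach_drive",
]

# compartments a drive of each kind may contact, per target class
PROXIMAL_TARGETS = {
    "L23_PN": ("basal", "oblique"),
    "L5_PN": ("basal", "oblique"),
    "L23_basket": ("soma",),
    "L5_basket": ("soma",),
}
DISTAL_TARGETS = {
    "L23_PN": ("apical_tuft",),
    "L5_PN": ("apical_tuft",),
    "L23_basket": ("soma",),
}


@dataclass(frozen=True)
class EvokedDrive:
    """One exogenous input: timing distribution, spike count, weights.

    ``weights`` maps (target cell class, receptor) -> uS applied at every
    compartment the drive kind allows on that class.
    """

    name: str
    kind: str  # "proximal" | "distal"
    mean_time_ms: float
    sd_time_ms: float
    weights: dict
    n_spikes: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("proximal", "distal"):
            raise ConfigError(f"unknown drive kind {self.kind!r}")
        if self.sd_time_ms < 0:
            raise ConfigError("sd_time must be >= 0")
        if self.n_spikes < 1:
            raise ConfigError("n_spikes must be >= 1")
        allowed = PROXIMAL_TARGETS if self.kind == "proximal" else DISTAL_TARGETS
        for (cls, rec), w in self.weights.items():
            if rec not in RECEPTORS:
                raise ConfigError(f"unknown receptor {rec!r}")
            if w < 0:
                raise ConfigError("drive weights must be >= 0")
            if cls not in allowed:
                if w > 0:
                    raise ConfigError(
                        f"{self.kind} drive may not target {cls} (weight > 0)")

    def with_timing(self, mean_time_ms=None, sd_time_ms=None) -> "EvokedDrive":
        return EvokedDrive(
            self.name, self.kind,
            self.mean_time_ms if mean_time_ms is None else float(mean_time_ms),
            self.sd_time_ms if sd_time_ms is None else float(sd_time_ms),
            dict(self.weights), self.n_spikes, self.seed)


def drive_target_map(kind: str) -> dict:
    return PROXIMAL_TARGETS if kind == "proximal" else DISTAL_TARGETS


@dataclass
class DriveSynapses:
    """A drive instantiated on a network: one row per target synapse."""

    drive: EvokedDrive
    comp_idx: np.ndarray      # flat compartment index per synapse
    receptor_idx: np.ndarray  # index into RECEPTOR_ORDER
    weight_uS: np.ndarray

    @property
    def n_synapses(self) -> int:
        return self.comp_idx.size


def attach_drive(network: ColumnNetwork, drive: EvokedDrive) -> ColumnNetwork:
    """Create the drive's synapses on exactly the mandated compartments.

    Zero-weight entries create no synapse; a distal drive with a nonzero
    layer-V basket weight is rejected at construction (see EvokedDrive).
    Returns the network with the instantiated drive appended.
    """
    allowed = drive_target_map(drive.kind)
    comp_idx, rec_idx, weights = [], [], []
    for (cls, rec), w in sorted(drive.weights.items()):
        if w <= 0 or cls not in allowed:
            continue
        for comp_name in allowed[cls]:
            idx = network.comp_indices(cls, comp_name)
            comp_idx.append(idx)
            rec_idx.append(np.full(idx.size, RECEPTOR_ORDER.index(rec),
                                   dtype=np.int8))
            weights.append(np.full(idx.size, float(w)))
    if comp_idx:
        syn = DriveSynapses(drive,
                            np.concatenate(comp_idx),
                            np.concatenate(rec_idx),
                            np.concatenate(weights))
    else:
        syn = DriveSynapses(drive, np.empty(0, dtype=np.int32),
                            np.empty(0, dtype=np.int8), np.empty(0))
    network.drives.append(syn)
    return network


def sample_drive_spikes(drive: EvokedDrive, n_targets: int,
                        trial_seed: int) -> np.ndarray:
    """Per-synapse spike times, shape (n_targets, n_spikes), ms.

    Times are i.i.d. Normal(mean_time, sd_time) per target synapse per
    trial, truncated at 0 ms; deterministic given (drive.seed, trial_seed).
    A stable digest of the drive name enters the seed so that coexisting
    drives sharing a seed still receive independent draws.
    """
    name_key = zlib.crc32(drive.name.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng([name_key,
                                 int(drive.seed) & 0x7FFFFFFF,
                                 int(trial_seed) & 0x7FFFFFFF])
    t = rng.normal(drive.mean_time_ms, drive.sd_time_ms,
                   size=(int(n_targets), int(drive.n_spikes)))
    return np.maximum(t, 0.0)
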