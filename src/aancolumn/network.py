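"""Reduced two-layer neocortical column: cells, geometry, and layout.

The column is the canonical template used to model source-localised
auditory evoked fields: two layers (II/III and V), each with a 10 x 10
grid of multicompartment pyramidal neurons (PNs) at 100 um pitch plus 35
single-compartment basket interneurons, for 200 PNs and 70 basket cells
(270 cells total).  PN apical dendrites are parallel to the vertical
(pia-directed) z axis, so their longitudinal currents sum into a net
primary current dipole, the quantity compared with source-localised MEG.

Only the relative apical extent and orientation of the two PN classes
matter qualitatively for the dipole; layer-V PNs are roughly three times
longer than layer-II/III PNs and carry the apical calcium machinery that
supports burst firing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .channels import CHANNELS, CA_BASELINE_UM, gate_steady_states, kca_open_fraction
from .errors import ConfigError

__all__ = [
    "CompartmentSpec",
    "CellSpec",
    "CellState",
    "ColumnNetwork",
    "default_cell_specs",
    "build_cell",
    "build_default_column",
    "steady_state_check",
    "CELL_CLASSES",
    "COMP_NAMES",
    "PN_CLASSES",
    "BASKET_CLASSES",
]

CELL_CLASSES = ("L23_PN", "L5_PN", "L23_basket", "L5_basket")
PN_CLASSES = ("L23_PN", "L5_PN")
BASKET_CLASSES = ("L23_basket", "L5_basket")
COMP_NAMES = ("basal", "oblique", "soma", "apical_trunk", "apical_tuft")

AXIAL_RESISTIVITY_OHM_CM = 150.0
MEMBRANE_CAP_UF_CM2 = 1.0

# soma depth of each layer on the absolute z axis (um; pia is near z ~ +1000)
LAYER_SOMA_Z = {"L23": 700.0, "L5": 0.0}
GRID_PITCH_UM = 100.0
GRID_SHAPE = (10, 10)
N_BASKETS_PER_LAYER = 35


@dataclass(frozen=True)
class CompartmentSpec:
    """One cylindrical compartment of a cell.

    ``z_offset`` is the compartment centre along the vertical axis relative
    to the soma (positive = toward the pia).  ``channels`` maps channel
    labels to peak conductance densities in S/cm^2.
    """

    name: str
    length_um: float
    diameter_um: float
    z_offset_um: float
    channels: dict
    parent: str | None = None

    def __post_init__(self):
        if self.name not in COMP_NAMES:
            raise ConfigError(f"unknown compartment name {self.name!r}")
        if self.length_um <= 0 or self.diameter_um <= 0:
            raise ConfigError(f"{self.name}: length and diameter must be > 0")
        if self.name in ("apical_trunk", "apical_tuft") and self.z_offset_um <= 0:
            raise ConfigError(f"{self.name}: apical compartments need z_offset > 0")
        if self.name == "basal" and self.z_offset_um >= 0:
            raise ConfigError("basal compartment needs z_offset < 0")
        for label in self.channels:
            if label not in CHANNELS:
                raise ConfigError(f"unknown channel label {label!r}")

    @property
    def area_um2(self) -> float:
        return math.pi * self.diameter_um * self.length_um

    @property
    def capacitance_nF(self) -> float:
        # 1 uF/cm^2 = 1e-5 nF/um^2
        return MEMBRANE_CAP_UF_CM2 * self.area_um2 * 1e-5

    def conductance_uS(self, label: str) -> float:
        # 1 S/cm^2 over 1 um^2 = 1e-2 uS
        return self.channels.get(label, 0.0) * self.area_um2 * 1e-2


@dataclass(frozen=True)
class CellSpec:
    """A cell class: ordered compartments plus spike/rest conventions."""

    cell_class: str
    compartments: tuple
    spike_threshold_mV: float = 0.0
    resting_potential_mV: float = -65.0

    def __post_init__(self):
        if self.cell_class not in CELL_CLASSES:
            raise ConfigError(f"unknown cell class {self.cell_class!r}")
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate compartment names")
        if self.cell_class in PN_CLASSES:
            if len(self.compartments) < 4 or "apical_tuft" not in names:
                raise ConfigError("PN classes need >=4 compartments incl. apical_tuft")
        else:
            if names != ["soma"]:
                raise ConfigError("basket classes have exactly one soma compartment")

    @property
    def apical_extent_um(self) -> float:
        ext = 0.0
        for c in self.compartments:
            if c.name.startswith("apical"):
                ext = max(ext, c.z_offset_um + c.length_um / 2.0)
        return ext

    def compartment(self, name: str) -> CompartmentSpec:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)


_DEND = {"na": 0.004, "kdr": 0.01, "leak": 1.3e-4}
# L2/3 apical dendrites carry a denser delayed rectifier: they repolarise
# after a single backpropagating spike instead of supporting the sustained
# plateau the layer-V calcium machinery provides
_L23_APICAL = {"na": 0.004, "kdr": 0.1, "leak": 1.3e-4}
_SOMA_PN = {"na": 0.20, "kdr": 0.08, "leak": 1.3e-4}
_SOMA_BASKET = {"na": 0.25, "kdr": 0.10, "leak": 5e-4}
# layer-V apical compartments: HVA Ca + Ca-dependent K on top of the
# dendritic Na/K/leak set; these densities set the burst propensity
_L5_APICAL = {"na": 0.004, "kdr": 0.02, "leak": 1.3e-4, "ca_hva": 0.008, "kca": 0.0015}


def default_cell_specs() -> dict:
    """Documented default morphologies and channel densities per class."""
    l23 = CellSpec(
        "L23_PN",
        (
            CompartmentSpec("basal", 150, 2.5, -100, dict(_DEND), parent="soma"),
            CompartmentSpec("oblique", 150, 2.0, -10, dict(_DEND), parent="soma"),
            CompartmentSpec("soma", 20, 20, 0.0, dict(_SOMA_PN)),
            CompartmentSpec("apical_trunk", 150, 5.0, 85, dict(_L23_APICAL), parent="soma"),
            CompartmentSpec("apical_tuft", 150, 3.0, 235, dict(_L23_APICAL),
                            parent="apical_trunk"),
        ),
    )
    l5 = CellSpec(
        "L5_PN",
        (
            CompartmentSpec("basal", 200, 3.0, -125, dict(_DEND), parent="soma"),
            CompartmentSpec("oblique", 200, 2.0, -10, dict(_DEND), parent="soma"),
            CompartmentSpec("soma", 25, 25, 0.0, dict(_SOMA_PN)),
            CompartmentSpec("apical_trunk", 600, 4.0, 312, dict(_L5_APICAL),
                            parent="soma"),
            CompartmentSpec("apical_tuft", 400, 3.0, 812, dict(_L5_APICAL),
                            parent="apical_trunk"),
        ),
    )
    l23b = CellSpec(
        "L23_basket",
        (CompartmentSpec("soma", 18, 18, 0.0, dict(_SOMA_BASKET)),),
    )
    l5b = CellSpec(
        "L5_basket",
        (CompartmentSpec("soma", 18, 18, 0.0, dict(_SOMA_BASKET)),),
    )
    specs = {s.cell_class: s for s in (l23, l5, l23b, l5b)}
    _validate_specs(specs)
    return specs


def _validate_specs(specs: dict) -> None:
    if specs["L5_PN"].apical_extent_um <= specs["L23_PN"].apical_extent_um:
        raise ConfigError("L5 PN apical extent must exceed L2/3 PN apical extent")
    for name in ("apical_trunk", "apical_tuft"):
        comp = specs["L5_PN"].compartment(name)
        if "ca_hva" not in comp.channels or "kca" not in comp.channels:
            raise ConfigError("L5 PN apical compartments must carry Ca and KCa")


@dataclass
class CellState:
    """Per-cell dynamic state at construction (rest, steady gates)."""

    cell_class: str
    voltages_mV: np.ndarray
    gates: dict
    calcium_uM: np.ndarray


def build_cell(spec: CellSpec) -> CellState:
    """Initialise a cell: all voltages at rest, gates at steady state,
    calcium pool at baseline concentration."""
    n = len(spec.compartments)
    v = np.full(n, spec.resting_potential_mV)
    ss = gate_steady_states(spec.resting_potential_mV)
    gates = {k: np.full(n, float(val)) for k, val in ss.items()}
    return CellState(spec.cell_class, v, gates, np.full(n, CA_BASELINE_UM))


# ---------------------------------------------------------------------------
# flattened column fabric used by the integrator


@dataclass
class ColumnFabric:
    """Flat per-compartment arrays for the whole column."""

    n_comp: int
    cell_id: np.ndarray          # int, per compartment
    cell_class: np.ndarray       # int code into CELL_CLASSES
    comp_name: np.ndarray        # int code into COMP_NAMES
    x_um: np.ndarray
    y_um: np.ndarray
    z_um: np.ndarray             # absolute compartment-centre depth
    cap_nF: np.ndarray
    v_rest: np.ndarray
    g_chan: dict                 # label -> uS per compartment
    e_leak: np.ndarray           # balanced leak reversal per compartment
    conn_a: np.ndarray           # axial connections (compartment indices)
    conn_b: np.ndarray
    conn_g: np.ndarray           # uS
    conn_dz: np.ndarray          # z_b - z_a, um
    conn_class: np.ndarray       # cell class code of the owning cell
    soma_idx: np.ndarray         # per cell, compartment index of its soma
    cell_class_by_cell: np.ndarray
    spike_threshold: np.ndarray  # per cell, mV


def _axial_g_uS(parent: CompartmentSpec, child: CompartmentSpec) -> float:
    ra = AXIAL_RESISTIVITY_OHM_CM * 1e4  # ohm*um
    r = 0.0
    for c in (parent, child):
        area = math.pi * (c.diameter_um / 2.0) ** 2
        r += ra * (c.length_um / 2.0) / area
    return 1e6 / r  # ohm -> uS


def _balanced_leak_reversal(comp: CompartmentSpec, v_rest: float) -> float:
    """Leak reversal that zeroes net channel current at rest.

    Guarantees the unstimulated column is an exact fixed point, so the
    quiescent network neither drifts nor fires.
    """
    g_leak = comp.conductance_uS("leak")
    if g_leak <= 0:
        raise ConfigError(f"{comp.name}: leak conductance required")
    ss = gate_steady_states(v_rest)
    i_other = 0.0
    for label, dens in comp.channels.items():
        if label == "leak" or dens == 0.0:
            continue
        kin = CHANNELS[label]
        g = comp.conductance_uS(label)
        if kin.ca_dependent:
            g *= float(kca_open_fraction(CA_BASELINE_UM))
        else:
            for gate, power in kin.gates.items():
                g *= float(ss[gate]) ** power
        i_other += g * (v_rest - kin.reversal_mV)
    return v_rest + i_other / g_leak


@dataclass
class ColumnNetwork:
    """The instantiated column: cell table plus flattened fabric arrays."""

    specs: dict
    cells: list                      # (cell_id, cell_class, x, y, z_soma)
    counts: dict
    grid_shape: tuple
    rng_seed: int
    scale: int
    fabric: ColumnFabric
    connectivity: object = None      # LocalConnectivity, set by attach
    drives: list = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def class_cell_ids(self, cell_class: str) -> np.ndarray:
        code = CELL_CLASSES.index(cell_class)
        return np.nonzero(self.fabric.cell_class_by_cell == code)[0]

    def comp_indices(self, cell_class: str, comp_name: str) -> np.ndarray:
        """Flat compartment indices for (class, compartment)."""
        ccode = CELL_CLASSES.index(cell_class)
        ncode = COMP_NAMES.index(comp_name)
        f = self.fabric
        return np.nonzero((f.cell_class == ccode) & (f.comp_name == ncode))[0]

    def describe(self) -> dict:
        """Counts and geometry summary (JSON-serialisable)."""
        return {
            "n_cells": self.n_cells,
            "counts": dict(self.counts),
            "n_pyramidal": self.counts["L23_PN"] + self.counts["L5_PN"],
            "grid_shape": list(self.grid_shape),
            "grid_pitch_um": GRID_PITCH_UM,
            "scale": self.scale,
            "apical_extent_um": {
                c: self.specs[c].apical_extent_um for c in PN_CLASSES
            },
            "n_compartments": int(self.fabric.n_comp),
        }


def _basket_sites() -> list:
    """35 deterministic, evenly spread grid sites for basket cells."""
    idx = np.round(np.linspace(0, GRID_SHAPE[0] * GRID_SHAPE[1] - 1,
                               N_BASKETS_PER_LAYER)).astype(int)
    return [(int(i // GRID_SHAPE[1]), int(i % GRID_SHAPE[1])) for i in idx]


def build_default_column(seed: int = 0, scale: int = 300,
                         specs: dict | None = None,
                         leak_shift_mV: float = 0.0) -> ColumnNetwork:
    """Construct the default 270-cell column.

    ``scale`` multiplies the dipole output only (it instantiates no extra
    cells); it is the factor relating the 200 simulated PNs to the tens of
    thousands of synchronously active PNs behind a measurable evoked field.
    ``leak_shift_mV`` displaces every leak reversal from its balanced value
    (useful to exercise the quiescence diagnostic).
    Construction geometry is deterministic and seed-independent; the seed
    is stored for downstream stochastic stages.
    """
    if not isinstance(scale, (int, np.integer)) or isinstance(scale, bool):
        raise ConfigError("scale must be an integer")
    if scale < 1:
        raise ConfigError("scale must be >= 1")
    specs = specs or default_cell_specs()
    _validate_specs(specs)

    cells = []  # (cell_id, cell_class, x, y, z_soma)
    cid = 0
    for layer, pn_class in (("L23", "L23_PN"), ("L5", "L5_PN")):
        z = LAYER_SOMA_Z[layer]
        for gx in range(GRID_SHAPE[0]):
            for gy in range(GRID_SHAPE[1]):
                cells.append((cid, pn_class, gx * GRID_PITCH_UM,
                              gy * GRID_PITCH_UM, z))
                cid += 1
    for layer, bk_class in (("L23", "L23_basket"), ("L5", "L5_basket")):
        z = LAYER_SOMA_Z[layer]
        for gx, gy in _basket_sites():
            cells.append((cid, bk_class,
                          gx * GRID_PITCH_UM + GRID_PITCH_UM / 2,
                          gy * GRID_PITCH_UM + GRID_PITCH_UM / 2, z))
            cid += 1

    counts = {c: sum(1 for _, cc, *_ in cells if cc == c) for c in CELL_CLASSES}

    # --- flatten
    cols = {k: [] for k in ("cell_id", "cell_class", "comp_name", "x", "y", "z",
                            "cap", "vrest", "eleak", "thresh")}
    g_chan = {label: [] for label in CHANNELS}
    conn_a, conn_b, conn_g, conn_dz, conn_class = [], [], [], [], []
    soma_idx, class_by_cell, thresh_by_cell = [], [], []

    comp_offset = 0
    for cell_id, cell_class, x, y, z_soma in cells:
        spec = specs[cell_class]
        local = {c.name: comp_offset + k for k, c in enumerate(spec.compartments)}
        ccode = CELL_CLASSES.index(cell_class)
        for c in spec.compartments:
            cols["cell_id"].append(cell_id)
            cols["cell_class"].append(ccode)
            cols["comp_name"].append(COMP_NAMES.index(c.name))
            cols["x"].append(x)
            cols["y"].append(y)
            cols["z"].append(z_soma + c.z_offset_um)
            cols["cap"].append(c.capacitance_nF)
            cols["vrest"].append(spec.resting_potential_mV)
            cols["eleak"].append(
                _balanced_leak_reversal(c, spec.resting_potential_mV)
                + leak_shift_mV)
            for label in CHANNELS:
                g_chan[label].append(c.conductance_uS(label))
            if c.parent is not None:
                a = local[c.parent]
                b = local[c.name]
                conn_a.append(a)
                conn_b.append(b)
                conn_g.append(_axial_g_uS(spec.compartment(c.parent), c))
                conn_dz.append(c.z_offset_um
                               - spec.compartment(c.parent).z_offset_um)
                conn_class.append(ccode)
        soma_idx.append(local["soma"])
        class_by_cell.append(ccode)
        thresh_by_cell.append(spec.spike_threshold_mV)
        comp_offset += len(spec.compartments)

    fabric = ColumnFabric(
        n_comp=comp_offset,
        cell_id=np.asarray(cols["cell_id"], dtype=np.int32),
        cell_class=np.asarray(cols["cell_class"], dtype=np.int8),
        comp_name=np.asarray(cols["comp_name"], dtype=np.int8),
        x_um=np.asarray(cols["x"]),
        y_um=np.asarray(cols["y"]),
        z_um=np.asarray(cols["z"]),
        cap_nF=np.asarray(cols["cap"]),
        v_rest=np.asarray(cols["vrest"]),
        g_chan={label: np.asarray(vals) for label, vals in g_chan.items()},
        e_leak=np.asarray(cols["eleak"]),
        conn_a=np.asarray(conn_a, dtype=np.int32),
        conn_b=np.asarray(conn_b, dtype=np.int32),
        conn_g=np.asarray(conn_g),
        conn_dz=np.asarray(conn_dz),
        conn_class=np.asarray(conn_class, dtype=np.int8),
        soma_idx=np.asarray(soma_idx, dtype=np.int32),
        cell_class_by_cell=np.asarray(class_by_cell, dtype=np.int8),
        spike_threshold=np.asarray(thresh_by_cell),
    )
    return ColumnNetwork(specs=specs, cells=cells, counts=counts,
                         grid_shape=GRID_SHAPE, rng_seed=int(seed),
                         scale=int(scale), fabric=fabric)


def steady_state_check(network: ColumnNetwork, duration_ms: float) -> float:
    """Maximum absolute voltage drift (mV) of the unstimulated column.

    Simulates ``duration_ms`` with no drives attached and returns the
    largest deviation of any compartment from its resting potential.
    """
    if duration_ms <= 0:
        return 0.0
    from .engine import SimulationConfig, integrate

    cfg = SimulationConfig(tstart_ms=0.0, duration_ms=duration_ms,
                           n_trials=1, base_seed=network.rng_seed,
                           record_drift=True)
    res = integrate(network, [], cfg, trial_seed=network.rng_seed)
    return float(res.max_drift_mV)
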