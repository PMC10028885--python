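"""Structured-text (YAML) configuration: schema, defaults, round trip.

The canonical config describes the whole study setup: the column (cell
classes, counts, compartment geometry, channel densities), the local
connectivity, the receptor kinetics, the evoked-drive sets of every model
variant, and the simulation/synthetic-target settings.  The shipped
``data/default_config.yaml`` is generated from the package defaults and
is the reference parameter record.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .drives import EvokedDrive
from .engine import SimulationConfig
from .errors import ConfigError
from .fitting import ModelVariant, VARIANT_NAMES, build_variant
from .network import default_cell_specs
from .synapses import RECEPTORS, default_connectivity
from .synthetic import ERFComponentSet

__all__ = ["default_config_dict", "load_config", "dump_config",
           "drives_from_config", "variant_from_config",
           "simulation_config_from_config", "read_default_config"]


def _drive_to_dict(d: EvokedDrive) -> dict:
    return {
        "name": d.name,
        "kind": d.kind,
        "mean_time_ms": d.mean_time_ms,
        "sd_time_ms": d.sd_time_ms,
        "n_spikes": d.n_spikes,
        "seed": d.seed,
        "weights": {f"{cls}:{rec}": w for (cls, rec), w in
                    sorted(d.weights.items())},
    }


def _drive_from_dict(d: dict) -> EvokedDrive:
    weights = {}
    for key, w in d.get("weights", {}).items():
        cls, _, rec = key.partition(":")
        if not rec:
            raise ConfigError(f"bad weight key {key!r} (want 'class:receptor')")
        weights[(cls, rec)] = float(w)
    return EvokedDrive(d["name"], d["kind"], float(d["mean_time_ms"]),
                       float(d["sd_time_ms"]), weights,
                       n_spikes=int(d.get("n_spikes", 1)),
                       seed=int(d.get("seed", 0)))


def default_config_dict() -> dict:
    """The package defaults as one plain dictionary."""
    specs = default_cell_specs()
    network = {
        "counts": {"L23_PN": 100, "L5_PN": 100,
                   "L23_basket": 35, "L5_basket": 35},
        "scale": 300,
        "grid": {"shape": [10, 10], "pitch_um": 100.0},
        "cells": {},
    }
    for cls, spec in specs.items():
        network["cells"][cls] = {
            "resting_potential_mV": spec.resting_potential_mV,
            "spike_threshold_mV": spec.spike_threshold_mV,
            "compartments": [
                {"name": c.name, "length_um": c.length_um,
                 "diameter_um": c.diameter_um, "z_offset_um": c.z_offset_um,
                 "channels_S_per_cm2": dict(c.channels)}
                for c in spec.compartments],
        }
    receptors = {name: {"rise_ms": r.rise_ms, "decay_ms": r.decay_ms,
                        "reversal_mV": r.reversal_mV,
                        "voltage_dependent": r.voltage_dependent}
                 for name, r in RECEPTORS.items()}
    connectivity = [
        {"source": c.source, "target": c.target,
         "target_comp": c.target_comp, "receptor": c.receptor,
         "weight_uS": c.weight_uS, "delay_ms": c.delay_ms,
         "space_constant_um": c.space_constant_um}
        for c in default_connectivity().connections]
    variants = {}
    for name in VARIANT_NAMES:
        v = build_variant(name)
        variants[name] = {
            "perisomatic_factor": v.perisomatic_factor,
            "drives": {cond: [_drive_to_dict(d) for d in ds]
                       for cond, ds in v.drives.items()},
            "frozen": {cond: list(fl) for cond, fl in v.frozen.items()},
        }
    sim = SimulationConfig()
    synth = ERFComponentSet()
    return {
        "network": network,
        "receptors": receptors,
        "connectivity": connectivity,
        "variants": variants,
        "simulation": {
            "dt_ms": sim.dt_ms, "duration_ms": sim.duration_ms,
            "tstart_ms": sim.tstart_ms, "n_trials": sim.n_trials,
            "base_seed": sim.base_seed, "record_dt_ms": sim.record_dt_ms,
        },
        "synthetic_targets": {
            "components": [
                {"label": c.label, "peak_ms": c.peak_ms,
                 "width_ms": c.width_ms, "amplitude_nAm": c.amplitude_nAm}
                for c in (synth.p1, synth.n1, synth.aan)],
            "noise_nAm": synth.noise_nAm,
            "sampling_hz": synth.sampling_hz,
            "band_hz": list(synth.band_hz),
            "seed": synth.seed,
        },
    }


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("network", "variants", "simulation"):
        if key not in cfg:
            raise ConfigError(f"config missing section {key!r}")
    return cfg


def read_default_config() -> dict:
    """The shipped canonical YAML config."""
    text = (resources.files("aancolumn") / "data"
            / "default_config.yaml").read_text()
    return yaml.safe_load(text)


def drives_from_config(cfg: dict, variant: str, condition: str) -> list:
    vd = cfg["variants"][variant]
    return [_drive_from_dict(d) for d in vd["drives"][condition]]


def variant_from_config(cfg: dict, name: str) -> ModelVariant:
    vd = cfg["variants"][name]
    return ModelVariant(
        name=name,
        drives={cond: [_drive_from_dict(d) for d in ds]
                for cond, ds in vd["drives"].items()},
        frozen={cond: tuple(bool(x) for x in fl)
                for cond, fl in vd["frozen"].items()},
        perisomatic_factor=float(vd.get("perisomatic_factor", 1.0)),
        scale=int(cfg["network"].get("scale", 300)),
    )


def simulation_config_from_config(cfg: dict, **overrides) -> SimulationConfig:
    s = dict(cfg["simulation"])
    s.update(overrides)
    return SimulationConfig(**s)
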