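# aancolumn

A reduced biophysical model of a human auditory-cortex column for
studying the **auditory awareness negativity (AAN)** — the extra
negativity at ~100–300 ms in the source-localised evoked response to
target tones that listeners consciously detect, absent when the same
tones are missed.  The package is for computational and cognitive
neuroscientists who want a laminar, cell-resolved account of an M/EEG
evoked component: it simulates the primary current dipole, the laminar
local field potential, and the spiking of a two-layer column of
pyramidal (PN) and basket neurons, drives it with sequences of evoked
inputs, and fits those inputs to target waveforms by RMSE.

## The model in brief

The column has 100 PNs and 35 basket cells per layer (II/III and V; 270
cells).  It is activated by two kinds of exogenous drive:

* **proximal** — feedforward (lemniscal thalamic) input to PN
  basal/oblique dendrites and basket somata in both layers; net
  excitation drives current *up* the apical dendrites (positive dipole);
* **distal** — cortico-cortical feedback or non-lemniscal thalamic input
  to PN apical tufts (both layers) and layer-II/III basket somata; net
  excitation drives current *down* (negative dipole).

The simulated dipole is

```
p(t) = Σ_segments  I_axial(t) · Δz ,
```

summed over PN apical-axis segments, scaled by a population factor of
300 (200 PNs ↦ 60,000 contributing cells) and decomposed into layer-II/III
and layer-V components.  The *preferred* model drives the column with a
proximal input at 47.8 ± 13.2 ms and a distal input at 84.3 ± 15.1 ms
(undetected condition: P1 then a small N1); the detected condition adds
one broad distal input at 169.3 ± 50.4 ms whose interaction with the
earlier inputs yields a sustained negativity peaking near 180–200 ms —
the AAN — together with calcium-dependent burst firing of layer-V PNs.
Three alternatives (doubled layer-V perisomatic GABA_B, a reduced input
sequence, and a proximal–distal–proximal sequence) are implemented for
comparison.  See `docs/methods.md` for assumptions, parameters and
calibration.

## Worked example

```python
from aancolumn import SimulationConfig, generate_targets, rmse
from aancolumn.fitting import build_variant, simulate_condition, difference_waveform
from aancolumn.observables import build_raster, spike_stats

und_t, det_t = generate_targets()                  # synthetic "empirical" waveforms
cfg = SimulationConfig(n_trials=10, base_seed=42)  # ten trials, like the study

v = build_variant("preferred")
und = simulate_condition(v, "undetected", cfg)
det, trials, _ = simulate_condition(v, "detected", cfg, return_trials=True)

print(f"RMSE undetected: {rmse(und, und_t):.2f} nAm")
print(f"RMSE detected:   {rmse(det, det_t):.2f} nAm")
diff = difference_waveform(det, und)
i = diff.amplitude_nAm.argmin()
print(f"AAN peak: {diff.amplitude_nAm[i]:.2f} nAm at {diff.times_ms[i]:.0f} ms")
l5 = sum(spike_stats(build_raster(t))['counts']['L5_PN'] for t in trials)
print(f"L5 PN spikes in 100-300 ms over 10 detected trials: {l5}")
```

prints

```
RMSE undetected: 0.07 nAm
RMSE detected:   0.17 nAm
AAN peak: -0.49 nAm at 191 ms
L5 PN spikes in 100-300 ms over 10 detected trials: 1204
```

The RMSEs say the calibrated model reproduces the synthetic targets to
within a fifth of a nAm; the difference waveform peaks where the AAN should
(~180–200 ms); and the detected condition shows the strong layer-V
spiking (absent in the undetected condition and in the
perisomatic-inhibition variant) that the circuit account predicts.

A thin CLI wraps the same pipeline: `aancolumn describe`, `aancolumn
synth`, `aancolumn simulate`, `aancolumn fit`, `aancolumn compare`,
`aancolumn dump-config`.  The canonical parameter record is the shipped
YAML config (`src/aancolumn/data/default_config.yaml`).

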