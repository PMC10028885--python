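# Methods

## The model and what it is for

`aancolumn` implements a reduced biophysical model of a single cortical
column in human auditory cortex, built to explain the *auditory awareness
negativity* (AAN): the extra negativity between roughly 100 and 300 ms in
the source-localised evoked response to target tones that listeners
consciously detect, absent when the same tones are missed.  The model's
central claim is circuit-level: the undetected response (a P1 positivity
near 50 ms and a small N1 negativity near 100 ms) is produced by a
proximal (feedforward) input followed by a distal (feedback) input, and
the AAN is produced by one additional, temporally broad distal input to
the apical dendrites whose interaction with the earlier inputs drives
current down the dendrites of layer-V pyramidal neurons (PNs) and makes
them fire calcium-dependent bursts.

### Column architecture

Two layers (II/III and V), each a 10 x 10 grid of multicompartment PNs at
100 um pitch plus 35 single-compartment basket interneurons, for 270
cells (200 PNs).  PN morphology is five cylinders: basal, oblique, soma,
apical trunk, apical tuft; apical axes are parallel to the vertical z
axis.  Compartment geometry is not constrained by any published table, so
the defaults are chosen for the two properties that matter for the
dipole: the layer-V apical extent (~1010 um) is roughly three times the
layer-II/III extent (~310 um), and both tufts end near the pia.  The
`scale` factor (default 300) multiplies the dipole output only - it
stands for the ~60,000 synchronously active PNs behind a measurable
evoked field - and instantiates no extra cells.

### Membrane and channels

All compartments carry transient Na, delayed-rectifier K (Traub-style
rate functions) and leak.  The leak reversal is balanced per compartment
so the quiescent column is an exact fixed point; this makes resting-drift
checks sharp (a deliberate imbalance is exposed as `leak_shift_mV` for
diagnostics).  Soma Na is dense (0.2 S/cm^2); dendritic Na is sparse
(0.004 S/cm^2) - enough for backpropagation, too little for dendritic
initiation.  Layer-II/III apical dendrites carry a dense delayed
rectifier (0.1 S/cm^2) so a tuft input yields at most a single somatic
spike.  Layer-V apical compartments additionally carry a high-voltage-
activated Ca channel (half-activation -35 mV), a Ca-dependent K channel
(half-activation 10 uM), and a first-order Ca pool (decay 40 ms) whose
influx is pump-balanced at rest.  These parameters were tuned once, as a
set, to a single target behaviour: a strong tuft conductance event drives
a 2-3 spike somatic burst in a layer-V PN that terminates and relaxes
back to rest, while the same event gives at most one spike in a
layer-II/III PN.  This is the apical-amplification asymmetry the AAN
mechanism requires.

### Synapses and connectivity

Receptors are normalised double exponentials: AMPA 0.5/5 ms, NMDA 1/20 ms
(with the standard sigmoidal magnesium block), GABA_A 0.5/5 ms at -80 mV,
GABA_B 6/20 ms at -95 mV.  The GABA_B constants are faster than the
metabotropic receptor's literature values; they were shortened during
calibration because the slow somatic clamp otherwise delays and smears
the late negativity far past the ~180 ms the difference waveform should
peak at.  What the model needs from GABA_B is inhibition that is slower
and more prolonged than GABA_A (which still holds by a factor of four in
decay) and strong enough at the printed 0.025 uS layer-V perisomatic
weight to silence layer-V PNs when doubled.

Local wiring is fixed by class and all-to-all between PNs, with per-pair
weights attenuated as exp(-(d/lambda)^2) in horizontal somatic distance
(lambda 150 um for excitation, 70 um for basket outputs, so the printed
per-connection conductances act at full strength only between
neighbours).  The layer-II/III PN -> layer-V basket projection is absent
(weight 0): with it, any strong layer-II/III volley recruited layer-V
somatic inhibition and produced an N1-shaped rebound even for a
proximal-only drive sequence, erasing the qualitative difference between
the preferred and reduced models.  With it removed, the N1 is genuinely
distal-driven, and a proximal-only model produces a P1 that decays
without an N1 - the behaviour that makes the reduced model identifiably
worse.

### Drives

An evoked drive delivers `n_spikes` input spikes to every target synapse,
times drawn i.i.d. Normal(mean, sd) per synapse per trial (truncated at
0 ms).  Proximal drives contact PN basal and oblique dendrites in both
layers plus both basket populations' somata; distal drives contact PN
apical tufts in both layers plus layer-II/III basket somata only.  Drive
timing means and spreads are the published per-variant values; the
synaptic weight sets are this package's calibration (see below).

### Integration

Fixed-step (default 25 us), with gating advanced by exponential Euler
through 0.025-mV lookup tables, and a semi-implicit exponential-Euler
membrane update followed by a midpoint corrector that re-evaluates the
voltage-dependent terms (NMDA block, axial sources) at the predicted
voltage.  The corrector matters: without it the interspike interval at
25 us runs ~5% long and single-neuron spike counts disagree with a
10x-finer reference; with it they match.  Spike detection is an upward
somatic crossing of 0 mV with a 3 ms refractory lockout.  A numba-fused
kernel and a plain-numpy path implement identical semantics; the numpy
path is the reference, serves the full current-bookkeeping mode, and the
two are held together by an equivalence test.  Trials use seeds
`base_seed + k`; every random draw descends from explicit seeds, so runs
are bit-reproducible.

### Observables

The primary current dipole is accumulated every step as the sum over PN
axial segments of (axial current x signed vertical extent), positive for
current toward the pia; basket cells contribute nothing.  Its laminar
decomposition restricts the sum to each PN class, and the two components
sum to the total by construction.  Averaged dipoles are scaled by the
population factor, smoothed with a normalised 30-ms Hamming window
(DC-preserving), and baseline-corrected over -50..0 ms.  The laminar LFP
uses the point-source forward model phi = I/(4 pi sigma r) with sigma =
0.3 S/m, all transmembrane currents (pyramidal and basket) included, on a
50-contact vertical array at 100-um spacing through the column's centre;
distances are floored at 10 um.  Bursts are >= 2 spikes of one cell with
consecutive gaps <= 30 ms.

### Fitting and model comparison

Fits minimise the RMSE (nAm) between the trial-averaged simulated dipole
and a target waveform over 0..450 ms.  The optimiser is a seeded,
derivative-free sequential strategy: free drives are tuned one at a time
(earliest first), each over its share of a fixed evaluation budget, with
bounded scalar search on the drive mean (optionally Nelder-Mead on
mean+spread).  Frozen drives pass through bit-identical, mirroring the
staged protocol in which the undetected-condition inputs are held fixed
while the detected condition's extra input is fitted.  Objective
evaluations run 3 trials at a 50-us step for speed; reported fits are
re-simulated at the production settings.  Self-consistency (parameter
recovery) uses matched settings for target and evaluations - common
random numbers - so the objective vanishes at the truth.

Four variants are shipped: `preferred` (proximal 47.8 +/- 13.2, distal
84.3 +/- 15.1; detected adds distal 169.3 +/- 50.4), the `perisomatic_inhibition`
circuit (layer-V somatic GABA_B doubled 0.025 -> 0.05 uS; proximal 36 +/-
25, distal 84.3 +/- 15.1; detected adds a proximal 169.3 +/- 50.4 input
with weak excitatory and strong inhibitory weights), `reduced` (single
proximal 47.8 +/- 13.3; detected adds distal 154 +/- 55.1), and
`prox_dist_prox` (reduced plus proximal 395.4 +/- 20).  The comparison
report evaluates all variants on the same targets and seeds and tallies
per-condition RMSE, layer-V spikes and bursts in 100-300 ms, and two
qualitative flags: *early-N1 captured* (the undetected trace dips below
-10% of its own peak-to-peak range within 80-130 ms) and *AAN captured*
(the detected-minus-undetected difference over 100-300 ms has a negative
mean with >= 60% of samples below zero).

### Calibration

No published table fixes the synaptic weights, so they are this package's
own calibration, performed once against the shipped synthetic targets and
committed as defaults (in `fitting.py` and the canonical YAML config):
the proximal drive excites layer II/III much more strongly than layer V
(0.016 vs 0.0004 uS AMPA), the first distal input is moderate (layer-V
tuft 0.002 uS AMPA, below the single-event burst threshold of ~0.006 uS),
and the second distal input is strong enough (0.0065 uS AMPA + NMDA) to
trigger layer-V bursts.  With these defaults the 10-trial column
produces: P1 ~ +2.4 nAm, N1 ~ -0.5 nAm, a detected-minus-undetected
difference peaking near 190-200 ms at ~ -0.5 nAm with support from ~60 to
~400 ms, layer-V PN spike counts of >= 100 per detected trial versus <= 1
per undetected trial, and zero layer-V spikes under the perisomatic
variant.  These are the regression-tested study conditions.

## The synthetic targets

Grand-average source waveforms for this paradigm are not publicly
deposited, so the targets are synthetic stand-ins: Gaussian components
(P1 +2.3 nAm at 52 ms, sigma 14; N1 -0.55 nAm at 105 ms, sigma 22; AAN
-0.5 nAm at 180 ms, sigma 65, support ~60-360 ms) on the empirical
conventions (500 Hz, -50..450 ms epoch), plus band-limited Gaussian noise
(0.15-15 Hz, zero-phase).  The band-pass is applied to the noise term
only - the component sum is already band-limited, and filtering it on a
250-sample epoch would break the exact component-recovery round trip.
Component amplitudes follow the calibrated model's scale (single-digit
nAm).  What passing tests against these targets shows is that the
pipeline is self-consistent and that the circuit mechanisms separate the
variants qualitatively; it does not validate the model against real MEG
data, and the published empirical RMSE values are out of reach by
construction.  The oddball generator reproduces the paradigm geometry
(ten 100-ms tones per 5-s sequence at 500-ms onset asynchrony, one
deviant at a uniform position) and a synthetic button press; the binning
rule counts the two *standard* tones immediately preceding the press as
detected (the deviant is excluded from modelling and from the
"two preceding" count - an interpretation, documented here).

## Numerical choices and degenerate inputs

Drive spike times are rounded to the integration grid; events before the
epoch start or after its end are dropped.  sd = 0 drives are exact
(degenerate Gaussian), and zero-weight entries create no synapse.
Voltage blow-up (|V| > 200 mV) aborts with a diagnostic.  The LFP guards
electrode/source coincidence with a 10-um distance floor.  Smoothing
windows are normalised against edge loss so constants are preserved.
Problem sizes in the test suite and the acceptance script (10 trials per
condition, 3-trial coarse-step fit evaluations, budget-21 recovery fits)
are the package's default study sizes.

## Known limitations

* The column is calibrated to synthetic targets; absolute amplitudes and
  fit errors are not comparable to values obtained against empirical
  grand averages.
* Layer-V basket cells are nearly silent in the undetected condition
  (their sustained firing in the original account relied on the
  inter-laminar PN -> basket projection removed here); they are engaged
  by the perisomatic variant's proximal inputs, which is what that
  variant's mechanism requires.
* GABA_B kinetics are faster than physiological; see above.
* No granular layer IV, no explicit thalamic or higher-order structures,
  no sensor-space projection, no deviant-tone (mismatch) responses, and
  no tonic/rhythmic background drives.
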