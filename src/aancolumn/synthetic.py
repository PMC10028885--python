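"""Synthetic target waveforms and behavioural-paradigm structures.

No grand-average source waveforms are publicly deposited for the
informational-masking paradigm this package models, so every pipeline
stage is exercised against synthetic stand-ins that emulate the empirical
conventions: source-localised evoked fields sampled at 500 Hz over a
-50..450 ms epoch, band-limited to 0.15-15 Hz, with an undetected-tone
morphology (P1 positivity near 50 ms, small N1 negativity near 100 ms)
and a detected-tone morphology that adds the broad auditory awareness
negativity (AAN) peaking near 180 ms; plus the auditory oddball timeline
(ten 100-ms tones at 500-ms onset asynchrony, one deviant) and the
button-press-based detected/undetected binning rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ConfigError

__all__ = [
    "ERFComponent",
    "ERFComponentSet",
    "OddballTimeline",
    "TargetWaveform",
    "generate_targets",
    "generate_oddball",
    "bin_tones",
    "epoch",
    "EPOCH_MS",
    "SAMPLING_HZ",
]

EPOCH_MS = (-50.0, 450.0)
SAMPLING_HZ = 500.0
BAND_HZ = (0.15, 15.0)

TONE_DURATION_MS = 100.0
SOA_MS = 500.0
TONES_PER_SEQUENCE = 10
SEQUENCE_S = 5.0


@dataclass
class TargetWaveform:
    """An empirical-like source waveform to fit against (nAm)."""

    times_ms: np.ndarray
    amplitude_nAm: np.ndarray
    condition: str                     # detected | undetected | difference
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.times_ms.shape != self.amplitude_nAm.shape:
            raise ConfigError("time grid and amplitude differ in length")
        if self.times_ms.size > 1:
            steps = np.diff(self.times_ms)
            if not np.allclose(steps, steps[0]):
                raise ConfigError("target waveform requires uniform sampling")
        if not np.all(np.isfinite(self.amplitude_nAm)):
            raise ConfigError("non-finite amplitudes")

    def to_table(self) -> np.ndarray:
        return np.column_stack([self.times_ms, self.amplitude_nAm])

    @classmethod
    def from_table(cls, table: np.ndarray, condition: str,
                   provenance=None) -> "TargetWaveform":
        table = np.asarray(table, dtype=float)
        return cls(table[:, 0], table[:, 1], condition,
                   dict(provenance or {}))


@dataclass(frozen=True)
class ERFComponent:
    label: str
    peak_ms: float
    width_ms: float       # Gaussian sigma
    amplitude_nAm: float  # signed

    def __post_init__(self):
        if self.width_ms <= 0:
            raise ConfigError(f"{self.label}: width must be > 0")

    def waveform(self, t_ms: np.ndarray) -> np.ndarray:
        return self.amplitude_nAm * np.exp(
            -0.5 * ((t_ms - self.peak_ms) / self.width_ms) ** 2)


@dataclass(frozen=True)
class ERFComponentSet:
    """Component recipe for the synthetic evoked waveforms.

    Default amplitudes match the scale of the calibrated column model
    (single-digit nAm); they are fully configurable.  The AAN component
    is broad so its support spans roughly 60-360 ms, as the empirical
    difference waveform does.
    """

    p1: ERFComponent = ERFComponent("P1", 52.0, 14.0, 2.3)
    n1: ERFComponent = ERFComponent("N1", 105.0, 22.0, -0.55)
    aan: ERFComponent = ERFComponent("AAN", 180.0, 65.0, -0.5)
    noise_nAm: float = 0.05
    sampling_hz: float = SAMPLING_HZ
    band_hz: tuple = BAND_HZ
    seed: int = 0

    def __post_init__(self):
        if self.sampling_hz <= 2 * self.band_hz[1]:
            raise ConfigError("sampling rate must exceed twice the band top")
        if self.noise_nAm < 0:
            raise ConfigError("noise amplitude must be >= 0")


def _band_limited_noise(n: int, fs: float, band, sigma: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Gaussian white noise band-passed zero-phase to ``band`` (Hz)."""
    x = rng.normal(0.0, 1.0, n)
    lo = max(band[0], 1e-3) / (fs / 2.0)
    hi = min(band[1] / (fs / 2.0), 0.99)
    sos = signal.butter(2, [lo, hi], btype="bandpass", output="sos")
    y = signal.sosfiltfilt(sos, x, padtype="even")
    sd = y.std()
    return y / sd * sigma if sd > 0 else y


def generate_targets(spec: ERFComponentSet | None = None):
    """(undetected, detected) synthetic target waveforms.

    undetected = P1 + N1 (+ band-limited noise); detected adds the AAN
    component on top of an independent noise draw.  The deterministic
    component sum is already band-limited by construction; the band-pass
    is applied to the noise term only, so with zero noise the detected
    minus undetected difference recovers the AAN component exactly.
    """
    spec = spec or ERFComponentSet()
    dt = 1000.0 / spec.sampling_hz
    t = np.arange(EPOCH_MS[0], EPOCH_MS[1], dt)
    base = spec.p1.waveform(t) + spec.n1.waveform(t)
    rng = np.random.default_rng(int(spec.seed) & 0x7FFFFFFF)
    prov = {"generator": "gaussian-components", "seed": spec.seed,
            "noise_nAm": spec.noise_nAm}
    und = base.copy()
    det = base + spec.aan.waveform(t)
    if spec.noise_nAm > 0:
        und = und + _band_limited_noise(t.size, spec.sampling_hz,
                                        spec.band_hz, spec.noise_nAm, rng)
        det = det + _band_limited_noise(t.size, spec.sampling_hz,
                                        spec.band_hz, spec.noise_nAm, rng)
    return (TargetWaveform(t, und, "undetected", dict(prov)),
            TargetWaveform(t.copy(), det, "detected", dict(prov)))


@dataclass(frozen=True)
class OddballTimeline:
    """One 5-s oddball sequence: ten evenly spaced tones, one deviant."""

    onsets_s: tuple
    deviant_index: int
    tone_duration_ms: float = TONE_DURATION_MS
    soa_ms: float = SOA_MS
    sequence_s: float = SEQUENCE_S
    press_time_s: float | None = None

    def __post_init__(self):
        if len(self.onsets_s) != TONES_PER_SEQUENCE:
            raise ConfigError("a sequence contains exactly ten tones")
        gaps = np.diff(self.onsets_s)
        if not np.allclose(gaps, self.soa_ms / 1000.0):
            raise ConfigError("onsets must be evenly spaced at the SOA")
        if not 0 <= self.deviant_index < TONES_PER_SEQUENCE:
            raise ConfigError("deviant index out of range")
        if self.onsets_s[-1] >= self.sequence_s:
            raise ConfigError("all onsets must fall within the sequence")

    @property
    def standard_onsets_s(self) -> tuple:
        return tuple(o for i, o in enumerate(self.onsets_s)
                     if i != self.deviant_index)


def generate_oddball(seed: int, n_sequences: int,
                     with_presses: bool = True) -> list:
    """Deterministic batch of oddball timelines.

    Deviant position is uniform over the ten slots.  When
    ``with_presses`` is set, a synthetic detection time is drawn per
    sequence (uniform over the middle of the sequence) for roughly half
    the sequences, emulating listeners who eventually hear out the
    stream; the rest carry no press (never detected).
    """
    if n_sequences < 1:
        raise ConfigError("n_sequences must be >= 1")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    onsets = tuple(np.arange(TONES_PER_SEQUENCE) * (SOA_MS / 1000.0))
    out = []
    for _ in range(int(n_sequences)):
        dev = int(rng.integers(0, TONES_PER_SEQUENCE))
        press = None
        if with_presses and rng.random() < 0.5:
            press = float(rng.uniform(1.0, SEQUENCE_S))
        out.append(OddballTimeline(onsets_s=onsets, deviant_index=dev,
                                   press_time_s=press))
    return out


def bin_tones(timeline: OddballTimeline):
    """Split standard-tone onsets into (detected, undetected) bins.

    At least two stimuli must be heard before a listener can detect the
    stream, so the two standard tones immediately preceding the button
    press, plus all standard tones after it, are detected; standards more
    than two (standard) tones before the press are undetected.  The
    deviant belongs to neither bin; without a press everything is
    undetected; a press before the first tone marks all standards
    detected.
    """
    standards = list(timeline.standard_onsets_s)
    press = timeline.press_time_s
    if press is None:
        return [], standards
    before = [o for o in standards if o < press]
    after = [o for o in standards if o >= press]
    detected = before[-2:] + after
    undetected = before[:-2]
    return detected, undetected


def epoch(times_s: np.ndarray, values: np.ndarray, onsets_s,
          window_ms=EPOCH_MS, sampling_hz: float = SAMPLING_HZ):
    """Cut fixed-length epochs around stimulus onsets.

    Returns (epochs, kept_onsets); onsets whose window leaves the
    recording are dropped.  Each epoch is a (n_samples,) slice on the
    -50..450 ms grid (250 samples at 500 Hz).
    """
    times_s = np.asarray(times_s, dtype=float)
    values = np.asarray(values, dtype=float)
    dt = 1.0 / sampling_hz
    n_samp = int(round((window_ms[1] - window_ms[0]) / 1000.0 / dt))
    epochs, kept = [], []
    for onset in onsets_s:
        t0 = onset + window_ms[0] / 1000.0
        i0 = int(round((t0 - times_s[0]) / dt))
        if i0 < 0 or i0 + n_samp > values.size:
            continue
        epochs.append(values[i0:i0 + n_samp].copy())
        kept.append(onset)
    return epochs, kept
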