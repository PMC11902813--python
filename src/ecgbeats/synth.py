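"""Synthetic single-lead ECG generator.

Emulates five beat classes (A, L, N, R, V) with class-distinct P-QRS-T
morphology so that the downstream pipeline — denoising, segmentation,
per-class autoencoders, classification — can be exercised without any real
recordings.  Each beat is a sum of five Gaussian bumps (one per wave), an
intentionally simple but fully controllable morphology model.  Records are
assembled by additive overlay of jittered beats on a zero baseline; three
noise sources can be layered on top: sub-1 Hz baseline wander, 50 Hz mains
(power-line) interference, and band-limited EMG-like noise.

Class distinctions follow textbook electrophysiology in caricature:

* ``N``  normal beat: upright P, narrow QRS, upright T;
* ``A``  premature atrial contraction: like N but with an early, reshaped P;
* ``L``  left bundle branch block: broad slurred QRS, discordant (inverted) T;
* ``R``  right bundle branch block: wide deep S wave;
* ``V``  premature ventricular contraction: no P wave, very broad tall QRS,
  deep discordant T.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .records import CLASSES, DEFAULT_FS, Annotation, Beat, EcgRecord

__all__ = [
    "Wave",
    "BeatMorphology",
    "NoiseSpec",
    "DatasetSpec",
    "DEFAULT_MORPHOLOGIES",
    "TABLE_COUNTS",
    "generate_beat",
    "add_noise",
    "generate_dataset",
    "scaled_counts",
]

#: Published per-class beat counts of the study dataset (97,300 beats total).
TABLE_COUNTS: dict[str, int] = {
    "A": 3000,
    "L": 8000,
    "R": 7200,
    "V": 7100,
    "N": 72000,
}

#: Default R-peak position inside a 300-sample beat window (99 before, 200 after).
R_OFFSET = 99
BEAT_LEN = 300


@dataclass(frozen=True)
class Wave:
    """One ECG wave as a Gaussian bump.

    amplitude
        Peak amplitude in mV (sign gives polarity).
    center
        Offset of the bump center from the R-peak, in samples.
    width
        Gaussian sigma in samples; must be positive.
    """

    amplitude: float
    center: int
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"wave width must be > 0, got {self.width}")


@dataclass(frozen=True)
class BeatMorphology:
    """Per-class P-QRS-T morphology: five Gaussian bumps keyed P, Q, R, S, T."""

    label: str
    waves: dict[str, Wave]

    def __post_init__(self) -> None:
        missing = {"P", "Q", "R", "S", "T"} - set(self.waves)
        if missing:
            raise ValueError(f"morphology {self.label!r} missing waves {missing}")
        if self.waves["R"].amplitude <= 0:
            raise ValueError("R wave amplitude must be positive")


DEFAULT_MORPHOLOGIES: dict[str, BeatMorphology] = {
    "N": BeatMorphology("N", {
        "P": Wave(0.15, -45, 6.0),
        "Q": Wave(-0.10, -10, 3.0),
        "R": Wave(1.20, 0, 4.0),
        "S": Wave(-0.20, 10, 3.0),
        "T": Wave(0.35, 60, 14.0),
    }),
    "A": BeatMorphology("A", {
        # early, taller and narrower P wave than N (ectopic atrial focus)
        "P": Wave(0.22, -65, 4.5),
        "Q": Wave(-0.10, -10, 3.0),
        "R": Wave(1.15, 0, 4.0),
        "S": Wave(-0.20, 10, 3.0),
        "T": Wave(0.30, 55, 12.0),
    }),
    "L": BeatMorphology("L", {
        "P": Wave(0.12, -45, 6.0),
        "Q": Wave(-0.05, -16, 4.0),
        "R": Wave(0.90, 0, 10.0),
        "S": Wave(-0.35, 20, 7.0),
        "T": Wave(-0.30, 65, 16.0),
    }),
    "R": BeatMorphology("R", {
        "P": Wave(0.14, -45, 6.0),
        "Q": Wave(-0.12, -10, 3.0),
        "R": Wave(1.05, 0, 5.0),
        "S": Wave(-0.55, 14, 7.0),
        "T": Wave(0.25, 62, 13.0),
    }),
    "V": BeatMorphology("V", {
        # no atrial activity; broad bizarre QRS with discordant T
        "P": Wave(0.0, -45, 6.0),
        "Q": Wave(-0.20, -20, 6.0),
        "R": Wave(1.40, 0, 13.0),
        "S": Wave(-0.60, 24, 9.0),
        "T": Wave(-0.50, 78, 18.0),
    }),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: baseline wander + mains interference + EMG band noise.

    ``powerline_phase=None`` means the generator draws a fresh phase per
    record, which is what real mains coupling looks like across recordings;
    pass a float (radians) to pin it.
    """

    baseline_amplitude: float = 0.1       # mV
    baseline_freq: float = 0.3            # Hz, must stay <= 1 Hz
    powerline_amplitude: float = 0.5      # mV
    powerline_freq: float = 50.0          # Hz
    powerline_phase: float | None = None  # rad; None -> random per record
    emg_rms: float = 0.1                  # mV
    emg_band: tuple[float, float] = (20.0, 180.0)  # Hz

    def __post_init__(self) -> None:
        if self.baseline_freq > 1.0:
            raise ValueError("baseline wander frequency must be <= 1 Hz")
        for a in (self.baseline_amplitude, self.powerline_amplitude, self.emg_rms):
            if a < 0:
                raise ValueError("noise amplitudes must be >= 0")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        return cls(baseline_amplitude=0.0, powerline_amplitude=0.0, emg_rms=0.0)


@dataclass(frozen=True)
class DatasetSpec:
    """What to generate: per-class counts, scale, timing and randomness.

    ``counts`` defaults to the published study distribution; ``scale`` shrinks
    every class count (rounded half-up per class).  One top-level ``seed``
    fixes all randomness; per-record streams are derived by counter so output
    is bit-reproducible.
    """

    counts: dict[str, int] = field(default_factory=lambda: dict(TABLE_COUNTS))
    scale: float = 1.0
    fs: float = DEFAULT_FS
    rr_mean: int = 300       # samples between successive R-peaks
    rr_jitter: int = 20      # max +- uniform jitter on the RR interval
    beats_per_record: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.scale <= 1:
            raise ValueError("scale must be in (0, 1]")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("class counts must be >= 0")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def scaled_counts(spec: DatasetSpec) -> dict[str, int]:
    """Per-class beat counts after applying ``spec.scale`` (round half-up)."""
    return {c: _round_half_up(n * spec.scale) for c, n in spec.counts.items()}


def generate_beat(
    morphology: BeatMorphology,
    length: int = BEAT_LEN,
    rng: np.random.Generator | None = None,
    r_offset: int = R_OFFSET,
    amplitude_jitter: float = 0.05,
    center_jitter: float = 1.5,
    width_jitter: float = 0.05,
) -> np.ndarray:
    """Render one clean beat of ``length`` samples with the R-peak at ``r_offset``.

    Each wave's amplitude/width is jittered multiplicatively and its center
    (except R, which anchors the annotation) by a rounded Gaussian, all drawn
    from ``rng``.  With ``rng=None`` the nominal morphology is rendered
    without jitter.  Deterministic given the generator state.
    """

    t = np.arange(length, dtype=np.float64)
    out = np.zeros(length)
    for name, w in morphology.waves.items():
        amp, center, width = w.amplitude, float(r_offset + w.center), w.width
        if rng is not None:
            amp *= 1.0 + amplitude_jitter * rng.standard_normal()
            width *= 1.0 + width_jitter * rng.standard_normal()
            if name != "R":
                center += round(center_jitter * rng.standard_normal())
        if not 0 <= center < length:
            raise ValueError(
                f"wave {name} center {center:.0f} outside [0, {length}) "
                f"for class {morphology.label!r}"
            )
        width = max(width, 0.5)
        if amp != 0.0:
            out += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return out


def _emg_noise(n: int, rms: float, band: tuple[float, float], fs: float,
               rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian noise rescaled to the requested RMS."""
    lo, hi = band
    if not 0 < lo < hi <= fs / 2:
        raise ValueError(f"EMG band {band} outside (0, fs/2] at fs={fs}")
    white = rng.standard_normal(n)
    if hi >= 0.999 * fs / 2:
        # band runs to Nyquist: a high-pass is the exact construction
        sos = _signal.butter(4, lo, btype="highpass", fs=fs, output="sos")
    else:
        sos = _signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    shaped = _signal.sosfiltfilt(sos, white)
    scale = np.std(shaped)
    return shaped * (rms / scale) if scale > 0 else shaped


def add_noise(
    sig: np.ndarray,
    spec: NoiseSpec,
    rng: np.random.Generator | None = None,
    fs: float = DEFAULT_FS,
) -> np.ndarray:
    """Return ``sig`` plus the three additive noise components.

    The baseline and power-line components are deterministic sinusoids given
    their parameters, so subtracting them with known parameters recovers
    ``sig`` plus the EMG component only.
    """

    sig = np.asarray(sig, dtype=np.float64)
    if sig.size == 0:
        raise ValueError("signal must be non-empty")
    rng = rng if rng is not None else np.random.default_rng(0)
    t = np.arange(sig.size) / fs
    out = sig.copy()
    if spec.baseline_amplitude > 0:
        out += spec.baseline_amplitude * np.sin(2 * np.pi * spec.baseline_freq * t)
    if spec.powerline_amplitude > 0:
        phase = spec.powerline_phase
        if phase is None:
            phase = rng.uniform(0, 2 * np.pi)
        out += spec.powerline_amplitude * np.sin(
            2 * np.pi * spec.powerline_freq * t + phase
        )
    if spec.emg_rms > 0:
        out += _emg_noise(sig.size, spec.emg_rms, spec.emg_band, fs, rng)
    return out


def _record_rng(seed: int, record_counter: int) -> np.random.Generator:
    # counter-derived per-record streams keep parallel generation reproducible
    return np.random.default_rng(np.random.SeedSequence((seed, record_counter)))


def generate_dataset(
    spec: DatasetSpec,
    noise: NoiseSpec | None = None,
    morphologies: dict[str, BeatMorphology] | None = None,
) -> tuple[list[EcgRecord], list[Beat]]:
    """Generate annotated records plus the beats segmented back out of them.

    The per-class beat counts equal ``scaled_counts(spec)`` exactly; classes
    whose scaled count rounds to zero are omitted (with a warning via the
    module logger in strict terms: here simply absent from the labels).
    Annotations point at the true R-peak samples, so re-segmenting the
    records with the default 99/200 window reproduces the returned beats.
    """

    from . import segment as _segment  # local import to avoid a cycle

    morphologies = morphologies or DEFAULT_MORPHOLOGIES
    counts = scaled_counts(spec)
    labels: list[str] = []
    for cls in CLASSES:
        labels.extend([cls] * counts.get(cls, 0))
    order_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xBEA7)))
    order = order_rng.permutation(len(labels))
    labels = [labels[i] for i in order]

    records: list[EcgRecord] = []
    beats: list[Beat] = []
    lead_in = 150
    tail = BEAT_LEN - R_OFFSET + 20
    for rec_no, start in enumerate(range(0, len(labels), spec.beats_per_record)):
        chunk = labels[start:start + spec.beats_per_record]
        rng = _record_rng(spec.seed, rec_no)
        rr = spec.rr_mean + rng.integers(
            -spec.rr_jitter, spec.rr_jitter + 1, size=len(chunk)
        )
        peaks = lead_in + np.concatenate(([0], np.cumsum(rr[:-1])))
        length = int(peaks[-1]) + tail
        samples = np.zeros(length)
        for peak, cls in zip(peaks, chunk):
            beat = generate_beat(morphologies[cls], BEAT_LEN, rng)
            samples[peak - R_OFFSET: peak - R_OFFSET + BEAT_LEN] += beat
        anns = [Annotation(int(p), c) for p, c in zip(peaks, chunk)]
        if noise is not None:
            samples = add_noise(samples, noise, rng, fs=spec.fs)
        rec = EcgRecord(f"synth-{rec_no:03d}", samples, fs=spec.fs,
                        annotations=anns)
        records.append(rec)
        beats.extend(_segment.segment_beats(rec))
    return records, beats


def dataset_manifest(spec: DatasetSpec) -> str:
    """JSON manifest of a generation run: counts, seed, scale, totals."""
    counts = scaled_counts(spec)
    return json.dumps(
        {
            "counts": counts,
            "total_beats": int(sum(counts.values())),
            "scale": spec.scale,
            "seed": spec.seed,
            "fs": spec.fs,
        },
        indent=2,
        sort_keys=True,
    )
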