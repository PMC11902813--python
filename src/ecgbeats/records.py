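"""Core in-memory containers for single-lead ECG data.

An :class:`EcgRecord` holds a raw sample sequence in millivolts together with
its sampling rate and a sorted list of beat annotations (sample index of the
R-peak plus a MIT-BIH beat symbol).  A :class:`Beat` is one fixed-length
segment cut around an annotated R-peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Beat classes used throughout the package, in canonical (alphabetical) order.
CLASSES: tuple[str, ...] = ("A", "L", "N", "R", "V")

#: Default sampling rate in Hz (MIT-BIH style single-lead recordings).
DEFAULT_FS: float = 360.0


@dataclass(frozen=True)
class Annotation:
    """One annotated R-peak: sample index (0-based) and beat symbol."""

    index: int
    symbol: str


@dataclass
class EcgRecord:
    """Single-lead ECG record: samples (mV), sampling rate, annotations."""

    record_id: str
    samples: np.ndarray
    fs: float = DEFAULT_FS
    lead: str = "MLII"
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("record samples must be one-dimensional")
        self.validate()

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        n = len(self.samples)
        prev = -1
        for ann in self.annotations:
            if not 0 <= ann.index < n:
                raise ValueError(
                    f"annotation index {ann.index} outside record "
                    f"[0, {n}) in {self.record_id!r}"
                )
            if ann.index <= prev:
                raise ValueError(
                    f"annotations not sorted ascending in {self.record_id!r}"
                )
            prev = ann.index

    def __len__(self) -> int:
        return len(self.samples)

    def with_samples(self, samples: np.ndarray) -> "EcgRecord":
        """Copy of this record with new samples, annotations carried through."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


@dataclass
class Beat:
    """One segmented heartbeat: fixed-length sample window around the R-peak.

    ``samples[pre]`` (index 99 with the default 99/200 window) is the
    annotated R-peak sample.
    """

    samples: np.ndarray
    label: str
    record_id: str = ""
    peak_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)


def beats_to_array(beats: list[Beat]) -> tuple[np.ndarray, np.ndarray]:
    """Stack beats into an (n_beats, beat_len) array plus a label array."""
    x = np.stack([b.samples for b in beats]) if beats else np.empty((0, 0))
    y = np.array([b.label for b in beats], dtype="<U1")
    return x, y
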