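"""Beat segmentation, symbol mapping, and train/test splitting.

A beat is the 300-sample window around an annotated R-peak: 99 samples
before, the peak, and 200 after (inclusive window [p-99, p+200], 0-based).
Annotated peaks too close to a record edge are skipped, not padded — padding
would distort the sample statistics the autoencoders learn.

The experiment classes are the raw MIT-BIH symbols {A, L, N, R, V}; the
AAMI five-group mapping (N, S, V, F, Q) is provided as a utility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .records import Annotation, Beat, EcgRecord

__all__ = [
    "PRE_SAMPLES",
    "POST_SAMPLES",
    "BEAT_SAMPLES",
    "MITBIH_TO_AAMI",
    "SplitSpec",
    "segment_beats",
    "map_to_aami",
    "split_train_test",
]

log = logging.getLogger(__name__)

PRE_SAMPLES = 99
POST_SAMPLES = 200
BEAT_SAMPLES = PRE_SAMPLES + 1 + POST_SAMPLES  # 300

#: MIT-BIH beat symbol -> AAMI class group.
MITBIH_TO_AAMI: dict[str, str] = {
    # N: normal and bundle-branch-block / escape beats
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    # S: supraventricular ectopic
    "A": "S", "a": "S", "J": "S", "S": "S",
    # V: ventricular ectopic
    "V": "V", "E": "V",
    # F: fusion
    "F": "F",
    # Q: paced / fusion-paced / unclassified
    "P": "Q", "/": "Q", "f": "Q", "U": "Q", "Q": "Q",
}


def map_to_aami(symbol: str, strict: bool = False) -> str:
    """Map a MIT-BIH beat symbol to its AAMI class.

    Unknown symbols map to ``Q`` with a warning; in strict mode they raise.
    """
    try:
        return MITBIH_TO_AAMI[symbol]
    except KeyError:
        if strict:
            raise ValueError(f"unknown MIT-BIH beat symbol {symbol!r}") from None
        log.warning("unknown MIT-BIH symbol %r mapped to Q", symbol)
        return "Q"


def segment_beats(
    record: EcgRecord,
    annotations: list[Annotation] | None = None,
    pre: int = PRE_SAMPLES,
    post: int = POST_SAMPLES,
    normalize: bool = False,
) -> list[Beat]:
    """Cut the annotated record into fixed-length beats.

    For each annotated peak ``p`` with ``p - pre >= 0`` and
    ``p + post < len(record)`` the inclusive window ``[p - pre, p + post]``
    (``pre + 1 + post`` samples) is emitted; out-of-range peaks are skipped
    and the skip count logged.  ``normalize`` applies an optional per-beat
    z-score (off by default; the source method normalizes nothing).
    """
    anns = annotations if annotations is not None else record.annotations
    if any(b.index <= a.index for a, b in zip(anns, anns[1:])):
        raise ValueError("annotations must be sorted ascending by index")
    n = len(record.samples)
    beats: list[Beat] = []
    skipped = 0
    for ann in anns:
        lo, hi = ann.index - pre, ann.index + post
        if lo < 0 or hi >= n:
            skipped += 1
            continue
        window = record.samples[lo:hi + 1].copy()
        if normalize:
            sd = window.std()
            window = (window - window.mean()) / (sd if sd > 0 else 1.0)
        beats.append(Beat(window, ann.symbol, record.record_id, ann.index))
    if skipped:
        log.info("segment_beats(%s): skipped %d edge peak(s)",
                 record.record_id, skipped)
    return beats


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition: fraction to train, stratification, seed."""

    train_fraction: float = 0.75
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train fraction must be in (0, 1)")


def split_train_test(
    beats: list[Beat], spec: SplitSpec | None = None
) -> tuple[list[Beat], list[Beat]]:
    """Deterministic (seeded) train/test partition of the beat list.

    Stratified mode draws ``floor(fraction * n_class)`` training beats per
    class, remainder to test; unstratified applies the same rule to the whole
    list.  The two outputs always partition the input.
    """
    spec = spec or SplitSpec()
    if not beats:
        return [], []
    rng = np.random.default_rng(spec.seed)
    groups: dict[str, list[int]]
    if spec.stratified:
        groups = {}
        for i, b in enumerate(beats):
            groups.setdefault(b.label, []).append(i)
        for label, idxs in groups.items():
            if not idxs:
                log.warning("class %s has no beats; excluded from split", label)
    else:
        groups = {"*": list(range(len(beats)))}
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in sorted(groups):
        idxs = np.array(groups[label])
        perm = rng.permutation(len(idxs))
        n_train = int(np.floor(spec.train_fraction * len(idxs)))
        train_idx.extend(idxs[perm[:n_train]].tolist())
        test_idx.extend(idxs[perm[n_train:]].tolist())
    train_idx.sort()
    test_idx.sort()
    return [beats[i] for i in train_idx], [beats[i] for i in test_idx]
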