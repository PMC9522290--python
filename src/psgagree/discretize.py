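"""Mini-epoch discretization of scorings and rater-pair contingency tables.

Agreement between scorers is computed on a shared grid of
non-overlapping analysis epochs anchored at lights-off: 30 s epochs
with the 5-stage alphabet for sleep staging, 0.5 s mini-epochs with a
binary present/absent alphabet for event scorings.  An event marks a
mini-epoch iff their intersection has strictly positive length
(half-open intervals; an event ending exactly at an epoch's start does
not mark it).  A trailing partial epoch is dropped (floor), which keeps
all scorers of a recording aligned since they share the TIB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .annotations import Hypnogram, ScoredRecording
from .errors import AlignmentError, CoverageError, StructuralError
from .vocab import STAGES

BINARY_ALPHABET: tuple[str, str] = ("absent", "present")
DEFAULT_EVENT_STEP = 0.5
_TOL = 1e-9


@dataclass(frozen=True)
class EpochGrid:
    """Uniform analysis grid: ``n_epochs`` bins of ``step`` seconds
    starting at ``start`` (= lights-off), labeled over ``alphabet``."""

    start: float
    step: float
    n_epochs: int
    alphabet: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.n_epochs < 1:
            raise StructuralError("empty grid (TIB shorter than one epoch)")

    @classmethod
    def for_events(cls, lights_off: float, lights_on: float,
                   step: float = DEFAULT_EVENT_STEP) -> "EpochGrid":
        n = int(math.floor((lights_on - lights_off) / step + _TOL))
        return cls(lights_off, step, n, BINARY_ALPHABET)

    @classmethod
    def for_stages(cls, hypnogram: Hypnogram) -> "EpochGrid":
        return cls(hypnogram.lights_off, hypnogram.epoch_duration,
                   hypnogram.n_epochs, STAGES)

    def compatible(self, other: "EpochGrid") -> bool:
        return (abs(self.start - other.start) < 1e-6
                and abs(self.step - other.step) < 1e-9
                and self.n_epochs == other.n_epochs
                and self.alphabet == other.alphabet)


@dataclass(frozen=True)
class LabelSequence:
    """Per-epoch labels on a grid, stored as integer codes into the
    grid alphabet."""

    grid: EpochGrid
    codes: np.ndarray  # int16, length n_epochs

    def __post_init__(self) -> None:
        if len(self.codes) != self.grid.n_epochs:
            raise ValueError("codes length does not match grid")
        k = len(self.grid.alphabet)
        if len(self.codes) and (self.codes.min() < 0 or self.codes.max() >= k):
            raise ValueError("codes outside alphabet range")

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(self.grid.alphabet[c] for c in self.codes)


@dataclass(frozen=True)
class ContingencyTable:
    """k x k rater-pair count matrix (rows = rater A, cols = rater B)."""

    alphabet: tuple[str, ...]
    counts: np.ndarray  # int64, shape (k, k)

    def __post_init__(self) -> None:
        k = len(self.alphabet)
        if self.counts.shape != (k, k):
            raise ValueError("counts shape does not match alphabet")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def discretize_events(rec: ScoredRecording, labels_of_interest: Iterable[str],
                      step: float = DEFAULT_EVENT_STEP) -> LabelSequence:
    """Binary presence/absence sequence of the selected event labels."""
    grid = EpochGrid.for_events(rec.lights_off, rec.lights_on, step)
    codes = np.zeros(grid.n_epochs, dtype=np.int16)
    wanted = set(labels_of_interest)
    for a in rec.annotations:
        if a.label not in wanted:
            continue
        # epochs with strictly positive intersection with [onset, end)
        lo = a.onset - grid.start
        hi = a.end - grid.start
        i0 = max(int(math.floor(lo / step + _TOL)), 0)
        i1 = min(int(math.ceil(hi / step - _TOL)), grid.n_epochs)
        if i1 > i0:
            codes[i0:i1] = 1
    return LabelSequence(grid, codes)


def discretize_stages(h: Hypnogram) -> LabelSequence:
    """Identity mapping of the stage sequence onto its 30 s grid."""
    grid = EpochGrid.for_stages(h)
    index = {s: i for i, s in enumerate(STAGES)}
    codes = np.array([index[s] for s in h.stages], dtype=np.int16)
    return LabelSequence(grid, codes)


def context_mask(h: Hypnogram, context: str, grid: EpochGrid) -> np.ndarray:
    """Boolean mask over ``grid`` marking epochs whose containing 30 s
    hypnogram epoch is W (``wake``) or non-W (``sleep``); all-true for
    ``tib``.  The hypnogram must cover the grid."""
    if context == "tib":
        return np.ones(grid.n_epochs, dtype=bool)
    if context not in ("wake", "sleep"):
        raise ValueError(f"unknown context {context!r}")
    span = h.n_epochs * h.epoch_duration
    last_start = grid.start + (grid.n_epochs - 1) * grid.step
    if last_start - h.lights_off >= span - _TOL:
        raise CoverageError(
            f"grid extends {last_start - h.lights_off - span:.3f}s beyond "
            f"the context hypnogram")
    starts = (np.arange(grid.n_epochs) * grid.step
              + (grid.start - h.lights_off))
    epoch_idx = np.floor(starts / h.epoch_duration + _TOL).astype(np.int64)
    is_wake = np.array([s == "W" for s in h.stages], dtype=bool)[epoch_idx]
    return is_wake if context == "wake" else ~is_wake


def build_contingency(a: LabelSequence, b: LabelSequence,
                      mask: Sequence[bool] | np.ndarray | None = None
                      ) -> ContingencyTable:
    """Count matrix of joint labels over (masked) epochs of a shared grid."""
    if not a.grid.compatible(b.grid):
        raise AlignmentError("label sequences are on different grids")
    ca, cb = a.codes, b.codes
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if len(mask) != a.grid.n_epochs:
            raise AlignmentError("mask length does not match grid")
        ca, cb = ca[mask], cb[mask]
    k = len(a.grid.alphabet)
    joint = np.bincount(ca.astype(np.int64) * k + cb, minlength=k * k)
    return ContingencyTable(a.grid.alphabet, joint.reshape(k, k))
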