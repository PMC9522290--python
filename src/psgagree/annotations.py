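"""Domain types and I/O for polysomnography scoring annotations.

A scoring is a list of labeled, half-open time intervals ``[onset,
onset+duration)`` in seconds from recording start, restricted to the
Time-In-Bed (TIB) period between the lights-off and lights-on markers.
Sleep stagings are additionally normalized onto a 30 s epoch grid
anchored at lights-off (the hypnogram).

Two file dialects are supported: a plain UTF-8 CSV
(``label,onset_s,duration_s``) and EDF+ annotation-only files (the TAL
track; see :mod:`psgagree.edfplus`).  A YAML manifest assembles files
into the study's recording x scorer x method x task structure.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import (
    ConflictError,
    ConsistencyError,
    ParseError,
    StructuralError,
)
from .vocab import (
    LIGHTS_OFF,
    LIGHTS_ON,
    MARKER_LABELS,
    STAGE_LABELS,
    STAGES,
    canonical_label,
)

EPOCH_SECONDS = 30.0
_TOL = 1e-6


@dataclass(frozen=True, order=True)
class Annotation:
    """One labeled half-open interval ``[onset, onset+duration)``.

    Times are seconds from recording start.  Zero duration is only
    legal for the lights markers.
    """

    onset: float
    duration: float
    label: str

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"negative onset {self.onset}")
        if self.duration < 0:
            raise ValueError(f"negative duration {self.duration}")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class Hypnogram:
    """Sequence of 30 s sleep-stage epochs anchored at lights-off."""

    lights_off: float
    stages: tuple[str, ...]
    epoch_duration: float = EPOCH_SECONDS

    def __post_init__(self) -> None:
        if not self.stages:
            raise StructuralError("empty hypnogram")
        bad = sorted({s for s in self.stages if s not in STAGES})
        if bad:
            raise StructuralError(f"hypnogram contains non-stage symbols {bad}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def span(self) -> float:
        """Seconds covered by the hypnogram (from lights-off)."""
        return self.n_epochs * self.epoch_duration

    def to_annotations(self) -> tuple[Annotation, ...]:
        """One ``stage-*`` annotation per epoch, recording-anchored."""
        return tuple(
            Annotation(self.lights_off + i * self.epoch_duration,
                       self.epoch_duration, f"stage-{s}")
            for i, s in enumerate(self.stages)
        )


@dataclass(frozen=True)
class ScoredRecording:
    """One scorer's output for one recording under one method and task."""

    recording_id: str
    scorer_id: str
    method: str
    task: str
    lights_off: float
    lights_on: float
    annotations: tuple[Annotation, ...] = ()
    hypnogram: Hypnogram | None = None
    context_hypnogram: Hypnogram | None = None
    context_events: tuple[Annotation, ...] = ()

    def __post_init__(self) -> None:
        if not self.lights_on > self.lights_off:
            raise StructuralError(
                f"lights_on ({self.lights_on}) must exceed lights_off "
                f"({self.lights_off})"
            )

    @property
    def tib(self) -> float:
        """Time in bed, seconds."""
        return self.lights_on - self.lights_off

    def events(self, labels: Iterable[str] | None = None) -> tuple[Annotation, ...]:
        """Annotations, optionally restricted to a set of labels."""
        if labels is None:
            return self.annotations
        wanted = set(labels)
        return tuple(a for a in self.annotations if a.label in wanted)


@dataclass(frozen=True)
class TimingRecord:
    """Active scoring time (minutes) of one scoring exercise."""

    recording_id: str
    scorer_id: str
    method: str
    task: str
    active_minutes: float

    def __post_init__(self) -> None:
        if not self.active_minutes > 0:
            raise ValueError("active_minutes must be positive")


# ---------------------------------------------------------------------------
# Assembly of raw (label, onset, duration) triples into a ScoredRecording
# ---------------------------------------------------------------------------

def _clip(a: Annotation, lo: float, hi: float) -> Annotation | None:
    onset = max(a.onset, lo)
    end = min(a.end, hi)
    if end - onset <= 0:
        return None
    return Annotation(onset, end - onset, a.label)


def _hypnogram_from_stage_annotations(
    stage_anns: Sequence[Annotation], lights_off: float, lights_on: float
) -> Hypnogram:
    n = int(math.floor((lights_on - lights_off) / EPOCH_SECONDS + _TOL))
    if n < 1:
        raise StructuralError("TIB shorter than one 30 s epoch")
    stages: list[str | None] = [None] * n
    for a in stage_anns:
        stage = a.label.removeprefix("stage-")
        i0 = int(math.floor((a.onset - lights_off) / EPOCH_SECONDS + _TOL))
        i1 = int(math.ceil((a.end - lights_off) / EPOCH_SECONDS - _TOL))
        for i in range(max(i0, 0), min(i1, n)):
            if stages[i] is not None and stages[i] != stage:
                raise StructuralError(
                    f"conflicting stages {stages[i]}/{stage} at epoch {i}"
                )
            stages[i] = stage
    gaps = [i for i, s in enumerate(stages) if s is None]
    if gaps:
        raise StructuralError(f"hypnogram gaps at epochs {gaps[:5]}"
                              + ("..." if len(gaps) > 5 else ""))
    return Hypnogram(lights_off, tuple(stages))  # type: ignore[arg-type]


def assemble_recording(
    raw: Iterable[tuple[str, float, float]],
    *,
    recording_id: str = "",
    scorer_id: str = "",
    method: str = "",
    task: str = "",
    aliases: Mapping[str, str] | None = None,
    source: str = "<memory>",
) -> ScoredRecording:
    """Build a validated :class:`ScoredRecording` from raw label triples.

    Labels are canonicalized through the alias map; events are clipped
    to TIB with zero-length residues dropped; stage annotations are
    normalized into a per-epoch hypnogram.
    """
    lights: dict[str, float] = {}
    anns: list[Annotation] = []
    for label, onset, duration in raw:
        token = canonical_label(label, dict(aliases) if aliases else None)
        onset, duration = float(onset), float(duration)
        if token in MARKER_LABELS:
            if token in lights:
                raise StructuralError(f"{source}: duplicate {token} marker")
            lights[token] = onset
            continue
        if duration <= 0:
            raise StructuralError(
                f"{source}: zero-duration annotation {token!r} at {onset}"
            )
        anns.append(Annotation(onset, duration, token))

    missing = [m for m in MARKER_LABELS if m not in lights]
    if missing:
        raise StructuralError(f"{source}: missing lights markers {missing}")
    lights_off, lights_on = lights[LIGHTS_OFF], lights[LIGHTS_ON]
    if not lights_on > lights_off:
        raise StructuralError(f"{source}: lights-on precedes lights-off")

    clipped = [c for a in anns if (c := _clip(a, lights_off, lights_on))]
    clipped.sort()

    stage_anns = tuple(a for a in clipped if a.label in STAGE_LABELS)
    hypnogram = None
    if stage_anns or task == "staging":
        if not stage_anns:
            raise StructuralError(f"{source}: staging task without stage annotations")
        hypnogram = _hypnogram_from_stage_annotations(stage_anns, lights_off, lights_on)
        events = tuple(a for a in clipped if a.label not in STAGE_LABELS)
        clipped = list(hypnogram.to_annotations() + events)
        clipped.sort()

    return ScoredRecording(
        recording_id=recording_id,
        scorer_id=scorer_id,
        method=method,
        task=task,
        lights_off=lights_off,
        lights_on=lights_on,
        annotations=tuple(clipped),
        hypnogram=hypnogram,
    )


# ---------------------------------------------------------------------------
# Tabular dialect
# ---------------------------------------------------------------------------

_TABULAR_HEADER = ["label", "onset_s", "duration_s"]


def _read_tabular_raw(path: os.PathLike | str) -> list[tuple[str, float, float]]:
    rows: list[tuple[str, float, float]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _TABULAR_HEADER:
            raise ParseError(f"{path}: expected header {_TABULAR_HEADER}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            label, onset_s, duration_s = row
            try:
                onset = float(onset_s)
                duration = float(duration_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed timestamp: {exc}") from exc
            rows.append((label, onset, duration))
    return rows


def _write_tabular(rec: ScoredRecording, path: os.PathLike | str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_TABULAR_HEADER)
        writer.writerow([LIGHTS_OFF, str(rec.lights_off), "0"])
        for a in rec.annotations:
            writer.writerow([a.label, str(a.onset), str(a.duration)])
        writer.writerow([LIGHTS_ON, str(rec.lights_on), "0"])


# ---------------------------------------------------------------------------
# Public read / write
# ---------------------------------------------------------------------------

DIALECTS = ("tabular", "edfplus")


def read_annotation_file(
    path: os.PathLike | str,
    dialect: str = "tabular",
    *,
    recording_id: str = "",
    scorer_id: str = "",
    method: str = "",
    task: str = "",
    aliases: Mapping[str, str] | None = None,
) -> ScoredRecording:
    """Read one scoring annotation file into a :class:`ScoredRecording`.

    ``dialect`` is ``"tabular"`` (CSV) or ``"edfplus"`` (EDF+ TAL
    annotation track).  Identity fields are not stored in the files
    themselves; they come from the caller (normally the study manifest).
    """
    if dialect == "tabular":
        raw = _read_tabular_raw(path)
    elif dialect == "edfplus":
        from .edfplus import read_edfplus_raw

        raw = read_edfplus_raw(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    return assemble_recording(
        raw,
        recording_id=recording_id,
        scorer_id=scorer_id,
        method=method,
        task=task,
        aliases=aliases,
        source=str(path),
    )


def write_annotation_file(
    rec: ScoredRecording, path: os.PathLike | str, dialect: str = "tabular"
) -> None:
    """Write a :class:`ScoredRecording`; output re-reads to an equal one."""
    if dialect == "tabular":
        _write_tabular(rec, path)
    elif dialect == "edfplus":
        from .edfplus import write_edfplus

        write_edfplus(rec, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


# ---------------------------------------------------------------------------
# Timing logs
# ---------------------------------------------------------------------------

_TIMING_HEADER = ["recording_id", "scorer_id", "method", "task", "active_minutes"]


def read_timing_log(path: os.PathLike | str) -> list[TimingRecord]:
    out: list[TimingRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _TIMING_HEADER:
            raise ParseError(f"{path}: expected header {_TIMING_HEADER}")
        for lineno, row in enumerate(reader, start=2):
            try:
                minutes = float(row["active_minutes"])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad active_minutes") from exc
            out.append(TimingRecord(row["recording_id"], row["scorer_id"],
                                    row["method"], row["task"], minutes))
    return out


def write_timing_log(records: Sequence[TimingRecord], path: os.PathLike | str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_TIMING_HEADER)
        for r in records:
            writer.writerow([r.recording_id, r.scorer_id, r.method, r.task,
                             str(r.active_minutes)])


# ---------------------------------------------------------------------------
# Study assembly
# ---------------------------------------------------------------------------

Cell = tuple[str, str, str, str]  # (task, recording_id, scorer_id, method)


@dataclass
class ScoringSet:
    """Cross-classified collection: task x recording x scorer x method."""

    cells: dict[Cell, ScoredRecording] = field(default_factory=dict)
    timing: list[TimingRecord] = field(default_factory=list)
    missing: list[Cell] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def tasks(self) -> tuple[str, ...]:
        return tuple(sorted({t for t, *_ in self.cells}))

    @property
    def scorers(self) -> tuple[str, ...]:
        return tuple(sorted({s for _, _, s, _ in self.cells}))

    @property
    def methods(self) -> tuple[str, ...]:
        return tuple(sorted({m for *_, m in self.cells}))

    def recordings(self, task: str) -> tuple[str, ...]:
        return tuple(sorted({r for t, r, _, _ in self.cells if t == task}))

    def get(self, task: str, recording_id: str, scorer_id: str,
            method: str) -> ScoredRecording:
        return self.cells[(task, recording_id, scorer_id, method)]

    def add(self, rec: ScoredRecording) -> None:
        key = (rec.task, rec.recording_id, rec.scorer_id, rec.method)
        if key in self.cells:
            raise ConflictError(f"duplicate cell {key}")
        self.cells[key] = rec


def _check_lights_consistency(sset: ScoringSet) -> None:
    seen: dict[tuple[str, str], tuple[float, float]] = {}
    for (task, rec_id, scorer, method), rec in sset.cells.items():
        key = (task, rec_id)
        marks = (rec.lights_off, rec.lights_on)
        if key in seen:
            prev = seen[key]
            if abs(prev[0] - marks[0]) > _TOL or abs(prev[1] - marks[1]) > _TOL:
                raise ConsistencyError(
                    f"inconsistent lights markers for {task}/{rec_id}: "
                    f"{prev} vs {marks} (scorer {scorer}, {method})"
                )
        else:
            seen[key] = marks


def load_study(root_dir: os.PathLike | str,
               manifest: os.PathLike | str | Mapping | None = None) -> ScoringSet:
    """Load a study directory described by a YAML manifest.

    The manifest enumerates per-cell file paths (relative to
    ``root_dir``), optional per-recording context hypnograms and
    respiratory context events, a timing log, and optionally the
    expected design.  Missing cells against the expected design are
    reported in ``ScoringSet.missing``, never silently skipped.
    """
    root = Path(root_dir)
    if manifest is None:
        manifest = root / "manifest.yaml"
    if isinstance(manifest, (str, os.PathLike)):
        with open(manifest, encoding="utf-8") as fh:
            spec = yaml.safe_load(fh)
    else:
        spec = dict(manifest)

    dialect = spec.get("dialect", "tabular")
    aliases = spec.get("aliases") or None
    sset = ScoringSet()

    context_h: dict[str, Hypnogram] = {}
    for rec_id, rel in (spec.get("context_hypnograms") or {}).items():
        crec = read_annotation_file(root / rel, dialect, recording_id=rec_id,
                                    task="staging", aliases=aliases)
        assert crec.hypnogram is not None
        context_h[rec_id] = crec.hypnogram

    context_r: dict[str, tuple[Annotation, ...]] = {}
    for rec_id, rel in (spec.get("context_respiratory") or {}).items():
        crec = read_annotation_file(root / rel, dialect, recording_id=rec_id,
                                    aliases=aliases)
        context_r[rec_id] = crec.annotations

    for entry in spec.get("cells", []):
        task = entry["task"]
        rec_id = entry["recording"]
        rec = read_annotation_file(
            root / entry["path"],
            entry.get("dialect", dialect),
            recording_id=rec_id,
            scorer_id=entry["scorer"],
            method=entry["method"],
            task=task,
            aliases=aliases,
        )
        if task != "staging":
            rec = replace(
                rec,
                context_hypnogram=context_h.get(rec_id),
                context_events=context_r.get(rec_id, ()),
            )
        sset.add(rec)

    _check_lights_consistency(sset)

    design = spec.get("design")
    if design:
        scorers = design["scorers"]
        methods = design["methods"]
        tasks = design["tasks"]  # mapping task -> recording ids
    else:
        scorers = sset.scorers
        methods = sset.methods
        tasks = {t: sset.recordings(t) for t in sset.tasks}
    for task, rec_ids in tasks.items():
        for rec_id in rec_ids:
            for scorer in scorers:
                for method in methods:
                    key = (task, rec_id, scorer, method)
                    if key not in sset.cells:
                        sset.missing.append(key)

    timing_rel = spec.get("timing")
    if timing_rel:
        sset.timing = read_timing_log(root / timing_rel)
    return sset


def write_study(sset: ScoringSet, out_dir: os.PathLike | str,
                dialect: str = "tabular",
                context_hypnograms: Mapping[str, Hypnogram] | None = None,
                context_respiratory: Mapping[str, Sequence[Annotation]] | None = None,
                ) -> Path:
    """Write a complete study directory (files + manifest) loadable by
    :func:`load_study`.  Returns the manifest path."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    ext = "csv" if dialect == "tabular" else "edf"
    cells = []
    for (task, rec_id, scorer, method), rec in sorted(sset.cells.items()):
        rel = Path(task) / rec_id / f"{scorer}_{method}.{ext}"
        (root / rel).parent.mkdir(parents=True, exist_ok=True)
        write_annotation_file(rec, root / rel, dialect)
        cells.append({"task": task, "recording": rec_id, "scorer": scorer,
                      "method": method, "path": str(rel)})

    spec: dict = {"dialect": dialect, "cells": cells}

    if context_hypnograms:
        ch = {}
        for rec_id, hyp in sorted(context_hypnograms.items()):
            rel = Path("context") / f"{rec_id}_hypnogram.{ext}"
            (root / rel).parent.mkdir(parents=True, exist_ok=True)
            crec = ScoredRecording(
                recording_id=rec_id, scorer_id="clinical", method="clinical",
                task="staging", lights_off=hyp.lights_off,
                lights_on=hyp.lights_off + hyp.span,
                annotations=hyp.to_annotations(), hypnogram=hyp)
            write_annotation_file(crec, root / rel, dialect)
            ch[rec_id] = str(rel)
        spec["context_hypnograms"] = ch

    if context_respiratory:
        cr = {}
        for rec_id, events in sorted(context_respiratory.items()):
            events = tuple(events)
            if not events:
                continue
            hyp = (context_hypnograms or {}).get(rec_id)
            lo = hyp.lights_off if hyp else min(e.onset for e in events)
            hi = hyp.lights_off + hyp.span if hyp else max(e.end for e in events)
            rel = Path("context") / f"{rec_id}_respiratory.{ext}"
            (root / rel).parent.mkdir(parents=True, exist_ok=True)
            crec = ScoredRecording(
                recording_id=rec_id, scorer_id="clinical", method="clinical",
                task="", lights_off=lo, lights_on=hi,
                annotations=tuple(sorted(events)))
            write_annotation_file(crec, root / rel, dialect)
            cr[rec_id] = str(rel)
        spec["context_respiratory"] = cr

    if sset.timing:
        write_timing_log(sset.timing, root / "timing.csv")
        spec["timing"] = "timing.csv"

    spec["design"] = {
        "scorers": list(sset.scorers),
        "methods": list(sset.methods),
        "tasks": {t: list(sset.recordings(t)) for t in sset.tasks},
    }

    manifest_path = root / "manifest.yaml"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(spec, fh, sort_keys=True)
    return manifest_path
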