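"""Percentile-stratified selection of study recordings.

Each candidate recording gets an automatic-vs-clinical agreement score
K_ac (Cohen's kappa between the automatic scoring and the clinical
scoring, computed with the exact task discretization used downstream).
From the resulting distribution, the recordings closest to the 12.5th,
37.5th, 50th, 62.5th and 87.5th percentiles — the middles of the
inter-quartile quarters plus the median — are selected, which samples
the difficulty spectrum uniformly while avoiding extreme outliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .agreement import KappaResult, average_channel_kappa, cohen_kappa
from .annotations import ScoredRecording
from .discretize import build_contingency, discretize_events, discretize_stages
from .errors import AlignmentError, DomainError
from .vocab import RESPIRATORY_LABELS

DEFAULT_PERCENTILES: tuple[float, ...] = (12.5, 37.5, 50.0, 62.5, 87.5)


@dataclass(frozen=True)
class SelectionResult:
    task: str
    kac_values: dict[str, float]
    percentiles: tuple[float, ...]
    #: selected recording ids, ordered by target percentile (ascending)
    selected: tuple[str, ...]
    #: percentile values of the K_ac distribution, same order
    targets: tuple[float, ...]


def compute_kac(auto_events: ScoredRecording,
                clinical_events: ScoredRecording, task: str) -> KappaResult:
    """Agreement K_ac between an automatic and the clinical scoring of
    one recording, using the task's own discretization (30 s 5-class
    grid for staging, 0.5 s binary grid otherwise; leg movements are
    scored per channel and the channel kappas averaged)."""
    if (abs(auto_events.lights_off - clinical_events.lights_off) > 1e-6
            or abs(auto_events.lights_on - clinical_events.lights_on) > 1e-6):
        raise AlignmentError("automatic and clinical scorings cover "
                             "different TIB periods")
    pair = (auto_events.scorer_id or "auto",
            clinical_events.scorer_id or "clinical")
    if task == "staging":
        a = discretize_stages(auto_events.hypnogram)
        c = discretize_stages(clinical_events.hypnogram)
        return cohen_kappa(build_contingency(a, c), pair=pair, context="tib")
    if task == "leg_movements":
        per_channel = []
        for label in ("lm-left", "lm-right"):
            a = discretize_events(auto_events, [label])
            c = discretize_events(clinical_events, [label])
            per_channel.append(cohen_kappa(build_contingency(a, c),
                                           pair=pair, context="tib"))
        return average_channel_kappa(*per_channel)
    labels = {"respiratory": RESPIRATORY_LABELS,
              "arousals": ("arousal",)}.get(task)
    if labels is None:
        raise DomainError(f"unknown task {task!r}")
    a = discretize_events(auto_events, labels)
    c = discretize_events(clinical_events, labels)
    return cohen_kappa(build_contingency(a, c), pair=pair, context="tib")


def select_recordings(kac_values: Mapping[str, float],
                      percentiles: Sequence[float] = DEFAULT_PERCENTILES,
                      n_target: int | None = None,
                      task: str = "") -> SelectionResult:
    """Pick, per target percentile of the K_ac distribution, the
    not-yet-selected recording whose K_ac is nearest the percentile
    value (linear interpolation); ties break toward the lower
    recording id.  Selection proceeds by ascending percentile, without
    replacement."""
    percentiles = tuple(sorted(percentiles))
    if n_target is None:
        n_target = len(percentiles)
    if n_target != len(percentiles):
        raise DomainError("n_target must match the number of percentiles")
    if len(kac_values) < n_target:
        raise DomainError(
            f"need at least {n_target} recordings, got {len(kac_values)}")

    ids = sorted(kac_values)
    values = np.array([kac_values[i] for i in ids], dtype=np.float64)
    targets = tuple(float(np.percentile(values, p)) for p in percentiles)

    selected: list[str] = []
    for target in targets:
        best = min(
            (i for i in ids if i not in selected),
            key=lambda i: (abs(kac_values[i] - target), i),
        )
        selected.append(best)

    return SelectionResult(task, dict(kac_values), percentiles,
                           tuple(selected), targets)
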