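"""Synthetic multi-scorer rescoring studies.

The generator produces what the analysis consumes: a ground-truth
"physiology" per recording (first-order Markov hypnogram on 30 s
epochs, Poisson event processes within TIB, explicit periodic
leg-movement trains, desaturations coupled to respiratory events),
per-scorer corrupted scorings under two conditions, and log-normal
active-scoring-time logs.

The two conditions differ in their dependence structure, which is what
drives the agreement comparison:

* ``manual`` — every scorer corrupts the ground truth independently;
* ``semiauto`` — all scorers edit one shared automatic draft (itself a
  corruption of the truth), so scorers share the draft's errors and
  their pairwise agreement rises even though each still edits noisily.

Default rates, times in bed and corruption levels are set once to the
study conditions this package analyzes: per-task TIB and index levels
in the clinically typical range, scoring-time medians of roughly 33/25,
45/19, 24/15 and 28/22 minutes (manual/semi-automatic) for staging,
leg movements, respiratory events and arousals, and corruption levels
that put median pairwise kappa near 0.76/0.80 (staging), 0.72/0.91
(leg movements), 0.55/0.66 (respiratory) and 0.58/0.65 (arousals).

All randomness flows from one master seed through named per-cell
substreams, so a study is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .annotations import (
    Annotation,
    Hypnogram,
    ScoredRecording,
    ScoringSet,
    TimingRecord,
)
from .vocab import APNEA_LABELS, STAGES, TASK_LABELS, TASKS

_STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}

#: default stage transition matrix (rows/cols ordered W, N1, N2, N3, R);
#: sojourn structure tuned for a typical diagnostic-population night:
#: sleep efficiency in the high-80s, a few awakenings, consolidated N2.
DEFAULT_TRANSITIONS = np.array([
    # W     N1    N2    N3    R
    [0.75, 0.20, 0.03, 0.01, 0.01],   # W
    [0.12, 0.42, 0.40, 0.03, 0.03],   # N1
    [0.03, 0.04, 0.81, 0.08, 0.04],   # N2
    [0.01, 0.01, 0.15, 0.80, 0.03],   # N3
    [0.04, 0.04, 0.09, 0.01, 0.82],   # R
])

#: (log-median duration s, log sd, min s, max s) per event label
DEFAULT_DURATIONS: dict[str, tuple[float, float, float, float]] = {
    "apnea-obstructive": (np.log(20.0), 0.4, 10.0, 80.0),
    "apnea-central": (np.log(18.0), 0.4, 10.0, 80.0),
    "apnea-mixed": (np.log(22.0), 0.4, 10.0, 80.0),
    "hypopnea": (np.log(25.0), 0.4, 10.0, 90.0),
    "rera": (np.log(15.0), 0.4, 10.0, 60.0),
    "arousal": (np.log(8.0), 0.5, 3.0, 30.0),
    "desaturation": (np.log(25.0), 0.4, 10.0, 90.0),
    "lm": (np.log(2.0), 0.5, 0.6, 9.0),
}


@dataclass(frozen=True)
class TruthModel:
    """Ground-truth generator parameters for one recording."""

    tib_hours: float = 7.3
    stage_transition_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITIONS.copy())
    #: Poisson event rates per hour of TST
    event_rates: Mapping[str, float] = field(default_factory=lambda: {
        "arousal": 13.5,
        "apnea-obstructive": 1.6,
        "apnea-central": 0.4,
        "apnea-mixed": 0.2,
        "hypopnea": 4.5,
        "rera": 1.0,
        "desaturation": 4.0,   # desaturations not coupled to a resp. event
        "lm-isolated": 17.0,   # leg movements outside periodic trains
    })
    #: periodic LM trains: (imi_lo, imi_hi, run_lo, run_hi) and PLM rate
    lm_train_imi: tuple[float, float] = (15.0, 45.0)
    lm_train_run: tuple[int, int] = (5, 14)
    plm_rate: float = 13.6     # periodic LMs per hour of TST
    bilateral_prob: float = 0.2
    #: probability that a leg movement is placed during sleep rather
    #: than uniformly over TIB (PLMs are predominantly a sleep
    #: phenomenon, which is what depresses wake-context agreement)
    lm_sleep_bias: float = 0.85
    desat_coupling: float = 0.6
    duration_params: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DURATIONS))

    def __post_init__(self) -> None:
        tm = np.asarray(self.stage_transition_matrix, dtype=np.float64)
        if tm.shape != (5, 5) or not np.allclose(tm.sum(axis=1), 1.0):
            raise ValueError("stage_transition_matrix must be 5x5 row-stochastic")
        if any(r < 0 for r in self.event_rates.values()):
            raise ValueError("event rates must be non-negative")


@dataclass(frozen=True)
class ScorerModel:
    """Corruption channel applied to a source scoring."""

    stage_error_rate: float = 0.0
    #: row-stochastic 5x5 replacement kernel; None = uniform off-diagonal
    stage_confusion_kernel: np.ndarray | None = None
    event_sensitivity: float = 1.0
    false_positive_rate: float = 0.0    # events per hour of TIB
    boundary_jitter_sd: float = 0.0     # seconds, onset and offset
    #: per-label parameter overrides, e.g. apneas are delineated more
    #: reliably than hypopneas; keys: ``sensitivity``, ``jitter_sd``,
    #: ``fp_rate`` (events/h TIB, replacing the label's apportioned share)
    label_overrides: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        for p in (self.stage_error_rate, self.event_sensitivity):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.boundary_jitter_sd < 0 or self.false_positive_rate < 0:
            raise ValueError("jitter sd and FP rate must be non-negative")
        if self.stage_confusion_kernel is not None:
            kern = np.asarray(self.stage_confusion_kernel)
            if kern.shape != (5, 5) or not np.allclose(kern.sum(axis=1), 1.0):
                raise ValueError("confusion kernel must be 5x5 row-stochastic")


IDENTITY_SCORER = ScorerModel()


def _uniform_offdiagonal_kernel() -> np.ndarray:
    kern = np.full((5, 5), 0.25)
    np.fill_diagonal(kern, 0.0)
    return kern


def _sample_duration(rng: np.random.Generator, label: str,
                     params: Mapping[str, tuple[float, float, float, float]]
                     ) -> float:
    key = "lm" if label.startswith("lm") else label
    log_med, log_sd, lo, hi = params[key]
    return float(np.clip(rng.lognormal(log_med, log_sd), lo, hi))


def generate_truth(model: TruthModel, seed, recording_id: str = "truth",
                   lights_off: float = 600.0) -> ScoredRecording:
    """Generate one ground-truth recording (hypnogram + all events)."""
    rng = np.random.default_rng(seed)
    n_epochs = int(round(model.tib_hours * 3600.0 / 30.0))
    tm = np.asarray(model.stage_transition_matrix, dtype=np.float64)

    stages = []
    state = 0  # start in W
    for _ in range(n_epochs):
        stages.append(STAGES[state])
        state = int(rng.choice(5, p=tm[state]))
    hyp = Hypnogram(lights_off, tuple(stages))
    lights_on = lights_off + hyp.span
    tst_h = sum(s != "W" for s in stages) * 30.0 / 3600.0

    events: list[Annotation] = []

    # sleep intervals (absolute seconds) for sleep-biased LM placement
    sleep_runs: list[tuple[float, float]] = []
    for i, s in enumerate(stages):
        if s == "W":
            continue
        t0 = lights_off + i * 30.0
        if sleep_runs and abs(sleep_runs[-1][1] - t0) < 1e-9:
            sleep_runs[-1] = (sleep_runs[-1][0], t0 + 30.0)
        else:
            sleep_runs.append((t0, t0 + 30.0))
    sleep_total = sum(b - a for a, b in sleep_runs)
    sleep_edges = np.cumsum([b - a for a, b in sleep_runs])

    def _lm_onset() -> float:
        if sleep_total > 0 and rng.random() < model.lm_sleep_bias:
            x = rng.uniform(0.0, sleep_total)
            k = int(np.searchsorted(sleep_edges, x, side="right"))
            prev = sleep_edges[k - 1] if k else 0.0
            return sleep_runs[k][0] + (x - prev)
        return rng.uniform(lights_off, lights_on)

    for label, rate in model.event_rates.items():
        count = rng.poisson(rate * tst_h)
        if label == "lm-isolated":
            for _ in range(count):
                dur = _sample_duration(rng, "lm", model.duration_params)
                onset = min(_lm_onset(), lights_on - dur)
                leg = "lm-left" if rng.random() < 0.5 else "lm-right"
                events.append(Annotation(onset, min(dur, lights_on - onset), leg))
        else:
            for _ in range(count):
                dur = _sample_duration(rng, label, model.duration_params)
                onset = rng.uniform(lights_off, max(lights_on - dur, lights_off))
                events.append(Annotation(onset, min(dur, lights_on - onset),
                                         label))

    # periodic LM trains
    target_plms = rng.poisson(model.plm_rate * tst_h)
    imi_lo, imi_hi = model.lm_train_imi
    run_lo, run_hi = model.lm_train_run
    n_plm = 0
    while n_plm < target_plms:
        run = int(rng.integers(run_lo, run_hi + 1))
        run = min(run, target_plms - n_plm) if target_plms - n_plm >= 4 else run
        imis = rng.uniform(imi_lo, imi_hi, size=max(run - 1, 0))
        span = float(imis.sum()) + 10.0
        onset = min(_lm_onset(), max(lights_on - span, lights_off))
        for j in range(run):
            dur = _sample_duration(rng, "lm", model.duration_params)
            if onset + dur >= lights_on:
                break
            leg = "lm-left" if rng.random() < 0.5 else "lm-right"
            events.append(Annotation(onset, dur, leg))
            if rng.random() < model.bilateral_prob:
                other = "lm-right" if leg == "lm-left" else "lm-left"
                off = rng.uniform(0.05, 0.3)
                events.append(Annotation(onset + off, dur, other))
            n_plm += 1
            if j < run - 1:
                onset += imis[j]

    # desaturations coupled to respiratory events
    for ev in [e for e in events
               if e.label in APNEA_LABELS + ("hypopnea",)]:
        if rng.random() < model.desat_coupling:
            delay = rng.normal(20.0, 5.0)
            dur = _sample_duration(rng, "desaturation", model.duration_params)
            onset = ev.end + max(delay, 1.0)
            if onset + dur < lights_on:
                events.append(Annotation(onset, dur, "desaturation"))

    events.sort()
    return ScoredRecording(
        recording_id=recording_id, scorer_id="truth", method="truth",
        task="truth", lights_off=lights_off, lights_on=lights_on,
        annotations=tuple(events), hypnogram=hyp)


def corrupt_scoring(truth: ScoredRecording, scorer: ScorerModel, seed,
                    task: str, *, recording_id: str | None = None,
                    scorer_id: str = "", method: str = "") -> ScoredRecording:
    """Apply a scorer's corruption channel to a source scoring.

    Staging: each epoch is resampled from
    ``(1 - e) * delta_truth + e * kernel_row``.  Events: each source
    event is kept with probability ``event_sensitivity`` and its
    boundaries jittered by independent zero-mean Gaussian noise
    (durations kept positive, clipped to TIB); false positives arrive
    as a Poisson process with uniform positions and source-like
    durations, apportioned over the task's labels like the source
    events.
    """
    rng = np.random.default_rng(seed)
    rec_id = recording_id or truth.recording_id

    if task == "staging":
        assert truth.hypnogram is not None
        kern = (np.asarray(scorer.stage_confusion_kernel)
                if scorer.stage_confusion_kernel is not None
                else _uniform_offdiagonal_kernel())
        stages = []
        for s in truth.hypnogram.stages:
            if rng.random() < scorer.stage_error_rate:
                stages.append(STAGES[int(rng.choice(5, p=kern[_STAGE_INDEX[s]]))])
            else:
                stages.append(s)
        hyp = Hypnogram(truth.hypnogram.lights_off, tuple(stages))
        return ScoredRecording(
            recording_id=rec_id, scorer_id=scorer_id, method=method,
            task=task, lights_off=truth.lights_off, lights_on=truth.lights_on,
            annotations=hyp.to_annotations(), hypnogram=hyp,
            context_hypnogram=truth.context_hypnogram)

    labels = TASK_LABELS[task]
    overrides = scorer.label_overrides or {}
    source = [a for a in truth.annotations if a.label in labels]
    lo, hi = truth.lights_off, truth.lights_on
    out: list[Annotation] = []
    for a in source:
        ov = overrides.get(a.label, {})
        sens = ov.get("sensitivity", scorer.event_sensitivity)
        jitter = ov.get("jitter_sd", scorer.boundary_jitter_sd)
        if rng.random() >= sens:
            continue
        onset, end = a.onset, a.end
        if jitter > 0:
            onset += rng.normal(0.0, jitter)
            end += rng.normal(0.0, jitter)
        min_dur = min(a.duration, 0.5)
        if end < onset + min_dur:
            end = onset + min_dur
        onset = max(onset, lo)
        end = min(end, hi)
        if onset == a.onset and end == a.end:
            out.append(a)  # untouched: keep the exact source annotation
        elif end - onset > 0:
            out.append(Annotation(onset, end - onset, a.label))

    # false positives: the global rate apportioned over the task's
    # labels like the source events, unless a label's rate is overridden
    tib_h = (hi - lo) / 3600.0
    counts = np.array([sum(a.label == lab for a in source)
                       for lab in labels], dtype=np.float64)
    shares = (counts / counts.sum() if counts.sum() > 0
              else np.full(len(labels), 1.0 / len(labels)))
    durations_by_label = {
        lab: [a.duration for a in source if a.label == lab]
        for lab in labels}
    for lab, share in zip(labels, shares):
        rate = overrides.get(lab, {}).get(
            "fp_rate", scorer.false_positive_rate * share)
        if rate <= 0:
            continue
        for _ in range(rng.poisson(rate * tib_h)):
            pool = durations_by_label[lab]
            dur = (float(rng.choice(pool)) if pool
                   else _sample_duration(rng, lab, DEFAULT_DURATIONS))
            onset = rng.uniform(lo, max(hi - dur, lo))
            out.append(Annotation(onset, min(dur, hi - onset), lab))

    out.sort()
    return ScoredRecording(
        recording_id=rec_id, scorer_id=scorer_id, method=method, task=task,
        lights_off=lo, lights_on=hi, annotations=tuple(out),
        hypnogram=None, context_hypnogram=truth.context_hypnogram,
        context_events=truth.context_events)


# ---------------------------------------------------------------------------
# Study-level generation
# ---------------------------------------------------------------------------

#: per-task time in bed, hours (clinically typical medians per task group)
DEFAULT_TASK_TIB = {"staging": 7.5, "leg_movements": 7.3,
                    "respiratory": 6.5, "arousals": 8.1}

#: per-(task, method) median active scoring time, minutes
DEFAULT_TIMING_MEDIANS = {
    ("staging", "manual"): 32.62, ("staging", "semiauto"): 24.54,
    ("leg_movements", "manual"): 44.53, ("leg_movements", "semiauto"): 18.50,
    ("respiratory", "manual"): 23.81, ("respiratory", "semiauto"): 14.58,
    ("arousals", "manual"): 27.50, ("arousals", "semiauto"): 21.78,
}

_RESP_MANUAL_OVERRIDES = {
    "apnea-obstructive": {"sensitivity": 0.92, "jitter_sd": 2.0,
                          "fp_rate": 0.12},
    "apnea-central": {"sensitivity": 0.92, "jitter_sd": 2.0, "fp_rate": 0.04},
    "apnea-mixed": {"sensitivity": 0.92, "jitter_sd": 2.0, "fp_rate": 0.02},
    "hypopnea": {"sensitivity": 0.78, "jitter_sd": 4.0, "fp_rate": 1.2},
    "rera": {"sensitivity": 0.68, "jitter_sd": 4.5, "fp_rate": 0.5},
}

_RESP_EDIT_OVERRIDES = {
    "apnea-obstructive": {"sensitivity": 0.98, "jitter_sd": 0.5,
                          "fp_rate": 0.05},
    "apnea-central": {"sensitivity": 0.98, "jitter_sd": 0.5, "fp_rate": 0.02},
    "apnea-mixed": {"sensitivity": 0.98, "jitter_sd": 0.5, "fp_rate": 0.01},
    "hypopnea": {"sensitivity": 0.82, "jitter_sd": 3.5, "fp_rate": 0.8},
    "rera": {"sensitivity": 0.75, "jitter_sd": 3.0, "fp_rate": 0.35},
}

#: manual condition: independent corruption of the truth, per task
DEFAULT_MANUAL_MODELS = {
    "staging": ScorerModel(stage_error_rate=0.095),
    "leg_movements": ScorerModel(event_sensitivity=0.92,
                                 false_positive_rate=2.2,
                                 boundary_jitter_sd=0.35),
    "respiratory": ScorerModel(event_sensitivity=0.80,
                               boundary_jitter_sd=4.0,
                               label_overrides=_RESP_MANUAL_OVERRIDES),
    "arousals": ScorerModel(event_sensitivity=0.85,
                            false_positive_rate=2.0,
                            boundary_jitter_sd=1.5),
}

#: semi-automatic condition: the shared automatic draft's corruption ...
DEFAULT_DRAFT_MODELS = {
    "staging": ScorerModel(stage_error_rate=0.14),
    "leg_movements": ScorerModel(event_sensitivity=0.90,
                                 false_positive_rate=3.0,
                                 boundary_jitter_sd=0.4),
    "respiratory": ScorerModel(event_sensitivity=0.80,
                               boundary_jitter_sd=4.0,
                               label_overrides=_RESP_MANUAL_OVERRIDES),
    "arousals": ScorerModel(event_sensitivity=0.80,
                            false_positive_rate=3.0,
                            boundary_jitter_sd=2.0),
}

#: ... and each scorer's independent edit noise applied to the draft
DEFAULT_EDIT_MODELS = {
    "staging": ScorerModel(stage_error_rate=0.080),
    "leg_movements": ScorerModel(event_sensitivity=0.97,
                                 false_positive_rate=0.6,
                                 boundary_jitter_sd=0.10),
    "respiratory": ScorerModel(event_sensitivity=0.90,
                               boundary_jitter_sd=2.0,
                               label_overrides=_RESP_EDIT_OVERRIDES),
    "arousals": ScorerModel(event_sensitivity=0.88,
                            false_positive_rate=1.2,
                            boundary_jitter_sd=1.3),
}


@dataclass(frozen=True)
class StudyDesign:
    """Shape and parameters of a synthetic rescoring study."""

    n_scorers: int = 12
    n_recordings: int = 5
    tasks: tuple[str, ...] = TASKS
    task_tib_hours: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TASK_TIB))
    manual_models: Mapping[str, ScorerModel] = field(
        default_factory=lambda: dict(DEFAULT_MANUAL_MODELS))
    draft_models: Mapping[str, ScorerModel] = field(
        default_factory=lambda: dict(DEFAULT_DRAFT_MODELS))
    edit_models: Mapping[str, ScorerModel] = field(
        default_factory=lambda: dict(DEFAULT_EDIT_MODELS))
    timing_medians: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TIMING_MEDIANS))
    #: log-sd of scoring times: shared per-scorer speed + exercise noise
    timing_scorer_sd: float = 0.35
    timing_noise_sd: float = 0.40
    #: between-recording heterogeneity: log-sd multiplying each event
    #: rate, and sd of the wake-persistence perturbation.  Patients
    #: differ far more from each other than scorers do, which is what
    #: gives the diagnostic indices their high ICC ceilings.
    rate_log_sd: float = 0.7
    wake_persistence_sd: float = 0.08

    @property
    def scorer_ids(self) -> tuple[str, ...]:
        return tuple(f"s{i+1:02d}" for i in range(self.n_scorers))


def _vary_truth(base: TruthModel, design: StudyDesign,
                rng: np.random.Generator) -> TruthModel:
    """Per-recording patient heterogeneity: scale each event rate by an
    independent log-normal factor and perturb wake persistence (which
    moves sleep efficiency, WASO and SOL between recordings)."""
    rates = {lab: r * float(rng.lognormal(0.0, design.rate_log_sd))
             for lab, r in base.event_rates.items()}
    tm = np.asarray(base.stage_transition_matrix, dtype=np.float64).copy()
    p_ww = float(np.clip(tm[0, 0] + rng.normal(0.0, design.wake_persistence_sd),
                         0.40, 0.95))
    rest = tm[0, 1:] / tm[0, 1:].sum()
    tm[0, 0] = p_ww
    tm[0, 1:] = (1.0 - p_ww) * rest
    return replace(base, event_rates=rates, stage_transition_matrix=tm)


def _cell_seed(master_seed: int, *fields: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(master_seed),
                                  spawn_key=tuple(int(f) for f in fields))


def generate_study(master_seed: int, design: StudyDesign | None = None,
                   truth_models: Mapping[str, TruthModel] | None = None,
                   ) -> tuple[ScoringSet, dict[str, ScoredRecording]]:
    """Generate a complete cross-classified study.

    Returns the :class:`ScoringSet` (cells + timing log, with clinical
    context hypnograms attached to non-staging cells) and the
    ground-truth recordings keyed by recording id.
    """
    design = design or StudyDesign()
    sset = ScoringSet()
    truths: dict[str, ScoredRecording] = {}

    for t_idx, task in enumerate(design.tasks):
        tib = design.task_tib_hours.get(task, 7.3)
        base_truth = (truth_models or {}).get(task, TruthModel(tib_hours=tib))
        for r_idx in range(design.n_recordings):
            rec_id = f"{task[:4]}{r_idx+1:02d}"
            vary_rng = np.random.default_rng(
                _cell_seed(master_seed, t_idx, r_idx, 4))
            rec_truth_model = _vary_truth(base_truth, design, vary_rng)
            truth = generate_truth(rec_truth_model,
                                   _cell_seed(master_seed, t_idx, r_idx, 0),
                                   recording_id=rec_id)
            if task != "staging":
                # the pre-filled clinical hypnogram shared by all scorers
                resp_ctx = tuple(
                    a for a in truth.annotations
                    if a.label in APNEA_LABELS + ("hypopnea",))
                truth = replace(truth, context_hypnogram=truth.hypnogram,
                                context_events=resp_ctx)
            truths[rec_id] = truth

            draft = corrupt_scoring(
                truth, design.draft_models[task],
                _cell_seed(master_seed, t_idx, r_idx, 1),
                task, scorer_id="autodraft", method="auto")

            for s_idx, scorer_id in enumerate(design.scorer_ids):
                manual = corrupt_scoring(
                    truth, design.manual_models[task],
                    _cell_seed(master_seed, t_idx, r_idx, 2, s_idx),
                    task, scorer_id=scorer_id, method="manual")
                semi = corrupt_scoring(
                    draft, design.edit_models[task],
                    _cell_seed(master_seed, t_idx, r_idx, 3, s_idx),
                    task, scorer_id=scorer_id, method="semiauto")
                sset.add(manual)
                sset.add(semi)

    sset.timing = generate_timing(
        master_seed, design,
        {task: sset.recordings(task) for task in design.tasks})
    return sset, truths


def generate_timing(master_seed: int, design: StudyDesign,
                    recordings_by_task: Mapping[str, Sequence[str]]
                    ) -> list[TimingRecord]:
    """Log-normal active-scoring times: per-(task, method) median times
    a per-scorer speed factor (shared across tasks and methods, which
    is what makes the manual/semi-automatic pairing informative) times
    independent exercise noise."""
    timing_rng = np.random.default_rng(_cell_seed(master_seed, 99))
    speed = {sid: timing_rng.normal(0.0, design.timing_scorer_sd)
             for sid in design.scorer_ids}
    out: list[TimingRecord] = []
    for task, rec_ids in recordings_by_task.items():
        for rec_id in rec_ids:
            for sid in design.scorer_ids:
                for method in ("manual", "semiauto"):
                    median = design.timing_medians[(task, method)]
                    minutes = median * float(np.exp(
                        speed[sid]
                        + timing_rng.normal(0.0, design.timing_noise_sd)))
                    out.append(TimingRecord(rec_id, sid, method, task,
                                            minutes))
    return out


def study_context_maps(truths: Mapping[str, ScoredRecording]
                       ) -> tuple[dict[str, Hypnogram],
                                  dict[str, Sequence[Annotation]]]:
    """Context hypnograms / respiratory events for
    :func:`psgagree.annotations.write_study`."""
    hyps = {}
    resp = {}
    for rec_id, truth in truths.items():
        if truth.context_hypnogram is None:  # staging recordings
            continue
        hyps[rec_id] = truth.context_hypnogram
        resp[rec_id] = truth.context_events
    return hyps, resp
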