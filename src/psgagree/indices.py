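"""Diagnostic indices derived from one scoring.

Hypnogram-derived: TIB, TST, sleep-onset latency (SOL), stage-R
latency, WASO and sleep efficiency.  Event-derived (all per hour of
TST): apnea / hypopnea / apnea-hypopnea indices (AI, HI, AHI — RERAs
are scored with the respiratory events but never counted in the AHI),
oxygen desaturation index (ODI), arousal index (ArI), and the WASM2016
leg-movement indices (LMI, PLMI) after bilateral combination of the
per-leg event trains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

from .annotations import Annotation, Hypnogram, ScoredRecording
from .errors import DomainError
from .vocab import APNEA_LABELS

MIN_LM_DURATION = 0.5        # shortest countable leg movement, seconds
MONOLATERAL_MAX = 10.0       # longest countable single-leg LM, seconds
BILATERAL_MAX = 15.0         # longest countable bilateral LM, seconds
BILATERAL_GAP = 0.5          # max end-to-onset gap merging opposite legs
IMI_MIN, IMI_MAX = 10.0, 90.0  # periodic inter-movement interval band
MIN_PERIODIC_RUN = 4
#: respiratory-related LM window around a respiratory event's end, seconds
RESP_WINDOW = (-2.0, 10.25)


@dataclass(frozen=True)
class HypnogramSummary:
    tib_h: float
    tst_h: float
    sol_min: float          # NaN when no sleep was scored
    rem_latency_min: float  # NaN when no stage R was scored
    waso_min: float         # NaN when no sleep was scored
    se_pct: float


@dataclass(frozen=True)
class EventIndexSet:
    """Events per hour of TST; all NaN (``undefined``) when TST = 0."""

    ahi: float
    ai: float
    hi: float
    odi: float
    ari: float
    lmi: float
    plmi: float
    undefined: bool = False

    def as_dict(self) -> dict[str, float]:
        return {"AHI": self.ahi, "AI": self.ai, "HI": self.hi,
                "ODI": self.odi, "ArI": self.ari, "LMI": self.lmi,
                "PLMI": self.plmi}


@dataclass(frozen=True)
class CombinedLM:
    onset: float
    duration: float
    laterality: str  # left | right | bilateral

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class LegMovementTrain:
    combined_lms: tuple[CombinedLM, ...]
    periodic_flags: tuple[bool, ...] = ()
    respiratory_related_flags: tuple[bool, ...] = ()


def summarize_hypnogram(h: Hypnogram, tib: float) -> HypnogramSummary:
    """Sleep-quality parameters from a hypnogram and the TIB (seconds).

    TST counts epochs staged N1/N2/N3/R; SOL is the latency to the
    first non-W epoch; stage-R latency is counted from sleep onset;
    WASO is defined through the identity TIB = SOL + TST + WASO.
    """
    ep = h.epoch_duration
    sleep_idx = [i for i, s in enumerate(h.stages) if s != "W"]
    tst_s = len(sleep_idx) * ep
    if not sleep_idx:
        return HypnogramSummary(tib / 3600.0, 0.0, math.nan, math.nan,
                                math.nan, 0.0)
    sol_s = sleep_idx[0] * ep
    rem_idx = [i for i, s in enumerate(h.stages) if s == "R"]
    rem_latency_min = ((rem_idx[0] - sleep_idx[0]) * ep / 60.0
                       if rem_idx else math.nan)
    waso_min = (tib - sol_s - tst_s) / 60.0
    return HypnogramSummary(
        tib_h=tib / 3600.0,
        tst_h=tst_s / 3600.0,
        sol_min=sol_s / 60.0,
        rem_latency_min=rem_latency_min,
        waso_min=waso_min,
        se_pct=100.0 * tst_s / tib,
    )


def _merge_within_leg(lms: Sequence[Annotation]) -> list[Annotation]:
    merged: list[Annotation] = []
    for a in sorted(lms):
        if merged and a.onset < merged[-1].end:
            warnings.warn("overlapping leg movements within one leg merged",
                          stacklevel=3)
            prev = merged.pop()
            a = Annotation(prev.onset, max(prev.end, a.end) - prev.onset,
                           prev.label)
        merged.append(a)
    return merged


def combine_bilateral(left_lms: Sequence[Annotation],
                      right_lms: Sequence[Annotation],
                      gap_threshold: float = BILATERAL_GAP,
                      min_duration: float = MIN_LM_DURATION,
                      monolateral_max: float = MONOLATERAL_MAX,
                      bilateral_max: float = BILATERAL_MAX,
                      ) -> LegMovementTrain:
    """WASM2016 bilateral combination of the per-leg movement trains.

    Opposite-leg movements whose end-to-onset gap is below
    ``gap_threshold`` merge into one bilateral movement spanning both.
    After combination, monolateral movements shorter than
    ``min_duration`` and movements exceeding the duration caps are
    discarded from the countable train.
    """
    tagged = ([(a, "left") for a in _merge_within_leg(left_lms)]
              + [(a, "right") for a in _merge_within_leg(right_lms)])
    tagged.sort(key=lambda t: (t[0].onset, t[0].end))

    combined: list[CombinedLM] = []
    last_leg: str | None = None
    for a, leg in tagged:
        if combined:
            cur = combined[-1]
            gap = a.onset - cur.end
            if gap < gap_threshold and (leg != last_leg or gap < 0):
                combined[-1] = CombinedLM(cur.onset,
                                          max(cur.end, a.end) - cur.onset,
                                          "bilateral")
                last_leg = leg
                continue
        combined.append(CombinedLM(a.onset, a.duration, leg))
        last_leg = leg

    kept = []
    for lm in combined:
        if lm.duration < min_duration:
            continue
        cap = bilateral_max if lm.laterality == "bilateral" else monolateral_max
        if lm.duration > cap:
            continue
        kept.append(lm)
    n = len(kept)
    return LegMovementTrain(tuple(kept), (False,) * n, (False,) * n)


def flag_respiratory_related(train: LegMovementTrain,
                             respiratory_events: Sequence[Annotation],
                             window: tuple[float, float] = RESP_WINDOW,
                             ) -> LegMovementTrain:
    """Mark LMs whose onset falls within ``window`` seconds around the
    end of a scored apnea or hypopnea (RERAs do not count)."""
    ends = [e.end for e in respiratory_events
            if e.label in APNEA_LABELS + ("hypopnea",)]
    flags = tuple(
        any(end + window[0] <= lm.onset <= end + window[1] for end in ends)
        for lm in train.combined_lms
    )
    return replace(train, respiratory_related_flags=flags)


def mark_periodic(train: LegMovementTrain,
                  imi_min: float = IMI_MIN, imi_max: float = IMI_MAX,
                  min_run: int = MIN_PERIODIC_RUN,
                  include_respiratory: bool = True) -> LegMovementTrain:
    """Flag periodic LMs: maximal runs of at least ``min_run`` movements
    whose successive onset-to-onset intervals all lie in
    [``imi_min``, ``imi_max``].

    With ``include_respiratory`` (the default) respiratory-related LMs
    take part in the periodic runs and counts; switching it off removes
    them from the candidate train first (the conventional WASM2016
    reading).
    """
    lms = train.combined_lms
    resp = train.respiratory_related_flags or (False,) * len(lms)
    if include_respiratory:
        cand_idx = list(range(len(lms)))
    else:
        cand_idx = [i for i in range(len(lms)) if not resp[i]]

    periodic = [False] * len(lms)
    run: list[int] = []
    prev_onset: float | None = None
    for i in cand_idx:
        onset = lms[i].onset
        if prev_onset is not None and imi_min <= onset - prev_onset <= imi_max:
            run.append(i)
        else:
            if len(run) >= min_run:
                for j in run:
                    periodic[j] = True
            run = [i]
        prev_onset = onset
    if len(run) >= min_run:
        for j in run:
            periodic[j] = True
    return replace(train, periodic_flags=tuple(periodic),
                   respiratory_related_flags=tuple(resp))


def leg_movement_train(rec: ScoredRecording,
                       include_respiratory_in_plmi: bool = True,
                       ) -> LegMovementTrain:
    """Full WASM2016 processing of a scoring's per-leg LM events:
    bilateral combination, respiratory-related flagging (using the
    recording's respiratory context events), periodicity marking."""
    train = combine_bilateral(rec.events(["lm-left"]), rec.events(["lm-right"]))
    resp_events = rec.context_events or rec.events(
        APNEA_LABELS + ("hypopnea",))
    train = flag_respiratory_related(train, resp_events)
    return mark_periodic(train,
                         include_respiratory=include_respiratory_in_plmi)


def event_indices(rec: ScoredRecording, summary: HypnogramSummary,
                  include_respiratory_in_plmi: bool = True) -> EventIndexSet:
    """All event-derived indices of one scoring, per hour of TST."""
    if summary.tst_h <= 0:
        nan = math.nan
        return EventIndexSet(nan, nan, nan, nan, nan, nan, nan,
                             undefined=True)
    tst = summary.tst_h
    n_apnea = len(rec.events(APNEA_LABELS))
    n_hyp = len(rec.events(["hypopnea"]))
    n_desat = len(rec.events(["desaturation"]))
    n_arousal = len(rec.events(["arousal"]))

    train = leg_movement_train(rec, include_respiratory_in_plmi)
    n_lm = len(train.combined_lms)
    n_plm = sum(train.periodic_flags)

    return EventIndexSet(
        ahi=(n_apnea + n_hyp) / tst,
        ai=n_apnea / tst,
        hi=n_hyp / tst,
        odi=n_desat / tst,
        ari=n_arousal / tst,
        lmi=n_lm / tst,
        plmi=n_plm / tst,
    )


def recording_summary(rec: ScoredRecording) -> HypnogramSummary:
    """Hypnogram summary of a scoring, using its own hypnogram for the
    staging task and the shared clinical context hypnogram otherwise."""
    h = rec.hypnogram or rec.context_hypnogram
    if h is None:
        raise DomainError(
            f"recording {rec.recording_id}/{rec.scorer_id} has no hypnogram")
    return summarize_hypnogram(h, rec.tib)
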