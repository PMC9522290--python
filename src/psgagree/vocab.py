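"""Controlled annotation vocabulary and the free-text alias map.

Annotation files in the wild carry free-text labels ("Sleep stage W",
"Limb movement left", ...).  Everything downstream works on canonical
tokens; the alias map translates on read and is user-extensible because
label strings differ between sleep labs and scoring software.
"""

from __future__ import annotations

from .errors import VocabularyError

STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")
STAGE_LABELS: tuple[str, ...] = tuple(f"stage-{s}" for s in STAGES)

APNEA_LABELS: tuple[str, ...] = (
    "apnea-obstructive",
    "apnea-central",
    "apnea-mixed",
)
RESPIRATORY_LABELS: tuple[str, ...] = APNEA_LABELS + ("hypopnea", "rera")
LM_LABELS: tuple[str, ...] = ("lm-left", "lm-right")

EVENT_LABELS: tuple[str, ...] = LM_LABELS + RESPIRATORY_LABELS + (
    "arousal",
    "desaturation",
)

LIGHTS_OFF = "lights-off"
LIGHTS_ON = "lights-on"
MARKER_LABELS: tuple[str, ...] = (LIGHTS_OFF, LIGHTS_ON)

VOCABULARY: frozenset[str] = frozenset(STAGE_LABELS + EVENT_LABELS + MARKER_LABELS)

#: Task identifiers of the rescoring study design.
TASKS: tuple[str, ...] = ("staging", "leg_movements", "respiratory", "arousals")
METHODS: tuple[str, ...] = ("manual", "semiauto")

#: Event labels each scoring task is concerned with.
TASK_LABELS: dict[str, tuple[str, ...]] = {
    "staging": STAGE_LABELS,
    "leg_movements": LM_LABELS,
    "respiratory": RESPIRATORY_LABELS + ("desaturation",),
    "arousals": ("arousal",),
}

# Common free-text spellings mapped onto canonical tokens.  The EDF+
# spellings for sleep stages are standardized; the rest mirror frequent
# lab conventions and can be extended per study.
DEFAULT_ALIASES: dict[str, str] = {
    "Sleep stage W": "stage-W",
    "Sleep stage N1": "stage-N1",
    "Sleep stage N2": "stage-N2",
    "Sleep stage N3": "stage-N3",
    "Sleep stage R": "stage-R",
    "Lights off": LIGHTS_OFF,
    "Lights on": LIGHTS_ON,
    "Limb movement (left)": "lm-left",
    "Limb movement (right)": "lm-right",
    "Leg movement left": "lm-left",
    "Leg movement right": "lm-right",
    "Obstructive apnea": "apnea-obstructive",
    "Central apnea": "apnea-central",
    "Mixed apnea": "apnea-mixed",
    "Hypopnea": "hypopnea",
    "RERA": "rera",
    "EEG arousal": "arousal",
    "Arousal": "arousal",
    "SpO2 desaturation": "desaturation",
    "Desaturation": "desaturation",
}


def canonical_label(raw: str, aliases: dict[str, str] | None = None) -> str:
    """Map a free-text annotation string to its canonical vocabulary token.

    Canonical tokens pass through unchanged.  Unknown strings raise
    :class:`~psgagree.errors.VocabularyError`.
    """
    raw = raw.strip()
    if raw in VOCABULARY:
        return raw
    table = DEFAULT_ALIASES if aliases is None else {**DEFAULT_ALIASES, **aliases}
    if raw in table:
        token = table[raw]
        if token not in VOCABULARY:
            raise VocabularyError(
                f"alias {raw!r} maps to {token!r} which is not a vocabulary token"
            )
        return token
    raise VocabularyError(f"unknown annotation label {raw!r}")
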