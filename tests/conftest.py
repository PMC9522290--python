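import numpy as np
import pytest

from psgagree.annotations import Hypnogram, ScoredRecording, assemble_recording
from psgagree.vocab import STAGES

MASTER_SEED = 20260925


@pytest.fixture
def rng():
    return np.random.default_rng(MASTER_SEED)


def random_event_recording(rng, n_events=30, tib=3600.0,
                           labels=("arousal",), **meta) -> ScoredRecording:
    """Random well-formed event scoring within a TIB of ``tib`` seconds."""
    raw = [("lights-off", 0.0, 0.0)]
    for _ in range(n_events):
        onset = float(rng.uniform(0.0, tib - 1.0))
        duration = float(rng.uniform(0.5, min(30.0, tib - onset)))
        raw.append((str(rng.choice(labels)), onset, duration))
    raw.append(("lights-on", tib, 0.0))
    return assemble_recording(raw, **meta)


def random_hypnogram(rng, n_epochs=100, lights_off=0.0) -> Hypnogram:
    stages = tuple(str(s) for s in rng.choice(STAGES, size=n_epochs))
    return Hypnogram(lights_off, stages)


@pytest.fixture(scope="session")
def paper_scale_study():
    """One full-size synthetic study (12 scorers x 2 methods x 4 tasks
    x 5 recordings) shared across tests."""
    from psgagree.simulate import generate_study

    study, truths = generate_study(MASTER_SEED)
    return study, truths


@pytest.fixture(scope="session")
def paper_scale_report(paper_scale_study):
    from psgagree.pipeline import run_agreement_analysis

    study, _ = paper_scale_study
    return run_agreement_analysis(study)
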