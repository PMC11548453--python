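import numpy as np
import pytest

from solestep.gait_synth import (
    SubjectSpec,
    TrackScript,
    _stand,
    _steps,
    make_annotation,
    simulate_subject,
)
from solestep.pipeline import prepare_subject


def mini_track(n_walk: int = 10, n_run: int = 0) -> TrackScript:
    """Small track for fast tests: a few walking (and optionally running) steps."""
    segments = [_steps("moderate_walk", n_walk)]
    if n_run:
        segments += [_stand(2.0), _steps("run", n_run)]
    return TrackScript(tuple(segments))


@pytest.fixture(scope="session")
def mini_subject():
    """One small simulated subject: recording, annotation, truth."""
    spec = SubjectSpec(subject_id=0, seed=42)
    rec, truth = simulate_subject(spec, mini_track(10, 5))
    ann = make_annotation(truth, seed=7)
    return rec, ann, truth


@pytest.fixture(scope="session")
def mini_cohort():
    """Three small prepared subjects for cross-validation tests."""
    out = []
    for sid in range(3):
        spec = SubjectSpec(subject_id=sid, seed=100 + sid)
        rec, truth = simulate_subject(spec, mini_track(12, 6))
        ann = make_annotation(truth, seed=200 + sid)
        out.append(prepare_subject(rec, ann, truth, sid))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)
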