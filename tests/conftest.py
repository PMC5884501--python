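import numpy as np
import pytest

from gazetex.gaze_core import GazeRecording, ScreenGeometry


@pytest.fixture(scope="session")
def geometry() -> ScreenGeometry:
    """Study-replica monitor: 23-inch 16:9 1920x1080 at 600 mm."""
    return ScreenGeometry()


def make_recording(rng: np.random.Generator, n: int = 50,
                   rate_hz: float = 300.0, subject: str = "S1",
                   question: str = "Q1", trial: int = 1) -> GazeRecording:
    """A random but well-formed recording for I/O and invariance tests."""
    t = np.arange(n) / rate_hz + rng.uniform(0, 1e-4)
    x = rng.uniform(0, 1920, n)
    y = rng.uniform(0, 1080, n)
    valid = rng.random(n) > 0.05
    return GazeRecording(t=t, x=x, y=y, valid=valid, rate_hz=rate_hz,
                         subject_id=subject, question_id=question, trial=trial)


@pytest.fixture(scope="session")
def cohort_benchmark():
    """End-to-end separability benchmark on the default synthetic cohort.

    Expensive (minutes): 10 well-separated subjects, 56 questions each,
    texture + gray-image features, short-term protocol over 10 random
    partitions and NoET in {2, 4, 8, 16}.  Session-scoped so the
    acceptance and property tests share one run.
    """
    from gazetex.cli import run_cohort_benchmark

    return run_cohort_benchmark(seed=1)
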