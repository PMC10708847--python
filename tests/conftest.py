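import numpy as np
import pytest

from betawatch.core import SessionAnnotation
from betawatch.synthetic import CohortSpec, SignalSpec, generate_cohort, generate_trace


@pytest.fixture(scope="session")
def short_annotation() -> SessionAnnotation:
    """A scaled-down session: two 16-s videos with 6-s survey/quiz blocks."""
    return SessionAnnotation.standard_session(
        n_video_segments=2, video_s=16.0, survey_s=6.0, quiz_s=6.0)


@pytest.fixture(scope="session")
def tiny_annotation() -> SessionAnnotation:
    """One 8-s video block, for per-trace tests."""
    return SessionAnnotation.standard_session(
        n_video_segments=1, video_s=8.0, survey_s=3.0, quiz_s=3.0)


@pytest.fixture(scope="session")
def small_cohort(short_annotation):
    """50 subjects with a 0.6 target rank association, fixed seed."""
    return generate_cohort(CohortSpec(
        n_subjects=50, target_assoc=0.6, seed=3, annotation=short_annotation))


@pytest.fixture()
def clean_trace():
    """A low-amplitude trace guaranteed to pass the 75 uV gate."""
    spec = SignalSpec(duration_s=8.0, band_gains={"beta": 3.0},
                      pink_gain=4.0, line_amp_uV=1.0, seed=12)
    return generate_trace(spec)


@pytest.fixture(scope="session")
def elliptical_cloud():
    """A bivariate normal cloud on which the skipped rule flags nothing."""
    rng = np.random.default_rng(0)
    x = rng.standard_normal(100)
    y = 0.6 * x + 0.8 * rng.standard_normal(100)
    return x, y


SMALL_GRID = {"hidden_layer_sizes": [(8,)], "alpha": [1e-3],
              "learning_rate_init": [1e-2]}


@pytest.fixture(scope="session")
def small_grid():
    return dict(SMALL_GRID)
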