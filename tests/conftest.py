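import numpy as np
import pytest

from nutriface.synthetic import CohortSpec, render_face, sample_subject


@pytest.fixture(scope="session")
def small_cohort_rendered():
    """Twelve rendered subjects at a 256-px canvas, with their params."""
    spec = CohortSpec(n_subjects=12, seed=11, canvas_size=256)
    out = []
    for i in range(spec.n_subjects):
        p = sample_subject(spec, i)
        out.append((p, *render_face(p, spec.canvas_size)))
    return spec, out


@pytest.fixture(scope="session")
def seg_fixtures_128():
    """Rendered 128-px faces/masks for desk-scale segmentation training."""
    spec = CohortSpec(
        n_subjects=41, seed=5, canvas_size=128, jitter_translation_px=4.0
    )
    return [render_face(sample_subject(spec, i), 128) for i in range(41)]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
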