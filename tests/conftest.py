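import numpy as np
import pytest
from shapely.geometry import Polygon

from rotadebulk.pipeline import compute_cohort_frames
from rotadebulk.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Six synthetic lesions (~50 frames), shared across the suite."""
    return generate_cohort(GeneratorConfig(seed=11, n_lesions=6))


@pytest.fixture(scope="session")
def small_frames(small_cohort):
    """Per-frame metrics table for both prediction modes."""
    return compute_cohort_frames(small_cohort)


def star_polygon(rng: np.random.Generator, n: int = 24,
                 r_lo: float = 0.5, r_hi: float = 2.0) -> Polygon:
    """A random simple star-shaped polygon around the origin."""
    theta = np.sort(rng.uniform(0, 2 * np.pi, n))
    # enforce distinct angles so edges are non-degenerate
    theta += np.linspace(0, 1e-6, n)
    r = rng.uniform(r_lo, r_hi, n)
    return Polygon(np.c_[r * np.cos(theta), r * np.sin(theta)])
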