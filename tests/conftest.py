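import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from contourspm import Contour, ShapeSample, SimilarityTransform

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def bumpy_curve(m: int = 101, a: float = 0.3, b: float = 0.2) -> np.ndarray:
    """Asymmetric star-shaped closed curve (no rotational symmetry)."""
    t = np.linspace(0, 2 * np.pi, m, endpoint=False)
    return np.column_stack([np.cos(t) * (1 + a * np.cos(3 * t)),
                            np.sin(t) * (1 + b * np.sin(2 * t))])


def circle(m: int = 101, r: float = 1.0) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, m, endpoint=False)
    return r * np.column_stack([np.cos(t), np.sin(t)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def bumpy_contour():
    return Contour(bumpy_curve(), "bumpy")


def noise_sample(rng, n_per_group=5, m=40, sd=0.05, group=("A", "B")):
    """Two groups of noisy circles with iid 2D point noise (null data)."""
    shapes, labels = [], []
    for g in group:
        for j in range(n_per_group):
            pts = circle(m) + sd * rng.standard_normal((m, 2))
            shapes.append(Contour(pts, f"{g}{j}"))
            labels.append(g)
    return ShapeSample(shapes=shapes, group=labels)


def random_similarity(rng) -> SimilarityTransform:
    return SimilarityTransform.from_angle(
        rng.uniform(0, 2 * np.pi), rng.uniform(0.5, 2.0), rng.uniform(-3, 3, 2))
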