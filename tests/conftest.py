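import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from icao2sat.phantom import ClusterSpec, PhantomConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_phantom_config(seed: int = 0, **overrides) -> PhantomConfig:
    """A reduced acquisition (16 x 16 x 3 grid, 256 frames) that keeps the
    full signal structure: peripheral systemic shell, one central
    tumour-specific cluster, window-harmonic frequencies."""
    n, dt = 256, 3.8
    kw = dict(
        shape=(3, 16, 16),
        n_frames=n,
        frame_interval=dt,
        mask_semiaxes=(1.7, 6.5, 6.5),
        systemic_inner_radius=4.5,
        systemic_frequency=4 / (n * dt),
        tumour_frequencies=(7 / (n * dt),),
        clusters=(
            ClusterSpec(centre=(1, 7, 7), radius=(1.2, 2.4, 2.4), amplitude=0.012),
        ),
        seed=seed,
    )
    kw.update(overrides)
    return PhantomConfig(**kw)


@pytest.fixture
def small_config() -> PhantomConfig:
    return small_phantom_config()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
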