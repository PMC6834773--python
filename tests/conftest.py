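import numpy as np
import pytest

from mpra_leakage.core import PWM, PWMOrder
from mpra_leakage.synthetic import (
    SyntheticConfig,
    default_pwm_set,
    generate_dataset,
)


@pytest.fixture(scope="session")
def default_dataset():
    """The generator's default study conditions (seed 0); shared session-wide."""
    return generate_dataset(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def small_dataset():
    """A miniature dataset for fast structural tests."""
    cfg = SyntheticConfig(
        n_reporters=3,
        reporter_length=150,
        n_planted_sites_per_reporter=2,
        pwm_set=default_pwm_set(seed=3, n_pwms=2, widths=(18, 20)),
        n_informative_tracks=2,
        n_alien_tracks=2,
        duplicate_reporter=True,
        seed=3,
    )
    return generate_dataset(cfg)


@pytest.fixture
def one_hot_acg_pwm():
    """Width-3 matrix scoring 1 per matching base of ACG, 0 otherwise."""
    weights = np.zeros((3, 4))
    weights[0, 0] = 1.0  # A
    weights[1, 1] = 1.0  # C
    weights[2, 2] = 1.0  # G
    return PWM(motif_id="ACG", order=PWMOrder.MONO, weights=weights)


def random_mono_pwm(rng, width=None, motif_id="rnd"):
    width = int(width if width is not None else rng.integers(2, 9))
    return PWM(motif_id=motif_id, order=PWMOrder.MONO,
               weights=rng.normal(0, 2, size=(width, 4)))


def random_di_pwm(rng, steps=None, motif_id="rnd_di"):
    steps = int(steps if steps is not None else rng.integers(1, 5))
    return PWM(motif_id=motif_id, order=PWMOrder.DI,
               weights=rng.normal(0, 2, size=(steps, 16)))
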