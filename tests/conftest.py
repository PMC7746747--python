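import numpy as np
import pytest

from wormskel import WormSpec, crop_blob, generate_worm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_worm_spec(rng, half_width=None, length=None, curved=True):
    """A seeded sinusoidal worm spec at the imaging scale of the pipeline
    (length 20-40 px, half-width 1-2.5 px)."""
    hw = half_width if half_width is not None else rng.choice([1.0, 1.5, 2.0, 2.5])
    L = length if length is not None else rng.uniform(20, 40)
    amp = rng.uniform(1.5, 4.5) if curved else 0.0
    return WormSpec.sinusoidal(
        start=(25.0 + rng.uniform(-3, 3), 8.0 + rng.uniform(0, 3)),
        length=L,
        amplitude=amp,
        wavelength=rng.uniform(18, 40),
        phase=rng.uniform(0, 2 * np.pi),
        half_width=float(hw),
    )


def worm_blob(spec, canvas=(56, 64)):
    mask, skel = generate_worm(spec, canvas)
    return crop_blob(mask), skel
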