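import numpy as np
import pytest

from fissuremap.phantom import PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 15-patient / 45-disc phantom cohort shared across test modules."""
    cfg = PhantomConfig(n_patients=15, seed=424242)
    discs, manifest = generate_cohort(cfg)
    return cfg, discs, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)


def random_small_roi(seed, shape=(2, 4, 4), n_levels=4, p_mask=0.8):
    """A random tiny discretized ROI for brute-force comparisons."""
    g = np.random.default_rng(seed)
    levels = g.integers(1, n_levels + 1, size=shape).astype(np.int32)
    mask = g.random(shape) < p_mask
    if not mask.any():
        mask[0, 0, 0] = True
    levels[~mask] = 0
    return levels, mask
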