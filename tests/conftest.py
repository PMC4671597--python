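import numpy as np
import pytest

from pulmopet import (
    PhantomSpec,
    TracerSimConfig,
    generate_phantom,
    simulate_fdg,
    simulate_nn13,
)


@pytest.fixture(scope="session")
def phantom():
    """Default digital lung phantom (one subject, fixed seed)."""
    spec = PhantomSpec()
    hu, mask, truth = generate_phantom(spec, seed=1)
    return spec, hu, mask, truth


@pytest.fixture(scope="session")
def nn13_noise_free(phantom):
    _, _, _, truth = phantom
    return simulate_nn13(truth, TracerSimConfig(noise="none"), seed=0)


@pytest.fixture(scope="session")
def fdg_noise_free(phantom):
    _, _, _, truth = phantom
    cfg = TracerSimConfig(noise="none")
    scan, plasma = simulate_fdg(truth, cfg, seed=0)
    return cfg, scan, plasma


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_kinetic_truth(k1, k2, k3, vb, n=1):
    """Hand-built single-compartment-set truth for FDG simulator oracles."""
    from pulmopet.core import VolumeGrid
    from pulmopet.phantom import PhantomTruth

    grid = VolumeGrid((n, 1, 1), (1, 1, 1))
    shape = grid.dims
    k1a, k2a, k3a, vba = (np.full(shape, v, dtype=float) for v in (k1, k2, k3, vb))
    ki = np.where(k2a + k3a > 0, k1a * k3a / np.maximum(k2a + k3a, 1e-300), 0.0)
    return PhantomTruth(
        grid=grid,
        lung_mask=np.ones(shape, bool),
        q_rel=np.ones(shape),
        sv_per_min=np.full(shape, 0.5),
        fgas=np.full(shape, 0.7),
        ki_per_min=ki,
        k1=k1a,
        k2=k2a,
        k3=k3a,
        vb=vba,
    )
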