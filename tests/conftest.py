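import numpy as np
import pytest

import svrecon as sv
from svrecon.acquisition import MotionModel, ProtocolConfig, simulate_protocol
from svrecon.phantom import PhantomConfig, generate_thorax_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless 0.75 mm phantom used by geometry-sensitive tests."""
    cfg = PhantomConfig(shape=(64, 64, 64), spacing=0.75, noise_sigma=0.0, seed=2)
    truth, vessels, mask = generate_thorax_phantom(cfg)
    return truth, vessels, mask


@pytest.fixture(scope="session")
def clean_single_stack(small_phantom):
    """One motionless, noiseless stack simulated from the small phantom."""
    truth, _, mask = small_phantom
    cfg = ProtocolConfig(
        n_stacks=1, noise_sigma=0.0, scale_jitter=0.0, motion=MotionModel.still(), seed=2
    )
    stacks, traces = simulate_protocol(truth, cfg)
    return stacks, traces


@pytest.fixture(scope="session")
def clean_three_stacks(small_phantom):
    """Three orthogonal motionless stacks from the small phantom."""
    truth, _, mask = small_phantom
    cfg = ProtocolConfig(
        n_stacks=3, noise_sigma=0.0, scale_jitter=0.0, motion=MotionModel.still(), seed=2
    )
    stacks, traces = simulate_protocol(truth, cfg)
    return stacks, traces


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_transforms(n, rng, scale_rot=10.0, scale_tr=5.0, center_scale=10.0):
    out = []
    for _ in range(n):
        out.append(
            sv.RigidTransform(
                rotation=scale_rot * rng.standard_normal(3),
                translation=scale_tr * rng.standard_normal(3),
                center=center_scale * rng.standard_normal(3),
            )
        )
    return out
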