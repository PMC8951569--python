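import numpy as np
import pytest

from angiotrack.contrast import ContrastWindow
from angiotrack.synthetic import BranchSpec, PhantomConfig, generate_synthetic_cine


def mini_config(**overrides) -> PhantomConfig:
    """Small, fast phantom: 96x96, 24 frames, period 8, bolus 8-19."""
    kwargs = dict(
        frame_size=(96, 96),
        n_frames=24,
        period_frames=8,
        bolus_window=ContrastWindow(8, 19),
        vessel_tree=(
            BranchSpec(control_points=((22, 30), (45, 62), (72, 40)), width=6.0),
        ),
        motion_amplitude_px=3.0,
        vessel_contrast=0.6,
        noise_sigma=0.015,
        background="edges",
        seed=7,
        name="mini",
    )
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def mini_phantom():
    """(sequence, truth) of the default mini phantom, shared across tests."""
    return generate_synthetic_cine(mini_config())


@pytest.fixture(scope="session")
def static_phantom():
    """Zero-motion, zero-noise phantom with a bolus (degenerate limit)."""
    return generate_synthetic_cine(
        mini_config(motion_amplitude_px=0.0, noise_sigma=0.0, seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_mask(rng: np.random.Generator, shape=(24, 24), p=0.4) -> np.ndarray:
    return rng.random(shape) < p
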