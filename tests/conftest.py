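import numpy as np
import pytest

from ihcscore.synthetic import PhantomSpec, generate_phantom, generate_trial

# small phantoms keep the suite fast while leaving enough pixels for the
# angle histogram and the 99th-percentile features to be stable
PHANTOM_SIZE = 64


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(width=PHANTOM_SIZE, height=PHANTOM_SIZE, noise_sigma=0.01)


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(
        width=PHANTOM_SIZE, height=PHANTOM_SIZE, noise_sigma=0.0, quantize=False
    )


@pytest.fixture(scope="session")
def phantom(small_spec):
    """One standard-dose phantom with its ground truth."""
    img, w_true, h_true = generate_phantom(small_spec)
    return img, w_true, h_true


@pytest.fixture(scope="session")
def graded_trial(small_spec):
    """10 images with a graded DAB dose, independent tissue fields."""
    return generate_trial(
        10, np.linspace(0.05, 1.2, 10), seed=7, base_spec=small_spec
    )


@pytest.fixture(scope="session")
def dilution_trial(small_spec):
    """10 images sharing one tissue structure; only the dose varies."""
    return generate_trial(
        10,
        np.linspace(0.05, 1.2, 10),
        seed=7,
        base_spec=small_spec,
        vary_structure=False,
    )


def angular_error_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees between two stain vectors."""
    c = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
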