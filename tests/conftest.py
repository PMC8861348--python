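import numpy as np
import pytest

from mrisct.phantom import PhantomSpec, generate_phantom, scaled_organ_geometry


@pytest.fixture(scope="session")
def default_case():
    """One seeded phantom with default (noisy, biased) rendering."""
    return generate_phantom(PhantomSpec(gas_pocket=True), seed=1)


@pytest.fixture(scope="session")
def clean_case():
    """Noise-free, bias-free phantom: every class renders at its exact mean."""
    spec = PhantomSpec(noise_sd={"ct": 0.0, "mri": 0.0}, bias_field_amplitude=0.0)
    return generate_phantom(spec, seed=2)


@pytest.fixture(scope="session")
def small_spec():
    """Compact grid (scaled anatomy) used by dose/gamma tests for speed."""
    return PhantomSpec(
        grid_shape=(32, 48, 48),
        spacing=(5.0, 5.0, 5.0),
        organ_geometry=scaled_organ_geometry(0.85),
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    return 2.0 * np.sum(a & b) / (a.sum() + b.sum())
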