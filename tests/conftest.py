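"""Shared fixtures: small deterministic phantoms and helper builders."""
import numpy as np
import pytest

from popatlas.register import DisplacementField
from popatlas.synthpop import SynthParams, make_phantom
from popatlas.volio import LabelMap, RegionTable


@pytest.fixture(scope="session")
def phantom32():
    """Noiseless 32^3 default phantom (volume, labels)."""
    p = SynthParams(grid_shape=(32, 32, 32), noise_scale=0.0, seed=5)
    return make_phantom(p)


@pytest.fixture(scope="session")
def noisy_phantom32():
    """32^3 default phantom with per-region noise (volume, labels)."""
    p = SynthParams(grid_shape=(32, 32, 32), seed=5)
    return make_phantom(p)


@pytest.fixture(scope="session")
def phantom48():
    """Default 48^3 phantom with per-region noise (volume, labels)."""
    p = SynthParams(seed=1)
    return make_phantom(p)


@pytest.fixture
def tiny_regions():
    return RegionTable.from_rows(
        [
            (1, "ring", "cortical", "midline"),
            (2, "core", "deep_gray", "midline"),
            (3, "shell", "white_matter", "midline"),
            (4, "pad", "other", "midline"),
            (5, "spare", "other", "midline"),
            (6, "extra", "other", "midline"),
        ]
    )


@pytest.fixture
def random_labelmap_factory(tiny_regions):
    """Seeded random label maps sharing one region table."""

    def make(seed, shape=(16, 16, 16), n_labels=6):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, n_labels + 1, size=shape).astype(np.int32)
        return LabelMap(labels, tiny_regions)

    return make


def sinusoidal_field(shape, amplitude=2.0, wavelength=32.0):
    """Smooth deterministic displacement field with peak norm `amplitude`."""
    idx = np.indices(shape)
    L = wavelength
    vec = np.stack(
        [
            np.sin(2 * np.pi * idx[1] / L) * np.cos(2 * np.pi * idx[2] / L),
            np.sin(2 * np.pi * idx[2] / L) * np.cos(2 * np.pi * idx[0] / L),
            np.sin(2 * np.pi * idx[0] / L) * np.cos(2 * np.pi * idx[1] / L),
        ],
        axis=-1,
    )
    vec *= amplitude / np.sqrt((vec**2).sum(-1)).max()
    return DisplacementField(vec)
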