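import numpy as np
import pytest

from cortibreak import (
    ChannelSpec,
    PhantomSpec,
    auto_contour,
    binarize_bone,
    build_cortical_mask,
    detect_interruptions,
    generate_phantom,
)
from cortibreak.phantom import fig2_gallery_channels


@pytest.fixture(scope="session")
def fig2_phantom():
    """Noise-free phantom with the six canonical channel configurations."""
    spec = PhantomSpec(channels=fig2_gallery_channels())
    return spec, *generate_phantom(spec)


@pytest.fixture(scope="session")
def fig2_result(fig2_phantom):
    """End-to-end detection on the noise-free six-channel phantom."""
    _, gray, truth = fig2_phantom
    solid = auto_contour(gray)
    bone = binarize_bone(gray, contour=solid)
    mask = build_cortical_mask(solid)
    return truth, solid, bone, mask, detect_interruptions(bone, mask)


@pytest.fixture(scope="session")
def small_sphere_phantom():
    """Small spherical-shell phantom with one minimal through-channel."""
    spec = PhantomSpec(
        shape=(48, 48, 48),
        geometry="spherical_shell",
        channels=[ChannelSpec(0, +1, "plus_cross", 3, "through", (23, 23))],
    )
    return spec, *generate_phantom(spec)


def random_solid(rng, shape):
    """A random blobby solid: union of a few balls, for oracle tests."""
    z, y, x = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij", sparse=True)
    solid = np.zeros(shape, dtype=bool)
    for _ in range(rng.integers(1, 4)):
        c = rng.uniform(0.3, 0.7, 3) * np.array(shape)
        r = rng.uniform(0.2, 0.38) * min(shape)
        solid |= (z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2 <= r * r
    return solid
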