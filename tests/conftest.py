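"""Shared fixtures: small seeded phantoms reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from heteromap import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(PhantomSpec(seed=42, noise_sigma=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_level_images(n_images: int, max_size: int = 8, max_levels: int = 4, seed: int = 0):
    """Battery of discretized images + masks for the texture oracles."""
    rng = np.random.default_rng(seed)
    battery = []
    for _ in range(n_images):
        h = int(rng.integers(2, max_size + 1))
        w = int(rng.integers(2, max_size + 1))
        ng = int(rng.integers(2, max_levels + 1))
        lev = rng.integers(1, ng + 1, size=(h, w))
        if rng.random() < 0.5:
            mask = np.ones((h, w), dtype=bool)
        else:
            mask = rng.random((h, w)) < 0.75
            if not mask.any():
                mask[h // 2, w // 2] = True
        battery.append((lev, mask, ng))
    # crafted edge cases
    battery.append((np.ones((3, 3), dtype=int), np.ones((3, 3), dtype=bool), 2))
    battery.append((np.array([[1, 2], [1, 2]]), np.ones((2, 2), dtype=bool), 2))
    alt = np.indices((5, 5)).sum(axis=0) % 2 + 1
    battery.append((alt, np.ones((5, 5), dtype=bool), 2))
    single = np.zeros((4, 4), dtype=bool)
    single[1, 2] = True
    battery.append((np.full((4, 4), 3), single, 4))
    return battery
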