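"""Shared fixtures: small synthetic mosaics and patch sets.

Training-related fixtures are session-scoped because a CPU U-net fit is the
expensive step of the suite; everything is seeded so the session is
reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest

import membrain as mb
from membrain.experiments import DOMAIN_A, DOMAIN_B, domain_patches, membrane_f1  # noqa: F401
from membrain.nn import UNetSegmenter


@pytest.fixture(scope="session")
def mosaic():
    """Default 256x256, 12-cell mosaic triple (em, instances, membrane)."""
    return mb.generate_mosaic(mb.MosaicSpec(rng_seed=3))


@pytest.fixture(scope="session")
def domain_a_train():
    return domain_patches(8, DOMAIN_A, seed0=1)


@pytest.fixture(scope="session")
def domain_a_test():
    return domain_patches(2, DOMAIN_A, seed0=99)


@pytest.fixture(scope="session")
def trained_segmenter(domain_a_train) -> UNetSegmenter:
    """A U-net fitted on domain-A fixtures; shared across learning tests."""
    X, y = domain_a_train
    est = UNetSegmenter(
        depth=2, base_channels=8, n_classes=2, epochs=15, batch_size=8,
        lr=0.05, random_state=0,
    )
    est.fit(X, y)
    return est


@pytest.fixture()
def tiny_unet():
    """A throwaway small network for fast structural tests."""
    from membrain.nn import UNetConfig, build_unet

    return build_unet(UNetConfig(depth=2, base_channels=2, n_classes=2), 0)
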