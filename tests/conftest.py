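import numpy as np
import pytest

from lossdiff.patchio import PatchManifest, PatchRecord
from lossdiff.synthgen import generate_patch_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """K=3 synthetic dataset, no injected noise: manifest + image store."""
    manifest, store, mask = generate_patch_dataset(
        K=3, n_per_class=60, size=32, difficulty=0.2, noise_rate=0.0, seed=7
    )
    return manifest, store, mask


@pytest.fixture(scope="session")
def noisy_dataset():
    """K=3 synthetic dataset with 30% symmetric train-label noise."""
    return generate_patch_dataset(
        K=3, n_per_class=60, size=32, difficulty=0.2, noise_rate=0.3, seed=11
    )


def make_flat_manifest(n: int, K: int = 2, n_slides: int = 10, split: str = "train"):
    """Minimal manifest of n records spread over slides, single split."""
    records = [
        PatchRecord(
            patch_id=f"p{i:05d}",
            slide_id=f"s{i % n_slides}",
            x=0,
            y=0,
            size=32,
            label=i % K,
            split=split,
        )
        for i in range(n)
    ]
    return PatchManifest(records, [f"c{k}" for k in range(K)])


@pytest.fixture
def flat_manifest():
    return make_flat_manifest
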