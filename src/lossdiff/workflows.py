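"""End-to-end experiment drivers built from the library modules.

These functions wire the synthetic generator, noise injection, the
denoising training loop and the evaluation suite into the standard
experiment: corrupt a known fraction of training labels, train a baseline
and a filtered model from identical initializations, and compare their
accuracy on the clean test split plus how precisely the filter recovered
the injected noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import SoftmaxNet
from .denoise import FilterPolicy, TrainConfig, TrainResult, train_lossdiff
from .evalmod import evaluate
from .noise import NoiseMask, noise_recovery_metrics
from .patchio import ImageStore, PatchManifest
from .synthgen import generate_patch_dataset


@dataclass
class ExperimentResult:
    baseline: TrainResult
    denoised: TrainResult
    baseline_test_accuracy: float
    denoised_test_accuracy: float
    recovery: dict
    noise_mask: NoiseMask


def _test_scores(result: TrainResult, manifest: PatchManifest, store: ImageStore):
    test = manifest.subset("test")
    scores = result.classifier.predict(store.batch(test))
    truths = np.array([r.label for r in test])
    return scores, truths


def run_noise_experiment(
    K: int = 3,
    n_per_class: int = 500,
    size: int = 64,
    difficulty: float = 0.2,
    noise_rate: float = 0.3,
    seed: int = 0,
    policy: FilterPolicy | None = None,
    config: TrainConfig | None = None,
) -> ExperimentResult:
    """Baseline vs filtered training on one synthetic noisy dataset.

    Both models start from the same seeded initialization and see the same
    seeded batch order, so the only difference is the in-loop filtering.
    Test accuracy is measured on the *clean* test split (noise only ever
    touches the train split).
    """
    policy = policy or FilterPolicy()
    config = config or TrainConfig(epochs=10, seed=seed)
    manifest, store, mask = generate_patch_dataset(
        K=K,
        n_per_class=n_per_class,
        size=size,
        difficulty=difficulty,
        noise_rate=noise_rate,
        seed=seed,
    )
    base = train_lossdiff(
        manifest, store, SoftmaxNet(K, seed=config.seed), None, config
    )
    filt = train_lossdiff(
        manifest, store, SoftmaxNet(K, seed=config.seed), policy, config
    )
    n_train = len(manifest.subset("train"))
    acted = filt.discarded_ids if policy.mode == "discard" else filt.flipped_ids
    recovery = noise_recovery_metrics(acted, mask, n_train)

    base_scores, truths = _test_scores(base, manifest, store)
    filt_scores, _ = _test_scores(filt, manifest, store)
    return ExperimentResult(
        baseline=base,
        denoised=filt,
        baseline_test_accuracy=evaluate(base_scores, truths).accuracy,
        denoised_test_accuracy=evaluate(filt_scores, truths).accuracy,
        recovery=recovery,
        noise_mask=mask,
    )
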