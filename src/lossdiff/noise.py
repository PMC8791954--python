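"""Synthetic symmetric label noise and recovery metrics.

Noise-robustness experiments corrupt a known fraction of training labels and
then ask how well a filtering method finds the corrupted samples.  Flip
counts are exact (``round(rate * n_train)`` samples chosen by a seeded
permutation) rather than per-sample Bernoulli draws, so the stated
percentages hold exactly and every run is reproducible.  In the binary case
a flip goes to the opposite class; with K > 2 classes the new label is drawn
uniformly from the other K - 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .patchio import PatchManifest


@dataclass(frozen=True)
class NoiseSpec:
    rate: float
    seed: int = 0
    scheme: str = "symmetric"

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate < 1.0:
            raise ValueError("noise rate must lie in [0, 1)")
        if self.scheme != "symmetric":
            raise ValueError(f"unsupported noise scheme {self.scheme!r}")


@dataclass
class NoiseMask:
    """Bookkeeping of which train patches were flipped and from what."""

    rate: float
    seed: int
    flips: dict[str, tuple[int, int]] = field(default_factory=dict)  # id -> (from, to)

    @property
    def flipped_ids(self) -> set[str]:
        return set(self.flips)

    @property
    def original_labels(self) -> dict[str, int]:
        return {pid: src for pid, (src, _dst) in self.flips.items()}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rate": self.rate,
            "seed": self.seed,
            "flips": [
                {"patch_id": pid, "from": src, "to": dst}
                for pid, (src, dst) in self.flips.items()
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NoiseMask":
        payload = json.loads(Path(path).read_text())
        flips = {
            f["patch_id"]: (int(f["from"]), int(f["to"])) for f in payload["flips"]
        }
        return cls(rate=payload["rate"], seed=payload["seed"], flips=flips)


def inject_symmetric_noise(
    manifest: PatchManifest, spec: NoiseSpec
) -> tuple[PatchManifest, NoiseMask]:
    """Flip ``round(rate * n_train)`` training labels; val/test untouched.

    Flipped records get ``clean_label`` set to the original class (so
    ``is_noisy`` becomes true); the returned mask supports exact restoration.
    """
    k = len(manifest.classes)
    if k < 2:
        raise ValueError("need at least 2 classes to inject label noise")
    train_idx = [i for i, r in enumerate(manifest.records) if r.split == "train"]
    n_train = len(train_idx)
    n_flip = int(np.rint(spec.rate * n_train))
    if n_flip >= n_train and n_flip > 0:
        raise ValueError(f"rate {spec.rate} would flip all {n_train} train records")
    rng = np.random.default_rng(spec.seed)
    chosen = [train_idx[i] for i in rng.permutation(n_train)[:n_flip]]
    records = list(manifest.records)
    mask = NoiseMask(rate=spec.rate, seed=spec.seed)
    for idx in chosen:
        rec = records[idx]
        if k == 2:
            new = 1 - rec.label
        else:
            others = [c for c in range(k) if c != rec.label]
            new = int(others[rng.integers(len(others))])
        records[idx] = replace(rec, label=new, clean_label=rec.label, is_noisy=True)
        mask.flips[rec.patch_id] = (rec.label, new)
    noisy = PatchManifest(records, list(manifest.classes), manifest.provenance)
    return noisy, mask


def restore_labels(manifest: PatchManifest, mask: NoiseMask) -> PatchManifest:
    """Invert an injection: put every flipped record's original label back."""
    records = []
    for rec in manifest.records:
        if rec.patch_id in mask.flips:
            src, _dst = mask.flips[rec.patch_id]
            records.append(replace(rec, label=src, clean_label=None, is_noisy=None))
        else:
            records.append(rec)
    return PatchManifest(records, list(manifest.classes), manifest.provenance)


def noise_recovery_metrics(
    acted_ids: set[str], mask: NoiseMask, n_train: int
) -> dict[str, float | None]:
    """Precision/recall/enrichment of a filter's actions against injected noise.

    ``enrichment`` is precision divided by the noise prior ``|flipped|/n_train``
    — how much better than chance the filter concentrates on corrupted
    samples.  Undefined quantities (empty acted set, empty mask) are reported
    as ``None`` rather than zero.
    """
    flipped = mask.flipped_ids
    hit = len(acted_ids & flipped)
    precision = hit / len(acted_ids) if acted_ids else None
    recall = hit / len(flipped) if flipped else None
    prior = len(flipped) / n_train if n_train else 0.0
    enrichment = precision / prior if (precision is not None and prior > 0) else None
    return {"precision": precision, "recall": recall, "enrichment": enrichment}
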