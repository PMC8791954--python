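"""Pluggable classifier contract and the reference backbone.

The denoising method is architecture-agnostic: it only needs a classifier
that exposes a per-sample cross-entropy training step, probabilistic
predictions, and penultimate-layer features, with seedable initialization
(:class:`ClassifierContract`).  Heavy pretrained CNN backbones plug in
through the same surface.

The reference backbone shipped here (:class:`SoftmaxNet`) is a deliberately
small, fully deterministic numpy network: a fixed average-pooling stem
(per-cell channel means plus a per-cell contrast channel) feeding a one-
hidden-layer ReLU perceptron with a softmax head, trained with Adam.  It is
CPU-trainable in seconds on the synthetic patches, yet has enough capacity
to memorize corrupted labels over a few epochs — the overfitting behaviour
the loss-based filter exploits.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np


@runtime_checkable
class ClassifierContract(Protocol):
    """Operations the training loop requires of any backbone."""

    n_classes: int

    def train_step(
        self, images: np.ndarray, labels: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """One optimizer step; returns (per-sample CE losses, predicted labels)
        evaluated on the model state *before* the update."""
        ...

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Class scores per sample (rows sum to 1)."""
        ...

    def features(self, images: np.ndarray) -> np.ndarray:
        """Penultimate-layer feature vectors."""
        ...


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SoftmaxNet:
    """Average-pool stem + 1-hidden-layer ReLU MLP with a softmax head.

    Parameters
    ----------
    n_classes:
        Size of the softmax head.
    pool:
        The stem averages the image over a ``pool x pool`` grid of cells;
        features are the 3 per-cell channel means plus the per-cell grayscale
        standard deviation (``4 * pool**2`` inputs).  Image height/width must
        be divisible by ``pool`` (excess rows/columns are cropped).
    hidden:
        Width of the ReLU layer (the feature vectors ``features`` returns).
    learning_rate:
        Adam step size (default matches the training default of 1e-3).
    whiten_power:
        Exponent of the spectral rescaling applied by :meth:`calibrate`:
        each principal direction of the reference features is scaled by
        ``lambda**-whiten_power`` (0 = centering only, 1 = full whitening).
        The default 0.5 balances the two failure modes: raw features are so
        ill-conditioned that gradient training cannot memorize at all, while
        fully whitened features are memorized instantly, clean and corrupted
        labels alike.  Half-power whitening lets the shared class structure
        fit within a couple of epochs while label noise is memorized slowly
        afterwards — the loss gap the filter needs.
    seed:
        Weight initialization seed; identical seeds give bit-identical runs.
    """

    def __init__(
        self,
        n_classes: int,
        pool: int = 16,
        hidden: int = 512,
        learning_rate: float = 1e-3,
        whiten_power: float = 0.5,
        seed: int = 0,
    ) -> None:
        self.n_classes = int(n_classes)
        self.pool = int(pool)
        self.hidden = int(hidden)
        self.learning_rate = float(learning_rate)
        rng = np.random.default_rng(seed)
        d = 4 * pool * pool
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, hidden))
        self.b1 = np.zeros(hidden)
        self.W2 = rng.normal(0.0, np.sqrt(2.0 / hidden), size=(hidden, n_classes))
        self.b2 = np.zeros(n_classes)
        # Adam state
        self._t = 0
        self._m = [np.zeros_like(p) for p in (self.W1, self.b1, self.W2, self.b2)]
        self._v = [np.zeros_like(p) for p in (self.W1, self.b1, self.W2, self.b2)]
        self.whiten_power = float(whiten_power)
        # feature conditioning (set by calibrate)
        self._mu: np.ndarray | None = None
        self._proj: np.ndarray | None = None

    def calibrate(self, images: np.ndarray) -> None:
        """Fit the feature-conditioning transform on a reference image set.

        Centers the stem features and rescales each principal direction by
        ``lambda**-whiten_power`` (lambda = singular value of the centered
        reference matrix, floored at 1e-4 of the largest).  Typically called
        once on the initial training split; deterministic for a fixed image
        set.
        """
        raw = self._raw_features(images)
        self._mu = raw.mean(axis=0)
        if self.whiten_power == 0.0:
            self._proj = None
            return
        centered = raw - self._mu
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        lam = s / np.sqrt(max(len(raw) - 1, 1))
        lam = np.maximum(lam, 1e-4 * lam.max() + 1e-12)
        proj = vt.T * lam**-self.whiten_power
        if proj.shape[1] < raw.shape[1]:
            # fewer reference samples than features: keep the input width so
            # the first layer's shape is independent of the reference size
            pad = np.zeros((raw.shape[1], raw.shape[1] - proj.shape[1]))
            proj = np.hstack([proj, pad])
        self._proj = proj

    # -- stem -------------------------------------------------------------
    def _featurize(self, images: np.ndarray) -> np.ndarray:
        feats = self._raw_features(images)
        if self._mu is not None:
            feats = feats - self._mu
            if self._proj is not None:
                feats = feats @ self._proj
        return feats

    def _raw_features(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=float) / 255.0
        if x.ndim != 4 or x.shape[3] != 3:
            raise ValueError("expected N x H x W x 3 images")
        p = self.pool
        h = (x.shape[1] // p) * p
        w = (x.shape[2] // p) * p
        if h == 0 or w == 0:
            raise ValueError(f"images too small for pool={p}")
        x = x[:, :h, :w, :]
        cells = x.reshape(x.shape[0], p, h // p, p, w // p, 3)
        means = cells.mean(axis=(2, 4))                       # N, p, p, 3
        gray = cells.mean(axis=5)                             # N, p, h/p, p, w/p
        stds = gray.std(axis=(2, 4))                          # N, p, p
        feats = np.concatenate(
            [means.reshape(x.shape[0], -1), stds.reshape(x.shape[0], -1)], axis=1
        )
        return feats

    def _forward(self, feats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a1 = np.maximum(feats @ self.W1 + self.b1, 0.0)
        probs = _softmax(a1 @ self.W2 + self.b2)
        return a1, probs

    # -- contract ---------------------------------------------------------
    def predict(self, images: np.ndarray) -> np.ndarray:
        _, probs = self._forward(self._featurize(images))
        return probs

    def features(self, images: np.ndarray) -> np.ndarray:
        a1, _ = self._forward(self._featurize(images))
        return a1

    def per_sample_loss(self, probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
        return -np.log(np.clip(probs[np.arange(len(labels)), labels], 1e-12, None))

    def train_step(
        self, images: np.ndarray, labels: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        labels = np.asarray(labels, dtype=int)
        feats = self._featurize(images)
        a1, probs = self._forward(feats)
        losses = self.per_sample_loss(probs, labels)
        preds = probs.argmax(axis=1)

        n = len(labels)
        delta2 = probs.copy()
        delta2[np.arange(n), labels] -= 1.0
        delta2 /= n
        gW2 = a1.T @ delta2
        gb2 = delta2.sum(axis=0)
        delta1 = (delta2 @ self.W2.T) * (a1 > 0)
        gW1 = feats.T @ delta1
        gb1 = delta1.sum(axis=0)
        self._adam_update([gW1, gb1, gW2, gb2])
        return losses, preds

    def _adam_update(
        self, grads: list[np.ndarray], beta1: float = 0.9, beta2: float = 0.999
    ) -> None:
        self._t += 1
        params = [self.W1, self.b1, self.W2, self.b2]
        for i, (p, g) in enumerate(zip(params, grads)):
            self._m[i] = beta1 * self._m[i] + (1 - beta1) * g
            self._v[i] = beta2 * self._v[i] + (1 - beta2) * g * g
            mhat = self._m[i] / (1 - beta1**self._t)
            vhat = self._v[i] / (1 - beta2**self._t)
            p -= self.learning_rate * mhat / (np.sqrt(vhat) + 1e-8)
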