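"""Loss-based patch label denoising (the LossDiff training loop).

The idea: a network fits clean patches early and confidently, while noisy
(mislabeled) patches are learned late and with persistently higher loss.
During training we keep per-class running averages of the cross-entropy
loss of *correctly classified* samples only.  Once a short warm-up has
accumulated statistics, any sample whose loss reaches ``alpha`` times its
class's running average triggers the abstain condition and is acted on:

* **discard** mode removes the sample from the training set permanently
  (the literal cleaning rule additionally requires the sample to be
  correctly classified, i.e. the model already reproduces its possibly
  corrupted label — a memorized sample; the ``require_correct`` toggle
  exposes the broader variant);
* **flip** mode relabels a high-loss *misclassified* sample with the
  model's current prediction and keeps it.

The multiplicative threshold ``alpha`` trades aggressiveness against the
risk of throwing away genuinely difficult cases.  The training set shrinks
(or is relabeled) epoch by epoch, and the model is effectively retrained on
a new version of the data every epoch; the surviving records are the
cleaned dataset D_c.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .classifier import ClassifierContract
from .patchio import ImageStore, PatchManifest, PatchRecord


@dataclass
class ClassLossTracker:
    """Per-class running sums/counts of correctly-classified losses.

    ``k`` counts training iterations (batches).  The class average is the
    mean of every loss recorded for that class so far; with
    ``scope="global"`` all classes pool into a single average.  A class with
    no recorded loss has no statistics and can never trigger filtering.
    """

    n_classes: int
    scope: str = "per_class"
    sums: np.ndarray = field(init=False)
    counts: np.ndarray = field(init=False)
    k: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if self.scope not in ("per_class", "global"):
            raise ValueError(f"unknown tracker scope {self.scope!r}")
        self.sums = np.zeros(self.n_classes)
        self.counts = np.zeros(self.n_classes, dtype=int)

    def class_average(self, label: int) -> float | None:
        """Running mean loss for the class (or pooled, in global scope).

        Returns ``None`` — the no-statistics marker — while no correctly
        classified loss has been recorded yet.
        """
        if self.scope == "global":
            total = int(self.counts.sum())
            return float(self.sums.sum() / total) if total else None
        if self.counts[label] == 0:
            return None
        return float(self.sums[label] / self.counts[label])


@dataclass(frozen=True)
class BatchOutcome:
    """Per-sample results of one forward pass on a minibatch."""

    patch_ids: tuple[str, ...]
    losses: np.ndarray
    y: np.ndarray
    y_hat: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.losses < 0):
            raise ValueError("per-sample losses must be nonnegative")
        n = len(self.patch_ids)
        if not (len(self.losses) == len(self.y) == len(self.y_hat) == n):
            raise ValueError("batch outcome arrays must share one length")

    @property
    def correct(self) -> np.ndarray:
        return np.asarray(self.y) == np.asarray(self.y_hat)


@dataclass(frozen=True)
class FilterPolicy:
    """Filtering configuration.

    ``require_correct`` defaults to the mode's natural condition: in discard
    mode only correctly classified samples are removed; flip mode targets
    misclassified samples by construction, so the toggle is ignored there.
    """

    alpha: float = 1.0
    mode: str = "discard"
    warmup_epochs: int = 2
    require_correct: bool | None = None
    tracker_scope: str = "per_class"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.mode not in ("discard", "flip"):
            raise ValueError(f"unknown filter mode {self.mode!r}")
        if self.require_correct is None:
            object.__setattr__(self, "require_correct", self.mode == "discard")


@dataclass(frozen=True)
class FilterDecision:
    epoch: int
    iteration: int
    patch_id: str
    loss: float
    class_average: float | None
    alpha: float
    correct: bool
    action: str  # "keep" | "discard" | "flip" | "stale"
    new_label: int | None = None

    def to_json(self) -> str:
        d = {
            "epoch": self.epoch,
            "iteration": self.iteration,
            "patch_id": self.patch_id,
            "loss": self.loss,
            "class_average": self.class_average,
            "alpha": self.alpha,
            "correct": self.correct,
            "action": self.action,
            "new_label": self.new_label,
        }
        return json.dumps(d)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def update_tracker(tracker: ClassLossTracker, outcome: BatchOutcome) -> ClassLossTracker:
    """Record the losses of correctly classified samples; bump the batch count.

    Misclassified samples contribute nothing to the statistics.
    """
    correct = outcome.correct
    for label in np.unique(outcome.y[correct]):
        sel = correct & (outcome.y == label)
        tracker.sums[label] += float(outcome.losses[sel].sum())
        tracker.counts[label] += int(sel.sum())
    tracker.k += 1
    return tracker


def class_average(tracker: ClassLossTracker, label: int) -> float | None:
    return tracker.class_average(label)


def abstain_condition(loss: float, class_avg: float | None, alpha: float) -> bool:
    """True iff ``loss >= alpha * class_avg`` (inclusive boundary).

    A missing class average (no statistics yet) never triggers.
    """
    if loss < 0:
        raise ValueError("loss must be nonnegative")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if class_avg is None:
        return False
    return loss >= alpha * class_avg


def filter_batch(
    outcome: BatchOutcome,
    tracker: ClassLossTracker,
    policy: FilterPolicy,
    epoch: int = 0,
    iteration: int = 0,
) -> list[FilterDecision]:
    """Decide keep/discard/flip per sample against the pre-batch tracker state.

    The tracker must not yet include this batch: a sample's own loss should
    not inflate the threshold it is judged against.
    """
    decisions = []
    correct = outcome.correct
    for i, pid in enumerate(outcome.patch_ids):
        loss = float(outcome.losses[i])
        avg = tracker.class_average(int(outcome.y[i]))
        triggered = abstain_condition(loss, avg, policy.alpha)
        action, new_label = "keep", None
        if triggered:
            if policy.mode == "discard":
                if correct[i] or not policy.require_correct:
                    action = "discard"
            else:  # flip mode targets high-loss misclassified samples
                if not correct[i]:
                    action, new_label = "flip", int(outcome.y_hat[i])
        decisions.append(
            FilterDecision(
                epoch=epoch,
                iteration=iteration,
                patch_id=pid,
                loss=loss,
                class_average=avg,
                alpha=policy.alpha,
                correct=bool(correct[i]),
                action=action,
                new_label=new_label,
            )
        )
    return decisions


def apply_decisions(
    manifest: PatchManifest, decisions: Sequence[FilterDecision], mode: str
) -> tuple[PatchManifest, list[FilterDecision]]:
    """Apply non-keep decisions to the manifest's train split.

    Discards remove records permanently; flips relabel in place.  A discard
    of an already-removed record is a no-op logged with action ``stale``.
    Decisions touching val/test records are a hard error.
    """
    by_id = {r.patch_id: i for i, r in enumerate(manifest.records)}
    records = list(manifest.records)
    removed: set[str] = set()
    log: list[FilterDecision] = []
    for dec in decisions:
        if dec.action == "keep":
            continue
        idx = by_id.get(dec.patch_id)
        if idx is None or dec.patch_id in removed:
            log.append(replace(dec, action="stale"))
            continue
        rec = records[idx]
        if rec.split != "train":
            raise ValueError(
                f"decision on non-train patch {dec.patch_id!r} ({rec.split})"
            )
        if dec.action == "discard":
            removed.add(dec.patch_id)
        elif dec.action == "flip":
            records[idx] = replace(rec, label=int(dec.new_label), is_noisy=None)
        else:
            raise ValueError(f"unknown action {dec.action!r}")
        log.append(dec)
    kept = [r for r in records if r.patch_id not in removed]
    return PatchManifest(kept, list(manifest.classes), manifest.provenance), log


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    classifier: ClassifierContract
    cleaned_manifest: PatchManifest      # D_c: surviving / relabeled records
    decisions: list[FilterDecision]      # non-keep actions, in order
    metrics: list[dict]                  # one entry per epoch
    tracker: ClassLossTracker

    @property
    def n_discarded(self) -> int:
        return sum(1 for d in self.decisions if d.action == "discard")

    @property
    def n_flipped(self) -> int:
        return sum(1 for d in self.decisions if d.action == "flip")

    @property
    def discarded_ids(self) -> set[str]:
        return {d.patch_id for d in self.decisions if d.action == "discard"}

    @property
    def flipped_ids(self) -> set[str]:
        return {d.patch_id for d in self.decisions if d.action == "flip"}

    def write_decision_log(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(d.to_json() + "\n" for d in self.decisions)
        )

    def write_metrics(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.metrics, indent=1))


def _evaluate(
    classifier: ClassifierContract,
    records: Sequence[PatchRecord],
    store: ImageStore,
    batch_size: int = 512,
) -> tuple[float, float]:
    if not records:
        return math.nan, math.nan
    losses, correct = [], []
    for start in range(0, len(records), batch_size):
        chunk = records[start : start + batch_size]
        probs = classifier.predict(store.batch(chunk))
        y = np.array([r.label for r in chunk])
        losses.append(-np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)))
        correct.append(probs.argmax(axis=1) == y)
    return float(np.concatenate(losses).mean()), float(np.concatenate(correct).mean())


def train_lossdiff(
    manifest: PatchManifest,
    store: ImageStore,
    classifier: ClassifierContract,
    policy: FilterPolicy | None,
    config: TrainConfig,
    batch_callback=None,
) -> TrainResult:
    """Epoch-wise training with in-loop loss-based filtering.

    Per epoch the surviving train records are shuffled (seeded) and consumed
    in minibatches.  Each batch is (1) used for one optimizer step, yielding
    per-sample losses and predictions, (2) filtered against the tracker
    state accumulated from *previous* batches (once ``warmup_epochs`` have
    passed), (3) applied — discards take effect from the next epoch's
    shuffle onward, flips immediately — and (4) recorded into the tracker.
    ``policy=None`` disables filtering entirely (the plain baseline).
    ``batch_callback``, if given, receives every :class:`BatchOutcome` right
    after the tracker update — useful for independent bookkeeping.

    Returns the trained classifier, the cleaned manifest D_c (surviving and
    possibly relabeled train records plus the untouched val/test records),
    the ordered non-keep decision log, and per-epoch metrics.
    """
    train = [r for r in manifest.records if r.split == "train"]
    val = [r for r in manifest.records if r.split == "val"]
    if not train:
        raise ValueError("train split is empty")
    if hasattr(classifier, "calibrate"):
        classifier.calibrate(store.batch(train))
    state: dict[str, PatchRecord] = {r.patch_id: r for r in train}
    alive: list[str] = [r.patch_id for r in train]
    tracker = ClassLossTracker(
        len(manifest.classes),
        scope=policy.tracker_scope if policy else "per_class",
    )
    rng = np.random.default_rng(config.seed)
    log: list[FilterDecision] = []
    metrics: list[dict] = []
    iteration = 0

    for epoch in range(config.epochs):
        order = rng.permutation(len(alive))
        epoch_ids = [alive[i] for i in order]
        removed_now: set[str] = set()
        n_disc = n_flip = 0
        loss_sum = 0.0
        correct_sum = 0
        seen = 0
        for start in range(0, len(epoch_ids), config.batch_size):
            batch_ids = epoch_ids[start : start + config.batch_size]
            batch = [state[pid] for pid in batch_ids]
            images = store.batch(batch)
            labels = np.array([r.label for r in batch])
            losses, preds = classifier.train_step(images, labels)
            iteration += 1
            outcome = BatchOutcome(tuple(batch_ids), losses, labels, preds)
            if policy is not None and epoch >= policy.warmup_epochs:
                decisions = filter_batch(outcome, tracker, policy, epoch, iteration)
                for dec in decisions:
                    if dec.action == "discard":
                        removed_now.add(dec.patch_id)
                        n_disc += 1
                        log.append(dec)
                    elif dec.action == "flip":
                        state[dec.patch_id] = replace(
                            state[dec.patch_id],
                            label=int(dec.new_label),
                            is_noisy=None,
                        )
                        n_flip += 1
                        log.append(dec)
            update_tracker(tracker, outcome)
            if batch_callback is not None:
                batch_callback(outcome)
            loss_sum += float(losses.sum())
            correct_sum += int((preds == labels).sum())
            seen += len(batch)
        alive = [pid for pid in alive if pid not in removed_now]
        if not alive:
            raise RuntimeError(
                f"all train records discarded by epoch {epoch}; "
                "alpha is too aggressive for this data"
            )
        val_loss, val_acc = _evaluate(classifier, val, store)
        metrics.append(
            {
                "epoch": epoch,
                "train_loss": loss_sum / seen,
                "val_loss": val_loss,
                "train_acc": correct_sum / seen,
                "val_acc": val_acc,
                "n_train_remaining": len(alive),
                "n_discarded": n_disc,
                "n_flipped": n_flip,
            }
        )

    survivors = {pid for pid in alive}
    cleaned_records = [
        state[r.patch_id] if r.patch_id in survivors else r
        for r in manifest.records
        if r.split != "train" or r.patch_id in survivors
    ]
    cleaned = PatchManifest(
        cleaned_records, list(manifest.classes), manifest.provenance
    )
    return TrainResult(classifier, cleaned, log, metrics, tracker)
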