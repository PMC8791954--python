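"""Evaluation suite: accuracy, confusion matrices, ROC-AUC, McNemar,
t-SNE feature export and slide heatmap reconstruction.

Accuracy, the confusion matrix, one-vs-rest ROC-AUC (per-class, micro and
macro averaged) and the McNemar test are implemented directly here — each
is simple enough to state exactly, and the test suite cross-checks them
against independent reference implementations.  AUC uses the rank statistic
with midranks for ties, which equals the trapezoidal area under the full
threshold-sweep ROC curve.  The McNemar test switches between the
continuity-corrected chi-square form and the exact two-sided binomial form
at the conventional small-sample boundary of 25 discordant pairs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

#: heatmap cell value for grid positions not covered by any patch
BACKGROUND_CELL = -1

#: per-class overlay colors (malignant red, dysplasia blue, uncategorized
#: yellow, benign green — the usual annotation convention), cycled for K > 4
CLASS_COLORS = ((220, 30, 30), (30, 30, 200), (230, 200, 20), (30, 160, 60))


def accuracy(predictions, truths) -> float:
    """Percent of samples whose predicted label equals the truth."""
    p = np.asarray(predictions)
    t = np.asarray(truths)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("predictions and truths must be equal-length, non-empty")
    return 100.0 * float((p == t).mean())


def confusion_matrix(predictions, truths, K: int) -> np.ndarray:
    """K x K counts; entry (i, j) = samples with truth i predicted j."""
    p = np.asarray(predictions, dtype=int)
    t = np.asarray(truths, dtype=int)
    if p.shape != t.shape:
        raise ValueError("length mismatch")
    if p.size and (p.min() < 0 or p.max() >= K or t.min() < 0 or t.max() >= K):
        raise ValueError(f"labels outside [0, {K})")
    cm = np.zeros((K, K), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


def _binary_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    """Mann-Whitney AUC with midranks for ties (= trapezoidal ROC area)."""
    n_pos = int(positives.sum())
    n_neg = len(positives) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative samples")
    ranks = stats.rankdata(scores)  # midranks on ties
    rank_sum = float(ranks[positives].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_auc(
    class_scores: np.ndarray, truths, averaging: str = "per_class"
) -> float | dict[int, float]:
    """One-vs-rest ROC-AUC from per-sample class-score vectors.

    ``per_class`` returns {class: AUC} (classes absent from the truths are
    omitted); ``micro`` pools the binarized labels and scores of all classes
    into one ranking (with two classes the label indicator binarizes to the
    single positive column, so binary micro equals the positive-class AUC);
    ``macro`` is the unweighted mean of the per-class AUCs (absent classes
    skipped with a warning).
    """
    scores = np.asarray(class_scores, dtype=float)
    t = np.asarray(truths, dtype=int)
    if scores.ndim != 2 or scores.shape[0] != t.shape[0]:
        raise ValueError("class_scores must be n_samples x K aligned with truths")
    K = scores.shape[1]
    if K < 2:
        raise ValueError("need at least 2 classes")

    if averaging == "micro":
        if K == 2:
            return _binary_auc(scores[:, 1], t == 1)
        onehot = np.zeros_like(scores, dtype=bool)
        onehot[np.arange(len(t)), t] = True
        return _binary_auc(scores.ravel(), onehot.ravel())

    per_class: dict[int, float] = {}
    for c in range(K):
        pos = t == c
        if pos.all() or not pos.any():
            if averaging == "macro":
                warnings.warn(
                    f"class {c} absent from truths; skipped in macro average",
                    stacklevel=2,
                )
            continue
        per_class[c] = _binary_auc(scores[:, c], pos)
    if averaging == "per_class":
        return per_class
    if averaging == "macro":
        if not per_class:
            raise ValueError("no class with both positives and negatives")
        return float(np.mean(list(per_class.values())))
    raise ValueError(f"unknown averaging {averaging!r}")


def mcnemar(preds_a, preds_b, truths, variant: str = "auto") -> dict:
    """Paired comparison of two classifiers on the same samples.

    ``b`` = samples A got right and B wrong, ``c`` = the reverse.  With 25
    or more discordant pairs the continuity-corrected statistic
    ``(|b-c|-1)^2 / (b+c)`` is referred to chi-square(1); below that, the
    exact two-sided binomial test on ``min(b, c)`` of ``b+c`` trials at 1/2
    is used.  ``variant`` forces one branch ("chi2" or "exact") instead of
    the count-based rule.  ``b + c = 0`` is degenerate: p = 1, statistic 0.
    """
    if variant not in ("auto", "chi2", "exact"):
        raise ValueError(f"unknown variant {variant!r}")
    a = np.asarray(preds_a)
    b_arr = np.asarray(preds_b)
    t = np.asarray(truths)
    if not (a.shape == b_arr.shape == t.shape):
        raise ValueError("preds_a, preds_b and truths must share a shape")
    a_ok = a == t
    b_ok = b_arr == t
    b = int((a_ok & ~b_ok).sum())
    c = int((~a_ok & b_ok).sum())
    n = b + c
    if n == 0:
        return {"statistic": 0.0, "p_value": 1.0, "b": b, "c": c,
                "method": "degenerate"}
    if variant == "chi2" or (variant == "auto" and n >= 25):
        statistic = (abs(b - c) - 1) ** 2 / n
        p = float(stats.chi2.sf(statistic, df=1))
        method = "chi2_continuity"
    else:
        statistic = float(min(b, c))
        p = float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5)))
        method = "exact_binomial"
    return {"statistic": float(statistic), "p_value": p, "b": b, "c": c,
            "method": method}


# ---------------------------------------------------------------------------
# report container
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    accuracy: float
    confusion: np.ndarray
    per_class_precision: list[float]
    per_class_recall: list[float]
    per_class_auc: dict[int, float]
    micro_auc: float
    macro_auc: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "per_class_precision": self.per_class_precision,
            "per_class_recall": self.per_class_recall,
            "per_class_auc": {str(k): v for k, v in self.per_class_auc.items()},
            "micro_auc": self.micro_auc,
            "macro_auc": self.macro_auc,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def confusion_tsv(self, path: str | Path, classes: list[str]) -> None:
        lines = ["truth\\pred\t" + "\t".join(classes)]
        for i, name in enumerate(classes):
            lines.append(name + "\t" + "\t".join(map(str, self.confusion[i])))
        Path(path).write_text("\n".join(lines) + "\n")


def evaluate(class_scores: np.ndarray, truths) -> EvalReport:
    """Full report from per-sample class scores and ground-truth labels."""
    scores = np.asarray(class_scores, dtype=float)
    t = np.asarray(truths, dtype=int)
    preds = scores.argmax(axis=1)
    K = scores.shape[1]
    cm = confusion_matrix(preds, t, K)
    with np.errstate(invalid="ignore"):
        prec = np.where(cm.sum(0) > 0, np.diag(cm) / np.maximum(cm.sum(0), 1), np.nan)
        rec = np.where(cm.sum(1) > 0, np.diag(cm) / np.maximum(cm.sum(1), 1), np.nan)
    return EvalReport(
        accuracy=accuracy(preds, t),
        confusion=cm,
        per_class_precision=[float(v) for v in prec],
        per_class_recall=[float(v) for v in rec],
        per_class_auc=roc_auc(scores, t, "per_class"),
        micro_auc=roc_auc(scores, t, "micro"),
        macro_auc=roc_auc(scores, t, "macro"),
    )


# ---------------------------------------------------------------------------
# slide heatmap reconstruction
# ---------------------------------------------------------------------------

def slide_heatmap(
    predictions,
    coords,
    slide_dims: tuple[int, int],
    patch_size: int,
) -> np.ndarray:
    """Reassemble patch predictions into a class-index grid over the slide.

    ``slide_dims`` is (width, height).  Cell (y // size, x // size) holds the
    predicted class of the patch anchored at tile-aligned (x, y); cells with
    no patch hold :data:`BACKGROUND_CELL`.  Duplicate patches for one cell
    are an error.
    """
    w, h = slide_dims
    rows = int(np.ceil(h / patch_size))
    cols = int(np.ceil(w / patch_size))
    grid = np.full((rows, cols), BACKGROUND_CELL, dtype=int)
    for pred, (x, y) in zip(predictions, coords):
        if x % patch_size or y % patch_size:
            raise ValueError(f"patch at ({x},{y}) is not tile-aligned")
        r, c = y // patch_size, x // patch_size
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"patch at ({x},{y}) outside slide bounds")
        if grid[r, c] != BACKGROUND_CELL:
            raise ValueError(f"duplicate patch for cell ({r},{c})")
        grid[r, c] = int(pred)
    return grid


def render_heatmap(grid: np.ndarray, cell_px: int = 8) -> np.ndarray:
    """RGB overlay of a heatmap grid (white background, per-class colors)."""
    rows, cols = grid.shape
    img = np.full((rows * cell_px, cols * cell_px, 3), 255, dtype=np.uint8)
    for r in range(rows):
        for c in range(cols):
            cls = grid[r, c]
            if cls == BACKGROUND_CELL:
                continue
            color = CLASS_COLORS[cls % len(CLASS_COLORS)]
            img[r * cell_px : (r + 1) * cell_px, c * cell_px : (c + 1) * cell_px] = color
    return img


# ---------------------------------------------------------------------------
# feature-space export
# ---------------------------------------------------------------------------

def tsne_export(features: np.ndarray, seed: int = 0) -> np.ndarray:
    """2-D t-SNE embedding of feature vectors (standard implementation,
    default parameters, fixed seed).

    Perplexity is auto-reduced (with a warning) when there are too few
    samples for the default of 30.
    """
    from sklearn.manifold import TSNE

    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 5:
        raise ValueError("need a 2-D feature matrix with at least 5 rows")
    perplexity = 30.0
    if x.shape[0] <= perplexity:
        perplexity = max(2.0, (x.shape[0] - 1) / 3.0)
        warnings.warn(
            f"too few samples for perplexity 30; reduced to {perplexity}",
            stacklevel=2,
        )
    emb = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    return emb.fit_transform(x)


def save_tsne_scatter(
    coords: np.ndarray, labels, classes: list[str], path: str | Path
) -> None:
    """Class-colored scatter plot of a t-SNE embedding, saved to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(6, 6))
    for c, name in enumerate(classes):
        sel = labels == c
        color = np.array(CLASS_COLORS[c % len(CLASS_COLORS)]) / 255.0
        ax.scatter(coords[sel, 0], coords[sel, 1], s=8, color=color, label=name)
    ax.legend()
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
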