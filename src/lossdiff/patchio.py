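"""Patch dataset model and slide-level plumbing.

Whole-slide images are far too large for a CNN, so they are processed as a
grid of fixed-size square patches.  This module holds the in-memory model of
a patch dataset (:class:`PatchRecord` / :class:`PatchManifest`), the tiling
and tissue-filtering steps that turn a slide into patches, annotation-based
labeling, slide-level (patient-level) train/val/test splitting, class
balancing, and I/O for the tab-separated manifest format and HDF5 patch
archives (PatchCamelyon layout: ``x`` = N x H x W x 3 uint8 images, ``y`` =
length-N labels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
from PIL import Image
from shapely.geometry import Point, Polygon, box

SPLITS = ("train", "val", "test")

#: background-pixel intensity threshold: a pixel is "white" (non-tissue)
#: when every channel is at or above this value
DEFAULT_BG_INTENSITY = 220
#: a tile is discarded when more than this fraction of its pixels is white
DEFAULT_MAX_BG_FRACTION = 0.7
#: minimum area overlap with an annotation region for a tile to inherit
#: the region's class
DEFAULT_OVERLAP_MIN = 0.5


class ManifestError(ValueError):
    """Malformed manifest file or violated manifest invariant."""


class ConfigurationError(ValueError):
    """Invalid split/balance configuration (e.g. an empty split)."""


@dataclass(frozen=True)
class PatchRecord:
    """One patch: its slide of origin, pixel position, label and split.

    ``clean_label`` records the pre-corruption label when synthetic label
    noise has been injected; ``is_noisy`` must then be consistent with it.
    """

    patch_id: str
    slide_id: str
    x: int
    y: int
    size: int
    label: int
    split: str
    image_ref: str = ""
    clean_label: int | None = None
    is_noisy: bool | None = None

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError(f"negative tile offset for {self.patch_id!r}")
        if self.size < 1:
            raise ValueError("patch size must be >= 1")
        if self.split not in SPLITS:
            raise ValueError(f"unknown split {self.split!r}")
        if self.clean_label is not None:
            noisy = self.clean_label != self.label
            if self.is_noisy is not None and self.is_noisy != noisy:
                raise ValueError(
                    f"is_noisy inconsistent with labels for {self.patch_id!r}"
                )
            object.__setattr__(self, "is_noisy", noisy)


@dataclass(frozen=True)
class AnnotationRegion:
    """A polygonal annotation on a slide, carrying a (non-benign) class."""

    slide_id: str
    polygon: tuple[tuple[float, float], ...]
    label: int

    def __post_init__(self) -> None:
        if len(self.polygon) < 3:
            raise ValueError("annotation polygon needs >= 3 vertices")

    def shapely(self) -> Polygon:
        return Polygon(self.polygon)


@dataclass
class PatchManifest:
    """Ordered collection of patch records plus the class vocabulary.

    This is the container for both the baseline (noisy) dataset D_b and the
    cleaned dataset D_c produced by filtering.
    """

    records: list[PatchRecord]
    classes: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        slide_split: dict[str, str] = {}
        k = len(self.classes)
        for rec in self.records:
            if rec.patch_id in seen:
                raise ManifestError(f"duplicate patch_id {rec.patch_id!r}")
            seen.add(rec.patch_id)
            if not 0 <= rec.label < k:
                raise ManifestError(
                    f"label {rec.label} of {rec.patch_id!r} outside vocabulary"
                )
            prev = slide_split.setdefault(rec.slide_id, rec.split)
            if prev != rec.split:
                raise ManifestError(
                    f"slide {rec.slide_id!r} appears in splits {prev!r} and "
                    f"{rec.split!r}; splits must partition slides"
                )

    # -- convenience accessors -------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> list[PatchRecord]:
        return [r for r in self.records if r.split == split]

    def ids(self, split: str | None = None) -> list[str]:
        return [r.patch_id for r in self.records if split is None or r.split == split]

    def labels(self, split: str | None = None) -> np.ndarray:
        return np.array(
            [r.label for r in self.records if split is None or r.split == split],
            dtype=int,
        )

    def class_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(self.classes, 0)
        for rec in self.records:
            counts[self.classes[rec.label]] += 1
        return counts

    def copy(self) -> "PatchManifest":
        return PatchManifest(list(self.records), list(self.classes), self.provenance)


# ---------------------------------------------------------------------------
# tiling and tissue filtering
# ---------------------------------------------------------------------------

def tile_image(
    image: np.ndarray, patch_size: int, stride: int | None = None
) -> list[tuple[int, int]]:
    """Enumerate top-left corners of all fully-contained square tiles.

    Coordinates are 0-based with the origin at the top-left; each tile covers
    the half-open square ``[x, x+patch_size) x [y, y+patch_size)``.  Returned
    row-major (y outer, x inner).
    """
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    stride = patch_size if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, w = image.shape[:2]
    if h < patch_size or w < patch_size:
        raise ValueError(
            f"image ({w}x{h}) smaller than patch_size {patch_size}: no tile fits"
        )
    ys = range(0, h - patch_size + 1, stride)
    xs = range(0, w - patch_size + 1, stride)
    return [(x, y) for y in ys for x in xs]


def tissue_filter(
    tile_pixels: np.ndarray,
    bg_intensity: int = DEFAULT_BG_INTENSITY,
    max_bg_fraction: float = DEFAULT_MAX_BG_FRACTION,
) -> bool:
    """Keep a tile unless it is mostly white (non-tissue) background.

    A pixel counts as background when all three channels are at or above
    ``bg_intensity``; the tile is kept iff the background fraction does not
    exceed ``max_bg_fraction``.
    """
    arr = np.asarray(tile_pixels)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.shape[0] == 0 or arr.shape[1] == 0:
        raise ValueError("tissue_filter expects a non-empty H x W x 3 RGB array")
    bg = np.all(arr >= bg_intensity, axis=2)
    return float(bg.mean()) <= max_bg_fraction


def assign_label(
    x: int,
    y: int,
    size: int,
    regions: Sequence[AnnotationRegion],
    overlap_min: float = DEFAULT_OVERLAP_MIN,
    benign_class: int = 0,
    mode: str = "area",
) -> int:
    """Label a tile from annotation regions; unannotated tissue is benign.

    ``mode="area"``: the tile takes the class of the region with maximal
    tile-overlap fraction, provided that fraction reaches ``overlap_min``;
    ties break toward the smallest class index.  ``mode="center"``: the tile
    takes the class of the first (lowest class index) region containing the
    tile center.  Tiles matching no region get ``benign_class`` — no
    annotation is ever drawn for benign tissue.
    """
    if mode == "center":
        center = Point(x + size / 2.0, y + size / 2.0)
        candidates = [r.label for r in regions if r.shapely().contains(center)]
        return min(candidates) if candidates else benign_class

    if mode != "area":
        raise ValueError(f"unknown labeling mode {mode!r}")
    tile = box(x, y, x + size, y + size)
    tile_area = float(size) * size
    best_label = benign_class
    best_frac = -1.0
    qualifying = 0
    for region in regions:
        frac = region.shapely().intersection(tile).area / tile_area
        if frac >= overlap_min:
            qualifying += 1
        if frac >= overlap_min and (
            frac > best_frac or (frac == best_frac and region.label < best_label)
        ):
            best_frac = frac
            best_label = region.label
    if qualifying > 1:
        warnings.warn(
            f"tile ({x},{y}) overlaps {qualifying} regions above threshold; "
            "resolved by max overlap then class index",
            stacklevel=2,
        )
    return best_label


# ---------------------------------------------------------------------------
# splitting and balancing
# ---------------------------------------------------------------------------

def split_by_slide(
    manifest: PatchManifest,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> PatchManifest:
    """Assign whole slides to train/val/test so splits never share a patient.

    Slides are shuffled with ``seed`` and cut at the cumulative fractions
    (floored); leftover slides go to train.  Every patch inherits its slide's
    split.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("split fractions must sum to 1")
    slides = sorted({r.slide_id for r in manifest.records})
    if len(slides) < 3:
        raise ConfigurationError("need at least 3 slides to form three splits")
    rng = np.random.default_rng(seed)
    order = [slides[i] for i in rng.permutation(len(slides))]
    n = len(order)
    n_val = int(fractions[1] * n)
    n_test = int(fractions[2] * n)
    n_train = n - n_val - n_test  # remainder goes to train
    if min(n_train, n_val, n_test) == 0:
        raise ConfigurationError(
            f"{n} slides with fractions {fractions} leave an empty split"
        )
    assignment = {s: "train" for s in order[:n_train]}
    assignment.update({s: "val" for s in order[n_train : n_train + n_val]})
    assignment.update({s: "test" for s in order[n_train + n_val :]})
    records = [replace(r, split=assignment[r.slide_id]) for r in manifest.records]
    return PatchManifest(records, list(manifest.classes), manifest.provenance)


def balance_classes(manifest: PatchManifest, seed: int = 0) -> PatchManifest:
    """Downsample every class to the minimum class count (seeded, w/o replacement)."""
    counts = manifest.class_counts()
    for name, c in counts.items():
        if c == 0:
            raise ConfigurationError(f"class {name!r} has no records; cannot balance")
    target = min(counts.values())
    rng = np.random.default_rng(seed)
    keep: set[str] = set()
    for label in range(len(manifest.classes)):
        ids = [r.patch_id for r in manifest.records if r.label == label]
        chosen = rng.choice(len(ids), size=target, replace=False)
        keep.update(ids[i] for i in chosen)
    records = [r for r in manifest.records if r.patch_id in keep]
    return PatchManifest(records, list(manifest.classes), manifest.provenance)


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------

_COLUMNS = (
    "patch_id",
    "slide_id",
    "x",
    "y",
    "size",
    "label",
    "split",
    "image_ref",
    "clean_label",
    "is_noisy",
)


def write_manifest(manifest: PatchManifest, path: str | Path) -> None:
    """Write the tab-separated manifest (with class vocabulary header lines)."""
    path = Path(path)
    lines = [f"# classes: {','.join(manifest.classes)}"]
    if manifest.provenance:
        lines.append(f"# provenance: {manifest.provenance}")
    lines.append("\t".join(_COLUMNS))
    for r in manifest.records:
        clean = "" if r.clean_label is None else str(r.clean_label)
        noisy = "" if r.is_noisy is None else str(int(r.is_noisy))
        lines.append(
            "\t".join(
                [
                    r.patch_id,
                    r.slide_id,
                    str(r.x),
                    str(r.y),
                    str(r.size),
                    manifest.classes[r.label],
                    r.split,
                    r.image_ref,
                    clean,
                    noisy,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> PatchManifest:
    """Read a tab-separated manifest; errors carry the offending line number."""
    path = Path(path)
    classes: list[str] = []
    provenance = ""
    header: list[str] | None = None
    records: list[PatchRecord] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        if raw.startswith("# classes:"):
            classes = [c.strip() for c in raw.split(":", 1)[1].split(",") if c.strip()]
            continue
        if raw.startswith("# provenance:"):
            provenance = raw.split(":", 1)[1].strip()
            continue
        fields = raw.split("\t")
        if header is None:
            header = fields
            missing = set(_COLUMNS) - set(header)
            if missing:
                raise ManifestError(
                    f"{path.name}:{lineno}: missing column(s) {sorted(missing)}"
                )
            continue
        row = dict(zip(header, fields))
        if row["label"] not in classes:
            raise ManifestError(
                f"{path.name}:{lineno}: unknown label {row['label']!r}"
            )
        clean = row.get("clean_label", "")
        noisy = row.get("is_noisy", "")
        try:
            rec = PatchRecord(
                patch_id=row["patch_id"],
                slide_id=row["slide_id"],
                x=int(row["x"]),
                y=int(row["y"]),
                size=int(row["size"]),
                label=classes.index(row["label"]),
                split=row["split"],
                image_ref=row.get("image_ref", ""),
                clean_label=int(clean) if clean != "" else None,
                is_noisy=bool(int(noisy)) if noisy != "" else None,
            )
        except ValueError as exc:
            raise ManifestError(f"{path.name}:{lineno}: {exc}") from exc
        records.append(rec)
    if header is None:
        raise ManifestError(f"{path.name}: missing header row")
    if not classes:
        raise ManifestError(f"{path.name}: missing '# classes:' line")
    try:
        return PatchManifest(records, classes, provenance)
    except ManifestError as exc:
        raise ManifestError(f"{path.name}: {exc}") from exc


# ---------------------------------------------------------------------------
# image stores
# ---------------------------------------------------------------------------

class ImageStore:
    """Maps patch ids to H x W x 3 uint8 arrays."""

    def get(self, record: PatchRecord) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def batch(self, records: Sequence[PatchRecord]) -> np.ndarray:
        return np.stack([self.get(r) for r in records])


class DictImageStore(ImageStore):
    """In-memory store keyed by patch id (the synthetic-data default)."""

    def __init__(self, images: Mapping[str, np.ndarray]):
        self.images = dict(images)

    def get(self, record: PatchRecord) -> np.ndarray:
        return self.images[record.patch_id]


class DirectoryImageStore(ImageStore):
    """PNG patches on disk; each record's image_ref is a path relative to root."""

    def __init__(self, root: str | Path):
        self.root = Path(root)

    def get(self, record: PatchRecord) -> np.ndarray:
        return np.asarray(Image.open(self.root / record.image_ref).convert("RGB"))


class Hdf5ImageStore(ImageStore):
    """Lazy accessor into an HDF5 patch archive; image_ref is the row index."""

    def __init__(self, path: str | Path, key: str = "x"):
        self.path = Path(path)
        self.key = key
        self._file: h5py.File | None = None

    def _dataset(self) -> h5py.Dataset:
        if self._file is None:
            self._file = h5py.File(self.path, "r")
        return self._file[self.key]

    def get(self, record: PatchRecord) -> np.ndarray:
        return np.asarray(self._dataset()[int(record.image_ref)])


def save_patch_images(
    manifest: PatchManifest, store: ImageStore, root: str | Path
) -> PatchManifest:
    """Write every patch as PNG under root and point image_refs at the files."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    records = []
    for rec in manifest.records:
        ref = f"{rec.patch_id}.png"
        Image.fromarray(store.get(rec).astype(np.uint8)).save(root / ref)
        records.append(replace(rec, image_ref=ref))
    return PatchManifest(records, list(manifest.classes), manifest.provenance)


def read_patch_archive(
    path: str | Path,
    classes: Sequence[str] = ("benign", "malignant"),
    split: str = "train",
    slide_id: str | None = None,
) -> tuple[PatchManifest, Hdf5ImageStore]:
    """Load an HDF5 patch archive (keys ``x`` images, ``y`` labels).

    Archives carry no slide identity, so all records share one synthetic
    slide id derived from the file name (one virtual slide per source split
    file).  Labels must index into ``classes``.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "x" not in f or "y" not in f:
            raise ManifestError(f"{path.name}: archive must contain 'x' and 'y'")
        images = f["x"]
        labels = np.asarray(f["y"]).reshape(-1)
        if images.ndim != 4 or images.shape[3] != 3:
            raise ManifestError(
                f"{path.name}: images must be N x H x W x 3, got {images.shape}"
            )
        if images.shape[0] != labels.shape[0]:
            raise ManifestError(
                f"{path.name}: {images.shape[0]} images vs {labels.shape[0]} labels"
            )
        size = int(images.shape[1])
    bad = (labels < 0) | (labels >= len(classes))
    if bad.any():
        raise ManifestError(
            f"{path.name}: labels outside vocabulary of {len(classes)} classes"
        )
    sid = slide_id or f"{path.stem}_{split}"
    records = [
        PatchRecord(
            patch_id=f"{sid}_{i:07d}",
            slide_id=sid,
            x=0,
            y=0,
            size=size,
            label=int(labels[i]),
            split=split,
            image_ref=str(i),
        )
        for i in range(labels.shape[0])
    ]
    manifest = PatchManifest(records, list(classes), provenance=f"archive:{path.name}")
    return manifest, Hdf5ImageStore(path)
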