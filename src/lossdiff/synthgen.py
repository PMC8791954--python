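"""Seeded synthetic patches and slides for exercising the full pipeline.

Real histopathology slides cannot be shipped with a test suite, so this
module generates class-distinguishable texture patches (base color +
oriented sinusoid + dark blobs + pixel jitter) and composite slides whose
annotations can be deliberately over-drawn.  Dilating the true region
polygons by ``annotation_dilation`` pixels before emitting them reproduces
the way coarse human annotations swallow surrounding benign tissue and turn
it into false-positive training patches — the label-noise mechanism the
denoising method targets.

A ``difficulty`` knob interpolates all class recipes toward their common
mean: 0 gives maximally separated classes (a nearest-centroid classifier on
channel means suffices), 1 gives identical recipes (chance-level task).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon
from skimage.draw import polygon as raster_polygon

from .noise import NoiseMask, NoiseSpec, inject_symmetric_noise
from .patchio import (
    AnnotationRegion,
    DictImageStore,
    PatchManifest,
    PatchRecord,
    assign_label,
    split_by_slide,
    tile_image,
    tissue_filter,
)

#: slides stay meaningful for slide-level splitting with roughly this many
#: patches each; at least MIN_SLIDES virtual slides are always created so an
#: 80/10/10 split never leaves a split empty
PATCHES_PER_SLIDE = 200
MIN_SLIDES = 10


@dataclass(frozen=True)
class ClassRecipe:
    """Rendering parameters of one synthetic tissue class."""

    class_index: int
    base_color: tuple[float, float, float]
    stripe_deg: float          # texture orientation, degrees
    frequency: float           # sinusoid cycles per patch
    blob_density: float        # expected dark blobs per patch
    jitter: float              # per-pixel gaussian noise std (intensity units)


@dataclass
class SlideLayout:
    """Geometry of one synthetic slide: regions on a white background."""

    width: int
    height: int
    regions: list[tuple[int, tuple[tuple[float, float], ...]]]  # (class, polygon)
    annotation_dilation: float = 0.0

    def __post_init__(self) -> None:
        if self.annotation_dilation < 0:
            raise ValueError("annotation_dilation must be >= 0")


def make_recipes(K: int, difficulty: float, seed: int) -> list[ClassRecipe]:
    """K seeded recipes, linearly pulled toward their mean by ``difficulty``."""
    if K < 2:
        raise ValueError("need at least 2 classes")
    if not 0.0 <= difficulty <= 1.0:
        raise ValueError("difficulty must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    # well-spread base colors on a ring in RGB space, plus distinct textures
    hues = np.linspace(0.0, 2 * np.pi, K, endpoint=False) + rng.uniform(0, 2 * np.pi)
    colors = np.stack(
        [
            150 + 70 * np.cos(hues),
            140 + 70 * np.cos(hues + 2 * np.pi / 3),
            150 + 70 * np.cos(hues + 4 * np.pi / 3),
        ],
        axis=1,
    )
    stripes = np.linspace(0.0, 180.0, K, endpoint=False)
    freqs = np.linspace(4.0, 4.0 + 3.0 * (K - 1), K)
    densities = np.linspace(2.0, 2.0 + 4.0 * (K - 1), K)
    params = np.column_stack([colors, stripes[:, None], freqs[:, None], densities[:, None]])
    mean = params.mean(axis=0, keepdims=True)
    params = params * (1.0 - difficulty) + mean * difficulty
    return [
        ClassRecipe(
            class_index=i,
            base_color=tuple(params[i, :3]),
            stripe_deg=float(params[i, 3]),
            frequency=float(params[i, 4]),
            blob_density=float(params[i, 5]),
            jitter=8.0,
        )
        for i in range(K)
    ]


def _texture(recipe: ClassRecipe, h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    theta = np.deg2rad(recipe.stripe_deg)
    phase = rng.uniform(0, 2 * np.pi)
    carrier = (xx * np.cos(theta) + yy * np.sin(theta)) / max(h, w)
    if recipe.frequency > 0:
        stripes = 20.0 * np.sin(2 * np.pi * recipe.frequency * carrier + phase)
    else:
        stripes = np.zeros((h, w))
    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(recipe.base_color)
    img += stripes[:, :, None]
    # dark nuclei-like blobs, Poisson count scaled to the patch area
    area_scale = (h * w) / (64.0 * 64.0)
    n_blobs = rng.poisson(recipe.blob_density * area_scale)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(2.0, 5.0)
        y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
        x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
        win_y, win_x = yy[y0:y1, x0:x1], xx[y0:y1, x0:x1]
        mask = (win_y - cy) ** 2 + (win_x - cx) ** 2 <= r * r
        img[y0:y1, x0:x1][mask] *= 0.55
    if recipe.jitter > 0:
        img += rng.normal(0.0, recipe.jitter, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def render_patch(recipe: ClassRecipe, size: int, seed: int) -> np.ndarray:
    """Render one ``size x size`` RGB patch; bit-identical per (recipe, seed)."""
    if size < 16:
        raise ValueError("patch size must be >= 16")
    rng = np.random.default_rng(seed)
    return _texture(recipe, size, size, rng)


def generate_patch_dataset(
    K: int = 3,
    n_per_class: int = 100,
    size: int = 64,
    difficulty: float = 0.2,
    noise_rate: float = 0.0,
    seed: int = 0,
    class_names: Sequence[str] | None = None,
    patches_per_slide: int = PATCHES_PER_SLIDE,
) -> tuple[PatchManifest, DictImageStore, NoiseMask]:
    """Full synthetic dataset: patches, slide-level 80/10/10 split, train noise.

    Patches are spread over virtual slides (about ``patches_per_slide`` each,
    never fewer than ten slides) so the slide-level split is exercised, then
    symmetric label noise at ``noise_rate`` is injected into the train split.
    """
    recipes = make_recipes(K, difficulty, seed)
    names = list(class_names) if class_names else [f"class{i}" for i in range(K)]
    if len(names) != K:
        raise ValueError("class_names length must equal K")
    total = K * n_per_class
    n_slides = max(MIN_SLIDES, int(np.ceil(total / patches_per_slide)))
    rng = np.random.default_rng(seed + 1)
    slide_of = rng.integers(n_slides, size=total)
    grid_w = int(np.ceil(np.sqrt(patches_per_slide)))
    slide_fill = [0] * n_slides

    records: list[PatchRecord] = []
    images: dict[str, np.ndarray] = {}
    seed_seq = np.random.SeedSequence(entropy=seed, spawn_key=(1,))
    patch_seeds = seed_seq.generate_state(total)
    i = 0
    for label in range(K):
        for _ in range(n_per_class):
            sid = int(slide_of[i])
            pos = slide_fill[sid]
            slide_fill[sid] += 1
            pid = f"p{i:06d}"
            records.append(
                PatchRecord(
                    patch_id=pid,
                    slide_id=f"slide{sid:03d}",
                    x=(pos % grid_w) * size,
                    y=(pos // grid_w) * size,
                    size=size,
                    label=label,
                    split="train",
                )
            )
            images[pid] = render_patch(recipes[label], size, int(patch_seeds[i]))
            i += 1
    manifest = PatchManifest(records, names, provenance=f"synthetic seed={seed}")
    manifest = split_by_slide(manifest, (0.8, 0.1, 0.1), seed=seed + 2)
    manifest, mask = inject_symmetric_noise(
        manifest, NoiseSpec(rate=noise_rate, seed=seed + 3)
    )
    return manifest, DictImageStore(images), mask


# ---------------------------------------------------------------------------
# composite slides with over-drawn annotations
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSlide:
    image: np.ndarray                 # H x W x 3 uint8, white background
    region_map: np.ndarray            # H x W int, -1 = background, else class
    annotations: list[AnnotationRegion]  # dilated non-benign polygons
    layout: SlideLayout


def generate_synthetic_slide(
    layout: SlideLayout,
    recipes: Sequence[ClassRecipe],
    seed: int,
    benign_class: int = 0,
) -> SyntheticSlide:
    """Render a slide region-by-region and emit dilated annotations.

    The pixel-level ``region_map`` is the ground truth.  Emitted annotations
    are the true non-benign polygons buffered outward by
    ``layout.annotation_dilation`` pixels, so tiling plus annotation-based
    labeling over-covers neighbouring benign tissue — measurable,
    annotation-induced label noise.  Dilated polygons are clipped to the
    slide bounds (with a warning).
    """
    h, w = layout.height, layout.width
    rng = np.random.default_rng(seed)
    image = np.full((h, w, 3), 255, dtype=np.uint8)
    region_map = np.full((h, w), -1, dtype=int)
    annotations: list[AnnotationRegion] = []
    bounds = Polygon([(0, 0), (w, 0), (w, h), (0, h)])
    for cls, poly in layout.regions:
        ys = [p[1] for p in poly]
        xs = [p[0] for p in poly]
        rr, cc = raster_polygon(ys, xs, shape=(h, w))
        texture = _texture(recipes[cls], h, w, rng)
        image[rr, cc] = texture[rr, cc]
        region_map[rr, cc] = cls
        if cls == benign_class:
            continue
        ann = Polygon(poly)
        if layout.annotation_dilation > 0:
            ann = ann.buffer(layout.annotation_dilation, join_style=2)
            if not bounds.covers(ann):
                warnings.warn(
                    "dilated annotation exceeds slide bounds; clipped", stacklevel=2
                )
                ann = ann.intersection(bounds)
        coords = tuple((float(x), float(y)) for x, y in ann.exterior.coords[:-1])
        annotations.append(AnnotationRegion("synthetic", coords, cls))
    return SyntheticSlide(image, region_map, annotations, layout)


def annotation_noise_rate(
    slide: SyntheticSlide,
    patch_size: int,
    overlap_min: float = 0.5,
    benign_class: int = 0,
) -> float:
    """Fraction of tissue tiles whose annotation label contradicts ground truth.

    Each kept (tissue) tile is labeled from the slide's emitted annotations
    and compared with the majority class of its ground-truth pixels (benign
    for tiles of pure background-free benign tissue).  Tiles with no tissue
    are excluded.
    """
    mismatches = 0
    tissue_tiles = 0
    for x, y in tile_image(slide.image, patch_size):
        tile = slide.image[y : y + patch_size, x : x + patch_size]
        if not tissue_filter(tile):
            continue
        truth_pixels = slide.region_map[y : y + patch_size, x : x + patch_size]
        tissue = truth_pixels[truth_pixels >= 0]
        if tissue.size == 0:
            continue
        tissue_tiles += 1
        truth = int(np.bincount(tissue).argmax())
        assigned = assign_label(
            x, y, patch_size, slide.annotations, overlap_min, benign_class
        )
        if assigned != truth:
            mismatches += 1
    if tissue_tiles == 0:
        return 0.0
    return mismatches / tissue_tiles


def save_slide(slide: SyntheticSlide, image_path: str | Path, ann_path: str | Path) -> None:
    """Slide image as PNG plus annotations as JSON [{label, polygon}]."""
    from PIL import Image

    Image.fromarray(slide.image).save(image_path)
    payload = [
        {"label": a.label, "polygon": [list(p) for p in a.polygon]}
        for a in slide.annotations
    ]
    Path(ann_path).write_text(json.dumps(payload))
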