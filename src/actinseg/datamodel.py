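"""Dataset construction: annotations, crops, normalization, augmentation.

The supervision unit is a set of polygonal regions per pattern class
(weak labels).  This module rasterizes them, cuts training crops with a
sliding window and a class-imbalance filter, fits the dataset-level
intensity normalization, applies training-time augmentation, and provides
the two label-corruption operators (instance omission, stepwise dilation)
used in the robustness experiments.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from matplotlib.path import Path as MplPath
from skimage.morphology import dilation, disk

__all__ = [
    "AnnotationSet",
    "NormalizationParams",
    "Crop",
    "CropSet",
    "rasterize",
    "extract_crops",
    "fit_normalization",
    "normalize",
    "augment",
    "corrupt_omit",
    "corrupt_dilate",
]

CLASSES = ("rings", "fibers")


@dataclass
class AnnotationSet:
    """Per-class polygonal regions (weak labels).

    Polygons are (n, 2) arrays of ``(x, y)`` vertices, 0-based, origin at
    the top-left pixel center, x = column.  A pixel belongs to a class if
    its center lies inside (or on) at least one of that class's polygons.
    """

    polygons: dict[str, list[np.ndarray]]
    pixel_size_nm: float

    def n_instances(self, cls: str) -> int:
        return len(self.polygons.get(cls, []))

    def to_json(self, path: str | Path) -> None:
        doc = {
            "classes": {
                cls: [np.asarray(p, dtype=float).tolist() for p in polys]
                for cls, polys in self.polygons.items()
            },
            "pixel_size_nm": float(self.pixel_size_nm),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnnotationSet":
        doc = json.loads(Path(path).read_text())
        polygons = {
            name: [np.asarray(p, dtype=np.float64) for p in polys]
            for name, polys in doc["classes"].items()
        }
        return cls(polygons=polygons, pixel_size_nm=float(doc["pixel_size_nm"]))


def rasterize(
    ann: AnnotationSet,
    shape: tuple[int, int],
    restrict_mask: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Rasterize each class's polygons onto a binary map of ``shape``.

    A pixel is set iff its center is inside or on >= 1 polygon of the class
    (even-odd rule; the polygons are simple so this equals the nonzero
    rule), then intersected with ``restrict_mask`` when given.  A polygon
    entirely outside the canvas contributes nothing (with a warning).
    """
    h, w = shape
    if restrict_mask is not None and restrict_mask.shape != (h, w):
        raise ValueError("restrict_mask shape does not match the target shape")
    out: dict[str, np.ndarray] = {}
    for cls, polys in ann.polygons.items():
        cmap = np.zeros((h, w), dtype=bool)
        for verts in polys:
            verts = np.asarray(verts, dtype=np.float64)
            if len(verts) < 3:
                continue
            xmin, ymin = verts.min(axis=0)
            xmax, ymax = verts.max(axis=0)
            c0, c1 = max(int(np.floor(xmin)), 0), min(int(np.ceil(xmax)) + 1, w)
            r0, r1 = max(int(np.floor(ymin)), 0), min(int(np.ceil(ymax)) + 1, h)
            if c0 >= c1 or r0 >= r1:
                warnings.warn("polygon entirely outside image bounds; skipped")
                continue
            cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
            pts = np.stack([cc.ravel(), rr.ravel()], axis=1)
            inside = MplPath(verts).contains_points(pts, radius=1e-9)
            cmap[r0:r1, c0:c1] |= inside.reshape(r1 - r0, c1 - c0)
        if restrict_mask is not None:
            cmap &= restrict_mask.astype(bool)
        out[cls] = cmap
    return out


# ---------------------------------------------------------------------------
# crops

@dataclass
class Crop:
    patch: np.ndarray                 # (window, window) float
    labels: dict[str, np.ndarray]     # class -> (window, window) bool
    source_id: str
    offset: tuple[int, int]           # (row, col) of the top-left corner


@dataclass
class CropSet:
    crops: list[Crop]
    window: int
    normalization: "NormalizationParams | None" = None

    def __len__(self) -> int:
        return len(self.crops)

    def __iter__(self):
        return iter(self.crops)

    def stacked(self, classes: tuple[str, ...] = CLASSES) -> tuple[np.ndarray, np.ndarray]:
        """(N, 1, H, W) inputs and (N, C, H, W) binary targets."""
        x = np.stack([c.patch for c in self.crops])[:, None, :, :].astype(np.float32)
        y = np.stack(
            [np.stack([c.labels[k] for k in classes]) for c in self.crops]
        ).astype(np.float32)
        return x, y


def _window_starts(extent: int, window: int, stride: int) -> list[int]:
    starts = list(range(0, extent - window + 1, stride))
    # cover the trailing edge with an extra flush window when needed
    if starts[-1] != extent - window:
        starts.append(extent - window)
    return starts


def extract_crops(
    image: np.ndarray,
    label_maps: dict[str, np.ndarray],
    window: int = 128,
    overlap: int = 16,
    min_label_frac: float = 0.01,
    source_id: str = "",
) -> CropSet:
    """Sliding-window crops with a class-imbalance filter.

    Stride is ``window - overlap``; a final window flush with each trailing
    edge is appended so the whole image is covered.  A crop is kept iff the
    union of its label maps covers at least ``min_label_frac`` of the
    window area; 0 disables the filter (the axonal dataset convention).
    """
    h, w = image.shape
    if h < window or w < window:
        raise ValueError(
            f"image of shape {image.shape} is smaller than the {window}x{window} window"
        )
    stride = window - overlap
    crops = []
    for r in _window_starts(h, window, stride):
        for c in _window_starts(w, window, stride):
            labels = {k: m[r:r + window, c:c + window].astype(bool)
                      for k, m in label_maps.items()}
            union = np.zeros((window, window), dtype=bool)
            for m in labels.values():
                union |= m
            if union.sum() >= min_label_frac * window * window:
                crops.append(Crop(
                    patch=np.asarray(image[r:r + window, c:c + window], dtype=np.float64),
                    labels=labels, source_id=source_id, offset=(r, c),
                ))
    return CropSet(crops=crops, window=window)


# ---------------------------------------------------------------------------
# normalization

@dataclass
class NormalizationParams:
    """Dataset-level intensity scaling.

    ``m`` is the median of per-image minima, ``M`` the median of per-image
    maxima plus three (population) standard deviations of those maxima.
    ``factor`` compresses [m, M] onto [0, factor] so that augmentation's
    intensity scaling rarely clips; values are finally clipped to [0, 1].
    """

    m: float
    M: float
    factor: float = 0.8

    def __post_init__(self):
        if not self.M > self.m:
            raise ValueError(f"need M > m, got m={self.m}, M={self.M}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(
            {"m": float(self.m), "M": float(self.M), "factor": float(self.factor)}
        ))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NormalizationParams":
        return cls(**yaml.safe_load(Path(path).read_text()))


def fit_normalization(images: list[np.ndarray], factor: float = 0.8) -> NormalizationParams:
    if not images:
        raise ValueError("need at least one image")
    minima = np.array([float(np.min(im)) for im in images])
    maxima = np.array([float(np.max(im)) for im in images])
    m = float(np.median(minima))
    M = float(np.median(maxima) + 3.0 * np.std(maxima, ddof=0))
    if M <= m:
        raise ValueError("degenerate dataset: median max + 3 SD does not exceed median min")
    return NormalizationParams(m=m, M=M, factor=factor)


def normalize(patch: np.ndarray, params: NormalizationParams) -> np.ndarray:
    scaled = params.factor * (np.asarray(patch, dtype=np.float64) - params.m) / (params.M - params.m)
    return np.clip(scaled, 0.0, 1.0)


# ---------------------------------------------------------------------------
# augmentation

def augment(
    patch: np.ndarray,
    labels: dict[str, np.ndarray],
    rng: np.random.Generator | int,
    scale_range: tuple[float, float] = (0.8, 1.2),
    gamma_range: tuple[float, float] = (0.8, 1.2),
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Training-time augmentation, each op applied independently with p=0.5.

    Flips act on image and labels alike; intensity scale and gamma act on
    the (already normalized) image only, re-clipped to [0, 1].
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    patch = np.asarray(patch, dtype=np.float64)
    labels = dict(labels)
    if rng.random() < 0.5:
        patch = np.flipud(patch)
        labels = {k: np.flipud(v) for k, v in labels.items()}
    if rng.random() < 0.5:
        patch = np.fliplr(patch)
        labels = {k: np.fliplr(v) for k, v in labels.items()}
    if rng.random() < 0.5:
        patch = patch * rng.uniform(*scale_range)
    if rng.random() < 0.5:
        patch = np.power(np.clip(patch, 0.0, None), rng.uniform(*gamma_range))
    return np.clip(patch, 0.0, 1.0), labels


# ---------------------------------------------------------------------------
# weak-label corruption

def corrupt_omit(ann: AnnotationSet, fraction: float, seed: int = 0) -> AnnotationSet:
    """Uniformly remove ``round(fraction * n)`` label instances per class."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    kept: dict[str, list[np.ndarray]] = {}
    for cls, polys in ann.polygons.items():
        n = len(polys)
        n_remove = int(round(fraction * n))
        drop = set(rng.choice(n, size=n_remove, replace=False)) if n_remove else set()
        kept[cls] = [p for i, p in enumerate(polys) if i not in drop]
    return AnnotationSet(polygons=kept, pixel_size_nm=ann.pixel_size_nm)


def corrupt_dilate(
    ann: AnnotationSet,
    radius_nm: float,
    shape: tuple[int, int],
    restrict_mask: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Rasterize, then dilate every class map by a disk of ``radius_nm``."""
    if radius_nm < 0:
        raise ValueError("radius_nm must be non-negative")
    maps = rasterize(ann, shape, restrict_mask=restrict_mask)
    radius_px = int(round(radius_nm / ann.pixel_size_nm))
    if radius_px < 1:
        if radius_nm > 0:
            warnings.warn("dilation radius below one pixel; labels unchanged")
        return maps
    footprint = disk(radius_px)
    return {cls: dilation(m, footprint=footprint).astype(bool) for cls, m in maps.items()}
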