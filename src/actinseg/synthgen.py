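"""Synthetic STED-like scene generator with exact ground truth.

Renders curvilinear neuronal processes (random smooth splines) whose
super-resolved structure channel carries one of three local patterns:

* transverse periodic stripes ("rings", the membrane periodic skeleton,
  spaced 180-190 nm),
* longitudinal lines parallel to the process axis ("fibers"),
* low-contrast diffuse speckle (unlabeled remainder).

Diffraction-limited marker channels (dendrite-like / axon-like) are smooth
blurred fills of the process masks, mimicking confocal acquisition of
MAP2 / SMI31 stains.  Everything is a pure function of the scene
specification and its seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import interpolate
from scipy.ndimage import binary_fill_holes, gaussian_filter
from scipy.spatial import cKDTree

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "NanoscopyImage",
    "generate_scene",
    "weak_labels_from_truth",
    "generate_condition_dataset",
    "condition_presets",
    "CHANNEL_SUFFIXES",
]

CHANNEL_SUFFIXES = {"structure": "_actin", "dendrite_like": "_dend", "axon_like": "_axon"}

MIN_IMAGE_SIDE = 128  # minimum crop size downstream


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic acquisition.

    Defaults emulate a 20 nm pixel STED image of neuronal processes with
    rings spaced 180-190 nm.  The PSF values are plausible stand-ins
    (typical commercial STED ~60 nm FWHM; confocal markers ~250 nm) --
    the real instrument values are not published, so both are exposed here.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size_nm: float = 20.0
    n_processes: int = 3
    process_width_nm: tuple[float, float] = (500.0, 900.0)
    ring_period_nm: tuple[float, float] = (180.0, 190.0)
    ring_fraction: float = 0.5
    fiber_fraction: float = 0.3
    fiber_count_per_process: tuple[int, int] = (2, 4)
    background_level: float = 5.0
    peak_signal: float = 80.0
    noise_model: str = "poisson"  # {"poisson", "poisson+gaussian", "none"}
    read_noise_sd: float = 2.0
    psf_fwhm_nm: float = 60.0
    marker_psf_fwhm_nm: float = 250.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_shape
        if h < MIN_IMAGE_SIDE or w < MIN_IMAGE_SIDE:
            raise ValueError(
                f"image_shape {self.image_shape} too small; minimum is "
                f"{MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE} (the downstream crop size)"
            )
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if min(self.ring_period_nm) / self.pixel_size_nm < 2.0:
            raise ValueError(
                "ring period below 2 pixels is not resolvable at this pixel size"
            )
        if not (0.0 <= self.ring_fraction <= 1.0 and 0.0 <= self.fiber_fraction <= 1.0):
            raise ValueError("ring_fraction and fiber_fraction must lie in [0, 1]")
        if self.ring_fraction + self.fiber_fraction > 1.0 + 1e-12:
            raise ValueError("ring_fraction + fiber_fraction must not exceed 1")
        if self.noise_model not in ("poisson", "poisson+gaussian", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.n_processes < 1:
            raise ValueError("need at least one process")


@dataclass
class NanoscopyImage:
    """Multi-channel raster with a physical pixel size.

    ``channels`` maps a role name (``structure``, ``dendrite_like``,
    ``axon_like``) to a 2-D float array in photon counts.
    """

    channels: dict[str, np.ndarray]
    pixel_size_nm: float

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def save(self, directory: str | Path, stem: str) -> dict[str, Path]:
        """Write one 16-bit grayscale TIFF per channel (role in suffix)."""
        import tifffile

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for role, arr in self.channels.items():
            p = directory / f"{stem}{CHANNEL_SUFFIXES[role]}.tif"
            tifffile.imwrite(p, np.clip(np.round(arr), 0, 65535).astype(np.uint16))
            paths[role] = p
        return paths

    @classmethod
    def load(cls, directory: str | Path, stem: str, pixel_size_nm: float) -> "NanoscopyImage":
        import tifffile

        directory = Path(directory)
        channels = {}
        for role, suffix in CHANNEL_SUFFIXES.items():
            p = directory / f"{stem}{suffix}.tif"
            if p.exists():
                channels[role] = tifffile.imread(p).astype(np.float64)
        if not channels:
            raise FileNotFoundError(f"no channel TIFFs with stem {stem!r} in {directory}")
        return cls(channels=channels, pixel_size_nm=pixel_size_nm)


@dataclass
class Centerline:
    """Dense polyline of one process, with cumulative arc length in pixels."""

    points: np.ndarray        # (n, 2) float, (row, col)
    arclength_px: np.ndarray  # (n,) cumulative, starts at 0
    width_px: float
    role: str                 # "dendrite_like" | "axon_like"
    ring_period_px: float

    @property
    def length_px(self) -> float:
        return float(self.arclength_px[-1])


@dataclass
class GroundTruth:
    class_maps: dict[str, np.ndarray]      # {"rings", "fibers"} -> bool map
    process_masks: dict[str, np.ndarray]   # {"dendrite_like", "axon_like"} -> bool
    centerlines: list[Centerline]
    pixel_size_nm: float

    def union_mask(self) -> np.ndarray:
        out = np.zeros(next(iter(self.process_masks.values())).shape, dtype=bool)
        for m in self.process_masks.values():
            out |= m
        return out

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(
            path,
            rings=self.class_maps["rings"],
            fibers=self.class_maps["fibers"],
            dendrite_like=self.process_masks["dendrite_like"],
            axon_like=self.process_masks["axon_like"],
            pixel_size_nm=self.pixel_size_nm,
        )

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        with np.load(path) as z:
            return cls(
                class_maps={"rings": z["rings"], "fibers": z["fibers"]},
                process_masks={
                    "dendrite_like": z["dendrite_like"],
                    "axon_like": z["axon_like"],
                },
                centerlines=[],
                pixel_size_nm=float(z["pixel_size_nm"]),
            )


def _fwhm_to_sigma_px(fwhm_nm: float, pixel_size_nm: float) -> float:
    return fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / pixel_size_nm


def _random_centerline(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Smooth random spline crossing the field of view.

    Control points walk from one border to the opposite one with bounded
    lateral perturbations, then a cubic spline is sampled at ~0.5 px steps.
    """
    h, w = shape
    n_ctrl = 6
    if rng.random() < 0.5:  # left-to-right
        xs = np.linspace(-0.05 * w, 1.05 * w, n_ctrl)
        ys = rng.uniform(0.15 * h, 0.85 * h) + np.cumsum(rng.normal(0, 0.09 * h, n_ctrl))
        ctrl = np.stack([ys, xs], axis=1)
    else:  # top-to-bottom
        ys = np.linspace(-0.05 * h, 1.05 * h, n_ctrl)
        xs = rng.uniform(0.15 * w, 0.85 * w) + np.cumsum(rng.normal(0, 0.09 * w, n_ctrl))
        ctrl = np.stack([ys, xs], axis=1)
    t = np.linspace(0.0, 1.0, n_ctrl)
    spline = interpolate.CubicSpline(t, ctrl, axis=0)
    dense = spline(np.linspace(0.0, 1.0, 40 * n_ctrl))
    # arc-length reparametrisation at ~0.5 px steps
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n_samp = max(int(s[-1] / 0.5), 8)
    points = interpolate.interp1d(s, dense, axis=0)(np.linspace(0.0, s[-1], n_samp))
    # clip to the canvas; keep the longest in-bounds run
    inside = (
        (points[:, 0] >= 0) & (points[:, 0] <= h - 1)
        & (points[:, 1] >= 0) & (points[:, 1] <= w - 1)
    )
    if not inside.any():
        return points[:2]
    idx = np.flatnonzero(inside)
    points = points[idx[0]: idx[-1] + 1]
    return points


def _centerline_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def generate_scene(spec: SceneSpec) -> tuple[NanoscopyImage, GroundTruth]:
    """Render one synthetic scene; identical spec+seed gives identical arrays."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    px = spec.pixel_size_nm

    rows, cols = np.mgrid[0:h, 0:w]
    grid = np.stack([rows.ravel(), cols.ravel()], axis=1).astype(np.float64)

    structure = np.zeros((h, w), dtype=np.float64)
    rings_map = np.zeros((h, w), dtype=bool)
    fibers_map = np.zeros((h, w), dtype=bool)
    masks = {
        "dendrite_like": np.zeros((h, w), dtype=bool),
        "axon_like": np.zeros((h, w), dtype=bool),
    }
    centerlines: list[Centerline] = []
    owner_dist = np.full((h, w), np.inf)
    owner_role = np.full((h, w), -1, dtype=np.int8)

    for i in range(spec.n_processes):
        pts = _random_centerline(rng, (h, w))
        if len(pts) < 8:
            continue
        arclen = _centerline_arclength(pts)
        width_px = rng.uniform(*spec.process_width_nm) / px
        period_px = rng.uniform(*spec.ring_period_nm) / px
        role = "dendrite_like" if i % 2 == 0 else "axon_like"
        n_fibers = int(rng.integers(spec.fiber_count_per_process[0],
                                    spec.fiber_count_per_process[1] + 1))
        fiber_offsets = rng.uniform(0.1, 0.9, size=n_fibers) * (width_px / 2.0)
        speckle = gaussian_filter(rng.uniform(0.0, 1.0, size=(h, w)), 2.0)

        tree = cKDTree(pts)
        dist, nearest = tree.query(grid, k=1)
        dist = dist.reshape(h, w)
        s_near = arclen[nearest].reshape(h, w)

        mask = dist <= width_px / 2.0
        masks[role] |= mask
        closer = dist < owner_dist
        owner_dist[closer] = dist[closer]
        owner_role[closer] = 0 if role == "dendrite_like" else 1

        total = arclen[-1]
        ring_end = spec.ring_fraction * total
        fiber_end = ring_end + spec.fiber_fraction * total

        in_rings = mask & (s_near < ring_end)
        in_fibers = mask & (s_near >= ring_end) & (s_near < fiber_end)
        in_diffuse = mask & (s_near >= fiber_end)

        intensity = np.zeros((h, w), dtype=np.float64)
        # transverse stripes: iso-phase lines of the arc length are locally
        # perpendicular to the centerline tangent
        intensity[in_rings] = 0.5 * (1.0 + np.cos(2.0 * np.pi * s_near[in_rings] / period_px))
        # longitudinal lines: narrow ridges at fixed distance from the axis
        if n_fibers:
            d = dist[in_fibers]
            prof = np.zeros_like(d)
            for off in fiber_offsets:
                prof = np.maximum(prof, np.exp(-0.5 * ((d - off) / 1.2) ** 2))
            intensity[in_fibers] = prof
        intensity[in_diffuse] = 0.15 + 0.25 * speckle[in_diffuse]

        structure = np.maximum(structure, intensity)
        rings_map |= in_rings
        fibers_map |= in_fibers
        centerlines.append(
            Centerline(points=pts, arclength_px=arclen, width_px=width_px,
                       role=role, ring_period_px=period_px)
        )

    if not centerlines:
        raise RuntimeError("no process fell inside the field of view; change the seed")

    # Hairpins and crossings can enclose pockets inside a class region; the
    # pattern there is geometrically ambiguous, so class regions are kept
    # simply connected (polygon annotations carry no holes) and the pocket
    # pixels join the mask of the nearest process, preserving the invariant
    # that class maps are subsets of the union of process masks.
    for cmap in (rings_map, fibers_map):
        pocket = binary_fill_holes(cmap) & ~cmap
        if pocket.any():
            cmap |= pocket
            masks["dendrite_like"] |= pocket & (owner_role == 0)
            masks["axon_like"] |= pocket & (owner_role == 1)

    psf_sigma = _fwhm_to_sigma_px(spec.psf_fwhm_nm, px)
    structure = gaussian_filter(structure, psf_sigma)
    photons = spec.background_level + spec.peak_signal * structure

    marker_sigma = _fwhm_to_sigma_px(spec.marker_psf_fwhm_nm, px)
    channels = {"structure": _apply_noise(photons, spec, rng)}
    for role, mask in masks.items():
        marker = spec.background_level + 0.6 * spec.peak_signal * gaussian_filter(
            mask.astype(np.float64), marker_sigma
        )
        channels[role] = _apply_noise(marker, spec, rng)

    image = NanoscopyImage(channels=channels, pixel_size_nm=px)
    truth = GroundTruth(
        class_maps={"rings": rings_map, "fibers": fibers_map},
        process_masks=masks,
        centerlines=centerlines,
        pixel_size_nm=px,
    )
    return image, truth


def _apply_noise(photons: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_model == "none":
        return photons
    noisy = rng.poisson(np.clip(photons, 0.0, None)).astype(np.float64)
    if spec.noise_model == "poisson+gaussian":
        noisy = noisy + rng.normal(0.0, spec.read_noise_sd, size=photons.shape)
    return np.clip(noisy, 0.0, None)


# ---------------------------------------------------------------------------
# weak labels

def weak_labels_from_truth(
    truth: GroundTruth,
    style: str = "polygon_box",
    margin_nm: float = 0.0,
    jitter_nm: float = 0.0,
    seed: int = 0,
):
    """Derive polygonal annotations from ground-truth class maps.

    ``precise`` traces exact pixel-boundary contours of every connected
    component, so rasterizing them recovers the class map bit-for-bit
    (interior holes, which thin synthetic patterns do not produce, would be
    filled).  ``polygon_box`` mimics an expert's coarse polygonal bounding
    boxes: the convex hull of each component, expanded by ``margin_nm`` plus
    half a pixel (plus the jitter amplitude, so coverage survives any jitter
    draw) and vertex-jittered.
    """
    import shapely
    from skimage.measure import label as cc_label

    from .datamodel import AnnotationSet

    if margin_nm < 0 or jitter_nm < 0:
        raise ValueError("margin_nm and jitter_nm must be non-negative")
    if style not in ("precise", "polygon_box"):
        raise ValueError(f"unknown style {style!r}")

    px = truth.pixel_size_nm
    rng = np.random.default_rng(seed)
    polygons: dict[str, list[np.ndarray]] = {}
    for cls, cmap in truth.class_maps.items():
        polys: list[np.ndarray] = []
        lab = cc_label(cmap, connectivity=2)
        for comp_id in range(1, lab.max() + 1):
            rr, cc = np.nonzero(lab == comp_id)
            if style == "precise":
                boxes = shapely.box(cc - 0.5, rr - 0.5, cc + 0.5, rr + 0.5)
                merged = shapely.union_all(boxes, grid_size=0.25)
                for geom in getattr(merged, "geoms", [merged]):
                    polys.append(np.asarray(geom.exterior.coords[:-1], dtype=np.float64))
            else:
                margin_px = margin_nm / px
                jitter_px = jitter_nm / px
                hull = shapely.MultiPoint(np.stack([cc, rr], axis=1)).convex_hull
                buffered = hull.buffer(margin_px + 0.5 + jitter_px + 1e-6, quad_segs=4)
                verts = np.asarray(buffered.exterior.coords[:-1], dtype=np.float64)
                if jitter_px > 0:
                    verts = verts + rng.uniform(-jitter_px, jitter_px, size=verts.shape)
                polys.append(verts)
        polygons[cls] = polys
    return AnnotationSet(polygons=polygons, pixel_size_nm=px)


# ---------------------------------------------------------------------------
# condition datasets

def condition_presets(base: SceneSpec | None = None) -> dict[str, SceneSpec]:
    """Four presets emulating treatment groups of increasing stimulation.

    Ring prevalence falls and fiber prevalence rises along the series, the
    qualitative ordering of activity-promoting treatments (low-activity
    block -> synaptic stimulation -> depolarisation -> glutamate).
    """
    base = base or SceneSpec()
    mixtures = {
        "high_Mg_low_Ca": (0.60, 0.10),
        "0Mg_Gly_Bic": (0.45, 0.25),
        "high_K": (0.30, 0.45),
        "Glu_Gly": (0.10, 0.60),
    }
    return {
        name: replace(base, ring_fraction=r, fiber_fraction=f)
        for name, (r, f) in mixtures.items()
    }


def _child_seed(master: int, *salt: int) -> int:
    ss = np.random.SeedSequence([int(master) % (2**31), *[int(s) % (2**31) for s in salt]])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_condition_dataset(
    conditions: dict[str, SceneSpec],
    n_images_per_condition: int,
    seed: int,
    out_dir: str | Path,
    weak_label_style: str = "polygon_box",
    weak_label_margin_nm: float = 60.0,
    weak_label_jitter_nm: float = 40.0,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Write a dataset (images, truth, weak labels) plus a CSV manifest.

    Every image gets its own seed derived from ``seed`` and its position, so
    the whole dataset is reproducible from the manifest.
    """
    if n_images_per_condition < 1:
        raise ValueError("n_images_per_condition must be >= 1")
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} exists; pass overwrite=True to replace the dataset"
        )
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for ci, (name, spec) in enumerate(conditions.items()):
        for j in range(n_images_per_condition):
            img_seed = _child_seed(seed, ci, j)
            img, truth = generate_scene(replace(spec, seed=img_seed))
            stem = f"{name}_{j:03d}"
            img.save(out_dir, stem)
            truth_path = out_dir / f"{stem}_truth.npz"
            truth.save(truth_path)
            ann = weak_labels_from_truth(
                truth, style=weak_label_style, margin_nm=weak_label_margin_nm,
                jitter_nm=weak_label_jitter_nm, seed=img_seed,
            )
            labels_path = out_dir / f"{stem}_labels.json"
            ann.to_json(labels_path)
            rows.append({
                "image": stem,
                "condition": name,
                "seed": img_seed,
                "truth": truth_path.name,
                "labels": labels_path.name,
            })
    manifest = pd.DataFrame(rows, columns=["image", "condition", "seed", "truth", "labels"])
    manifest.to_csv(manifest_path, index=False)
    return manifest


def manifest_hash(manifest: pd.DataFrame) -> str:
    return hashlib.sha256(manifest.to_csv(index=False).encode()).hexdigest()
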