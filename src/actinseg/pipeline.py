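"""Orchestration of the three experiment families.

1. training + threshold calibration (``prepare_training_data`` /
   ``train_replicates`` / ``calibrate_model``),
2. weak-label robustness (``run_robustness_experiment``): corrupt the
   training labels (instance omission and/or stepwise dilation), train
   replicate networks per corruption level, and compare each network's
   average precision against the fixed-segmentation AP of the very labels
   it was trained on,
3. condition comparison (``run_condition_experiment``): segment every
   image of a manifest, measure area fractions inside the marker-derived
   foreground mask plus morphometry, and run the randomization tests.

Dendritic and axonal analyses are separate runs with separate models and
masks; their outputs are never merged (different networks and masks make
the absolute detected areas incomparable).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import calibration as cal
from . import datamodel as dm
from . import fcn, metrics, quantify, synthgen
from . import stats as resampling

__all__ = [
    "ExperimentConfig", "prepare_training_data", "train_replicates",
    "calibrate_model", "model_segmenter", "truth_segmenter",
    "run_robustness_experiment", "run_condition_experiment",
]

MASK_ROLE_FOR_MODEL = {"h_d": "dendrite_like", "h_a": "axon_like"}


@dataclass
class ExperimentConfig:
    """Resolved YAML configuration of one run (stored verbatim per run)."""

    seed: int = 0
    n_images: int = 4
    scene: dict = field(default_factory=dict)
    conditions: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    window: int = 128
    overlap: int = 16
    min_label_frac: float = 0.01
    omission_fractions: tuple[float, ...] = (0.0, 0.3, 0.5, 0.7)
    dilation_radii_nm: tuple[float, ...] = (0.0, 100.0, 240.0, 500.0, 1000.0)
    replicates: int = 5
    max_epochs: int = 200
    patience: int = 10
    n_rep: int = 10_000
    stats_pairs: list = field(default_factory=list)

    def __post_init__(self):
        self.omission_fractions = tuple(self.omission_fractions)
        self.dilation_radii_nm = tuple(self.dilation_radii_nm)

    def validate(self) -> "ExperimentConfig":
        if self.replicates < 1 or self.n_images < 1:
            raise ValueError("replicates and n_images must be positive")
        if not 0 <= self.min_label_frac <= 1:
            raise ValueError("min_label_frac must lie in [0, 1]")
        for f in self.omission_fractions:
            if not 0 <= f <= 1:
                raise ValueError("omission fractions must lie in [0, 1]")
        if any(r < 0 for r in self.dilation_radii_nm):
            raise ValueError("dilation radii must be non-negative")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc).validate()

    def to_yaml(self, path: str | Path) -> None:
        doc = {k: getattr(self, k) for k in self.__dataclass_fields__}
        for k, v in doc.items():
            if isinstance(v, tuple):
                doc[k] = list(v)
        Path(path).write_text(yaml.safe_dump(doc))


# ---------------------------------------------------------------------------
# training data assembly

def _scene_label_maps(
    truth: synthgen.GroundTruth,
    ann: dm.AnnotationSet,
    restrict_role: str | None,
    dilate_nm: float = 0.0,
) -> dict[str, np.ndarray]:
    shape = next(iter(truth.class_maps.values())).shape
    restrict = truth.process_masks[restrict_role] if restrict_role else None
    if dilate_nm > 0:
        return dm.corrupt_dilate(ann, dilate_nm, shape, restrict_mask=restrict)
    return dm.rasterize(ann, shape, restrict_mask=restrict)


def prepare_training_data(
    scenes: list[tuple[synthgen.NanoscopyImage, synthgen.GroundTruth]],
    window: int = 128,
    overlap: int = 16,
    min_label_frac: float = 0.01,
    label_style: str = "polygon_box",
    label_margin_nm: float = 60.0,
    label_jitter_nm: float = 40.0,
    omit_fraction: float = 0.0,
    dilate_nm: float = 0.0,
    seed: int = 0,
    restrict_to_mask: bool = False,
    normalization: dm.NormalizationParams | None = None,
) -> dm.CropSet:
    """Weak labels -> rasters -> filtered, normalized crops.

    Corruption keeps the crop population constant: crops are selected with
    the *uncorrupted* labels' class-imbalance filter, then their label
    planes are replaced by the corrupted rasters.
    """
    images = [img.channels["structure"] for img, _ in scenes]
    if normalization is None:
        normalization = dm.fit_normalization(images)

    crops: list[dm.Crop] = []
    for i, (img, truth) in enumerate(scenes):
        ann = synthgen.weak_labels_from_truth(
            truth, style=label_style, margin_nm=label_margin_nm,
            jitter_nm=label_jitter_nm, seed=synthgen._child_seed(seed, i),
        )
        base_maps = _scene_label_maps(truth, ann, None)
        base = dm.extract_crops(
            dm.normalize(img.channels["structure"], normalization),
            base_maps, window=window, overlap=overlap,
            min_label_frac=min_label_frac, source_id=str(i),
        )
        if omit_fraction > 0 or dilate_nm > 0:
            corrupted = ann
            if omit_fraction > 0:
                corrupted = dm.corrupt_omit(
                    corrupted, omit_fraction, seed=synthgen._child_seed(seed, i, 1))
            cor_maps = _scene_label_maps(truth, corrupted, None, dilate_nm=dilate_nm)
            for crop in base:
                r, c = crop.offset
                crop.labels = {
                    k: m[r:r + window, c:c + window].astype(bool)
                    for k, m in cor_maps.items()
                }
        crops.extend(base.crops)
    out = dm.CropSet(crops=crops, window=window, normalization=normalization)
    if not len(out):
        raise ValueError("no crop survived the class-imbalance filter")
    return out


def train_replicates(
    spec: fcn.ModelSpec,
    train_set: dm.CropSet,
    val_set: dm.CropSet,
    k: int = 5,
    max_epochs: int = 200,
    patience: int = 10,
    seed: int = 0,
) -> list[fcn.TrainedModel]:
    """k independently seeded trainings of the same configuration."""
    out = []
    for i in range(k):
        s = synthgen._child_seed(seed, i)
        model = fcn.build_model(replace(spec, seed=s))
        out.append(fcn.train(model, train_set, val_set,
                             max_epochs=max_epochs, patience=patience, seed=s))
    return out


def calibrate_model(
    trained: fcn.TrainedModel,
    val_scenes: list[tuple[synthgen.NanoscopyImage, synthgen.GroundTruth]],
    grid: int | str = 512,
) -> fcn.TrainedModel:
    """Attach ROC-optimal per-class thresholds computed on validation scenes."""
    pairs: dict[str, list] = {cls: [] for cls in trained.spec.class_names}
    for img, truth in val_scenes:
        preds = fcn.predict(trained, img.channels["structure"])
        for cls in pairs:
            pairs[cls].append((preds[cls], truth.class_maps[cls]))
    result = cal.calibrate(pairs, grid=grid)
    trained.thresholds = result.thresholds
    return trained


# ---------------------------------------------------------------------------
# segmenters

def model_segmenter(trained: fcn.TrainedModel, thresholds: dict[str, float] | None = None):
    """Image -> binary segmentation maps via predict + hard thresholds."""
    thr = thresholds or trained.thresholds
    if thr is None:
        thr = cal.DEFAULT_THRESHOLDS[trained.spec.name]

    def segment(img: synthgen.NanoscopyImage) -> dict[str, np.ndarray]:
        preds = fcn.predict(trained, img.channels["structure"])
        return {cls: preds[cls] >= thr[cls] for cls in preds}

    return segment


def truth_segmenter(truths: dict[str, synthgen.GroundTruth]):
    """Oracle segmenter backed by ground truth, keyed by image id.

    Stands in for a trained network in scaled-down runs that exercise the
    quantification and statistics stages only.
    """

    def segment(img_id: str) -> dict[str, np.ndarray]:
        return dict(truths[img_id].class_maps)

    return segment


# ---------------------------------------------------------------------------
# experiment 2: weak-label robustness

def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    m = values.mean()
    if len(values) < 2:
        return (m, m)
    half = sps.t.ppf(0.5 + level / 2, df=len(values) - 1) * sps.sem(values)
    return (m - half, m + half)


def run_robustness_experiment(
    train_scenes,
    val_scenes,
    test_scenes,
    model_spec: fcn.ModelSpec,
    corruption_levels: list[dict],
    replicates: int = 5,
    window: int = 128,
    overlap: int = 16,
    min_label_frac: float = 0.01,
    max_epochs: int = 200,
    patience: int = 10,
    seed: int = 0,
) -> dict:
    """AP of replicate networks vs the AP of their own corrupted labels.

    ``corruption_levels`` is a list of ``{"omit_fraction": f}`` and/or
    ``{"dilate_nm": r}`` dicts; the empty dict is plain training.  Returns
    per-replicate AP values, the per-level mean and 95% t-interval, and
    the fixed-segmentation AP of the corrupted training labels themselves,
    all scored against the precise ground truth of held-out test scenes.
    """
    rows = []
    levels = []
    for li, level in enumerate(corruption_levels):
        omit = float(level.get("omit_fraction", 0.0))
        dil = float(level.get("dilate_nm", 0.0))
        train_set = prepare_training_data(
            train_scenes, window=window, overlap=overlap,
            min_label_frac=min_label_frac, omit_fraction=omit, dilate_nm=dil,
            seed=synthgen._child_seed(seed, li),
        )
        val_set = prepare_training_data(
            val_scenes, window=window, overlap=overlap,
            min_label_frac=min_label_frac,
            seed=synthgen._child_seed(seed, li, 7),
            normalization=train_set.normalization,
        )
        # AP of the corrupted labels themselves on the held-out truth
        label_aps = {cls: [] for cls in model_spec.class_names}
        for i, (img, truth) in enumerate(test_scenes):
            ann = synthgen.weak_labels_from_truth(
                truth, style="polygon_box", margin_nm=60.0, jitter_nm=40.0,
                seed=synthgen._child_seed(seed, li, 100 + i),
            )
            if omit > 0:
                ann = dm.corrupt_omit(ann, omit,
                                      seed=synthgen._child_seed(seed, li, 200 + i))
            maps = _scene_label_maps(truth, ann, None, dilate_nm=dil)
            for cls in label_aps:
                try:
                    label_aps[cls].append(metrics.ap_of_fixed_segmentation(
                        maps[cls], truth.class_maps[cls]))
                except ValueError:
                    pass
        label_ap = {cls: float(np.mean(v)) if v else np.nan
                    for cls, v in label_aps.items()}

        models = train_replicates(
            model_spec, train_set, val_set, k=replicates,
            max_epochs=max_epochs, patience=patience,
            seed=synthgen._child_seed(seed, li, 3),
        )
        for ri, trained in enumerate(models):
            trained = calibrate_model(trained, val_scenes)
            for cls in model_spec.class_names:
                aps = []
                for img, truth in test_scenes:
                    pred = fcn.predict(trained, img.channels["structure"])[cls]
                    try:
                        aps.append(metrics.pr_curve(pred, truth.class_maps[cls]).ap)
                    except ValueError:
                        pass
                rows.append({
                    "level": li, "omit_fraction": omit, "dilate_nm": dil,
                    "replicate": ri, "class": cls,
                    "ap": float(np.mean(aps)) if aps else np.nan,
                    "threshold": trained.thresholds[cls],
                })
        levels.append({"level": li, "omit_fraction": omit, "dilate_nm": dil,
                       **{f"label_ap_{cls}": v for cls, v in label_ap.items()}})

    per_rep = pd.DataFrame(rows)
    summary = []
    for (li, cls), grp in per_rep.groupby(["level", "class"]):
        lo, hi = _t_ci(grp["ap"].to_numpy())
        summary.append({
            "level": li, "class": cls, "ap_mean": grp["ap"].mean(),
            "ap_ci_low": lo, "ap_ci_high": hi, "n_replicates": len(grp),
        })
    summary = pd.DataFrame(summary).merge(pd.DataFrame(levels), on="level")
    return {"per_replicate": per_rep, "summary": summary}


# ---------------------------------------------------------------------------
# experiment 3: condition comparison

def run_condition_experiment(
    images: dict[str, synthgen.NanoscopyImage],
    conditions: dict[str, str],
    segment,
    mask_role: str = "dendrite_like",
    mask_sigma_px: float = 20.0,
    pairs: list[tuple[str, str]] | None = None,
    n_rep: int = 10_000,
    seed: int = 0,
) -> dict:
    """Per image: segment -> foreground mask -> fractions + morphometry.

    ``segment`` is a callable; it receives the NanoscopyImage (model
    segmenter) or the image id (truth segmenter) -- dispatch is on a
    one-argument call with the image falling back to the id.  Images
    missing the required marker channel are skipped and listed.
    """
    rows = []
    skipped = []
    for img_id in sorted(images):
        img = images[img_id]
        if mask_role not in img.channels:
            skipped.append(img_id)
            continue
        try:
            seg_maps = segment(img)
        except (TypeError, KeyError):
            seg_maps = segment(img_id)
        mask = quantify.foreground_mask(img.channels[mask_role],
                                        sigma_px=mask_sigma_px, role=mask_role)
        rows.append(quantify.condition_table_row(
            img_id, conditions[img_id], seg_maps, mask, img.pixel_size_nm))
    table = pd.DataFrame(rows)
    report = {"table": table, "skipped": skipped, "stats": None}
    if pairs:
        report["stats"] = resampling.compare_conditions(
            table, pairs, n_rep=n_rep, seed=seed)
    return report
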