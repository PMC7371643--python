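"""Encoder-decoder segmentation networks, training loop and tiled inference.

Two configurations are shipped: ``h_d`` (dendritic rings + fibers, RMSE
loss, filters 16/32/64/128, batch 72) and ``h_a`` (axonal rings only,
cross-entropy loss, filters 8/16/32/64, batch 96).  Each output channel
is an independent per-pixel score in [0, 1] (sigmoid), because a region
may contain both pattern classes at once.

The contracting path has one resolution step per entry of
``encoder_filters`` ([3x3 conv - batchnorm - ReLU] x 2 then 2x2 max-pool),
a same-width bottleneck block, and a symmetric expanding path (2x2
stride-2 transposed convolution, concatenated skip from the matching
encoder step, then a conv block).  A final 1x1 convolution collapses the
features into the class score maps.  Input sides must be divisible by
``2 ** len(encoder_filters)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._nn import (
    Adam, Conv2d, ConvBlock, ConvTranspose2, Sigmoid, bce_loss, rmse_loss,
)
from .datamodel import CropSet, NormalizationParams, augment, normalize

__all__ = [
    "ModelSpec", "UNet", "TrainedModel", "build_model", "train", "predict",
    "save_checkpoint", "load_checkpoint",
]

CLASS_NAMES = {1: ("rings",), 2: ("rings", "fibers")}


@dataclass
class ModelSpec:
    name: str = "h_d"
    encoder_filters: tuple[int, ...] = (16, 32, 64, 128)
    out_channels: int = 2
    loss: str = "rmse"                # {"rmse", "cross_entropy"}
    learning_rate: float = 0.001
    batch_size: int = 72
    seed: int = 0

    def __post_init__(self):
        if list(self.encoder_filters) != sorted(set(self.encoder_filters)):
            raise ValueError("encoder_filters must be strictly increasing")
        if self.out_channels not in (1, 2):
            raise ValueError("out_channels must be 1 or 2")
        if self.loss not in ("rmse", "cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")

    @property
    def class_names(self) -> tuple[str, ...]:
        return CLASS_NAMES[self.out_channels]

    @classmethod
    def h_d(cls, **overrides) -> "ModelSpec":
        """Dendritic network: rings + fibers, RMSE loss."""
        kw = dict(name="h_d", encoder_filters=(16, 32, 64, 128), out_channels=2,
                  loss="rmse", batch_size=72)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def h_a(cls, **overrides) -> "ModelSpec":
        """Axonal network: rings only, cross-entropy loss."""
        kw = dict(name="h_a", encoder_filters=(8, 16, 32, 64), out_channels=1,
                  loss="cross_entropy", batch_size=96)
        kw.update(overrides)
        return cls(**kw)


class UNet:
    """Fixed-topology encoder-decoder with concatenated skip links."""

    def __init__(self, spec: ModelSpec, in_channels: int = 1):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        f = list(spec.encoder_filters)
        self.depth = len(f)
        self.enc = []
        cin = in_channels
        for cout in f:
            self.enc.append(ConvBlock(cin, cout, rng))
            cin = cout
        self.bottleneck = ConvBlock(f[-1], f[-1], rng)
        self.up = []
        self.dec = []
        cur = f[-1]
        for cout in reversed(f):
            self.up.append(ConvTranspose2(cur, cout, rng))
            self.dec.append(ConvBlock(2 * cout, cout, rng))
            cur = cout
        self.head = Conv2d(f[0], spec.out_channels, 1, rng)
        self.sigmoid = Sigmoid()
        from ._nn import MaxPool2
        self.pools = [MaxPool2() for _ in f]

    def params(self):
        out = []
        for block in self.enc:
            out += block.params()
        out += self.bottleneck.params()
        for up, dec in zip(self.up, self.dec):
            out += up.params() + dec.params()
        out += self.head.params()
        return out

    def check_input(self, x: np.ndarray) -> None:
        factor = 2 ** self.depth
        h, w = x.shape[-2:]
        if h % factor or w % factor:
            raise ValueError(
                f"input sides ({h}, {w}) must be divisible by {factor}; pad to "
                f"({-(-h // factor) * factor}, {-(-w // factor) * factor})"
            )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self.check_input(x)
        x = x.astype(np.float32)
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self.bottleneck.forward(x, training)
        self._skip_channels = []
        for up, dec, skip in zip(self.up, self.dec, reversed(skips)):
            x = up.forward(x, training)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, training)
        x = self.head.forward(x, training)
        return self.sigmoid.forward(x, training)

    def backward(self, dy: np.ndarray) -> None:
        dy = self.sigmoid.backward(dy)
        dy = self.head.backward(dy)
        dskips = []
        for i in range(len(self.dec) - 1, -1, -1):
            dy = self.dec[i].backward(dy)
            csk = self._skip_channels[i]
            dskip, dy = dy[:, :csk], dy[:, csk:]
            dskips.append(dskip)
            dy = self.up[i].backward(dy)
        dy = self.bottleneck.backward(dy)
        # dskips[k] pairs with encoder block k (filled shallow-first above)
        for i in range(self.depth - 1, -1, -1):
            dy = self.pools[i].backward(dy)
            dy = dy + dskips[i]
            dy = self.enc[i].backward(dy)

    def state(self) -> list[np.ndarray]:
        arrays = [p.value.copy() for p in self.params()]
        for bn in self._batchnorms():
            arrays += [bn.running_mean.copy(), bn.running_var.copy()]
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        params = self.params()
        for p, a in zip(params, arrays[: len(params)]):
            p.value = a.astype(np.float32).copy()
        rest = arrays[len(params):]
        for bn, i in zip(self._batchnorms(), range(0, len(rest), 2)):
            bn.running_mean = rest[i].astype(np.float32).copy()
            bn.running_var = rest[i + 1].astype(np.float32).copy()

    def _batchnorms(self):
        from ._nn import BatchNorm2d
        blocks = self.enc + [self.bottleneck] + self.dec
        out = []
        for block in blocks:
            out += [l for l in block.layers if isinstance(l, BatchNorm2d)]
        return out


def build_model(spec: ModelSpec) -> UNet:
    return UNet(spec)


@dataclass
class TrainedModel:
    spec: ModelSpec
    model: UNet
    normalization: NormalizationParams
    history: pd.DataFrame
    stopped_epoch: int
    best_epoch: int
    window: int = 128
    thresholds: dict[str, float] | None = None


_LOSSES = {"rmse": rmse_loss, "cross_entropy": bce_loss}


def _batched_loss(model: UNet, x: np.ndarray, y: np.ndarray, loss_fn,
                  batch_size: int) -> float:
    total, n = 0.0, 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i:i + batch_size], y[i:i + batch_size]
        loss, _ = loss_fn(model.forward(xb, training=False), yb)
        total += loss * len(xb)
        n += len(xb)
    return total / n


def train(
    model: UNet,
    train_set: CropSet,
    val_set: CropSet,
    max_epochs: int = 200,
    patience: int = 10,
    seed: int = 0,
    augment_crops: bool = True,
    verbose: bool = False,
) -> TrainedModel:
    """Adam training with per-epoch validation and early stopping.

    Keeps the weights of the best validation epoch; stops after
    ``patience`` epochs without improvement.  Augmentation redraws every
    epoch from a seeded generator, so the run is reproducible.
    """
    if not len(train_set) or not len(val_set):
        raise ValueError("train and validation sets must be non-empty")
    spec = model.spec
    loss_fn = _LOSSES[spec.loss]
    classes = spec.class_names
    rng = np.random.default_rng(seed)
    opt = Adam(model.params(), lr=spec.learning_rate)

    x_val, y_val = val_set.stacked(classes)
    x_tr_raw, y_tr_raw = train_set.stacked(classes)

    best_val = np.inf
    best_state = model.state()
    best_epoch = 0
    history = []
    since_best = 0
    for epoch in range(1, max_epochs + 1):
        if augment_crops:
            x_tr = np.empty_like(x_tr_raw)
            y_tr = np.empty_like(y_tr_raw)
            for i in range(len(x_tr_raw)):
                labels = {k: y_tr_raw[i, j] for j, k in enumerate(classes)}
                patch, labels = augment(x_tr_raw[i, 0], labels, rng)
                x_tr[i, 0] = patch
                for j, k in enumerate(classes):
                    y_tr[i, j] = labels[k]
        else:
            x_tr, y_tr = x_tr_raw, y_tr_raw

        order = rng.permutation(len(x_tr))
        epoch_loss, nb = 0.0, 0
        for i in range(0, len(order), spec.batch_size):
            idx = order[i:i + spec.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            opt.zero_grad()
            pred = model.forward(xb, training=True)
            loss, grad = loss_fn(pred, yb)
            model.backward(grad)
            opt.step()
            epoch_loss += loss
            nb += 1

        val_loss = _batched_loss(model, x_val, y_val, loss_fn, spec.batch_size)
        if np.isnan(val_loss):
            raise FloatingPointError(
                f"validation loss became NaN at epoch {epoch}; "
                "check normalization and learning rate"
            )
        history.append({"epoch": epoch, "train_loss": epoch_loss / nb,
                        "val_loss": val_loss})
        if verbose:
            print(f"epoch {epoch}: train {epoch_loss / nb:.4f} val {val_loss:.4f}")
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best > patience:
                break

    model.load_state(best_state)
    return TrainedModel(
        spec=spec, model=model,
        normalization=train_set.normalization,
        history=pd.DataFrame(history),
        stopped_epoch=history[-1]["epoch"], best_epoch=best_epoch,
        window=train_set.window,
    )


def predict(
    trained: TrainedModel,
    image: np.ndarray,
    overlap: int = 16,
    already_normalized: bool = False,
) -> dict[str, np.ndarray]:
    """Whole-image prediction maps, one score plane in [0, 1] per class.

    Small images whose sides divide the pooling factor go through in one
    pass; anything else is tiled with the training window and ``overlap``
    pixels of overlap, averaging scores where tiles meet.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("predict expects a single-channel 2-D image")
    if not already_normalized:
        if trained.normalization is None:
            raise ValueError("model carries no normalization parameters")
        image = normalize(image, trained.normalization)
    h, w = image.shape
    factor = 2 ** trained.model.depth
    classes = trained.spec.class_names
    if h % factor == 0 and w % factor == 0 and max(h, w) <= 4 * trained.window:
        scores = trained.model.forward(image[None, None], training=False)[0]
        return {k: scores[i].astype(np.float64) for i, k in enumerate(classes)}

    window = trained.window
    if h < window or w < window:
        raise ValueError(f"image smaller than the {window}px inference window")
    from .datamodel import _window_starts
    stride = window - overlap
    acc = np.zeros((len(classes), h, w), dtype=np.float64)
    cnt = np.zeros((h, w), dtype=np.float64)
    tiles = [(r, c) for r in _window_starts(h, window, stride)
             for c in _window_starts(w, window, stride)]
    batch = []
    offs = []
    for r, c in tiles:
        batch.append(image[r:r + window, c:c + window])
        offs.append((r, c))
        if len(batch) == 16 or (r, c) == tiles[-1]:
            out = trained.model.forward(np.stack(batch)[:, None], training=False)
            for o, (rr, cc) in enumerate(offs):
                acc[:, rr:rr + window, cc:cc + window] += out[o]
                cnt[rr:rr + window, cc:cc + window] += 1.0
            batch, offs = [], []
    acc /= cnt[None]
    return {k: acc[i] for i, k in enumerate(classes)}


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(trained: TrainedModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = trained.model.state()
    np.savez_compressed(directory / "weights.npz",
                        **{f"arr_{i}": a for i, a in enumerate(arrays)})
    spec = trained.spec
    doc = {
        "name": spec.name, "encoder_filters": list(spec.encoder_filters),
        "out_channels": spec.out_channels, "loss": spec.loss,
        "learning_rate": spec.learning_rate, "batch_size": spec.batch_size,
        "seed": spec.seed, "window": trained.window,
        "best_epoch": trained.best_epoch, "stopped_epoch": int(trained.stopped_epoch),
        "thresholds": trained.thresholds,
    }
    (directory / "spec.yaml").write_text(yaml.safe_dump(doc))
    if trained.normalization is not None:
        trained.normalization.to_yaml(directory / "normalization.yaml")
    trained.history.to_csv(directory / "history.csv", index=False)


def load_checkpoint(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    doc = yaml.safe_load((directory / "spec.yaml").read_text())
    spec = ModelSpec(
        name=doc["name"], encoder_filters=tuple(doc["encoder_filters"]),
        out_channels=doc["out_channels"], loss=doc["loss"],
        learning_rate=doc["learning_rate"], batch_size=doc["batch_size"],
        seed=doc["seed"],
    )
    model = UNet(spec)
    with np.load(directory / "weights.npz") as z:
        model.load_state([z[f"arr_{i}"] for i in range(len(z.files))])
    norm_path = directory / "normalization.yaml"
    normalization = NormalizationParams.from_yaml(norm_path) if norm_path.exists() else None
    history = pd.read_csv(directory / "history.csv")
    return TrainedModel(
        spec=spec, model=model, normalization=normalization, history=history,
        stopped_epoch=doc["stopped_epoch"], best_epoch=doc["best_epoch"],
        window=doc["window"], thresholds=doc.get("thresholds"),
    )
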