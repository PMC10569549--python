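"""Patch-based 3D U-Net training and full-volume inference.

The network follows the classic 3D U-Net: a contracting path of repeated
[3x3x3 conv + batch norm + ReLU] x 2 blocks, each followed by 2x2x2 max
pooling with stride 2 and a doubling of feature channels from
``base_channels`` up to ``max_channels``; an expansive path of nearest
upsampling, concatenation with the corresponding encoder feature map and two
more conv+BN+ReLU blocks; and a final 1x1x1 convolution onto the label
scores.  Training minimises voxel-wise categorical cross-entropy with
stochastic gradient descent (learning rate 0.01, decay 1e-6, momentum 0.9,
Nesterov).

Volumes are rescaled to a common grid (trilinear for images, nearest for
labels), standardized to zero mean / unit variance, and cut into overlapping
cubic patches on a stride grid; at inference the per-patch class scores are
fused back (averaged over overlaps, or majority-voted on labels) and the
result is rescaled to the input grid.  Validation Dice is computed on
stitched full volumes after each epoch and only the best-performing weights
are kept.

Profiles: :meth:`NetConfig.full` is the full-scale configuration (256-cubed
grid, channels 32..1024, 200 epochs, batch 24 — GPU-scale, impractical on a
single CPU); :meth:`NetConfig.desk` and :meth:`NetConfig.mini` are reduced
profiles for desk-scale and test-scale runs on synthetic phantoms.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nn
from .core import (
    ConfigError,
    DEFAULT_LABEL_MAP,
    InvalidParameterError,
    LabelVolume,
    ShapeError,
    Volume3D,
    logger,
)
from .metrics import dice
from .preprocess import normalize_intensity


@dataclass
class NetConfig:
    patch_size: int = 64
    stride: int = 32
    scaled_shape: tuple[int, int, int] = (256, 256, 256)
    base_channels: int = 32
    max_channels: int = 1024
    epochs: int = 200
    batch_size: int = 24
    learning_rate: float = 0.01
    decay: float = 1e-6
    momentum: float = 0.9
    nesterov: bool = True
    n_labels: int = 7          # six neuropils + background
    fusion: str = "average"    # or "vote"
    validation_interval: int = 1
    select_best: bool = True
    seed: int = 0

    def __post_init__(self):
        self.validate()

    @property
    def levels(self) -> int:
        """Number of pooling steps (channel doublings base -> max)."""
        ratio = self.max_channels / self.base_channels
        lv = int(round(np.log2(ratio)))
        if 2 ** lv != ratio or lv < 1:
            raise ConfigError(
                f"max_channels/base_channels must be a power of two >= 2, got {ratio}"
            )
        return lv

    def validate(self) -> None:
        lv = self.levels
        if self.patch_size % (2 ** lv) != 0:
            raise ConfigError(
                f"patch_size {self.patch_size} not divisible by 2^levels = {2 ** lv}"
            )
        if not 0 < self.stride <= self.patch_size:
            raise ConfigError("stride must be in (0, patch_size]")
        if self.fusion not in ("average", "vote"):
            raise ConfigError(f"unknown fusion mode {self.fusion!r}")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")

    @classmethod
    def full(cls, **overrides) -> "NetConfig":
        return cls(**overrides)

    @classmethod
    def desk(cls, **overrides) -> "NetConfig":
        defaults = dict(
            patch_size=64, stride=32, scaled_shape=(96, 96, 96),
            base_channels=8, max_channels=128, epochs=40, batch_size=4,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def mini(cls, **overrides) -> "NetConfig":
        """Test-scale profile: one 32-cubed patch per scaled volume and a
        learning rate raised to 0.1 — with only a handful of gradient steps
        per epoch (vs hundreds at full scale) the full-scale rate of 0.01
        undertrains badly."""
        defaults = dict(
            patch_size=32, stride=32, scaled_shape=(32, 32, 32),
            base_channels=8, max_channels=64, epochs=60, batch_size=4,
            learning_rate=0.1, validation_interval=2,
        )
        defaults.update(overrides)
        return cls(**defaults)


# patch grid -----------------------------------------------------------------


def _axis_positions(length: int, patch: int, stride: int) -> tuple[int, list[int]]:
    """Padded length and patch start offsets covering one axis."""
    if length < patch:
        padded = patch
    else:
        n_steps = int(np.ceil((length - patch) / stride))
        padded = patch + n_steps * stride
    return padded, list(range(0, padded - patch + 1, stride))


def patch_grid(
    shape: tuple[int, int, int], patch: int, stride: int
) -> tuple[list[tuple[int, int, int]], tuple[int, int, int]]:
    """Patch start offsets and padded shape for a volume shape (no data)."""
    if patch <= 0 or stride <= 0 or stride > patch:
        raise InvalidParameterError("require 0 < stride <= patch")
    padded_shape, positions = [], []
    for length in shape:
        padded, pos = _axis_positions(length, patch, stride)
        padded_shape.append(padded)
        positions.append(pos)
    offsets = [(z, y, x) for z in positions[0] for y in positions[1] for x in positions[2]]
    return offsets, tuple(padded_shape)


def extract_patches(
    data: np.ndarray, patch: int, stride: int, pad_value: float = 0.0
) -> tuple[np.ndarray, list[tuple[int, int, int]], tuple[int, int, int]]:
    """Cut a volume into an overlapping grid of cubic patches.

    The volume is padded (with ``pad_value``) up to the next stride multiple
    so the grid tiles it exactly; offsets are recorded so stitching is exact.
    Returns (patches, offsets, padded_shape).
    """
    offsets, padded_shape = patch_grid(data.shape, patch, stride)
    pads = [(0, p - s) for p, s in zip(padded_shape, data.shape)]
    padded = np.pad(data, pads, constant_values=pad_value)
    patches = np.stack(
        [padded[z:z + patch, y:y + patch, x:x + patch] for z, y, x in offsets]
    )
    return patches, offsets, tuple(padded_shape)


def stitch_scores(
    scores: np.ndarray, offsets, padded_shape, n_labels: int, mode: str = "average"
) -> np.ndarray:
    """Fuse per-patch class scores back onto the padded grid.

    ``average`` accumulates scores and divides by the overlap count;
    ``vote`` counts per-patch argmax votes.  Returns (n_labels, *padded_shape).
    """
    patch = scores.shape[-1]
    acc = np.zeros((n_labels, *padded_shape), dtype=np.float64)
    if mode == "average":
        count = np.zeros(padded_shape, dtype=np.int32)
        for s, (z, y, x) in zip(scores, offsets):
            acc[:, z:z + patch, y:y + patch, x:x + patch] += s
            count[z:z + patch, y:y + patch, x:x + patch] += 1
        acc /= np.maximum(count, 1)
    elif mode == "vote":
        for s, (z, y, x) in zip(scores, offsets):
            lab = s.argmax(axis=0)
            block = acc[:, z:z + patch, y:y + patch, x:x + patch]
            for lid in range(n_labels):
                block[lid] += lab == lid
    else:
        raise ConfigError(f"unknown fusion mode {mode!r}")
    return acc


# model ----------------------------------------------------------------------


class _ConvBlock(nn.Sequential):
    def __init__(self, c_in, c_out, rng, name):
        super().__init__(
            nn.Conv(c_in, c_out, (3, 3, 3), rng, name=f"{name}.conv1"),
            nn.BatchNorm(c_out, 3, name=f"{name}.bn1"),
            nn.ReLU(),
            nn.Conv(c_out, c_out, (3, 3, 3), rng, name=f"{name}.conv2"),
            nn.BatchNorm(c_out, 3, name=f"{name}.bn2"),
            nn.ReLU(),
        )


class UNet3D:
    """3D U-Net; built from a :class:`NetConfig`, in_channels fixed to 1."""

    def __init__(self, cfg: NetConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        lv = cfg.levels
        chans = [cfg.base_channels * 2 ** i for i in range(lv)]  # encoder channels
        self.enc = []
        c_prev = 1
        for i, c in enumerate(chans):
            self.enc.append(_ConvBlock(c_prev, c, rng, f"enc{i}"))
            c_prev = c
        self.pool = nn.MaxPool((2, 2, 2))
        self.bottleneck = _ConvBlock(c_prev, cfg.max_channels, rng, "bottleneck")
        self.up = nn.Upsample((2, 2, 2))
        self.dec = []
        c_prev = cfg.max_channels
        for i, c in reversed(list(enumerate(chans))):
            self.dec.append(_ConvBlock(c_prev + c, c, rng, f"dec{i}"))
            c_prev = c
        self.final = nn.Conv(c_prev, cfg.n_labels, (1, 1, 1), rng, name="final")
        # per-stage pool/upsample instances (they cache shapes/indices)
        self._pools = [nn.MaxPool((2, 2, 2)) for _ in chans]
        self._ups = [nn.Upsample((2, 2, 2)) for _ in chans]

    # -- parameter access

    def params(self) -> list[nn.Param]:
        out = []
        for b in self.enc:
            out += b.params()
        out += self.bottleneck.params()
        for b in self.dec:
            out += b.params()
        out += self.final.params()
        return out

    def encoder_params(self) -> list[nn.Param]:
        """Contracting-path parameters (encoder blocks + bottleneck)."""
        out = []
        for b in self.enc:
            out += b.params()
        out += self.bottleneck.params()
        return out

    def decoder_params(self) -> list[nn.Param]:
        out = []
        for b in self.dec:
            out += b.params()
        out += self.final.params()
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    # -- forward / backward

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        skips = []
        h = x
        for block, pool in zip(self.enc, self._pools):
            h = block.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        for block, up, skip in zip(self.dec, self._ups, reversed(skips)):
            h = up.forward(h, train)
            h = np.concatenate([h, skip], axis=1)
            h = block.forward(h, train)
        self._skip_channels = [s.shape[1] for s in skips]
        return self.final.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.final.backward(dlogits)
        dskips = []
        for block, up, c_skip in zip(
            reversed(self.dec), reversed(self._ups), self._skip_channels
        ):
            d = block.backward(d)
            d, dskip = d[:, :-c_skip], d[:, -c_skip:]
            dskips.append(dskip)
            d = up.backward(d)
        d = self.bottleneck.backward(d)
        for block, pool, dskip in zip(
            reversed(self.enc), reversed(self._pools), reversed(dskips)
        ):
            d = pool.backward(d)
            d = d + dskip
            d = block.backward(d)
        return d


def build_unet(cfg: NetConfig) -> UNet3D:
    """Construct an untrained 3D U-Net; parameter count is a pure function
    of the config."""
    return UNet3D(cfg)


@dataclass
class TrainedModel:
    """Best-validation-epoch weights, config and training history."""

    weights: list[np.ndarray]
    cfg: NetConfig
    history: dict
    best_epoch: int
    label_map: dict[int, tuple[str, bool]] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_MAP)
    )

    @property
    def best_val_dice(self) -> float:
        vals = [d for d in self.history.get("val_dice", []) if d is not None]
        return max(vals) if vals else float("nan")

    def build(self) -> UNet3D:
        model = build_unet(self.cfg)
        _set_flat(model, self.weights)
        return model


def _iter_layers(model: UNet3D):
    for b in model.enc:
        yield from b.layers
    yield from model.bottleneck.layers
    for b in model.dec:
        yield from b.layers
    yield model.final


def _get_flat(model: UNet3D) -> list[np.ndarray]:
    """Full model state: weights plus batch-norm running statistics."""
    out = []
    for layer in _iter_layers(model):
        out += [p.value.copy() for p in layer.params()]
        if isinstance(layer, nn.BatchNorm):
            out += [layer.running_mean.copy(), layer.running_var.copy()]
    return out


def _set_flat(model: UNet3D, weights: list[np.ndarray]) -> None:
    it = iter(weights)
    for layer in _iter_layers(model):
        for p in layer.params():
            p.value = next(it).copy()
            p.grad = np.zeros_like(p.value)
        if isinstance(layer, nn.BatchNorm):
            layer.running_mean = next(it).copy()
            layer.running_var = next(it).copy()
    if next(it, None) is not None:
        raise InvalidParameterError("weight list does not match the architecture")


# scaling --------------------------------------------------------------------


def resize3d(data: np.ndarray, shape: tuple[int, int, int], order: int) -> np.ndarray:
    """Resize to an exact target shape (order 0 = nearest for labels,
    order 1 = trilinear for images)."""
    if tuple(data.shape) == tuple(shape):
        return data.copy()
    factors = [t / s for t, s in zip(shape, data.shape)]
    out = ndimage.zoom(data, factors, order=order, mode="nearest",
                       grid_mode=True, prefilter=False)
    # zoom occasionally rounds a voxel off the target; crop/pad defensively
    slices = tuple(slice(0, min(a, b)) for a, b in zip(out.shape, shape))
    fixed = np.zeros(shape, dtype=out.dtype)
    fixed[slices] = out[slices]
    for ax in range(3):
        if out.shape[ax] < shape[ax]:
            # replicate trailing edge
            idx = [slice(None)] * 3
            idx[ax] = slice(out.shape[ax], shape[ax])
            src = [slice(None)] * 3
            src[ax] = slice(out.shape[ax] - 1, out.shape[ax])
            fixed[tuple(idx)] = fixed[tuple(src)]
    return fixed


def _prepare_pair(v: Volume3D, lv: LabelVolume | None, cfg: NetConfig):
    img = resize3d(v.data.astype(np.float32), cfg.scaled_shape, order=1)
    img = normalize_intensity(Volume3D(img, v.spacing_mm)).data
    lab = None
    if lv is not None:
        if int(lv.data.max()) >= cfg.n_labels:
            raise InvalidParameterError(
                f"label id {int(lv.data.max())} outside the {cfg.n_labels}-class map"
            )
        lab = resize3d(lv.data, cfg.scaled_shape, order=0)
    return img, lab


# training -------------------------------------------------------------------


def _predict_scaled(model: UNet3D, img: np.ndarray, cfg: NetConfig) -> np.ndarray:
    """Argmax label field on the scaled grid for a standardized image."""
    patches, offsets, padded = extract_patches(img, cfg.patch_size, cfg.stride)
    scores = []
    for s in range(0, len(patches), cfg.batch_size):
        batch = patches[s:s + cfg.batch_size][:, None]
        logits = model.forward(batch, train=False)
        scores.append(nn.softmax(logits, axis=1))
    scores = np.concatenate(scores)
    fused = stitch_scores(scores, offsets, padded, cfg.n_labels, cfg.fusion)
    lab = fused.argmax(axis=0).astype(np.uint8)
    return lab[tuple(slice(0, s) for s in cfg.scaled_shape)]


def _val_dice(model, val_arrays, cfg, label_map) -> float:
    scores = []
    for img, lab in val_arrays:
        pred = _predict_scaled(model, img, cfg)
        _, total = dice(
            LabelVolume(pred, label_map=dict(label_map)),
            LabelVolume(lab.astype(np.uint8), label_map=dict(label_map)),
        )
        scores.append(total)
    return float(np.mean(scores))


def _fit(
    model: UNet3D,
    train_pairs,
    val_pairs,
    cfg: NetConfig,
    label_map,
    trainable_params,
) -> TrainedModel:
    if not train_pairs:
        raise InvalidParameterError("need at least one training pair")
    if cfg.select_best and not val_pairs:
        raise ConfigError("best-epoch selection requires a validation set")
    train_arrays = [_prepare_pair(v, l, cfg) for v, l in train_pairs]
    val_arrays = [_prepare_pair(v, l, cfg) for v, l in val_pairs]

    xs, ys = [], []
    for img, lab in train_arrays:
        px, off, padded = extract_patches(img, cfg.patch_size, cfg.stride)
        py, _, _ = extract_patches(lab, cfg.patch_size, cfg.stride, pad_value=0)
        xs.append(px)
        ys.append(py)
    x = np.concatenate(xs)[:, None].astype(np.float32)
    y = np.concatenate(ys).astype(np.int64)

    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.SGD(trainable_params, lr=cfg.learning_rate, momentum=cfg.momentum,
                 nesterov=cfg.nesterov, decay=cfg.decay)
    history = {"train_loss": [], "train_acc": [], "val_dice": []}
    best = (-np.inf, None, -1)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        losses, accs = [], []
        for s in range(0, len(x), cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            logits = model.forward(x[idx], train=True)
            loss, grad, acc = nn.softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
            accs.append(acc)
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(float(np.mean(accs)))
        if val_arrays and (epoch + 1) % cfg.validation_interval == 0:
            vd = _val_dice(model, val_arrays, cfg, label_map)
            history["val_dice"].append(vd)
            if vd > best[0]:
                best = (vd, _get_flat(model), epoch)
        else:
            history["val_dice"].append(None)
        logger.info(
            "epoch %d/%d loss %.4f acc %.4f val %s",
            epoch + 1, cfg.epochs, history["train_loss"][-1],
            history["train_acc"][-1], history["val_dice"][-1],
        )
    if cfg.select_best and best[1] is not None:
        weights, best_epoch = best[1], best[2]
    else:
        weights, best_epoch = _get_flat(model), cfg.epochs - 1
    history["n_parameters"] = model.n_parameters()
    history["n_trainable"] = sum(p.value.size for p in trainable_params)
    return TrainedModel(
        weights=weights, cfg=copy.deepcopy(cfg), history=history,
        best_epoch=best_epoch, label_map=dict(label_map),
    )


def train_unet(
    train: list[tuple[Volume3D, LabelVolume]],
    val: list[tuple[Volume3D, LabelVolume]],
    cfg: NetConfig,
) -> TrainedModel:
    """Train a 3D U-Net from scratch; keeps the best-validation-Dice weights."""
    label_map = train[0][1].label_map if train else DEFAULT_LABEL_MAP
    for _, l in list(train) + list(val):
        if l.label_map != label_map:
            raise InvalidParameterError("all pairs must share one label map")
    model = build_unet(cfg)
    return _fit(model, train, val, cfg, label_map, model.params())


def finetune_encoder(
    m: TrainedModel,
    train: list[tuple[Volume3D, LabelVolume]],
    val: list[tuple[Volume3D, LabelVolume]],
    cfg: NetConfig | None = None,
) -> TrainedModel:
    """Fine-tune with the decoder frozen: only contracting-path weights move."""
    if not train:
        raise InvalidParameterError("fine-tuning requires at least one new pair")
    for _, l in list(train) + list(val):
        if l.label_map != m.label_map:
            raise InvalidParameterError("label map mismatch with the base model")
    cfg = cfg or m.cfg
    model = m.build()
    for p in model.decoder_params():
        p.trainable = False
    out = _fit(model, train, val, cfg, m.label_map, model.encoder_params())
    # frozen decoder weights must survive verbatim
    return out


def predict_volume(m: TrainedModel, v: Volume3D) -> LabelVolume:
    """Segment a full volume: scale, patch, forward, fuse, rescale."""
    cfg = m.cfg
    model = m.build()
    img, _ = _prepare_pair(v, None, cfg)
    lab_scaled = _predict_scaled(model, img, cfg)
    lab = resize3d(lab_scaled, v.shape, order=0)
    return LabelVolume(lab.astype(np.uint8), spacing_mm=v.spacing_mm,
                       label_map=dict(m.label_map))


def learning_curve(
    pool: list[tuple[Volume3D, LabelVolume]],
    k_values: list[int],
    val: list[tuple[Volume3D, LabelVolume]],
    test: list[tuple[Volume3D, LabelVolume]],
    cfg: NetConfig,
    epochs_per_k: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Mean test Dice/ASSD after training from scratch on the first k pool
    items, for each k.

    ``epochs_per_k`` optionally overrides the epoch count per k, e.g. to
    equalise the total number of gradient steps across k (with a fixed epoch
    count, the step count grows with k and confounds the effect of more
    training images with longer optimisation).
    """
    from .metrics import assd as _assd

    if any(k <= 0 for k in k_values):
        raise ConfigError("k values must be positive")
    if max(k_values) > len(pool):
        raise ConfigError(f"max k {max(k_values)} exceeds pool size {len(pool)}")
    if not test:
        raise ConfigError("test set must not be empty")
    rows = []
    for k in k_values:
        cfg_k = cfg
        if epochs_per_k is not None:
            cfg_k = replace(cfg, epochs=int(epochs_per_k[k]))
        m = train_unet(pool[:k], val, cfg_k)
        dices, assds = [], []
        for v, truth in test:
            pred = predict_volume(m, v)
            _, td = dice(pred, truth)
            _, ta = _assd(pred, truth)
            dices.append(td)
            assds.append(ta)
        rows.append({
            "k": k,
            "mean_total_dice": float(np.mean(dices)),
            "mean_total_assd_vox": float(np.mean(assds)),
            "best_epoch": m.best_epoch,
        })
        logger.info("learning curve k=%d: dice %.4f", k, rows[-1]["mean_total_dice"])
    return pd.DataFrame(rows)
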