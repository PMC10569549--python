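"""Volume preprocessing: denoising, intensity standardisation, orientation,
and cropping to the neuropil region (manual bounding box or learned per-axis
slice classification).

The denoiser is an arithmetic mean filter with a 3x3x3 mask: each voxel is
replaced by the mean of its 27-neighbourhood.  Borders are handled by
reflect padding (the operator is linear and never leaves the input's value
range).

Automatic cropping trains, per axis, a small 2D convolutional slice
classifier deciding whether a slice contains any foreground object, in two
phases: first only the dense head is optimised (Adam, lr 1e-3), then the
whole network is fine-tuned at lr 1e-5.  The first/last slice classified as
containing the object on each axis, expanded by a buffer of slices (25 for
256-voxel axes, scaled proportionally with a floor of 2 for smaller grids),
defines the crop box.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import nn
from .core import (
    ConfigError,
    DegenerateInputError,
    EmptyDetectionError,
    InvalidParameterError,
    LabelVolume,
    Volume3D,
    logger,
)

Bbox = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # half-open per axis


def denoise_mean3(v: Volume3D) -> Volume3D:
    """Arithmetic 3x3x3 mean filter with reflect borders."""
    if v.data.size == 0:
        raise InvalidParameterError("volume is empty")
    out = ndimage.uniform_filter(v.data.astype(np.float64), size=3, mode="reflect")
    return replace(v, data=out.astype(v.data.dtype if np.issubdtype(v.data.dtype, np.floating) else np.float64))


def normalize_intensity(v: Volume3D, ref_mean: float = 0.0, ref_var: float = 1.0) -> Volume3D:
    """Affine rescale so the volume has the reference mean and variance."""
    data = v.data.astype(np.float64)
    var = data.var()
    if var <= 0:
        raise DegenerateInputError("cannot standardize a constant volume")
    out = (data - data.mean()) / np.sqrt(var) * np.sqrt(ref_var) + ref_mean
    return replace(v, data=out.astype(np.float32))


def flip_z(v: Volume3D) -> Volume3D:
    """Reverse slice order along z (an involution); records the flip."""
    return replace(v, data=v.data[::-1].copy(), z_flipped=not v.z_flipped)


def foreground_bbox(lv: LabelVolume) -> Bbox:
    """Tight half-open bounding box of all non-background voxels."""
    fg = lv.data != 0
    if not fg.any():
        raise EmptyDetectionError("label volume has no foreground")
    box = []
    for ax in range(3):
        proj = fg.any(axis=tuple(i for i in range(3) if i != ax))
        idx = np.where(proj)[0]
        box.append((int(idx[0]), int(idx[-1]) + 1))
    return tuple(box)


def expand_bbox(bbox: Bbox, buffer: int | tuple[int, int, int], shape) -> Bbox:
    buffers = (buffer,) * 3 if np.isscalar(buffer) else tuple(buffer)
    out = []
    for (lo, hi), b, size in zip(bbox, buffers, shape):
        out.append((max(0, lo - b), min(size, hi + b)))
    return tuple(out)


def crop_to_bbox(v: Volume3D | LabelVolume, bbox: Bbox, buffer: int = 0):
    """Subvolume covering ``bbox`` expanded by ``buffer`` slices per side,
    clamped to the volume; spacing preserved."""
    for (lo, hi), size in zip(bbox, v.shape):
        if not (0 <= lo < hi <= size):
            raise InvalidParameterError(f"invalid bbox {bbox} for shape {v.shape}")
    (z0, z1), (y0, y1), (x0, x1) = expand_bbox(bbox, buffer, v.shape)
    return replace(v, data=v.data[z0:z1, y0:y1, x0:x1].copy())


# automatic cropping ---------------------------------------------------------


@dataclass
class CropConfig:
    slice_size: int = 32
    epochs_head: int = 50
    epochs_finetune: int = 50
    lr_head: float = 1e-3
    lr_finetune: float = 1e-5
    batch_size: int = 32
    dropout: float = 0.3
    threshold: float = 0.5
    buffer_base: int = 25      # buffer slices for a buffer_ref-voxel axis
    buffer_ref: int = 256
    buffer_floor: int = 2
    val_fraction: float = 0.25
    seed: int = 0

    @classmethod
    def desk(cls, **overrides) -> "CropConfig":
        """Short schedule for small synthetic grids.

        The full-scale fine-tune rate of 1e-5 presumes a pre-trained
        backbone; training the small network from scratch needs a real
        learning rate in the second phase."""
        return cls(**{"epochs_head": 10, "epochs_finetune": 40,
                      "lr_finetune": 1e-3, "batch_size": 16, **overrides})


@dataclass
class CropModel:
    """Per-axis binary slice classifiers plus decision/buffer policy.

    ``norm_mean``/``norm_sd`` are the training-set intensity statistics;
    applying them (rather than per-volume statistics) at prediction time
    keeps an all-background volume looking like training background."""

    nets: tuple  # three nn.Sequential, axes (z, y, x)
    cfg: CropConfig
    norm_mean: float = 0.0
    norm_sd: float = 1.0
    history: dict = field(default_factory=dict)

    def buffer_for(self, axis_len: int) -> int:
        b = round(self.cfg.buffer_base * axis_len / self.cfg.buffer_ref)
        return max(self.cfg.buffer_floor, b)


def _build_slice_net(cfg: CropConfig, rng) -> nn.Sequential:
    drop_rng = np.random.default_rng(rng.integers(2**31))
    return nn.Sequential(
        nn.Conv(1, 4, (1, 3, 3), rng, name="c1"),
        nn.BatchNorm(4, 3, name="b1"),
        nn.ReLU(),
        nn.MaxPool((1, 2, 2)),
        nn.Conv(4, 8, (1, 3, 3), rng, name="c2"),
        nn.BatchNorm(8, 3, name="b2"),
        nn.ReLU(),
        nn.MaxPool((1, 2, 2)),
        nn.GlobalAvgPool(),
        nn.Dropout(cfg.dropout, drop_rng),
        nn.Dense(8, 1, rng, name="head"),
    )


def _slice_features(
    volume: np.ndarray, axis: int, size: int, mean: float, sd: float
) -> np.ndarray:
    """All slices along ``axis`` resized to (size, size), standardized with
    the supplied (training-set) statistics so slice-level brightness — the
    object-presence signal — survives."""
    arr = np.moveaxis(volume, axis, 0).astype(np.float64)
    arr = (arr - mean) / (sd if sd > 0 else 1.0)
    n, h, w = arr.shape
    zoomed = ndimage.zoom(arr, (1.0, size / h, size / w), order=1, mode="nearest")
    zoomed = zoomed[:, :size, :size]
    return zoomed[:, None, None, :, :].astype(np.float32)  # (N, 1, 1, size, size)


def _slice_labels(labels: np.ndarray, axis: int) -> np.ndarray:
    other = tuple(i for i in range(3) if i != axis)
    return (labels != 0).any(axis=other).astype(np.float32)


def _run_phase(net, x, y, params, lr, epochs, batch_size, rng):
    opt = nn.Adam(params, lr=lr)
    accs = []
    for _ in range(epochs):
        order = rng.permutation(len(x))
        ep_acc = []
        for s in range(0, len(x), batch_size):
            idx = order[s:s + batch_size]
            logits = net.forward(x[idx], train=True)
            _, grad, acc = nn.binary_cross_entropy(logits, y[idx, None])
            opt.zero_grad()
            net.backward(grad)
            opt.step()
            ep_acc.append(acc)
        accs.append(float(np.mean(ep_acc)))
    return accs


def train_crop_classifier(
    pairs: list[tuple[Volume3D, LabelVolume]], cfg: CropConfig | None = None
) -> CropModel:
    """Train the three per-axis slice classifiers on image/label pairs.

    Phase 1 trains the dense head only; phase 2 fine-tunes all weights at a
    much lower learning rate.  A random held-out fraction of slices provides
    the validation accuracy log.
    """
    cfg = cfg or CropConfig()
    if len(pairs) < 2:
        raise InvalidParameterError("need at least 2 training volumes")
    if cfg.epochs_head <= 0 and cfg.epochs_finetune <= 0:
        raise ConfigError("training requires a positive number of epochs")
    rng = np.random.default_rng(cfg.seed)
    nets = []
    history: dict = {"val_accuracy": [], "train_accuracy": []}
    all_data = np.concatenate([v.data.ravel() for v, _ in pairs])
    norm_mean = float(all_data.mean())
    norm_sd = float(all_data.std())
    del all_data
    for axis in range(3):
        x = np.concatenate([
            _slice_features(v.data, axis, cfg.slice_size, norm_mean, norm_sd)
            for v, _ in pairs
        ])
        y = np.concatenate([_slice_labels(l.data, axis) for _, l in pairs])
        if y.min() == y.max():
            raise DegenerateInputError(
                f"all slices on axis {'zyx'[axis]} belong to one class"
            )
        order = rng.permutation(len(x))
        n_val = max(1, int(len(x) * cfg.val_fraction))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        net = _build_slice_net(cfg, rng)
        head = [p for p in net.params() if p.name.startswith("head")]
        accs = []
        if cfg.epochs_head > 0:
            accs += _run_phase(net, x[tr_idx], y[tr_idx], head, cfg.lr_head,
                               cfg.epochs_head, cfg.batch_size, rng)
        if cfg.epochs_finetune > 0:
            accs += _run_phase(net, x[tr_idx], y[tr_idx], net.params(), cfg.lr_finetune,
                               cfg.epochs_finetune, cfg.batch_size, rng)
        logits = net.forward(x[val_idx], train=False)
        _, _, val_acc = nn.binary_cross_entropy(logits, y[val_idx, None])
        history["train_accuracy"].append(accs)
        history["val_accuracy"].append(float(val_acc))
        logger.info("crop classifier axis %s: val accuracy %.3f", "zyx"[axis], val_acc)
        nets.append(net)
    return CropModel(nets=tuple(nets), cfg=cfg, norm_mean=norm_mean,
                     norm_sd=norm_sd, history=history)


def predict_slice_presence(model: CropModel, v: Volume3D, axis: int) -> np.ndarray:
    x = _slice_features(v.data, axis, model.cfg.slice_size,
                        model.norm_mean, model.norm_sd)
    logits = model.nets[axis].forward(x, train=False)
    return nn.sigmoid(logits[:, 0])


def auto_crop(v: Volume3D, model: CropModel) -> Bbox:
    """Bounding box from per-axis slice presence, expanded by the buffer.

    Raises :class:`EmptyDetectionError` when no slice reaches the decision
    threshold on some axis.
    """
    box = []
    for axis in range(3):
        probs = predict_slice_presence(model, v, axis)
        present = np.where(probs >= model.cfg.threshold)[0]
        if len(present) == 0:
            raise EmptyDetectionError(f"no object slice detected on axis {'zyx'[axis]}")
        box.append((int(present[0]), int(present[-1]) + 1))
    return expand_bbox(tuple(box), tuple(model.buffer_for(s) for s in v.shape), v.shape)
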