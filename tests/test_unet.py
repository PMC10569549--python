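"""Patch extraction, U-Net construction, training contracts and inference."""

import numpy as np
import pytest

from beemorph import (
    LabelVolume,
    NetConfig,
    Volume3D,
    build_unet,
    dice,
    extract_patches,
    finetune_encoder,
    learning_curve,
    patch_grid,
    predict_volume,
    train_unet,
)
from beemorph.core import ConfigError, InvalidParameterError
from beemorph.unet import _predict_scaled, resize3d, stitch_scores
from beemorph import nn


# patch grid -----------------------------------------------------------------


def test_patch_grid_overlapping_256():
    """256-cubed volume, patch 64, stride 32: 7 positions per axis, 343 patches."""
    offsets, padded = patch_grid((256, 256, 256), 64, 32)
    assert padded == (256, 256, 256)
    assert len(offsets) == 343
    zs = sorted({o[0] for o in offsets})
    assert zs == [0, 32, 64, 96, 128, 160, 192]


def test_patch_grid_exact_tiling():
    offsets, padded = patch_grid((256, 256, 256), 64, 64)
    assert len(offsets) == 64 and padded == (256, 256, 256)


def test_single_patch_volume(rng):
    data = rng.normal(size=(64, 64, 64))
    patches, offsets, padded = extract_patches(data, 64, 32)
    assert patches.shape == (1, 64, 64, 64)
    assert offsets == [(0, 0, 0)] and padded == (64, 64, 64)
    assert np.array_equal(patches[0], data)


def test_patches_pad_then_stitch_exactly(rng):
    data = rng.normal(size=(20, 20, 20)).astype(np.float32)
    patches, offsets, padded = extract_patches(data, 16, 8)
    assert padded == (24, 24, 24)
    # one-hot "scores" reassemble the padded volume exactly under averaging
    scores = patches[:, None]
    fused = stitch_scores(scores, offsets, padded, 1, "average")
    assert np.allclose(fused[0, :20, :20, :20], data, atol=1e-6)


def test_patch_size_errors():
    with pytest.raises(InvalidParameterError):
        extract_patches(np.zeros((8, 8, 8)), 4, 8)   # stride > patch
    with pytest.raises(InvalidParameterError):
        patch_grid((8, 8, 8), 0, 1)


# architecture ---------------------------------------------------------------


def test_channel_doubling_levels():
    cfg = NetConfig.mini()
    assert cfg.levels == 3          # 8 -> 16 -> 32 -> 64
    assert NetConfig(base_channels=32, max_channels=1024).levels == 5
    assert NetConfig(base_channels=32, max_channels=512).levels == 4
    with pytest.raises(ConfigError):
        NetConfig(base_channels=32, max_channels=48)
    with pytest.raises(ConfigError):
        NetConfig.mini(patch_size=20)    # not divisible by 2^levels


def test_unet_output_channels_match_labels():
    cfg = NetConfig.mini(n_labels=1)
    model = build_unet(cfg)
    x = np.zeros((1, 1, 32, 32, 32), dtype=np.float32)
    out = model.forward(x, train=False)
    assert out.shape == (1, 1, 32, 32, 32)


def test_parameter_count_is_config_function():
    a = build_unet(NetConfig.mini(seed=0))
    b = build_unet(NetConfig.mini(seed=123))
    assert a.n_parameters() == b.n_parameters()
    wider = build_unet(NetConfig.mini(base_channels=16, max_channels=128))
    assert wider.n_parameters() > a.n_parameters()


# training contracts ---------------------------------------------------------


@pytest.fixture(scope="module")
def trained(trained_mini):
    return trained_mini


@pytest.fixture(scope="module")
def memorized(phantoms32):
    """One phantom trained to convergence with itself as validation."""
    ph = phantoms32["phantoms"]
    cfg = NetConfig.mini(seed=0, epochs=150, validation_interval=25)
    return train_unet(ph[:1], ph[:1], cfg)


def test_best_epoch_contract(trained):
    vals = [v for v in trained.history["val_dice"] if v is not None]
    assert trained.best_val_dice == pytest.approx(max(vals))


def test_training_is_deterministic(phantoms32):
    ph = phantoms32["phantoms"]
    cfg = NetConfig.mini(seed=3, epochs=3, validation_interval=1)
    a = train_unet(ph[:2], ph[8:9], cfg)
    b = train_unet(ph[:2], ph[8:9], cfg)
    assert a.history["train_loss"] == b.history["train_loss"]
    assert a.history["val_dice"] == b.history["val_dice"]


def test_empty_validation_with_best_selection_rejected(phantoms32):
    ph = phantoms32["phantoms"]
    with pytest.raises(ConfigError):
        train_unet(ph[:2], [], NetConfig.mini(epochs=1))


def test_memorization_reaches_high_dice(memorized, phantoms32):
    """A model trained to convergence on one phantom reproduces it."""
    vol, truth = phantoms32["phantoms"][0]
    assert memorized.best_val_dice > 0.95
    pred = predict_volume(memorized, vol)
    assert pred.shape == vol.shape
    assert set(np.unique(pred.data)) <= set(range(7))
    _, total = dice(pred, truth)
    assert total > 0.95


def test_overlap_fusion_modes_agree_on_easy_input(trained, phantoms32):
    """Halving the stride changes only patch-border behaviour."""
    vol, truth = phantoms32["phantoms"][10]
    import dataclasses

    m2 = dataclasses.replace(trained, cfg=dataclasses.replace(trained.cfg, stride=16))
    _, d1 = dice(predict_volume(trained, vol), truth)
    _, d2 = dice(predict_volume(m2, vol), truth)
    assert abs(d1 - d2) < 0.02


def test_finetune_freezes_decoder(trained, phantoms32):
    ph = phantoms32["phantoms"]
    cfg = NetConfig.mini(seed=1, epochs=2, validation_interval=1)
    base = trained.build()
    dec_before = [p.value.copy() for p in base.decoder_params()]
    tuned = finetune_encoder(trained, ph[10:12], ph[8:9], cfg)
    model = tuned.build()
    dec_after = [p.value for p in model.decoder_params()]
    for w0, w1 in zip(dec_before, dec_after):
        assert np.array_equal(w0, w1)
    assert tuned.history["n_trainable"] < tuned.history["n_parameters"]


def test_finetune_requires_new_data(trained):
    with pytest.raises(InvalidParameterError):
        finetune_encoder(trained, [], [], NetConfig.mini(epochs=1))


def test_label_id_outside_map_rejected(phantoms32):
    vol, lab = phantoms32["phantoms"][0]
    bad = LabelVolume(
        np.full(lab.shape, 3, dtype=np.uint8),
        label_map={3: ("CX", False)},
    )
    with pytest.raises(InvalidParameterError):
        train_unet([(vol, bad)], [(vol, bad)], NetConfig.mini(epochs=1, n_labels=2))


# scaling and stitching invariants -------------------------------------------


def test_label_scaling_roundtrip_preserves_structure(phantoms32):
    """96 -> 64 -> 96 nearest-neighbour round trip keeps Dice > 0.9."""
    from beemorph import PhantomParams, render_phantom, sample_cohort

    params = PhantomParams(grid_shape=(96, 96, 96), seed=21)
    cohort = sample_cohort(params, 1, {"H": 1})
    _, lab = render_phantom(cohort.iloc[0], params)
    down = resize3d(lab.data, (64, 64, 64), order=0)
    back = resize3d(down, (96, 96, 96), order=0)
    _, total = dice(
        LabelVolume(back.astype(np.uint8), label_map=dict(lab.label_map)),
        lab,
    )
    assert total > 0.9


def test_stitching_without_overlap_equals_per_patch_argmax(rng):
    """stride = patch and identity scaling: stitched argmax is exactly the
    per-patch argmax reassembly."""
    cfg = NetConfig.mini(seed=5, scaled_shape=(32, 32, 32), stride=32)
    model = build_unet(cfg)   # random weights are fine for this identity
    img = rng.normal(size=(32, 32, 32)).astype(np.float32)
    img = (img - img.mean()) / img.std()
    stitched = _predict_scaled(model, img, cfg)
    logits = model.forward(img[None, None], train=False)
    direct = nn.softmax(logits, axis=1)[0].argmax(axis=0)
    assert np.array_equal(stitched, direct)


# learning curve -------------------------------------------------------------


def test_learning_curve_contracts(phantoms24):
    ph = phantoms24["phantoms"]
    cfg = NetConfig.mini(
        seed=0, epochs=2, batch_size=2, validation_interval=1,
        patch_size=24, stride=24, scaled_shape=(24, 24, 24),
    )
    with pytest.raises(ConfigError):
        learning_curve(ph[:4], [0, 2], ph[4:5], ph[5:6], cfg)
    with pytest.raises(ConfigError):
        learning_curve(ph[:4], [8], ph[4:5], ph[5:6], cfg)
    with pytest.raises(ConfigError):
        learning_curve(ph[:4], [2], ph[4:5], [], cfg)
    a = learning_curve(ph[:2], [2], ph[4:5], ph[5:6], cfg)
    b = learning_curve(ph[:2], [2], ph[4:5], ph[5:6], cfg)
    assert a.equals(b)
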