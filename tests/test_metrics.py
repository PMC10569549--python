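"""Dice and ASSD against brute-force oracles and closed-form cases."""

import numpy as np
import pytest

from beemorph import LabelVolume, assd, dice, error_category, evaluate
from beemorph.core import InvalidParameterError, ShapeError

MAP2 = {1: ("A", False), 2: ("B", False)}


def lv(arr, label_map=None, spacing=1.0):
    return LabelVolume(
        np.asarray(arr, dtype=np.uint8), spacing_mm=spacing,
        label_map=label_map or MAP2,
    )


def brute_dice(a, b, labels):
    """Set-based Dice, straight from the definition."""
    per = {}
    inter_total = 0
    for lid in labels:
        xa = {tuple(p) for p in np.argwhere(a == lid)}
        xb = {tuple(p) for p in np.argwhere(b == lid)}
        inter = len(xa & xb)
        inter_total += inter
        per[lid] = 1.0 if not (xa or xb) else 2 * inter / (len(xa) + len(xb))
    na = int((a != 0).sum())
    nb = int((b != 0).sum())
    total = 1.0 if na + nb == 0 else 2 * inter_total / (na + nb)
    return per, total


def brute_surface(mask):
    """Voxels of the mask with a face neighbour outside it (array border
    counts as outside)."""
    pts = []
    shape = mask.shape
    for p in np.argwhere(mask):
        for ax in range(3):
            for d in (-1, 1):
                q = p.copy()
                q[ax] += d
                if not (0 <= q[ax] < shape[ax]) or not mask[tuple(q)]:
                    pts.append(tuple(p))
                    break
            else:
                continue
            break
    return pts


def brute_assd(a, b, labels):
    """O(n^2) all-pairs symmetric surface distance."""
    dist_sum, surf_sum = 0.0, 0
    per = {}
    for lid in labels:
        sa = brute_surface(a == lid)
        sb = brute_surface(b == lid)
        if not sa and not sb:
            per[lid] = 0.0
            continue
        if not sa or not sb:
            per[lid] = float("nan")
            continue
        pa = np.array(sa, dtype=float)
        pb = np.array(sb, dtype=float)
        dmat = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
        s = dmat.min(axis=1).sum() + dmat.min(axis=0).sum()
        per[lid] = s / (len(sa) + len(sb))
        dist_sum += s
        surf_sum += len(sa) + len(sb)
    total = 0.0 if surf_sum == 0 else dist_sum / surf_sum
    return per, total


def test_identical_volumes_score_perfectly(rng):
    a = rng.integers(0, 3, size=(6, 6, 6)).astype(np.uint8)
    pl, total = dice(lv(a), lv(a.copy()))
    assert total == 1.0 and all(v == 1.0 for v in pl.values())
    pa, ta = assd(lv(a), lv(a.copy()))
    assert ta == 0.0 and all(v == 0.0 for v in pa.values())


def test_half_overlap_dice_is_half():
    a = np.zeros((1, 1, 8), dtype=np.uint8)
    b = np.zeros((1, 1, 8), dtype=np.uint8)
    a[0, 0, 0:4] = 1
    b[0, 0, 2:6] = 1
    pl, total = dice(lv(a), lv(b))
    assert pl["A"] == pytest.approx(2 * 2 / (4 + 4))
    assert total == pytest.approx(0.5)


def test_two_point_surfaces_three_apart():
    a = np.zeros((7, 7, 7), dtype=np.uint8)
    b = np.zeros((7, 7, 7), dtype=np.uint8)
    a[3, 3, 1] = 1
    b[3, 3, 4] = 1
    pl, total = assd(lv(a), lv(b))
    assert pl["A"] == pytest.approx(3.0)
    assert total == pytest.approx(3.0)


def test_dice_matches_brute_force_on_random_volumes(rng):
    for _ in range(100):
        shape = tuple(rng.integers(3, 13, size=3))
        a = rng.integers(0, 3, size=shape).astype(np.uint8)
        b = rng.integers(0, 3, size=shape).astype(np.uint8)
        pl, total = dice(lv(a), lv(b))
        bl, btotal = brute_dice(a, b, [1, 2])
        assert total == pytest.approx(btotal, abs=0)
        assert pl["A"] == pytest.approx(bl[1], abs=0)
        assert pl["B"] == pytest.approx(bl[2], abs=0)


def test_assd_matches_brute_force_on_random_volumes(rng):
    for _ in range(100):
        shape = tuple(rng.integers(3, 13, size=3))
        # blobby masks so surfaces are non-trivial
        a = (rng.random(shape) < 0.35).astype(np.uint8)
        b = (rng.random(shape) < 0.35).astype(np.uint8)
        la = lv(a, label_map={1: ("A", False)})
        lb = lv(b, label_map={1: ("A", False)})
        pl, total = assd(la, lb)
        bl, btotal = brute_assd(a, b, [1])
        if np.isnan(bl[1]):
            assert np.isnan(pl["A"])
        else:
            assert pl["A"] == pytest.approx(bl[1], abs=1e-9)
            assert total == pytest.approx(btotal, abs=1e-9)


def test_metrics_are_symmetric(rng):
    a = rng.integers(0, 3, size=(8, 8, 8)).astype(np.uint8)
    b = rng.integers(0, 3, size=(8, 8, 8)).astype(np.uint8)
    assert dice(lv(a), lv(b)) == dice(lv(b), lv(a))
    pa, ta = assd(lv(a), lv(b))
    pb, tb = assd(lv(b), lv(a))
    assert ta == pytest.approx(tb, abs=1e-12)


def test_dice_monotone_in_overlap():
    """Growing the overlap at fixed sizes never decreases Dice."""
    prev = -1.0
    for overlap in range(0, 5):
        a = np.zeros((1, 1, 12), dtype=np.uint8)
        b = np.zeros((1, 1, 12), dtype=np.uint8)
        a[0, 0, 0:4] = 1
        b[0, 0, 4 - overlap: 8 - overlap] = 1
        _, total = dice(lv(a), lv(b))
        assert total >= prev
        prev = total


def test_empty_label_conventions():
    z = np.zeros((4, 4, 4), dtype=np.uint8)
    pl, total = dice(lv(z), lv(z.copy()))
    assert pl["A"] == 1.0 and total == 1.0
    pa, ta = assd(lv(z), lv(z.copy()))
    assert pa["A"] == 0.0 and ta == 0.0
    one = z.copy()
    one[1, 1, 1] = 1
    pa, _ = assd(lv(one), lv(z))
    assert np.isnan(pa["A"])


def test_shape_mismatch_rejected():
    with pytest.raises(ShapeError):
        dice(lv(np.zeros((2, 2, 2), np.uint8)), lv(np.zeros((3, 3, 3), np.uint8)))


@pytest.mark.parametrize(
    "d, cat",
    [
        (1.0, "negligible"),
        (0.99995, "negligible"),
        (0.987, "slight"),    # error 1.3%: a slight correction
        (0.9995, "slight"),   # error 0.05% needs a slight correction
        (0.95, "flawed"),
        (0.877, "flawed"),    # error 12.3%: significantly flawed
    ],
)
def test_error_categories(d, cat):
    assert error_category(d) == cat


def test_error_category_domain():
    with pytest.raises(InvalidParameterError):
        error_category(1.2)
    with pytest.raises(InvalidParameterError):
        error_category(-0.1)


def test_evaluate_bundles_units(rng):
    a = rng.integers(0, 2, size=(6, 6, 6)).astype(np.uint8)
    b = rng.integers(0, 2, size=(6, 6, 6)).astype(np.uint8)
    la = lv(a, {1: ("A", False)}, spacing=0.5)
    lb = lv(b, {1: ("A", False)}, spacing=0.5)
    ev = evaluate(la, lb)
    assert ev.total_assd_mm == pytest.approx(ev.total_assd_vox * 0.5)
    assert ev.error_pct == pytest.approx((1 - ev.total_dice) * 100)
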