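"""Segmentation agreement metrics: Dice, average symmetric surface distance.

For two segmentations X and X' over the same grid with labels i = 1..n,

    Dice = 2 * sum_i |X_i ∩ X'_i| / (|X| + |X'|)

where X_i is the set of voxels of X carrying label i and |X| is the total
number of *non-background* voxels (background is not a label; including it
would inflate scores toward 1).  Per-label Dice restricts the formula to one
label.  The ASSD sums, over every surface voxel of each label in either
segmentation, the Euclidean distance to the nearest surface voxel of the
same label in the other segmentation, divided by the total surface voxel
count.  Surface voxels are labelled voxels with at least one face neighbour
(6-connectivity) outside the label; the array border counts as outside.

Conventions for degenerate labels: a label empty in both segmentations
contributes Dice 1 and ASSD 0 (logged); a label empty in exactly one is
undefined for ASSD (NaN, excluded from the total, logged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import InvalidParameterError, LabelVolume, check_same_grid, logger

#: error bands for manual-correction triage, in % of Dice score
NEGLIGIBLE_MAX = 0.01
SLIGHT_MAX = 4.0

_FACE = ndimage.generate_binary_structure(3, 1)


@dataclass
class EvalResult:
    per_label_dice: dict[str, float]
    total_dice: float
    per_label_assd_vox: dict[str, float]
    per_label_assd_mm: dict[str, float]
    total_assd_vox: float
    total_assd_mm: float

    @property
    def error_pct(self) -> float:
        return (1.0 - self.total_dice) * 100.0

    @property
    def category(self) -> str:
        return error_category(self.total_dice)


def dice(a: LabelVolume, b: LabelVolume) -> tuple[dict[str, float], float]:
    """Per-label and total Dice of two label volumes on the same grid."""
    check_same_grid(a, b)
    per_label: dict[str, float] = {}
    inter_sum = 0
    for lid in a.label_ids:
        ma = a.data == lid
        mb = b.data == lid
        na, nb = int(ma.sum()), int(mb.sum())
        inter = int(np.logical_and(ma, mb).sum())
        inter_sum += inter
        if na + nb == 0:
            logger.info("dice: label %s empty on both sides, scored 1.0", a.name_of(lid))
            per_label[a.name_of(lid)] = 1.0
        else:
            per_label[a.name_of(lid)] = 2.0 * inter / (na + nb)
    fg = int((a.data != 0).sum()) + int((b.data != 0).sum())
    total = 1.0 if fg == 0 else 2.0 * inter_sum / fg
    return per_label, total


def _surface(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask, structure=_FACE, border_value=0)


def assd(a: LabelVolume, b: LabelVolume) -> tuple[dict[str, float], float]:
    """Per-label and total average symmetric surface distance, in voxel units.

    Multiply by the (isotropic) voxel spacing for mm.
    """
    check_same_grid(a, b)
    per_label: dict[str, float] = {}
    dist_sum = 0.0
    surf_sum = 0
    for lid in a.label_ids:
        name = a.name_of(lid)
        sa = _surface(a.data == lid)
        sb = _surface(b.data == lid)
        na, nb = int(sa.sum()), int(sb.sum())
        if na == 0 and nb == 0:
            logger.info("assd: label %s empty on both sides, scored 0.0", name)
            per_label[name] = 0.0
            continue
        if na == 0 or nb == 0:
            logger.warning("assd: label %s empty on one side only; undefined (NaN)", name)
            per_label[name] = float("nan")
            continue
        d_to_b = ndimage.distance_transform_edt(~sb)
        d_to_a = ndimage.distance_transform_edt(~sa)
        s = float(d_to_b[sa].sum() + d_to_a[sb].sum())
        per_label[name] = s / (na + nb)
        dist_sum += s
        surf_sum += na + nb
    total = 0.0 if surf_sum == 0 else dist_sum / surf_sum
    return per_label, total


def error_category(total_dice: float) -> str:
    """Triage by required manual correction: (1 - Dice) x 100 in %.

    < 0.01%: negligible; 0.01-4%: slight; > 4%: flawed.
    """
    if not 0.0 <= total_dice <= 1.0:
        raise InvalidParameterError(f"total Dice must be in [0, 1], got {total_dice}")
    err = (1.0 - total_dice) * 100.0
    if err < NEGLIGIBLE_MAX:
        return "negligible"
    if err <= SLIGHT_MAX:
        return "slight"
    return "flawed"


def evaluate(a: LabelVolume, b: LabelVolume) -> EvalResult:
    """Full evaluation of segmentation ``a`` against reference ``b``."""
    pl_dice, total_dice = dice(a, b)
    pl_assd, total_assd = assd(a, b)
    sp = a.spacing_mm
    return EvalResult(
        per_label_dice=pl_dice,
        total_dice=total_dice,
        per_label_assd_vox=pl_assd,
        per_label_assd_mm={k: v * sp for k, v in pl_assd.items()},
        total_assd_vox=total_assd,
        total_assd_mm=total_assd * sp,
    )
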