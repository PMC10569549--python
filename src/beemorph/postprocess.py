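"""Segmentation cleanup, left/right splitting and volumetry.

Island removal mirrors the cleanup applied to automatic segmentations:
per label (CX excluded — it is a single small midline structure whose
removal threshold semantics do not apply), 26-connected components are
computed and any component smaller than ``threshold`` times the label's
largest component is relabelled to background.  The default threshold 0.1
is deliberately low so that the smaller body of a paired neuropil (size
ratio near 1) is never deleted.

Left/right splitting estimates the midline as the x-centroid of all
paired-label voxels, assigns each 26-connected component of a paired label
to the side containing its centroid, and flags a label non-separable when a
component straddles the midline with more than 5% of its voxels on each
side (the typical midline-merged mushroom-body case); counts are withheld
for non-separable labels.

Volumes are voxel counts times spacing³ (mm³); relative volumes are
percentages of the total over the five reporting groups AL, MB, OL (=ME+LO),
CX, OTH.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    EmptySegmentationError,
    InvalidParameterError,
    LabelVolume,
    PAIRED_NEUROPILS,
    logger,
)

_CONN26 = np.ones((3, 3, 3), dtype=bool)

#: a single component is non-separable when both sides hold > this fraction
BILATERAL_SPAN_FRACTION = 0.05


def remove_islands(
    lv: LabelVolume,
    threshold: float = 0.1,
    exclude: tuple[str, ...] = ("CX",),
) -> LabelVolume:
    """Remove per-label islands smaller than ``threshold`` x the label's
    largest 26-connected component.  Idempotent; excluded labels pass
    through untouched."""
    if not 0 < threshold <= 1:
        raise InvalidParameterError("threshold must be in (0, 1]")
    out = lv.copy()
    for lid in lv.label_ids:
        name = lv.name_of(lid)
        if name in exclude:
            continue
        mask = out.data == lid
        if not mask.any():
            continue
        comp, n = ndimage.label(mask, structure=_CONN26)
        if n <= 1:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        cutoff = threshold * sizes.max()
        small = np.where(sizes < cutoff)[0] + 1
        if len(small):
            out.data[np.isin(comp, small)] = 0
            logger.debug(
                "remove_islands: %s dropped %d of %d components", name, len(small), n
            )
    return out


@dataclass
class SideSplit:
    """Left/right voxel counts per paired label."""

    midline_x: float
    counts: dict[str, tuple[int, int]]        # name -> (left, right)
    separable: dict[str, bool]
    missing: tuple[str, ...] = ()


def split_left_right(
    lv: LabelVolume,
    paired: tuple[str, ...] = PAIRED_NEUROPILS,
    span_fraction: float = BILATERAL_SPAN_FRACTION,
) -> SideSplit:
    """Split paired labels at the cohort midline; "left" = lower x index."""
    name_to_id = {lv.name_of(lid): lid for lid in lv.label_ids}
    unknown = [p for p in paired if p not in name_to_id]
    if unknown:
        raise InvalidParameterError(f"paired labels not in label map: {unknown}")
    paired_mask = np.isin(lv.data, [name_to_id[p] for p in paired])
    if not paired_mask.any():
        logger.warning("split_left_right: no paired-label voxels present")
        return SideSplit(
            midline_x=lv.shape[2] / 2.0,
            counts={p: (0, 0) for p in paired},
            separable={p: False for p in paired},
            missing=tuple(paired),
        )
    midline = float(np.nonzero(paired_mask)[2].mean())

    counts: dict[str, tuple[int, int]] = {}
    separable: dict[str, bool] = {}
    missing = []
    for p in paired:
        mask = lv.data == name_to_id[p]
        if not mask.any():
            logger.warning("split_left_right: label %s absent, zero counts", p)
            counts[p] = (0, 0)
            separable[p] = False
            missing.append(p)
            continue
        comp, n = ndimage.label(mask, structure=_CONN26)
        left = right = 0
        ok = True
        for ci in range(1, n + 1):
            xs = np.nonzero(comp == ci)[2]
            frac_left = float((xs < midline).mean())
            if min(frac_left, 1.0 - frac_left) > span_fraction:
                ok = False
                break
            centroid = float(xs.mean())
            if centroid == midline:
                # tie: majority voxel side, then left
                logger.warning(
                    "split_left_right: %s component centroid on midline; "
                    "assigning by majority side", p
                )
                to_left = frac_left >= 0.5
            else:
                to_left = centroid < midline
            if to_left:
                left += xs.size
            else:
                right += xs.size
        if ok:
            counts[p] = (left, right)
            separable[p] = True
        else:
            counts[p] = (0, 0)     # withheld
            separable[p] = False
            logger.info("split_left_right: label %s spans the midline (merged)", p)
    return SideSplit(midline_x=midline, counts=counts,
                     separable=separable, missing=tuple(missing))


@dataclass
class SpecimenRecord:
    """One specimen's absolute/relative neuropil volumes and grouping."""

    specimen_id: str
    species: str = ""
    population: str = ""
    hive: str = ""
    volumes_mm3: dict[str, float] = field(default_factory=dict)   # incl. OL, total
    left_mm3: dict[str, float] = field(default_factory=dict)
    right_mm3: dict[str, float] = field(default_factory=dict)
    relative_pct: dict[str, float] = field(default_factory=dict)
    mb_separable: bool = True

    @property
    def total_mm3(self) -> float:
        return self.volumes_mm3["total"]


def measure_volumes(
    lv: LabelVolume,
    sides: SideSplit | None = None,
    meta: dict | None = None,
) -> SpecimenRecord:
    """Volumetry of a cleaned segmentation: volume = voxel count x spacing³."""
    meta = meta or {}
    voxel = lv.spacing_mm ** 3
    vols = {lv.name_of(lid): lv.voxel_count(lid) * voxel for lid in lv.label_ids}
    total = sum(vols.values())
    if total == 0:
        raise EmptySegmentationError("segmentation contains no foreground voxels")
    vols["OL"] = vols.get("ME", 0.0) + vols.get("LO", 0.0)
    vols["total"] = total
    rel = {g: vols[g] / total * 100.0 for g in ("AL", "MB", "OL", "CX", "OTH") if g in vols}

    left: dict[str, float] = {}
    right: dict[str, float] = {}
    mb_separable = True
    if sides is not None:
        for p, (lc, rc) in sides.counts.items():
            if sides.separable.get(p, False):
                left[p] = lc * voxel
                right[p] = rc * voxel
        if "ME" in left and "LO" in left:
            left["OL"] = left["ME"] + left["LO"]
            right["OL"] = right["ME"] + right["LO"]
        mb_separable = sides.separable.get("MB", False)

    return SpecimenRecord(
        specimen_id=str(meta.get("specimen_id", "")),
        species=str(meta.get("species", "")),
        population=str(meta.get("population", "")),
        hive=str(meta.get("hive", "")),
        volumes_mm3=vols,
        left_mm3=left,
        right_mm3=right,
        relative_pct=rel,
        mb_separable=mb_separable,
    )


def records_to_frame(records: list[SpecimenRecord]):
    """Stack specimen records into the per-specimen table schema."""
    import pandas as pd

    rows = []
    for r in records:
        row = {
            "specimen_id": r.specimen_id, "species": r.species,
            "population": r.population, "hive": r.hive,
            "mb_separable": r.mb_separable,
        }
        for k, v in r.volumes_mm3.items():
            row[f"{k}_mm3"] = v
        for k, v in r.left_mm3.items():
            row[f"{k}_left_mm3"] = v
        for k, v in r.right_mm3.items():
            row[f"{k}_right_mm3"] = v
        for k, v in r.relative_pct.items():
            row[f"rel_{k}_pct"] = v
        rows.append(row)
    return pd.DataFrame(rows)
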