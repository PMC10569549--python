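"""Synthetic bee-brain phantoms: cohort draws and voxel renderings.

The generator produces (a) cohort tables of per-specimen neuropil volumes with
the statistical structure the downstream analyses assume — lognormal
inter-individual variation, colony (hive) effects shared within hive, and an
optional systematic left/right asymmetry of paired neuropils — and (b)
image/label volume pairs in which six neuropil classes are rendered as smooth
ellipsoidal bodies in anatomically inspired positions, with tissue-dependent
grayscale, Gaussian blur and additive noise emulating stained micro-CT
contrast.

Volume draws
------------
Per specimen and neuropil, the absolute volume (mm³) is drawn lognormally
with the preset mean and coefficient of variation, multiplied by a lognormal
hive-level factor shared by all specimens of a hive.  Paired neuropils are
split into left and right halves through the log side ratio

    ln(L/R) = ln(1 - delta) + eps,   eps ~ N(0, lateral_noise_cv),

so with ``lateral_noise_cv = 0`` the left side is exactly ``(1-delta)`` times
the right side, and the population mean of ``ln(L/R)`` equals ``ln(1-delta)``.
Mushroom bodies may touch across the midline with probability ``p_merge_mb``,
in which case their left/right volumes are withheld from exported tables
(mirroring segmentations in which the two bodies cannot be separated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import (
    BACKGROUND,
    DEFAULT_LABEL_MAP,
    LABEL_BY_NAME,
    NEUROPILS,
    PAIRED_NEUROPILS,
    InvalidParameterError,
    LabelVolume,
    RenderError,
    Volume3D,
    logger,
)

# Honey-bee cohort scale: mean (mm^3) and coefficient of variation of the six
# neuropil volumes in foraging honey bees; bumblebee presets use the same
# means with ~1.6x the dispersions (bumblebee cohorts are more heterogeneous).
_HONEYBEE_MEANS = {
    "AL": 0.0284,
    "MB": 0.134,
    "CX": 0.0033,
    "ME": 0.146,
    "LO": 0.045,
    "OTH": 0.166,
}
_HONEYBEE_CV = {
    "AL": 0.0033 / 0.0284,
    "MB": 0.011 / 0.134,
    "CX": 0.0004 / 0.0033,
    "ME": 0.011 / 0.146,
    "LO": 0.004 / 0.045,
    "OTH": 0.019 / 0.166,
}

_DEFAULT_TISSUE_GRAY = {0: 0.15, 1: 0.45, 2: 0.56, 3: 0.67, 4: 0.78, 5: 0.89, 6: 1.00}

# Structure layout: per neuropil, (z, y, x) centre as grid fractions for the
# left body (right mirrored in x), and semi-axis ratios (rz, ry, rx) with
# product ~1 applied to the volume-equivalent sphere radius.  "left" = lower x.
_LAYOUT = {
    "AL": {"center": (0.50, 0.14, 0.34), "ratios": (1.00, 1.00, 1.00)},
    "MB": {"center": (0.82, 0.28, None), "ratios": (0.85, 1.05, 1.12)},
    "CX": {"center": (0.42, 0.50, 0.50), "ratios": (1.00, 1.00, 1.00)},
    "ME": {"center": (0.48, 0.44, 0.115), "ratios": (1.40, 1.22, 0.59)},
    "LO": {"center": (0.46, 0.60, 0.31), "ratios": (1.35, 1.00, 0.74)},
    "OTH": {"center": (0.50, 0.82, 0.50), "ratios": (1.15, 0.55, 1.60)},
}
# MB x-centre is volume dependent: 0.5 -/+ factor * x-semi-axis, touching
# (slightly overlapping) across the midline when merged.
_MB_GAP_MERGED = 0.95
_MB_GAP_SPLIT = 1.18


@dataclass
class PhantomParams:
    """Generation parameters; defaults are the honey-bee preset at desk grid."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = 0.0054
    neuropil_means: dict[str, float] = field(default_factory=lambda: dict(_HONEYBEE_MEANS))
    neuropil_cv: dict[str, float] = field(default_factory=lambda: dict(_HONEYBEE_CV))
    hive_cv: float = 0.03
    lateral_delta: dict[str, float] = field(default_factory=dict)
    lateral_noise_cv: float = 0.02
    p_merge_mb: float = 0.46
    tissue_gray: dict[int, float] = field(default_factory=lambda: dict(_DEFAULT_TISSUE_GRAY))
    noise_sd: float = 0.05
    blur_sigma: float = 0.7
    fill_fraction: float = 0.10
    species: str = "honeybee"
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if any(cv < 0 for cv in self.neuropil_cv.values()) or self.hive_cv < 0:
            raise InvalidParameterError("coefficients of variation must be >= 0")
        if self.lateral_noise_cv < 0:
            raise InvalidParameterError("lateral_noise_cv must be >= 0")
        for name, delta in self.lateral_delta.items():
            if not 0 <= delta < 1:
                raise InvalidParameterError(f"lateral_delta[{name}] must be in [0, 1)")
        if not 0 <= self.p_merge_mb <= 1:
            raise InvalidParameterError("p_merge_mb must be in [0, 1]")
        if set(self.neuropil_means) != set(NEUROPILS):
            raise InvalidParameterError(f"neuropil_means must cover {NEUROPILS}")
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise InvalidParameterError("noise_sd and blur_sigma must be >= 0")
        if not 0 < self.fill_fraction < 0.5:
            raise InvalidParameterError("fill_fraction must be in (0, 0.5)")

    @classmethod
    def honeybee(cls, **overrides) -> "PhantomParams":
        return cls(**overrides)

    @classmethod
    def bumblebee(cls, **overrides) -> "PhantomParams":
        defaults = dict(
            neuropil_cv={k: 1.6 * v for k, v in _HONEYBEE_CV.items()},
            hive_cv=0.045,
            p_merge_mb=0.53,
            species="bumblebee",
        )
        defaults.update(overrides)
        return cls(**defaults)


#: the reference study colony designs (post-exclusion specimen counts per hive)
HONEYBEE_HIVE_PLAN = {
    "H1": 9, "H2": 11, "H3": 18, "H4": 19, "H5": 17, "H6": 16,
    "H7": 6, "H8": 11, "H9": 3,
}
HONEYBEE_POPULATIONS = {
    "H1": "A", "H2": "A", "H3": "A", "H4": "A", "H5": "A", "H6": "A",
    "H7": "B", "H8": "B", "H9": "B",
}
BUMBLEBEE_HIVE_PLAN = {"C1": 18, "C2": 20, "C3": 21, "C4": 18}
BUMBLEBEE_POPULATIONS = {"C1": "A", "C2": "A", "C3": "A", "C4": "A"}


def _lognormal(rng, mean, cv, size=None):
    """Draw lognormal values with the requested arithmetic mean and CV."""
    if cv == 0:
        return np.full(size, mean) if size is not None else mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return np.exp(rng.normal(mu, np.sqrt(sigma2), size=size))


def sample_cohort(
    params: PhantomParams,
    n_specimens: int,
    hive_plan: dict[str, int],
    populations: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Draw a cohort of per-specimen neuropil volumes.

    Returns one row per specimen with grouping metadata, absolute volumes in
    mm³ per neuropil, left/right volumes of paired neuropils, the derived
    OL (= ME + LO) and total, and the midline-merge flag for MB.
    """
    if not hive_plan:
        raise InvalidParameterError("hive_plan must not be empty")
    if n_specimens != sum(hive_plan.values()):
        raise InvalidParameterError(
            f"n_specimens={n_specimens} does not match hive_plan total "
            f"{sum(hive_plan.values())}"
        )
    params.validate()
    populations = populations or {h: "A" for h in hive_plan}
    rng = np.random.default_rng(params.seed)

    hive_mult = {
        hive: {n: _lognormal(rng, 1.0, params.hive_cv) for n in NEUROPILS}
        for hive in hive_plan
    }

    rows = []
    idx = 0
    for hive, count in hive_plan.items():
        for _ in range(count):
            idx += 1
            row = {
                "specimen_id": f"{params.species[:2].upper()}{idx:03d}",
                "species": params.species,
                "population": populations[hive],
                "hive": hive,
            }
            for n in NEUROPILS:
                row[n] = float(
                    _lognormal(rng, params.neuropil_means[n], params.neuropil_cv[n])
                    * hive_mult[hive][n]
                )
            for n in PAIRED_NEUROPILS:
                delta = params.lateral_delta.get(n, 0.0)
                log_ratio = np.log1p(-delta) + rng.normal(0.0, params.lateral_noise_cv)
                ratio = float(np.exp(log_ratio))  # L/R
                row[f"{n}_left"] = row[n] * ratio / (1.0 + ratio)
                row[f"{n}_right"] = row[n] / (1.0 + ratio)
            row["mb_merged"] = bool(rng.random() < params.p_merge_mb)
            rows.append(row)

    cohort = pd.DataFrame(rows)
    cohort["OL"] = cohort["ME"] + cohort["LO"]
    cohort["OL_left"] = cohort["ME_left"] + cohort["LO_left"]
    cohort["OL_right"] = cohort["ME_right"] + cohort["LO_right"]
    cohort["total"] = cohort[list(NEUROPILS)].sum(axis=1)
    return cohort


# rendering ------------------------------------------------------------------


def _volume_scale(params: PhantomParams) -> float:
    """mm³ -> rendered-voxel scale so the mean brain fills ``fill_fraction``."""
    grid_vox = float(np.prod(params.grid_shape))
    total_mean = sum(params.neuropil_means.values())
    return params.fill_fraction * grid_vox / total_mean


def _paint_ellipsoid(labels, occupied, center_vox, semi_vox, label_id, name):
    shape = labels.shape
    lo, hi = [], []
    for ax in range(3):
        if center_vox[ax] - semi_vox[ax] < -0.5 or center_vox[ax] + semi_vox[ax] > shape[ax] - 0.5:
            raise RenderError(
                f"structure {name} overflows the grid on axis {'zyx'[ax]} "
                f"(center {center_vox[ax]:.1f}, semi-axis {semi_vox[ax]:.1f}, "
                f"size {shape[ax]})"
            )
        lo.append(max(0, int(np.floor(center_vox[ax] - semi_vox[ax]))))
        hi.append(min(shape[ax], int(np.ceil(center_vox[ax] + semi_vox[ax])) + 1))
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    mask = (
        ((zz - center_vox[0]) / semi_vox[0]) ** 2
        + ((yy - center_vox[1]) / semi_vox[1]) ** 2
        + ((xx - center_vox[2]) / semi_vox[2]) ** 2
    ) <= 1.0
    region = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    occ = occupied[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    clash = mask & occ & (region != label_id)
    if np.any(clash):
        other = int(region[clash][0])
        raise RenderError(
            f"structure {name} collides with label {other} on the grid; "
            "reduce fill_fraction or volume draws"
        )
    region[mask] = label_id
    occ |= mask


def render_phantom(
    spec_row: pd.Series | dict,
    params: PhantomParams,
    render_seed: int | None = None,
) -> tuple[Volume3D, LabelVolume]:
    """Render one specimen's volumes as an image/label phantom pair.

    Neuropil target volumes from ``spec_row`` (mm³) are rescaled so the mean
    brain occupies ``params.fill_fraction`` of the grid, then rasterized as
    ellipsoids (exact label volume = voxel count × spacing³; rasterization
    quantizes the targets).  The image is a tissue-gray lookup of the labels,
    Gaussian-blurred, with additive Gaussian noise.
    """
    row = dict(spec_row)
    shape = params.grid_shape
    scale = _volume_scale(params)
    labels = np.zeros(shape, dtype=np.uint8)
    occupied = np.zeros(shape, dtype=bool)

    merged = bool(row.get("mb_merged", False))
    bodies: list[tuple[str, str, float, float]] = []  # (neuropil, side, vox, xsign)
    for n in NEUROPILS:
        if n in PAIRED_NEUROPILS:
            bodies.append((n, "left", row[f"{n}_left"] * scale, -1.0))
            bodies.append((n, "right", row[f"{n}_right"] * scale, +1.0))
        else:
            bodies.append((n, "", row[n] * scale, 0.0))

    # paint large structures first so collisions name the smaller intruder
    bodies.sort(key=lambda b: -b[2])
    for n, side, vox, xsign in bodies:
        lay = _LAYOUT[n]
        r = (3.0 * vox / (4.0 * np.pi)) ** (1.0 / 3.0)
        semi = tuple(r * ratio for ratio in lay["ratios"])
        cz, cy, cx = lay["center"]
        if n == "MB":
            gap = _MB_GAP_MERGED if merged else _MB_GAP_SPLIT
            cx_frac = 0.5 + xsign * gap * semi[2] / shape[2]
        elif xsign < 0:
            cx_frac = cx
        elif xsign > 0:
            cx_frac = 1.0 - cx
        else:
            cx_frac = cx
        center = (cz * (shape[0] - 1), cy * (shape[1] - 1), cx_frac * (shape[2] - 1))
        name = f"{n}_{side}" if side else n
        _paint_ellipsoid(labels, occupied, center, semi, LABEL_BY_NAME[n], name)

    grays = np.zeros(max(params.tissue_gray) + 1, dtype=np.float32)
    for lid, g in params.tissue_gray.items():
        grays[lid] = g
    image = grays[labels]
    if params.blur_sigma > 0:
        image = gaussian_filter(image, params.blur_sigma)
    if params.noise_sd > 0:
        if render_seed is None:
            render_seed = params.seed
        rng = np.random.default_rng(render_seed)
        image = image + rng.normal(0.0, params.noise_sd, size=shape).astype(np.float32)

    return (
        Volume3D(image.astype(np.float32), spacing_mm=params.spacing_mm),
        LabelVolume(labels, spacing_mm=params.spacing_mm, label_map=dict(DEFAULT_LABEL_MAP)),
    )


def achieved_volumes(lv: LabelVolume) -> dict[str, float]:
    """Voxel-true volume (mm³) per neuropil of a rendered label volume."""
    out = {}
    voxel = lv.spacing_mm ** 3
    for lid, (name, _) in lv.label_map.items():
        out[name] = lv.voxel_count(lid) * voxel
    return out


def render_cohort(
    cohort: pd.DataFrame, params: PhantomParams
) -> tuple[list[tuple[Volume3D, LabelVolume]], pd.DataFrame]:
    """Render every cohort row; records achieved voxel-true volumes.

    Returns the phantoms and a copy of the cohort with ``achieved_<N>``
    columns (mm³ on the rendered grid).
    """
    phantoms = []
    cohort = cohort.reset_index(drop=True).copy()
    for name in NEUROPILS:
        cohort[f"achieved_{name}"] = np.nan
    for i, row in cohort.iterrows():
        vol, lab = render_phantom(row, params, render_seed=_render_seed(params.seed, i))
        phantoms.append((vol, lab))
        for name, v in achieved_volumes(lab).items():
            cohort.loc[i, f"achieved_{name}"] = v
    return phantoms, cohort


def _render_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % (2**31))


# table export ---------------------------------------------------------------

TABLE_COLUMNS_META = ["specimen_id", "species", "population", "hive"]


def cohort_to_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Export a cohort as a per-specimen volume table.

    One row per specimen: grouping metadata, absolute volumes (mm³) per
    neuropil plus OL (= ME + LO) and total, left/right volumes of paired
    neuropils (MB left/right withheld for midline-merged specimens), the
    ``mb_separable`` flag, and relative volumes (% of total over the five
    reporting groups AL, MB, OL, CX, OTH, which sum to 100).
    """
    if len(cohort) == 0:
        raise InvalidParameterError("cohort is empty")
    t = pd.DataFrame()
    for c in TABLE_COLUMNS_META:
        t[c] = cohort[c]
    for n in NEUROPILS:
        t[f"{n}_mm3"] = cohort[n]
    t["OL_mm3"] = cohort["ME"] + cohort["LO"]
    t["total_mm3"] = cohort[list(NEUROPILS)].sum(axis=1)
    for n in PAIRED_NEUROPILS + ("OL",):
        t[f"{n}_left_mm3"] = cohort[f"{n}_left"]
        t[f"{n}_right_mm3"] = cohort[f"{n}_right"]
    merged = cohort.get("mb_merged", pd.Series(False, index=cohort.index))
    t["mb_separable"] = ~merged.astype(bool)
    t.loc[~t["mb_separable"], ["MB_left_mm3", "MB_right_mm3"]] = np.nan
    for g in ("AL", "MB", "OL", "CX", "OTH"):
        t[f"rel_{g}_pct"] = t[f"{g}_mm3"] / t["total_mm3"] * 100.0
    logger.debug("exported cohort table with %d specimens", len(t))
    return t
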