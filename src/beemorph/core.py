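"""Shared containers and conventions for volumetric bee-brain analysis.

Conventions used throughout the package:

* arrays are ordered ``(z, y, x)``;
* the anatomical left–right axis is ``x`` and "left" means lower x index;
* voxel spacing is isotropic and given in millimetres;
* segmentation labels are ``0`` background, ``1`` AL (antennal lobes),
  ``2`` MB (mushroom bodies), ``3`` CX (central complex), ``4`` ME
  (medullae), ``5`` LO (lobulae), ``6`` OTH (remaining neuropils).
  The optic lobes OL are always derived as ME + LO and never stored as a
  voxel label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger("beemorph")

# label ids ------------------------------------------------------------------

BACKGROUND = 0
AL, MB, CX, ME, LO, OTH = 1, 2, 3, 4, 5, 6

#: id -> (name, is_paired)
DEFAULT_LABEL_MAP: dict[int, tuple[str, bool]] = {
    AL: ("AL", True),
    MB: ("MB", True),
    CX: ("CX", False),
    ME: ("ME", True),
    LO: ("LO", True),
    OTH: ("OTH", False),
}

NEUROPILS = ("AL", "MB", "CX", "ME", "LO", "OTH")
PAIRED_NEUROPILS = ("AL", "MB", "ME", "LO")
#: composite neuropils reported in tables, derived from voxel labels
RELATIVE_GROUPS = ("AL", "MB", "OL", "CX", "OTH")

LABEL_BY_NAME = {name: lid for lid, (name, _) in DEFAULT_LABEL_MAP.items()}


# errors ---------------------------------------------------------------------


class BeemorphError(Exception):
    """Base class for package errors."""


class InvalidParameterError(BeemorphError, ValueError):
    pass


class RenderError(BeemorphError, RuntimeError):
    """A phantom structure does not fit on the requested grid."""


class DegenerateInputError(BeemorphError, ValueError):
    """Input has no usable signal (constant volume, one-class labels...)."""


class ShapeError(BeemorphError, ValueError):
    pass


class EmptyDetectionError(BeemorphError, RuntimeError):
    """Automatic cropping found no object slice on some axis."""


class EmptySegmentationError(BeemorphError, ValueError):
    pass


class FormatError(BeemorphError, ValueError):
    """Unreadable or unsupported volume / table file."""


class SchemaError(BeemorphError, ValueError):
    """Specimen table is missing mandatory columns."""


class ConfigError(BeemorphError, ValueError):
    pass


class StageError(BeemorphError, RuntimeError):
    """Pipeline stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"{stage}: {message}")
        self.stage = stage


# containers -----------------------------------------------------------------


@dataclass
class Volume3D:
    """A 3D scalar image with isotropic voxel spacing in mm, axes (z, y, x)."""

    data: np.ndarray
    spacing_mm: float = 1.0
    z_flipped: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not self.spacing_mm > 0:
            raise InvalidParameterError("spacing_mm must be positive")
        if not np.all(np.isfinite(self.data)):
            raise InvalidParameterError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "Volume3D":
        return replace(self, data=self.data.copy())


@dataclass
class LabelVolume:
    """Integer-labelled 3D field sharing a grid with a :class:`Volume3D`."""

    data: np.ndarray
    spacing_mm: float = 1.0
    label_map: dict[int, tuple[str, bool]] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_MAP)
    )

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise InvalidParameterError("label volume must have integer dtype")
        present = set(np.unique(self.data).tolist()) - {BACKGROUND}
        unknown = present - set(self.label_map)
        if unknown:
            raise InvalidParameterError(f"labels outside label map: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def label_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.label_map))

    def name_of(self, label_id: int) -> str:
        return self.label_map[label_id][0]

    def is_paired(self, label_id: int) -> bool:
        return self.label_map[label_id][1]

    def voxel_count(self, label_id: int) -> int:
        return int(np.count_nonzero(self.data == label_id))

    def copy(self) -> "LabelVolume":
        return replace(self, data=self.data.copy(), label_map=dict(self.label_map))


def check_same_grid(a, b) -> None:
    if a.shape != b.shape:
        raise ShapeError(f"shape mismatch: {a.shape} vs {b.shape}")
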