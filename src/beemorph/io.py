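"""File formats: volumes (NRRD / NIfTI-1 / multi-page TIFF) and specimen
tables (CSV / XLSX with header-synonym mapping).

Volumes are exchanged through open formats only.  Arrays are normalised to
(z, y, x) axis order on read; voxel spacing is taken from the file header
(NRRD/NIfTI) or from ImageJ TIFF metadata, defaulting to 1 mm with a warning
when absent.  Integer-typed files are read as label volumes; their label map
comes from a ``<name>.labels.json`` sidecar when present, otherwise the
default six-neuropil map is assumed.

Specimen tables accept the supplementary-table header dialects via a synonym
map (overridable with a JSON/YAML mapping file) and are validated into the
package's canonical column schema (``AL_mm3``, ``AL_left_mm3``,
``rel_AL_pct``, ...).  Rows with missing left/right mushroom-body values are
marked non-separable.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

from .core import (
    DEFAULT_LABEL_MAP,
    FormatError,
    LabelVolume,
    NEUROPILS,
    PAIRED_NEUROPILS,
    SchemaError,
    Volume3D,
    logger,
)

_SITK_EXTS = {".nrrd", ".nhdr", ".nii", ".gz"}
_TIFF_EXTS = {".tif", ".tiff"}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".labels.json")


def _label_map_for(path: Path, data: np.ndarray) -> dict[int, tuple[str, bool]]:
    sc = _sidecar(path)
    if sc.exists():
        raw = json.loads(sc.read_text())
        return {int(k): (v[0], bool(v[1])) for k, v in raw.items()}
    present = set(int(v) for v in np.unique(data)) - {0}
    if present <= set(DEFAULT_LABEL_MAP):
        return dict(DEFAULT_LABEL_MAP)
    return {lid: (f"L{lid}", False) for lid in sorted(present)}


def read_volume(path) -> Volume3D | LabelVolume:
    """Read a 3D volume; returns a LabelVolume for integer-typed data."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in _TIFF_EXTS:
            data = tifffile.imread(path)
            spacing = _tiff_spacing(path)
        elif suffix in _SITK_EXTS:
            img = sitk.ReadImage(str(path))
            data = sitk.GetArrayFromImage(img)       # (z, y, x)
            sp = img.GetSpacing()                    # (x, y, z)
            if not np.allclose(sp, sp[0], rtol=1e-4):
                logger.warning("anisotropic spacing %s; using %.6g", sp, sp[0])
            spacing = float(sp[0])
        else:
            raise FormatError(f"unsupported volume format: {path.suffix}")
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D data, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.integer):
        return LabelVolume(data, spacing_mm=spacing, label_map=_label_map_for(path, data))
    return Volume3D(data, spacing_mm=spacing)


def _tiff_spacing(path: Path) -> float:
    with tifffile.TiffFile(path) as tf:
        meta = tf.imagej_metadata or {}
        if "spacing" in meta:
            return float(meta["spacing"])
    logger.warning("%s: no spacing metadata; defaulting to 1 mm", path)
    return 1.0


def write_volume(path, v: Volume3D | LabelVolume) -> None:
    """Write a volume; label volumes get a ``.labels.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = path.suffix.lower()
    is_label = isinstance(v, LabelVolume)
    data = v.data.astype(np.uint8) if is_label else v.data.astype(np.float32)
    if suffix in _TIFF_EXTS:
        tifffile.imwrite(path, data, imagej=True,
                         metadata={"spacing": v.spacing_mm, "unit": "mm"})
    elif suffix in _SITK_EXTS:
        img = sitk.GetImageFromArray(data)
        img.SetSpacing((v.spacing_mm,) * 3)
        sitk.WriteImage(img, str(path))
    else:
        raise FormatError(f"unsupported volume format: {path.suffix}")
    if is_label:
        _sidecar(path).write_text(
            json.dumps({str(k): [n, p] for k, (n, p) in v.label_map.items()})
        )


# specimen tables ------------------------------------------------------------

META_COLUMNS = ("specimen_id", "species", "population", "hive")
MANDATORY_COLUMNS = ("specimen_id",) + tuple(f"{n}_mm3" for n in NEUROPILS)

#: canonicalised header -> schema column
_SYNONYMS: dict[str, str] = {
    "id": "specimen_id", "specimen": "specimen_id", "specimen id": "specimen_id",
    "bee id": "specimen_id", "bee": "specimen_id",
    "hive": "hive", "colony": "hive",
    "population": "population", "apiary": "population", "pop": "population",
    "species": "species",
    "total": "total_mm3", "total brain": "total_mm3", "brain": "total_mm3",
    "total brain volume": "total_mm3",
}
for _n in NEUROPILS + ("OL",):
    _l = _n.lower()
    _SYNONYMS[_l] = f"{_n}_mm3"
    _SYNONYMS[f"{_l} volume"] = f"{_n}_mm3"
    for _side in ("left", "right"):
        _SYNONYMS[f"{_l} {_side}"] = f"{_n}_{_side}_mm3"
        _SYNONYMS[f"{_side} {_l}"] = f"{_n}_{_side}_mm3"
        _SYNONYMS[f"{_l} {_side} volume"] = f"{_n}_{_side}_mm3"
    _SYNONYMS[f"rel {_l}"] = f"rel_{_n}_pct"
    _SYNONYMS[f"relative {_l}"] = f"rel_{_n}_pct"
    _SYNONYMS[f"{_l} relative"] = f"rel_{_n}_pct"


def _canon(header: str) -> str:
    h = str(header).strip().lower()
    h = re.sub(r"\((mm.?3|mm³|%)\)", " ", h)
    h = re.sub(r"[_\.\-/]", " ", h)
    h = re.sub(r"\s+", " ", h).strip()
    return h


@dataclass
class SpecimenTable:
    """Validated per-specimen volume table in the canonical schema."""

    frame: pd.DataFrame

    def for_species(self, species: str) -> "SpecimenTable":
        if "species" not in self.frame.columns:
            return self
        return SpecimenTable(self.frame[self.frame["species"] == species].copy())

    def __len__(self) -> int:
        return len(self.frame)


def read_specimen_table(path, mapping=None, ol_tolerance: float = 1e-3) -> SpecimenTable:
    """Read and validate a CSV/XLSX per-specimen volume table.

    ``mapping`` may be a dict or a JSON/YAML file mapping raw headers to
    schema columns (applied after the built-in synonyms).  Derived columns
    (OL, total, relative volumes) are completed when absent; rows where OL
    differs from ME + LO beyond ``ol_tolerance`` (relative) are warned about.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    try:
        if path.suffix.lower() in (".xlsx", ".xls"):
            raw = pd.read_excel(path)
        else:
            raw = pd.read_csv(path)
    except Exception as exc:
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    if raw.empty:
        raise SchemaError(f"{path}: table has no rows")

    user_map = {}
    if mapping is not None:
        if isinstance(mapping, (str, Path)):
            text = Path(mapping).read_text()
            if str(mapping).endswith((".yaml", ".yml")):
                import yaml

                user_map = yaml.safe_load(text)
            else:
                user_map = json.loads(text)
        else:
            user_map = dict(mapping)

    renames = {}
    for col in raw.columns:
        if col in user_map:
            renames[col] = user_map[col]
        elif col in _SYNONYMS.values():
            renames[col] = col
        else:
            canon = _canon(col)
            if canon in _SYNONYMS:
                renames[col] = _SYNONYMS[canon]
    df = raw.rename(columns=renames)
    df = df.loc[:, ~df.columns.duplicated()]

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")

    if "OL_mm3" not in df.columns:
        df["OL_mm3"] = df["ME_mm3"] + df["LO_mm3"]
    if "total_mm3" not in df.columns:
        df["total_mm3"] = df[[f"{n}_mm3" for n in NEUROPILS]].sum(axis=1)
    for side in ("left", "right"):
        ol, me, lo = (f"OL_{side}_mm3", f"ME_{side}_mm3", f"LO_{side}_mm3")
        if ol not in df.columns and me in df.columns and lo in df.columns:
            df[ol] = df[me] + df[lo]
    for g in ("AL", "MB", "OL", "CX", "OTH"):
        if f"rel_{g}_pct" not in df.columns:
            df[f"rel_{g}_pct"] = df[f"{g}_mm3"] / df["total_mm3"] * 100.0

    bad = np.abs(df["OL_mm3"] - (df["ME_mm3"] + df["LO_mm3"])) > (
        ol_tolerance * df["OL_mm3"].abs().clip(lower=1e-12)
    )
    for idx in df.index[bad.fillna(False)]:
        logger.warning("row %s: OL volume differs from ME + LO", idx)

    if "mb_separable" not in df.columns:
        has_mb = ("MB_left_mm3" in df.columns) and ("MB_right_mm3" in df.columns)
        if has_mb:
            df["mb_separable"] = ~(df["MB_left_mm3"].isna() | df["MB_right_mm3"].isna())
        else:
            df["mb_separable"] = False
    return SpecimenTable(df)


def write_specimen_table(path, table: SpecimenTable | pd.DataFrame) -> None:
    df = table.frame if isinstance(table, SpecimenTable) else table
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)
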