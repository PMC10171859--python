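"""File formats: NIfTI volumes and masks, CSV tables, PNG/TIFF stain images.

All round trips are lossless: volumes preserve data and voxel spacing,
label maps are int32, masks uint8, stain channels 16-bit. Tables are
schema-checked on read with errors naming the missing column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Tuple

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .imgproc import LabelMap, Volume


class SchemaError(ValueError):
    """A table does not match its required schema."""


def _affine(voxel_size_mm: Sequence[float]) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def save_volume(volume: Volume, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.data), _affine(volume.voxel_size_mm))
    img.header.set_zooms(volume.voxel_size_mm)
    nib.save(img, str(path))
    return path


def load_volume(path, contrast_tag: str = "PDw", week: float = 0.0) -> Volume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data, voxel_size_mm=zooms, contrast_tag=contrast_tag, week=week)


def save_mask(mask: np.ndarray, voxel_size_mm, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(voxel_size_mm))
    nib.save(img, str(path))
    return path


def load_mask(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    return np.asarray(nib.load(str(path)).dataobj).astype(bool)


def save_labelmap(label_map: LabelMap, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(label_map.labels.astype(np.int32),
                          _affine(label_map.voxel_size_mm))
    nib.save(img, str(path))
    return path


def load_labelmap(path) -> LabelMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label map file not found: {path}")
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMap(labels, int(labels.max()), voxel_size_mm=zooms)


def read_table(path, required_columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table file not found: {path}")
    df = pd.read_csv(path)
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{path.name}: missing required column(s) {missing}"
            )
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def save_stain_image(channel: np.ndarray, path) -> Path:
    """Write a stain channel as 16-bit PNG or TIFF (by file extension)."""
    path = Path(path)
    arr = np.asarray(channel)
    if arr.dtype != np.uint16:
        raise ValueError(f"stain channels must be uint16, got {arr.dtype}")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), arr)
    else:
        iio.imwrite(str(path), arr, extension=path.suffix or ".png")
    return path


def load_stain_image(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stain image not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(str(path))
    return np.asarray(iio.imread(str(path)))


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if hasattr(o, "value"):
            return o.value
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))
    return path


def read_json(path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"JSON file not found: {path}")
    return json.loads(path.read_text())
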