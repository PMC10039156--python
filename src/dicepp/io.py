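"""Readers and writers for images, label masks, probability maps and
manifests.

Formats: PNG (2D, via Pillow), TIFF (2D images and multi-channel float
probability maps, via tifffile), NIfTI (3D, via nibabel) and NPZ containers.
The on-disk convention for probability maps is class axis last; in NIfTI the
classes are the 4th dimension.  Greyscale/palette PNG masks are mapped to
labels 0..C-1 by sorted unique value, and the mapping is logged.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .data import ValidationError, as_label_mask, validate_probability_map

log = logging.getLogger("dicepp.io")

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(_NIFTI_SUFFIXES)


def read_image(path) -> np.ndarray:
    """Read an intensity image (PNG/TIFF 2D, NIfTI 3D) as float64."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(str(path)).astype(np.float64)
    if path.suffix.lower() == ".png":
        return np.asarray(Image.open(path).convert("F"), dtype=np.float64)
    raise ValueError(f"unsupported image format: {path.suffix}")


def read_mask(path) -> np.ndarray:
    """Read a label mask; stored grey values are mapped to 0..C-1 by sorted
    unique value (e.g. {0, 255} -> {0, 1}), and the mapping is logged."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        raw = np.asarray(nib.load(str(path)).dataobj)
    elif path.suffix.lower() in (".tif", ".tiff"):
        raw = tifffile.imread(str(path))
    elif path.suffix.lower() == ".png":
        img = Image.open(path)
        if img.mode == "P":
            img = img.convert("L")
        raw = np.asarray(img)
    else:
        raise ValueError(f"unsupported mask format: {path.suffix}")
    if not np.allclose(raw, np.rint(raw)):
        raise ValidationError(f"mask {path} has non-integral values")
    raw = np.rint(raw).astype(np.int64)
    values = np.unique(raw)
    mapped = np.searchsorted(values, raw)
    if not np.array_equal(values, np.arange(values.size)):
        log.info("mask %s: mapped stored values %s -> labels 0..%d",
                 path.name, values.tolist(), values.size - 1)
    return as_label_mask(mapped)


def write_image(path, image) -> None:
    path = Path(path)
    image = np.asarray(image)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(image.astype(np.float64), np.eye(4)), str(path))
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), image.astype(np.float32))
    elif path.suffix.lower() == ".png":
        arr = image.astype(np.float64)
        lo, hi = arr.min(), arr.max()
        scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo) * 255
        Image.fromarray(scaled.astype(np.uint8), mode="L").save(path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


def write_mask(path, mask) -> None:
    path = Path(path)
    mask = as_label_mask(mask)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(mask.astype(np.int16), np.eye(4)), str(path))
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), mask.astype(np.int32))
    elif path.suffix.lower() == ".png":
        if mask.max() > 255:
            raise ValidationError("PNG masks support at most 256 labels")
        Image.fromarray(mask.astype(np.uint8), mode="L").save(path)
    else:
        raise ValueError(f"unsupported mask format: {path.suffix}")


def write_probmap(path, p) -> None:
    """Write a probability map (class axis last) to NPZ, multi-channel TIFF
    or 4D NIfTI, losslessly for NPZ/NIfTI (float64)."""
    path = Path(path)
    p = validate_probability_map(p)
    if path.suffix == ".npz":
        np.savez_compressed(str(path), prob=p)
    elif _is_nifti(path):
        nib.save(nib.Nifti1Image(p.astype(np.float64), np.eye(4)), str(path))
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), p.astype(np.float64))
    else:
        raise ValueError(f"unsupported probability-map format: {path.suffix}")


def read_probmap(path, renormalise: bool = False) -> np.ndarray:
    """Read and validate a probability map (class axis last; NIfTI stores
    classes as the 4th dimension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npz":
        with np.load(str(path)) as fh:
            arr = fh["prob"]
    elif _is_nifti(path):
        arr = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    elif path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        raise ValueError(f"unsupported probability-map format: {path.suffix}")
    return validate_probability_map(arr, renormalise=renormalise)


MANIFEST_COLUMNS = ("image", "mask", "probmap", "split")


def write_manifest(path, rows) -> None:
    """Write a manifest CSV with columns image, mask, probmap, split."""
    df = pd.DataFrame(rows)
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df[list(MANIFEST_COLUMNS)].to_csv(path, index=False)


def read_manifest(path, require_exists: bool = True) -> pd.DataFrame:
    """Read a manifest CSV; by default every referenced file must exist."""
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False)
    if "image" not in df.columns or "mask" not in df.columns:
        raise ValidationError("manifest needs 'image' and 'mask' columns")
    if require_exists:
        base = path.parent
        for col in ("image", "mask", "probmap"):
            if col not in df.columns:
                continue
            for entry in df[col]:
                if not entry:
                    continue
                p = Path(entry)
                if not p.is_absolute():
                    p = base / p
                if not p.exists():
                    raise FileNotFoundError(f"manifest references missing file {p}")
    return df


def resolve(path, base) -> Path:
    p = Path(path)
    return p if p.is_absolute() else Path(base) / p
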