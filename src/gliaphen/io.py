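"""File-format plumbing: TIFF channels, NIfTI volumes, CSV tables, YAML config."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .petquant import PetVolume
from .segmentation import FieldImage


def write_channel_tiff(path: str | Path, image: FieldImage) -> None:
    """Write one channel as a float32 TIFF with pixel-size resolution tags."""
    px_per_cm = 1e4 / image.pixel_size_um
    tifffile.imwrite(
        str(path),
        image.pixels.astype(np.float32),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        metadata={"channel": image.channel, "pixel_size_um": image.pixel_size_um},
    )


def read_channel_tiff(path: str | Path, pixel_size_um: float | None = None, channel: str | None = None) -> FieldImage:
    """Read a single-channel TIFF (8/16-bit or float) into a FieldImage.

    Pixel size and channel label come from the embedded ImageJ/shaped
    metadata when present; explicit arguments override.
    """
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if pixel_size_um is None:
        pixel_size_um = float(meta.get("pixel_size_um", 1.0))
    if channel is None:
        channel = str(meta.get("channel", "DAPI"))
    return FieldImage(np.asarray(arr, dtype=float), pixel_size_um, channel)


def write_mask_tiff(path: str | Path, mask: np.ndarray) -> None:
    """Binary mask as 8-bit TIFF (0/255) or label mask as 16-bit TIFF."""
    if mask.dtype == bool:
        tifffile.imwrite(str(path), (mask.astype(np.uint8) * 255))
    else:
        tifffile.imwrite(str(path), mask.astype(np.uint16))


def write_pet_nifti(path: str | Path, volume: PetVolume) -> None:
    affine = np.diag(list(volume.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), affine), str(path))


def read_pet_nifti(path: str | Path, injected_dose_kBq: float, body_weight_g: float) -> PetVolume:
    img = nib.load(str(path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PetVolume(np.asarray(img.dataobj, dtype=float), voxel_size, injected_dose_kBq, body_weight_g)


def write_voi_niftis(out_dir: str | Path, vois: dict[str, np.ndarray], voxel_size_mm) -> dict[str, Path]:
    """One NIfTI mask per VOI; file names are slugified VOI names."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(voxel_size_mm) + [1.0])
    paths = {}
    for name, mask in vois.items():
        p = out_dir / (name.replace(" ", "_") + ".nii.gz")
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(p))
        paths[name] = p
    return paths


def read_voi_niftis(voi_dir: str | Path) -> dict[str, np.ndarray]:
    vois = {}
    for p in sorted(Path(voi_dir).glob("*.nii*")):
        name = p.name.split(".nii")[0].replace("_", " ")
        vois[name] = np.asarray(nib.load(str(p)).dataobj) > 0
    return vois


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(path: str | Path, obj: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def write_csv(path: str | Path, df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_obj(obj) -> str:
    """Stable hash of a JSON-serialisable object (canonical key order)."""
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()
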