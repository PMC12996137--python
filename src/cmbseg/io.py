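"""NIfTI and CSV plumbing.

Arrays are kept in (z, y, x) voxel order throughout the package: NIfTI axis
i maps to z (the axial slicing axis), j to y, k to x, and voxel spacing is
taken from the header zooms in the same order.  Coordinates are 0-based
voxel indices everywhere, which keeps centroid matching free of off-by-one
drift between modules.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import Lesion, Volume


def write_volume(volume: Volume, path: str) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.intensities), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, path)


def read_volume(path: str, mask_path: str | None = None) -> Volume:
    """Read a NIfTI volume (and optional mask), preserving spacing."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    mask = None
    if mask_path is not None:
        mimg = nib.load(mask_path)
        mask = np.asarray(mimg.dataobj).astype(np.uint8)
        if mask.shape != data.shape:
            raise ValueError("mask shape does not match volume shape")
    sid = os.path.basename(path)
    for suffix in (".nii.gz", ".nii"):
        if sid.endswith(suffix):
            sid = sid[: -len(suffix)]
    return Volume(intensities=data, spacing=spacing, mask=mask, subject_id=sid)


def read_lesion_table(path: str) -> list[Lesion]:
    df = pd.read_csv(path)
    lesions = []
    for _, row in df.iterrows():
        lesions.append(
            Lesion(
                id=int(row["id"]),
                centroid=(float(row["z"]), float(row["y"]), float(row["x"])),
                voxels=frozenset(),
                equiv_diameter_mm=float(row["diameter_mm"]),
            )
        )
    return lesions
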