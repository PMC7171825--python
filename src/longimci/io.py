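"""NIfTI and tabular I/O helpers.

Volumes are stored as NIfTI-1 with a 1.5 mm isotropic affine (the grid
spacing typical of smoothed template-space PET); the affine carries no
information used by the pipeline, which operates purely on voxel grids.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import AtlasLabelMap, VoxelImage

__all__ = [
    "save_nifti",
    "load_nifti",
    "load_image",
    "load_atlas",
    "load_subject_table",
    "load_image_dir",
]

_VOXEL_MM = 1.5


def save_nifti(array: np.ndarray, path: str | Path) -> None:
    affine = np.diag([_VOXEL_MM, _VOXEL_MM, _VOXEL_MM, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(array), affine), str(path))


def load_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def load_image(
    path: str | Path,
    mask: np.ndarray | None = None,
    subject_id: str = "",
    timepoint: str = "",
) -> VoxelImage:
    values = load_nifti(path)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return VoxelImage(values, mask, subject_id=subject_id, timepoint=timepoint)


def load_atlas(path: str | Path) -> AtlasLabelMap:
    data = load_nifti(path)
    return AtlasLabelMap(np.rint(data).astype(np.int32))


def load_subject_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_image_dir(
    directory: str | Path, mask: np.ndarray | None = None
) -> dict[tuple[str, str], VoxelImage]:
    """Load all ``<subject>_<timepoint>.nii.gz`` volumes from a directory."""
    directory = Path(directory)
    images: dict[tuple[str, str], VoxelImage] = {}
    for path in sorted(directory.glob("*.nii.gz")):
        stem = path.name[: -len(".nii.gz")]
        sid, _, tp = stem.rpartition("_")
        if not sid:
            raise ValueError(f"cannot parse subject/timepoint from {path.name}")
        images[(sid, tp)] = load_image(path, mask=mask, subject_id=sid, timepoint=tp)
    if not images:
        raise ValueError(f"no .nii.gz volumes found in {directory}")
    return images
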