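"""Two-step reference-cluster intensity normalization.

FDG-PET intensities are conventionally scaled to the cerebral global
mean.  In degenerative disease the whole brain is hypometabolic, so
global-mean scaling inflates patient values and shrinks the apparent
group difference.  The reference-cluster (Yakushev) procedure instead
normalizes to regions that are *relatively preserved* in patients:

1. scale every image to its cerebral global mean;
2. voxel-wise two-sample t-test, patients versus healthy controls, and
   keep the voxels that appear hypermetabolic in patients (patient mean
   greater than control mean, one-sided p below ``alpha``) — the
   *reference cluster*;
3. rescale each image to the mean intensity inside that cluster.

The hypermetabolic contrast is implemented one-sided (a two-sided test
would also admit hypometabolic voxels) with a pooled-variance t by
default; a Welch variant and an optional minimum connected-component
size are available but off by default.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats

from .types import VoxelImage, VoxelMask

__all__ = [
    "EmptyReferenceClusterError",
    "global_mean_normalize",
    "find_reference_cluster",
    "reference_cluster_normalize",
    "normalize_images",
]


class EmptyReferenceClusterError(RuntimeError):
    """No voxel passed the hypermetabolic contrast.

    Callers should either relax ``alpha`` or fall back to plain
    global-mean normalization; the fallback is never applied silently.
    """


def global_mean_normalize(img: VoxelImage) -> VoxelImage:
    """Scale an image so its in-mask mean intensity is exactly 1.

    Out-of-mask voxels are zeroed.  The input image is left unchanged.

    Raises
    ------
    ValueError
        If the in-mask mean is not strictly positive (degenerate image).
    """
    mean = float(img.values[img.mask].mean())
    if mean <= 0:
        raise ValueError(f"non-positive global mean ({mean}); cannot normalize")
    values = np.where(img.mask, img.values / mean, 0.0)
    return VoxelImage(values, img.mask.copy(), img.subject_id, img.timepoint)


def _check_grids(images: list[VoxelImage]) -> tuple[tuple[int, int, int], np.ndarray]:
    shape = images[0].shape
    mask = images[0].mask
    for im in images[1:]:
        if im.shape != shape or not np.array_equal(im.mask, mask):
            raise ValueError("images must share grid dimensions and brain mask")
    return shape, mask


def find_reference_cluster(
    patient_imgs: list[VoxelImage],
    control_imgs: list[VoxelImage],
    alpha: float = 0.05,
    equal_var: bool = True,
    min_cluster_size: int = 0,
) -> VoxelMask:
    """Voxel-wise hypermetabolic contrast of patients versus controls.

    All images must already be global-mean normalized and share one grid
    and brain mask.  For every in-mask voxel a two-sample t-test
    (pooled-variance by default, Welch if ``equal_var=False``) compares
    the patient group with the control group; voxels with patient mean
    above control mean at one-sided p < ``alpha`` form the reference
    cluster.  ``min_cluster_size`` optionally drops 6-connected
    components smaller than the given voxel count.

    Returns the selection with the full t- and p-maps retained for
    inspection (NaN outside the brain mask).
    """
    if not patient_imgs or not control_imgs:
        raise ValueError("both image lists must be non-empty")
    if len(patient_imgs) < 2 or len(control_imgs) < 2:
        raise ValueError("each group needs at least 2 images for a t-test")
    shape, mask = _check_grids(list(patient_imgs) + list(control_imgs))
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")

    pat = np.stack([im.values[mask] for im in patient_imgs])
    ctl = np.stack([im.values[mask] for im in control_imgs])
    t, p = stats.ttest_ind(pat, ctl, axis=0, equal_var=equal_var,
                           alternative="greater")

    t_map = np.full(shape, np.nan)
    p_map = np.full(shape, np.nan)
    t_map[mask] = t
    p_map[mask] = p

    selected = np.zeros(shape, dtype=bool)
    selected[mask] = p < alpha

    if min_cluster_size > 0 and selected.any():
        comp, n_comp = ndimage.label(selected)
        sizes = ndimage.sum_labels(selected, comp, index=np.arange(1, n_comp + 1))
        keep = np.flatnonzero(sizes >= min_cluster_size) + 1
        selected = np.isin(comp, keep)

    if not selected.any():
        raise EmptyReferenceClusterError(
            "no hypermetabolic voxels at alpha="
            f"{alpha}; consider global-mean normalization instead"
        )
    return VoxelMask(selected, t_map=t_map, p_map=p_map)


def reference_cluster_normalize(img: VoxelImage, ref: VoxelMask) -> VoxelImage:
    """Scale an image to mean 1 inside the reference cluster.

    Raises
    ------
    ValueError
        If the cluster is empty, lies outside the brain mask, or its
        mean intensity is not strictly positive.
    """
    if ref.selected.shape != img.shape:
        raise ValueError("reference mask grid does not match the image grid")
    if ref.n_selected == 0:
        raise ValueError("reference cluster is empty")
    if not np.all(img.mask[ref.selected]):
        raise ValueError("reference cluster must lie inside the brain mask")
    ref_mean = float(img.values[ref.selected].mean())
    if ref_mean <= 0:
        raise ValueError(f"non-positive reference-cluster mean ({ref_mean})")
    values = np.where(img.mask, img.values / ref_mean, 0.0)
    return VoxelImage(values, img.mask.copy(), img.subject_id, img.timepoint)


def normalize_images(
    patient_images: dict[tuple[str, str], VoxelImage],
    control_images: list[VoxelImage],
    timepoints: tuple[str, ...],
    alpha: float = 0.05,
    per_timepoint: bool = True,
    equal_var: bool = True,
    min_cluster_size: int = 0,
) -> tuple[dict[tuple[str, str], VoxelImage], dict[str, VoxelMask]]:
    """Run the full two-step normalization over a patient image set.

    Every image (patients and controls) is first global-mean scaled.
    Then a reference cluster is estimated — per follow-up timepoint from
    that timepoint's patient images against the control baseline set
    (``per_timepoint=True``), or once from the pooled baseline contrast
    and shared across timepoints — and each patient image is rescaled to
    its timepoint's cluster.

    Returns the normalized patient images and the cluster per timepoint.
    """
    controls_gm = [global_mean_normalize(im) for im in control_images]
    patients_gm = {key: global_mean_normalize(im) for key, im in patient_images.items()}

    clusters: dict[str, VoxelMask] = {}
    if per_timepoint:
        for tp in timepoints:
            tp_imgs = [im for (sid, t), im in patients_gm.items() if t == tp]
            clusters[tp] = find_reference_cluster(
                tp_imgs, controls_gm, alpha=alpha, equal_var=equal_var,
                min_cluster_size=min_cluster_size,
            )
    else:
        bl_imgs = [im for (sid, t), im in patients_gm.items() if t == timepoints[0]]
        shared = find_reference_cluster(
            bl_imgs, controls_gm, alpha=alpha, equal_var=equal_var,
            min_cluster_size=min_cluster_size,
        )
        clusters = {tp: shared for tp in timepoints}

    normalized = {
        (sid, tp): reference_cluster_normalize(im, clusters[tp])
        for (sid, tp), im in patients_gm.items()
    }
    return normalized, clusters
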