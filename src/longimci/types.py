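"""Core in-memory containers shared across the pipeline.

The pipeline operates on 3-D intensity volumes (one per subject and
timepoint), an integer-labeled parcellation atlas on the same voxel grid,
and a per-subject table of demographics and cognitive scores.  Everything
downstream (normalization, parcellation, dynamic features, classification)
is expressed in terms of these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical timepoint codes: baseline, then 6/12/18-month follow-ups.
TIMEPOINTS: tuple[str, ...] = ("bl", "m6", "m12", "m18")

#: Group labels used in the subject table.
GROUP_SMCI = "sMCI"
GROUP_PMCI = "pMCI"
GROUP_HC = "HC"

#: pMCI (converters) are the positive class everywhere.
POSITIVE_LABEL = GROUP_PMCI


@dataclass
class VoxelImage:
    """One subject/timepoint 3-D intensity grid with a brain mask.

    Parameters
    ----------
    values
        3-D float array of metabolic intensity (arbitrary units).
    mask
        3-D boolean array marking brain voxels; same shape as ``values``.
    subject_id, timepoint
        Metadata carried through the pipeline for provenance.
    """

    values: np.ndarray
    mask: np.ndarray
    subject_id: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D, got ndim={self.values.ndim}")
        if self.values.shape != self.mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape {self.mask.shape}"
            )
        if not self.mask.any():
            raise ValueError("brain mask is empty")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite intensities inside the brain mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def in_mask(self) -> np.ndarray:
        """Return the 1-D vector of in-mask intensities."""
        return self.values[self.mask]


@dataclass
class AtlasLabelMap:
    """Integer region labels on a voxel grid; 0 marks background.

    Labels are positive integers; every label present must be non-empty.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if (self.labels < 0).any():
            raise ValueError("atlas labels must be non-negative")

    @property
    def region_ids(self) -> np.ndarray:
        """Sorted array of distinct positive labels."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_regions(self) -> int:
        return int(self.region_ids.size)

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid of labeled (non-background) voxels."""
        return self.labels > 0


@dataclass
class RegionVector:
    """Per-region mean intensity for one subject/timepoint."""

    values: np.ndarray
    region_ids: np.ndarray
    subject_id: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = np.asarray(self.region_ids)
        if self.values.shape != self.region_ids.shape:
            raise ValueError("values and region_ids must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite region means")


@dataclass
class VoxelMask:
    """A selected voxel set (e.g. the reference cluster) with its test maps."""

    selected: np.ndarray
    t_map: np.ndarray | None = None
    p_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=bool)
        if self.selected.ndim != 3:
            raise ValueError("selection mask must be 3-D")

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


@dataclass
class GroupSummary:
    """Printed-table style summary of one group: mean, SD, size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be at least 2")
        if self.sd < 0:
            raise ValueError("standard deviation must be non-negative")


@dataclass
class TwoByTwo:
    """A 2x2 contingency table (rows = group, columns = category)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("cell counts must be non-negative integers")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)
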