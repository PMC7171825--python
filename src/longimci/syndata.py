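"""Synthetic longitudinal FDG-PET cohorts.

Real studies of MCI-to-AD conversion use access-controlled PET archives.
This module generates desk-scale stand-ins with the statistical structure
the downstream analysis assumes:

* two MCI groups (stable and progressive) whose metabolic intensity
  declines over follow-up timepoints, with the decline concentrated in a
  planted subset of atlas regions and faster in the progressive group;
* a set of *reference* regions that are spared the patients' otherwise
  global metabolic deficit, so that after global-mean scaling they appear
  relatively hypermetabolic in patients versus healthy controls — the
  signature the reference-cluster normalization searches for;
* a healthy-control group imaged at baseline only (controls enter the
  pipeline solely as the comparison set for normalization);
* additive age and gender effects on intensity, plus i.i.d. Gaussian
  voxel noise;
* MMSE and ADAS-cog trajectories that worsen faster in progressors.

Intensity model for a patient voxel v of subject s at follow-up index
``i`` (0 = baseline):

    I(v, s, i) = B * g_ref(v, s) * g_base(v, s) * (1 - delta_g)^i
                 + beta_age * (age_s - age_ref) + beta_sex * sex_s + noise

where ``B`` is the global baseline mean, ``g_ref`` applies the
non-reference deficit, ``g_base`` a group-specific baseline deficit in
affected regions, and ``delta_g`` the group decline rate (affected
regions only).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    GROUP_HC,
    GROUP_PMCI,
    GROUP_SMCI,
    TIMEPOINTS,
    AtlasLabelMap,
    VoxelImage,
)

__all__ = [
    "CognitiveGroupParams",
    "CognitiveParams",
    "CohortConfig",
    "SyntheticCohort",
    "make_atlas",
    "generate_cohort",
    "write_cohort",
    "subject_table_columns",
]


@dataclass
class CognitiveGroupParams:
    """Cognitive-score generator for one group.

    Baseline scores are drawn N(mean, sd) per subject; each later
    timepoint adds ``drift`` plus small visit-level noise.  MMSE falls
    and ADAS-cog rises with disease progression, so progressive-MCI
    defaults use a negative MMSE drift and positive ADAS drift larger in
    magnitude than the stable group's.
    """

    mmse_mean: float
    mmse_sd: float
    mmse_drift: float
    adas_mean: float
    adas_sd: float
    adas_drift: float
    visit_noise_sd: float = 0.5


def _default_cognitive() -> dict[str, CognitiveGroupParams]:
    # Baseline means/SDs follow typical amnestic-MCI cohorts (MMSE ~27-28,
    # ADAS-cog 14-18); progressors start slightly worse and worsen faster.
    return {
        GROUP_SMCI: CognitiveGroupParams(27.8, 1.4, -0.3, 13.9, 5.5, 0.5),
        GROUP_PMCI: CognitiveGroupParams(27.1, 1.6, -1.0, 18.1, 4.0, 1.8),
        GROUP_HC: CognitiveGroupParams(29.0, 1.0, 0.0, 5.0, 2.0, 0.0),
    }


@dataclass
class CognitiveParams:
    """Per-group cognitive trajectory parameters."""

    groups: dict[str, CognitiveGroupParams] = field(default_factory=_default_cognitive)


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort.

    The defaults describe the canonical study condition: equal baseline
    metabolism in both MCI groups, with the group difference planted in
    the longitudinal decline *rate* of the affected regions.  Setting
    ``baseline_deficit_pmci`` instead of the decline rates plants the
    difference in baseline level only.
    """

    n_smci: int = 46
    n_pmci: int = 33
    n_hc: int = 20
    grid_dims: tuple[int, int, int] = (18, 18, 12)
    n_regions: int = 246
    n_timepoints: int = 4
    baseline_mean: float = 100.0
    decline_per_tp_pmci: float = 0.04
    decline_per_tp_smci: float = 0.01
    baseline_deficit_pmci: float = 0.0
    baseline_deficit_smci: float = 0.0
    n_affected_regions: int = 40
    n_reference_regions: int = 20
    nonreference_deficit: float = 0.05
    age_effect: float = -0.3
    gender_effect: float = 2.0
    age_range: tuple[float, float] = (55.0, 85.0)
    age_ref: float = 70.0
    p_male: float = 0.65
    noise_sd: float = 4.0
    cognitive_params: CognitiveParams = field(default_factory=CognitiveParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_smci", "n_pmci", "n_hc", "n_regions", "n_affected_regions",
                     "n_reference_regions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.n_timepoints > len(TIMEPOINTS):
            raise ValueError(f"n_timepoints must be <= {len(TIMEPOINTS)}")
        if len(self.grid_dims) != 3 or any(d < 1 for d in self.grid_dims):
            raise ValueError("grid_dims must be three positive integers")
        if self.n_affected_regions + self.n_reference_regions > self.n_regions:
            raise ValueError(
                "n_affected_regions + n_reference_regions must not exceed n_regions"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.grid_dims = tuple(int(d) for d in self.grid_dims)  # type: ignore[assignment]

    @property
    def timepoints(self) -> tuple[str, ...]:
        return TIMEPOINTS[: self.n_timepoints]


@dataclass
class SyntheticCohort:
    """Generated images, atlas, subject table, and ground truth.

    ``images`` maps ``(subject_id, timepoint)`` to a :class:`VoxelImage`;
    healthy controls carry a baseline image only.  ``truth`` records the
    planted affected/reference region ids and the effect sizes used.
    """

    images: dict[tuple[str, str], VoxelImage]
    atlas: AtlasLabelMap
    subjects: pd.DataFrame
    truth: dict

    def mci_subjects(self) -> pd.DataFrame:
        return self.subjects[self.subjects["group"] != GROUP_HC]

    def hc_baseline_images(self) -> list[VoxelImage]:
        hc_ids = self.subjects.loc[self.subjects["group"] == GROUP_HC, "subject_id"]
        return [self.images[(sid, "bl")] for sid in hc_ids]


def subject_table_columns(timepoints: tuple[str, ...] = TIMEPOINTS) -> list[str]:
    """Canonical column order of the subject table."""
    cols = ["subject_id", "group", "age", "gender"]
    cols += [f"mmse_{tp}" for tp in timepoints]
    cols += [f"adas_{tp}" for tp in timepoints]
    return cols


def _snake_path(dims: tuple[int, int, int]) -> np.ndarray:
    """Boustrophedon path through the grid: consecutive voxels face-adjacent."""
    nx, ny, nz = dims
    slice_path = []
    for y in range(ny):
        xs = range(nx) if y % 2 == 0 else range(nx - 1, -1, -1)
        slice_path.extend((x, y) for x in xs)
    path = []
    for z in range(nz):
        sp = slice_path if z % 2 == 0 else slice_path[::-1]
        path.extend((x, y, z) for x, y in sp)
    return np.array(path, dtype=int)


def make_atlas(
    grid_dims: tuple[int, int, int], n_regions: int, seed: int = 0
) -> AtlasLabelMap:
    """Partition a grid into ``n_regions`` contiguous, non-empty regions.

    The grid is traversed along a serpentine path (so consecutive voxels
    are 6-connected) and cut into near-equal runs; each run becomes one
    region.  The assignment of label ids to runs is permuted by ``seed``
    so that region ids carry no spatial order.

    Raises
    ------
    ValueError
        If the grid holds fewer voxels than regions.
    """
    grid_dims = tuple(int(d) for d in grid_dims)  # type: ignore[assignment]
    n_voxels = int(np.prod(grid_dims))
    if n_voxels < n_regions:
        raise ValueError(
            f"cannot split {n_voxels} voxels into {n_regions} non-empty regions"
        )
    path = _snake_path(grid_dims)
    rng = np.random.default_rng(seed)
    label_for_run = rng.permutation(n_regions) + 1
    labels = np.zeros(grid_dims, dtype=np.int32)
    for run, chunk in enumerate(np.array_split(np.arange(n_voxels), n_regions)):
        xyz = path[chunk]
        labels[xyz[:, 0], xyz[:, 1], xyz[:, 2]] = label_for_run[run]
    return AtlasLabelMap(labels)


def _cognitive_scores(
    rng: np.random.Generator,
    params: CognitiveGroupParams,
    n_timepoints: int,
) -> tuple[np.ndarray, np.ndarray]:
    mmse0 = rng.normal(params.mmse_mean, params.mmse_sd)
    adas0 = rng.normal(params.adas_mean, params.adas_sd)
    idx = np.arange(n_timepoints)
    mmse = mmse0 + params.mmse_drift * idx + rng.normal(0, params.visit_noise_sd, n_timepoints)
    adas = adas0 + params.adas_drift * idx + rng.normal(0, params.visit_noise_sd, n_timepoints)
    return mmse, adas


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort from ``config``.

    Deterministic given ``config.seed``: the same configuration produces
    bit-identical images and tables.
    """
    ss = np.random.SeedSequence(config.seed)
    seed_atlas, seed_regions, seed_demo, seed_cog, seed_noise = ss.spawn(5)

    atlas = make_atlas(
        config.grid_dims,
        config.n_regions,
        seed=int(seed_atlas.generate_state(1)[0] % (2**31)),
    )
    region_ids = atlas.region_ids

    rng_regions = np.random.default_rng(seed_regions)
    chosen = rng_regions.choice(
        region_ids,
        size=config.n_affected_regions + config.n_reference_regions,
        replace=False,
    )
    affected = np.sort(chosen[: config.n_affected_regions])
    reference = np.sort(chosen[config.n_affected_regions:])

    affected_vox = np.isin(atlas.labels, affected)
    reference_vox = np.isin(atlas.labels, reference)
    nonref_vox = atlas.mask & ~reference_vox

    groups = (
        [GROUP_SMCI] * config.n_smci
        + [GROUP_PMCI] * config.n_pmci
        + [GROUP_HC] * config.n_hc
    )
    n_total = len(groups)
    subject_ids = [f"S{i + 1:03d}" for i in range(n_total)]

    rng_demo = np.random.default_rng(seed_demo)
    ages = rng_demo.uniform(*config.age_range, size=n_total)
    genders = (rng_demo.random(n_total) < config.p_male).astype(int)

    rng_cog = np.random.default_rng(seed_cog)
    rng_noise = np.random.default_rng(seed_noise)

    decline = {GROUP_SMCI: config.decline_per_tp_smci,
               GROUP_PMCI: config.decline_per_tp_pmci,
               GROUP_HC: 0.0}
    base_deficit = {GROUP_SMCI: config.baseline_deficit_smci,
                    GROUP_PMCI: config.baseline_deficit_pmci,
                    GROUP_HC: 0.0}

    mask = atlas.mask
    timepoints = config.timepoints
    images: dict[tuple[str, str], VoxelImage] = {}
    rows = []
    for sid, group, age, sex in zip(subject_ids, groups, ages, genders):
        gain = np.ones(config.grid_dims, dtype=float)
        if group != GROUP_HC:
            gain[nonref_vox] *= 1.0 - config.nonreference_deficit
            gain[affected_vox] *= 1.0 - base_deficit[group]
        covar = config.age_effect * (age - config.age_ref) + config.gender_effect * sex

        tps = timepoints if group != GROUP_HC else ("bl",)
        for i, tp in enumerate(tps):
            values = config.baseline_mean * gain.copy()
            if group != GROUP_HC and i > 0:
                values[affected_vox] *= (1.0 - decline[group]) ** i
            values += covar
            if config.noise_sd > 0:
                values += rng_noise.normal(0.0, config.noise_sd, size=config.grid_dims)
            values[~mask] = 0.0
            images[(sid, tp)] = VoxelImage(values, mask, subject_id=sid, timepoint=tp)

        cog = config.cognitive_params.groups[group]
        mmse, adas = _cognitive_scores(rng_cog, cog, config.n_timepoints)
        row = {"subject_id": sid, "group": group, "age": age, "gender": int(sex)}
        for i, tp in enumerate(timepoints):
            row[f"mmse_{tp}"] = mmse[i]
            row[f"adas_{tp}"] = adas[i]
        rows.append(row)

    subjects = pd.DataFrame(rows, columns=subject_table_columns(timepoints))
    truth = {
        "affected_regions": [int(r) for r in affected],
        "reference_regions": [int(r) for r in reference],
        "decline_per_tp": {GROUP_SMCI: config.decline_per_tp_smci,
                           GROUP_PMCI: config.decline_per_tp_pmci},
        "baseline_deficit": {GROUP_SMCI: config.baseline_deficit_smci,
                             GROUP_PMCI: config.baseline_deficit_pmci},
        "nonreference_deficit": config.nonreference_deficit,
        "age_effect": config.age_effect,
        "gender_effect": config.gender_effect,
        "seed": config.seed,
    }
    return SyntheticCohort(images=images, atlas=atlas, subjects=subjects, truth=truth)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write a cohort to disk: NIfTI volumes, TSV subject table, JSON truth."""
    from .io import save_nifti

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    save_nifti(cohort.atlas.labels, outdir / "atlas.nii.gz")
    for (sid, tp), img in cohort.images.items():
        save_nifti(img.values, outdir / "images" / f"{sid}_{tp}.nii.gz")
    save_nifti(
        cohort.atlas.mask.astype(np.uint8), outdir / "brain_mask.nii.gz"
    )
    cohort.subjects.to_csv(outdir / "subjects.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(json.dumps(cohort.truth, indent=2))
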