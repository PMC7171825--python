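"""Feature extraction: static region intensities, dynamic change, cognition.

Three feature families are produced per MCI subject:

* **Static** — mean normalized metabolic intensity of every atlas region
  at each timepoint (blocks ``Static_mbl``, ``Static_m6``,
  ``Static_m12``, ``Static_m18``).
* **Dynamic** — per-region intensity loss from baseline,
  ``D_i = T_baseline - T_i``, and its change rate
  ``R_i = D_i / T_baseline`` for the three follow-ups (i = 1, 2, 3
  mapping to m6, m12, m18); blocks ``Dynamic_1..3`` and ``R1..3``.
* **Cognitive** — MMSE and ADAS-cog at all four timepoints (8 columns).

Age and gender confounds are removed from the imaging data by linear
regression.  Residualization is linear in the response with a shared
design matrix, so removing confounds at the voxel level and then
averaging within regions equals averaging first and residualizing the
region means; the implementation uses the region-level path.  By default
the fitted mean is added back to the adjusted values (only the centered
covariate contributions are removed), which keeps normalized intensities
near 1 so the ratio features R stay well defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import (
    GROUP_HC,
    TIMEPOINTS,
    AtlasLabelMap,
    RegionVector,
    VoxelImage,
)

__all__ = [
    "FeatureMatrix",
    "BLOCK_SETS",
    "parcellate",
    "residualize_confounds",
    "dynamic_features",
    "assemble_cognitive",
    "combine_feature_sets",
    "build_feature_matrix",
]

#: Named feature-set configurations evaluated in the benchmark tables.
#: ``Dynamic_all`` is the three difference blocks; the change-rate blocks
#: R1-3 are reported separately and excluded from the combinations.
BLOCK_SETS: dict[str, tuple[str, ...]] = {
    "Static_mbl": ("Static_mbl",),
    "Static_m6": ("Static_m6",),
    "Static_m12": ("Static_m12",),
    "Static_m18": ("Static_m18",),
    "Static_all": ("Static_mbl", "Static_m6", "Static_m12", "Static_m18"),
    "Dynamic_1": ("Dynamic_1",),
    "Dynamic_2": ("Dynamic_2",),
    "Dynamic_3": ("Dynamic_3",),
    "R1": ("R1",),
    "R2": ("R2",),
    "R3": ("R3",),
    "Dynamic_all": ("Dynamic_1", "Dynamic_2", "Dynamic_3"),
    "Cognitive": ("Cognitive",),
    "Static&Dynamic": (
        "Static_mbl", "Static_m6", "Static_m12", "Static_m18",
        "Dynamic_1", "Dynamic_2", "Dynamic_3",
    ),
    "Static&Cognitive": (
        "Static_mbl", "Static_m6", "Static_m12", "Static_m18", "Cognitive",
    ),
    "Dynamic&Cognitive": ("Dynamic_1", "Dynamic_2", "Dynamic_3", "Cognitive"),
    "All": (
        "Static_mbl", "Static_m6", "Static_m12", "Static_m18",
        "Dynamic_1", "Dynamic_2", "Dynamic_3", "Cognitive",
    ),
}


@dataclass
class FeatureMatrix:
    """Subjects x features with named, non-overlapping column blocks.

    ``data`` is indexed by subject id; ``blocks`` maps each block name to
    its ordered column names (the block ranges partition the columns);
    ``labels`` holds the per-subject group label (two values for
    classification cohorts).
    """

    data: pd.DataFrame
    blocks: dict[str, list[str]]
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        block_cols = [c for cols in self.blocks.values() for c in cols]
        if list(self.data.columns) != block_cols:
            raise ValueError("block column lists must partition data columns in order")
        if len(set(block_cols)) != len(block_cols):
            raise ValueError("duplicate feature column names")
        if self.data.isna().any().any():
            raise ValueError("feature matrix contains missing cells")
        if self.labels is not None:
            if not self.labels.index.equals(self.data.index):
                raise ValueError("labels index must match subject index")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset(self, block_names: Sequence[str]) -> "FeatureMatrix":
        """Return the FeatureMatrix restricted to the named blocks."""
        missing = [b for b in block_names if b not in self.blocks]
        if missing:
            raise KeyError(f"unknown blocks: {missing}")
        blocks = {b: list(self.blocks[b]) for b in block_names}
        cols = [c for cols in blocks.values() for c in cols]
        return FeatureMatrix(self.data[cols], blocks, self.labels)

    def feature_set(self, name: str) -> "FeatureMatrix":
        """Return one of the named benchmark configurations (``BLOCK_SETS``)."""
        if name not in BLOCK_SETS:
            raise KeyError(f"unknown feature set {name!r}; known: {sorted(BLOCK_SETS)}")
        return self.subset(BLOCK_SETS[name])

    def to_tsv(self, path: str | Path) -> None:
        """Write values as TSV with a ``.blocks.json`` sidecar."""
        path = Path(path)
        out = self.data.copy()
        if self.labels is not None:
            out.insert(0, "group", self.labels)
        out.to_csv(path, sep="\t", index_label="subject_id")
        sidecar = path.with_suffix(path.suffix + ".blocks.json")
        sidecar.write_text(json.dumps(self.blocks, indent=2))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col="subject_id")
        labels = None
        if "group" in df.columns:
            labels = df.pop("group")
        blocks = json.loads(
            path.with_suffix(path.suffix + ".blocks.json").read_text()
        )
        return cls(df, {k: list(v) for k, v in blocks.items()}, labels)


def parcellate(img: VoxelImage, atlas: AtlasLabelMap) -> RegionVector:
    """Mean in-mask intensity per atlas region.

    Raises
    ------
    ValueError
        If the grids differ or a region is empty under the brain mask
        (the offending region id is named).
    """
    if atlas.labels.shape != img.shape:
        raise ValueError("atlas grid does not match image grid")
    region_ids = atlas.region_ids
    labels = np.where(img.mask, atlas.labels, 0)
    counts = ndimage.sum_labels(np.ones_like(labels), labels, index=region_ids)
    empty = region_ids[counts == 0]
    if empty.size:
        raise ValueError(f"region {int(empty[0])} is empty under the brain mask")
    means = ndimage.mean(img.values, labels, index=region_ids)
    return RegionVector(np.asarray(means, dtype=float), region_ids,
                        img.subject_id, img.timepoint)


def residualize_confounds(
    data: np.ndarray,
    covariates: pd.DataFrame,
    keep_mean: bool = False,
) -> np.ndarray:
    """Remove linear age and gender effects from each column of ``data``.

    ``data`` is subjects x variables; ``covariates`` must provide ``age``
    and ``gender`` columns aligned row-for-row.  Each variable is
    regressed on (intercept, age, gender) and replaced by its
    least-squares residual, which is exactly orthogonal to the age and
    gender columns.  With ``keep_mean=True`` the variable's mean is
    added back, i.e. only the centered covariate contributions are
    removed — the form used for intensity features so they stay on their
    original scale.

    Raises
    ------
    ValueError
        If fewer than 3 subjects are supplied or the design matrix is
        rank-deficient (e.g. a single-gender cohort).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects to fit the confound model")
    if len(covariates) != n:
        raise ValueError("covariate rows must match data rows")
    design = np.column_stack([
        np.ones(n),
        covariates["age"].to_numpy(dtype=float),
        covariates["gender"].to_numpy(dtype=float),
    ])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient confound design (constant age or gender?)")
    beta, *_ = np.linalg.lstsq(design, data, rcond=None)
    resid = data - design @ beta
    if keep_mean:
        resid = resid + data.mean(axis=0, keepdims=True)
    return resid


def dynamic_features(
    statics: Mapping[str, RegionVector],
    eps: float = 1e-12,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Difference and change-rate features from per-timepoint region means.

    ``statics`` maps timepoint codes (``bl`` plus follow-ups in
    ``TIMEPOINTS`` order) to region vectors on one region set.  Returns
    ``(D, R)`` where ``D["Dynamic_i"] = T_bl - T_i`` and
    ``R["Ri"] = D_i / T_bl`` element-wise, so ``R_i * T_bl == D_i``.

    Raises
    ------
    ValueError
        If the baseline is missing, region sets differ, or any baseline
        magnitude falls below ``eps`` (the ratio would be undefined).
    """
    if "bl" not in statics:
        raise ValueError("baseline ('bl') region vector is required")
    base = statics["bl"]
    if np.any(np.abs(base.values) < eps):
        bad = int(base.region_ids[np.argmin(np.abs(base.values))])
        raise ValueError(
            f"baseline intensity below eps={eps} in region {bad}; ratio undefined"
        )
    followups = [tp for tp in TIMEPOINTS[1:] if tp in statics]
    if not followups:
        raise ValueError("at least one follow-up timepoint is required")
    d: dict[str, np.ndarray] = {}
    r: dict[str, np.ndarray] = {}
    for i, tp in enumerate(followups, start=1):
        vec = statics[tp]
        if not np.array_equal(vec.region_ids, base.region_ids):
            raise ValueError(f"region set mismatch at timepoint {tp}")
        diff = base.values - vec.values
        d[f"Dynamic_{i}"] = diff
        r[f"R{i}"] = diff / base.values
    return d, r


def assemble_cognitive(subjects: pd.DataFrame) -> pd.DataFrame:
    """Per-subject cognitive block: MMSE x4 then ADAS-cog x4.

    Expects the subject table columns ``mmse_bl..mmse_m18`` and
    ``adas_bl..adas_m18``; raises with the subject id on any missing
    score.
    """
    cols = [f"mmse_{tp}" for tp in TIMEPOINTS] + [f"adas_{tp}" for tp in TIMEPOINTS]
    missing_cols = [c for c in cols if c not in subjects.columns]
    if missing_cols:
        raise ValueError(f"subject table lacks columns {missing_cols}")
    block = subjects.set_index("subject_id")[cols].astype(float)
    if block.isna().any().any():
        bad = block[block.isna().any(axis=1)].index[0]
        raise ValueError(f"missing cognitive score for subject {bad}")
    return block


def combine_feature_sets(parts: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation of feature matrices, preserving blocks.

    All parts must share the subject ordering; duplicate block or column
    names are rejected.
    """
    if not parts:
        raise ValueError("no feature matrices to combine")
    index = parts[0].data.index
    labels = parts[0].labels
    blocks: dict[str, list[str]] = {}
    frames = []
    for fm in parts:
        if not fm.data.index.equals(index):
            raise ValueError("subject ordering differs between feature matrices")
        for name, cols in fm.blocks.items():
            if name in blocks:
                raise ValueError(f"duplicate block name {name!r}")
            blocks[name] = list(cols)
        frames.append(fm.data)
    data = pd.concat(frames, axis=1)
    if data.columns.duplicated().any():
        dup = data.columns[data.columns.duplicated()][0]
        raise ValueError(f"duplicate feature column name {dup!r}")
    return FeatureMatrix(data, blocks, labels)


def build_feature_matrix(
    images: Mapping[tuple[str, str], VoxelImage],
    atlas: AtlasLabelMap,
    subjects: pd.DataFrame,
    residualize: bool = True,
    eps: float = 1e-12,
) -> FeatureMatrix:
    """Assemble the full block-structured feature matrix for MCI subjects.

    ``images`` are the normalized patient volumes keyed by
    ``(subject_id, timepoint)``.  Static blocks are region means
    (confound-adjusted when ``residualize`` is on), dynamic blocks are
    computed from the adjusted statics, and the cognitive block is taken
    from the subject table as-is (cognitive scores are not residualized).
    """
    mci = subjects[subjects["group"] != GROUP_HC].reset_index(drop=True)
    sids = list(mci["subject_id"])
    region_ids = atlas.region_ids

    statics: dict[str, np.ndarray] = {}
    for tp in TIMEPOINTS:
        rows = [parcellate(images[(sid, tp)], atlas).values for sid in sids]
        statics[tp] = np.vstack(rows)

    if residualize:
        covars = mci[["age", "gender"]]
        for tp in TIMEPOINTS:
            statics[tp] = residualize_confounds(statics[tp], covars, keep_mean=True)

    block_frames: list[FeatureMatrix] = []
    index = pd.Index(sids, name="subject_id")
    labels = pd.Series(mci["group"].to_numpy(), index=index, name="group")
    tp_block = {"bl": "Static_mbl", "m6": "Static_m6",
                "m12": "Static_m12", "m18": "Static_m18"}
    for tp in TIMEPOINTS:
        name = tp_block[tp]
        cols = [f"{name}_r{r}" for r in region_ids]
        df = pd.DataFrame(statics[tp], index=index, columns=cols)
        block_frames.append(FeatureMatrix(df, {name: cols}, labels))

    d_rows: dict[str, list[np.ndarray]] = {f"Dynamic_{i}": [] for i in (1, 2, 3)}
    r_rows: dict[str, list[np.ndarray]] = {f"R{i}": [] for i in (1, 2, 3)}
    for row, sid in enumerate(sids):
        vecs = {
            tp: RegionVector(statics[tp][row], region_ids, sid, tp)
            for tp in TIMEPOINTS
        }
        d, r = dynamic_features(vecs, eps=eps)
        for k, v in d.items():
            d_rows[k].append(v)
        for k, v in r.items():
            r_rows[k].append(v)
    for name, rows in list(d_rows.items()) + list(r_rows.items()):
        cols = [f"{name}_r{r}" for r in region_ids]
        df = pd.DataFrame(np.vstack(rows), index=index, columns=cols)
        block_frames.append(FeatureMatrix(df, {name: cols}, labels))

    cog = assemble_cognitive(mci).loc[index]
    cog.columns = [f"Cognitive_{c}" for c in cog.columns]
    block_frames.append(
        FeatureMatrix(cog, {"Cognitive": list(cog.columns)}, labels)
    )
    return combine_feature_sets(block_frames)
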