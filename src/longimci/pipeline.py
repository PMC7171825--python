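"""End-to-end orchestration: simulate → normalize → extract → evaluate.

One :class:`RunConfig` drives the whole chain and a single global seed
fans out to per-stage seeds through ``numpy.random.SeedSequence``, so a
run is reproducible end to end and each stage is independently
re-runnable.  Stage outputs are plain files (NIfTI, TSV, JSON), so any
stage can also be fed real data of the right shape.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import SvmConfig, loo_evaluate, sweep_feature_count
from .features import BLOCK_SETS, FeatureMatrix, build_feature_matrix
from .normalize import normalize_images
from .select import f_score
from .syndata import CohortConfig, SyntheticCohort, generate_cohort, write_cohort
from .types import GROUP_HC, POSITIVE_LABEL

__all__ = ["RunConfig", "RunReport", "run_all", "stage_seeds"]

log = logging.getLogger("longimci")

DEFAULT_BLOCKS = (
    "Static_mbl", "Static_m6", "Static_m12", "Static_m18", "Static_all",
    "Dynamic_1", "Dynamic_2", "Dynamic_3", "R1", "R2", "R3", "Dynamic_all",
    "Cognitive", "Static&Dynamic", "Static&Cognitive", "Dynamic&Cognitive",
    "All",
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    alpha: float = 0.05
    per_timepoint_cluster: bool = True
    blocks: tuple[str, ...] = ("Static_mbl", "Static_m6", "Dynamic_1", "Cognitive")
    k: int = 46
    k_sweep: tuple[int, ...] | None = None
    svm: SvmConfig = field(default_factory=SvmConfig)
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = [b for b in self.blocks if b not in BLOCK_SETS]
        if unknown:
            raise ValueError(f"unknown feature blocks {unknown}; known: {sorted(BLOCK_SETS)}")


@dataclass
class RunReport:
    """Outputs of one pipeline run."""

    metrics: pd.DataFrame
    features: FeatureMatrix
    cohort: SyntheticCohort
    rankings: dict[str, np.ndarray]
    sweeps: dict[str, pd.DataFrame]
    provenance: dict


def stage_seeds(seed: int) -> dict[str, int]:
    """Derive per-stage seeds (< 2**31) from the global seed."""
    names = ("cohort", "svm", "misc")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage in order and assemble the per-block report.

    The report table has one row per requested feature set with
    ACC/SEN/SPE (percent) and AUC columns, mirroring the usual benchmark
    layout.  Errors in any stage propagate annotated with the stage
    name.
    """
    seeds = stage_seeds(config.seed)
    cohort_cfg = config.cohort
    if cohort_cfg.seed != seeds["cohort"]:
        cohort_cfg = CohortConfig(**{**cohort_cfg.__dict__, "seed": seeds["cohort"]})

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        cohort = generate_cohort(cohort_cfg)
        log.info("simulate: %d subjects in %.1fs",
                 len(cohort.subjects), time.perf_counter() - t0)

        stage = "normalize"
        t0 = time.perf_counter()
        mci_ids = set(cohort.mci_subjects()["subject_id"])
        patient_images = {
            key: im for key, im in cohort.images.items() if key[0] in mci_ids
        }
        normalized, clusters = normalize_images(
            patient_images,
            cohort.hc_baseline_images(),
            timepoints=cohort_cfg.timepoints,
            alpha=config.alpha,
            per_timepoint=config.per_timepoint_cluster,
        )
        log.info("normalize: clusters %s in %.1fs",
                 {tp: m.n_selected for tp, m in clusters.items()},
                 time.perf_counter() - t0)

        stage = "extract"
        t0 = time.perf_counter()
        fm = build_feature_matrix(normalized, cohort.atlas, cohort.subjects)
        log.info("extract: %d x %d in %.1fs", fm.n_subjects, fm.n_features,
                 time.perf_counter() - t0)

        stage = "evaluate"
        svm = SvmConfig(**{**config.svm.__dict__, "seed": seeds["svm"]})
        rows = []
        rankings: dict[str, np.ndarray] = {}
        sweeps: dict[str, pd.DataFrame] = {}
        for name in config.blocks:
            sub = fm.feature_set(name)
            k = min(config.k, sub.n_features)
            if config.k_sweep is not None:
                ks = [kk for kk in config.k_sweep if kk <= sub.n_features]
                curve, k = sweep_feature_count(sub, k_range=ks, svm=svm)
                sweeps[name] = curve
            res = loo_evaluate(sub, k=k, svm=svm)
            fs = f_score(sub.data.to_numpy(), sub.labels.to_numpy(), POSITIVE_LABEL)
            rankings[name] = fs.ranking
            rows.append({"feature_set": name, **res.summary()})
            log.info("evaluate %s: ACC %.2f (k=%d)", name, res.acc, k)
        metrics = pd.DataFrame(rows).set_index("feature_set")
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "alpha": config.alpha,
        "blocks": list(config.blocks),
        "k": config.k,
        "svm": {"C": config.svm.C, "sigma": config.svm.sigma,
                "gamma": config.svm.gamma, "scale": config.svm.scale},
        "cohort": {k: v for k, v in cohort_cfg.__dict__.items()
                   if not k.startswith("cognitive")},
    }
    report = RunReport(metrics=metrics, features=fm, cohort=cohort,
                       rankings=rankings, sweeps=sweeps, provenance=provenance)
    if config.outdir is not None:
        _write_report(report, clusters, Path(config.outdir))
    return report


def _write_report(report: RunReport, clusters, outdir: Path) -> None:
    from .io import save_nifti

    outdir.mkdir(parents=True, exist_ok=True)
    write_cohort(report.cohort, outdir / "cohort")
    report.metrics.to_csv(outdir / "metrics.tsv", sep="\t")
    report.features.to_tsv(outdir / "features.tsv")
    for tp, mask in clusters.items():
        save_nifti(mask.selected.astype(np.uint8),
                   outdir / f"reference_cluster_{tp}.nii.gz")
        save_nifti(np.nan_to_num(mask.t_map), outdir / f"tmap_{tp}.nii.gz")
        save_nifti(np.nan_to_num(mask.p_map, nan=1.0), outdir / f"pmap_{tp}.nii.gz")
    for name, ranking in report.rankings.items():
        safe = name.replace("&", "_and_")
        np.savetxt(outdir / f"ranking_{safe}.tsv", ranking, fmt="%d")
    for name, curve in report.sweeps.items():
        safe = name.replace("&", "_and_")
        curve.to_csv(outdir / f"sweep_{safe}.tsv", sep="\t", index=False)
    (outdir / "provenance.json").write_text(
        json.dumps(report.provenance, indent=2, default=str)
    )


def plot_sweep(curve: pd.DataFrame, path: str | Path) -> None:
    """Plain metrics-versus-feature-count plot for a sweep curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for col in ("ACC", "SEN", "SPE"):
        ax.plot(curve["k"], curve[col], label=col)
    ax.set_xlabel("number of selected features")
    ax.set_ylabel("metric (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
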