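"""End-to-end orchestration: simulate -> extract -> curves -> stability ->
consensus -> classify, with per-stage caching.

Every stage writes its outputs under the configured output directory and a
``.stage_hash`` file recording the hash of the configuration slice it
depends on.  A re-run with an unchanged configuration skips the stage; a
changed noise seed re-runs the noise stage and everything downstream while
the clean phantom geometry is reused.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import stability as stab_mod
from .classify import TreeConfig, evaluate_all_features, split_subjects, stability_accuracy_correlation
from .curves import FeatureCurve, build_curves, curves_to_table, normalize_all
from .errors import PipelineError
from .features import ExtractionConfig, extract_instance
from .io import read_cine_nifti, read_table, write_cine_nifti, write_json, write_table
from .phantom import (
    CohortSubject,
    NoiseInstance,
    generate_cohort,
    generate_phantom,
    make_noise_instances,
    rescale_to_unit,
)

logger = logging.getLogger("dynrad.pipeline")

__all__ = [
    "CohortSpec",
    "NoiseSpec",
    "ClassifySpec",
    "PipelineConfig",
    "run_pipeline",
]


@dataclass(frozen=True)
class CohortSpec:
    """Which synthetic subjects to simulate."""

    n_per_class: dict[str, int] | None = None
    n_subjects: int | None = 3
    frame_range: tuple[int, int] = (12, 50)
    cohort_seed: int = 0


@dataclass(frozen=True)
class NoiseSpec:
    """Noise levels (fraction of [0,1] range), replicates and base seed."""

    levels: tuple[float, ...] = (0.010, 0.020, 0.030, 0.040)
    replicates: int = 10
    base_seed: int = 0


@dataclass(frozen=True)
class ClassifySpec:
    """Per-class split counts and tree settings; disabled when None counts."""

    enabled: bool = False
    counts: tuple[int, int, int] = (12, 4, 4)
    seed: int = 0
    n_subsample_frames: int = 12


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    classify: ClassifySpec = field(default_factory=ClassifySpec)
    outdir: str = "dynrad_out"

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            return obj

        return clean(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def tup(x):
            return tuple(x) if isinstance(x, list) else x

        cohort = CohortSpec(
            n_per_class=d["cohort"].get("n_per_class"),
            n_subjects=d["cohort"].get("n_subjects"),
            frame_range=tup(d["cohort"].get("frame_range", (12, 50))),
            cohort_seed=d["cohort"].get("cohort_seed", 0),
        )
        noise = NoiseSpec(
            levels=tup(d["noise"].get("levels", (0.01, 0.02, 0.03, 0.04))),
            replicates=d["noise"].get("replicates", 10),
            base_seed=d["noise"].get("base_seed", 0),
        )
        e = d.get("extraction", {})
        extraction = ExtractionConfig(
            n_bins=e.get("n_bins", 32),
            glcm_offsets=tuple(tuple(o) for o in e.get("glcm_offsets", ((0, 1), (1, 0), (1, 1), (1, -1)))),
            glcm_symmetric=e.get("glcm_symmetric", True),
            zone_connectivity=e.get("zone_connectivity", 8),
            lbp_radius=e.get("lbp_radius", 1.0),
            lbp_points=e.get("lbp_points", 8),
            filters=tup(e.get("filters", ("original", "wavelet", "lbp2d"))),
            families=tup(e.get("families", ("firstorder", "glcm", "glszm"))),
        )
        c = d.get("classify", {})
        classify = ClassifySpec(
            enabled=c.get("enabled", False),
            counts=tup(c.get("counts", (12, 4, 4))),
            seed=c.get("seed", 0),
            n_subsample_frames=c.get("n_subsample_frames", 12),
        )
        return cls(
            cohort=cohort,
            noise=noise,
            extraction=extraction,
            classify=classify,
            outdir=d.get("outdir", "dynrad_out"),
        )

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return _hash_dict(payload)


def _hash_dict(d: dict) -> str:
    return hashlib.sha256(
        json.dumps(d, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage_fresh(stage_dir: Path, stage_hash: str, outputs: list[Path]) -> bool:
    hash_file = stage_dir / ".stage_hash"
    if not hash_file.exists():
        return False
    if hash_file.read_text().strip() != stage_hash:
        return False
    return all(p.exists() for p in outputs)


def _mark_stage(stage_dir: Path, stage_hash: str) -> None:
    stage_dir.mkdir(parents=True, exist_ok=True)
    (stage_dir / ".stage_hash").write_text(stage_hash + "\n")


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> Path:
    """Generate the cohort's phantoms and noise instances; write NIfTIs.

    Phantom rendering and noise injection carry separate cache keys so a
    changed noise seed reuses the clean geometry.
    """
    out = Path(config.outdir)
    cohort_hash = _hash_dict(config.to_dict()["cohort"])
    noise_hash = _hash_dict(
        {"cohort": config.to_dict()["cohort"], "noise": config.to_dict()["noise"]}
    )
    phantom_dir = out / "phantoms"
    noise_dir = out / "noise"
    manifest_path = noise_dir / "cohort_manifest.csv"

    cohort = _build_cohort(config.cohort)

    if not _stage_fresh(
        phantom_dir,
        cohort_hash,
        [phantom_dir / s.subject_id / "reference.nii.gz" for s in cohort],
    ):
        logger.info("simulate/phantoms: rendering %d subjects", len(cohort))
        for subj in cohort:
            seq = rescale_to_unit(generate_phantom(subj.params, subject_id=subj.subject_id))
            write_cine_nifti(
                seq,
                phantom_dir / subj.subject_id / "reference.nii.gz",
                phantom_dir / subj.subject_id / "reference_mask.nii.gz",
            )
        _mark_stage(phantom_dir, cohort_hash)
    else:
        logger.info("simulate/phantoms: cache hit")

    if _stage_fresh(noise_dir, noise_hash, [manifest_path]):
        logger.info("simulate/noise: cache hit")
        return manifest_path

    logger.info(
        "simulate/noise: levels=%s replicates=%d base_seed=%d",
        config.noise.levels,
        config.noise.replicates,
        config.noise.base_seed,
    )
    rows = []
    for subj in cohort:
        seq = read_cine_nifti(
            phantom_dir / subj.subject_id / "reference.nii.gz",
            phantom_dir / subj.subject_id / "reference_mask.nii.gz",
            subject_id=subj.subject_id,
        )
        instances = make_noise_instances(
            seq, list(config.noise.levels), config.noise.replicates, config.noise.base_seed
        )
        for inst in instances:
            stem = (
                "reference"
                if inst.level_label == "reference"
                else f"{inst.level_label}_{inst.replicate_index}"
            )
            ipath = noise_dir / subj.subject_id / f"{stem}.nii.gz"
            mpath = noise_dir / subj.subject_id / f"{stem}_mask.nii.gz"
            write_cine_nifti(inst.sequence, ipath, mpath)
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "class_label": subj.class_label,
                    "n_frames": inst.sequence.n_frames,
                    "level_label": inst.level_label,
                    "noise_std": inst.noise_std,
                    "replicate_index": inst.replicate_index,
                    "seed": inst.seed,
                    "image_path": str(ipath.relative_to(out)),
                    "mask_path": str(mpath.relative_to(out)),
                }
            )
    write_table(pd.DataFrame(rows), manifest_path, noise_hash)
    _mark_stage(noise_dir, noise_hash)
    return manifest_path


def _build_cohort(spec: CohortSpec) -> list[CohortSubject]:
    return generate_cohort(
        n_per_class=spec.n_per_class,
        n_subjects=spec.n_subjects,
        frame_range=spec.frame_range,
        cohort_seed=spec.cohort_seed,
    )


def stage_extract(config: PipelineConfig) -> Path:
    """Read the noise instances back from disk and extract feature tables."""
    out = Path(config.outdir)
    d = config.to_dict()
    stage_hash = _hash_dict({k: d[k] for k in ("cohort", "noise", "extraction")})
    stage_dir = out / "features"
    features_path = stage_dir / "features.csv"
    if _stage_fresh(stage_dir, stage_hash, [features_path]):
        logger.info("extract: cache hit")
        return features_path
    manifest = read_table(Path(config.outdir) / "noise" / "cohort_manifest.csv")
    logger.info("extract: %d instances", len(manifest))
    tables = []
    for _, row in manifest.iterrows():
        seq = read_cine_nifti(
            out / row["image_path"], out / row["mask_path"], subject_id=row["subject_id"]
        )
        inst = NoiseInstance(
            subject_id=row["subject_id"],
            level_label=row["level_label"],
            noise_std=float(row["noise_std"]),
            replicate_index=int(row["replicate_index"]),
            seed=int(row["seed"]),
            sequence=seq,
        )
        tables.append(extract_instance(inst, config.extraction))
    write_table(pd.concat(tables, ignore_index=True), features_path, stage_hash)
    _mark_stage(stage_dir, stage_hash)
    return features_path


def stage_curves(config: PipelineConfig) -> tuple[Path, Path]:
    """Assemble curves, normalize by the reference, report exclusions."""
    out = Path(config.outdir)
    d = config.to_dict()
    stage_hash = _hash_dict({k: d[k] for k in ("cohort", "noise", "extraction")})
    stage_dir = out / "curves"
    curves_path = stage_dir / "normalized_curves.csv"
    excl_path = stage_dir / "exclusions.csv"
    if _stage_fresh(stage_dir, stage_hash, [curves_path, excl_path]):
        logger.info("curves: cache hit")
        return curves_path, excl_path
    table = read_table(out / "features" / "features.csv")
    curves = build_curves(table)
    normalized, report = normalize_all(curves)
    logger.info(
        "curves: %d curves, %d (subject,feature) exclusions",
        len(normalized),
        int(report["excluded"].sum()),
    )
    write_table(curves_to_table(normalized), curves_path, stage_hash)
    write_table(report, excl_path, stage_hash)
    _mark_stage(stage_dir, stage_hash)
    return curves_path, excl_path


def _load_normalized_curves(path: Path) -> list[FeatureCurve]:
    table = read_table(path)
    return build_curves(table.drop(columns=["normalized"]))


def stage_stability(config: PipelineConfig) -> dict[str, Path]:
    """Stability scores, per-subject ranks, consensus and Spearman matrix."""
    out = Path(config.outdir)
    d = config.to_dict()
    stage_hash = _hash_dict({k: d[k] for k in ("cohort", "noise", "extraction")})
    stage_dir = out / "stability"
    paths = {
        "stability": stage_dir / "stability.csv",
        "consensus": stage_dir / "consensus.csv",
        "correlation": stage_dir / "correlation_matrix.csv",
        "summary": stage_dir / "stability_summary.json",
    }
    if _stage_fresh(stage_dir, stage_hash, list(paths.values())):
        logger.info("stability: cache hit")
        return paths
    normalized = _load_normalized_curves(out / "curves" / "normalized_curves.csv")
    exclusions = read_table(out / "curves" / "exclusions.csv")
    table = stab_mod.compute_stability(normalized, exclusions)
    consensus = stab_mod.consensus_ranking(table)
    rankings = {
        sid: sub[~sub["excluded"]].set_index("feature_id")["rank"]
        for sid, sub in table.groupby("subject_id")
    }
    if len(rankings) >= 2:
        corr, median_off = stab_mod.correlation_matrix(rankings)
    else:
        only = next(iter(rankings))
        corr = pd.DataFrame([[1.0]], index=[only], columns=[only])
        median_off = float("nan")
    logger.info("stability: median off-diagonal Spearman rho = %.3f", median_off)
    write_table(table, paths["stability"], stage_hash)
    write_table(consensus, paths["consensus"], stage_hash)
    write_table(corr.reset_index(names="subject_id"), paths["correlation"], stage_hash)
    write_json(
        {
            "median_offdiagonal_spearman_rho": median_off,
            "n_subjects": int(table["subject_id"].nunique()),
            "n_features_ranked": int(consensus["consensus_rank"].notna().sum()),
            "n_excluded_pairs": int(table["excluded"].sum()),
        },
        paths["summary"],
    )
    _mark_stage(stage_dir, stage_hash)
    return paths


def stage_classify(config: PipelineConfig) -> dict[str, Path]:
    """Per-feature decision trees and the rank-accuracy summary."""
    if not config.classify.enabled:
        raise PipelineError("classify", "classification disabled in config")
    if config.cohort.n_per_class is None:
        raise PipelineError("classify", "classification requires a class-labelled cohort")
    out = Path(config.outdir)
    d = config.to_dict()
    stage_hash = _hash_dict(
        {k: d[k] for k in ("cohort", "noise", "extraction", "classify")}
    )
    stage_dir = out / "classification"
    paths = {
        "results": stage_dir / "tree_results.csv",
        "summary": stage_dir / "classification_summary.json",
    }
    if _stage_fresh(stage_dir, stage_hash, list(paths.values())):
        logger.info("classify: cache hit")
        return paths
    normalized = _load_normalized_curves(out / "curves" / "normalized_curves.csv")
    consensus = read_table(out / "stability" / "consensus.csv")
    manifest = read_table(out / "noise" / "cohort_manifest.csv")
    labels = dict(
        manifest[["subject_id", "class_label"]].drop_duplicates().itertuples(index=False)
    )
    split = split_subjects(labels, config.classify.counts, config.classify.seed)
    tree_config = TreeConfig(
        seed=config.classify.seed,
        n_subsample_frames=config.classify.n_subsample_frames,
    )
    results = evaluate_all_features(normalized, split, labels, tree_config)
    results = results.merge(
        consensus[["feature_id", "consensus_rank"]], on="feature_id", how="left"
    )
    summary = stability_accuracy_correlation(consensus, results)
    logger.info(
        "classify: %d informative features, rank-accuracy rho = %.3f",
        summary["n_informative"],
        summary["rank_accuracy_rho"],
    )
    write_table(results, paths["results"], stage_hash)
    write_json(summary, paths["summary"])
    _mark_stage(stage_dir, stage_hash)
    return paths


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order; returns the artifact manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    logger.info("pipeline start: config_hash=%s outdir=%s", chash, out)
    artifacts: dict[str, str] = {}
    stage = "simulate"
    try:
        artifacts["cohort_manifest"] = str(stage_simulate(config))
        stage = "extract"
        artifacts["features"] = str(stage_extract(config))
        stage = "curves"
        cpath, epath = stage_curves(config)
        artifacts["normalized_curves"] = str(cpath)
        artifacts["exclusions"] = str(epath)
        stage = "stability"
        artifacts.update({k: str(v) for k, v in stage_stability(config).items()})
        if config.classify.enabled:
            stage = "classify"
            cls = stage_classify(config)
            artifacts["tree_results"] = str(cls["results"])
            artifacts["classification_summary"] = str(cls["summary"])
    except PipelineError:
        raise
    except Exception as exc:  # partial outputs are retained on disk
        raise PipelineError(stage, str(exc)) from exc
    manifest = {"config_hash": chash, "config": config.to_dict(), "artifacts": artifacts}
    write_json(manifest, out / "manifest.json")
    return manifest
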