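"""End-to-end orchestration: records -> calibrate -> cluster -> annotate
-> quantify per set -> differential abundance -> test-set verification.

A run is deterministic given (inputs, config, seed).  When an output
directory is supplied, every stage's table is written there along with
a stage-count log and a resolved-config snapshot (both timestamp-free,
so reruns are byte-identical).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotation as annotation_mod
from . import calibration as calibration_mod
from . import clustering as clustering_mod
from . import io_formats
from . import quantification as quant_mod
from . import stats as stats_mod
from .exceptions import ConfigError
from .io_formats import AnnotationTable, PeptideRecord, StudyDesign

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Every stage parameter with the pipeline's standard defaults."""

    max_rank: int = 5
    allowed_confidence: tuple[str, ...] = ("high", "medium", "low")
    lowess_fraction: float = 0.3
    lowess_iterations: int = 3
    min_calibration_pairs: int = 10
    mass_window_ppm: float = 5.0
    rt_window_frac: float = 0.05
    cluster_max_iter: int = 50
    cluster_tol: float = 1e-6
    min_members: int = 2
    mass_accuracy_ppm: float = 5.0
    protein_count_mode: str = "clusters"
    detection_fraction: float = 0.5
    min_peptides: int = 2
    fold: float = 2.0
    alpha: float = 0.05
    split_fraction: float = 2.0 / 3.0
    mw_mode: str = "auto"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "allowed_confidence" in data:
            data["allowed_confidence"] = tuple(data["allowed_confidence"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["allowed_confidence"] = list(data["allowed_confidence"])
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class PipelineResult:
    design: StudyDesign
    calibration_report: "object"  # pandas DataFrame
    clusters: list
    annotated_clusters: list
    peptide_matrices: dict[str, object]  # set -> AbundanceMatrix
    protein_matrices: dict[str, object]
    de_records: list
    counts: dict[str, int] = field(default_factory=dict)


def run_pipeline(
    records_by_sample: dict[str, list[PeptideRecord]],
    design: StudyDesign,
    config: PipelineConfig = PipelineConfig(),
    annotation: AnnotationTable | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the whole pipeline on in-memory records.

    ``design`` may lack discovery/test labels, in which case the seeded
    group-wise 2/3 : 1/3 split is applied first.
    """
    counts: dict[str, int] = {}
    counts["records_read"] = sum(len(v) for v in records_by_sample.values())

    design = quant_mod.assign_sets(design, config.seed, config.split_fraction)

    filtered = {
        s: io_formats.filter_peptide_records(
            recs, config.max_rank, config.allowed_confidence
        )
        for s, recs in records_by_sample.items()
    }
    counts["records_after_confidence_filter"] = sum(
        len(v) for v in filtered.values()
    )

    calibrated, report = calibration_mod.calibrate_study(
        filtered,
        design,
        fraction=config.lowess_fraction,
        iterations=config.lowess_iterations,
        min_pairs=config.min_calibration_pairs,
    )

    candidates = clustering_mod.build_clusters(
        calibrated,
        mass_window_ppm=config.mass_window_ppm,
        rt_window_frac=config.rt_window_frac,
        max_iter=config.cluster_max_iter,
        tol=config.cluster_tol,
    )
    counts["candidate_clusters"] = len(candidates)
    clusters = clustering_mod.filter_min_members(candidates, config.min_members)
    counts["clusters_min_members"] = len(clusters)

    annotated = annotation_mod.annotate_clusters(
        clusters,
        calibrated,
        annotation=annotation,
        max_ppm=config.mass_accuracy_ppm,
        min_members=config.min_members,
        count_mode=config.protein_count_mode,
    )
    counts["clusters_annotated"] = len(annotated)

    peptide_matrices = {}
    protein_matrices = {}
    for set_name in ("discovery", "test"):
        pep, prot = quant_mod.quantify_set(
            annotated,
            calibrated,
            design,
            set_name,
            min_fraction=config.detection_fraction,
        )
        peptide_matrices[set_name] = pep
        protein_matrices[set_name] = prot
        counts[f"peptides_{set_name}"] = pep.values.shape[0]
        counts[f"proteins_{set_name}"] = prot.values.shape[0]

    de_records = stats_mod.de_filter(
        protein_matrices["discovery"],
        design,
        annotation=dict(annotation) if annotation else None,
        min_peptides=config.min_peptides,
        alpha=config.alpha,
        fold=config.fold,
        mode=config.mw_mode,
    )
    stats_mod.verify_in_test(
        de_records,
        protein_matrices["test"],
        design,
        fold=config.fold,
        alpha=config.alpha,
        mode=config.mw_mode,
    )
    counts["de_discovery"] = sum(r.is_de_discovery for r in de_records)
    counts["verified_test"] = sum(r.is_verified_test for r in de_records)
    counts["significant_test"] = sum(r.is_significant_test for r in de_records)

    result = PipelineResult(
        design=design,
        calibration_report=report,
        clusters=clusters,
        annotated_clusters=annotated,
        peptide_matrices=peptide_matrices,
        protein_matrices=protein_matrices,
        de_records=de_records,
        counts=counts,
    )
    if outdir is not None:
        _write_run(result, config, Path(outdir))
    for stage, n in counts.items():
        logger.info("%s: %d", stage, n)
    return result


def _write_run(result: PipelineResult, config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    io_formats.write_design(result.design, outdir / "design.tsv")
    result.calibration_report.to_csv(
        outdir / "calibration_report.tsv", sep="\t", lineterminator="\n"
    )
    io_formats.write_cluster_list(result.clusters, outdir / "cluster_list.tsv")
    io_formats.write_cluster_list(
        result.annotated_clusters, outdir / "cluster_list_annotated.tsv"
    )
    for set_name in ("discovery", "test"):
        io_formats.write_abundance_matrix(
            result.peptide_matrices[set_name],
            outdir / f"peptide_abundance_{set_name}.tsv",
        )
        io_formats.write_abundance_matrix(
            result.protein_matrices[set_name],
            outdir / f"protein_abundance_{set_name}.tsv",
        )
    io_formats.write_de_table(result.de_records, outdir / "de_table.tsv")
    with (outdir / "run_log.txt").open("w", encoding="utf-8") as fh:
        for stage, n in result.counts.items():
            fh.write(f"{stage}\t{n}\n")


def run_from_files(
    manifest_path: str | Path,
    config: PipelineConfig = PipelineConfig(),
    annotation_path: str | Path | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """File-based entry point: YAML manifest -> full run."""
    records, design = read_manifest(manifest_path)
    annotation = (
        io_formats.read_annotation_table(annotation_path) if annotation_path else None
    )
    return run_pipeline(records, design, config, annotation=annotation, outdir=outdir)


def read_manifest(path: str | Path) -> tuple[dict[str, list[PeptideRecord]], StudyDesign]:
    """YAML manifest: a ``samples`` list of mappings with keys
    sample_id, path (relative to the manifest), group, optional set,
    optional is_reference."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "samples" not in data:
        raise ConfigError(f"{path}: manifest must contain a 'samples' list")
    samples = []
    records: dict[str, list[PeptideRecord]] = {}
    for entry in data["samples"]:
        sid = str(entry["sample_id"])
        samples.append(
            io_formats.SampleInfo(
                sample_id=sid,
                group=entry["group"],
                set_name=entry.get("set"),
                is_reference=bool(entry.get("is_reference", False)),
            )
        )
        records[sid] = io_formats.read_peptide_export(
            path.parent / entry["path"], sample_id=sid
        )
    return records, StudyDesign(tuple(samples))


def write_manifest(
    records_by_sample: dict[str, list[PeptideRecord]],
    design: StudyDesign,
    outdir: str | Path,
) -> Path:
    """Write per-sample exports plus a YAML manifest; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in design.samples:
        fname = f"{s.sample_id}.tsv"
        io_formats.write_peptide_export(
            records_by_sample[s.sample_id], outdir / fname
        )
        entry = {
            "sample_id": s.sample_id,
            "path": fname,
            "group": s.group,
            "is_reference": s.is_reference,
        }
        if s.set_name is not None:
            entry["set"] = s.set_name
        entries.append(entry)
    manifest = outdir / "manifest.yaml"
    with manifest.open("w", encoding="utf-8") as fh:
        yaml.safe_dump({"samples": entries}, fh, sort_keys=False)
    return manifest
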