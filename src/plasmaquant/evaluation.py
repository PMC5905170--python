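"""Ground-truth evaluation metrics for synthetic studies.

These helpers score a pipeline run against the generator's
:class:`~plasmaquant.synth.GroundTruth`: cluster-level feature
recovery, cross-run rt agreement after calibration, and the
differential-abundance confusion summary.
"""

from __future__ import annotations

from collections import defaultdict

from .clustering import FeatureCluster
from .io_formats import PeptideRecord, StudyDesign
from .stats import DERecord
from .synth import GroundTruth


def cluster_recovery(
    clusters: list[FeatureCluster], truth: GroundTruth
) -> tuple[float, int]:
    """Fraction of true features recovered as a single pure cluster.

    A feature counts as recovered when exactly one retained cluster
    contains any of its records and that cluster contains records of no
    other feature (decoy members disqualify it too).
    """
    feature_clusters: dict[str, set[str]] = defaultdict(set)
    cluster_pure: dict[str, str | None] = {}
    for c in clusters:
        feats = {truth.record_to_feature.get(m) for m in c.members}
        cluster_pure[c.cluster_id] = (
            next(iter(feats)) if len(feats) == 1 and None not in feats else None
        )
        for f in feats:
            if f is not None:
                feature_clusters[f].add(c.cluster_id)
    n_recovered = 0
    for f in truth.features:
        cids = feature_clusters.get(f.feature_id, set())
        if len(cids) == 1 and cluster_pure[next(iter(cids))] == f.feature_id:
            n_recovered += 1
    return n_recovered / len(truth.features), len(truth.features)


def calibration_agreement(
    calibrated: dict[str, list[PeptideRecord]],
    design: StudyDesign,
    truth: GroundTruth,
    rel_tol: float = 0.01,
) -> tuple[float, int]:
    """Fraction of corresponding feature observations whose calibrated
    rt lands within ``rel_tol`` (relative) of the reference run's rt for
    the same feature."""
    ref_id = design.reference_id
    ref_rt: dict[str, float] = {}
    for i, rec in enumerate(calibrated[ref_id]):
        feat = truth.record_to_feature.get((ref_id, i))
        if feat is not None:
            ref_rt[feat] = rec.rt
    n_total = 0
    n_close = 0
    for sample_id, records in calibrated.items():
        if sample_id == ref_id:
            continue
        for i, rec in enumerate(records):
            feat = truth.record_to_feature.get((sample_id, i))
            if feat is None or feat not in ref_rt:
                continue
            n_total += 1
            if abs(rec.rt - ref_rt[feat]) < rel_tol * ref_rt[feat]:
                n_close += 1
    return (n_close / n_total if n_total else 0.0), n_total


def de_confusion(de_records: list[DERecord], truth: GroundTruth) -> dict[str, float]:
    """Discovery-set DE calls vs the generator's true DE labels."""
    called = {r.accession for r in de_records if r.is_de_discovery}
    tp = len(called & truth.de_proteins)
    fp = len(called - truth.de_proteins)
    fn = len(truth.de_proteins - called)
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
        "fdp": fp / (tp + fp) if tp + fp else 0.0,
    }
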