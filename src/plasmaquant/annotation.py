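"""Sequence and protein assignment for the cluster list, plus the
measured-vs-theoretical mass-accuracy filter.

Each cluster receives the member sequence with the highest frequency
across its members; frequency ties are broken by the highest Xcorr
attained among the tied sequences' members, then lexicographically.
Shared peptides (several candidate accessions) are resolved to the
accession represented with the highest frequency across the whole
cluster list — by default counting clusters whose candidate sets
include the accession; counting member records instead is available via
``count_mode="records"``.  Members whose measured mass deviates from
the theoretical mass by 5 ppm or more are removed (strict ``< 5 ppm``
is retained), and clusters thereby falling below two members are
dropped.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace

from .clustering import FeatureCluster
from .io_formats import AnnotationTable, PeptideRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotatedCluster(FeatureCluster):
    representative_sequence: str = ""
    accession: str = ""
    protein_name: str = ""
    gene_symbol: str = ""


def _member_records(
    cluster: FeatureCluster, records_by_sample: dict[str, list[PeptideRecord]]
) -> list[PeptideRecord]:
    return [records_by_sample[s][i] for s, i in cluster.members]


def assign_representative_sequence(
    cluster: FeatureCluster, records_by_sample: dict[str, list[PeptideRecord]]
) -> str:
    """Modal member sequence; ties by max Xcorr, then lexicographic."""
    records = _member_records(cluster, records_by_sample)
    counts = Counter(r.sequence for r in records)
    top = max(counts.values())
    tied = [seq for seq, c in counts.items() if c == top]
    if len(tied) == 1:
        return tied[0]
    best_xcorr = {
        seq: max(r.xcorr for r in records if r.sequence == seq) for seq in tied
    }
    top_x = max(best_xcorr.values())
    return min(seq for seq in tied if best_xcorr[seq] == top_x)


def candidate_accessions(
    cluster: FeatureCluster, records_by_sample: dict[str, list[PeptideRecord]]
) -> tuple[str, ...]:
    """Union of the members' candidate lists, first-seen order."""
    seen: dict[str, None] = {}
    for r in _member_records(cluster, records_by_sample):
        for acc in r.proteins:
            seen.setdefault(acc)
    return tuple(seen)


def assign_protein(
    clusters: list[FeatureCluster],
    records_by_sample: dict[str, list[PeptideRecord]],
    annotation: AnnotationTable | None = None,
    count_mode: str = "clusters",
    representative_sequences: list[str] | None = None,
) -> list[AnnotatedCluster]:
    """Assign the representative sequence and a single protein per cluster.

    Protein choice for shared peptides is a function of the *whole*
    cluster list: the accession occurring most frequently across it
    wins (ties lexicographically smallest).  ``representative_sequences``
    may carry sequences computed earlier in the pipeline (before the
    mass-accuracy filter); otherwise they are computed here.
    """
    if count_mode not in ("clusters", "records"):
        raise ValueError("count_mode must be 'clusters' or 'records'")
    annotation = annotation or {}
    cand_sets = [candidate_accessions(c, records_by_sample) for c in clusters]
    freq: Counter[str] = Counter()
    for cluster, cands in zip(clusters, cand_sets):
        if count_mode == "clusters":
            freq.update(set(cands))
        else:
            for r in _member_records(cluster, records_by_sample):
                freq.update(set(r.proteins))
    if representative_sequences is None:
        representative_sequences = [
            assign_representative_sequence(c, records_by_sample) for c in clusters
        ]
    out: list[AnnotatedCluster] = []
    for cluster, cands, seq in zip(clusters, cand_sets, representative_sequences):
        if len(cands) == 1:
            acc = cands[0]
        else:
            top = max(freq[a] for a in cands)
            acc = min(a for a in cands if freq[a] == top)
        name, gene = annotation.get(acc, ("", ""))
        if acc not in annotation and annotation:
            logger.warning("accession %s absent from annotation table", acc)
        out.append(
            AnnotatedCluster(
                cluster_id=cluster.cluster_id,
                center_mass=cluster.center_mass,
                center_rt=cluster.center_rt,
                members=cluster.members,
                representative_sequence=seq,
                accession=acc,
                protein_name=name,
                gene_symbol=gene,
            )
        )
    return out


def filter_mass_accuracy(
    clusters: list[FeatureCluster],
    records_by_sample: dict[str, list[PeptideRecord]],
    max_ppm: float = 5.0,
    min_members: int = 2,
) -> list[FeatureCluster]:
    """Drop members at >= ``max_ppm`` measured-vs-theoretical deviation
    (strict ``<`` retained) and cascade-drop clusters that fall below
    ``min_members``.  Works on plain or annotated clusters."""
    out = []
    for c in clusters:
        kept = tuple(
            (s, i)
            for s, i in c.members
            if abs(records_by_sample[s][i].mass_error_ppm) < max_ppm
        )
        if len(kept) >= min_members:
            out.append(replace(c, members=kept))
    return out


def annotate_clusters(
    clusters: list[FeatureCluster],
    records_by_sample: dict[str, list[PeptideRecord]],
    annotation: AnnotationTable | None = None,
    max_ppm: float = 5.0,
    min_members: int = 2,
    count_mode: str = "clusters",
) -> list[AnnotatedCluster]:
    """Sequence assignment, then mass-accuracy filter, then protein
    assignment (the pipeline's stage order)."""
    sequences = {
        c.cluster_id: assign_representative_sequence(c, records_by_sample)
        for c in clusters
    }
    filtered = filter_mass_accuracy(
        clusters, records_by_sample, max_ppm=max_ppm, min_members=min_members
    )
    return assign_protein(
        filtered,
        records_by_sample,
        annotation=annotation,
        count_mode=count_mode,
        representative_sequences=[sequences[c.cluster_id] for c in filtered],
    )
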