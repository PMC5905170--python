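"""Per-set peptide and protein abundance matrices.

Stage order within a set (discovery or test):

1. build the peptide (cluster) x sample table of raw areas together
   with the per-cell detection state — *detected with area*,
   *identified but no area retrieved*, or *not identified*;
2. discovery only: keep peptides detected in at least half the samples
   of cases or of controls (no filter in the test set);
3. impute — identified-but-no-area cells get the mean observed area of
   the sample's group within the set (zero if the group has no observed
   area), not-identified cells get zero;
4. ppm-normalize — each cell divided by its sample's total area and
   scaled by 1e6, so every sample column sums to one million;
5. protein abundance = sum of the protein's normalized peptide areas,
   with the per-protein peptide count (distinct representative
   sequences surviving the set's filters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .annotation import AnnotatedCluster
from .exceptions import DesignError, NormalizationError
from .io_formats import PeptideRecord, SampleInfo, StudyDesign


@dataclass
class PeptideTable:
    """Cluster x sample area grid with detection states.

    ``areas`` holds raw (or, later, normalized) areas with ``NaN`` where
    no area value exists; ``detected`` flags cells where the peptide was
    identified in the run at all.  ``identified & isna(area)`` is the
    identified-but-no-area state; ``~identified`` is not-identified.
    """

    areas: pd.DataFrame
    detected: pd.DataFrame
    cluster_to_protein: pd.Series
    cluster_to_sequence: pd.Series

    def subset_samples(self, sample_ids: list[str]) -> "PeptideTable":
        return PeptideTable(
            areas=self.areas[sample_ids].copy(),
            detected=self.detected[sample_ids].copy(),
            cluster_to_protein=self.cluster_to_protein,
            cluster_to_sequence=self.cluster_to_sequence,
        )

    def subset_clusters(self, cluster_ids: pd.Index) -> "PeptideTable":
        return PeptideTable(
            areas=self.areas.loc[cluster_ids].copy(),
            detected=self.detected.loc[cluster_ids].copy(),
            cluster_to_protein=self.cluster_to_protein.loc[cluster_ids],
            cluster_to_sequence=self.cluster_to_sequence.loc[cluster_ids],
        )


@dataclass
class AbundanceMatrix:
    """Peptide- or protein-level normalized abundances (entities x samples)."""

    level: str  # "peptide" | "protein"
    set_name: str  # "discovery" | "test"
    values: pd.DataFrame
    peptide_count: pd.Series | None = None  # protein level only

    def __post_init__(self) -> None:
        if self.level not in ("peptide", "protein"):
            raise ValueError("level must be 'peptide' or 'protein'")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")


def split_sets(
    design: StudyDesign, seed: int, fraction: float = 2.0 / 3.0
) -> tuple[list[str], list[str]]:
    """Discovery/test sample ids under the group-wise 2/3 : 1/3 rule.

    Pre-assigned set labels are honored unchanged.  Otherwise each
    group is shuffled with a seeded generator and its first
    ``ceil(fraction * n)`` samples go to discovery, preserving the
    case/control balance; the reference sample is guaranteed a
    discovery slot (swapped with the first discovery sample of its
    group if needed).
    """
    if design.has_split:
        return design.sample_ids("discovery"), design.sample_ids("test")
    rng = np.random.default_rng(seed)
    discovery: list[str] = []
    test: list[str] = []
    for group in ("case", "control"):
        ids = design.group_ids(group)
        n_disc = math.ceil(fraction * len(ids))
        if n_disc >= len(ids):
            raise DesignError(
                f"group {group!r} too small to split ({len(ids)} samples)"
            )
        perm = list(rng.permutation(ids))
        discovery.extend(perm[:n_disc])
        test.extend(perm[n_disc:])
    ref = design.reference_id
    if ref in test:
        group = design.group_of(ref)
        swap = next(s for s in discovery if design.group_of(s) == group)
        discovery[discovery.index(swap)] = ref
        test[test.index(ref)] = swap
    order = {s.sample_id: i for i, s in enumerate(design.samples)}
    return sorted(discovery, key=order.get), sorted(test, key=order.get)


def assign_sets(design: StudyDesign, seed: int, fraction: float = 2.0 / 3.0) -> StudyDesign:
    """Return a design with discovery/test labels filled in."""
    if design.has_split:
        return design
    discovery, _ = split_sets(design, seed, fraction)
    disc = set(discovery)
    return StudyDesign(
        tuple(
            replace(s, set_name="discovery" if s.sample_id in disc else "test")
            for s in design.samples
        )
    )


def build_peptide_table(
    clusters: list[AnnotatedCluster],
    records_by_sample: dict[str, list[PeptideRecord]],
    design: StudyDesign,
) -> PeptideTable:
    """Cluster x sample grid of raw areas and detection states.

    A cluster may hold several records from one run (repeated
    identifications of the same feature); their observed areas are
    averaged.  A cluster with members from a run but no observed area
    in it is identified-but-no-area.
    """
    sample_ids = design.sample_ids()
    index = [c.cluster_id for c in clusters]
    areas = pd.DataFrame(np.nan, index=index, columns=sample_ids)
    detected = pd.DataFrame(False, index=index, columns=sample_ids)
    for c in clusters:
        per_sample: dict[str, list[float]] = {}
        for s, i in c.members:
            vals = per_sample.setdefault(s, [])
            a = records_by_sample[s][i].area
            if a is not None:
                vals.append(a)
        for s, vals in per_sample.items():
            detected.loc[c.cluster_id, s] = True
            if vals:
                areas.loc[c.cluster_id, s] = float(np.mean(vals))
    return PeptideTable(
        areas=areas,
        detected=detected,
        cluster_to_protein=pd.Series(
            {c.cluster_id: c.accession for c in clusters}, name="accession"
        ).loc[index],
        cluster_to_sequence=pd.Series(
            {c.cluster_id: c.representative_sequence for c in clusters},
            name="sequence",
        ).loc[index],
    )


def detection_filter(
    table: PeptideTable,
    design: StudyDesign,
    set_name: str,
    min_fraction: float = 0.5,
    apply: bool = True,
) -> PeptideTable:
    """Keep peptides detected in >= ``min_fraction`` of the samples of
    at least one group (cases OR controls); identity when ``apply`` is
    False (the test-set analysis applies no filter)."""
    if not apply:
        return table
    keep = pd.Series(False, index=table.detected.index)
    for group in ("case", "control"):
        ids = design.group_ids(group, set_name)
        if not ids:
            continue
        frac = table.detected[ids].sum(axis=1) / len(ids)
        keep |= frac >= min_fraction
    return table.subset_clusters(table.detected.index[keep])


def impute_missing(
    table: PeptideTable, design: StudyDesign, set_name: str
) -> pd.DataFrame:
    """Complete area grid for one set.

    identified-but-no-area -> mean of the peptide's *observed* areas in
    the sample's group within the set (zero if the group has none);
    not-identified -> zero.  Observed cells are never altered.
    """
    sample_ids = list(table.areas.columns)
    out = table.areas.copy()
    for group in ("case", "control"):
        ids = [s for s in design.group_ids(group, set_name) if s in sample_ids]
        if not ids:
            continue
        group_mean = out[ids].mean(axis=1)  # skips NaN; NaN if none observed
        for s in ids:
            no_area = table.detected[s] & out[s].isna()
            out.loc[no_area, s] = group_mean[no_area]
    return out.fillna(0.0)


def ppm_normalize(areas: pd.DataFrame) -> pd.DataFrame:
    """normalized peak area = (peptide peak area / total peak area) * 1e6."""
    totals = areas.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise NormalizationError(
            f"all-zero sample column(s): {', '.join(map(str, zero.index))}"
        )
    return areas.div(totals, axis=1) * 1e6


def protein_abundance(
    normalized: pd.DataFrame, table: PeptideTable, set_name: str
) -> AbundanceMatrix:
    """Protein abundance = sum of its peptides' normalized areas.

    ``peptide_count`` is the number of distinct representative
    sequences per protein among the set's surviving clusters.
    """
    protein = table.cluster_to_protein.loc[normalized.index]
    values = normalized.groupby(protein).sum().sort_index()
    values.index.name = "accession"
    seqs = table.cluster_to_sequence.loc[normalized.index]
    counts = (
        pd.DataFrame({"accession": protein, "sequence": seqs})
        .groupby("accession")["sequence"]
        .nunique()
        .sort_index()
    )
    return AbundanceMatrix(
        level="protein",
        set_name=set_name,
        values=values,
        peptide_count=counts.loc[values.index],
    )


def quantify_set(
    clusters: list[AnnotatedCluster],
    records_by_sample: dict[str, list[PeptideRecord]],
    design: StudyDesign,
    set_name: str,
    min_fraction: float = 0.5,
) -> tuple[AbundanceMatrix, AbundanceMatrix]:
    """Full quantification for one set: returns (peptide, protein)
    normalized abundance matrices."""
    table = build_peptide_table(clusters, records_by_sample, design)
    table = table.subset_samples(design.sample_ids(set_name))
    table = detection_filter(
        table, design, set_name, min_fraction=min_fraction,
        apply=(set_name == "discovery"),
    )
    complete = impute_missing(table, design, set_name)
    normalized = ppm_normalize(complete)
    peptide_matrix = AbundanceMatrix(
        level="peptide", set_name=set_name, values=normalized
    )
    return peptide_matrix, protein_abundance(normalized, table, set_name)
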