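"""Domain types and the TSV dialect used by every stage of the pipeline.

All tables are UTF-8, tab-separated, one header row, decimal point only
(no locale-dependent formatting, no thousands separators).  A peptide
export carries one identified peptide feature per row with the columns

    sample_id  sequence  measured_mass  theoretical_mass  rt  area
    xcorr  confidence  rank  proteins

where ``proteins`` is a semicolon-joined, ordered list of candidate
accessions and a *missing* peak area (identified, but no area could be
retrieved by the search software) is encoded as an empty field —
distinct from ``0.0``, because the two cases are imputed differently
downstream.
"""

from __future__ import annotations

import csv
import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import DesignError, FormatError

logger = logging.getLogger(__name__)

CONFIDENCE_LEVELS = ("high", "medium", "low")

#: Official Uniprot accession syntax; the synthetic generator emits
#: accessions matching this.  Record validation is deliberately more
#: permissive (any semicolon/whitespace-free token) so that toy inputs
#: remain usable.
UNIPROT_ACCESSION_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)

_ACCESSION_TOKEN_RE = re.compile(r"^[A-Za-z0-9_.\-]+$")

PEPTIDE_COLUMNS = (
    "sample_id",
    "sequence",
    "measured_mass",
    "theoretical_mass",
    "rt",
    "area",
    "xcorr",
    "confidence",
    "rank",
    "proteins",
)


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide feature from one LC-MS/MS run.

    Masses are neutral monoisotopic Da; ``rt`` is minutes; ``area`` is
    the integrated peak area or ``None`` when the identification carries
    no area (the MISSING sentinel).  ``proteins`` is the ordered list of
    candidate accessions reported by the search engine.
    """

    sample_id: str
    sequence: str
    measured_mass: float
    theoretical_mass: float
    rt: float
    area: float | None
    xcorr: float
    confidence: str
    rank: int
    proteins: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.measured_mass <= 0 or self.theoretical_mass <= 0:
            raise ValueError("masses must be positive")
        if self.rt <= 0:
            raise ValueError("rt must be positive")
        if self.area is not None and self.area < 0:
            raise ValueError("area must be non-negative or MISSING")
        if self.xcorr < 0:
            raise ValueError("xcorr must be non-negative")
        if self.confidence not in CONFIDENCE_LEVELS:
            raise ValueError(f"confidence must be one of {CONFIDENCE_LEVELS}")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if not self.proteins:
            raise ValueError("at least one candidate accession is required")
        for acc in self.proteins:
            if not _ACCESSION_TOKEN_RE.match(acc):
                raise ValueError(f"invalid accession token: {acc!r}")

    @property
    def mass_error_ppm(self) -> float:
        """Signed measured-vs-theoretical deviation in ppm."""
        return (
            (self.measured_mass - self.theoretical_mass)
            / self.theoretical_mass
            * 1e6
        )

    def with_rt(self, rt: float) -> "PeptideRecord":
        return replace(self, rt=rt)


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    group: str  # "case" | "control"
    set_name: str | None = None  # "discovery" | "test" | None (unsplit)
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise DesignError(f"group must be case/control, got {self.group!r}")
        if self.set_name not in (None, "discovery", "test"):
            raise DesignError(f"set must be discovery/test, got {self.set_name!r}")


@dataclass(frozen=True)
class StudyDesign:
    """Sample metadata: group, discovery/test set, reference-run flag.

    Exactly one sample is the rt-calibration reference and, once the
    discovery/test split is assigned, it must lie in the discovery set.
    """

    samples: tuple[SampleInfo, ...]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise DesignError("sample_ids must be unique")
        refs = [s for s in self.samples if s.is_reference]
        if len(refs) != 1:
            raise DesignError(
                f"exactly one reference sample required, found {len(refs)}"
            )
        labelled = [s for s in self.samples if s.set_name is not None]
        if labelled and len(labelled) != len(self.samples):
            raise DesignError("either all or no samples carry a set label")
        if labelled and refs[0].set_name != "discovery":
            raise DesignError("the reference sample must be in the discovery set")

    @property
    def reference_id(self) -> str:
        return next(s.sample_id for s in self.samples if s.is_reference)

    @property
    def has_split(self) -> bool:
        return self.samples[0].set_name is not None if self.samples else False

    def sample_ids(self, set_name: str | None = None) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if set_name is None or s.set_name == set_name
        ]

    def group_of(self, sample_id: str) -> str:
        return next(s.group for s in self.samples if s.sample_id == sample_id)

    def group_ids(self, group: str, set_name: str | None = None) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if s.group == group and (set_name is None or s.set_name == set_name)
        ]


#: accession -> (protein_name, gene_symbol)
AnnotationTable = Mapping[str, tuple[str, str]]
#: accession -> reported plasma concentration (> 0, arbitrary units)
ConcentrationTable = Mapping[str, float]


# ---------------------------------------------------------------------------
# peptide exports
# ---------------------------------------------------------------------------

def _parse_float(text: str, column: str, line_no: int) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise FormatError(
            f"line {line_no}: non-numeric {column} value {text!r}"
        ) from exc


def read_peptide_export(path: str | Path, sample_id: str | None = None) -> list[PeptideRecord]:
    """Read one per-sample peptide export (documented TSV dialect).

    ``sample_id``, when given, overrides the file's sample_id column
    (useful when a manifest names the sample).  Row order is preserved;
    an empty ``area`` field maps to the MISSING sentinel (``None``).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            warnings.warn(f"{path}: empty peptide export", stacklevel=2)
            return []
        missing = [c for c in PEPTIDE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(
                f"{path}: missing mandatory column(s): {', '.join(missing)}"
            )
        records: list[PeptideRecord] = []
        for line_no, row in enumerate(reader, start=2):
            area_text = (row["area"] or "").strip()
            try:
                rec = PeptideRecord(
                    sample_id=sample_id if sample_id is not None else row["sample_id"],
                    sequence=row["sequence"],
                    measured_mass=_parse_float(row["measured_mass"], "measured_mass", line_no),
                    theoretical_mass=_parse_float(row["theoretical_mass"], "theoretical_mass", line_no),
                    rt=_parse_float(row["rt"], "rt", line_no),
                    area=None if area_text == "" else _parse_float(area_text, "area", line_no),
                    xcorr=_parse_float(row["xcorr"], "xcorr", line_no),
                    confidence=row["confidence"],
                    rank=int(_parse_float(row["rank"], "rank", line_no)),
                    proteins=tuple(p for p in row["proteins"].split(";") if p),
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {line_no}: {exc}") from exc
            records.append(rec)
    if not records:
        warnings.warn(f"{path}: peptide export contains no data rows", stacklevel=2)
    return records


def write_peptide_export(records: Iterable[PeptideRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PEPTIDE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.sample_id,
                    r.sequence,
                    repr(r.measured_mass),
                    repr(r.theoretical_mass),
                    repr(r.rt),
                    "" if r.area is None else repr(r.area),
                    repr(r.xcorr),
                    r.confidence,
                    r.rank,
                    ";".join(r.proteins),
                ]
            )


def filter_peptide_records(
    records: Sequence[PeptideRecord],
    max_rank: int = 5,
    allowed_confidence: Iterable[str] = CONFIDENCE_LEVELS,
) -> list[PeptideRecord]:
    """Keep records with ``rank <= max_rank`` and an allowed confidence.

    Mirrors the search-export filters applied before any cross-run
    processing (all confidence levels, peptide rank up to 5 by default);
    relative record order is preserved.
    """
    allowed = set(allowed_confidence)
    if max_rank < 1:
        raise ValueError("max_rank must be >= 1")
    if not allowed:
        raise ValueError("allowed_confidence must be non-empty")
    return [r for r in records if r.rank <= max_rank and r.confidence in allowed]


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> StudyDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "set", "is_reference"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing design column(s): {sorted(missing)}")
    samples = []
    for row in df.itertuples(index=False):
        set_name = None if pd.isna(row.set) or row.set == "" else row.set
        samples.append(
            SampleInfo(
                sample_id=row.sample_id,
                group=row.group,
                set_name=set_name,
                is_reference=str(row.is_reference).lower() in ("1", "true", "yes"),
            )
        )
    return StudyDesign(tuple(samples))


def write_design(design: StudyDesign, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "group", "set", "is_reference"])
        for s in design.samples:
            writer.writerow(
                [s.sample_id, s.group, s.set_name or "", str(s.is_reference).lower()]
            )


# ---------------------------------------------------------------------------
# annotation / concentration tables
# ---------------------------------------------------------------------------

def read_annotation_table(path: str | Path) -> dict[str, tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("accession", "protein_name", "gene_symbol"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if df["accession"].duplicated().any():
        raise FormatError(f"{path}: duplicate accessions in annotation table")
    return {
        row.accession: (row.protein_name, row.gene_symbol)
        for row in df.itertuples(index=False)
    }


def write_annotation_table(table: AnnotationTable, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["accession", "protein_name", "gene_symbol"])
        for acc in sorted(table):
            name, gene = table[acc]
            writer.writerow([acc, name, gene])


def read_concentration_table(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    for col in ("accession", "concentration"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    table = dict(zip(df["accession"].astype(str), df["concentration"].astype(float)))
    if any(v <= 0 for v in table.values()):
        raise FormatError(f"{path}: concentrations must be positive")
    return table


def write_concentration_table(table: ConcentrationTable, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["accession", "concentration"])
        for acc in sorted(table):
            writer.writerow([acc, repr(float(table[acc]))])


# ---------------------------------------------------------------------------
# cluster list / abundance matrix / DE table
# ---------------------------------------------------------------------------

def write_cluster_list(clusters, path: str | Path) -> None:
    """Write the (possibly annotated) cluster list, sorted by cluster id.

    ``members`` is encoded as ``sample:index`` joined by semicolons.
    Annotated columns are included when the clusters carry them.
    """
    from .annotation import AnnotatedCluster  # deferred: avoid cycle

    annotated = bool(clusters) and isinstance(clusters[0], AnnotatedCluster)
    cols = ["cluster_id", "center_mass", "center_rt", "member_count", "members"]
    if annotated:
        cols += ["representative_sequence", "accession", "protein_name", "gene_symbol"]
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for c in sorted(clusters, key=lambda c: c.cluster_id):
            row = [
                c.cluster_id,
                repr(c.center_mass),
                repr(c.center_rt),
                c.member_count,
                ";".join(f"{s}:{i}" for s, i in c.members),
            ]
            if annotated:
                row += [
                    c.representative_sequence,
                    c.accession,
                    c.protein_name,
                    c.gene_symbol,
                ]
            writer.writerow(row)


def read_cluster_list(path: str | Path):
    """Re-read a cluster list written by :func:`write_cluster_list`."""
    from .annotation import AnnotatedCluster
    from .clustering import FeatureCluster

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    annotated = "representative_sequence" in df.columns
    clusters = []
    for row in df.itertuples(index=False):
        members = tuple(
            (part.rsplit(":", 1)[0], int(part.rsplit(":", 1)[1]))
            for part in row.members.split(";")
            if part
        )
        common = dict(
            cluster_id=row.cluster_id,
            center_mass=float(row.center_mass),
            center_rt=float(row.center_rt),
            members=members,
        )
        if annotated:
            clusters.append(
                AnnotatedCluster(
                    **common,
                    representative_sequence=row.representative_sequence,
                    accession=row.accession,
                    protein_name=row.protein_name,
                    gene_symbol=row.gene_symbol,
                )
            )
        else:
            clusters.append(FeatureCluster(**common))
    return clusters


def write_abundance_matrix(matrix, path: str | Path) -> None:
    """Write an AbundanceMatrix: one row per entity (sorted), samples as
    columns; protein matrices carry a ``peptide_count`` column."""
    df = matrix.values.sort_index().copy()
    entity_col = "accession" if matrix.level == "protein" else "cluster_id"
    out = df.reset_index(names=entity_col)
    if matrix.peptide_count is not None:
        out.insert(1, "peptide_count", matrix.peptide_count.loc[df.index].to_numpy())
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_abundance_matrix(path: str | Path, level: str, set_name: str):
    """Re-read a matrix written by :func:`write_abundance_matrix`."""
    from .quantification import AbundanceMatrix  # deferred: avoid cycle

    df = pd.read_csv(path, sep="\t")
    entity_col = "accession" if level == "protein" else "cluster_id"
    df = df.set_index(entity_col)
    peptide_count = None
    if "peptide_count" in df.columns:
        peptide_count = df.pop("peptide_count").astype(int)
    return AbundanceMatrix(
        level=level, set_name=set_name, values=df.astype(float),
        peptide_count=peptide_count,
    )


def write_de_table(records, path: str | Path) -> None:
    """Write DE records as a flat per-protein table (sorted by accession)."""
    from .stats import de_table  # deferred: avoid cycle

    de_table(records).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
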