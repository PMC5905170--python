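"""Differential abundance between cases and controls, test-set
verification, and concordance correlations.

A protein is differentially expressed in the discovery set when it is
quantified from at least two peptides, its two-sided Mann-Whitney
p-value is <= 0.05, and its case/control ratio of group-mean abundances
changes at least twofold (>= 2 or <= 0.5, with proteins seen only in
one group counting as changed in that direction).  A discovery hit is
*verified* when the independent test set shows the same trend with at
least a twofold change; it is additionally *significant in the test
set* when the test-set Mann-Whitney p-value is also <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .exceptions import StatsError
from .io_formats import ConcentrationTable, StudyDesign
from .quantification import AbundanceMatrix

#: fold-change sentinels for proteins observed in only one group
ONLY_IN_CASES = "only_in_cases"
ONLY_IN_CONTROLS = "only_in_controls"
UNDEFINED = "undefined"

FoldChange = float | str


@dataclass(frozen=True)
class SetStats:
    """Per-set summary for one protein."""

    n_peptides: int
    ratio: FoldChange
    p_value: float
    p_method: str  # "exact" | "asymptotic"


@dataclass
class DERecord:
    accession: str
    protein_name: str
    discovery: SetStats
    test: SetStats | None = None
    is_de_discovery: bool = False
    is_verified_test: bool = False
    is_significant_test: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n_pairs: int
    n_dropped: int
    transform: str = "log10"


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def mann_whitney(
    values_cases, values_controls, mode: str = "auto"
) -> tuple[float, str]:
    """Two-sided Mann-Whitney U p-value and the branch used.

    The exact rank-sum distribution is enumerated when ``mode="exact"``
    or automatically for tie-free samples with n1 + n2 <= 30; otherwise
    the normal approximation with tie and continuity correction is
    used.  Two identical constant groups have p = 1 by definition.
    """
    x = np.asarray(values_cases, dtype=float)
    y = np.asarray(values_controls, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("both groups must be non-empty")
    if mode not in ("exact", "auto"):
        raise ValueError("mode must be 'exact' or 'auto'")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0, "exact"
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "exact" or (not has_ties and x.size + y.size <= 30):
        method = "exact"
    else:
        method = "asymptotic"
    res = sp_stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue), method


def fold_change(values_cases, values_controls) -> FoldChange:
    """Ratio of group means, with only-in-one-group sentinels."""
    mc = float(np.mean(np.asarray(values_cases, dtype=float)))
    mk = float(np.mean(np.asarray(values_controls, dtype=float)))
    if mc < 0 or mk < 0:
        raise ValueError("abundances must be non-negative")
    if mk == 0 and mc == 0:
        return UNDEFINED
    if mk == 0:
        return ONLY_IN_CASES
    if mc == 0:
        return ONLY_IN_CONTROLS
    return mc / mk


def fold_direction(ratio: FoldChange, fold: float = 2.0) -> str | None:
    """'up' / 'down' when the ratio meets the fold criterion (sentinels
    count in their direction), else None."""
    if ratio == ONLY_IN_CASES:
        return "up"
    if ratio == ONLY_IN_CONTROLS:
        return "down"
    if isinstance(ratio, str):
        return None
    if ratio >= fold:
        return "up"
    if ratio <= 1.0 / fold:
        return "down"
    return None


# ---------------------------------------------------------------------------
# discovery DE and test-set verification
# ---------------------------------------------------------------------------

def _set_stats(
    matrix: AbundanceMatrix,
    design: StudyDesign,
    accession: str,
    mode: str,
) -> SetStats:
    cases = design.group_ids("case", matrix.set_name)
    controls = design.group_ids("control", matrix.set_name)
    row = matrix.values.loc[accession]
    p, method = mann_whitney(row[cases], row[controls], mode=mode)
    n_pep = (
        int(matrix.peptide_count.loc[accession])
        if matrix.peptide_count is not None
        else 0
    )
    return SetStats(
        n_peptides=n_pep,
        ratio=fold_change(row[cases], row[controls]),
        p_value=p,
        p_method=method,
    )


def de_filter(
    matrix: AbundanceMatrix,
    design: StudyDesign,
    annotation: dict[str, tuple[str, str]] | None = None,
    min_peptides: int = 2,
    alpha: float = 0.05,
    fold: float = 2.0,
    mode: str = "auto",
) -> list[DERecord]:
    """Discovery-set DE records, one per protein, sorted by accession.

    ``is_de_discovery`` requires peptide count >= ``min_peptides``,
    p <= ``alpha`` and an at-least-``fold`` change (sentinels qualify).
    """
    if matrix.level != "protein" or matrix.set_name != "discovery":
        raise ValueError("expected the discovery protein matrix")
    annotation = annotation or {}
    records = []
    for acc in matrix.values.index:
        st = _set_stats(matrix, design, acc, mode)
        records.append(
            DERecord(
                accession=acc,
                protein_name=annotation.get(acc, ("", ""))[0],
                discovery=st,
                is_de_discovery=(
                    st.n_peptides >= min_peptides
                    and st.p_value <= alpha
                    and fold_direction(st.ratio, fold) is not None
                ),
            )
        )
    return records


def verify_in_test(
    records: list[DERecord],
    test_matrix: AbundanceMatrix,
    design: StudyDesign,
    fold: float = 2.0,
    alpha: float = 0.05,
    mode: str = "auto",
) -> list[DERecord]:
    """Fill test-set stats and the verification flags in place.

    A discovery hit is verified when the test set shows the same trend
    with >= ``fold`` change; significance in the test set additionally
    requires test p <= ``alpha``.  Proteins absent from the test matrix
    are not verified.
    """
    if test_matrix.level != "protein" or test_matrix.set_name != "test":
        raise ValueError("expected the test protein matrix")
    for rec in records:
        if rec.accession not in test_matrix.values.index:
            rec.is_verified_test = False
            rec.is_significant_test = False
            continue
        st = _set_stats(test_matrix, design, rec.accession, mode)
        rec.test = st
        disc_dir = fold_direction(rec.discovery.ratio, fold)
        test_dir = fold_direction(st.ratio, fold)
        rec.is_verified_test = bool(
            rec.is_de_discovery and disc_dir is not None and disc_dir == test_dir
        )
        rec.is_significant_test = bool(rec.is_verified_test and st.p_value <= alpha)
    return records


def de_table(records: list[DERecord]) -> pd.DataFrame:
    """Flat per-protein table (one row per record, sorted by accession).

    A Benjamini-Hochberg column on the discovery p-values is included
    for information only; it plays no part in the DE calls.
    """
    rows = []
    for r in sorted(records, key=lambda r: r.accession):
        rows.append(
            {
                "accession": r.accession,
                "protein_name": r.protein_name,
                "n_peptides_discovery": r.discovery.n_peptides,
                "ratio_discovery": r.discovery.ratio,
                "p_discovery": r.discovery.p_value,
                "p_method_discovery": r.discovery.p_method,
                "n_peptides_test": r.test.n_peptides if r.test else "",
                "ratio_test": r.test.ratio if r.test else "",
                "p_test": r.test.p_value if r.test else "",
                "p_method_test": r.test.p_method if r.test else "",
                "is_de_discovery": r.is_de_discovery,
                "is_verified_test": r.is_verified_test,
                "is_significant_test": r.is_significant_test,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj_bh_discovery"] = multipletests(
            df["p_discovery"].to_numpy(), method="fdr_bh"
        )[1]
    return df


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def spearman_log(x, y) -> CorrelationResult:
    """Spearman rank correlation on log10-transformed positive pairs.

    Pairs with a non-positive member are dropped (their count is
    reported); at least three surviving pairs are required.  rho is
    invariant under the strictly increasing log transform; it is
    applied and reported for fidelity with standard practice.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = (x > 0) & (y > 0)
    n_dropped = int((~keep).sum())
    xs, ys = np.log10(x[keep]), np.log10(y[keep])
    if xs.size < 3:
        raise StatsError(f"need >= 3 positive pairs, got {xs.size}")
    rho, p = sp_stats.spearmanr(xs, ys)
    return CorrelationResult(
        rho=float(rho), p_value=float(p), n_pairs=int(xs.size), n_dropped=n_dropped
    )


def correlate_with_concentrations(
    matrix: AbundanceMatrix,
    concentrations: ConcentrationTable,
    design: StudyDesign,
    group: str,
) -> CorrelationResult:
    """Concordance of group-mean protein abundances with externally
    reported plasma concentrations (shared accessions only)."""
    ids = design.group_ids(group, matrix.set_name)
    means = matrix.values[ids].mean(axis=1)
    shared = sorted(set(means.index) & set(concentrations))
    if not shared:
        raise StatsError("no shared accessions with the concentration table")
    return spearman_log(
        means.loc[shared].to_numpy(),
        np.array([concentrations[a] for a in shared]),
    )


# ---------------------------------------------------------------------------
# bundled reference dataset
# ---------------------------------------------------------------------------

def load_reference_shortlist() -> pd.DataFrame:
    """Bundled shortlist of verified differentially abundant plasma
    proteins from a published CVD case-control study: per-set peptide
    counts, case/control ratios and Mann-Whitney p-values for the 39
    proteins that replicated their trend in the test set.  The
    ``ratio_test`` column uses the pipeline's only-in-controls sentinel
    where the test-set cases had no signal."""
    path = resources.files("plasmaquant").joinpath("data/cvd_plasma_shortlist.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    for col in ("p_discovery", "p_test"):
        df[col] = df[col].astype(float)
    return df


def classify_shortlist(
    df: pd.DataFrame, fold: float = 2.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Apply the DE/verification predicates to a printed shortlist.

    Re-derives, from the published per-set ratios and p-values, which
    rows pass discovery DE, which verify in the test set (same trend,
    >= fold), and which are also test-set significant.
    """
    def parse_ratio(v) -> FoldChange:
        if isinstance(v, str) and not v.replace(".", "", 1).isdigit():
            return v
        return float(v)

    out = df.copy()
    disc_dir = [fold_direction(parse_ratio(v), fold) for v in df["ratio_discovery"]]
    test_dir = [fold_direction(parse_ratio(v), fold) for v in df["ratio_test"]]
    out["is_de_discovery"] = [
        (n >= 2) and (p <= alpha) and (d is not None)
        for n, p, d in zip(df["n_peptides_discovery"], df["p_discovery"], disc_dir)
    ]
    out["is_verified_test"] = [
        de and (dd is not None) and (dd == td)
        for de, dd, td in zip(out["is_de_discovery"], disc_dir, test_dir)
    ]
    out["is_significant_test"] = out["is_verified_test"] & (df["p_test"] <= alpha)
    return out
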