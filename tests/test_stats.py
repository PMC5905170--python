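"""Mann-Whitney testing, fold-change rules, DE calls, verification,
Spearman concordance, and the synthetic recovery regression bound."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from plasmaquant.exceptions import StatsError
from plasmaquant.io_formats import SampleInfo, StudyDesign
from plasmaquant.pipeline import PipelineConfig, run_pipeline
from plasmaquant.quantification import AbundanceMatrix
from plasmaquant.stats import (
    ONLY_IN_CASES,
    ONLY_IN_CONTROLS,
    UNDEFINED,
    classify_shortlist,
    de_filter,
    de_table,
    fold_change,
    fold_direction,
    load_reference_shortlist,
    mann_whitney,
    spearman_log,
    verify_in_test,
)
from plasmaquant.synth import SynthConfig, generate_study
from plasmaquant.evaluation import de_confusion


def exact_mw_p(cases, controls):
    """Full enumeration of the rank-sum null: every labeling of the
    pooled values, two-sided tail probability of the observed U."""
    pooled = list(cases) + list(controls)
    n1 = len(cases)

    def u_stat(case_idx):
        case_vals = [pooled[i] for i in case_idx]
        ctrl_vals = [pooled[i] for i in range(len(pooled)) if i not in case_idx]
        return sum(
            (c > k) + 0.5 * (c == k) for c in case_vals for k in ctrl_vals
        )

    u_obs = u_stat(tuple(range(n1)))
    m = n1 * (len(pooled) - n1)
    lo = min(u_obs, m - u_obs)
    us = [u_stat(idx) for idx in itertools.combinations(range(len(pooled)), n1)]
    tail = sum(u <= lo for u in us) + sum(u >= m - lo for u in us)
    return min(1.0, tail / len(us))  # tails overlap when U is central


class TestMannWhitney:
    def test_fully_separated_three_vs_three(self):
        # most extreme of the C(6,3) = 20 equally likely labelings
        p, method = mann_whitney([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert method == "exact"

    def test_identical_constant_groups(self):
        assert mann_whitney([5, 5, 5], [5, 5, 5]) == (1.0, "exact")

    def test_exact_branch_matches_full_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 13 - n1))
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
            cases, controls = vals[:n1], vals[n1:]
            p, method = mann_whitney(cases, controls)
            assert method == "exact"
            assert p == pytest.approx(exact_mw_p(cases, controls), abs=1e-12)

    def test_ties_switch_to_asymptotic(self):
        p, method = mann_whitney([1, 2, 2, 3], [2, 4, 5, 6])
        assert method == "asymptotic"
        assert 0 < p <= 1

    def test_large_samples_switch_to_asymptotic(self):
        rng = np.random.default_rng(0)
        p, method = mann_whitney(rng.normal(size=20), rng.normal(size=20))
        assert method == "asymptotic"

    def test_exact_p_lies_on_discrete_lattice_for_13_vs_8(self):
        # exact two-sided p-values are multiples of 1 / C(21, 8)
        rng = np.random.default_rng(23)
        denom = math.comb(21, 8)
        for _ in range(20):
            vals = rng.permutation(np.arange(1.0, 22.0))
            p, method = mann_whitney(vals[:13], vals[13:], mode="exact")
            assert method == "exact"
            assert p * denom == pytest.approx(round(p * denom), abs=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            mann_whitney([], [1.0])


class TestFoldChange:
    def test_ratio_of_means(self):
        assert fold_change([4, 4], [2, 2]) == pytest.approx(2.0)

    def test_equal_groups_give_one(self):
        assert fold_change([3, 5], [4, 4]) == pytest.approx(1.0)

    def test_sentinels(self):
        assert fold_change([1, 1], [0, 0]) == ONLY_IN_CASES
        assert fold_change([0, 0], [1, 1]) == ONLY_IN_CONTROLS
        assert fold_change([0, 0], [0, 0]) == UNDEFINED

    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (2.0, "up"),
            (0.5, "down"),
            (1.8, None),
            (ONLY_IN_CASES, "up"),
            (ONLY_IN_CONTROLS, "down"),
            (UNDEFINED, None),
        ],
    )
    def test_fold_direction(self, ratio, expected):
        assert fold_direction(ratio) == expected


def _matrix(set_name, data, counts):
    """Protein AbundanceMatrix + matching design from per-group values."""
    rows = {}
    n_case = len(next(iter(data.values()))[0])
    n_ctrl = len(next(iter(data.values()))[1])
    case_ids = [f"{set_name[:1]}A{i}" for i in range(n_case)]
    ctrl_ids = [f"{set_name[:1]}B{i}" for i in range(n_ctrl)]
    for acc, (case_vals, ctrl_vals) in data.items():
        rows[acc] = dict(zip(case_ids + ctrl_ids, list(case_vals) + list(ctrl_vals)))
    values = pd.DataFrame(rows).T
    samples = [SampleInfo(s, "case", set_name) for s in case_ids]
    samples += [
        SampleInfo(s, "control", set_name, is_reference=False) for s in ctrl_ids
    ]
    matrix = AbundanceMatrix(
        "protein", set_name, values, pd.Series(counts).loc[values.index]
    )
    return matrix, samples


def _toy_study():
    """Discovery 5v4 and test 4v3 matrices with known DE structure."""
    disc_data = {
        # strong up-regulation, many peptides -> DE
        "P1": ([100, 120, 110, 130, 140], [20, 25, 22, 30]),
        # clear separation but under twofold -> not DE
        "P2": ([18, 19, 20, 21, 22], [10, 11, 12, 13]),
        # one peptide only -> not DE
        "P3": ([100, 120, 110, 130, 140], [20, 25, 22, 30]),
        # down-regulated -> DE
        "P4": ([10, 12, 11, 9, 10], [40, 44, 39, 41]),
        # only in cases -> sentinel DE
        "P5": ([50, 60, 55, 58, 52], [0, 0, 0, 0]),
        # flat -> not DE
        "P6": ([30, 31, 29, 30, 31], [30, 29, 31, 30]),
    }
    counts = {"P1": 68, "P2": 5, "P3": 1, "P4": 3, "P5": 2, "P6": 4}
    disc, disc_samples = _matrix("discovery", disc_data, counts)
    disc_samples[-1] = SampleInfo(
        disc_samples[-1].sample_id, "control", "discovery", is_reference=True
    )
    test_data = {
        "P1": ([200, 260, 240, 220], [40, 50, 45]),  # same trend, >= 2x -> verified
        "P2": ([18, 19, 20, 21], [10, 11, 12]),
        "P3": ([5, 5, 5, 5], [5, 5, 5]),
        "P4": ([12, 11, 13, 12], [30, 33, 31]),  # 0.37 vs 0.26: down again
        "P5": ([1, 2, 1, 2], [1.1, 1.9, 1.4]),  # trend lost -> not verified
        "P6": ([30, 31, 29, 30], [30, 29, 31]),
    }
    test, test_samples = _matrix("test", test_data, counts)
    design = StudyDesign(tuple(disc_samples + test_samples))
    return disc, test, design


class TestDeFilter:
    def test_toy_study_flags(self):
        disc, _, design = _toy_study()
        records = de_filter(disc, design)
        flags = {r.accession: r.is_de_discovery for r in records}
        assert flags == {
            "P1": True,
            "P2": False,
            "P3": False,
            "P4": True,
            "P5": True,
            "P6": False,
        }
        p1 = next(r for r in records if r.accession == "P1")
        assert p1.discovery.ratio == pytest.approx(
            np.mean([100, 120, 110, 130, 140]) / np.mean([20, 25, 22, 30])
        )
        p5 = next(r for r in records if r.accession == "P5")
        assert p5.discovery.ratio == ONLY_IN_CASES

    def test_matches_three_predicate_conjunction(self):
        rng = np.random.default_rng(9)
        data = {}
        counts = {}
        for i in range(40):
            acc = f"P{i:03d}"
            data[acc] = (rng.uniform(0, 50, 5), rng.uniform(0, 50, 4))
            counts[acc] = int(rng.integers(1, 6))
        matrix, samples = _matrix("discovery", data, counts)
        samples[0] = SampleInfo(samples[0].sample_id, "case", "discovery", True)
        design = StudyDesign(tuple(samples))
        # design invariant needs the reference in discovery: rebuild with ref
        records = de_filter(matrix, design)
        for r in records:
            cases, controls = data[r.accession]
            p, _ = mann_whitney(cases, controls)
            ratio = fold_change(cases, controls)
            expected = (
                counts[r.accession] >= 2
                and p <= 0.05
                and fold_direction(ratio) is not None
            )
            assert r.is_de_discovery == expected

    def test_flag_count_monotone_in_fold_and_alpha(self):
        disc, _, design = _toy_study()
        n = lambda recs: sum(r.is_de_discovery for r in recs)
        assert n(de_filter(disc, design, fold=1.0)) >= n(de_filter(disc, design, fold=2.0))
        assert n(de_filter(disc, design, alpha=0.01)) <= n(de_filter(disc, design, alpha=0.05))


class TestVerifyInTest:
    def test_toy_study_verification(self):
        disc, test, design = _toy_study()
        records = verify_in_test(de_filter(disc, design), test, design)
        by_acc = {r.accession: r for r in records}
        assert by_acc["P1"].is_verified_test  # up in both sets, >= 2x
        assert not by_acc["P5"].is_verified_test  # trend lost in test
        assert by_acc["P4"].is_verified_test  # down in both sets
        assert not by_acc["P2"].is_verified_test  # never DE in discovery

    def test_under_twofold_in_test_is_not_verified(self):
        disc, test, design = _toy_study()
        test.values.loc["P1"] = [30, 31, 29, 30, 20, 21, 22]  # ~1.4x
        records = verify_in_test(de_filter(disc, design), test, design)
        assert not next(r for r in records if r.accession == "P1").is_verified_test

    def test_verified_but_not_significant(self):
        disc, test, design = _toy_study()
        # overlapping test groups: same trend and fold, but weak p
        test.values.loc["P4"] = [10, 11, 60, 12, 70, 75, 2]
        records = verify_in_test(de_filter(disc, design), test, design)
        p4 = next(r for r in records if r.accession == "P4")
        assert p4.is_verified_test
        assert p4.test.p_value > 0.05
        assert not p4.is_significant_test

    def test_absent_from_test_matrix_is_not_verified(self):
        disc, test, design = _toy_study()
        test.values.drop(index="P1", inplace=True)
        records = verify_in_test(de_filter(disc, design), test, design)
        p1 = next(r for r in records if r.accession == "P1")
        assert not p1.is_verified_test and p1.test is None

    def test_de_table_mirrors_per_set_structure(self):
        disc, test, design = _toy_study()
        df = de_table(verify_in_test(de_filter(disc, design), test, design))
        for col in (
            "accession",
            "n_peptides_discovery",
            "ratio_discovery",
            "p_discovery",
            "n_peptides_test",
            "ratio_test",
            "p_test",
            "is_de_discovery",
            "is_verified_test",
            "is_significant_test",
        ):
            assert col in df.columns
        assert list(df["accession"]) == sorted(df["accession"])


class TestSpearmanLog:
    def test_monotone_pairs(self):
        x = np.arange(1.0, 11.0)
        assert spearman_log(x, 2 * x).rho == pytest.approx(1.0)

    def test_hand_ranked_example(self):
        res = spearman_log([1, 2, 3, 4, 5], [5, 6, 4, 8, 7])
        assert res.rho == pytest.approx(0.6)
        assert res.n_pairs == 5

    def test_anti_monotone_pairs(self):
        x = np.arange(1.0, 11.0)
        assert spearman_log(x, 1.0 / x).rho == pytest.approx(-1.0)

    def test_non_positive_pairs_dropped_and_reported(self):
        res = spearman_log([1, 2, 3, 0, 5], [5, 6, 4, 8, -1])
        assert res.n_pairs == 3
        assert res.n_dropped == 2

    def test_too_few_pairs_rejected(self):
        with pytest.raises(StatsError):
            spearman_log([1, 2, 0], [1, 2, 3])


class TestReferenceShortlist:
    def test_shortlist_loads_39_verified_proteins(self):
        df = load_reference_shortlist()
        assert len(df) == 39
        assert df["accession"].is_unique

    def test_verification_rule_recount(self):
        cl = classify_shortlist(load_reference_shortlist())
        assert int(cl["is_de_discovery"].sum()) == 39
        assert int(cl["is_verified_test"].sum()) == 39
        assert int(cl["is_significant_test"].sum()) == 9


class TestSyntheticRecoveryBound:
    def test_sensitivity_and_fdp_over_twenty_seeds(self):
        """Regression bound under the default study conditions
        (|log2 effect| 1.5, 13 vs 8 discovery samples): pooled
        sensitivity >= 0.7 and pooled false-discovery proportion
        <= 0.15 across 20 seeded replicates."""
        tp = fp = fn = 0
        for seed in range(20):
            records, design, truth = generate_study(SynthConfig(seed=seed))
            result = run_pipeline(records, design, PipelineConfig())
            conf = de_confusion(result.de_records, truth)
            tp += conf["tp"]
            fp += conf["fp"]
            fn += conf["fn"]
        assert tp / (tp + fn) >= 0.7
        assert fp / (tp + fp) <= 0.15
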