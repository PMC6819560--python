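"""Counts, summaries, loads, burden statistics and carrier probabilities."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from mitoburden.annotation import annotate
from mitoburden.classification import classify
from mitoburden.cohort import (
    CATEGORIES,
    SubjectCounts,
    carrier_probability,
    chi_square_statistic,
    group_summary,
    mutational_load,
    rank_tests,
    rare_common_burden_test,
    rare_common_ratio_of_ratios,
    subject_counts,
)
from mitoburden.errors import DegenerateTableError, ValidationError
from mitoburden.variants import (
    PathogenicityTable,
    Variant,
    parse_variant_label,
)


def _classified(labels, reference, freqs):
    return [classify(annotate(parse_variant_label(lab), reference), freqs)
            for lab in labels]


def _mk_counts(subject_id, cells, group="g", jk=False):
    """cells: dict (category, rarity) -> n."""
    matrix = tuple(tuple(cells.get((cat, rar), 0)
                         for rar in ("rare", "common"))
                   for cat in CATEGORIES)
    return SubjectCounts(subject_id, group, None, jk, matrix)


class TestSubjectCounts:
    def test_two_pathogenic_rare_variants(self, reference, freqs):
        classified = _classified(["m.3243A>G", "m.1555A>G"], reference, freqs)
        counts = subject_counts("S1", classified)
        assert counts.cell("tRNA", "rare") == 1
        assert counts.cell("rRNA", "rare") == 1
        assert counts.total == 2

    def test_empty_profile(self, reference, freqs):
        counts = subject_counts("S1", _classified([], reference, freqs))
        assert counts.total == 0

    def test_overlap_variant_counted_once(self, reference, freqs):
        """A nonsynonymous substitution hitting both overlap genes is one
        variant, one cell increment."""
        for pos in range(8528, 8572):
            ref = reference.base_at(pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                ann = annotate(Variant(pos, ref, alt), reference)
                if ann.category == "nonsynonymous" and len(ann.aa_changes) == 2:
                    cv = classify(ann, freqs)
                    counts = subject_counts("S1", [cv])
                    assert counts.total == 1
                    return
        pytest.fail("no double-frame nonsynonymous variant found")

    def test_nonfunctional_not_counted(self, reference, freqs):
        classified = _classified(["m.16519T>C", "m.11719G>A",
                                  "m.523_524delAC"], reference, freqs)
        assert subject_counts("S1", classified).total == 0


class TestGroupSummary:
    def test_hand_checked_mean_sd(self):
        counts = [_mk_counts(f"S{i}", {("tRNA", "rare"): v})
                  for i, v in enumerate([1, 2, 3])]
        (summary,) = group_summary(counts, "group")
        assert summary.means[("tRNA", "rare")] == pytest.approx(2.0)
        assert summary.sds[("tRNA", "rare")] == pytest.approx(1.0)
        assert summary.n == 3

    def test_single_subject_flagged(self):
        (summary,) = group_summary([_mk_counts("S", {})], "group")
        assert "single-subject-sd-undefined" in summary.flags
        assert all(v == 0.0 for v in summary.sds.values())

    def test_totals_row_equals_sum_of_category_means(self):
        rng = np.random.default_rng(3)
        counts = [
            _mk_counts(f"S{i}", {(cat, rar): int(rng.integers(0, 4))
                                 for cat in CATEGORIES
                                 for rar in ("rare", "common")},
                       group="g1" if i % 2 else "g2")
            for i in range(30)]
        for summary in group_summary(counts, "group"):
            for rarity in ("rare", "common"):
                assert summary.totals[rarity] == pytest.approx(
                    sum(summary.means[(cat, rarity)] for cat in CATEGORIES))

    def test_jk_grouping(self):
        counts = [_mk_counts("S1", {}, jk=True), _mk_counts("S2", {})]
        labels = [s.group for s in group_summary(counts, "jk")]
        assert labels == ["J and K", "Other haplogroups"]

    def test_poisson_rate_recovery(self):
        """Planted Poisson rates are recovered within 3 SE."""
        rng = np.random.default_rng(5)
        rate, n = 0.83, 500
        counts = [_mk_counts(f"S{i}",
                             {("nonsynonymous", "rare"): int(x)})
                  for i, x in enumerate(rng.poisson(rate, size=n))]
        (summary,) = group_summary(counts, "group")
        se = math.sqrt(rate / n)
        assert abs(summary.means[("nonsynonymous", "rare")] - rate) < 3 * se


class TestMutationalLoad:
    def test_excluded_variant_contributes_nothing(self, reference, freqs):
        classified = _classified(["m.8860A>G"], reference, freqs)
        load = mutational_load("S", classified, PathogenicityTable({}),
                               load_exclusions=("m.8860A>G",))
        assert load.common_load == 0 and load.rare_load == 0
        assert load.missing == ()

    def test_sum_of_probabilities(self, reference, freqs):
        table = PathogenicityTable({(4216, "T", "C"): 0.3,
                                    (13708, "G", "A"): 0.2})
        classified = _classified(["m.4216T>C", "m.13708G>A"],
                                 reference, freqs)
        load = mutational_load("S", classified, table)
        assert load.common_load == pytest.approx(0.5)  # both MAF >= 1%
        assert load.rare_load == 0

    def test_missing_scores_logged_and_zero(self, reference, freqs):
        classified = _classified(["m.4216T>C"], reference, freqs)
        load = mutational_load("S", classified, PathogenicityTable({}))
        assert load.common_load == 0
        assert load.missing == ("m.4216T>C",)

    def test_nonneutral_mode_keeps_only_above_half(self, reference, freqs):
        table = PathogenicityTable({(4216, "T", "C"): 0.3,
                                    (15257, "G", "A"): 0.55})
        classified = _classified(["m.4216T>C", "m.15257G>A"],
                                 reference, freqs)
        load = mutational_load("S", classified, table, mode="nonneutral")
        assert load.common_load == pytest.approx(0.55)

    def test_additive_over_disjoint_subsets(self, reference, freqs, path_table):
        labels = ["m.4216T>C", "m.13708G>A", "m.9055G>A", "m.3308T>C"]
        classified = _classified(labels, reference, freqs)
        whole = mutational_load("S", classified, path_table)
        part1 = mutational_load("S", classified[:2], path_table)
        part2 = mutational_load("S", classified[2:], path_table)
        assert whole.common_load == pytest.approx(
            part1.common_load + part2.common_load)
        assert whole.rare_load == pytest.approx(
            part1.rare_load + part2.rare_load)


def _groups_from_tables(tables):
    """Build per-group SubjectCounts whose pooled totals equal `tables`."""
    return {f"g{i}": [_mk_counts(f"g{i}S", {("tRNA", "rare"): rare,
                                            ("tRNA", "common"): common})]
            for i, (rare, common) in enumerate(tables)}


class TestBurdenTest:
    def test_homogeneous_table(self):
        res = rare_common_burden_test(_groups_from_tables([(10, 10),
                                                           (10, 10)]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.dof == 1

    def test_statistic_equals_direct_formula_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            rows = rng.integers(0, 21, size=(rng.integers(2, 5), 2))
            if (rows.sum(axis=0) == 0).any() or (rows.sum(axis=1) == 0).any():
                continue
            expected = np.outer(rows.sum(axis=1), rows.sum(axis=0)) / rows.sum()
            direct = ((rows - expected) ** 2 / expected).sum()
            stat, dof = chi_square_statistic(rows)
            assert stat == pytest.approx(direct)
            assert dof == (rows.shape[0] - 1)

    def test_degenerate_marginal(self):
        with pytest.raises(DegenerateTableError):
            rare_common_burden_test(_groups_from_tables([(0, 10), (0, 20)]))

    def test_permutation_mode_agrees_roughly_with_pooled_on_iid_data(self):
        rng = np.random.default_rng(13)
        groups = {
            g: [_mk_counts(f"{g}{i}",
                           {("tRNA", "rare"): int(rng.poisson(1.0)),
                            ("tRNA", "common"): int(rng.poisson(3.0))},
                           group=g)
                for i in range(60)]
            for g in ("a", "b")}
        pooled = rare_common_burden_test(groups, mode="pooled")
        perm = rare_common_burden_test(groups, mode="permutation",
                                       n_permutations=2000, seed=1)
        assert perm.statistic == pytest.approx(pooled.statistic)
        assert abs(perm.p_value - pooled.p_value) < 0.12


class TestRatioOfRatios:
    def test_examples(self):
        assert rare_common_ratio_of_ratios((1, 2), (1, 1)) == pytest.approx(0.5)
        assert rare_common_ratio_of_ratios((5, 7), (5, 7)) == pytest.approx(1.0)

    def test_scale_invariance(self):
        base = rare_common_ratio_of_ratios((3, 11), (7, 13))
        for k in (2, 10, 0.5):
            scaled = rare_common_ratio_of_ratios((3 * k, 11 * k),
                                                 (7 * k, 13 * k))
            assert scaled == pytest.approx(base)

    def test_zero_denominators(self):
        with pytest.raises(ValidationError):
            rare_common_ratio_of_ratios((1, 0), (1, 1))
        with pytest.raises(ValidationError):
            rare_common_ratio_of_ratios((1, 1), (0, 1))

    def test_from_subject_counts(self):
        a = [_mk_counts("S1", {("tRNA", "rare"): 1, ("tRNA", "common"): 2})]
        b = [_mk_counts("S2", {("tRNA", "rare"): 1, ("tRNA", "common"): 1})]
        assert rare_common_ratio_of_ratios(a, b) == pytest.approx(0.5)


class TestCarrierProbability:
    def test_printed_percentages(self):
        assert round(100 * carrier_probability(89, 0.0014, 1)) == 11
        assert round(100 * carrier_probability(89, 0.0033, 1)) == 22

    def test_matches_closed_form(self):
        n, f, k = 89, 0.0033, 1
        closed = math.comb(n, k) * f ** k * (1 - f) ** (n - k)
        assert carrier_probability(n, f, k) == pytest.approx(closed)

    def test_normalisation(self):
        for n, f in [(10, 0.3), (89, 0.0014), (5, 0.0)]:
            total = sum(carrier_probability(n, f, k) for k in range(n + 1))
            assert total == pytest.approx(1.0)
        assert carrier_probability(50, 0.0, 0) == pytest.approx(1.0)

    def test_invalid_parameters(self):
        with pytest.raises(ValidationError):
            carrier_probability(10, 0.5, 11)
        with pytest.raises(ValidationError):
            carrier_probability(10, 1.5, 1)


def _exact_mannwhitney_p(x, y):
    """Oracle: exhaustive permutation distribution of U (no ties)."""
    pooled = list(x) + list(y)
    n_x = len(x)

    def u_stat(xs, ys):
        return sum(1 for xi in xs for yi in ys if xi > yi) \
            + 0.5 * sum(1 for xi in xs for yi in ys if xi == yi)

    observed = u_stat(x, y)
    n_y = len(pooled) - n_x
    mid = n_x * n_y / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_x):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(xs, ys)
        total += 1
        if abs(u - mid) >= abs(observed - mid) - 1e-12:
            count += 1
    return count / total


class TestRankTests:
    def test_identical_groups(self):
        res = rank_tests({"a": [1.0, 1.0], "b": [1.0, 1.0, 1.0]})
        assert res.p_value == 1.0 and "all-values-identical" in res.flags

    def test_complete_separation_u_statistic(self):
        res = rank_tests({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        assert res.test == "mann-whitney"
        assert res.statistic in (0.0, 9.0)  # U of one side is zero

    @pytest.mark.parametrize("x, y", [
        ([1.0, 5.0, 2.0, 8.0], [3.0, 4.0, 9.0, 7.0]),
        ([0.5, 1.5, 2.5], [3.5, 4.5, 0.1, 6.0, 7.0]),
    ])
    def test_small_sample_matches_exhaustive_enumeration(self, x, y):
        res = rank_tests({"a": x, "b": y})
        assert res.p_value == pytest.approx(_exact_mannwhitney_p(x, y))

    def test_three_groups_use_kruskal_wallis(self):
        groups = {"a": [1.0, 2.0], "b": [2.0, 3.0], "c": [9.0, 10.0]}
        res = rank_tests(groups)
        ref = sps.kruskal(*groups.values())
        assert res.test == "kruskal-wallis"
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_validation(self):
        with pytest.raises(ValidationError):
            rank_tests({"a": [1.0]})
        with pytest.raises(ValidationError):
            rank_tests({"a": [1.0], "b": []})
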