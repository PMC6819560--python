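"""Per-subject counts, group summaries, mutational load, burden statistics
and carrier probabilities.

The summary tables mirror the field's reporting layout: a category
(nonsynonymous / tRNA / rRNA) × rarity (rare / common) matrix of
per-subject means ± sample SD with a totals row per rarity, computed per
cohort group or per haplogroup stratum (J/K vs the rest).

The rare-vs-common burden contrast is a Pearson chi-square (no continuity
correction) on the groups × {rare, common} table of pooled variant counts;
a subject-label permutation variant of the same statistic is provided
because pooled counting assumes independent variant draws. Mutational load
is the per-subject sum of pathogenicity probabilities over nonsynonymous
variants (all of them by default, or only the nonneutral ones with
probability > 0.5), minus a fixed exclusion list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .classification import COMMON, RARE, ClassifiedVariant
from .errors import DegenerateTableError, ValidationError
from .variants import PathogenicityTable

logger = logging.getLogger(__name__)

CATEGORIES = ("nonsynonymous", "tRNA", "rRNA")
RARITIES = (RARE, COMMON)


@dataclass(frozen=True)
class SubjectCounts:
    """Functional-variant counts of one subject, category × rarity."""

    subject_id: str
    group: str | None
    haplogroup: str | None
    jk: bool
    counts: tuple[tuple[int, ...], ...]  # rows CATEGORIES, cols RARITIES

    def cell(self, category: str, rarity: str) -> int:
        return self.counts[CATEGORIES.index(category)][RARITIES.index(rarity)]

    def rarity_total(self, rarity: str) -> int:
        j = RARITIES.index(rarity)
        return sum(row[j] for row in self.counts)

    @property
    def total(self) -> int:
        return sum(sum(row) for row in self.counts)


def subject_counts(subject_id: str,
                   classified: Sequence[ClassifiedVariant],
                   group: str | None = None,
                   haplogroup: str | None = None,
                   jk: bool = False) -> SubjectCounts:
    """Count the subject's functional variants into the 3×2 matrix.

    Each functional substitution increments exactly one cell (a variant in
    an overlapping gene pair is still one variant). Classification and
    analysis exclusions must already have been applied.
    """
    matrix = [[0, 0] for _ in CATEGORIES]
    for cv in classified:
        if not cv.functional or cv.rarity not in RARITIES:
            continue
        matrix[CATEGORIES.index(cv.category)][RARITIES.index(cv.rarity)] += 1
    return SubjectCounts(subject_id, group, haplogroup, jk,
                         tuple(tuple(row) for row in matrix))


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SD per category × rarity cell for one group of subjects."""

    group: str
    n: int
    means: dict
    sds: dict
    totals: dict  # rarity -> sum of the three category means
    flags: tuple[str, ...] = ()


def group_summary(all_counts: Sequence[SubjectCounts],
                  grouping: str = "group") -> list[GroupSummary]:
    """Summarise counts per cohort group or per J/K stratum.

    ``grouping="group"`` uses the subject's group label;
    ``grouping="jk"`` splits into "J and K" vs "Other haplogroups".
    Sample SD uses the n−1 denominator; a single-subject group reports
    SD 0 with a flag.
    """
    if grouping == "group":
        def key(c: SubjectCounts) -> str:
            return c.group or "unknown"
    elif grouping == "jk":
        def key(c: SubjectCounts) -> str:
            return "J and K" if c.jk else "Other haplogroups"
    else:
        raise ValidationError(f"unknown grouping {grouping!r}")
    buckets: dict[str, list[SubjectCounts]] = {}
    for c in all_counts:
        buckets.setdefault(key(c), []).append(c)
    summaries = []
    for label in sorted(buckets):
        members = buckets[label]
        if not members:
            raise ValidationError(f"empty group {label!r}")
        means, sds = {}, {}
        flags: list[str] = []
        for cat in CATEGORIES:
            for rar in RARITIES:
                values = np.array([m.cell(cat, rar) for m in members], float)
                means[(cat, rar)] = float(values.mean())
                if len(values) > 1:
                    sds[(cat, rar)] = float(values.std(ddof=1))
                else:
                    sds[(cat, rar)] = 0.0
        if len(members) == 1:
            flags.append("single-subject-sd-undefined")
        totals = {rar: sum(means[(cat, rar)] for cat in CATEGORIES)
                  for rar in RARITIES}
        summaries.append(GroupSummary(label, len(members), means, sds,
                                      totals, tuple(flags)))
    return summaries


@dataclass(frozen=True)
class SubjectLoad:
    subject_id: str
    group: str | None
    jk: bool
    common_load: float
    rare_load: float
    missing: tuple[str, ...] = ()  # nonsynonymous variants without a score


def mutational_load(subject_id: str,
                    classified: Sequence[ClassifiedVariant],
                    path_table: PathogenicityTable,
                    load_exclusions: Sequence[str] = (),
                    mode: str = "all",
                    group: str | None = None,
                    jk: bool = False) -> SubjectLoad:
    """Sum pathogenicity probabilities over nonsynonymous variants.

    ``mode="all"`` sums every nonsynonymous variant's probability;
    ``mode="nonneutral"`` only those with probability > 0.5. Variants on
    the exclusion list contribute nothing; variants absent from the table
    contribute 0 and are recorded in ``missing`` (and logged).
    """
    if mode not in ("all", "nonneutral"):
        raise ValidationError(f"unknown load mode {mode!r}")
    excluded = set(load_exclusions)
    loads = {RARE: 0.0, COMMON: 0.0}
    missing: list[str] = []
    for cv in classified:
        if cv.category != "nonsynonymous" or cv.rarity not in RARITIES:
            continue
        label = cv.variant.label
        if label in excluded:
            continue
        p = path_table.get(cv.variant)
        if p is None:
            missing.append(label)
            logger.debug("no pathogenicity score for %s (subject %s)",
                         label, subject_id)
            continue
        if mode == "nonneutral" and p <= 0.5:
            continue
        loads[cv.rarity] += p
    return SubjectLoad(subject_id, group, jk, loads[COMMON], loads[RARE],
                       tuple(missing))


# ---------------------------------------------------------------------------
# burden statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BurdenTestResult:
    groups: tuple[str, ...]
    table: tuple[tuple[int, int], ...]  # rows per group: (rare, common)
    statistic: float
    dof: int
    p_value: float
    mode: str
    n_permutations: int | None = None


def _pooled_table(groups: Mapping[str, Sequence[SubjectCounts]]
                  ) -> tuple[tuple[str, ...], np.ndarray]:
    labels = tuple(sorted(groups))
    if len(labels) < 2:
        raise ValidationError("burden test needs at least two groups")
    table = np.array(
        [[sum(c.rarity_total(RARE) for c in groups[lb]),
          sum(c.rarity_total(COMMON) for c in groups[lb])] for lb in labels],
        dtype=int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError(
            f"zero marginal in pooled rare/common table {table.tolist()}")
    return labels, table


def chi_square_statistic(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square (no continuity correction) and its dof."""
    statistic, _, dof, _ = sps.chi2_contingency(np.asarray(table),
                                                correction=False)
    return float(statistic), int(dof)


def rare_common_burden_test(groups: Mapping[str, Sequence[SubjectCounts]],
                            mode: str = "pooled",
                            n_permutations: int = 9999,
                            seed: int | None = None) -> BurdenTestResult:
    """Chi-square contrast of pooled rare vs common counts across groups.

    ``mode="pooled"`` refers the Pearson statistic to the chi-square
    distribution with (groups−1) degrees of freedom. ``mode="permutation"``
    keeps the same statistic but draws its null distribution by permuting
    subject group labels (robust to within-subject clustering of variants).
    """
    labels, table = _pooled_table(groups)
    statistic, dof = chi_square_statistic(table)
    if mode == "pooled":
        p_value = float(sps.chi2.sf(statistic, dof))
        n_perm = None
    elif mode == "permutation":
        rng = np.random.default_rng(seed)
        subjects = [c for lb in labels for c in groups[lb]]
        sizes = [len(groups[lb]) for lb in labels]
        pairs = np.array([[c.rarity_total(RARE), c.rarity_total(COMMON)]
                          for c in subjects], dtype=int)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(len(subjects))
            start = 0
            rows = []
            for size in sizes:
                idx = perm[start:start + size]
                rows.append(pairs[idx].sum(axis=0))
                start += size
            perm_table = np.array(rows)
            if (perm_table.sum(axis=1) == 0).any():
                continue
            perm_stat, _ = chi_square_statistic(perm_table)
            if perm_stat >= statistic - 1e-12:
                exceed += 1
        p_value = (1 + exceed) / (1 + n_permutations)
        n_perm = n_permutations
    else:
        raise ValidationError(f"unknown burden test mode {mode!r}")
    return BurdenTestResult(labels, tuple(map(tuple, table.tolist())),
                            statistic, dof, float(p_value), mode, n_perm)


def rare_common_ratio_of_ratios(stratum_a, stratum_b) -> float:
    """(rareA/commonA) / (rareB/commonB) for two strata.

    Each stratum is either a (rare_total, common_total) pair or a sequence
    of :class:`SubjectCounts`.
    """
    def totals(stratum) -> tuple[float, float]:
        if (isinstance(stratum, (tuple, list)) and len(stratum) == 2
                and all(isinstance(x, (int, float)) for x in stratum)):
            return float(stratum[0]), float(stratum[1])
        return (float(sum(c.rarity_total(RARE) for c in stratum)),
                float(sum(c.rarity_total(COMMON) for c in stratum)))

    rare_a, common_a = totals(stratum_a)
    rare_b, common_b = totals(stratum_b)
    if common_a == 0 or common_b == 0 or rare_b == 0:
        raise ValidationError(
            "ratio of rare/common ratios undefined with zero denominators")
    return (rare_a / common_a) / (rare_b / common_b)


def carrier_probability(n: int, freq: float, k: int) -> float:
    """Binomial probability of exactly ``k`` carriers among ``n`` subjects.

    ``freq`` is the population carrier frequency;
    P(K = k) = C(n, k) · freq^k · (1 − freq)^(n−k).
    """
    if n < 0 or not 0 <= k <= n:
        raise ValidationError(f"invalid carrier count k={k} for n={n}")
    if not 0 <= freq <= 1:
        raise ValidationError(f"carrier frequency {freq} outside [0,1]")
    return float(sps.binom.pmf(k, n, freq))


@dataclass(frozen=True)
class RankTestResult:
    test: str
    statistic: float
    p_value: float
    flags: tuple[str, ...] = ()


def rank_tests(groups: Mapping[str, Sequence[float]]) -> RankTestResult:
    """Mann–Whitney (two groups) or Kruskal–Wallis (more) on raw values.

    Two-sided; the Mann–Whitney p-value is exact for small untied samples
    and tie-corrected normal-approximate otherwise. All-identical values
    across every group yield p = 1 with a flag.
    """
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValidationError("rank test needs at least two groups")
    samples = [np.asarray(groups[lb], dtype=float) for lb in labels]
    if any(len(s) == 0 for s in samples):
        raise ValidationError("rank test groups must be non-empty")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        name = "mann-whitney" if len(labels) == 2 else "kruskal-wallis"
        return RankTestResult(name, math.nan, 1.0, ("all-values-identical",))
    if len(labels) == 2:
        res = sps.mannwhitneyu(samples[0], samples[1],
                               alternative="two-sided")
        return RankTestResult("mann-whitney", float(res.statistic),
                              float(res.pvalue))
    res = sps.kruskal(*samples)
    return RankTestResult("kruskal-wallis", float(res.statistic),
                          float(res.pvalue))
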