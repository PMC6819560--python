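"""Synthetic cohort generator.

Emulates the statistical structure the burden analysis assumes: each
subject carries a haplogroup-defining variant backbone drawn from a
frequency vector over the packaged tree, common polymorphisms sampled
per-site from the frequency table's MAF spectrum, Poisson-distributed
private rare variants with group- and category-specific rates, and
pathogenic mutations planted by Bernoulli draws at their stated population
carrier frequencies (defaults m.3243A>G at 0.14%, m.1555A>G at 0.33%).

Default rare rates are the published per-subject means for the three study
groups, so synthetic cohorts are shaped like the study they emulate; all
of it is configuration, not constants. Per-subject random substreams are
derived deterministically from (seed, group, subject index), so changing
one group's size never reshuffles another subject's draws. Private-variant
positions avoid every position named in the frequency table and the
exclusion lists, so exclusion filtering cannot silently change simulated
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import stats as sps

from .annotation import NONSYNONYMOUS, RRNA, TRNA, make_annotator
from .classification import ExclusionConfig
from .cohort import rare_common_burden_test
from .errors import ValidationError
from .haplogroups import HaploTree, load_tree
from .reference import ReferenceGenome, load_reference
from .variants import (
    FrequencyTable,
    SubjectProfile,
    Variant,
    make_profile,
    parse_variant_label,
)
from .workflow import analyze_profiles, counts_by_group, \
    load_demo_frequency_table

PRIVATE_CATEGORIES = (NONSYNONYMOUS, TRNA, RRNA)

DEFAULT_GROUP_SIZES = {"endurance": 52, "sprint": 89, "control": 77}

# Rare-variant Poisson rates per group and category (per-subject means).
DEFAULT_RARE_RATES = {
    "endurance": {NONSYNONYMOUS: 0.83, TRNA: 0.19, RRNA: 0.37},
    "sprint": {NONSYNONYMOUS: 0.63, TRNA: 0.10, RRNA: 0.36},
    "control": {NONSYNONYMOUS: 0.61, TRNA: 0.14, RRNA: 0.19},
}

# Haplogroup frequency vector loosely shaped like a Finnish cohort, with
# roughly 10% of subjects in the J/K stratum.
DEFAULT_HAPLOGROUP_FREQS = {
    "H": 0.47, "U": 0.15, "K": 0.03, "J": 0.04, "J1": 0.02, "J2": 0.01,
    "T": 0.08, "T2": 0.03, "T2c": 0.01, "V": 0.06, "W": 0.04, "I": 0.03,
    "X": 0.02, "N1": 0.01,
}

DEFAULT_PLANTED = (("m.3243A>G", 0.0014, 0.43), ("m.1555A>G", 0.0033, 1.0))


@dataclass(frozen=True)
class SimulationConfig:
    group_sizes: dict = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    haplogroup_freqs: dict = field(
        default_factory=lambda: dict(DEFAULT_HAPLOGROUP_FREQS))
    rare_rates: dict = field(
        default_factory=lambda: {g: dict(r)
                                 for g, r in DEFAULT_RARE_RATES.items()})
    common_maf_threshold: float = 0.01
    planted: tuple = DEFAULT_PLANTED
    seed: int = 0

    def validate(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValidationError("negative group size")
        freq_sum = sum(self.haplogroup_freqs.values())
        if abs(freq_sum - 1.0) > 1e-9:
            raise ValidationError(
                f"haplogroup frequencies sum to {freq_sum}, not 1")
        for group, rates in self.rare_rates.items():
            if any(r < 0 for r in rates.values()):
                raise ValidationError(f"negative rate for group {group}")
        for _, freq, _ in self.planted:
            if not 0 <= freq <= 1:
                raise ValidationError("planted frequency outside [0,1]")


@dataclass(frozen=True)
class SimulatedCohort:
    profiles: tuple[SubjectProfile, ...]
    truth: dict  # subject_id -> provenance of every non-backbone variant
    config: SimulationConfig


class _PositionPools:
    """Candidate positions for private variants, per category.

    Excludes every position referenced by the frequency table, the
    exclusion lists or the reference placeholder, so private draws are
    guaranteed to be rare (absent from the table) and never filtered.
    """

    def __init__(self, reference: ReferenceGenome, freqs: FrequencyTable,
                 exclusions: ExclusionConfig, tree: HaploTree):
        reserved = {pos for (pos, _, _) in
                    (key for key, _ in freqs.items())}
        reserved |= set(exclusions.hotspot_c_insertion_positions)
        for label in exclusions.hotspot_variants + exclusions.load_exclusions:
            v = parse_variant_label(label)
            reserved.update(range(v.position,
                                  v.position + max(len(v.ref), 1)))
        for label, _ in exclusions.analysis_exclusions:
            reserved.add(parse_variant_label(label).position)
        for node_label in tree.labels():
            for lab in tree.path_variants(node_label):
                reserved.add(parse_variant_label(lab).position)
        reserved.add(3107)
        pools: dict[str, list[int]] = {NONSYNONYMOUS: [], TRNA: [], RRNA: []}
        product_to_cat = {"protein": NONSYNONYMOUS, "tRNA": TRNA,
                          "rRNA": RRNA}
        for gene in reference.genes:
            cat = product_to_cat[gene.product]
            pools[cat].extend(p for p in range(gene.start, gene.end + 1)
                              if p not in reserved)
        for cat, positions in pools.items():
            if not positions:
                raise ValidationError(
                    f"no candidate positions for category {cat}")
        self.pools = {cat: np.array(sorted(set(p)), dtype=int)
                      for cat, p in pools.items()}


def _draw_private(category: str, pools: _PositionPools,
                  reference: ReferenceGenome, annotator,
                  rng: np.random.Generator,
                  used_positions: set[int]) -> Variant:
    """Sample one private variant of the requested category.

    tRNA/rRNA substitutions hit their category by construction; protein
    positions are rejection-sampled through the annotator until the call
    is nonsynonymous (synonymous proposals are discarded).
    """
    pool = pools.pools[category]
    for _ in range(1000):
        pos = int(pool[rng.integers(len(pool))])
        if pos in used_positions:
            continue
        ref = reference.base_at(pos)
        if ref == "N":
            continue
        alts = [b for b in "ACGT" if b != ref]
        alt = alts[rng.integers(3)]
        variant = Variant(pos, ref, alt)
        if category == NONSYNONYMOUS:
            if annotator(variant).category != NONSYNONYMOUS:
                continue
        used_positions.add(pos)
        return variant
    raise ValidationError(
        f"could not draw a {category} private variant (pool exhausted?)")


def simulate_cohort(config: SimulationConfig | None = None,
                    reference: ReferenceGenome | None = None,
                    tree: HaploTree | None = None,
                    freqs: FrequencyTable | None = None,
                    exclusions: ExclusionConfig | None = None
                    ) -> SimulatedCohort:
    """Generate one cohort; fully deterministic under ``config.seed``."""
    config = config or SimulationConfig()
    config.validate()
    reference = reference or load_reference()
    tree = tree or load_tree()
    freqs = freqs if freqs is not None else load_demo_frequency_table()
    exclusions = exclusions or ExclusionConfig()
    annotator = make_annotator(reference)
    pools = _PositionPools(reference, freqs, exclusions, tree)

    hap_labels = sorted(config.haplogroup_freqs)
    hap_probs = np.array([config.haplogroup_freqs[h] for h in hap_labels])
    for label in hap_labels:
        if label not in tree:
            raise ValidationError(f"haplogroup {label} not in tree")
    # Panel of common polymorphisms sampled per subject by their MAF.
    # Haplogroup-defining variants are excluded: lineage markers enter a
    # profile only through the drawn backbone, not as independent draws.
    tree_labels = {lab for node in tree.labels()
                   for lab in tree.path_variants(node)}
    common_entries = sorted(
        (key, maf) for key, maf in freqs.items()
        if maf >= config.common_maf_threshold
        and f"m.{key[0]}{key[1]}>{key[2]}" not in tree_labels)
    planted = [(parse_variant_label(label), freq, het)
               for label, freq, het in config.planted]

    profiles: list[SubjectProfile] = []
    truth: dict[str, dict] = {}
    for group_index, group in enumerate(sorted(config.group_sizes)):
        rates = config.rare_rates.get(group)
        if rates is None:
            raise ValidationError(f"no rare rates for group {group!r}")
        for subject_index in range(config.group_sizes[group]):
            rng = np.random.default_rng(np.random.SeedSequence(
                [config.seed, group_index, subject_index]))
            subject_id = f"{group[:3].upper()}{subject_index + 1:04d}"
            haplogroup = hap_labels[rng.choice(len(hap_labels), p=hap_probs)]
            backbone = [parse_variant_label(lab)
                        for lab in sorted(tree.path_variants(haplogroup))]
            used = {v.position for v in backbone}
            variants = list(backbone)
            commons: list[str] = []
            for (pos, ref, alt), maf in common_entries:
                if pos in used:
                    continue
                if rng.random() < maf:
                    variants.append(Variant(pos, ref, alt))
                    used.add(pos)
                    commons.append(f"m.{pos}{ref}>{alt}")
            privates: list[tuple[str, str]] = []
            for category in PRIVATE_CATEGORIES:
                for _ in range(rng.poisson(rates.get(category, 0.0))):
                    v = _draw_private(category, pools, reference, annotator,
                                      rng, used)
                    variants.append(v)
                    privates.append((v.label, category))
            planted_here: list[str] = []
            for variant, freq, het in planted:
                if variant.position in used:
                    continue
                if rng.random() < freq:
                    v = replace(variant, heteroplasmy=het,
                                het_flag=het < 1.0)
                    variants.append(v)
                    used.add(v.position)
                    planted_here.append(v.label)
            profiles.append(make_profile(subject_id, variants, group=group,
                                         haplogroup=haplogroup))
            truth[subject_id] = {
                "group": group,
                "haplogroup": haplogroup,
                "backbone": [v.label for v in backbone],
                "common": commons,
                "private": privates,
                "planted": planted_here,
                "rates": dict(rates),
            }
    return SimulatedCohort(tuple(profiles), truth, config)


def recovery_experiment(config: SimulationConfig | None = None,
                        replicates: int = 1000,
                        alpha: float = 0.05,
                        rate_multipliers: Mapping[str, float] | None = None,
                        mode: str = "pooled",
                        reference: ReferenceGenome | None = None,
                        tree: HaploTree | None = None,
                        freqs: FrequencyTable | None = None) -> dict:
    """Estimate the burden test's rejection rate over simulated cohorts.

    With no ``rate_multipliers`` (equal group rates are still whatever the
    config says) this measures type-I error when the config's rates are
    equal, or power otherwise. ``rate_multipliers`` scales the named
    groups' rare rates. Returns the rejection fraction with a 95% binomial
    confidence interval.
    """
    if replicates < 100:
        raise ValidationError("recovery experiments need >= 100 replicates")
    config = config or SimulationConfig()
    if rate_multipliers:
        rates = {g: {c: r * rate_multipliers.get(g, 1.0)
                     for c, r in group_rates.items()}
                 for g, group_rates in config.rare_rates.items()}
        config = replace(config, rare_rates=rates)
    reference = reference or load_reference()
    tree = tree or load_tree()
    freqs = freqs if freqs is not None else load_demo_frequency_table()
    annotator = make_annotator(reference)
    rejections = 0
    for rep in range(replicates):
        rep_config = replace(config,
                             seed=int((config.seed * 1_000_003 + rep)
                                      % 2**31))
        cohort = simulate_cohort(rep_config, reference, tree, freqs)
        analyses = analyze_profiles(cohort.profiles, reference, tree, freqs,
                                    annotator=annotator)
        result = rare_common_burden_test(counts_by_group(analyses),
                                         mode=mode, seed=rep_config.seed)
        if result.p_value < alpha:
            rejections += 1
    ci = sps.binomtest(rejections, replicates).proportion_ci(0.95)
    return {
        "replicates": replicates,
        "alpha": alpha,
        "rejections": rejections,
        "rejection_rate": rejections / replicates,
        "ci_low": float(ci.low),
        "ci_high": float(ci.high),
        "mode": mode,
    }
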