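"""Synthetic cohort generator: determinism, truth records, round trips."""

import math

import pytest

from mitoburden.annotation import NONSYNONYMOUS, RRNA, TRNA
from mitoburden.errors import ValidationError
from mitoburden.haplogroups import assign_haplogroup
from mitoburden.simulate import (
    SimulationConfig,
    recovery_experiment,
    simulate_cohort,
)
from mitoburden.variants import make_profile


def _zero_rate_config(**kwargs):
    rates = {g: {NONSYNONYMOUS: 0.0, TRNA: 0.0, RRNA: 0.0}
             for g in ("endurance", "sprint", "control")}
    return SimulationConfig(rare_rates=rates, planted=(), **kwargs)


@pytest.fixture(scope="module")
def default_cohort():
    return simulate_cohort(SimulationConfig(seed=42))


def test_group_sizes(default_cohort):
    groups = {}
    for p in default_cohort.profiles:
        groups[p.group] = groups.get(p.group, 0) + 1
    assert groups == {"endurance": 52, "sprint": 89, "control": 77}


def test_same_seed_same_cohort():
    a = simulate_cohort(SimulationConfig(seed=7))
    b = simulate_cohort(SimulationConfig(seed=7))
    assert a.profiles == b.profiles and a.truth == b.truth
    c = simulate_cohort(SimulationConfig(seed=8))
    assert c.profiles != a.profiles


def test_group_size_change_does_not_reshuffle_other_subjects():
    base = simulate_cohort(SimulationConfig(seed=3))
    bigger = simulate_cohort(SimulationConfig(
        seed=3, group_sizes={"endurance": 52, "sprint": 120, "control": 77}))
    base_by_id = {p.subject_id: p for p in base.profiles}
    for p in bigger.profiles:
        if p.subject_id in base_by_id:
            assert p == base_by_id[p.subject_id]


def test_truth_explains_every_non_backbone_variant(default_cohort, tree):
    for profile in default_cohort.profiles:
        record = default_cohort.truth[profile.subject_id]
        explained = (set(record["backbone"]) | set(record["common"])
                     | {lab for lab, _ in record["private"]}
                     | set(record["planted"]))
        assert {v.label for v in profile.variants} == explained
        assert set(record["backbone"]) == tree.path_variants(
            record["haplogroup"])


def test_zero_rates_give_pure_backbones(tree):
    cohort = simulate_cohort(_zero_rate_config(seed=5))
    for profile in cohort.profiles:
        record = cohort.truth[profile.subject_id]
        backbone = tree.path_variants(record["haplogroup"])
        non_common = {v.label for v in profile.variants} - set(record["common"])
        assert non_common == backbone
        assert record["private"] == [] and record["planted"] == []


def test_generator_annotator_category_round_trip(default_cohort, annotator):
    """Every private variant's intended category is recovered on
    re-annotation."""
    by_label = {}
    for record in default_cohort.truth.values():
        by_label.update(dict(record["private"]))
    assert by_label  # the default rates produce private variants
    for profile in default_cohort.profiles:
        for v in profile.variants:
            if v.label in by_label:
                assert annotator(v).category == by_label[v.label], v.label


def test_haplogroup_round_trip_on_simulated_profiles(default_cohort, tree):
    """Profiles recover their drawn haplogroup: private/panel variants are
    off-tree by construction, so the backbone decides the call."""
    for profile in default_cohort.profiles:
        call = assign_haplogroup(
            make_profile(profile.subject_id, profile.variants), tree)
        assert call.label == default_cohort.truth[
            profile.subject_id]["haplogroup"]


def test_rare_rate_recovered_within_three_se():
    """Endurance rare nonsynonymous Poisson rate 0.83 at n=52."""
    rate, total, n = 0.83, 0.0, 0
    for seed in (11, 12, 13, 14):  # 4 cohorts -> n = 208
        cohort = simulate_cohort(SimulationConfig(seed=seed))
        for record in cohort.truth.values():
            if record["group"] != "endurance":
                continue
            total += sum(1 for _, cat in record["private"]
                         if cat == NONSYNONYMOUS)
            n += 1
    se = math.sqrt(rate / n)
    assert abs(total / n - rate) < 3 * se


def test_planted_carrier_frequency_matches_binomial():
    """Monte-Carlo carrier counts vs the closed-form binomial pmf."""
    config = _zero_rate_config()
    config = SimulationConfig(
        group_sizes={"sprint": 89},
        rare_rates={"sprint": {NONSYNONYMOUS: 0.0, TRNA: 0.0, RRNA: 0.0}},
        planted=(("m.3243A>G", 0.0014, 0.43),))
    replicates, exactly_one = 400, 0
    for rep in range(replicates):
        cohort = simulate_cohort(SimulationConfig(
            group_sizes=config.group_sizes, rare_rates=config.rare_rates,
            planted=config.planted, seed=20_000 + rep))
        carriers = sum(1 for record in cohort.truth.values()
                       if record["planted"])
        exactly_one += carriers == 1
    p = 0.1102  # binomial pmf at k=1, n=89, f=0.0014
    se = math.sqrt(p * (1 - p) / replicates)
    assert abs(exactly_one / replicates - p) < 3.5 * se


def test_planted_heteroplasmy_recorded(default_cohort):
    for profile in default_cohort.profiles:
        for v in profile.variants:
            if v.label in default_cohort.truth[
                    profile.subject_id]["planted"]:
                if v.position == 3243:
                    assert v.heteroplasmy == pytest.approx(0.43)
                    assert v.het_flag
                if v.position == 1555:
                    assert v.heteroplasmy == pytest.approx(1.0)


def test_config_validation():
    with pytest.raises(ValidationError):
        SimulationConfig(haplogroup_freqs={"H": 0.5}).validate()
    with pytest.raises(ValidationError):
        SimulationConfig(group_sizes={"endurance": -1}).validate()
    with pytest.raises(ValidationError):
        recovery_experiment(replicates=10)


def test_recovery_experiment_reports_interval():
    config = SimulationConfig(
        seed=99,
        group_sizes={"endurance": 20, "control": 20},
        rare_rates={g: {NONSYNONYMOUS: 0.6, TRNA: 0.15, RRNA: 0.3}
                    for g in ("endurance", "control")})
    result = recovery_experiment(config, replicates=100)
    assert 0 <= result["ci_low"] <= result["rejection_rate"] \
        <= result["ci_high"] <= 1
    assert result["replicates"] == 100
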