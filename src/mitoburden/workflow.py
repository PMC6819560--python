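"""Shared per-subject analysis chain used by the pipeline, the simulator's
recovery experiments and the acceptance harness.

Order of operations per subject: hotspot exclusions → haplogroup
(metadata overrides the computed call) → back-mutation analysis
exclusions → annotation → classification → category × rarity counts.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Callable, Sequence

from .annotation import AnnotatedVariant, make_annotator
from .classification import (
    DEFAULT_RARE_MAF_THRESHOLD,
    ClassifiedVariant,
    ExclusionConfig,
    apply_analysis_exclusions,
    apply_hotspot_exclusions,
    classify,
)
from .cohort import SubjectCounts, subject_counts
from .haplogroups import HaploCall, HaploTree, effective_haplogroup, \
    in_jk_stratum, load_tree
from .reference import ReferenceGenome, load_reference
from .variants import (
    FrequencyTable,
    PathogenicityTable,
    SubjectProfile,
    read_frequency_table,
    read_pathogenicity_table,
)


def demo_frequency_table_path() -> str:
    return str(importlib.resources.files("mitoburden.data")
               .joinpath("demo_frequencies.tsv"))


def demo_pathogenicity_table_path() -> str:
    return str(importlib.resources.files("mitoburden.data")
               .joinpath("demo_pathogenicity.tsv"))


def load_demo_frequency_table() -> FrequencyTable:
    return read_frequency_table(demo_frequency_table_path())


def load_demo_pathogenicity_table() -> PathogenicityTable:
    return read_pathogenicity_table(demo_pathogenicity_table_path())


@dataclass(frozen=True)
class SubjectAnalysis:
    profile: SubjectProfile
    haplogroup: str
    call: HaploCall
    jk: bool
    annotated: tuple[AnnotatedVariant, ...]   # after analysis exclusions
    classified: tuple[ClassifiedVariant, ...]
    counts: SubjectCounts


def analyze_profiles(profiles: Sequence[SubjectProfile],
                     reference: ReferenceGenome | None = None,
                     tree: HaploTree | None = None,
                     freqs: FrequencyTable | None = None,
                     exclusions: ExclusionConfig | None = None,
                     threshold: float = DEFAULT_RARE_MAF_THRESHOLD,
                     missing_policy: str = "zero",
                     annotator: Callable | None = None
                     ) -> list[SubjectAnalysis]:
    """Run the per-subject chain for a whole cohort."""
    reference = reference or load_reference()
    tree = tree or load_tree()
    freqs = freqs if freqs is not None else load_demo_frequency_table()
    exclusions = exclusions or ExclusionConfig()
    annotator = annotator or make_annotator(reference)
    results = []
    for profile in profiles:
        for_tree = apply_hotspot_exclusions(profile.sorted_variants(),
                                            exclusions)
        haplogroup, call = effective_haplogroup(
            SubjectProfile(profile.subject_id, profile.group,
                           profile.haplogroup, frozenset(for_tree)), tree)
        kept = apply_analysis_exclusions(profile.sorted_variants(),
                                         exclusions, haplogroup, tree)
        annotated = tuple(annotator(v) for v in kept)
        classified = tuple(classify(a, freqs, threshold, missing_policy)
                           for a in annotated)
        jk = in_jk_stratum(haplogroup, tree)
        counts = subject_counts(profile.subject_id, classified,
                                group=profile.group, haplogroup=haplogroup,
                                jk=jk)
        results.append(SubjectAnalysis(profile, haplogroup, call, jk,
                                       annotated, classified, counts))
    return results


def counts_by_group(analyses: Sequence[SubjectAnalysis]
                    ) -> dict[str, list[SubjectCounts]]:
    out: dict[str, list[SubjectCounts]] = {}
    for a in analyses:
        out.setdefault(a.profile.group or "unknown", []).append(a.counts)
    return out
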