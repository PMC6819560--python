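"""Functional / rarity classification and the study's exclusion lists.

Rarity follows the MAF < 1% convention: a functional variant is *rare*
when its minor allele frequency in the reference frequency source is below
the threshold and *common* when MAF ≥ threshold (boundary inclusive on the
common side). Variants absent from the frequency table are treated as
MAF 0, hence rare — a variant unseen in the frequency source is by
construction below any threshold; set ``missing_policy="unclassified"``
for sensitivity analyses.

Three exclusion lists are applied at different stages:

* mutational hotspots (m.523_524delAC, m.16182A>C, m.16183A>C, m.16519T>C
  and C-insertions at 309/315/16193) are removed before tree building /
  haplogroup assignment;
* four back-mutation-prone variants (m.9966G>A and m.2702G>A in subclade
  N1, m.6261G>A in subclade T2c, m.10398A>G in haplogroup J) are removed
  from all counting — by default only in carriers of the named clade, or
  unconditionally in ``strict`` mode;
* five variants connecting L3 and the rCRS node in the phylogeny
  (given here rCRS-relative: m.10398A>G, m.8701A>G, m.14766C>T,
  m.15326A>G, m.8860A>G) are excluded from mutational load only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotation import AnnotatedVariant, INDEL, NONSYNONYMOUS, RRNA, TRNA
from .errors import ValidationError
from .haplogroups import HaploTree, in_clade
from .variants import INSERTION, FrequencyTable, Variant

RARE = "rare"
COMMON = "common"
UNCLASSIFIED = "unclassified"

FUNCTIONAL_CATEGORIES = frozenset({NONSYNONYMOUS, TRNA, RRNA})

DEFAULT_RARE_MAF_THRESHOLD = 0.01


@dataclass(frozen=True)
class ClassifiedVariant:
    annotated: AnnotatedVariant
    functional: bool
    rarity: str
    maf: float | None

    @property
    def variant(self) -> Variant:
        return self.annotated.variant

    @property
    def category(self) -> str:
        return self.annotated.category


@dataclass(frozen=True)
class ExclusionConfig:
    """The three exclusion lists, overridable via config files."""

    hotspot_variants: tuple[str, ...] = (
        "m.523_524delAC", "m.16182A>C", "m.16183A>C", "m.16519T>C")
    hotspot_c_insertion_positions: tuple[int, ...] = (309, 315, 16193)
    # (variant label, clade context or None for unconditional)
    analysis_exclusions: tuple[tuple[str, str | None], ...] = (
        ("m.9966G>A", "N1"), ("m.2702G>A", "N1"),
        ("m.6261G>A", "T2c"), ("m.10398A>G", "J"))
    load_exclusions: tuple[str, ...] = (
        "m.10398A>G", "m.8701A>G", "m.14766C>T", "m.15326A>G", "m.8860A>G")
    strict: bool = False  # apply clade-conditional exclusions unconditionally

    @classmethod
    def from_json(cls, path: str) -> "ExclusionConfig":
        with open(path) as handle:
            raw = json.load(handle)
        kwargs = {}
        for name in ("hotspot_variants", "load_exclusions"):
            if name in raw:
                kwargs[name] = tuple(raw[name])
        if "hotspot_c_insertion_positions" in raw:
            kwargs["hotspot_c_insertion_positions"] = tuple(
                int(p) for p in raw["hotspot_c_insertion_positions"])
        if "analysis_exclusions" in raw:
            kwargs["analysis_exclusions"] = tuple(
                (entry[0], entry[1]) for entry in raw["analysis_exclusions"])
        if "strict" in raw:
            kwargs["strict"] = bool(raw["strict"])
        return cls(**kwargs)


def classify(annotated: AnnotatedVariant, freqs: FrequencyTable,
             threshold: float = DEFAULT_RARE_MAF_THRESHOLD,
             missing_policy: str = "zero") -> ClassifiedVariant:
    """Attach the functional flag and MAF-based rarity to a variant."""
    if not 0 < threshold < 1:
        raise ValidationError(f"threshold {threshold} outside (0,1)")
    if annotated.category == INDEL:
        return ClassifiedVariant(annotated, False, UNCLASSIFIED,
                                 freqs.get(annotated.variant))
    functional = annotated.category in FUNCTIONAL_CATEGORIES
    maf = freqs.get(annotated.variant)
    if maf is None:
        if missing_policy == "zero":
            maf = 0.0
        elif missing_policy != "unclassified":
            raise ValidationError(
                f"unknown missing_policy {missing_policy!r}")
    if maf is None:
        rarity = UNCLASSIFIED
    else:
        rarity = RARE if maf < threshold else COMMON
    return ClassifiedVariant(annotated, functional, rarity, maf)


def is_hotspot(variant: Variant, config: ExclusionConfig) -> bool:
    if variant.label in config.hotspot_variants:
        return True
    return (variant.kind == INSERTION
            and variant.position in config.hotspot_c_insertion_positions
            and set(variant.alt) == {"C"})


def apply_hotspot_exclusions(variants: Iterable[Variant],
                             config: ExclusionConfig | None = None
                             ) -> list[Variant]:
    """Drop mutational hotspots (applied before haplogroup assignment)."""
    config = config or ExclusionConfig()
    return [v for v in variants if not is_hotspot(v, config)]


def apply_analysis_exclusions(variants: Iterable[Variant],
                              config: ExclusionConfig | None = None,
                              haplogroup: str | None = None,
                              tree: HaploTree | None = None
                              ) -> list[Variant]:
    """Drop back-mutation-prone variants from all counting.

    Clade-conditional entries are removed only when the subject's
    haplogroup equals or descends from the named clade (or always, in
    strict mode).
    """
    config = config or ExclusionConfig()
    removed = set()
    for label, clade in config.analysis_exclusions:
        if clade is None or config.strict:
            removed.add(label)
        elif haplogroup is not None and in_clade(haplogroup, clade, tree):
            removed.add(label)
    return [v for v in variants if v.label not in removed]


def classify_all(annotated: Sequence[AnnotatedVariant],
                 freqs: FrequencyTable,
                 threshold: float = DEFAULT_RARE_MAF_THRESHOLD,
                 missing_policy: str = "zero") -> list[ClassifiedVariant]:
    return [classify(a, freqs, threshold, missing_policy) for a in annotated]
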