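"""Gene-context annotation of mtDNA variants.

Functional categories follow the study definition: a *functional* variant
is a single-nucleotide variant in a tRNA or rRNA gene, or a protein-coding
substitution that changes the encoded amino acid. Substitutions inside the
overlapping reading frames (ATP8/ATP6, ND4L/ND4) are called nonsynonymous
if they change the amino acid in ANY overlapping frame; every per-gene
consequence is retained in ``aa_changes``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .errors import FormatError
from .reference import COMPLEMENT, ReferenceGenome, load_reference, translate
from .variants import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    IUPAC2,
    Variant,
)

NONSYNONYMOUS = "nonsynonymous"
SYNONYMOUS = "synonymous"
TRNA = "tRNA"
RRNA = "rRNA"
NONCODING = "noncoding"
INDEL = "indel"

#: Category precedence when a variant hits multiple features.
CATEGORY_PRECEDENCE = (NONSYNONYMOUS, TRNA, RRNA, SYNONYMOUS, NONCODING)


@dataclass(frozen=True)
class AaChange:
    gene: str
    ref_aa: str
    codon_index: int
    alt_aa: str

    def __str__(self) -> str:
        return f"{self.gene}:{self.ref_aa}{self.codon_index}{self.alt_aa}"


@dataclass(frozen=True)
class AnnotatedVariant:
    variant: Variant
    features: tuple  # GeneFeature hits, genome order
    category: str
    aa_changes: tuple[AaChange, ...] = ()

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)


def annotate(variant: Variant,
             reference: ReferenceGenome | None = None) -> AnnotatedVariant:
    """Assign gene context and functional category to one variant.

    Annotation is pure: the result depends only on (position, ref, alt,
    kind) and the reference. Heteroplasmy does not affect the category.
    """
    reference = reference or load_reference()
    features = tuple(reference.genes_at(variant.position))
    if variant.kind != SUBSTITUTION:
        return AnnotatedVariant(variant, features, INDEL)
    aa_changes = []
    has_protein_hit = False
    for gene in features:
        if gene.product != "protein":
            continue
        has_protein_hit = True
        ctx = reference.codon_context(variant.position, gene)
        alt_base = (variant.alt if gene.strand == "heavy"
                    else COMPLEMENT[variant.alt])
        alt_codon = (ctx.ref_codon[:ctx.offset - 1] + alt_base
                     + ctx.ref_codon[ctx.offset:])
        alt_aa = translate(alt_codon)
        if alt_aa != ctx.ref_aa:
            aa_changes.append(AaChange(gene.name, ctx.ref_aa,
                                       ctx.codon_index, alt_aa))
    if aa_changes:
        category = NONSYNONYMOUS
    elif any(g.product == "tRNA" for g in features):
        category = TRNA
    elif any(g.product == "rRNA" for g in features):
        category = RRNA
    elif has_protein_hit:
        category = SYNONYMOUS
    else:
        category = NONCODING
    return AnnotatedVariant(variant, features, category, tuple(aa_changes))


def make_annotator(reference: ReferenceGenome | None = None):
    """Return a memoised ``annotate`` bound to one reference.

    Annotation is pure, so results for recurring (position, ref, alt)
    triples are cached; used heavily by the simulation/benchmark loops.
    """
    reference = reference or load_reference()

    @lru_cache(maxsize=200_000)
    def _cached(position: int, ref: str, alt: str, kind: str,
                ins_offset: int) -> AnnotatedVariant:
        return annotate(Variant(position, ref, alt, kind,
                                ins_offset=ins_offset), reference)

    def annotator(variant: Variant) -> AnnotatedVariant:
        ann = _cached(variant.position, variant.ref, variant.alt,
                      variant.kind, variant.ins_offset)
        if ann.variant is not variant:
            ann = AnnotatedVariant(variant, ann.features, ann.category,
                                   ann.aa_changes)
        return ann

    return annotator


def call_substitutions(sample_seq: str,
                       reference: ReferenceGenome | None = None,
                       align_if_needed: bool = False,
                       length_tolerance: int = 50) -> list[Variant]:
    """Call variants from a full-length mtDNA sample sequence.

    The sample must be pre-aligned to the reference (equal length, ``-``
    allowed for deletions). With ``align_if_needed`` a global pairwise
    alignment (affine gaps) is performed for samples whose length differs
    by at most ``length_tolerance`` — a convenience path; pre-aligned
    input is the reference path.

    Per mismatching column: ACGT mismatches give substitutions; IUPAC
    two-base codes give heteroplasmy-flagged substitutions for each
    non-reference base they encode; ``N`` columns (including the rCRS
    placeholder at 3107) give nothing; gap columns give deletions.
    """
    reference = reference or load_reference()
    sample = sample_seq.upper().replace("U", "T")
    if len(sample) != len(reference):
        if not align_if_needed:
            raise FormatError(
                f"sample length {len(sample)} != {len(reference)}; "
                "enable alignment or pre-align the input")
        if abs(len(sample) - len(reference)) > length_tolerance:
            raise FormatError(
                f"sample length {len(sample)} beyond tolerance "
                f"{length_tolerance}")
        sample = _align_to_reference(sample, reference.sequence)
    variants: list[Variant] = []
    for i, (ref_base, sample_base) in enumerate(
            zip(reference.sequence, sample)):
        position = i + 1
        if ref_base == "N" or sample_base == "N":
            continue
        if sample_base == ref_base:
            continue
        if sample_base == "-":
            variants.append(Variant(position, ref_base, "", DELETION))
        elif sample_base in "ACGT":
            variants.append(Variant(position, ref_base, sample_base))
        elif sample_base in IUPAC2:
            for alt in IUPAC2[sample_base]:
                if alt != ref_base:
                    variants.append(Variant(position, ref_base, alt,
                                            het_flag=True))
        else:
            raise FormatError(
                f"unsupported base {sample_base!r} at position {position}")
    return _merge_deletion_runs(variants)


def _merge_deletion_runs(variants: list[Variant]) -> list[Variant]:
    """Collapse adjacent single-base deletions into one run."""
    merged: list[Variant] = []
    for v in variants:
        if (merged and v.kind == DELETION and merged[-1].kind == DELETION
                and merged[-1].position + len(merged[-1].ref) == v.position):
            prev = merged.pop()
            merged.append(Variant(prev.position, prev.ref + v.ref, "",
                                  DELETION))
        else:
            merged.append(v)
    return merged


def _align_to_reference(sample: str, reference_seq: str) -> str:
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    alignment = aligner.align(reference_seq, sample)[0]
    ref_aln = str(alignment[0])
    sample_aln = str(alignment[1])
    # project the sample onto reference coordinates; sample bases inserted
    # relative to the reference are dropped (insertions are not called on
    # this convenience path)
    out = []
    for r, s in zip(ref_aln, sample_aln):
        if r != "-":
            out.append(s)
    return "".join(out)
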