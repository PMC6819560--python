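"""Deterministic *synthetic* stand-in for the rCRS reference genome.

This module builds a 16,569 bp genome that is NOT the real revised
Cambridge Reference Sequence: outside a set of pinned anchor positions the
sequence is pseudo-random. It is a synthetic reference object constructed so
that every position-level fact the pipeline's rules depend on holds exactly
as on the real rCRS:

* gene intervals follow the NC_012920 annotation (see ``data/gene_map.tsv``),
* position 3107 carries the historical placeholder ``N``,
* every protein gene is a valid open reading frame under the vertebrate
  mitochondrial code — start codon (``ATA`` for MT-ND1, ``ATG`` elsewhere),
  no internal stops in any frame that is actually coding (including both
  frames of the ATP8/ATP6 and ND4L/ND4 overlaps), and a stop codon that is
  either complete or completed by ``A``-padding exactly as on real mtDNA
  transcripts,
* reference alleles at the well-known positions used by the exclusion
  lists, the haplogroup tree and the demonstration lookup tables (m.3243A,
  m.1555A, m.4216T, m.13708G, m.16519T, ...) match the real rCRS,
* pinned codons reproduce the documented coding consequences
  (e.g. m.3243A>G is a tRNA variant, m.4216T>C and m.13708G>A are
  nonsynonymous, m.11467A>G is synonymous, MT-ND6 variants are evaluated on
  the reverse-complemented coding strand).

Analyses of real data must supply the real rCRS via
``load_reference(fasta_path=...)``; the synthetic genome exists so the
pipeline, its tests and its simulations are fully self-contained.
"""

from __future__ import annotations

import numpy as np

from .reference import (
    MT_LENGTH,
    PLACEHOLDER_POS,
    STOP_CODONS,
    GeneFeature,
    ReferenceGenome,
    load_gene_map,
    reverse_complement,
    translate,
)

_BUILD_SEED = 16_569  # fixed: the synthetic genome is versioned data
_BASES = np.array(list("ACGT"))
_NONSTOP = [c for c in sorted(
    a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
    if c not in STOP_CODONS]

# Reference alleles pinned outside protein genes (control region, rRNA,
# tRNA). Values match the real rCRS at each position.
PINNED_BASES = {
    73: "A", 204: "T", 295: "C", 309: "C", 315: "C", 462: "C", 489: "T",
    523: "A", 524: "C",
    709: "G", 980: "T", 1243: "T", 1555: "A",            # MT-RNR1
    2220: "A", 2702: "G", 2831: "G", 3010: "G",          # MT-RNR2
    3243: "A",                                           # MT-TL1
    5600: "T",                                           # MT-TA
    7476: "C",                                           # MT-TS1
    10034: "T",                                          # MT-TG
    10463: "T",                                          # MT-TR
    12280: "A", 12308: "A",                              # MT-TL2
    15904: "C",                                          # MT-TT
    16067: "C", 16069: "C", 16126: "T", 16129: "G", 16182: "A",
    16183: "A", 16189: "T", 16193: "C", 16311: "T", 16519: "T",
}

# Pinned codons: (gene, 1-based codon index) -> coding-strand codon.
# Chosen so substitutions at anchor positions reproduce their documented
# synonymous/nonsynonymous consequences.
PINNED_CODONS = {
    "MT-ND1": {1: "ATA", 30: "TAC", 58: "GGA", 304: "TAC"},
    "MT-ND2": {1: "ATG", 37: "CCG", 150: "AAC", 284: "AAC"},
    "MT-CO1": {1: "ATG", 106: "GCT", 120: "GCC", 375: "ATC", 514: "TAA"},
    "MT-CO2": {1: "ATG", 228: "TAA"},
    "MT-ATP8": {1: "ATG"},
    "MT-ATP6": {1: "ATG", 20: "GCC", 59: "ACC", 112: "ACC", 177: "GCT",
                226: "TAA"},
    "MT-CO3": {1: "ATG", 206: "CGC", 254: "GTC"},
    "MT-ND3": {1: "ATG", 60: "ATT", 114: "ACC"},
    "MT-ND4L": {1: "ATG"},
    "MT-ND4": {1: "ATG", 180: "ACT", 236: "CTA", 320: "GCG", 351: "CCA"},
    "MT-ND5": {1: "ATG", 12: "CTG", 92: "GTA", 202: "GCA", 344: "GGG",
               458: "GCC", 531: "AGC", 604: "TAA"},
    "MT-ND6": {1: "ATG", 68: "CCA", 147: "GGT", 175: "TAA"},
    "MT-CYB": {1: "ATG", 7: "ACA", 18: "TTC", 171: "GAC", 194: "ACC",
               236: "CTC"},
}

# Post-build sanity anchors (position -> expected reference base), covering
# the documented anchor variants, the exclusion lists, the packaged haplogroup
# tree and the demo lookup tables.
EXPECTED_REF = dict(PINNED_BASES)
EXPECTED_REF.update({
    3107: "N",
    3308: "T", 3394: "T", 3480: "A", 4216: "T", 4580: "G", 4917: "A",
    5319: "A", 6221: "T", 6261: "G", 7028: "C", 8584: "G", 8701: "A",
    8860: "A", 9055: "G", 9822: "C", 9966: "G", 10238: "T", 10398: "A",
    11299: "T", 11467: "A", 11719: "G", 11812: "A", 12372: "G", 12612: "A",
    12940: "G", 13368: "G", 13708: "G", 13928: "G", 14233: "A", 14470: "T",
    14766: "C", 14798: "T", 15257: "G", 15326: "A", 15452: "C",
})


def _random_nonstop(rng: np.random.Generator, n: int) -> list[str]:
    return [_NONSTOP[i] for i in rng.integers(0, len(_NONSTOP), size=n)]


def _gene_codons(gene: GeneFeature, rng: np.random.Generator) -> list[str]:
    """Full codons of a gene (remainder bases handled by the caller)."""
    n_full = gene.length // 3
    codons = _random_nonstop(rng, n_full)
    for idx, codon in PINNED_CODONS.get(gene.name, {}).items():
        if idx <= n_full:
            codons[idx - 1] = codon
    return codons


def _partial_tail(gene: GeneFeature) -> str:
    """Bases of an incomplete terminal codon; A-completion yields TAA."""
    r = gene.length % 3
    return {0: "", 1: "T", 2: "TA"}[r]


def _write(seq: list[str], start: int, text: str) -> None:
    seq[start - 1:start - 1 + len(text)] = list(text)


def _build_atp6_region(rng: np.random.Generator) -> str:
    """ATP6 codons 1..16 jointly satisfying the overlapping ATP8 frame.

    ATP8's last fifteen codons read the ATP6 region shifted by one base;
    codons 55..68 of ATP8 must be non-stop and codon 69 must be a stop.
    """
    while True:
        codons = ["ATG"] + _random_nonstop(rng, 13)
        codons.append(rng.choice(list("ACGT")) + "TA")       # codon 15: _TA
        tail = _random_nonstop(rng, 1)[0]
        codons.append("A" + tail[1:])                        # codon 16: A__
        if codons[15] in STOP_CODONS:
            continue
        region = "".join(codons)[:46]  # genome 8527..8572
        frame_b = [region[1 + 3 * k:4 + 3 * k] for k in range(15)]
        if frame_b[-1] not in STOP_CODONS:
            continue  # should not happen: bases 44..46 are T,A,A
        if any(c in STOP_CODONS for c in frame_b[:-1]):
            continue
        return "".join(codons)


def _build_nd4_head(rng: np.random.Generator) -> list[str]:
    """First three ND4 codons; ND4L's overlapping stop codon reads TAA."""
    while True:
        c2 = rng.choice(list("ACGT")) + "TA"
        c3 = "A" + _random_nonstop(rng, 1)[0][1:]
        if c2 in STOP_CODONS or c3 in STOP_CODONS:
            continue
        return ["ATG", c2, c3]


def build_synthetic_reference() -> ReferenceGenome:
    """Assemble the synthetic reference genome (deterministic)."""
    rng = np.random.default_rng(_BUILD_SEED)
    genes = load_gene_map()
    by_name = {g.name: g for g in genes}

    seq = list(rng.choice(_BASES, size=MT_LENGTH))
    for pos, base in PINNED_BASES.items():
        seq[pos - 1] = base

    # Heavy-strand proteins without overlap complications.
    for name in ("MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-CO3",
                 "MT-ND3", "MT-ND5", "MT-CYB"):
        gene = by_name[name]
        _write(seq, gene.start, "".join(_gene_codons(gene, rng))
               + _partial_tail(gene))

    # MT-ND6 is encoded on the light strand: build the coding-strand ORF,
    # then write its reverse complement into heavy-strand coordinates.
    nd6 = by_name["MT-ND6"]
    _write(seq, nd6.start, reverse_complement("".join(_gene_codons(nd6, rng))))

    # ATP8/ATP6 overlap (8527..8572): ATP6 written first with its head
    # solved jointly for both frames, then ATP8's non-overlapping part.
    atp6 = by_name["MT-ATP6"]
    atp6_codons = _gene_codons(atp6, rng)
    atp6_codons[:16] = [_build_atp6_region(rng)[i:i + 3]
                        for i in range(0, 48, 3)]
    _write(seq, atp6.start, "".join(atp6_codons))
    atp8 = by_name["MT-ATP8"]
    atp8_codons = _gene_codons(atp8, rng)[:53]
    atp8_codons[0] = "ATG"
    while True:
        c54 = _random_nonstop(rng, 1)[0][:2]
        if c54 not in ("TA", "AG"):  # third base is ATP6's fixed 'A'
            break
    _write(seq, atp8.start, "".join(atp8_codons) + c54)

    # ND4L/ND4 overlap (10760..10766): ND4 written first with a solved
    # head, then ND4L's non-overlapping part plus two bases of codon 97.
    nd4 = by_name["MT-ND4"]
    nd4_codons = _gene_codons(nd4, rng)
    nd4_codons[:3] = _build_nd4_head(rng)
    _write(seq, nd4.start, "".join(nd4_codons) + _partial_tail(nd4))
    nd4l = by_name["MT-ND4L"]
    nd4l_codons = _gene_codons(nd4l, rng)[:96]
    nd4l_codons[0] = "ATG"
    while True:
        c97 = _random_nonstop(rng, 1)[0][:2]
        if c97 not in ("TA", "AG"):
            break
    _write(seq, nd4l.start, "".join(nd4l_codons) + c97)

    seq[PLACEHOLDER_POS - 1] = "N"

    genome = ReferenceGenome("".join(seq), genes, name="rCRS-synthetic")
    _validate(genome)
    return genome


def _validate(genome: ReferenceGenome) -> None:
    for pos, base in EXPECTED_REF.items():
        got = genome.base_at(pos)
        if got != base:
            raise AssertionError(
                f"synthetic reference anchor failed at {pos}: "
                f"expected {base}, built {got}")
    for gene in genome.genes:
        if gene.product != "protein":
            continue
        cds = genome.coding_sequence(gene)
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        aa = [translate(c) for c in codons]
        if "*" in aa[:-1] or aa[-1] != "*":
            raise AssertionError(
                f"synthetic reference: invalid ORF in {gene.name}")


def write_reference_fasta(path: str,
                          genome: ReferenceGenome | None = None) -> None:
    """Write the (synthetic) reference to a FASTA file, 70 cols per line."""
    if genome is None:
        genome = build_synthetic_reference()
    with open(path, "w") as handle:
        handle.write(f">{genome.name} synthetic mtDNA reference, "
                     f"{MT_LENGTH} bp\n")
        for i in range(0, MT_LENGTH, 70):
            handle.write(genome.sequence[i:i + 70] + "\n")
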