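"""Reference genome services for human mtDNA.

The analysis works in 1-based rCRS coordinates (the ``m.<pos><ref>><alt>``
notation) against a 16,569 bp circular genome. This module provides

* :class:`ReferenceGenome` — sequence plus gene map, with position→feature
  lookup (:meth:`ReferenceGenome.genes_at`),
* :func:`codon_context` via :meth:`ReferenceGenome.codon_context` — codon
  number, offset and reference codon for a position inside a protein gene,
  with light-strand (MT-ND6) genes read in their own coding orientation and
  incomplete terminal codons completed with ``A`` bases (the mRNA stop codon
  of several mtDNA genes is completed by polyadenylation),
* :func:`translate` — the vertebrate mitochondrial genetic code
  (translation table 2: ``AGA``/``AGG`` are stops, ``ATA`` is Met, ``TGA``
  is Trp).

The default genome returned by :func:`load_reference` is a *synthetic*
stand-in for the rCRS built by :mod:`mitoburden.synthref`: it has the real
gene coordinates and reproduces the reference alleles and codon consequences
at all positions this pipeline's rules reference, but is otherwise random
sequence. Pass a FASTA path to analyse against the real rCRS.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

from .errors import CoordinateError, FormatError, SequenceError

MT_LENGTH = 16_569
PLACEHOLDER_POS = 3107  # historical spacer kept as 'N' so numbering matches

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}

#: Vertebrate mitochondrial genetic code (NCBI translation table 2).
#: Differs from the standard code at ATA (Met), TGA (Trp), AGA/AGG (stop).
MITO_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "M", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "W", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "*", "AGG": "*",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in MITO_CODE.items() if aa == "*")


def translate(codon: str) -> str:
    """Translate a 3-mer under the vertebrate mitochondrial code.

    Returns a one-letter amino acid, or ``"*"`` for a stop codon.
    Raises :class:`SequenceError` for anything that is not a 3-mer over ACGT.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise SequenceError(f"not an ACGT codon: {codon!r}")
    return MITO_CODE[codon]


def reverse_complement(seq: str) -> str:
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:  # pragma: no cover - defensive
        raise SequenceError(f"cannot complement base {exc}") from exc


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature of the mitochondrial genome.

    ``start``/``end`` are 1-based inclusive rCRS positions; ``strand`` is
    ``"heavy"`` or ``"light"``; ``product`` is ``protein``/``tRNA``/``rRNA``;
    ``complex_`` carries the OXPHOS complex label (I, III, IV, V) for
    protein genes and ``None`` otherwise.
    """

    name: str
    start: int
    end: int
    strand: str
    product: str
    complex_: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end <= MT_LENGTH):
            raise CoordinateError(
                f"{self.name}: invalid interval {self.start}..{self.end}")
        if self.strand not in ("heavy", "light"):
            raise FormatError(f"{self.name}: bad strand {self.strand!r}")
        if self.product not in ("protein", "tRNA", "rRNA"):
            raise FormatError(f"{self.name}: bad product {self.product!r}")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_codons(self) -> int:
        """Codon count after terminal-codon completion (protein genes)."""
        return (self.length + 2) // 3


@dataclass(frozen=True)
class CodonContext:
    """Codon-level context of a position inside a protein gene."""

    gene: GeneFeature
    codon_index: int  # 1-based codon number on the coding strand
    offset: int       # 1..3, position within the codon
    ref_codon: str    # coding-strand 3-mer (A-completed if terminal-partial)
    ref_aa: str


class ReferenceGenome:
    """A 16,569 bp mtDNA reference with its gene map."""

    def __init__(self, sequence: str, genes: Iterable[GeneFeature],
                 name: str = "rCRS-synthetic"):
        sequence = sequence.upper()
        if len(sequence) != MT_LENGTH:
            raise FormatError(
                f"reference must be {MT_LENGTH} bp, got {len(sequence)}")
        bad = set(sequence) - set("ACGTN")
        if bad:
            raise SequenceError(f"reference contains invalid bases {bad}")
        self.sequence = sequence
        self.name = name
        self.genes = tuple(sorted(genes, key=lambda g: (g.start, g.end)))
        self._by_name = {g.name: g for g in self.genes}

    def __len__(self) -> int:
        return MT_LENGTH

    def base_at(self, position: int) -> str:
        """Reference base at a 1-based position."""
        self._check_position(position)
        return self.sequence[position - 1]

    def gene(self, name: str) -> GeneFeature:
        try:
            return self._by_name[name]
        except KeyError:
            raise CoordinateError(f"unknown gene {name!r}") from None

    def genes_at(self, position: int) -> list[GeneFeature]:
        """All features whose interval contains ``position``.

        Returns an empty list for non-genic positions (control region,
        intergenic spacers); the ATP8/ATP6 and ND4L/ND4 overlaps return two
        features.
        """
        self._check_position(position)
        return [g for g in self.genes if position in g]

    def coding_sequence(self, gene: GeneFeature, complete: bool = True) -> str:
        """Coding-strand sequence of a protein gene, 5'→3'.

        Light-strand genes are reverse-complemented. With ``complete=True``
        an incomplete terminal codon is padded with ``A`` (polyadenylation
        completes the stop codon of these mRNAs).
        """
        raw = self.sequence[gene.start - 1:gene.end]
        if gene.strand == "light":
            raw = reverse_complement(raw)
        if complete and len(raw) % 3:
            raw += "A" * (3 - len(raw) % 3)
        return raw

    def codon_context(self, position: int, gene: GeneFeature) -> CodonContext:
        """Codon number/offset/reference codon of ``position`` in ``gene``.

        The codon is computed on the coding strand: for the light-strand
        gene (MT-ND6) the genomic region is reverse-complemented and read in
        the gene's own 5'→3' direction, so codon 1 sits at the *highest*
        genomic coordinate.
        """
        if gene.product != "protein":
            raise SequenceError(
                f"codon context requested in non-protein gene {gene.name}")
        if position not in gene:
            raise CoordinateError(
                f"position {position} outside {gene.name} "
                f"({gene.start}..{gene.end})")
        if gene.strand == "heavy":
            idx = position - gene.start + 1  # 1-based coding index
        else:
            idx = gene.end - position + 1
        codon_index = (idx + 2) // 3
        offset = (idx - 1) % 3 + 1
        cds = self.coding_sequence(gene)
        ref_codon = cds[3 * (codon_index - 1):3 * codon_index]
        return CodonContext(gene, codon_index, offset, ref_codon,
                            translate(ref_codon))

    def _check_position(self, position: int) -> None:
        if not (1 <= position <= MT_LENGTH):
            raise CoordinateError(
                f"position {position} outside 1..{MT_LENGTH}")


def load_gene_map(path: str | None = None) -> list[GeneFeature]:
    """Read a gene-map TSV (name, start, end, strand, product, complex).

    With no path, the packaged map (NC_012920 coordinates) is used.
    Lines starting with ``#`` are comments; ``-`` means no complex label.
    """
    if path is None:
        text = (importlib.resources.files("mitoburden.data")
                .joinpath("gene_map.tsv").read_text())
    else:
        with open(path) as handle:
            text = handle.read()
    genes = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise FormatError(f"gene map row needs 6 columns: {line!r}")
        name, start, end, strand, product, cplx = fields
        genes.append(GeneFeature(name, int(start), int(end), strand, product,
                                 None if cplx == "-" else cplx))
    if not genes:
        raise FormatError("gene map is empty")
    return genes


def read_fasta_sequence(path: str) -> str:
    from Bio import SeqIO

    records = list(SeqIO.parse(path, "fasta"))
    if len(records) != 1:
        raise FormatError(
            f"expected a single-record mtDNA FASTA, got {len(records)}")
    return str(records[0].seq).upper()


@lru_cache(maxsize=4)
def _default_reference() -> ReferenceGenome:
    from .synthref import build_synthetic_reference

    return build_synthetic_reference()


def load_reference(fasta_path: str | None = None,
                   gene_map_path: str | None = None) -> ReferenceGenome:
    """Load the reference genome.

    ``fasta_path=None`` returns the packaged synthetic stand-in (see module
    docstring); a path to a real rCRS FASTA overrides it. ``gene_map_path``
    optionally overrides the packaged gene map.
    """
    if fasta_path is None and gene_map_path is None:
        return _default_reference()
    genes = load_gene_map(gene_map_path)
    if fasta_path is None:
        return ReferenceGenome(_default_reference().sequence, genes)
    return ReferenceGenome(read_fasta_sequence(fasta_path), genes,
                           name="user-supplied")
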