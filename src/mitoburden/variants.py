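"""Variant/cohort data model and file I/O.

Variants are stored as differences from the rCRS reference (1-based
positions), the same convention HaploGrep-style profiles use. Canonical
labels follow the field's notation:

* substitutions   ``m.3243A>G``
* deletions       ``m.523Ad`` (single base) / ``m.523_524delAC`` (run)
* insertions      ``m.309.1C`` (decimal-point position: the base the
  insert follows, then the insert index)

Heteroplasmy is carried as an optional mutant fraction in [0, 1]
(1.0 = homoplasmic) plus a boolean flag for calls where only the presence
of heteroplasmy is known (IUPAC ambiguity codes in FASTA-derived calls).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, ParseError, ValidationError
from .reference import MT_LENGTH, ReferenceGenome, load_reference

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"

#: IUPAC two-base ambiguity codes seen in heteroplasmic base calls.
IUPAC2 = {"R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC"}

_SUB_RE = re.compile(r"^(?:m\.)?(\d+)([ACGT])>([ACGT])$")
_DEL1_RE = re.compile(r"^(?:m\.)?(\d+)([ACGT]+)d$")
_DELN_RE = re.compile(r"^(?:m\.)?(\d+)_(\d+)del([ACGT]+)$")
_INS_RE = re.compile(r"^(?:m\.)?(\d+)\.(\d+)([ACGT]+)$")
_HSD_RE = re.compile(r"^(\d+)([ACGTRYSWKM])$")


@dataclass(frozen=True)
class Variant:
    """A single mtDNA change in rCRS coordinates."""

    position: int
    ref: str
    alt: str
    kind: str = SUBSTITUTION
    ins_offset: int = 0
    heteroplasmy: float | None = None
    het_flag: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.position <= MT_LENGTH):
            raise ValidationError(f"position {self.position} out of range")
        if self.kind == SUBSTITUTION:
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise ValidationError(
                    f"bad substitution {self.position}{self.ref}>{self.alt}")
        elif self.kind == DELETION:
            if not self.ref or self.alt:
                raise ValidationError("deletion needs ref bases and empty alt")
        elif self.kind == INSERTION:
            if self.ref or not self.alt or self.ins_offset < 1:
                raise ValidationError(
                    "insertion needs empty ref, alt bases and offset >= 1")
        else:
            raise ValidationError(f"unknown variant kind {self.kind!r}")
        if self.heteroplasmy is not None and not 0 <= self.heteroplasmy <= 1:
            raise ValidationError(
                f"heteroplasmy {self.heteroplasmy} outside [0,1]")

    @property
    def key(self) -> tuple:
        """Identity used for deduplication (fraction-independent)."""
        return (self.position, self.ref, self.alt, self.kind, self.ins_offset)

    @property
    def label(self) -> str:
        return format_variant_label(self)

    @property
    def is_heteroplasmic(self) -> bool:
        if self.heteroplasmy is not None:
            return self.heteroplasmy < 1.0
        return self.het_flag


def format_variant_label(variant: Variant) -> str:
    """Canonical ``m.``-prefixed label of a variant."""
    if variant.kind == SUBSTITUTION:
        return f"m.{variant.position}{variant.ref}>{variant.alt}"
    if variant.kind == DELETION:
        if len(variant.ref) == 1:
            return f"m.{variant.position}{variant.ref}d"
        end = variant.position + len(variant.ref) - 1
        return f"m.{variant.position}_{end}del{variant.ref}"
    return f"m.{variant.position}.{variant.ins_offset}{variant.alt}"


def parse_variant_label(label: str) -> Variant:
    """Parse a canonical variant label; inverse of `format_variant_label`."""
    if not label or not isinstance(label, str):
        raise ParseError("empty variant label")
    token = label.strip()
    if m := _SUB_RE.match(token):
        return Variant(int(m.group(1)), m.group(2), m.group(3), SUBSTITUTION)
    if m := _DELN_RE.match(token):
        start, end, ref = int(m.group(1)), int(m.group(2)), m.group(3)
        if end - start + 1 != len(ref):
            raise ParseError(f"deletion span/bases mismatch in {token!r}")
        return Variant(start, ref, "", DELETION)
    if m := _DEL1_RE.match(token):
        return Variant(int(m.group(1)), m.group(2), "", DELETION)
    if m := _INS_RE.match(token):
        return Variant(int(m.group(1)), "", m.group(3), INSERTION,
                       ins_offset=int(m.group(2)))
    raise ParseError(f"cannot parse variant label {token!r}")


def parse_hsd_token(token: str,
                    reference: ReferenceGenome) -> list[Variant]:
    """Parse one HSD-style variant token into variants.

    Bare tokens like ``3243G`` carry only position and alternate base; the
    reference allele is looked up in ``reference``. IUPAC ambiguity letters
    (R/S/Y/W/K/M) mark heteroplasmic positions and yield one flagged variant
    per non-reference base they encode. ``m.``-prefixed canonical labels are
    accepted as-is.
    """
    token = token.strip()
    if not token:
        raise ParseError("empty HSD token")
    if m := _HSD_RE.match(token):
        pos, base = int(m.group(1)), m.group(2)
        ref = reference.base_at(pos)
        if base in IUPAC2:
            alts = [b for b in IUPAC2[base] if b != ref]
            if not alts:
                raise ParseError(
                    f"IUPAC token {token!r} encodes only the reference base")
            return [Variant(pos, ref, alt, SUBSTITUTION, het_flag=True)
                    for alt in alts]
        if base == ref:
            raise ParseError(
                f"token {token!r} matches the reference allele {ref}")
        return [Variant(pos, ref, base, SUBSTITUTION)]
    if m := re.match(r"^(\d+)d$", token):  # bare single-base deletion
        pos = int(m.group(1))
        return [Variant(pos, reference.base_at(pos), "", DELETION)]
    return [parse_variant_label(token)]


@dataclass(frozen=True)
class SubjectProfile:
    """One subject's variant set (differences from rCRS) plus labels."""

    subject_id: str
    group: str | None = None
    haplogroup: str | None = None
    variants: frozenset[Variant] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        keys = [v.key for v in self.variants]
        if len(keys) != len(set(keys)):
            raise ValidationError(
                f"{self.subject_id}: duplicate variant (position, alt) pairs")

    def sorted_variants(self) -> list[Variant]:
        return sorted(self.variants,
                      key=lambda v: (v.position, v.ins_offset, v.alt, v.ref))


def make_profile(subject_id: str, variants: Iterable[Variant],
                 group: str | None = None,
                 haplogroup: str | None = None) -> SubjectProfile:
    """Build a profile, deduplicating identical (position, alt) records.

    When duplicates differ only in heteroplasmy information, the record
    with a known fraction wins.
    """
    chosen: dict[tuple, Variant] = {}
    for v in variants:
        prev = chosen.get(v.key)
        if prev is None or (prev.heteroplasmy is None
                            and v.heteroplasmy is not None):
            chosen[v.key] = v
    return SubjectProfile(subject_id, group, haplogroup,
                          frozenset(chosen.values()))


class _LookupTable:
    """Validated (position, ref, alt) → value table."""

    value_name = "value"

    def __init__(self, mapping: Mapping[tuple[int, str, str], float]):
        for key, value in mapping.items():
            if not 0 <= value <= 1:
                raise ValidationError(
                    f"{self.value_name} {value} for {key} outside [0,1]")
        self._map = dict(mapping)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, variant: Variant) -> bool:
        return (variant.position, variant.ref, variant.alt) in self._map

    def get(self, variant: Variant, default: float | None = None):
        return self._map.get(
            (variant.position, variant.ref, variant.alt), default)

    def items(self):
        return self._map.items()


class FrequencyTable(_LookupTable):
    """Minor-allele frequencies keyed by (position, ref, alt)."""

    value_name = "MAF"

    def __init__(self, mapping, source_size: int | None = None):
        super().__init__(mapping)
        self.source_size = source_size


class PathogenicityTable(_LookupTable):
    """Pathogenicity probabilities keyed by (position, ref, alt)."""

    value_name = "pathogenicity probability"


def _read_lookup(path: str, value_columns: Sequence[str]) -> tuple[dict, pd.DataFrame]:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"ref": str, "alt": str})
    needed = {"position", "ref", "alt"}
    if not needed.issubset(frame.columns):
        raise FormatError(
            f"{path}: expected columns position/ref/alt, got {list(frame.columns)}")
    value_col = next((c for c in value_columns if c in frame.columns), None)
    if value_col is None:
        raise FormatError(f"{path}: no value column among {value_columns}")
    mapping: dict[tuple[int, str, str], float] = {}
    for row in frame.itertuples(index=False):
        key = (int(row.position), str(row.ref), str(row.alt))
        if key in mapping:
            raise ValidationError(f"{path}: duplicate key {key}")
        mapping[key] = float(getattr(row, value_col))
    return mapping, frame


def read_frequency_table(path: str) -> FrequencyTable:
    """Read a TSV of position/ref/alt/maf (+ optional source_size column)."""
    mapping, frame = _read_lookup(path, ("maf", "value", "frequency"))
    source_size = None
    if "source_size" in frame.columns and len(frame):
        source_size = int(frame["source_size"].iloc[0])
    return FrequencyTable(mapping, source_size=source_size)


def read_pathogenicity_table(path: str) -> PathogenicityTable:
    """Read a TSV of position/ref/alt/probability."""
    mapping, _ = _read_lookup(path, ("probability", "value", "pathogenicity"))
    return PathogenicityTable(mapping)


def read_metadata(path: str) -> dict[str, str]:
    """Cohort metadata TSV (subject_id, group) → {subject_id: group}."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"subject_id", "group"}.issubset(frame.columns):
        raise FormatError(f"{path}: expected subject_id and group columns")
    return dict(zip(frame["subject_id"], frame["group"]))


# ---------------------------------------------------------------------------
# profile I/O
# ---------------------------------------------------------------------------

def read_profiles(path: str, format: str,
                  reference: ReferenceGenome | None = None,
                  metadata: Mapping[str, str] | None = None
                  ) -> list[SubjectProfile]:
    """Read subject profiles from ``hsd``, ``vcf`` or ``tsv`` input.

    ``metadata`` (subject_id → group) is merged into the returned profiles
    when given; HSD and VCF files do not carry group labels themselves.
    """
    if format == "hsd":
        profiles = _read_hsd(path, reference or load_reference())
    elif format == "vcf":
        profiles = _read_vcf(path)
    elif format == "tsv":
        profiles = _read_tsv(path)
    else:
        raise FormatError(f"unknown profile format {format!r}")
    if metadata:
        profiles = [replace(p, group=metadata.get(p.subject_id, p.group))
                    for p in profiles]
    return profiles


def _read_hsd(path: str, reference: ReferenceGenome) -> list[SubjectProfile]:
    profiles = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.lower().startswith("sampleid\t"):
                continue  # HaploGrep-style header
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{line_no}: HSD rows need id, range, haplogroup")
            subject_id, _range, haplogroup = fields[0], fields[1], fields[2]
            tokens = " ".join(fields[3:]).split()
            variants: list[Variant] = []
            for token in tokens:
                variants.extend(parse_hsd_token(token, reference))
            profiles.append(make_profile(
                subject_id, variants,
                haplogroup=haplogroup if haplogroup not in ("", "-", "?")
                else None))
    return profiles


def write_profiles_hsd(profiles: Sequence[SubjectProfile], path: str) -> None:
    """Write HSD-style rows: id, range, haplogroup, variant tokens.

    Heteroplasmy fractions are not representable in HSD; flagged
    heteroplasmic substitutions are written as IUPAC ambiguity tokens.
    """
    with open(path, "w") as handle:
        handle.write("SampleId\tRange\tHaplogroup\tPolymorphisms\n")
        for profile in profiles:
            tokens = []
            for v in profile.sorted_variants():
                if v.kind == SUBSTITUTION and v.is_heteroplasmic:
                    code = next(c for c, pair in IUPAC2.items()
                                if set(pair) == {v.ref, v.alt})
                    tokens.append(f"{v.position}{code}")
                elif v.kind == SUBSTITUTION:
                    tokens.append(f"{v.position}{v.alt}")
                elif v.kind == DELETION and len(v.ref) == 1:
                    tokens.append(f"{v.position}d")
                else:
                    tokens.append(v.label)
            handle.write("\t".join([profile.subject_id, f"1-{MT_LENGTH}",
                                    profile.haplogroup or "?",
                                    " ".join(tokens)]) + "\n")


def _read_tsv(path: str) -> list[SubjectProfile]:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                        keep_default_na=False)
    needed = {"subject_id", "variant"}
    if not needed.issubset(frame.columns):
        raise FormatError(f"{path}: expected subject_id and variant columns")
    profiles = []
    for subject_id, rows in frame.groupby("subject_id", sort=True):
        group = rows["group"].iloc[0] if "group" in rows else None
        haplogroup = rows["haplogroup"].iloc[0] if "haplogroup" in rows else None
        variants = []
        for row in rows.itertuples(index=False):
            if not row.variant:
                continue
            v = parse_variant_label(row.variant)
            het = getattr(row, "heteroplasmy", "")
            if het not in ("", None):
                v = replace(v, heteroplasmy=float(het),
                            het_flag=float(het) < 1.0)
            profiles_flag = getattr(row, "het_flag", "")
            if profiles_flag in ("1", "True", "true"):
                v = replace(v, het_flag=True)
            variants.append(v)
        profiles.append(make_profile(str(subject_id), variants,
                                     group=group or None,
                                     haplogroup=haplogroup or None))
    return profiles


def write_profiles_tsv(profiles: Sequence[SubjectProfile], path: str) -> None:
    rows = []
    for p in sorted(profiles, key=lambda p: p.subject_id):
        if not p.variants:
            rows.append((p.subject_id, p.group or "", p.haplogroup or "",
                         "", "", ""))
        for v in p.sorted_variants():
            rows.append((p.subject_id, p.group or "", p.haplogroup or "",
                         v.label,
                         "" if v.heteroplasmy is None else repr(v.heteroplasmy),
                         "1" if v.het_flag else ""))
    frame = pd.DataFrame(rows, columns=["subject_id", "group", "haplogroup",
                                        "variant", "heteroplasmy", "het_flag"])
    frame.to_csv(path, sep="\t", index=False)


def _read_vcf(path: str) -> list[SubjectProfile]:
    import pysam

    with pysam.VariantFile(path) as vcf:
        contigs = list(vcf.header.contigs)
        for name in contigs:
            length = vcf.header.contigs[name].length
            if length is not None and length != MT_LENGTH:
                raise FormatError(
                    f"{path}: contig {name} length {length} != {MT_LENGTH}"
                    " (not an rCRS-coordinate VCF)")
        samples = list(vcf.header.samples)
        per_sample: dict[str, list[Variant]] = {s: [] for s in samples}
        for record in vcf:
            for alt_index, alt in enumerate(record.alts or (), start=1):
                variant = _vcf_to_variant(record.pos, record.ref, alt)
                for sample in samples:
                    call = record.samples[sample]
                    gt = call.get("GT") or ()
                    if alt_index not in gt:
                        continue
                    hf = call.get("HF")
                    v = variant
                    if hf is not None:
                        frac = hf[alt_index - 1] if isinstance(hf, tuple) else hf
                        if frac is not None:
                            v = replace(v, heteroplasmy=float(frac),
                                        het_flag=float(frac) < 1.0)
                    per_sample[sample].append(v)
    return [make_profile(s, vs) for s, vs in per_sample.items()]


def _vcf_to_variant(pos: int, ref: str, alt: str) -> Variant:
    ref, alt = ref.upper(), alt.upper()
    if len(ref) == 1 and len(alt) == 1:
        return Variant(pos, ref, alt, SUBSTITUTION)
    if len(ref) > len(alt) and ref.startswith(alt):
        return Variant(pos + len(alt), ref[len(alt):], "", DELETION)
    if len(alt) > len(ref) and alt.startswith(ref):
        return Variant(pos + len(ref) - 1, "", alt[len(ref):], INSERTION,
                       ins_offset=1)
    raise FormatError(f"unsupported VCF allele pair {ref}>{alt} at {pos}")


def write_profiles_vcf(profiles: Sequence[SubjectProfile], path: str,
                       contig: str = "chrM") -> None:
    """Write substitution calls to a minimal single-contig VCF."""
    import pysam

    header = pysam.VariantHeader()
    header.contigs.add(contig, length=MT_LENGTH)
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"),
                                     ("Description", "Genotype")])
    header.add_meta("FORMAT", items=[("ID", "HF"), ("Number", "A"),
                                     ("Type", "Float"),
                                     ("Description", "Heteroplasmy fraction")])
    for p in profiles:
        header.add_sample(p.subject_id)
    sites: dict[tuple[int, str, str], dict[str, Variant]] = {}
    for p in profiles:
        for v in p.variants:
            if v.kind != SUBSTITUTION:
                continue
            sites.setdefault((v.position, v.ref, v.alt), {})[p.subject_id] = v
    with pysam.VariantFile(path, "w", header=header) as out:
        for (pos, ref, alt), carriers in sorted(sites.items()):
            record = out.new_record(contig=contig, start=pos - 1,
                                    alleles=(ref, alt))
            record.id = f"m.{pos}{ref}>{alt}"
            for p in profiles:
                call = record.samples[p.subject_id]
                v = carriers.get(p.subject_id)
                if v is None:
                    call["GT"] = (0,)
                else:
                    call["GT"] = (1,)
                    if v.heteroplasmy is not None:
                        call["HF"] = (v.heteroplasmy,)
            out.write(record)
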