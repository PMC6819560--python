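"""Variant labels, profile containers and file round trips."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoburden.errors import FormatError, ParseError, ValidationError
from mitoburden.variants import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    FrequencyTable,
    SubjectProfile,
    Variant,
    format_variant_label,
    make_profile,
    parse_hsd_token,
    parse_variant_label,
    read_frequency_table,
    read_profiles,
    write_profiles_hsd,
    write_profiles_tsv,
    write_profiles_vcf,
)


@pytest.mark.parametrize("label, expected", [
    ("m.3243A>G", (3243, "A", "G", SUBSTITUTION)),
    ("m.1555A>G", (1555, "A", "G", SUBSTITUTION)),
    ("m.523_524delAC", (523, "AC", "", DELETION)),
    ("m.16183Ad", (16183, "A", "", DELETION)),
    ("m.309.1C", (309, "", "C", INSERTION)),
])
def test_parse_variant_label(label, expected):
    v = parse_variant_label(label)
    assert (v.position, v.ref, v.alt, v.kind) == expected


@pytest.mark.parametrize("bad", [
    "", "3243", "m.3243A>A", "m.3243A-G", "m.0A>G", "m.99999A>G",
    "m.523_525delAC", "m.309.0C", "banana",
])
def test_parse_rejects_malformed_labels(bad):
    with pytest.raises((ParseError, ValidationError)):
        parse_variant_label(bad)


_positions = st.integers(min_value=1, max_value=16569)
_bases = st.sampled_from("ACGT")


@st.composite
def canonical_variants(draw):
    kind = draw(st.sampled_from([SUBSTITUTION, DELETION, INSERTION]))
    pos = draw(st.integers(min_value=1, max_value=16000))
    if kind == SUBSTITUTION:
        ref = draw(_bases)
        alt = draw(_bases.filter(lambda b: b != ref))
        return Variant(pos, ref, alt)
    if kind == DELETION:
        ref = draw(st.text(alphabet="ACGT", min_size=1, max_size=4))
        return Variant(pos, ref, "", DELETION)
    alt = draw(st.text(alphabet="ACGT", min_size=1, max_size=3))
    return Variant(pos, "", alt, INSERTION,
                   ins_offset=draw(st.integers(min_value=1, max_value=3)))


@settings(max_examples=200, derandomize=True)
@given(canonical_variants())
def test_label_round_trip(variant):
    assert parse_variant_label(format_variant_label(variant)).key == variant.key


def test_hsd_token_with_reference_lookup(reference):
    (v,) = parse_hsd_token("3243G", reference)
    assert v.label == "m.3243A>G" and not v.het_flag
    (v,) = parse_hsd_token("3243R", reference)  # IUPAC A/G, ref A
    assert v.label == "m.3243A>G" and v.het_flag
    with pytest.raises(ParseError):
        parse_hsd_token("3243A", reference)  # reference allele
    (v,) = parse_hsd_token("16183d", reference)
    assert (v.kind, v.ref) == (DELETION, "A")


def test_profile_rejects_duplicate_position_alt():
    a = Variant(3243, "A", "G")
    b = Variant(3243, "A", "G", heteroplasmy=0.4, het_flag=True)
    with pytest.raises(ValidationError):
        SubjectProfile("S1", variants=frozenset({a, b}))
    # make_profile dedups, preferring the known fraction
    profile = make_profile("S1", [a, b])
    assert len(profile.variants) == 1
    assert next(iter(profile.variants)).heteroplasmy == 0.4


def test_frequency_table_demo_values(freqs):
    assert freqs.get(Variant(3243, "A", "G")) == pytest.approx(0.0014)
    assert freqs.get(Variant(1555, "A", "G")) == pytest.approx(0.0033)
    assert freqs.source_size == 30589
    assert freqs.get(Variant(9000, "A", "G")) is None


def test_frequency_table_validation(tmp_path):
    bad = tmp_path / "bad.tsv"
    bad.write_text("position\tref\talt\tmaf\n3243\tA\tG\t1.2\n")
    with pytest.raises(ValidationError):
        read_frequency_table(str(bad))
    dup = tmp_path / "dup.tsv"
    dup.write_text("position\tref\talt\tmaf\n"
                   "3243\tA\tG\t0.1\n3243\tA\tG\t0.2\n")
    with pytest.raises(ValidationError):
        read_frequency_table(str(dup))
    with pytest.raises(ValidationError):
        FrequencyTable({(1, "A", "G"): -0.1})


@pytest.fixture
def sample_profiles():
    return [
        make_profile("S1", [Variant(3243, "A", "G", het_flag=True),
                            Variant(4216, "T", "C"),
                            Variant(523, "AC", "", DELETION),
                            Variant(309, "", "C", INSERTION, ins_offset=1)],
                     group="sprint", haplogroup="JT"),
        make_profile("S2", [], group="control"),  # the rCRS haplotype
    ]


def test_hsd_round_trip(tmp_path, reference, sample_profiles):
    path = tmp_path / "cohort.hsd"
    write_profiles_hsd(sample_profiles, str(path))
    back = read_profiles(str(path), "hsd", reference=reference)
    by_id = {p.subject_id: p for p in back}
    assert set(by_id) == {"S1", "S2"}
    assert by_id["S2"].variants == frozenset()
    orig = {v.key for v in sample_profiles[0].variants}
    assert {v.key for v in by_id["S1"].variants} == orig
    # heteroplasmy flag survives via the IUPAC token
    het = next(v for v in by_id["S1"].variants if v.position == 3243)
    assert het.het_flag


def test_tsv_round_trip_preserves_heteroplasmy(tmp_path):
    profiles = [make_profile(
        "S1", [Variant(3243, "A", "G", heteroplasmy=0.43, het_flag=True),
               Variant(1555, "A", "G", heteroplasmy=1.0)],
        group="sprint", haplogroup="H")]
    path = tmp_path / "cohort.tsv"
    write_profiles_tsv(profiles, str(path))
    (back,) = read_profiles(str(path), "tsv")
    assert back.group == "sprint" and back.haplogroup == "H"
    assert {(v.position, v.heteroplasmy) for v in back.variants} == \
        {(3243, 0.43), (1555, 1.0)}


def test_vcf_round_trip_two_samples(tmp_path):
    profiles = [
        make_profile("S1", [Variant(3243, "A", "G", heteroplasmy=0.43,
                                    het_flag=True)]),
        make_profile("S2", [Variant(4216, "T", "C")]),
    ]
    path = tmp_path / "cohort.vcf"
    write_profiles_vcf(profiles, str(path))
    back = read_profiles(str(path), "vcf")
    assert len(back) == 2
    by_id = {p.subject_id: p for p in back}
    (v1,) = by_id["S1"].variants
    assert v1.label == "m.3243A>G"
    assert v1.heteroplasmy == pytest.approx(0.43, abs=1e-6)
    (v2,) = by_id["S2"].variants
    assert v2.label == "m.4216T>C" and v2.heteroplasmy is None


def test_read_profiles_unknown_format(tmp_path):
    path = tmp_path / "x.txt"
    path.write_text("")
    with pytest.raises(FormatError):
        read_profiles(str(path), "xlsx")
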