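"""Variant nomenclature parsing, formatting and profile I/O."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtqc import (
    DELETION,
    Variant,
    VariantParseError,
    VariantProfile,
    format_variant,
    make_profile,
    parse_variant,
    read_profiles,
    read_vcf,
    variants_match,
    write_profiles,
)

BASES = "ACGT"
PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


@pytest.mark.parametrize(
    "token, position, ref, alt, mclass, het",
    [
        ("A7146G", 7146, "A", "G", "transition", False),
        ("h12519", 12519, None, None, "unknown", True),
        ("16318t", 16318, None, "T", "transversion", False),
        ("16166d", 16166, None, DELETION, "deletion", False),
        ("hC16147a", 16147, "C", "A", "transversion", True),
        ("7028T", 7028, "C", "T", "transition", False),  # ref inferred
        ("A16265c", 16265, "A", "C", "transversion", False),
        ("hT489C", 489, "T", "C", "transition", True),
    ],
)
def test_parse_variant_grammar(token, position, ref, alt, mclass, het):
    v = parse_variant(token)
    assert (v.position, v.ref_allele, v.alt_allele) == (position, ref, alt)
    assert v.mutation_class == mclass
    assert v.heteroplasmic is het


@pytest.mark.parametrize(
    "token",
    ["A0G", "A16570G", "", "  ", "X123Y", "315+C", "315.1C", "A7146", "A7146g", "12q"],
)
def test_parse_variant_rejects(token):
    with pytest.raises(VariantParseError):
        parse_variant(token)


@st.composite
def variants(draw):
    position = draw(st.integers(min_value=1, max_value=16569))
    het = draw(st.booleans())
    kind = draw(st.sampled_from(["full", "transversion", "position_only", "deletion"]))
    if kind == "position_only":
        return Variant(position, None, None, het)
    if kind == "deletion":
        ref = draw(st.one_of(st.none(), st.sampled_from(BASES)))
        return Variant(position, ref, DELETION, het)
    ref = draw(st.sampled_from(BASES))
    if kind == "full":
        alt = draw(st.sampled_from([b for b in BASES if b != ref]))
        return Variant(position, ref, alt, het)
    alt = draw(st.sampled_from([b for b in BASES if b not in (ref, PARTNER[ref])]))
    keep_ref = draw(st.booleans())
    return Variant(position, ref if keep_ref else None, alt, het)


@given(variants())
@settings(max_examples=300, derandomize=True)
def test_format_parse_roundtrip(v):
    assert parse_variant(format_variant(v)) == v


@given(variants(), variants())
@settings(max_examples=200, derandomize=True)
def test_variants_match_symmetric_reflexive(a, b):
    assert variants_match(a, a)
    assert variants_match(a, b) == variants_match(b, a)


def test_wildcard_matching_links_positions_to_motifs():
    assert variants_match(parse_variant("h12519"), parse_variant("T12519C"))
    assert variants_match(parse_variant("A7146G"), parse_variant("A7146G"))
    assert not variants_match(parse_variant("A7146G"), parse_variant("A7146t"))
    # heteroplasmy flags are ignored for matching
    assert variants_match(parse_variant("hA7146G"), parse_variant("A7146G"))


def test_read_profiles_case11_row():
    tsv = (
        "sample\ttissue\tvariants\n"
        "case11\tnormal\tT12519C,A14203G,T16126C,C16264T,A9221G,C13506T\n"
        "empty\ttumor\t\n"
    )
    profiles = read_profiles(tsv)
    assert len(profiles[0]) == 6
    assert profiles[1].variants == frozenset()


def test_read_profiles_dedup_warns(caplog):
    tsv = "sample\ttissue\tvariants\ns1\ttumor\tA7146G,A7146G\n"
    with caplog.at_level("WARNING", logger="mtqc"):
        (profile,) = read_profiles(tsv)
    assert len(profile) == 1
    assert any("duplicate" in r.message for r in caplog.records)


def test_read_profiles_errors_carry_row_number():
    with pytest.raises(VariantParseError, match="row 3"):
        read_profiles("sample\ttissue\tvariants\nok\tnormal\tA7146G\nbad\ttumor\tZZZ\n")
    with pytest.raises(VariantParseError, match="missing column"):
        read_profiles("sample\tvariants\nx\tA7146G\n")


def test_profile_rejects_duplicate_position_allele():
    v = parse_variant("A7146G")
    with pytest.raises(ValueError, match="repeats"):
        VariantProfile("s", "tumor", frozenset({v, parse_variant("hA7146G")}))


def test_profile_roundtrip_through_tsv():
    p = make_profile("s1", "leukocyte", ["A7146G", "h12519", "16166d", "16318t"])
    (back,) = read_profiles(write_profiles([p]))
    assert back == p


def test_read_vcf_minimal(tmp_path):
    vcf = tmp_path / "s.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chrM\t7146\t.\tA\tG\t.\t.\t.\n"
        "chrM\t16317\t.\tCA\tC\t.\t.\t.\n"
        "chrM\t12519\t.\tT\tC\t.\t.\tHET\n"
        "chrM\t8000\t.\tA\tC\t.\t.\t.\n"
    )
    profile = read_vcf(str(vcf), sample_id="s", tissue="tumor")
    tokens = {format_variant(v) for v in profile.variants}
    assert tokens == {"A7146G", "A16318d", "hT12519C", "A8000c"}
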