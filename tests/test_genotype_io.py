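import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import haplogwas as h
from haplogwas.errors import BiallelismError, ParameterError, ParseError, ValidationError
from haplogwas.genotype import (
    MISSING,
    MafFilterSpec,
    chromosome_sort_key,
    filter_biallelic,
    filter_maf,
    parse_region,
    read_genotype_tsv,
    read_genotype_vcf,
    region_query,
    write_genotype_tsv,
)

from helpers import gm_from_strings, random_gm


def assert_gm_equal(a, b):
    assert a.strains == b.strains
    assert a.sites == b.sites
    assert np.array_equal(a.calls, b.calls)


# ---------------------------------------------------------------- TSV dialect

def test_roundtrip_small(tmp_path):
    gm = gm_from_strings(
        [("I", 10, "AAGG"), ("I", 20, "CTCT"), ("II", 5, "GGGT")]
    )
    path = tmp_path / "g.tsv"
    write_genotype_tsv(gm, path)
    back = read_genotype_tsv(path)
    assert back.n_sites == 3 and back.n_strains == 4
    assert int(np.sum(back.calls == MISSING)) == 0
    assert_gm_equal(gm, back)


def test_site_key_parsing_fig4a_positions(tmp_path):
    path = tmp_path / "g.tsv"
    path.write_text(
        "site\ts1\ts2\ts3\n"
        "IV:3562999\tA\tG\tA\n"
        "IV:3562998\tC\tT\tC\n"
        "IV:3562957\tG\tG\tA\n"
    )
    gm = read_genotype_tsv(path)
    assert [(s.chromosome, s.position) for s in gm.sites] == [
        ("IV", 3562957), ("IV", 3562998), ("IV", 3562999)
    ]
    top = [s for s in gm.sites if s.position == 3562999][0]
    assert top.alleles == ("A", "G")


def test_triallelic_row_errors_strict_parses_lenient(tmp_path):
    path = tmp_path / "g.tsv"
    path.write_text("site\ts1\ts2\ts3\nI:1\tA\tC\tG\n")
    with pytest.raises(BiallelismError, match="I:1"):
        read_genotype_tsv(path)
    gm = read_genotype_tsv(path, lenient=True)
    assert gm.sites[0].alleles == ("A", "C", "G")
    assert filter_biallelic(gm).n_sites == 0


def test_ragged_row_names_line(tmp_path):
    path = tmp_path / "g.tsv"
    path.write_text("site\ts1\ts2\nI:1\tA\n")
    with pytest.raises(ParseError, match=":2"):
        read_genotype_tsv(path)


def test_duplicate_site_error(tmp_path):
    path = tmp_path / "g.tsv"
    path.write_text("site\ts1\nI:5\tA\nI:5\tC\n")
    with pytest.raises(ValidationError, match="duplicate site"):
        read_genotype_tsv(path)


def test_malformed_cell_strict_vs_lenient(tmp_path):
    path = tmp_path / "g.tsv"
    path.write_text("site\ts1\ts2\nI:1\tA\tXX\n")
    with pytest.raises(ParseError, match="malformed"):
        read_genotype_tsv(path)
    gm = read_genotype_tsv(path, lenient=True)
    assert gm.calls[0, 1] == MISSING


def test_bad_header_and_empty(tmp_path):
    path = tmp_path / "g.tsv"
    path.write_text("snp\ts1\nI:1\tA\n")
    with pytest.raises(ParseError, match="site"):
        read_genotype_tsv(path)


def test_empty_matrix_roundtrip(tmp_path):
    gm = gm_from_strings([], strains=["a", "b"])  # header-only file
    path = tmp_path / "g.tsv"
    write_genotype_tsv(gm, path)
    back = read_genotype_tsv(path)
    assert back.n_sites == 0 and back.strains == ["a", "b"]


def test_roundtrip_random_medium(tmp_path, rng):
    gm = random_gm(rng, n_sites=500, n_strains=30, missing_rate=0.15)
    path = tmp_path / "g.tsv"
    write_genotype_tsv(gm, path)
    assert_gm_equal(gm, read_genotype_tsv(path))
    # bit-exact on re-write
    write_genotype_tsv(read_genotype_tsv(path), tmp_path / "g2.tsv")
    assert (tmp_path / "g.tsv").read_bytes() == (tmp_path / "g2.tsv").read_bytes()


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 2**31 - 1), st.integers(1, 40), st.integers(2, 12))
def test_roundtrip_property(tmp_path_factory, seed, n_sites, n_strains):
    rng = np.random.default_rng(seed)
    gm = random_gm(rng, n_sites=n_sites, n_strains=n_strains, missing_rate=0.2)
    path = tmp_path_factory.mktemp("rt") / "g.tsv"
    write_genotype_tsv(gm, path)
    assert_gm_equal(gm, read_genotype_tsv(path))


# ------------------------------------------------------------------ filtering

def test_filter_biallelic_examples():
    gm = gm_from_strings(
        [("I", 1, "AAAA"), ("I", 2, "AGAG"), ("I", 3, "A.A."), ("I", 4, "ACGT")]
    )
    out = filter_biallelic(gm)
    assert [s.position for s in out.sites] == [2]
    assert out.strains == gm.strains


def test_filter_biallelic_matches_naive_oracle(rng):
    for _ in range(20):
        gm = random_gm(rng, n_sites=30, n_strains=6, missing_rate=0.3)
        expected = [
            i
            for i in range(gm.n_sites)
            if len({int(c) for c in gm.calls[i] if c != MISSING}) == 2
        ]
        out = filter_biallelic(gm)
        assert [s.key for s in out.sites] == [gm.sites[i].key for i in expected]


def test_maf_boundary_is_strict():
    # 24 strains; 6 minor carriers = exactly 25% -> removed; 7 -> retained
    gm6 = gm_from_strings([("I", 1, "G" * 6 + "A" * 18)])
    gm7 = gm_from_strings([("I", 2, "G" * 7 + "A" * 17)])
    spec = MafFilterSpec(0.25)
    assert filter_maf(gm6, spec).n_sites == 0
    assert filter_maf(gm7, spec).n_sites == 1


def test_maf_missing_policy():
    # 2 minor / 6 observed of 10 total: observed 0.333 > 0.25, total 0.2 <= 0.25
    gm = gm_from_strings([("I", 1, "GGAAAA....")])
    assert filter_maf(gm, MafFilterSpec(0.25, "observed")).n_sites == 1
    assert filter_maf(gm, MafFilterSpec(0.25, "total")).n_sites == 0


def test_maf_parameter_domain():
    with pytest.raises(ParameterError):
        MafFilterSpec(0.0)
    with pytest.raises(ParameterError):
        MafFilterSpec(0.6)
    with pytest.raises(ParameterError):
        MafFilterSpec(0.25, "imputed")


def test_maf_limits_and_idempotence(rng):
    gm = filter_biallelic(random_gm(rng, n_sites=50, n_strains=10, missing_rate=0.1))
    tiny = MafFilterSpec(1e-9)
    assert filter_maf(gm, tiny).n_sites == gm.n_sites  # threshold -> 0 keeps all
    assert filter_maf(gm, MafFilterSpec(0.5)).n_sites == 0  # 0.5 > 0.5 never
    spec = MafFilterSpec(0.25)
    once = filter_maf(gm, spec)
    twice = filter_maf(once, spec)
    assert_gm_equal(once, twice)


def test_compose_filters_equals_single_pass_oracle(rng):
    gm = random_gm(rng, n_sites=200, n_strains=9, missing_rate=0.2)
    out = filter_maf(filter_biallelic(gm), MafFilterSpec(0.25))
    expected_keys = []
    for i in range(gm.n_sites):
        obs = [int(c) for c in gm.calls[i] if c != MISSING]
        counts = {v: obs.count(v) for v in set(obs)}
        if len(counts) != 2:
            continue
        if min(counts.values()) / len(obs) > 0.25:
            expected_keys.append(gm.sites[i].key)
    assert [s.key for s in out.sites] == expected_keys


# -------------------------------------------------------------- region query

def test_region_query_fig4a_window():
    gm = gm_from_strings(
        [
            ("IV", 3562957, "AGGA"),
            ("IV", 3562998, "CTTC"),
            ("IV", 3562999, "AGGA"),
            ("IV", 3600000, "ATAT"),
            ("V", 3562999, "ATAT"),
        ]
    )
    sub = region_query(gm, "IV", 3562957, 3562999)
    assert [s.position for s in sub.sites] == [3562957, 3562998, 3562999]
    assert sub.strains == gm.strains


def test_region_query_empty_and_unknown():
    gm = gm_from_strings([("I", 5, "AG")])
    assert region_query(gm, "I", 1, 1).n_sites == 0
    with pytest.raises(ValidationError, match="unknown chromosome"):
        region_query(gm, "XII", 1, 10)
    with pytest.raises(ParameterError):
        region_query(gm, "I", 10, 1)


def test_region_query_matches_linear_scan(rng):
    for _ in range(10):
        gm = random_gm(rng, n_sites=60, n_strains=5, chroms=("I", "II", "III"))
        lo, hi = sorted(rng.integers(1, 10_000, size=2).tolist())
        sub = region_query(gm, "II", lo, hi)
        expected = [
            s.key for s in gm.sites if s.chromosome == "II" and lo <= s.position <= hi
        ]
        assert [s.key for s in sub.sites] == expected
        assert [s.position for s in sub.sites] == sorted(s.position for s in sub.sites)
        assert set(s.key for s in sub.sites) <= set(s.key for s in gm.sites)


def test_parse_region():
    assert parse_region("IV:3562957-3562999") == ("IV", 3562957, 3562999)
    with pytest.raises(ParameterError):
        parse_region("IV")


# ---------------------------------------------------------- chromosome order

def test_roman_numeral_ordering(tmp_path):
    path = tmp_path / "g.tsv"
    path.write_text(
        "site\ts1\ts2\nVII:1\tA\tG\nIV:9\tC\tT\nI:5\tA\tC\n"
    )
    gm = read_genotype_tsv(path)
    assert [s.chromosome for s in gm.sites] == ["I", "IV", "VII"]


def test_non_roman_first_appearance_order():
    key = chromosome_sort_key(["sc22", "sc3", "sc11"])
    assert sorted(["sc11", "sc22", "sc3"], key=key) == ["sc22", "sc3", "sc11"]


# ------------------------------------------------------------------------ VCF

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=IV>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4\n"
)


def test_vcf_haploid_calls(tmp_path):
    path = tmp_path / "x.vcf"
    path.write_text(
        VCF_HEADER + "IV\t3562957\t.\tA\tG\t.\t.\t.\tGT\t0\t1\t.\t1\n"
    )
    gm = read_genotype_vcf(path)
    assert gm.n_sites == 1
    site = gm.sites[0]
    assert (site.chromosome, site.position) == ("IV", 3562957)
    codes = [site.alleles[c] if c != MISSING else "." for c in gm.calls[0]]
    assert codes == ["A", "G", ".", "G"]


def test_vcf_triallelic_skipped(tmp_path):
    path = tmp_path / "x.vcf"
    path.write_text(
        VCF_HEADER + "IV\t100\t.\tA\tG,T\t.\t.\t.\tGT\t0\t1\t2\t0\n"
    )
    gm = read_genotype_vcf(path)
    assert gm.n_sites == 0
    assert gm.skipped_records == 1


def test_vcf_diploid_rejected(tmp_path):
    path = tmp_path / "x.vcf"
    path.write_text(
        VCF_HEADER + "IV\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\t0/0\t1/1\t0/0\n"
    )
    with pytest.raises(ValidationError, match="haploid"):
        read_genotype_vcf(path)
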