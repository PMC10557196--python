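"""Variant I/O: Wilson intervals, VCF parsing/splitting, round trips."""

import math

import pytest

from mitoshift.vcfio import (
    ContigError,
    SampleProfile,
    UndefinedCiError,
    VariantCall,
    VcfFormatError,
    normalize_variant,
    read_tsv,
    read_vcf,
    wilson_ci,
    write_tsv,
    write_vcf,
)

Z = 1.959963984540054


def wilson_textbook(k, n, z=Z):
    """Closed-form Wilson score interval, written independently."""
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    return centre - half, centre + half


@pytest.mark.parametrize("k,n", [(5, 1000), (0, 100), (50, 100), (99, 100), (1, 1)])
def test_wilson_matches_closed_form(k, n):
    lo, hi = wilson_ci(k, n)
    elo, ehi = wilson_textbook(k, n)
    assert lo == pytest.approx(elo, abs=1e-9)
    assert hi == pytest.approx(ehi, abs=1e-9)
    assert 0 <= lo <= hi <= 1


def test_wilson_boundary_and_monotonicity():
    lo0, _ = wilson_ci(0, 100)
    assert lo0 == 0.0
    lows = [wilson_ci(k, 200)[0] for k in range(0, 201, 10)]
    assert lows == sorted(lows)
    lo, hi = wilson_ci(50, 100)
    assert 0.5 - lo == pytest.approx(hi - 0.5, abs=1e-12)
    with pytest.raises(UndefinedCiError):
        wilson_ci(0, 0)


def _call(pos, ref, alt, hl=0.3, depth=800, **kw):
    k = int(round(hl * depth))
    lo, hi = wilson_ci(k, depth)
    return VariantCall(
        "S1", "biopsy", pos, ref, alt, k, depth, round(hl, 6),
        round(min(lo, hl), 6), round(max(hi, hl), 6), **kw
    )


def test_variantcall_invariants():
    with pytest.raises(ValueError):
        VariantCall("S", "biopsy", 5, "A", "G", 10, 100, 0.1, 0.2, 0.3)
    with pytest.raises(ValueError):
        VariantCall("S", "biopsy", 5, "A", "G", 200, 100, 0.5, 0.4, 0.6)
    v = _call(8000, "C", "CA")
    assert v.var_class == "insertion"
    assert _call(8000, "CA", "C").var_class == "deletion"
    assert _call(8000, "C", "T").var_class == "SNV"


def test_read_fixture_passthrough(fixture_vcfs):
    profile = read_vcf(fixture_vcfs["biopsy"], "F001", "biopsy")
    by_key = {v.position: v for v in profile.variants if not v.multiallelic_site}
    assert by_key[16093].hl == pytest.approx(0.52)
    assert by_key[16093].depth == 800
    multi = [v for v in profile.variants if v.multiallelic_site]
    assert len(multi) == 4  # two sites x two alternates
    assert {v.position for v in multi} == {7000, 7100}


def test_multiallelic_split_conserves_alleles(fixture_vcfs):
    profile = read_vcf(fixture_vcfs["biopsy"], "F001", "biopsy")
    site = [v for v in profile.variants if v.position == 7000]
    assert len(site) == 2 and all(v.multiallelic_site for v in site)
    assert sorted(round(v.hl, 2) for v in site) == [0.03, 0.40]


def test_hf_precedence_over_allelic_depths(tmp_path, ann):
    """When HF and AD disagree, the explicit HF field wins."""
    vcf = tmp_path / "hf.vcf"
    ref = ann.base(5000)
    alt = "A" if ref != "A" else "G"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chrM,length=16569>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
        '##FORMAT=<ID=HF,Number=A,Type=Float,Description="h">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        f"chrM\t5000\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:HF:DP:AD\t0/1:0.4:1000:900,100\n"
    )
    profile = read_vcf(vcf, "S1", "biopsy")
    assert profile.variants[0].hl == pytest.approx(0.4)


def test_ad_fallback_and_format_error(tmp_path, ann):
    ref = ann.base(5000)
    alt = "A" if ref != "A" else "G"
    header = (
        "##fileformat=VCFv4.2\n##contig=<ID=chrM,length=16569>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
    )
    ok = tmp_path / "ad.vcf"
    ok.write_text(header + f"chrM\t5000\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:DP:AD\t0/1:1000:900,100\n")
    v = read_vcf(ok, "S1", "biopsy").variants[0]
    assert v.hl == pytest.approx(0.1)
    assert v.ci_low < 0.1 < v.ci_high  # Wilson CI filled in

    bad = tmp_path / "bad.vcf"
    bad.write_text(header.replace(":AD", "") + f"chrM\t5000\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:DP\t0/1:1000\n")
    with pytest.raises(VcfFormatError):
        read_vcf(bad, "S1", "biopsy")


def test_non_mitochondrial_contig_rejected(tmp_path, ann):
    vcf = tmp_path / "contig.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=16569>\n"
        '##FORMAT=<ID=HF,Number=A,Type=Float,Description="h">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        "chr1\t5000\t.\tA\tG\t.\tPASS\t.\tHF:DP\t0.4:1000\n"
    )
    with pytest.raises(ContigError):
        read_vcf(vcf, "S1", "biopsy")


@pytest.mark.parametrize("kind", ["snv", "indel", "multiallelic"])
def test_round_trip(tmp_path, ann, kind):
    """read(write(x)) preserves all retained fields."""
    ref = ann.base(9000)
    alt = "A" if ref != "A" else "G"
    if kind == "snv":
        calls = [_call(9000, ref, alt, 0.52), _call(16093, "T", "C", 0.2)]
    elif kind == "indel":
        calls = [_call(9000, ref, ref + "AC", 0.25), _call(9500, ann.base(9500), alt if ann.base(9500) != alt else "C", 0.4)]
    else:
        others = [b for b in "ACGT" if b != ref]
        calls = [
            _call(9000, ref, others[0], 0.4, multiallelic_site=True),
            _call(9000, ref, others[1], 0.1, multiallelic_site=True),
        ]
    profile = SampleProfile("S1", "biopsy", calls)
    fields = lambda p: sorted(
        (v.position, v.ref, v.alt, v.hl, v.ci_low, v.ci_high, v.alt_reads,
         v.depth, v.multiallelic_site)
        for v in p.variants
    )
    vcf_path = tmp_path / f"{kind}.vcf"
    write_vcf(profile, vcf_path)
    assert fields(read_vcf(vcf_path, "S1", "biopsy")) == fields(profile)
    tsv_path = tmp_path / f"{kind}.tsv"
    write_tsv(profile, tsv_path)
    assert fields(read_tsv(tsv_path)) == fields(profile)


def test_normalize_left_aligns_and_is_idempotent(ann):
    seq = "CCGAAAATG" + ann.sequence[9:]
    # deletion of one A inside the A-run, given right-anchored
    pos, ref, alt = normalize_variant(6, "AA", "A", seq)
    assert (pos, ref, alt) == (3, "GA", "G")
    assert normalize_variant(pos, ref, alt, seq) == (pos, ref, alt)
    # SNV untouched
    assert normalize_variant(16093, "T", "C", ann.sequence) == (16093, "T", "C")
    # shared-prefix MNV trimmed
    assert normalize_variant(100, ann.sequence[99] + "X", ann.sequence[99] + "Y", ann.sequence) == (101, "X", "Y")
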