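"""Reference annotation: coordinate queries, codon effects, CpG, contexts."""

import pytest
from Bio.Seq import Seq

from mitoshift import MT_LENGTH
from mitoshift.annotation import (
    CoordinateError,
    ReferenceMismatchError,
    UnsupportedVariantError,
)


def oracle_effect(ann, feat, position, alt):
    """Brute force: extract the whole CDS, mutate, translate both proteins."""
    cds = "".join(ann.sequence[p - 1] for p in feat.positions())
    idx = position - feat.start if feat.strand == "heavy" else feat.end - position
    sub = alt
    if feat.strand == "light":
        cds = str(Seq(cds).reverse_complement())
        sub = str(Seq(alt).complement())
    pad = (3 - len(cds) % 3) % 3
    cds += "A" * pad
    mut = cds[:idx] + sub + cds[idx + 1 :]
    ref_prot = str(Seq(cds).translate(table=2))
    alt_prot = str(Seq(mut).translate(table=2))
    return "synonymous" if ref_prot == alt_prot else "nonsynonymous"


@pytest.mark.parametrize(
    "position, expected",
    [(16093, {"MT-DLOOP"}), (1888, {"MT-RNR2"}), (10398, {"MT-ND3"})],
)
def test_locate_known_sites(ann, position, expected):
    assert {f.name for f in ann.locate(position)} == expected


def test_locate_rejects_out_of_range(ann):
    with pytest.raises(CoordinateError):
        ann.locate(0)
    with pytest.raises(CoordinateError):
        ann.locate(MT_LENGTH + 1)


def test_region_lengths_partition(ann):
    """Unique bases per region class match the published landscape table."""
    assert ann.class_lengths() == {
        "dloop": 1122,
        "protein": 11341,
        "rRNA": 2513,
        "tRNA": 1504,
    }


def test_dloop_wraps_origin(ann):
    dloop = next(f for f in ann.features if f.kind == "dloop")
    assert dloop.wraps and dloop.length == 1122
    assert dloop.contains(16400) and dloop.contains(200)
    assert not dloop.contains(1000)


def test_seventeen_subregions_inside_dloop(ann):
    assert len(ann.dloop_subregions) == 17
    names = {s.name for s in ann.dloop_subregions}
    assert {"MT-HSP1", "MT-TFH", "MT-TAS2"} <= names
    dloop = next(f for f in ann.features if f.kind == "dloop")
    for s in ann.dloop_subregions:
        assert dloop.contains(s.start) and dloop.contains(s.end)


def test_coding_effect_known_substitutions(ann):
    eff = ann.coding_effect(10398, "A", "G")
    assert eff.per_gene == {"MT-ND3": "nonsynonymous"}
    assert eff.overall == "nonsynonymous"
    assert ann.coding_effect(16093, "T", "C").overall == "noncoding"


def test_coding_effect_fourfold_degenerate_site(ann):
    """The oracle can find a site where every alternate is synonymous."""
    found = None
    for feat in ann.features:
        if feat.kind != "protein" or feat.strand != "heavy":
            continue
        for pos in range(feat.start + 2, min(feat.end, feat.start + 300), 3):
            ref = ann.sequence[pos - 1]
            alts = [a for a in "ACGT" if a != ref]
            if all(
                oracle_effect(ann, feat, pos, a) == "synonymous" for a in alts
            ):
                found = (feat, pos, ref, alts)
                break
        if found:
            break
    assert found is not None
    feat, pos, ref, alts = found
    for alt in alts:
        assert ann.coding_effect(pos, ref, alt).per_gene[feat.name] == "synonymous"


def test_coding_effect_light_strand_gene_sample(ann):
    nd6 = next(f for f in ann.features if f.name == "MT-ND6")
    for pos in range(nd6.start, nd6.start + 60):
        ref = ann.sequence[pos - 1]
        for alt in "ACGT":
            if alt == ref:
                continue
            got = ann.coding_effect(pos, ref, alt).per_gene["MT-ND6"]
            assert got == oracle_effect(ann, nd6, pos, alt)


def test_coding_effect_overlapping_orfs(ann):
    """Positions shared by two reading frames report an effect for each."""
    atp8 = next(f for f in ann.features if f.name == "MT-ATP8")
    atp6 = next(f for f in ann.features if f.name == "MT-ATP6")
    overlap = range(atp6.start, atp8.end + 1)
    assert len(overlap) > 0
    for pos in list(overlap)[:15]:
        ref = ann.sequence[pos - 1]
        alt = "A" if ref != "A" else "G"
        eff = ann.coding_effect(pos, ref, alt)
        assert set(eff.per_gene) == {"MT-ATP8", "MT-ATP6"}
        collapsed = eff.overall
        if "nonsynonymous" in eff.per_gene.values():
            assert collapsed == "nonsynonymous"
        else:
            assert collapsed == "synonymous"


def test_coding_effect_errors(ann):
    ref = ann.sequence[10397]
    wrong = "C" if ref != "C" else "T"
    with pytest.raises(ReferenceMismatchError):
        ann.coding_effect(10398, wrong, "G")
    with pytest.raises(UnsupportedVariantError):
        ann.coding_effect(10398, "AC", "A")


def test_cpg_definition_and_wrap(ann):
    seq = ann.sequence
    for pos in range(1, 2000):
        here = seq[pos - 1]
        nxt = seq[pos % MT_LENGTH]
        prev = seq[(pos - 2) % MT_LENGTH]
        expected = (here == "C" and nxt == "G") or (prev == "C" and here == "G")
        assert ann.is_cpg(pos) == expected
    # wrap pair evaluated circularly
    junction = ann.is_cpg(MT_LENGTH)
    expected = (seq[-1] == "C" and seq[0] == "G") or (
        seq[-2] == "C" and seq[-1] == "G"
    )
    assert junction == expected


def test_cpg_set_strand_symmetric(ann):
    """The CpG site set equals its own reverse-complement image."""
    sites = {p for p in range(1, MT_LENGTH + 1) if ann.is_cpg(p)}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc_seq = "".join(comp[b] for b in reversed(ann.sequence))
    rc_sites = set()
    for p in range(1, MT_LENGTH + 1):
        here = rc_seq[p - 1]
        nxt = rc_seq[p % MT_LENGTH]
        prev = rc_seq[(p - 2) % MT_LENGTH]
        if (here == "C" and nxt == "G") or (prev == "C" and here == "G"):
            rc_sites.add(MT_LENGTH + 1 - p)  # map back to forward coordinates
    assert sites == rc_sites


def test_trinucleotide_context_strand_collapse(ann):
    pos = next(p for p in range(100, 400) if ann.sequence[p - 1] == "C")
    left, right = ann.sequence[pos - 2], ann.sequence[pos]
    assert ann.trinucleotide_context(pos, "C", "T") == f"{left}[C>T]{right}"
    gpos = next(p for p in range(100, 400) if ann.sequence[p - 1] == "G")
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    gl, gr = ann.sequence[gpos - 2], ann.sequence[gpos]
    assert (
        ann.trinucleotide_context(gpos, "G", "A")
        == f"{comp[gr]}[C>T]{comp[gl]}"
    )
    with pytest.raises(UnsupportedVariantError):
        ann.trinucleotide_context(pos, "CA", "C")


def test_trinucleotide_histogram_conserves_counts(ann, small_cohort):
    from mitoshift.mutstats import trinucleotide_spectrum

    truth = small_cohort.truth
    snvs = [
        (int(r.position), r.ref, r.alt)
        for r in truth.itertuples()
        if len(r.ref) == 1 and len(r.alt) == 1
    ]
    hist = trinucleotide_spectrum(snvs, ann)
    assert len(hist) == 96
    assert hist.sum() == len(snvs)
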