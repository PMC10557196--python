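"""Landscape statistics: ratios, spectra, rate and enrichment tests."""

import math
from itertools import product

import numpy as np
import pytest
from scipy import stats as sps

from mitoshift import mutstats
from mitoshift.mutstats import (
    RatioResult,
    UndefinedRatioError,
    bonferroni,
    cpg_ratio,
    dloop_enrichment,
    dn_ds,
    dn_ds_per_gene,
    exact_rate_test,
    hl_group_compare,
    ks_compare,
    poisson_glm_rate_test,
    shift_direction_test,
    spectrum_compare,
    spectrum_counts,
    ti_tv,
)


class FakeShift:
    def __init__(self, region, shift):
        self.region = region
        self.shift = shift


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = prob(a)
    return sum(p for x in range(lo, hi + 1) if (p := prob(x)) <= p_obs * (1 + 1e-9))


def test_ti_tv_counts_and_modes():
    variants = [("A", "G")] * 5 + [("A", "C")]
    assert ti_tv(variants).value == pytest.approx(5.0)
    # A/T exchanges count as transversions in standard mode only
    mixed = [("A", "G")] * 4 + [("A", "T"), ("C", "G")]
    assert ti_tv(mixed, "standard").value == pytest.approx(2.0)
    assert math.isinf(ti_tv(mixed, "paper_literal").value)
    assert ti_tv(mixed, "paper_literal").degenerate
    no_tv = [("A", "G"), ("G", "A"), ("C", "T")]
    r = ti_tv(no_tv)
    assert math.isinf(r.value) and r.degenerate
    with pytest.raises(UndefinedRatioError):
        ti_tv([])


def test_ti_tv_matches_pair_classification_oracle():
    rng = np.random.default_rng(4)
    types = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]
    variants = [types[i] for i in rng.integers(0, 12, size=200)]
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    ti = sum(v in transitions for v in variants)
    r = ti_tv(variants)
    assert (r.numerator, r.denominator) == (ti, 200 - ti)


def test_dn_ds_counts(ann):
    syn, non = [], []
    for feat in ann.features:
        if feat.kind != "protein" or feat.strand != "heavy":
            continue
        for pos in range(feat.start, feat.end - 2):
            ref = ann.sequence[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                eff = ann.coding_effect(pos, ref, alt).overall
                if eff == "synonymous" and len(syn) < 6:
                    syn.append((pos, ref, alt))
                elif eff == "nonsynonymous" and len(non) < 7:
                    non.append((pos, ref, alt))
            if len(syn) >= 6 and len(non) >= 7:
                break
        if len(syn) >= 6 and len(non) >= 7:
            break
    r = dn_ds(non + syn, ann)
    assert (r.numerator, r.denominator) == (7, 6)
    assert r.value == pytest.approx(7 / 6)
    all_syn = dn_ds(syn, ann)
    assert all_syn.value == 0.0
    per_gene = dn_ds_per_gene(non + syn, ann)
    assert per_gene["nonsynonymous"].sum() >= 7
    assert per_gene.loc[per_gene["synonymous"] == 0, "degenerate"].all()


def test_dn_ds_recovers_generator_labels(small_cohort, ann):
    """Pipeline dN/dS equals the ratio of planted effect labels exactly."""
    truth = small_cohort.truth
    coding = truth[truth.effect.isin(["synonymous", "nonsynonymous"])]
    r = dn_ds(
        [(int(t.position), t.ref, t.alt) for t in coding.itertuples()], ann
    )
    assert r.numerator == int((coding.effect == "nonsynonymous").sum())
    assert r.denominator == int((coding.effect == "synonymous").sum())


def test_cpg_ratio(ann):
    cpg_pos = [p for p in range(1, 3000) if ann.is_cpg(p)]
    non_pos = [p for p in range(1, 3000) if not ann.is_cpg(p)]
    mk = lambda p: (p, ann.sequence[p - 1], "A" if ann.sequence[p - 1] != "A" else "G")
    r = cpg_ratio([mk(p) for p in cpg_pos[:1]] + [mk(p) for p in non_pos[:9]], ann)
    assert r.value == pytest.approx(1 / 9)
    assert cpg_ratio([mk(p) for p in non_pos[:5]], ann).value == 0.0
    # exact recovery of planted CpG labels
    truth = [mk(p) for p in cpg_pos[:7]] + [mk(p) for p in non_pos[:13]]
    r = cpg_ratio(truth, ann)
    assert (r.numerator, r.denominator) == (7, 13)


def test_spectrum_identical_groups_p_one():
    group = [("C", "T")] * 5 + [("T", "A")] * 3 + [("G", "A")] * 2
    df = spectrum_compare(group, list(group))
    assert np.allclose(df.loc[~df["skipped"], "p_raw"], 1.0)
    counts = spectrum_counts(group)
    assert counts.sum() == 10
    assert counts["C>T"] == 7  # G>A collapses onto C>T


def test_spectrum_fisher_matches_enumeration():
    a = [("C", "T")] * 10
    b = [("T", "A")] * 10
    df = spectrum_compare(a, b)
    expected = fisher_oracle(10, 0, 0, 10)
    assert df.loc["C>T", "p_raw"] == pytest.approx(expected, rel=1e-9)
    assert df["count_a"].sum() == 10 and df["count_b"].sum() == 10
    twelve = spectrum_compare(a, b, "twelve_class")
    assert len(twelve) == 12


def test_spectrum_empty_group_flagged():
    df = spectrum_compare([("C", "T")], [])
    assert df["skipped"].all()


def test_shift_direction_closed_forms():
    up10 = [FakeShift("dloop", +0.1)] * 10
    df = shift_direction_test(up10)
    assert df.loc["dloop", "p_raw"] == pytest.approx(2 * 0.5**10)
    balanced = [FakeShift("gene", +0.1)] * 8 + [FakeShift("gene", -0.1)] * 8
    df = shift_direction_test(balanced)
    assert df.loc["gene", "p_raw"] == pytest.approx(1.0)
    # ties excluded, and k vs n-k symmetry
    with_ties = balanced + [FakeShift("gene", 0.0)] * 5
    assert shift_direction_test(with_ties).loc["gene", "p_raw"] == pytest.approx(1.0)
    for n in (5, 12):
        for k in range(n + 1):
            pa = shift_direction_test(
                [FakeShift("r", 1)] * k + [FakeShift("r", -1)] * (n - k)
            ).loc["r", "p_raw"]
            pb = shift_direction_test(
                [FakeShift("r", 1)] * (n - k) + [FakeShift("r", -1)] * k
            ).loc["r", "p_raw"]
            assert pa == pytest.approx(pb)


def test_exact_rate_test_symmetry_and_glm_agreement():
    assert exact_rate_test(10, 10, 1122.0, 1122.0) == pytest.approx(1.0)
    assert math.isnan(exact_rate_test(0, 0, 10.0, 10.0))
    # asymptotic GLM agrees with the exact test at large counts
    p_exact = exact_rate_test(200, 120, 5e4, 5e4)
    p_glm = poisson_glm_rate_test(200, 120, 5e4, 5e4)
    assert p_glm == pytest.approx(p_exact, rel=0.25)
    assert p_exact < 1e-4


def test_region_rate_compare_shapes(small_cohort, ann):
    from mitoshift.refine import apply_refinement

    refined_b = [apply_refinement(b)[0] for b, _ in small_cohort.pairs]
    refined_w = [apply_refinement(w)[0] for _, w in small_cohort.pairs]
    df = mutstats.region_rate_compare(refined_b, refined_w, ann)
    assert set(df["kind"]) <= {"dloop", "protein", "rRNA", "tRNA"}
    tested = df[~df["skipped"]]
    assert (tested["count_a"] + tested["count_b"] > 0).all()
    assert (tested["p_adjusted"] >= tested["p_raw"] - 1e-12).all()
    with pytest.raises(ValueError):
        mutstats.region_rate_compare(refined_b, refined_w, ann, method="bogus")


def test_dloop_enrichment_null_false_positive_rate(ann):
    """Uniform events: corrected significance is rare across sub-regions."""
    dloop = next(f for f in ann.features if f.kind == "dloop")
    positions = np.array(list(dloop.positions()))
    significant = tested = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        events = [
            (int(p), "T", "C")
            for p in positions[rng.integers(0, len(positions), size=60)]
        ]
        for r in dloop_enrichment(events, ann, n_samples=50):
            tested += 1
            significant += r.p_adjusted < 0.05
    assert tested == 17 * 20
    assert significant / tested < 0.05


def test_dloop_enrichment_oracle(ann):
    rng = np.random.default_rng(9)
    dloop = next(f for f in ann.features if f.kind == "dloop")
    positions = list(dloop.positions())
    events = [
        (int(positions[i]), "T", "C")
        for i in rng.integers(0, len(positions), size=60)
    ]
    results = dloop_enrichment(events, ann, n_samples=50)
    assert len(results) == 17
    for r in results:
        a, b, c, d = r.counts
        assert a + c == len(events)
        if b * c:
            assert r.odds_ratio == pytest.approx((a * d) / (b * c))
        assert r.p_raw == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-6)
        assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * 17))


def test_dloop_enrichment_detects_planted_hotspot(ann):
    """Events concentrated in MT-HSP1 come out with a large, significant OR."""
    rng = np.random.default_rng(10)
    hsp1 = next(s for s in ann.dloop_subregions if s.name == "MT-HSP1")
    dloop = next(f for f in ann.features if f.kind == "dloop")
    background = [p for p in dloop.positions() if not hsp1.contains(p)]
    events = [(int(p), "T", "C") for p in rng.choice(background, size=40)]
    events += [
        (int(rng.integers(hsp1.start, hsp1.end + 1)), "T", "C") for _ in range(25)
    ]
    results = {r.subregion: r for r in dloop_enrichment(events, ann, n_samples=50)}
    top = results["MT-HSP1"]
    assert top.odds_ratio > 5
    assert top.p_adjusted < 1e-6


def test_subregion_outside_dloop_rejected(ann):
    from mitoshift.annotation import Subregion

    with pytest.raises(ValueError):
        dloop_enrichment([], ann, 1, subregions=[Subregion("BAD", 5000, 5100)])


def test_hl_group_compare():
    rng = np.random.default_rng(2)
    a = rng.uniform(10, 20, size=20)
    b = a - 9.5
    stat, p = hl_group_compare(a, b)
    assert p < 1e-5
    # invariant under monotone transform of the pooled data
    _, p_log = hl_group_compare(np.log(a), np.log(b))
    assert p_log == pytest.approx(p)
    _, p_tied = hl_group_compare([1.0, 1.0], [1.0, 1.0])
    assert p_tied == 1.0
    with pytest.raises(ValueError):
        hl_group_compare([], [1.0])


def test_ks_compare():
    assert ks_compare([1, 2, 3], [1, 2, 3])[1] == pytest.approx(1.0)
    rng = np.random.default_rng(3)
    stat, p = ks_compare(rng.normal(0, 1, 200), rng.normal(2, 1, 200))
    assert p < 1e-10 and 0 < stat <= 1


def test_bonferroni_properties():
    rng = np.random.default_rng(5)
    p = rng.uniform(size=40)
    adj = bonferroni(p)
    assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
    assert (bonferroni(p, 80) >= adj - 1e-15).all()  # monotone in test count
    assert bonferroni([0.5], 3)[0] == pytest.approx(1.0)
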