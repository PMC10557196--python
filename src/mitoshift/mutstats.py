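"""Descriptive and inferential statistics of the mutation landscape.

Count-based summaries (Ti/Tv, dN/dS, CpG ratio, substitution and
trinucleotide spectra) and the tests used to compare them between groups:
Fisher's exact test per spectrum class, exact/GLM Poisson rate comparison
per genomic region, the exact binomial sign test on heteroplasmy-shift
directions, Fisher enrichment of D-loop sub-regions against the remainder
of the control region, Wilcoxon rank-sum and Kolmogorov–Smirnov for
heteroplasmy-level distributions, and Bonferroni correction throughout.

dN/dS here is the plain count ratio (nonsynonymous / synonymous calls in
protein-coding regions) without per-site opportunity normalisation; a
value above 1 is read as positive selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .annotation import GenomeAnnotation, Subregion
from .refine import HETEROPLASMIC, RefinedVariant

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
PAPER_LITERAL_TRANSVERSIONS = {("A", "C"), ("C", "A"), ("T", "G"), ("G", "T")}

SIX_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class UndefinedRatioError(ValueError):
    pass


@dataclass(frozen=True)
class RatioResult:
    """A count ratio with its numerator/denominator and a degeneracy flag."""

    value: float
    numerator: int
    denominator: int

    @property
    def degenerate(self) -> bool:
        return self.denominator == 0


@dataclass(frozen=True)
class EnrichmentResult:
    subregion: str
    odds_ratio: float
    p_raw: float
    p_adjusted: float
    counts: tuple[int, int, int, int]  # a, b, c, d of the 2x2 table


def _alleles(v) -> tuple[str, str]:
    if isinstance(v, tuple):
        return (v[1], v[2]) if len(v) == 3 else (v[0], v[1])
    return v.ref, v.alt


def _position_alleles(v) -> tuple[int, str, str]:
    if isinstance(v, tuple):
        return int(v[0]), v[1], v[2]
    return v.position, v.ref, v.alt


def _snv_only(variants):
    out = []
    for v in variants:
        ref, alt = _alleles(v)
        if len(ref) == 1 and len(alt) == 1:
            out.append(v)
    return out


def bonferroni(p_values, n_tests: int | None = None) -> np.ndarray:
    """p_adjusted = min(1, p_raw * number of tests)."""
    p = np.asarray(p_values, dtype=float)
    m = n_tests if n_tests is not None else p.size
    return np.minimum(1.0, p * m)


# -- count ratios ----------------------------------------------------------


def ti_tv(variants, mode: str = "standard") -> RatioResult:
    """Transition / transversion count ratio.

    ``standard`` counts every non-transition SNV as a transversion;
    ``paper_literal`` counts only A/C and T/G exchanges in the denominator
    (the reduced definition some summary tables print).
    """
    snvs = _snv_only(variants)
    if not snvs:
        raise UndefinedRatioError("Ti/Tv undefined on an empty variant set")
    ti = tv = 0
    for v in snvs:
        pair = _alleles(v)
        if pair in TRANSITIONS:
            ti += 1
        elif mode == "paper_literal":
            tv += pair in PAPER_LITERAL_TRANSVERSIONS
        else:
            tv += 1
    value = ti / tv if tv else math.inf
    return RatioResult(value, ti, tv)


def dn_ds(variants, annotation: GenomeAnnotation | None = None) -> RatioResult:
    """Nonsynonymous / synonymous count ratio over protein-coding SNVs."""
    ann = annotation or GenomeAnnotation.default()
    n_non = n_syn = 0
    for v in _snv_only(variants):
        pos, ref, alt = _position_alleles(v)
        effect = ann.coding_effect(pos, ref, alt).overall
        n_non += effect == "nonsynonymous"
        n_syn += effect == "synonymous"
    value = n_non / n_syn if n_syn else (math.inf if n_non else math.nan)
    return RatioResult(value, n_non, n_syn)


def dn_ds_per_gene(
    variants, annotation: GenomeAnnotation | None = None
) -> pd.DataFrame:
    """Per-gene nonsynonymous/synonymous counts; zero-count genes flagged."""
    ann = annotation or GenomeAnnotation.default()
    counts: dict[str, list[int]] = {
        f.name: [0, 0] for f in ann.features if f.kind == "protein"
    }
    for v in _snv_only(variants):
        pos, ref, alt = _position_alleles(v)
        for gene, effect in ann.coding_effect(pos, ref, alt).per_gene.items():
            counts[gene][effect == "synonymous"] += 1
    rows = []
    for gene, (n_non, n_syn) in counts.items():
        rows.append(
            {
                "gene": gene,
                "nonsynonymous": n_non,
                "synonymous": n_syn,
                "dn_ds": n_non / n_syn if n_syn else np.nan,
                "degenerate": n_syn == 0 or n_non == 0,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def cpg_ratio(variants, annotation: GenomeAnnotation | None = None) -> RatioResult:
    """CpG-site / non-CpG-site mutation count ratio."""
    ann = annotation or GenomeAnnotation.default()
    snvs = _snv_only(variants)
    if not snvs:
        raise UndefinedRatioError("CpG ratio undefined on an empty variant set")
    in_cpg = sum(ann.is_cpg(_position_alleles(v)[0]) for v in snvs)
    out_cpg = len(snvs) - in_cpg
    value = in_cpg / out_cpg if out_cpg else math.inf
    return RatioResult(value, in_cpg, out_cpg)


# -- spectra ---------------------------------------------------------------


def substitution_class(ref: str, alt: str, classes: str = "six_class") -> str:
    if classes == "twelve_class":
        return f"{ref}>{alt}"
    if ref in "GA":  # collapse onto the pyrimidine reference
        ref, alt = _COMP[ref], _COMP[alt]
    return f"{ref}>{alt}"


def spectrum_counts(variants, classes: str = "six_class") -> pd.Series:
    labels = (
        SIX_CLASSES
        if classes == "six_class"
        else tuple(
            f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
        )
    )
    counts = dict.fromkeys(labels, 0)
    for v in _snv_only(variants):
        ref, alt = _alleles(v)
        counts[substitution_class(ref, alt, classes)] += 1
    return pd.Series(counts, name="count")


def spectrum_compare(
    group_a, group_b, classes: str = "six_class"
) -> pd.DataFrame:
    """Per-class counts and Fisher's exact p for two SNV sets."""
    ca = spectrum_counts(group_a, classes)
    cb = spectrum_counts(group_b, classes)
    total_a, total_b = int(ca.sum()), int(cb.sum())
    rows = []
    for cls in ca.index:
        a, b = int(ca[cls]), int(cb[cls])
        if total_a == 0 or total_b == 0:
            p, skipped = np.nan, True
        else:
            table = [[a, total_a - a], [b, total_b - b]]
            p = float(sps.fisher_exact(table)[1])
            skipped = False
        rows.append(
            {
                "class": cls,
                "count_a": a,
                "count_b": b,
                "total_a": total_a,
                "total_b": total_b,
                "p_raw": p,
                "skipped": skipped,
            }
        )
    df = pd.DataFrame(rows).set_index("class")
    df["p_adjusted"] = bonferroni(df["p_raw"].to_numpy(), len(df))
    return df


def trinucleotide_spectrum(
    variants, annotation: GenomeAnnotation | None = None
) -> pd.Series:
    """96-channel pyrimidine-centred trinucleotide histogram."""
    ann = annotation or GenomeAnnotation.default()
    labels = [
        f"{l}[{r}>{a}]{g}"
        for r, alts in (("C", "AGT"), ("T", "ACG"))
        for a in alts
        for l in "ACGT"
        for g in "ACGT"
    ]
    counts = dict.fromkeys(labels, 0)
    for v in _snv_only(variants):
        pos, ref, alt = _position_alleles(v)
        counts[ann.trinucleotide_context(pos, ref, alt)] += 1
    return pd.Series(counts, name="count")


# -- rate comparisons ------------------------------------------------------


def _region_counts(profiles, feature, scope: str) -> int:
    n = 0
    for refined in profiles:
        for rv in refined:
            if scope == "heteroplasmic" and rv.plasmy != HETEROPLASMIC:
                continue
            if scope == "homoplasmic" and rv.plasmy != "homoplasmic":
                continue
            n += feature.contains(rv.position)
    return n


def exact_rate_test(
    count_a: int, count_b: int, exposure_a: float, exposure_b: float
) -> float:
    """Two-Poisson comparison conditioned on the total (exact binomial)."""
    total = count_a + count_b
    if total == 0:
        return math.nan
    p0 = exposure_a / (exposure_a + exposure_b)
    return float(sps.binomtest(count_a, total, p0).pvalue)


def poisson_glm_rate_test(
    count_a: int, count_b: int, exposure_a: float, exposure_b: float
) -> float:
    """Wald p for the group effect in a Poisson log-linear model with offset."""
    y = np.array([count_a, count_b])
    X = np.array([[1.0, 1.0], [1.0, 0.0]])  # col 2: group A indicator
    offset = np.log([exposure_a, exposure_b])
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    res = model.fit()
    return float(res.pvalues[1])


def region_rate_compare(
    group_a_profiles,
    group_b_profiles,
    annotation: GenomeAnnotation | None = None,
    method: str = "exact_conditional",
    scope: str = "heteroplasmic",
) -> pd.DataFrame:
    """Per-region mutation rate ratio between two groups of refined profiles.

    Counts are modelled against an exposure of region length × number of
    samples.  ``exact_conditional`` conditions the two Poisson counts on
    their sum (exact at small counts); ``poisson_glm`` fits the log-linear
    model the asymptotic way.
    """
    if method not in ("exact_conditional", "poisson_glm"):
        raise ValueError(f"unknown method {method!r}")
    ann = annotation or GenomeAnnotation.default()
    n_a, n_b = len(group_a_profiles), len(group_b_profiles)
    rows = []
    for feat in ann.features:
        ka = _region_counts(group_a_profiles, feat, scope)
        kb = _region_counts(group_b_profiles, feat, scope)
        ea, eb = feat.length * n_a, feat.length * n_b
        if ka + kb == 0:
            rows.append(
                {
                    "region": feat.name, "kind": feat.kind, "length": feat.length,
                    "count_a": ka, "count_b": kb,
                    "rate_a": 0.0, "rate_b": 0.0,
                    "rate_ratio": np.nan, "p_raw": np.nan, "skipped": True,
                }
            )
            continue
        rate_a, rate_b = ka / ea, kb / eb
        ratio = rate_a / rate_b if rate_b else math.inf
        p = (
            exact_rate_test(ka, kb, ea, eb)
            if method == "exact_conditional"
            else poisson_glm_rate_test(ka, kb, ea, eb)
        )
        rows.append(
            {
                "region": feat.name, "kind": feat.kind, "length": feat.length,
                "count_a": ka, "count_b": kb,
                "rate_a": rate_a, "rate_b": rate_b,
                "rate_ratio": ratio, "p_raw": p, "skipped": False,
            }
        )
    df = pd.DataFrame(rows).set_index("region")
    tested = ~df["skipped"]
    df["p_adjusted"] = np.nan
    df.loc[tested, "p_adjusted"] = bonferroni(
        df.loc[tested, "p_raw"].to_numpy(), int(tested.sum())
    )
    return df


# -- shift direction sign test --------------------------------------------


def shift_direction_test(categorized) -> pd.DataFrame:
    """Exact binomial test of positive vs negative HL shifts per region.

    Zero shifts are excluded (a sign test is undefined for ties); regions
    with no nonzero shift are skipped; Bonferroni across tested regions.
    """
    by_region: dict[str, list[float]] = {}
    for v in categorized:
        by_region.setdefault(v.region, []).append(v.shift)
    rows = []
    for region, shifts in sorted(by_region.items()):
        nonzero = [s for s in shifts if s != 0]
        n_up = sum(s > 0 for s in nonzero)
        n_down = len(nonzero) - n_up
        if not nonzero:
            rows.append(
                {
                    "region": region, "n_up": 0, "n_down": 0,
                    "p_raw": np.nan, "skipped": True,
                }
            )
            continue
        p = float(sps.binomtest(n_up, len(nonzero), 0.5).pvalue)
        rows.append(
            {
                "region": region, "n_up": n_up, "n_down": n_down,
                "p_raw": p, "skipped": False,
            }
        )
    df = pd.DataFrame(rows).set_index("region")
    tested = ~df["skipped"]
    df["p_adjusted"] = np.nan
    df.loc[tested, "p_adjusted"] = bonferroni(
        df.loc[tested, "p_raw"].to_numpy(), int(tested.sum())
    )
    return df


# -- D-loop sub-region enrichment -----------------------------------------


def dloop_enrichment(
    heteroplasmies,
    annotation: GenomeAnnotation | None = None,
    n_samples: int = 1,
    subregions: list[Subregion] | None = None,
) -> list[EnrichmentResult]:
    """Fisher enrichment of each control-region element vs the D-loop remainder.

    Each 2×2 table compares heteroplasmic events against non-event
    base-pair opportunities (length × number of samples − events) inside
    versus outside the sub-region, within the D-loop only.
    """
    ann = annotation or GenomeAnnotation.default()
    subs = subregions if subregions is not None else ann.dloop_subregions
    dloop = next(f for f in ann.features if f.kind == "dloop")
    for s in subs:
        if not (dloop.contains(s.start) and dloop.contains(s.end)):
            raise ValueError(f"sub-region {s.name} lies outside the D-loop")
    positions = [
        _position_alleles(v)[0]
        for v in heteroplasmies
        if dloop.contains(_position_alleles(v)[0])
    ]
    total_events = len(positions)
    dloop_opportunity = dloop.length * n_samples
    results = []
    raw_p = []
    for s in subs:
        a = sum(s.contains(p) for p in positions)  # events inside
        c = total_events - a  # events in the remainder
        b = s.length * n_samples - a  # non-event opportunities inside
        d = (dloop_opportunity - s.length * n_samples) - c
        if b < 0 or d < 0:
            raise ValueError(f"sub-region {s.name} saturated by events")
        p = float(sps.fisher_exact([[a, b], [c, d]])[1])
        odds = (a * d) / (b * c) if b * c else math.inf
        raw_p.append(p)
        results.append((s.name, odds, p, (a, b, c, d)))
    adj = bonferroni(raw_p, len(subs))
    return [
        EnrichmentResult(name, odds, p, float(pa), counts)
        for (name, odds, p, counts), pa in zip(results, adj)
    ]


# -- distribution comparisons ---------------------------------------------


def hl_group_compare(group_a_hls, group_b_hls) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p for two HL samples.

    Exact for small tie-free samples, normal approximation with tie
    correction otherwise; fully tied input returns p = 1.
    """
    a = np.asarray(list(group_a_hls), dtype=float)
    b = np.asarray(list(group_b_hls), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2), 1.0
    method = "exact" if (
        a.size <= 50 and b.size <= 50 and np.unique(pooled).size == pooled.size
    ) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def ks_compare(dist_a, dist_b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov statistic and p."""
    a = np.asarray(list(dist_a), dtype=float)
    b = np.asarray(list(dist_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    res = sps.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)
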