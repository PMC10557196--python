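"""Reading, normalising and writing per-sample mitochondrial variant calls.

One :class:`VariantCall` is one alternate allele at one reference position
in one sample, with its heteroplasmy level (HL = alt reads / depth), a 95%
confidence interval on that fraction, and the site depth.  VCF handling is
delegated to :mod:`pysam`; multi-allelic records are split into per-allele
calls, indels are left-aligned against the loaded reference, and the
mitochondrial contig name is accepted under its common aliases.

Heteroplasmy fractions and CI bounds are rounded to six decimals on both
read and write so a write/read cycle is exact despite VCF single-precision
FORMAT floats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import pysam
from statsmodels.stats.proportion import proportion_confint

from .annotation import MT_LENGTH, GenomeAnnotation

MT_CONTIG_ALIASES = {"chrM", "MT", "chrMT", "NC_012920.1"}

_ROUND = 6


class VcfFormatError(ValueError):
    """A record lacks both a heteroplasmy fraction and allelic depths."""


class ContigError(ValueError):
    """A record sits on a non-mitochondrial contig."""


class UndefinedCiError(ValueError):
    """Confidence interval requested at zero depth."""


@dataclass(frozen=True)
class VariantCall:
    """One alternate allele at one position in one sample."""

    sample_id: str
    tissue: str  # biopsy | blood | plasma
    position: int  # 1-based
    ref: str
    alt: str
    alt_reads: int
    depth: int
    hl: float
    ci_low: float
    ci_high: float
    multiallelic_site: bool = False

    @property
    def var_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def is_snv(self) -> bool:
        return self.var_class == "SNV"

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref, self.alt)

    def __post_init__(self):
        if not 0.0 <= self.ci_low <= self.hl <= self.ci_high <= 1.0:
            raise ValueError(
                f"CI/HL ordering violated at {self.position}: "
                f"{self.ci_low} <= {self.hl} <= {self.ci_high}"
            )
        if self.alt_reads > self.depth:
            raise ValueError(f"alt_reads > depth at {self.position}")


@dataclass
class SampleProfile:
    """All calls of one sample, at most one record per (position, ref, alt)."""

    sample_id: str
    tissue: str
    variants: list[VariantCall] = field(default_factory=list)

    @property
    def mean_depth(self) -> float:
        if not self.variants:
            return float("nan")
        return sum(v.depth for v in self.variants) / len(self.variants)

    def dedupe(self) -> "SampleProfile":
        seen: dict[tuple, VariantCall] = {}
        for v in self.variants:
            seen[v.key] = v
        return SampleProfile(self.sample_id, self.tissue, list(seen.values()))


def wilson_ci(
    alt_reads: int, depth: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for the binomial heteroplasmy fraction."""
    if depth < 1:
        raise UndefinedCiError("depth must be >= 1 for a confidence interval")
    if not 0 <= alt_reads <= depth:
        raise ValueError("alt_reads must lie in [0, depth]")
    low, high = proportion_confint(
        alt_reads, depth, alpha=1 - confidence, method="wilson"
    )
    if alt_reads == 0:
        low = 0.0
    if alt_reads == depth:
        high = 1.0
    return float(low), float(high)


def normalize_variant(
    position: int, ref: str, alt: str, sequence: str
) -> tuple[int, str, str]:
    """Trim shared bases and left-align an indel against the reference.

    Indels shifting across the circular origin are disallowed.
    """
    ref, alt = ref.upper(), alt.upper()
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif len(ref) != len(alt) and ref and alt and ref[-1] == alt[-1]:
            # extend left so the shared trailing base can be dropped
            if position <= 1:
                raise ValueError("indel left-alignment crossed the circular origin")
            base = sequence[position - 2]
            position -= 1
            ref, alt = base + ref[:-1], base + alt[:-1]
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return position, ref, alt


def _round_frac(x: float) -> float:
    return round(min(1.0, max(0.0, float(x))), _ROUND)


def read_vcf(
    path: str | Path,
    sample_id: str | None = None,
    tissue: str = "biopsy",
    annotation: GenomeAnnotation | None = None,
) -> SampleProfile:
    """Read one sample's calls from a VCF 4.x file.

    Per-allele heteroplasmy is taken from FORMAT/HF when present,
    otherwise reconstructed from FORMAT/AD; missing CI bounds are filled
    with the Wilson interval at the call's depth.
    """
    annotation = annotation or GenomeAnnotation.default()
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        file_samples = list(vcf.header.samples)
        if sample_id is None:
            sample_id = file_samples[0] if file_samples else Path(path).stem
        for rec in vcf:
            if rec.chrom not in MT_CONTIG_ALIASES:
                raise ContigError(f"non-mitochondrial contig {rec.chrom!r}")
            calls.extend(
                _split_record(rec, file_samples, sample_id, tissue, annotation)
            )
    return SampleProfile(sample_id, tissue, calls).dedupe()


def _split_record(rec, file_samples, sample_id, tissue, annotation):
    alts = [a for a in (rec.alts or []) if a and a != "."]
    if not alts:
        return []
    try:
        multi_flag = bool(rec.info.get("MULTIALLELIC", False))
    except ValueError:  # key absent from the header
        multi_flag = False
    multi = len(alts) > 1 or multi_flag
    fmt = rec.samples[file_samples[0]] if file_samples else None

    def _per_allele(key):
        if fmt is not None and key in fmt and fmt[key] is not None:
            val = fmt[key]
            return list(val) if isinstance(val, tuple) else [val]
        if key in rec.info:
            val = rec.info[key]
            return list(val) if isinstance(val, tuple) else [val]
        return None

    hfs = _per_allele("HF")
    ci_lows = _per_allele("CI_LOW")
    ci_highs = _per_allele("CI_HIGH")
    ads = _per_allele("AD")
    dp = _per_allele("DP")
    depth = int(dp[0]) if dp else (sum(ads) if ads else None)
    if depth is None:
        raise VcfFormatError(f"no DP or AD at {rec.chrom}:{rec.pos}")

    out = []
    for i, alt in enumerate(alts):
        if hfs is not None and i < len(hfs) and hfs[i] is not None:
            hl = float(hfs[i])  # HF takes precedence over allelic depths
            alt_reads = int(round(hl * depth))
        elif ads is not None and len(ads) > i + 1:
            alt_reads = int(ads[i + 1])
            hl = alt_reads / depth if depth else 0.0
        else:
            raise VcfFormatError(
                f"record {rec.chrom}:{rec.pos} has neither HF nor AD for "
                f"allele {alt}"
            )
        hl = _round_frac(hl)
        if ci_lows is not None and ci_highs is not None and i < len(ci_lows):
            lo, hi = float(ci_lows[i]), float(ci_highs[i])
        else:
            lo, hi = wilson_ci(alt_reads, depth)
        lo = min(_round_frac(lo), hl)
        hi = max(_round_frac(hi), hl)
        pos, ref, alt_n = normalize_variant(
            rec.pos, rec.ref, alt, annotation.sequence
        )
        out.append(
            VariantCall(
                sample_id=sample_id,
                tissue=tissue,
                position=pos,
                ref=ref,
                alt=alt_n,
                alt_reads=min(alt_reads, depth),
                depth=depth,
                hl=hl,
                ci_low=lo,
                ci_high=hi,
                multiallelic_site=multi,
            )
        )
    return out


def _vcf_header(sample_id: str) -> pysam.VariantHeader:
    hdr = pysam.VariantHeader()
    hdr.add_line(f"##contig=<ID=chrM,length={MT_LENGTH}>")
    hdr.add_line(
        '##INFO=<ID=MULTIALLELIC,Number=0,Type=Flag,'
        'Description="Site had more than one alternate allele before splitting">'
    )
    hdr.add_line(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    hdr.add_line(
        '##FORMAT=<ID=HF,Number=A,Type=Float,'
        'Description="Heteroplasmy fraction of the alternate allele">'
    )
    hdr.add_line(
        '##FORMAT=<ID=CI_LOW,Number=A,Type=Float,'
        'Description="Lower 95% bound of the heteroplasmy fraction">'
    )
    hdr.add_line(
        '##FORMAT=<ID=CI_HIGH,Number=A,Type=Float,'
        'Description="Upper 95% bound of the heteroplasmy fraction">'
    )
    hdr.add_line(
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">'
    )
    hdr.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    hdr.add_sample(sample_id)
    return hdr


def write_vcf(profile: SampleProfile, path: str | Path) -> None:
    """Write a profile as a single-sample uncompressed VCF (one line per allele)."""
    hdr = _vcf_header(profile.sample_id)
    with pysam.VariantFile(str(path), "w", header=hdr) as out:
        for v in sorted(profile.variants, key=lambda x: x.key):
            rec = out.new_record(
                contig="chrM",
                start=v.position - 1,
                alleles=(v.ref, v.alt),
            )
            if v.multiallelic_site:
                rec.info["MULTIALLELIC"] = True
            smp = rec.samples[profile.sample_id]
            smp["GT"] = (0, 1)
            smp["HF"] = (v.hl,)
            smp["CI_LOW"] = (v.ci_low,)
            smp["CI_HIGH"] = (v.ci_high,)
            smp["DP"] = v.depth
            smp["AD"] = (v.depth - v.alt_reads, v.alt_reads)
            out.write(rec)


_TSV_COLUMNS = [
    "sample_id", "tissue", "position", "ref", "alt", "var_class",
    "alt_reads", "depth", "hl", "ci_low", "ci_high", "multiallelic_site",
]


def write_tsv(profile: SampleProfile, path: str | Path) -> None:
    rows = [
        {c: getattr(v, c) for c in _TSV_COLUMNS}
        for v in sorted(profile.variants, key=lambda x: x.key)
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> SampleProfile:
    df = pd.read_csv(path, sep="\t")
    calls = [
        VariantCall(
            sample_id=str(r.sample_id),
            tissue=str(r.tissue),
            position=int(r.position),
            ref=str(r.ref),
            alt=str(r.alt),
            alt_reads=int(r.alt_reads),
            depth=int(r.depth),
            hl=float(r.hl),
            ci_low=float(r.ci_low),
            ci_high=float(r.ci_high),
            multiallelic_site=bool(r.multiallelic_site),
        )
        for r in df.itertuples()
    ]
    if calls:
        return SampleProfile(calls[0].sample_id, calls[0].tissue, calls)
    return SampleProfile(Path(path).stem, "biopsy", [])


def read_manifest(path: str | Path) -> list[dict]:
    """Manifest TSV with columns subject_id, biopsy_vcf, blood_vcf."""
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "biopsy_vcf", "blood_vcf"}
    if not required.issubset(df.columns):
        raise VcfFormatError(f"manifest must have columns {sorted(required)}")
    base = Path(path).parent
    out = []
    for r in df.itertuples():
        out.append(
            {
                "subject_id": str(r.subject_id),
                "biopsy_vcf": str((base / r.biopsy_vcf)),
                "blood_vcf": str((base / r.blood_vcf)),
            }
        )
    return out
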