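"""End-to-end driver: refine → classify → stats → enrich (→ assoc).

Each stage is a pure function from files to files so that ``run_all`` is
literally the composition of the stage functions on intermediate
artifacts; the single report JSON aggregates the per-stage outputs.  All
randomness in upstream simulation is routed through one seed recorded in
the report.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import mutstats
from .annotation import GenomeAnnotation
from .assoc import CaseControlModel
from .pairs import (
    CategorizedVariant,
    PairedProfile,
    categorize_pair,
    categorized_frame,
    shift_profile,
)
from .refine import HETEROPLASMIC, QcConfig, RefinedVariant, apply_refinement
from .vcfio import SampleProfile, VariantCall, read_manifest, read_vcf, write_vcf

SCHEMA_VERSION = 1

_REFINED_COLUMNS = [
    "sample_id", "tissue", "position", "ref", "alt", "alt_reads", "depth",
    "hl", "ci_low", "ci_high", "multiallelic_site", "plasmy",
]


def load_qc_config(path: str | Path | None) -> QcConfig:
    """QcConfig from a TOML file (missing keys keep their defaults)."""
    if path is None:
        return QcConfig()
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    if "blacklist" in raw:
        raw["blacklist"] = tuple(tuple(iv) for iv in raw["blacklist"])
    return QcConfig(**raw)


def write_refined_tsv(
    sample_id: str, tissue: str, refined: list[RefinedVariant], path: Path
) -> None:
    rows = []
    for rv in sorted(refined, key=lambda r: r.key):
        row = {c: getattr(rv.call, c) for c in _REFINED_COLUMNS[:-1]}
        row["plasmy"] = rv.plasmy
        rows.append(row)
    pd.DataFrame(rows, columns=_REFINED_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_refined_tsv(path: str | Path) -> list[RefinedVariant]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        call = VariantCall(
            sample_id=str(r.sample_id), tissue=str(r.tissue),
            position=int(r.position), ref=str(r.ref), alt=str(r.alt),
            alt_reads=int(r.alt_reads), depth=int(r.depth), hl=float(r.hl),
            ci_low=float(r.ci_low), ci_high=float(r.ci_high),
            multiallelic_site=bool(r.multiallelic_site),
        )
        out.append(RefinedVariant(call, str(r.plasmy)))
    return out


def stage_refine(
    manifest_path: str | Path,
    out_dir: str | Path,
    qc: QcConfig | None = None,
    annotation: GenomeAnnotation | None = None,
) -> Path:
    """Refine every profile in a manifest; emit refined TSV/VCF and audits."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    qc = qc or QcConfig()
    ann = annotation or GenomeAnnotation.default()
    audits = {}
    rows = []
    for entry in read_manifest(manifest_path):
        sid = entry["subject_id"]
        row = {"subject_id": sid}
        for tissue in ("biopsy", "blood"):
            profile = read_vcf(entry[f"{tissue}_vcf"], sid, tissue, ann)
            refined, audit = apply_refinement(profile, qc)
            audits[f"{sid}_{tissue}"] = audit
            tsv = out / f"{sid}_{tissue}.refined.tsv"
            write_refined_tsv(sid, tissue, refined, tsv)
            write_vcf(
                SampleProfile(sid, tissue, [rv.call for rv in refined]),
                out / f"{sid}_{tissue}.refined.vcf",
            )
            row[f"{tissue}_refined"] = tsv.name
        rows.append(row)
    manifest = out / "refined_manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    with open(out / "refinement_audit.json", "w") as fh:
        json.dump(_jsonable(audits), fh, indent=1)
    return manifest


def _read_refined_manifest(path: str | Path) -> list[PairedProfile]:
    base = Path(path).parent
    pairs = []
    for r in pd.read_csv(path, sep="\t").itertuples():
        pairs.append(
            PairedProfile(
                subject_id=str(r.subject_id),
                biopsy=read_refined_tsv(base / r.biopsy_refined),
                blood=read_refined_tsv(base / r.blood_refined),
            )
        )
    return pairs


def stage_classify(
    refined_manifest: str | Path,
    out_dir: str | Path,
    scope: str = "heteroplasmic_only",
    annotation: GenomeAnnotation | None = None,
) -> Path:
    """Categorize every pair; emit the categorized table and shift summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann = annotation or GenomeAnnotation.default()
    categorized: list[CategorizedVariant] = []
    for pair in _read_refined_manifest(refined_manifest):
        categorized.extend(categorize_pair(pair, scope, ann))
    path = out / "categorized.tsv"
    categorized_frame(categorized).to_csv(path, sep="\t", index=False)
    if categorized:
        shifts, summary = shift_profile(categorized)
        shifts.to_csv(out / "shifts.tsv", sep="\t", index=False)
        summary.to_csv(out / "category_summary.tsv", sep="\t")
    return path


def _categorized_from_tsv(path: str | Path) -> list[CategorizedVariant]:
    df = pd.read_csv(path, sep="\t")
    return [
        CategorizedVariant(
            subject_id=str(r.subject_id), position=int(r.position),
            ref=str(r.ref), alt=str(r.alt), category=str(r.category),
            hl_biopsy=float(r.hl_biopsy), hl_blood=float(r.hl_blood),
            region=str(r.region),
            subregion=None if pd.isna(r.subregion) else str(r.subregion),
        )
        for r in df.itertuples()
    ]


def stage_stats(
    refined_manifest: str | Path,
    categorized_tsv: str | Path,
    out_dir: str | Path,
    annotation: GenomeAnnotation | None = None,
) -> dict:
    """Landscape statistics comparing the biopsy and blood groups."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann = annotation or GenomeAnnotation.default()
    pairs = _read_refined_manifest(refined_manifest)
    biopsy_profiles = [p.biopsy for p in pairs]
    blood_profiles = [p.blood for p in pairs]

    def het_calls(profiles):
        return [
            rv.call
            for profile in profiles
            for rv in profile
            if rv.plasmy == HETEROPLASMIC
        ]

    het_biopsy, het_blood = het_calls(biopsy_profiles), het_calls(blood_profiles)
    categorized = _categorized_from_tsv(categorized_tsv)
    stats: dict = {"n_pairs": len(pairs)}
    for label, calls in (("biopsy", het_biopsy), ("blood", het_blood)):
        if calls:
            titv = mutstats.ti_tv(calls)
            dnds = mutstats.dn_ds(calls, ann)
            cpg = mutstats.cpg_ratio(calls, ann)
            stats[label] = {
                "n_heteroplasmic": len(calls),
                "ti_tv": titv.value, "ti": titv.numerator, "tv": titv.denominator,
                "dn_ds": dnds.value, "dn": dnds.numerator, "ds": dnds.denominator,
                "cpg_ratio": cpg.value,
            }
    if het_biopsy and het_blood:
        spectra = mutstats.spectrum_compare(het_biopsy, het_blood)
        spectra.to_csv(out / "spectrum_compare.tsv", sep="\t")
        rates = mutstats.region_rate_compare(
            biopsy_profiles, blood_profiles, ann
        )
        rates.to_csv(out / "region_rates.tsv", sep="\t")
        stats["spectrum_min_p_adjusted"] = float(
            np.nanmin(spectra["p_adjusted"])
        )
    if categorized:
        shift_tests = mutstats.shift_direction_test(categorized)
        shift_tests.to_csv(out / "shift_direction.tsv", sep="\t")
        stats["shift_direction_regions_tested"] = int(
            (~shift_tests["skipped"]).sum()
        )
        dnds_by_cat = {}
        for cat in ("germline", "de_novo", "lost"):
            subset = [
                (v.position, v.ref, v.alt)
                for v in categorized
                if v.category == cat
            ]
            if subset:
                r = mutstats.dn_ds(subset, ann)
                dnds_by_cat[cat] = {
                    "dn_ds": r.value, "dn": r.numerator, "ds": r.denominator,
                }
        stats["dn_ds_by_category"] = dnds_by_cat
        counts = categorized_frame(categorized)["category"].value_counts()
        stats["category_counts"] = {k: int(v) for k, v in counts.items()}
    with open(out / "stats.json", "w") as fh:
        json.dump(_jsonable(stats), fh, indent=1)
    return stats


def stage_enrich(
    categorized_tsv: str | Path,
    out_dir: str | Path,
    annotation: GenomeAnnotation | None = None,
) -> pd.DataFrame:
    """D-loop sub-region enrichment over the categorized heteroplasmies."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann = annotation or GenomeAnnotation.default()
    categorized = _categorized_from_tsv(categorized_tsv)
    n_pairs = len({v.subject_id for v in categorized}) or 1
    events = [(v.position, v.ref, v.alt) for v in categorized]
    results = mutstats.dloop_enrichment(events, ann, n_samples=n_pairs)
    df = pd.DataFrame(
        [
            {
                "subregion": r.subregion, "odds_ratio": r.odds_ratio,
                "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
                "a": r.counts[0], "b": r.counts[1],
                "c": r.counts[2], "d": r.counts[3],
            }
            for r in results
        ]
    ).set_index("subregion")
    df.to_csv(out / "dloop_enrichment.tsv", sep="\t")
    return df


def confusion_matrix(
    truth: pd.DataFrame, categorized: list[CategorizedVariant]
) -> pd.DataFrame:
    """Planted-category vs pipeline-category counts for simulated cohorts."""
    cats = ("germline", "de_novo", "lost")
    called = {
        (v.subject_id, v.position, v.ref, v.alt): v.category
        for v in categorized
    }
    matrix = pd.DataFrame(
        0, index=list(cats), columns=list(cats) + ["missing"]
    )
    for r in truth.itertuples():
        if r.category not in cats:
            continue
        got = called.get(
            (r.subject_id, int(r.position), r.ref, r.alt), "missing"
        )
        matrix.loc[r.category, got] += 1
    return matrix


def run_all(
    manifest_path: str | Path,
    out_dir: str | Path,
    qc: QcConfig | None = None,
    annotation: GenomeAnnotation | None = None,
    scope: str = "heteroplasmic_only",
    case_control_path: str | Path | None = None,
    truth_path: str | Path | None = None,
    seed: int = 0,
) -> dict:
    """Compose the stages on intermediate files and write report.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann = annotation or GenomeAnnotation.default()
    qc = qc or QcConfig()
    refined_manifest = stage_refine(manifest_path, out, qc, ann)
    categorized_tsv = stage_classify(refined_manifest, out, scope, ann)
    stats = stage_stats(refined_manifest, categorized_tsv, out, ann)
    enrichment = stage_enrich(categorized_tsv, out, ann)
    with open(out / "refinement_audit.json") as fh:
        audits = json.load(fh)
    report = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "qc_config": asdict(qc),
        "refinement": {
            "per_sample": audits,
            "total_input": sum(a["input"] for a in audits.values()),
            "total_retained": sum(a["retained"] for a in audits.values()),
            "total_removed": sum(a["removed_total"] for a in audits.values()),
        },
        "stats": stats,
        "dloop_enrichment_top": enrichment.sort_values("p_adjusted")
        .head(3)
        .reset_index()
        .to_dict(orient="records"),
    }
    if truth_path is not None:
        truth = pd.read_csv(truth_path, sep="\t")
        categorized = _categorized_from_tsv(categorized_tsv)
        matrix = confusion_matrix(truth, categorized)
        report["confusion_matrix"] = {
            row: {col: int(matrix.loc[row, col]) for col in matrix.columns}
            for row in matrix.index
        }
    if case_control_path is not None:
        model = CaseControlModel.from_tsv(case_control_path)
        report["association"] = (
            model.summary().reset_index().to_dict(orient="records")
        )
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=1)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj
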