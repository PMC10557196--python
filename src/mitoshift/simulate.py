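"""Synthetic cohorts: paired biopsy/blood variant calls and case-control tables.

The raw study data are not redistributable, so every pipeline input can be
generated here with known truth.  The pair generator emulates the reported
study conditions: 50 biopsy/blood pairs, category-specific heteroplasmy
beta distributions moment-matched to the published means/SDs (germline
blood 10.7% ± 23.1%, germline biopsy 14.1% ± 24.6%, de novo 9.9% ± 20.3%,
lost 3.8% ± 9.6%), sequencing depths around 1105× (biopsy) and 1218×
(blood), a transition-dominated substitution spectrum, a control-region
rate excess, homoplasmies near fixation, and optional artifact channels
(extra low-HL alleles at called sites, homopolymer-tract calls) whose
removal by the refinement rules is verifiable against the truth table.

Observed heteroplasmy is re-derived from a binomial read draw at the
sampled depth, so HL, alt reads, depth and the Wilson CI are mutually
consistent in the emitted calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps

from .annotation import MT_LENGTH, GenomeAnnotation
from .vcfio import SampleProfile, VariantCall, wilson_ci, write_vcf

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class SaturationError(ValueError):
    """Configured event rate would exhaust a region's positions."""


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta(a, b) parameters matching a mean and standard deviation."""
    var = sd * sd
    if not 0 < mean < 1 or var <= 0 or var >= mean * (1 - mean):
        raise ValueError(f"no beta distribution has mean {mean}, sd {sd}")
    nu = mean * (1 - mean) / var - 1
    return mean * nu, (1 - mean) * nu


def _truncated_beta(rng, a: float, b: float, lo: float, hi: float, size=None):
    """Inverse-CDF sampling of Beta(a, b) restricted to [lo, hi]."""
    u = rng.uniform(size=size)
    flo, fhi = sps.beta.cdf([lo, hi], a, b)
    return sps.beta.ppf(flo + u * (fhi - flo), a, b)


@dataclass(frozen=True)
class PairCohortConfig:
    """Conditions for the paired biopsy/blood simulation."""

    n_pairs: int = 50
    # events per base pair per sample (pair), before the D-loop multiplier
    germline_rate: float = 2.4e-4
    de_novo_rate: float = 1.6e-4
    lost_rate: float = 6.0e-5
    homoplasmy_rate: float = 1.1e-3
    dloop_rate_multiplier: float = 5.0
    # heteroplasmy beta moments (mean, sd), matched to the reported summaries
    hl_germline_blood: tuple[float, float] = (0.107, 0.231)
    hl_germline_biopsy: tuple[float, float] = (0.141, 0.246)
    hl_de_novo: tuple[float, float] = (0.099, 0.203)
    hl_lost: tuple[float, float] = (0.038, 0.096)
    # draws are restricted to this window so planted calls are resolvable
    hl_window: tuple[float, float] = (0.03, 0.88)
    depth_mean_biopsy: float = 1105.0
    depth_mean_blood: float = 1218.0
    depth_sd: float = 150.0
    depth_min: int = 300
    transition_weight: float = 0.85
    multiallelic_rate: float = 0.01
    homopolymer_artifact_rate: float = 0.3  # expected artifact calls/sample
    de_novo_coding_dnds: float | None = 2.0
    seed: int = 0

    @classmethod
    def noise_free(cls, **overrides) -> "PairCohortConfig":
        """No artifacts, no homoplasmies, HLs inside a safely-retained band."""
        defaults = dict(
            homoplasmy_rate=0.0,
            multiallelic_rate=0.0,
            homopolymer_artifact_rate=0.0,
            hl_window=(0.06, 0.80),
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SimulatedPairCohort:
    pairs: list[tuple[SampleProfile, SampleProfile]]  # (biopsy, blood)
    truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> Path:
        """Write per-sample VCFs, a manifest TSV and the truth table."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for biopsy, blood in self.pairs:
            bpath = out / f"{biopsy.sample_id}_biopsy.vcf"
            wpath = out / f"{blood.sample_id}_blood.vcf"
            write_vcf(biopsy, bpath)
            write_vcf(blood, wpath)
            rows.append(
                {
                    "subject_id": biopsy.sample_id,
                    "biopsy_vcf": bpath.name,
                    "blood_vcf": wpath.name,
                }
            )
        manifest = out / "manifest.tsv"
        pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        return manifest


def _position_weights(ann: GenomeAnnotation, multiplier: float) -> np.ndarray:
    w = np.ones(MT_LENGTH)
    dloop = next(f for f in ann.features if f.kind == "dloop")
    for p in dloop.positions():
        w[p - 1] = multiplier
    # genuine events avoid the homopolymer tracts: calls there are
    # unconditionally discarded downstream, so only the artifact channel
    # plants into them
    from .refine import default_blacklist

    for s, e in default_blacklist():
        w[s - 1 : e] = 0.0
    return w


def _sample_positions(rng, weights, probs, n: int, used: set[int]) -> list[int]:
    if n > 0.5 * MT_LENGTH:
        raise SaturationError(f"{n} events would saturate the genome")
    out: list[int] = []
    while len(out) < n:
        p = int(rng.choice(MT_LENGTH, p=probs)) + 1
        if p not in used:
            used.add(p)
            out.append(p)
    return out


def _matching_alts(ann, position: int, want_effect: str) -> list[str]:
    ref = ann.base(position)
    return [
        a
        for a in "ACGT"
        if a != ref
        and ann.coding_effect(position, ref, a).overall == want_effect
    ]


def _choose_alt(rng, ann, position, cfg, want_effect: str | None):
    ref = ann.base(position)
    alts = [b for b in "ACGT" if b != ref]
    if want_effect is not None:
        matching = [
            a
            for a in alts
            if ann.coding_effect(position, ref, a).overall == want_effect
        ]
        if matching:
            ts = [a for a in matching if a == _TRANSITION[ref]]
            return ref, (ts[0] if ts else matching[int(rng.integers(len(matching)))])
    if rng.uniform() < cfg.transition_weight:
        return ref, _TRANSITION[ref]
    tvs = [a for a in alts if a != _TRANSITION[ref]]
    return ref, tvs[int(rng.integers(len(tvs)))]


def _observe(rng, cfg, sample_id, tissue, position, ref, alt, hl_true,
             multiallelic=False, depth=None):
    if depth is None:
        mean = (
            cfg.depth_mean_biopsy if tissue == "biopsy" else cfg.depth_mean_blood
        )
        depth = max(cfg.depth_min, int(round(rng.normal(mean, cfg.depth_sd))))
    alt_reads = max(1, int(rng.binomial(depth, hl_true)))
    hl = round(alt_reads / depth, 6)
    lo, hi = wilson_ci(alt_reads, depth)
    return VariantCall(
        sample_id=sample_id,
        tissue=tissue,
        position=position,
        ref=ref,
        alt=alt,
        alt_reads=alt_reads,
        depth=depth,
        hl=hl,
        ci_low=round(min(lo, hl), 6),
        ci_high=round(max(hi, hl), 6),
        multiallelic_site=multiallelic,
    )


def simulate_pair_cohort(
    config: PairCohortConfig | None = None,
    annotation: GenomeAnnotation | None = None,
    out_dir: str | Path | None = None,
) -> SimulatedPairCohort:
    """Generate a paired cohort with a per-variant truth table.

    The truth table records every planted event's category, true HLs,
    coding effect, CpG membership and six-class substitution type, plus
    any artifact calls planted for the refinement rules to remove.
    """
    cfg = config or PairCohortConfig()
    ann = annotation or GenomeAnnotation.default()
    rng = np.random.default_rng(cfg.seed)
    weights = _position_weights(ann, cfg.dloop_rate_multiplier)
    probs = weights / weights.sum()
    effective_bp = float(weights.sum())

    ab = {
        "germline_blood": beta_from_moments(*cfg.hl_germline_blood),
        "germline_biopsy": beta_from_moments(*cfg.hl_germline_biopsy),
        "de_novo": beta_from_moments(*cfg.hl_de_novo),
        "lost": beta_from_moments(*cfg.hl_lost),
    }
    lo, hi = cfg.hl_window
    pairs = []
    truth_rows = []
    for i in range(cfg.n_pairs):
        sid = f"P{i+1:03d}"
        used: set[int] = set()
        biopsy_calls: list[VariantCall] = []
        blood_calls: list[VariantCall] = []

        def plant(category, n_events):
            for pos in _sample_positions(rng, weights, probs, n_events, used):
                want = None
                if (
                    category == "de_novo"
                    and cfg.de_novo_coding_dnds is not None
                    and ann.region_kind(pos) == "protein"
                ):
                    # draw the coding effect first, then keep the event in a
                    # coding position where that effect is achievable, so the
                    # realized nonsyn:syn ratio is Bernoulli at the target
                    r = cfg.de_novo_coding_dnds
                    want = (
                        "nonsynonymous"
                        if rng.uniform() < r / (1 + r)
                        else "synonymous"
                    )
                    while not _matching_alts(ann, pos, want):
                        used.discard(pos)
                        while True:
                            pos = _sample_positions(rng, weights, probs, 1, used)[0]
                            if ann.region_kind(pos) == "protein":
                                break
                            used.discard(pos)
                ref, alt = _choose_alt(rng, ann, pos, cfg, want)
                if category == "germline":
                    u = rng.uniform()
                    flo_b, fhi_b = sps.beta.cdf([lo, hi], *ab["germline_blood"])
                    flo_t, fhi_t = sps.beta.cdf([lo, hi], *ab["germline_biopsy"])
                    hl_blood = float(
                        sps.beta.ppf(flo_b + u * (fhi_b - flo_b), *ab["germline_blood"])
                    )
                    hl_biopsy = float(
                        sps.beta.ppf(flo_t + u * (fhi_t - flo_t), *ab["germline_biopsy"])
                    )
                elif category == "de_novo":
                    hl_biopsy = float(_truncated_beta(rng, *ab["de_novo"], lo, hi))
                    hl_blood = 0.0
                else:
                    hl_blood = float(_truncated_beta(rng, *ab["lost"], lo, hi))
                    hl_biopsy = 0.0
                if hl_biopsy:
                    biopsy_calls.append(
                        _observe(rng, cfg, sid, "biopsy", pos, ref, alt, hl_biopsy)
                    )
                if hl_blood:
                    blood_calls.append(
                        _observe(rng, cfg, sid, "blood", pos, ref, alt, hl_blood)
                    )
                effect = ann.coding_effect(pos, ref, alt).overall
                truth_rows.append(
                    {
                        "subject_id": sid,
                        "position": pos,
                        "ref": ref,
                        "alt": alt,
                        "category": category,
                        "hl_biopsy_true": hl_biopsy,
                        "hl_blood_true": hl_blood,
                        "effect": effect,
                        "cpg": ann.is_cpg(pos),
                        "class6": _six_class(ref, alt),
                        "region": ann.region_kind(pos),
                    }
                )

        plant("germline", rng.poisson(cfg.germline_rate * effective_bp))
        plant("de_novo", rng.poisson(cfg.de_novo_rate * effective_bp))
        plant("lost", rng.poisson(cfg.lost_rate * effective_bp))

        # shared homoplasmies near fixation
        n_homo = rng.poisson(cfg.homoplasmy_rate * effective_bp)
        for pos in _sample_positions(rng, weights, probs, n_homo, used):
            ref, alt = _choose_alt(rng, ann, pos, cfg, None)
            hl_true = rng.uniform(0.995, 1.0)
            biopsy_calls.append(
                _observe(rng, cfg, sid, "biopsy", pos, ref, alt, hl_true)
            )
            blood_calls.append(
                _observe(rng, cfg, sid, "blood", pos, ref, alt, hl_true)
            )
            truth_rows.append(
                {
                    "subject_id": sid, "position": pos, "ref": ref, "alt": alt,
                    "category": "homoplasmic",
                    "hl_biopsy_true": hl_true, "hl_blood_true": hl_true,
                    "effect": ann.coding_effect(pos, ref, alt).overall,
                    "cpg": ann.is_cpg(pos), "class6": _six_class(ref, alt),
                    "region": ann.region_kind(pos),
                }
            )

        # artifact channels (targets of rules R2 and R4)
        if cfg.multiallelic_rate > 0:
            for calls in (biopsy_calls, blood_calls):
                extra = []
                for v in calls:
                    if v.hl < 0.95 and rng.uniform() < cfg.multiallelic_rate:
                        second = [
                            b for b in "ACGT" if b not in (v.ref, v.alt)
                        ][int(rng.integers(2))]
                        shadow = _observe(
                            rng, cfg, sid, v.tissue, v.position, v.ref,
                            second, rng.uniform(0.005, 0.04),
                            multiallelic=True, depth=v.depth,
                        )
                        extra.append((v, shadow))
                for v, shadow in extra:
                    calls[calls.index(v)] = replace(v, multiallelic_site=True)
                    calls.append(shadow)
                    truth_rows.append(
                        {
                            "subject_id": sid, "position": shadow.position,
                            "ref": shadow.ref, "alt": shadow.alt,
                            "category": "artifact_multiallelic",
                            "hl_biopsy_true": np.nan, "hl_blood_true": np.nan,
                            "effect": "artifact", "cpg": False,
                            "class6": _six_class(shadow.ref, shadow.alt),
                            "region": ann.region_kind(shadow.position),
                        }
                    )
        if cfg.homopolymer_artifact_rate > 0:
            from .refine import default_blacklist

            spots = [
                p for s, e in default_blacklist() for p in range(s, e + 1)
            ]
            for tissue, calls in (("biopsy", biopsy_calls), ("blood", blood_calls)):
                for _ in range(rng.poisson(cfg.homopolymer_artifact_rate)):
                    pos = spots[int(rng.integers(len(spots)))]
                    if pos in used:
                        continue
                    used.add(pos)
                    ref, alt = _choose_alt(rng, ann, pos, cfg, None)
                    calls.append(
                        _observe(
                            rng, cfg, sid, tissue, pos, ref, alt,
                            rng.uniform(0.05, 0.3),
                        )
                    )
                    truth_rows.append(
                        {
                            "subject_id": sid, "position": pos, "ref": ref,
                            "alt": alt, "category": "artifact_homopolymer",
                            "hl_biopsy_true": np.nan, "hl_blood_true": np.nan,
                            "effect": "artifact", "cpg": ann.is_cpg(pos),
                            "class6": _six_class(ref, alt),
                            "region": ann.region_kind(pos),
                        }
                    )

        pairs.append(
            (
                SampleProfile(sid, "biopsy", biopsy_calls),
                SampleProfile(sid, "blood", blood_calls),
            )
        )

    truth = pd.DataFrame(truth_rows).sort_values(
        ["subject_id", "position"]
    ).reset_index(drop=True)
    cohort = SimulatedPairCohort(pairs=pairs, truth=truth)
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort


def _six_class(ref: str, alt: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if ref in "GA":
        ref, alt = comp[ref], comp[alt]
    return f"{ref}>{alt}"


# -- case-control ----------------------------------------------------------


@dataclass(frozen=True)
class CaseControlConfig:
    """Conditions for the nested case-control simulation."""

    n_cases: int = 304  # expected; realized counts are stochastic
    n_controls: int = 359
    control_prevalence: float = 0.08  # carrier fraction among the cancer-free
    true_or: float = 1.67
    cutoff: float = 0.10
    covariate_effects: dict = field(default_factory=dict)  # log-odds per unit
    seed: int = 0


def simulate_case_control(
    config: CaseControlConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """One plasma-mutation case-control table with a configured true OR.

    Carrier status is Bernoulli at the control prevalence; the outcome is
    assigned by a logistic model whose exposure coefficient is ln(true OR)
    and whose intercept is solved so the expected case fraction matches
    n_cases / (n_cases + n_controls).  Heteroplasmy levels are drawn so
    that dichotomizing at the cutoff reproduces carrier status exactly;
    covariates are independent of the exposure unless given an effect.
    """
    cfg = config or CaseControlConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cases + cfg.n_controls
    truth = {
        "true_or": cfg.true_or,
        "control_prevalence": cfg.control_prevalence,
        "degenerate": cfg.control_prevalence == 0,
    }
    x = rng.uniform(size=n) < cfg.control_prevalence

    cov = pd.DataFrame(
        {
            "age": np.round(rng.normal(55.0, 2.8, n).clip(50, 60), 1),
            "bmi": np.round(rng.normal(25.5, 3.9, n).clip(16, 45), 1),
            "education": rng.choice([1, 2, 3], size=n, p=[0.45, 0.3, 0.25]),
            "smoking": rng.choice([1, 2, 3], size=n, p=[0.55, 0.25, 0.2]),
            "alcohol": rng.choice([1, 2, 3], size=n, p=[0.25, 0.55, 0.2]),
            "activity_work": rng.choice([1, 2, 3], size=n, p=[0.35, 0.45, 0.2]),
            "activity_home": rng.choice([1, 2], size=n, p=[0.45, 0.55]),
            "diabetes": (rng.uniform(size=n) < 0.05).astype(int),
            "hypertension": (rng.uniform(size=n) < 0.25).astype(int),
            "family_history": (rng.uniform(size=n) < 0.12).astype(int),
        }
    )

    target = cfg.n_cases / n
    log_or = np.log(cfg.true_or)

    lin_cov = np.zeros(n)
    for name, eff in cfg.covariate_effects.items():
        col = cov[name].to_numpy(dtype=float)
        lin_cov += eff * (col - col.mean())

    def mean_case_fraction(b0):
        p = special.expit(b0 + log_or * x.astype(float) + lin_cov)
        return p.mean() - target

    b0 = optimize.brentq(mean_case_fraction, -20, 20)
    p_case = special.expit(b0 + log_or * x.astype(float) + lin_cov)
    y = rng.uniform(size=n) < p_case

    span = 0.95 - cfg.cutoff
    hl = np.where(
        x,
        cfg.cutoff + span * rng.beta(1.2, 2.8, size=n),
        cfg.cutoff * rng.beta(0.8, 3.0, size=n),
    )
    df = pd.DataFrame(
        {
            "subject_id": [f"C{i:04d}" for i in range(n)],
            "outcome": np.where(y, "case", "control"),
            "hl": np.round(hl, 6),
            "mutation_state": np.where(x, "mutated", "wild_type"),
        }
    ).join(cov)
    truth["n_cases_realized"] = int(y.sum())
    truth["n_controls_realized"] = int(n - y.sum())
    truth["intercept"] = float(b0)
    return df, truth


# -- deterministic hand-built fixtures ------------------------------------


def make_fixture_vcfs(
    out_dir: str | Path, annotation: GenomeAnnotation | None = None
) -> dict[str, Path]:
    """Small deterministic biopsy/blood VCFs exercising every refinement rule.

    One variant per rule (R1 low-CI, R2 multi-allelic prune and discard,
    R3 promotion, R4 homopolymer, R5 depth and low-HL depth), an indel,
    a wrapped-D-loop call, and one clean variant per pair category.
    """
    ann = annotation or GenomeAnnotation.default()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def fmt(hl, dp, ci=None, alt2=None, hl2=None):
        lows, highs = [], []
        for h in ([hl] if hl2 is None else [hl, hl2]):
            lo, hi = wilson_ci(int(round(h * dp)), dp)
            lows.append(round(min(lo, h), 6))
            highs.append(round(max(hi, h), 6))
        if ci is not None:
            lows[0], highs[0] = ci
        hf = f"{hl}" if hl2 is None else f"{hl},{hl2}"
        gt = "0/1" if hl2 is None else "1/2"
        return (
            f"{gt}:{hf}:{','.join(map(str, lows))}:"
            f"{','.join(map(str, highs))}:{dp}"
        )

    b = ann.base

    def line(pos, alt, sample_field, ref=None):
        return (
            f"chrM\t{pos}\t.\t{ref or b(pos)}\t{alt}\t.\tPASS\t.\t"
            f"GT:HF:CI_LOW:CI_HIGH:DP\t{sample_field}"
        )

    header = (
        "##fileformat=VCFv4.2\n"
        f"##contig=<ID=chrM,length={MT_LENGTH}>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=HF,Number=A,Type=Float,Description="Heteroplasmy fraction">\n'
        '##FORMAT=<ID=CI_LOW,Number=A,Type=Float,Description="CI lower bound">\n'
        '##FORMAT=<ID=CI_HIGH,Number=A,Type=Float,Description="CI upper bound">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sid}\n"
    )

    def other(pos):
        return "A" if b(pos) != "A" else "G"

    biopsy_lines = [
        line(400, other(400), fmt(0.20, 700)),        # germline, wrapped D-loop
        line(1888, "A", fmt(0.89, 1200, ci=(0.85, 0.985))),  # R3 promotion
        line(6000, other(6000), fmt(0.30, 90)),       # R5: depth < 100
        line(6100, other(6100), fmt(0.04, 200)),      # R5: low HL, depth < 250
        line(6200, other(6200), fmt(0.012, 400)),     # R1: CI lower bound < 1%
        line(310, other(310), fmt(0.15, 500)),        # R4: homopolymer tract
        line(7000, ",".join([x for x in "ACGT" if x != b(7000)][:2]),
             fmt(0.40, 800, hl2=0.03)),               # R2: prune the 3% allele
        line(7100, ",".join([x for x in "ACGT" if x != b(7100)][:2]),
             fmt(0.30, 800, hl2=0.20)),               # R2: still multi-allelic
        line(8000, b(8000) + "A", fmt(0.25, 600)),    # indel
        line(10398, "G", fmt(0.30, 900)),             # germline coding
        line(16093, "C", fmt(0.52, 800)),             # de novo hotspot
    ]
    blood_lines = [
        line(400, other(400), fmt(0.18, 900)),
        line(10398, "G", fmt(0.28, 1000)),
        line(12000, other(12000), fmt(0.06, 900)),    # lost
    ]
    paths = {}
    for sid, tissue, lines in (
        ("F001", "biopsy", biopsy_lines),
        ("F001", "blood", blood_lines),
    ):
        path = out / f"{sid}_{tissue}.vcf"
        body = "\n".join(sorted(lines, key=lambda l: int(l.split("\t")[1])))
        path.write_text(header.format(sid=sid) + body + "\n")
        paths[tissue] = path
    manifest = out / "manifest.tsv"
    manifest.write_text(
        "subject_id\tbiopsy_vcf\tblood_vcf\n"
        f"F001\t{paths['biopsy'].name}\t{paths['blood'].name}\n"
    )
    paths["manifest"] = manifest
    return paths
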