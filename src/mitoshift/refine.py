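"""Post-calling refinement of mitochondrial variant calls.

Five quality-control rules are applied to each sample profile, in order:

R1  low-confidence heteroplasmies — heteroplasmic candidates whose lower CI
    bound falls below ``ci_low_floor`` (1%) are removed.  A ``literal``
    mode retains them instead (see :class:`QcConfig.rule1_mode`).
R2  multi-allelic sites — alleles with HL < ``min_allele_hl`` (5%) are
    pruned; if more than one alternate allele still remains at the site,
    every allele at the site is discarded.
R3  near-fixed heteroplasmies — calls whose upper CI bound exceeds
    ``homoplasmy_ci_high`` (98%) are re-labelled homoplasmic.
R4  homopolymeric-tract artifacts — calls inside the blacklist intervals
    (poly-C stretches prone to misalignment) are removed.
R5  depth — heteroplasmic calls with depth < ``min_depth`` (100×), or with
    HL < ``low_hl_threshold`` (5%) and depth < ``low_hl_min_depth``
    (250×), are removed.

Before the rules run, each SNV gets an initial plasmy label from the
caller's heteroplasmy window: HL in [``hf_min``, ``hf_max``] (or below it)
is heteroplasmic, HL above ``hf_max`` is homoplasmic.  Indels are retained
with their own label and only pass through R2/R4.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from importlib import resources
from pathlib import Path

from .vcfio import SampleProfile, VariantCall

HETEROPLASMIC = "heteroplasmic"
HOMOPLASMIC = "homoplasmic"
INDEL = "indel"

RULES = ("R1", "R2", "R3", "R4", "R5")


class RefinementError(ValueError):
    pass


@dataclass(frozen=True)
class QcConfig:
    hf_min: float = 0.10
    hf_max: float = 0.90
    ci_low_floor: float = 0.01
    min_allele_hl: float = 0.05
    homoplasmy_ci_high: float = 0.98
    min_depth: int = 100
    low_hl_threshold: float = 0.05
    low_hl_min_depth: int = 250
    blacklist: tuple[tuple[int, int], ...] | None = None  # None -> bundled default
    rule1_mode: str = "discard_below_floor"  # or literal_retain_below_floor

    def __post_init__(self):
        if not 0 < self.hf_min < self.hf_max < self.homoplasmy_ci_high <= 1:
            raise ValueError("need 0 < hf_min < hf_max < homoplasmy_ci_high <= 1")
        if self.min_depth > self.low_hl_min_depth:
            raise ValueError("min_depth must be <= low_hl_min_depth")
        if self.rule1_mode not in (
            "discard_below_floor",
            "literal_retain_below_floor",
        ):
            raise ValueError(f"unknown rule1_mode {self.rule1_mode!r}")

    def resolved_blacklist(self) -> list[tuple[int, int]]:
        if self.blacklist is None:
            return default_blacklist()
        return merge_intervals(list(self.blacklist))


@dataclass(frozen=True)
class RefinedVariant:
    """A retained call plus its plasmy class and the rules that examined it."""

    call: VariantCall
    plasmy: str  # heteroplasmic | homoplasmic | indel
    filter_trace: tuple[str, ...] = ()

    # convenience pass-throughs
    @property
    def position(self) -> int:
        return self.call.position

    @property
    def ref(self) -> str:
        return self.call.ref

    @property
    def alt(self) -> str:
        return self.call.alt

    @property
    def hl(self) -> float:
        return self.call.hl

    @property
    def key(self):
        return self.call.key


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping 1-based inclusive intervals (silently)."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for s, e in ordered[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def default_blacklist(path: str | Path | None = None) -> list[tuple[int, int]]:
    """Homopolymeric-tract intervals (1-based inclusive), user-overridable via BED."""
    if path is None:
        path = resources.files("mitoshift.data") / "homopolymer_blacklist.bed"
    intervals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            intervals.append((int(parts[1]) + 1, int(parts[2])))
    return merge_intervals(intervals)


def _in_blacklist(position: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= position <= e for s, e in intervals)


def _initial_plasmy(v: VariantCall, cfg: QcConfig) -> str:
    if not v.is_snv:
        return INDEL
    return HOMOPLASMIC if v.hl > cfg.hf_max else HETEROPLASMIC


def apply_refinement(
    profile: SampleProfile, config: QcConfig | None = None
) -> tuple[list[RefinedVariant], dict]:
    """Run the five rules over one profile.

    Returns the retained :class:`RefinedVariant` list and an audit dict with
    per-rule examined/removed counts satisfying retained + removed = input.
    """
    cfg = config or QcConfig()
    blacklist = cfg.resolved_blacklist()
    audit = {r: {"examined": 0, "removed": 0, "relabelled": 0} for r in RULES}
    audit["input"] = len(profile.variants)

    current: list[RefinedVariant] = [
        RefinedVariant(v, _initial_plasmy(v, cfg)) for v in profile.variants
    ]

    # R1: heteroplasmic candidates with CI lower bound below the floor
    kept = []
    for rv in current:
        if rv.plasmy == HETEROPLASMIC:
            audit["R1"]["examined"] += 1
            rv = dc_replace(rv, filter_trace=rv.filter_trace + ("R1",))
            if (
                cfg.rule1_mode == "discard_below_floor"
                and rv.call.ci_low < cfg.ci_low_floor
            ):
                audit["R1"]["removed"] += 1
                continue
        kept.append(rv)
    current = kept

    # R2: prune low-HL alleles at multi-allelic sites, then discard sites
    # that are still multi-allelic
    by_pos: dict[int, list[RefinedVariant]] = {}
    for rv in current:
        by_pos.setdefault(rv.position, []).append(rv)
    kept = []
    for rv in current:
        site = by_pos[rv.position]
        if len(site) > 1:
            audit["R2"]["examined"] += 1
            rv = dc_replace(rv, filter_trace=rv.filter_trace + ("R2",))
            if rv.hl < cfg.min_allele_hl:
                audit["R2"]["removed"] += 1
                continue
            survivors = [
                x for x in site if x.hl >= cfg.min_allele_hl
            ]
            if len(survivors) > 1:  # still multi-allelic: discard the site
                audit["R2"]["removed"] += 1
                continue
        kept.append(rv)
    current = kept

    # R3: re-categorize near-fixed heteroplasmies as homoplasmic
    relabelled = []
    for rv in current:
        if rv.plasmy == HETEROPLASMIC:
            audit["R3"]["examined"] += 1
            if rv.call.ci_high > cfg.homoplasmy_ci_high:
                audit["R3"]["relabelled"] += 1
                rv = dc_replace(
                    rv,
                    plasmy=HOMOPLASMIC,
                    filter_trace=rv.filter_trace + ("R3",),
                )
        relabelled.append(rv)
    current = relabelled

    # R4: homopolymeric-tract blacklist
    kept = []
    for rv in current:
        audit["R4"]["examined"] += 1
        if _in_blacklist(rv.position, blacklist):
            audit["R4"]["removed"] += 1
            continue
        kept.append(rv)
    current = kept

    # R5: depth filters on heteroplasmic calls
    kept = []
    for rv in current:
        if rv.plasmy == HETEROPLASMIC:
            audit["R5"]["examined"] += 1
            rv = dc_replace(rv, filter_trace=rv.filter_trace + ("R5",))
            if rv.call.depth < cfg.min_depth or (
                rv.hl < cfg.low_hl_threshold
                and rv.call.depth < cfg.low_hl_min_depth
            ):
                audit["R5"]["removed"] += 1
                continue
        kept.append(rv)
    current = kept

    audit["retained"] = len(current)
    audit["removed_total"] = audit["input"] - len(current)
    return current, audit


def refined_profile(
    profile: SampleProfile, refined: list[RefinedVariant]
) -> SampleProfile:
    """Repackage retained calls as a profile (for idempotence checks / writing)."""
    return SampleProfile(
        profile.sample_id, profile.tissue, [rv.call for rv in refined]
    )
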