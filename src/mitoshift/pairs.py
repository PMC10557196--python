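"""Matching refined variants across a subject's biopsy and blood profiles.

A heteroplasmy is *germline* when the same (position, ref, alt) allele is
present in both tissues, *de novo* when present only in the biopsy, and
*lost* when present only in the whole-blood sample.  The heteroplasmy
shift of a variant is HL(biopsy) − HL(blood), with the absent side
contributing 0.  Matching is allele-exact: a site heteroplasmic for
different alternate alleles in the two tissues yields one de novo and one
lost record, not a germline one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .refine import HETEROPLASMIC, RefinedVariant

GERMLINE = "germline"
DE_NOVO = "de_novo"
LOST = "lost"


class PairIntegrityError(ValueError):
    """Duplicate (position, ref, alt) keys inside one profile."""


@dataclass
class PairedProfile:
    subject_id: str
    biopsy: list[RefinedVariant]
    blood: list[RefinedVariant]


@dataclass(frozen=True)
class CategorizedVariant:
    subject_id: str
    position: int
    ref: str
    alt: str
    category: str  # germline | de_novo | lost
    hl_biopsy: float  # 0 if absent from the biopsy
    hl_blood: float  # 0 if absent from the blood
    region: str = "intergenic"
    subregion: str | None = None

    @property
    def shift(self) -> float:
        return self.hl_biopsy - self.hl_blood

    @property
    def key(self):
        return (self.position, self.ref, self.alt)


def _index(
    variants: list[RefinedVariant], scope: str
) -> dict[tuple, RefinedVariant]:
    if scope == "heteroplasmic_only":
        pool = [v for v in variants if v.plasmy == HETEROPLASMIC]
    else:
        pool = list(variants)
    out: dict[tuple, RefinedVariant] = {}
    for v in pool:
        if v.key in out:
            raise PairIntegrityError(f"duplicate variant key {v.key}")
        out[v.key] = v
    return out


def categorize_pair(
    pair: PairedProfile,
    scope: str = "heteroplasmic_only",
    annotation: GenomeAnnotation | None = None,
) -> list[CategorizedVariant]:
    """Assign germline / de novo / lost to every in-scope variant of a pair."""
    if scope not in ("heteroplasmic_only", "all"):
        raise ValueError(f"unknown scope {scope!r}")
    ann = annotation or GenomeAnnotation.default()
    biopsy = _index(pair.biopsy, scope)
    blood = _index(pair.blood, scope)
    out = []
    for key in sorted(set(biopsy) | set(blood)):
        in_b, in_w = key in biopsy, key in blood
        category = GERMLINE if (in_b and in_w) else (DE_NOVO if in_b else LOST)
        position = key[0]
        subs = ann.subregions_at(position)
        subregion = min(subs, key=lambda s: s.length).name if subs else None
        out.append(
            CategorizedVariant(
                subject_id=pair.subject_id,
                position=position,
                ref=key[1],
                alt=key[2],
                category=category,
                hl_biopsy=biopsy[key].hl if in_b else 0.0,
                hl_blood=blood[key].hl if in_w else 0.0,
                region=ann.region_kind(position),
                subregion=subregion,
            )
        )
    return out


def categorized_frame(categorized: list[CategorizedVariant]) -> pd.DataFrame:
    cols = [
        "subject_id", "position", "ref", "alt", "category",
        "hl_biopsy", "hl_blood", "shift", "region", "subregion",
    ]
    rows = [
        {
            **{c: getattr(v, c) for c in cols if c != "shift"},
            "shift": v.shift,
        }
        for v in categorized
    ]
    return pd.DataFrame(rows, columns=cols)


def shift_profile(
    categorized: list[CategorizedVariant],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shift table ordered by magnitude, plus per-category HL/shift summaries.

    Germline HL means are reported per tissue (biopsy and blood separately);
    de novo / lost report the HL in the tissue where they exist.
    """
    if not categorized:
        raise ValueError("no categorized variants to summarize")
    df = categorized_frame(categorized)
    shifts = df.sort_values(
        "shift", key=lambda s: s.abs(), ascending=False
    ).reset_index(drop=True)
    rows = []
    for category, grp in df.groupby("category"):
        row = {
            "category": category,
            "n": len(grp),
            "mean_shift": grp["shift"].mean(),
            "sd_shift": grp["shift"].std(ddof=1) if len(grp) > 1 else 0.0,
        }
        if category in (GERMLINE, DE_NOVO):
            row["mean_hl_biopsy"] = grp["hl_biopsy"].mean()
            row["sd_hl_biopsy"] = (
                grp["hl_biopsy"].std(ddof=1) if len(grp) > 1 else 0.0
            )
        else:
            row["mean_hl_biopsy"] = np.nan
            row["sd_hl_biopsy"] = np.nan
        if category in (GERMLINE, LOST):
            row["mean_hl_blood"] = grp["hl_blood"].mean()
            row["sd_hl_blood"] = (
                grp["hl_blood"].std(ddof=1) if len(grp) > 1 else 0.0
            )
        else:
            row["mean_hl_blood"] = np.nan
            row["sd_hl_blood"] = np.nan
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("category").sort_index()
    return shifts, summary
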