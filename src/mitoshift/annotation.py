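"""Reference annotation for the human mitochondrial genome.

Coordinates are 1-based inclusive on the 16,569-bp circular mitochondrial
reference (rCRS coordinate system); the control region (D-loop) wraps the
replication origin and is stored as a single feature with ``start > end``.
The bundled sequence (``data/rcrs_synthetic.fa``) is a synthetic stand-in:
it uses the real gene coordinate model but randomly generated bases except
where published fragments pin the truth (the assay context sequences around
mt.1888 and mt.16093, the mt.10398 codon, and the classical homopolymeric
tracts).  All coordinate queries, codon reconstruction and CpG/context
logic are independent of which sequence is loaded; a user can substitute
the true reference with :meth:`GenomeAnnotation.from_files`.

Translation uses the vertebrate mitochondrial genetic code (NCBI table 2).
Genes encoded on the light strand (MT-ND6 and eight tRNAs) are read from
the reverse complement.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

from Bio.Data.CodonTable import unambiguous_dna_by_id

MT_LENGTH = 16569

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_MITO_TABLE = unambiguous_dna_by_id[2]
#: codon -> amino acid, with '*' for the four vertebrate-mitochondrial stops
MITO_CODE: dict[str, str] = dict(_MITO_TABLE.forward_table)
MITO_CODE.update({c: "*" for c in _MITO_TABLE.stop_codons})

#: overlap-resolution priority used when a base must carry a single label
KIND_PRIORITY = ("dloop", "protein", "rRNA", "tRNA")


class CoordinateError(ValueError):
    """Position outside [1, 16569]."""


class ReferenceMismatchError(ValueError):
    """Supplied reference allele disagrees with the loaded sequence."""


class UnsupportedVariantError(ValueError):
    """Operation defined for SNVs only."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """One annotated interval; ``start > end`` means it wraps the origin."""

    name: str
    kind: str  # dloop | protein | rRNA | tRNA
    start: int
    end: int
    strand: str = "heavy"  # heavy | light
    frame: int = 0

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    @property
    def length(self) -> int:
        if self.wraps:
            return (MT_LENGTH - self.start + 1) + self.end
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        if self.wraps:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end

    def positions(self):
        """All contained 1-based positions, in reading order along the heavy strand."""
        if self.wraps:
            yield from range(self.start, MT_LENGTH + 1)
            yield from range(1, self.end + 1)
        else:
            yield from range(self.start, self.end + 1)


@dataclass(frozen=True)
class Subregion:
    """A D-loop regulatory element (promoter, TFAM site, CSB, ...)."""

    name: str
    start: int
    end: int

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    @property
    def length(self) -> int:
        if self.wraps:
            return (MT_LENGTH - self.start + 1) + self.end
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        if self.wraps:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end


@dataclass(frozen=True)
class CodingEffect:
    """Per-gene and collapsed consequence of one substitution.

    ``per_gene`` maps gene name to ``synonymous`` / ``nonsynonymous``;
    ``overall`` collapses overlapping reading frames, preferring
    ``nonsynonymous`` (conservative for dN/dS numerators), and is
    ``noncoding`` outside every protein feature.
    """

    per_gene: dict[str, str] = field(default_factory=dict)

    @property
    def overall(self) -> str:
        if not self.per_gene:
            return "noncoding"
        if "nonsynonymous" in self.per_gene.values():
            return "nonsynonymous"
        return "synonymous"


def _check_position(position: int) -> None:
    if not 1 <= position <= MT_LENGTH:
        raise CoordinateError(f"position {position} outside [1, {MT_LENGTH}]")


class GenomeAnnotation:
    """Sequence + feature map answering "what is at position p" queries."""

    def __init__(
        self,
        sequence: str,
        features: list[Feature],
        dloop_subregions: list[Subregion] | None = None,
    ):
        if len(sequence) != MT_LENGTH:
            raise ValueError(
                f"sequence length {len(sequence)} != circular length {MT_LENGTH}"
            )
        self.sequence = sequence.upper()
        self.features = list(features)
        self.dloop_subregions = list(dloop_subregions or [])
        self.circular_length = MT_LENGTH
        dloops = [f for f in self.features if f.kind == "dloop"]
        for sub in self.dloop_subregions:
            if not any(
                dl.contains(sub.start) and dl.contains(sub.end) for dl in dloops
            ):
                raise ValueError(f"sub-region {sub.name} outside the D-loop")

    # -- construction ----------------------------------------------------

    @classmethod
    def from_files(
        cls,
        fasta: str | Path,
        features_tsv: str | Path,
        subregions_tsv: str | Path | None = None,
    ) -> "GenomeAnnotation":
        sequence = _read_single_fasta(fasta)
        features = _read_features_tsv(features_tsv)
        subs = _read_subregions_tsv(subregions_tsv) if subregions_tsv else []
        return cls(sequence, features, subs)

    @classmethod
    @lru_cache(maxsize=1)
    def default(cls) -> "GenomeAnnotation":
        data = resources.files("mitoshift.data")
        return cls.from_files(
            data / "rcrs_synthetic.fa",
            data / "features.tsv",
            data / "dloop_subregions.tsv",
        )

    # -- base-level queries ----------------------------------------------

    def base(self, position: int) -> str:
        """Heavy-strand base at a 1-based position, with circular wrap."""
        _check_position(((position - 1) % MT_LENGTH) + 1)
        return self.sequence[(position - 1) % MT_LENGTH]

    def locate(self, position: int) -> list[Feature]:
        """Every feature whose (possibly wrapping) interval contains the position."""
        _check_position(position)
        return [f for f in self.features if f.contains(position)]

    def region_kind(self, position: int) -> str:
        """Single region label for the position under the documented priority."""
        kinds = {f.kind for f in self.locate(position)}
        for kind in KIND_PRIORITY:
            if kind in kinds:
                return kind
        return "intergenic"

    def subregions_at(self, position: int) -> list[Subregion]:
        _check_position(position)
        return [s for s in self.dloop_subregions if s.contains(position)]

    def class_lengths(self) -> dict[str, int]:
        """Unique base count per region class (overlapping bases counted once)."""
        out: dict[str, set[int]] = {}
        for f in self.features:
            out.setdefault(f.kind, set()).update(f.positions())
        return {kind: len(pos) for kind, pos in out.items()}

    # -- substitution queries --------------------------------------------

    def is_cpg(self, position: int) -> bool:
        """True iff the position overlaps a CG dinucleotide on either strand."""
        _check_position(position)
        here = self.base(position)
        nxt = self.base(position % MT_LENGTH + 1)
        prev = self.base((position - 2) % MT_LENGTH + 1)
        return (here == "C" and nxt == "G") or (prev == "C" and here == "G")

    def coding_effect(self, position: int, ref: str, alt: str) -> CodingEffect:
        """Synonymous / nonsynonymous call per overlapping reading frame.

        ``ref``/``alt`` are heavy-strand alleles (VCF convention); for
        light-strand genes the codon is rebuilt from the reverse
        complement.  Trailing incomplete codons (stops completed by mRNA
        polyadenylation) are padded with A.
        """
        _check_position(position)
        if len(ref) != 1 or len(alt) != 1:
            raise UnsupportedVariantError("coding_effect is defined for SNVs")
        if self.base(position) != ref.upper():
            raise ReferenceMismatchError(
                f"reference allele {ref} != sequence base "
                f"{self.base(position)} at {position}"
            )
        effects: dict[str, str] = {}
        for feat in self.features:
            if feat.kind != "protein" or not feat.contains(position):
                continue
            ref_codon, alt_codon = self._codons(feat, position, alt.upper())
            ref_aa = MITO_CODE[ref_codon]
            alt_aa = MITO_CODE[alt_codon]
            effects[feat.name] = (
                "synonymous" if ref_aa == alt_aa else "nonsynonymous"
            )
        return CodingEffect(per_gene=effects)

    def _codons(self, feat: Feature, position: int, alt: str) -> tuple[str, str]:
        if feat.strand == "heavy":
            idx = position - feat.start - feat.frame
            codon_start = feat.start + feat.frame + 3 * (idx // 3)
            pos_list = [codon_start, codon_start + 1, codon_start + 2]
            ref_codon = "".join(
                self.base(p) if p <= feat.end else "A" for p in pos_list
            )
            within = idx % 3
            alt_codon = ref_codon[:within] + alt + ref_codon[within + 1 :]
        else:
            # reading proceeds end -> start on the heavy strand, complemented
            idx = feat.end - position - feat.frame
            codon_top = feat.end - feat.frame - 3 * (idx // 3)
            pos_list = [codon_top, codon_top - 1, codon_top - 2]
            ref_codon = "".join(
                self.base(p).translate(_COMPLEMENT) if p >= feat.start else "A"
                for p in pos_list
            )
            within = idx % 3
            alt_codon = (
                ref_codon[:within]
                + alt.translate(_COMPLEMENT)
                + ref_codon[within + 1 :]
            )
        return ref_codon, alt_codon

    def trinucleotide_context(self, position: int, ref: str, alt: str) -> str:
        """Pyrimidine-centred 96-channel context class, e.g. ``A[C>T]G``.

        Purine-reference substitutions are reverse-complemented onto the
        pyrimidine strand; flanks are read circularly.
        """
        _check_position(position)
        if len(ref) != 1 or len(alt) != 1:
            raise UnsupportedVariantError("trinucleotide context requires an SNV")
        ref, alt = ref.upper(), alt.upper()
        if self.base(position) != ref:
            raise ReferenceMismatchError(
                f"reference allele {ref} != sequence base at {position}"
            )
        left = self.base((position - 2) % MT_LENGTH + 1)
        right = self.base(position % MT_LENGTH + 1)
        if ref in "GA":  # collapse onto the pyrimidine strand
            left, right = right.translate(_COMPLEMENT), left.translate(_COMPLEMENT)
            ref = ref.translate(_COMPLEMENT)
            alt = alt.translate(_COMPLEMENT)
        return f"{left}[{ref}>{alt}]{right}"


# -- file readers ---------------------------------------------------------


def _read_single_fasta(path) -> str:
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                if chunks:
                    raise ValueError("expected a single-record FASTA")
                continue
            chunks.append(line.strip())
    return "".join(chunks).upper()


def _read_features_tsv(path) -> list[Feature]:
    feats = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            feats.append(
                Feature(
                    name=row["name"],
                    kind=row["kind"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    frame=0 if row["frame"] in (".", "") else int(row["frame"]),
                )
            )
    return feats


def _read_subregions_tsv(path) -> list[Subregion]:
    with open(path) as fh:
        return [
            Subregion(row["name"], int(row["start"]), int(row["end"]))
            for row in csv.DictReader(fh, delimiter="\t")
        ]


def read_features_bed(path) -> list[Feature]:
    """Load a user feature override from BED (0-based half-open).

    Columns: chrom, start, end, name, kind, strand(+/-), [frame].
    """
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start0, end0, name = parts[:4]
            kind = parts[4] if len(parts) > 4 else "protein"
            strand = "light" if len(parts) > 5 and parts[5] == "-" else "heavy"
            frame = int(parts[6]) if len(parts) > 6 and parts[6] != "." else 0
            feats.append(
                Feature(name, kind, int(start0) + 1, int(end0), strand, frame)
            )
    return feats
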