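"""Mitochondrial genome comparison and variant classification.

The subject mt genome is compared base-by-base against a circular reference
(no alignment; the sequences must be the same length in reference
coordinates).  Each substitution is assigned to one annotated region —
control region (D-loop), other non-coding, RNA gene, or protein-coding gene —
and protein-coding variants are split into synonymous / non-synonymous using
the vertebrate mitochondrial genetic code (TGA = Trp, AGA/AGG = stop).
Region intervals are 1-based inclusive and may wrap the origin of the
circular molecule; the wrap is handled on an unrolled doubled sequence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from Bio.Seq import Seq

from ._util import revcomp

CATEGORIES = ("control", "noncoding", "rna", "protein_coding")


@dataclass(frozen=True)
class MtRegion:
    """Annotated region of the circular mt reference.

    start/end are 1-based inclusive; start > end denotes an origin-wrapping
    interval.  Protein-coding regions carry the strand and the 1-based
    position of the first codon base (frame_start).
    """

    start: int
    end: int
    category: str
    strand: str = "+"
    frame_start: int | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "protein_coding" and self.frame_start is None:
            object.__setattr__(self, "frame_start", self.start)

    def wraps(self) -> bool:
        return self.start > self.end

    def contains(self, pos: int, length: int) -> bool:
        if self.wraps():
            return pos >= self.start or pos <= self.end
        return self.start <= pos <= self.end

    def length(self, genome_length: int) -> int:
        if self.wraps():
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1


def mt_variants(subject_mt: str, reference_mt: str) -> list[tuple[int, str, str]]:
    """Coordinate-wise substitutions (1-based position, ref, alt)."""
    if len(subject_mt) != len(reference_mt):
        raise ValueError(
            f"sequence lengths differ ({len(subject_mt)} vs {len(reference_mt)}); "
            "indels/alignment are out of scope"
        )
    return [
        (i + 1, r, s)
        for i, (r, s) in enumerate(zip(reference_mt.upper(), subject_mt.upper()))
        if r != s
    ]


def _unrolled_offset(pos: int, start: int, L: int) -> int:
    """Offset of 1-based pos from 1-based start on the unrolled circle."""
    idx = pos - 1 if pos >= start else pos - 1 + L
    return idx - (start - 1)


def mt_codon_effect(
    pos: int, alt: str, region: MtRegion, reference_mt: str
) -> str:
    """synonymous | nonsynonymous for a substitution in a coding mt region."""
    L = len(reference_mt)
    doubled = reference_mt.upper() * 2
    if region.strand == "+":
        # frame_start is the first codon base; reading moves rightward
        off = _unrolled_offset(pos, region.frame_start, L)
        codon_idx, within = divmod(off, 3)
        base0 = ((region.frame_start - 1) + 3 * codon_idx) % L
        codon = doubled[base0 : base0 + 3]
        alt_t = alt.upper()
    else:
        # frame_start is the first codon base on the minus strand, i.e. the
        # highest plus-strand coordinate of the gene; reading moves leftward
        off = _unrolled_offset(region.frame_start, pos, L)
        codon_idx, within = divmod(off, 3)
        base0 = ((region.frame_start - 1) - 3 * codon_idx - 2) % L
        codon = revcomp(doubled[base0 : base0 + 3])
        alt_t = revcomp(alt.upper())
    mutated = codon[:within] + alt_t + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate(table=2))
    aa_alt = str(Seq(mutated).translate(table=2))
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def mt_classify(
    variants: list[tuple[int, str, str]],
    regions: list[MtRegion],
    reference_mt: str,
) -> dict:
    """Per-category variant counts plus the syn/nonsyn split in coding genes.

    Every variant position must fall in exactly one region (the first
    containing region wins if annotations overlap); an uncovered position is
    an error.  Category counts sum to the total variant count.
    """
    L = len(reference_mt)
    counts: Counter = Counter({c: 0 for c in CATEGORIES})
    syn = nonsyn = 0
    per_variant = []
    for pos, ref, alt in variants:
        region = next((r for r in regions if r.contains(pos, L)), None)
        if region is None:
            raise ValueError(f"position {pos} not covered by any mt region")
        counts[region.category] += 1
        label = region.category
        if region.category == "protein_coding":
            effect = mt_codon_effect(pos, alt, region, reference_mt)
            if effect == "synonymous":
                syn += 1
            else:
                nonsyn += 1
            label = f"protein_coding/{effect}"
        per_variant.append((pos, ref, alt, label))
    return {
        "n_total": len(variants),
        "counts": dict(counts),
        "syn": syn,
        "nonsyn": nonsyn,
        "per_variant": per_variant,
    }
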