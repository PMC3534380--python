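"""Cross-genome comparison: shared-SNP fractions, novel variants, partitions.

A subject catalog is compared against panel genomes and public catalogs.
Sharing by default requires an overlapping alternate allele at the same
(contig, pos), not merely a shared position; position-only sharing is
available via a flag since published shared percentages mix the two rules.
Indels are normalized (shared-suffix then shared-prefix trimming, position
adjusted) before keying so that representation differences do not inflate
novelty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from ._util import round_half_up
from .functional_annotation import RepeatFeature, TranscriptModel
from .variant_qc import VariantCall

SiteKey = tuple[str, int]


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-normalize a variant representation.

    Trims the shared suffix, then the shared prefix (advancing pos), keeping
    at least one base on each side.  SNPs pass through unchanged.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass
class VariantCatalog:
    """Named set of variant sites: (contig, pos) -> set of alt alleles."""

    name: str
    sites: dict[SiteKey, frozenset[str]] = field(default_factory=dict)

    @classmethod
    def from_calls(cls, name: str, calls: list[VariantCall]) -> "VariantCatalog":
        sites: dict[SiteKey, set[str]] = {}
        for c in calls:
            for alt in c.alts:
                pos, _, a = normalize_variant(c.pos, c.ref, alt)
                sites.setdefault((c.contig, pos), set()).add(a)
        return cls(name, {k: frozenset(v) for k, v in sites.items()})

    @classmethod
    def from_tuples(
        cls, name: str, entries: list[tuple[str, int, str, str]]
    ) -> "VariantCatalog":
        sites: dict[SiteKey, set[str]] = {}
        for contig, pos, ref, alt in entries:
            pos, _, a = normalize_variant(pos, ref, alt)
            sites.setdefault((contig, pos), set()).add(a)
        return cls(name, {k: frozenset(v) for k, v in sites.items()})

    def __len__(self):
        return len(self.sites)


def _shares(subject_alts, other_alts, allele_aware: bool) -> bool:
    if not allele_aware:
        return True
    return bool(subject_alts & other_alts)


def shared_fraction(
    subject: VariantCatalog, other: VariantCatalog, allele_aware: bool = True
) -> float:
    """Percentage of subject sites also carried by ``other`` (two decimals)."""
    if not subject.sites:
        raise ValueError("empty subject catalog")
    n_shared = sum(
        1
        for key, alts in subject.sites.items()
        if key in other.sites and _shares(alts, other.sites[key], allele_aware)
    )
    return round_half_up(100.0 * n_shared / len(subject.sites), 2)


def novel_variants(
    subject: VariantCatalog,
    panels: list[VariantCatalog],
    catalogs: list[VariantCatalog],
    allele_aware: bool = True,
) -> tuple[set[SiteKey], float]:
    """Subject sites present in no panel and no catalog, with their share.

    The percentage of the subject total is reported at one decimal.
    """
    others = list(panels) + list(catalogs)
    if not others:
        raise ValueError("at least one comparison catalog is required")
    novel = {
        key
        for key, alts in subject.sites.items()
        if not any(
            key in o.sites and _shares(alts, o.sites[key], allele_aware) for o in others
        )
    }
    pct = round_half_up(100.0 * len(novel) / len(subject.sites), 1) if subject.sites else 0.0
    return novel, pct


def partition_novel(
    novel: set[SiteKey],
    transcripts: list[TranscriptModel],
    repeats: list[RepeatFeature],
) -> dict:
    """Partition novel sites into gene-only / repeat-only / both / other.

    Gene membership means lying within some transcript's genomic span.
    The four labels are mutually exclusive and sum to |novel|; percentages of
    the novel total are reported at two decimals (all zero, flagged, when the
    novel set is empty).
    """
    gene_trees: dict[str, IntervalTree] = {}
    for t in transcripts:
        s, e = t.span
        gene_trees.setdefault(t.contig, IntervalTree()).addi(s, e)
    rep_trees: dict[str, IntervalTree] = {}
    for r in repeats:
        rep_trees.setdefault(r.contig, IntervalTree()).addi(r.start, r.end)
    counts = {"gene_only": 0, "repeat_only": 0, "both": 0, "other": 0}
    for contig, pos in novel:
        p0 = pos - 1
        in_gene = contig in gene_trees and bool(gene_trees[contig].overlap(p0, p0 + 1))
        in_rep = contig in rep_trees and bool(rep_trees[contig].overlap(p0, p0 + 1))
        if in_gene and in_rep:
            counts["both"] += 1
        elif in_gene:
            counts["gene_only"] += 1
        elif in_rep:
            counts["repeat_only"] += 1
        else:
            counts["other"] += 1
    n = len(novel)
    empty = n == 0
    pct = {
        k: (0.0 if empty else round_half_up(100.0 * v / n, 2)) for k, v in counts.items()
    }
    return {"counts": counts, "pct": pct, "n_novel": n, "empty": empty}


def comparison_report(
    subject: VariantCatalog,
    panels: list[VariantCatalog],
    catalogs: list[VariantCatalog],
    transcripts: list[TranscriptModel],
    repeats: list[RepeatFeature],
    allele_aware: bool = True,
) -> dict:
    shared = {
        o.name: shared_fraction(subject, o, allele_aware) for o in panels + catalogs
    }
    novel, pct = novel_variants(subject, panels, catalogs, allele_aware)
    part = partition_novel(novel, transcripts, repeats)
    return {
        "shared_pct": shared,
        "n_novel": len(novel),
        "novel_pct": pct,
        "novel_partition": part,
        "novel_sites": sorted(novel),
    }
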