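"""Functional and regulatory annotation of variants.

Classifies each variant by genomic region (coding exon, UTRs, non-coding exon,
intron, intergenic), calls coding consequences by codon translation
(synonymous / missense / nonsense for substitutions, in-frame / frameshift
with premature-stop index for indels), overlaps variants with repeat and
regulatory tracks, computes strand-oriented variant metaprofiles around
transcription start sites, and tests gene sets for enrichment with a
hypergeometric tail + Benjamini-Hochberg FDR.

All internal interval arithmetic is 0-based half-open; 1-based formats are
converted at the I/O boundary (see pgi.io).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import revcomp
from .variant_qc import VariantCall

REGION_CODING = "coding_exon"
REGION_UTR5 = "utr5"
REGION_UTR3 = "utr3"
REGION_NC_EXON = "noncoding_exon"
REGION_INTRON = "intron"
REGION_INTERGENIC = "intergenic"
# severity precedence, most severe first
REGION_ORDER = (
    REGION_CODING,
    REGION_UTR5,
    REGION_UTR3,
    REGION_NC_EXON,
    REGION_INTRON,
    REGION_INTERGENIC,
)
_REGION_RANK = {r: i for i, r in enumerate(REGION_ORDER)}

STANDARD_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-aware transcript: exon/CDS structure and TSS.

    Intervals are 0-based half-open tuples in ascending genomic order; the
    translation order on '-' is handled internally.  ``tss`` is the 0-based
    strand-aware 5' end.
    """

    id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    tss: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in {self.id}")
        object.__setattr__(self, "exons", tuple(ex))
        object.__setattr__(self, "cds", tuple(sorted(self.cds)))
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ValueError(f"CDS interval ({cs},{ce}) outside exons in {self.id}")
        if self.cds_length % 3:
            raise ValueError(f"CDS length of {self.id} not a multiple of 3")

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def cds_span(self) -> tuple[int, int] | None:
        if not self.cds:
            return None
        return (self.cds[0][0], self.cds[-1][1])


@dataclass(frozen=True)
class RepeatFeature:
    """BED-convention repeat element (0-based half-open)."""

    contig: str
    start: int
    end: int
    name: str
    rclass: str
    family: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("empty repeat interval")
        if not self.rclass:
            raise ValueError("repeat class must be nonempty")


@dataclass(frozen=True)
class RegulatoryFeature:
    """Conserved TFBS or enhancer element (BED convention)."""

    contig: str
    start: int
    end: int
    kind: str  # tfbs | enhancer
    label: str

    def __post_init__(self):
        if self.kind not in ("tfbs", "enhancer"):
            raise ValueError(f"kind must be tfbs|enhancer, got {self.kind!r}")


@dataclass
class AnnotatedVariant:
    variant: VariantCall
    region: str
    transcript_id: str | None = None
    per_transcript: dict[str, str] = field(default_factory=dict)
    coding_effect: str = "none"
    premature_stop_at: int | None = None
    repeat_labels: list[tuple[str, str]] = field(default_factory=list)
    regulatory_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.coding_effect != "none" and self.region != REGION_CODING:
            raise ValueError("coding effect on a non-coding variant")


# ---------------------------------------------------------------------------
# region classification


def _overlaps(span: tuple[int, int], iv: tuple[int, int]) -> bool:
    return span[0] < iv[1] and iv[0] < span[1]


def region_in_transcript(span: tuple[int, int], t: TranscriptModel) -> str | None:
    """Region of a variant span within one transcript, or None if outside."""
    if not _overlaps(span, t.span):
        return None
    in_exon = any(_overlaps(span, e) for e in t.exons)
    if not in_exon:
        return REGION_INTRON
    if not t.cds:
        return REGION_NC_EXON
    if any(_overlaps(span, c) for c in t.cds):
        return REGION_CODING
    # exonic but outside CDS: 5' or 3' UTR, strand-aware
    cds_lo, cds_hi = t.cds_span
    if span[1] <= cds_lo:  # genomically left of CDS
        return REGION_UTR5 if t.strand == "+" else REGION_UTR3
    if span[0] >= cds_hi:
        return REGION_UTR3 if t.strand == "+" else REGION_UTR5
    # spans the CDS boundary without touching CDS cannot happen; fallback
    return REGION_NC_EXON


class TranscriptIndex:
    """Interval index over transcript spans for fast region queries."""

    def __init__(self, transcripts: list[TranscriptModel]):
        self.transcripts = list(transcripts)
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for t in transcripts:
            s, e = t.span
            self._trees[t.contig].addi(s, e, t)

    def overlapping(self, contig: str, span: tuple[int, int]) -> list[TranscriptModel]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(*span)]


def classify_region(
    variant: VariantCall,
    transcripts: list[TranscriptModel] | TranscriptIndex,
) -> tuple[str, str | None, dict[str, str]]:
    """Single most-severe region label for a variant across transcripts.

    Returns (region, transcript id that supplied the label or None, and the
    full per-transcript label map).  With no overlapping transcript the
    variant is intergenic.
    """
    index = (
        transcripts
        if isinstance(transcripts, TranscriptIndex)
        else TranscriptIndex(transcripts)
    )
    span = variant.span
    best = (REGION_INTERGENIC, None)
    per_t: dict[str, str] = {}
    for t in sorted(index.overlapping(variant.contig, span), key=lambda t: t.id):
        r = region_in_transcript(span, t)
        if r is None:
            continue
        per_t[t.id] = r
        if _REGION_RANK[r] < _REGION_RANK[best[0]]:
            best = (r, t.id)
    return best[0], best[1], per_t


# ---------------------------------------------------------------------------
# coding consequences


def _cds_plus_sequence(t: TranscriptModel, reference: dict[str, str]) -> str:
    seq = reference[t.contig]
    return "".join(seq[s:e] for s, e in t.cds)


def _cds_offset_plus(t: TranscriptModel, gpos0: int) -> int:
    """Offset of a genomic position within the plus-strand CDS concatenation."""
    off = 0
    for s, e in t.cds:
        if s <= gpos0 < e:
            return off + (gpos0 - s)
        off += e - s
    raise ValueError(f"position {gpos0 + 1} not inside the CDS of {t.id}")


def coding_effect_snp(
    variant: VariantCall,
    transcript: TranscriptModel,
    reference: dict[str, str],
) -> str:
    """synonymous | missense | nonsense for a single-base substitution in CDS.

    The reference codon is built in transcript orientation (reverse-complement
    on '-'), the alternate base substituted, and both codons translated with
    the standard nuclear code; an alternate stop codon is nonsense.
    """
    if variant.vtype != "snp":
        raise ValueError("coding_effect_snp handles single-base substitutions only")
    gpos0 = variant.pos - 1
    off_plus = _cds_offset_plus(transcript, gpos0)  # raises if outside CDS
    plus_seq = _cds_plus_sequence(transcript, reference)
    if transcript.strand == "+":
        cds_seq, off, alt = plus_seq, off_plus, variant.alts[0]
    else:
        cds_seq = revcomp(plus_seq)
        off = len(plus_seq) - 1 - off_plus
        alt = revcomp(variant.alts[0])
    ci = off // 3
    codon = cds_seq[3 * ci : 3 * ci + 3]
    mutated = codon[: off % 3] + alt + codon[off % 3 + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    if aa_alt == aa_ref:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    return "missense"


def coding_effect_indel(
    variant: VariantCall,
    transcript: TranscriptModel,
    reference: dict[str, str],
) -> tuple[str, int | None, bool]:
    """(inframe|frameshift, premature stop codon index, boundary flag).

    Frame is decided by the net CDS length change modulo 3, counting only
    bases inside the CDS for deletions that straddle a boundary (flagged).
    For frameshifts the mutated CDS is translated until the first stop and
    its 1-based codon index reported (None if no stop before CDS end).
    """
    if variant.vtype != "indel":
        raise ValueError("not an indel")
    ref, alt = variant.ref, variant.alts[0]
    anchor0 = variant.pos - 1
    cds_ivs = transcript.cds
    in_cds = lambda p: any(s <= p < e for s, e in cds_ivs)

    boundary = False
    if len(ref) > len(alt):  # deletion of ref[1:] after the anchor base
        deleted = range(anchor0 + 1, anchor0 + len(ref))
        del_in = [p for p in deleted if in_cds(p)]
        if not del_in and not in_cds(anchor0):
            raise ValueError("indel does not touch the CDS")
        boundary = len(del_in) != len(deleted)
        net = -len(del_in)
    else:  # insertion after the anchor base
        if not in_cds(anchor0):
            raise ValueError("indel anchor not inside the CDS")
        net = len(alt) - len(ref)

    kind = "inframe" if net % 3 == 0 else "frameshift"
    stop_at = None
    if kind == "frameshift":
        plus = _cds_plus_sequence(transcript, reference)
        # apply the edit in plus-strand CDS coordinates
        if len(ref) > len(alt):
            keep = [
                i
                for i, p in enumerate(_cds_positions(transcript))
                if p not in set(deleted)
            ]
            mut_plus = "".join(plus[i] for i in keep)
        else:
            off = _cds_offset_plus(transcript, anchor0)
            if transcript.strand == "+":
                mut_plus = plus[: off + 1] + alt[1:] + plus[off + 1 :]
            else:
                # inserted bases follow the anchor on the genome regardless of
                # transcript strand
                mut_plus = plus[: off + 1] + alt[1:] + plus[off + 1 :]
        mut = mut_plus if transcript.strand == "+" else revcomp(mut_plus)
        for ci in range(len(mut) // 3):
            if mut[3 * ci : 3 * ci + 3] in STANDARD_STOPS:
                stop_at = ci + 1
                break
    return kind, stop_at, boundary


def _cds_positions(t: TranscriptModel) -> list[int]:
    out = []
    for s, e in t.cds:
        out.extend(range(s, e))
    return out


# ---------------------------------------------------------------------------
# repeats, regulatory, TSS profiles


def repeat_overlap(
    variants: list[VariantCall], repeats: list[RepeatFeature]
) -> dict:
    """Per-class and per-family counts of variants overlapping repeats.

    A variant overlapping repeats of k distinct classes contributes once to
    each class label but only once to the in-repeat denominator.  Class
    percentages are reported over variants-in-repeats and over all variants
    (the two candidate denominators).
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for r in repeats:
        trees[r.contig].addi(r.start, r.end, r)
    per_variant: list[list[tuple[str, str]]] = []
    class_counts: Counter = Counter()
    family_counts: Counter = Counter()
    n_in_repeat = 0
    for v in variants:
        tree = trees.get(v.contig)
        hits = [iv.data for iv in tree.overlap(*v.span)] if tree else []
        labels = sorted({(r.rclass, r.family) for r in hits})
        per_variant.append(labels)
        if labels:
            n_in_repeat += 1
            for c in {r.rclass for r in hits}:
                class_counts[c] += 1
            for f in {(r.rclass, r.family) for r in hits}:
                family_counts[f] += 1
    n_total = len(variants)
    pct_of_repeat = {
        c: 100.0 * n / n_in_repeat for c, n in class_counts.items()
    } if n_in_repeat else {}
    pct_of_all = {c: 100.0 * n / n_total for c, n in class_counts.items()} if n_total else {}
    return {
        "n_variants": n_total,
        "n_in_repeat": n_in_repeat,
        "class_counts": dict(class_counts),
        "family_counts": {f"{c}/{f}": n for (c, f), n in family_counts.items()},
        "pct_of_in_repeat": pct_of_repeat,
        "pct_of_all": pct_of_all,
        "per_variant": per_variant,
    }


def tss_profile(
    variants: list[VariantCall],
    transcripts: list[TranscriptModel],
    half_window: int = 2000,
    bin_size: int = 50,
) -> dict:
    """Mean variant count per bin around TSSs, strand-oriented.

    Bin edges run from -half_window to +half_window in steps of bin_size;
    position x relative to the TSS is negative upstream of transcription and
    positive downstream ('-'-strand transcripts are mirrored).  The profile
    value is total variants in the bin divided by the number of transcripts.
    """
    if half_window % bin_size:
        raise ValueError("half_window must be a multiple of bin_size")
    n_bins = 2 * half_window // bin_size
    counts = np.zeros(n_bins)
    by_contig: dict[str, list[int]] = defaultdict(list)
    for v in variants:
        by_contig[v.contig].append(v.pos - 1)
    for t in transcripts:
        positions = by_contig.get(t.contig, ())
        for p in positions:
            rel = p - t.tss if t.strand == "+" else t.tss - p
            if -half_window <= rel < half_window:
                counts[(rel + half_window) // bin_size] += 1
    n_t = len(transcripts)
    profile = counts / n_t if n_t else counts
    edges = np.arange(-half_window, half_window + 1, bin_size)
    return {"bin_left": edges[:-1], "bin_right": edges[1:], "profile": profile}


def upstream_window(t: TranscriptModel, size: int = 5000) -> tuple[int, int]:
    """Strand-aware window of ``size`` bases immediately upstream of the TSS."""
    if t.strand == "+":
        return (max(0, t.tss - size), t.tss)
    return (t.tss + 1, t.tss + 1 + size)


def regulatory_overlap(
    variants: list[VariantCall],
    features: list[RegulatoryFeature],
    transcripts: list[TranscriptModel],
    upstream: int = 5000,
) -> dict:
    """Counts of SNPs / indels in TFBSs (promoter-proximal) and enhancers.

    A TFBS hit counts only when the variant also lies within ``upstream``
    bases upstream of some gene's TSS; enhancer hits count genome-wide.
    """
    up_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for t in transcripts:
        s, e = upstream_window(t, upstream)
        if e > s:
            up_trees[t.contig].addi(s, e)
    feat_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for f in features:
        feat_trees[f.contig].addi(f.start, f.end, f)
    counts = {"tfbs": {"snp": 0, "indel": 0}, "enhancer": {"snp": 0, "indel": 0}}
    per_variant: list[list[str]] = []
    for v in variants:
        span = v.span
        tree = feat_trees.get(v.contig)
        hits = [iv.data for iv in tree.overlap(*span)] if tree else []
        kinds = set()
        in_upstream = bool(
            up_trees.get(v.contig) and up_trees[v.contig].overlap(*span)
        )
        for f in hits:
            if f.kind == "enhancer":
                kinds.add("enhancer")
            elif f.kind == "tfbs" and in_upstream:
                kinds.add("tfbs")
        for k in kinds:
            counts[k][v.vtype] += 1
        per_variant.append(sorted(kinds))
    return {"counts": counts, "per_variant": per_variant}


# ---------------------------------------------------------------------------
# gene-set enrichment


def geneset_enrichment(
    hit_genes: set[str],
    universe: set[str],
    genesets: dict[str, set[str]],
    fdr_threshold: float = 0.05,
):
    """Hypergeometric over-representation test with Benjamini-Hochberg FDR.

    For each set: p = P(X >= k) drawing n = |hit_genes| from a universe of
    N genes containing K set members.  Returns a DataFrame with one row per
    set (p, BH-adjusted q, enriched flag at q <= fdr_threshold).
    """
    import pandas as pd

    if not universe:
        raise ValueError("empty gene universe")
    if not hit_genes <= universe:
        raise ValueError("hit_genes must be a subset of the universe")
    N, n = len(universe), len(hit_genes)
    rows = []
    for name in sorted(genesets):
        members = genesets[name] & universe
        K = len(members)
        k = len(members & hit_genes)
        # upper tail P(X >= k); k = 0 gives p = 1 under this convention
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append({"geneset": name, "K": K, "k": k, "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if len(df):
        _, q, _, _ = multipletests(df["p"], method="fdr_bh")
        df["q"] = q
        df["enriched"] = df["q"] <= fdr_threshold
    return df
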