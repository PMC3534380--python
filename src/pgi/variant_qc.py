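"""Variant quality control: hard filters, array concordance, coverage summaries.

Filters follow standard short-read calling practice for a single deeply
sequenced genome: calls are retained when read depth lies in [depth_min,
depth_max] (the depth rule is waived on the mitochondrial contig, whose copy
number puts it far above any nuclear cap), the variant quality is at least
qual_min, and heterozygous calls sharing no allele with the reference base are
discarded as likely alignment artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._util import norm_genotype, round_half_up

FAIL_DEPTH = "depth"
FAIL_QUALITY = "quality"
FAIL_HET_NO_REF = "het_no_ref"
# first-failing-rule attribution order; makes report counts additive
FILTER_ORDER = (FAIL_DEPTH, FAIL_QUALITY, FAIL_HET_NO_REF)


@dataclass(frozen=True)
class VariantCall:
    """One called substitution or indel.

    pos is 1-based (VCF convention).  genotype is an unordered allele pair;
    None means missing.  quality is phred-scaled.
    """

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotype: tuple[str, ...] | None
    depth: int
    quality: float

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        for a in self.alts:
            if a == self.ref:
                raise ValueError(f"ref == alt ({a}) at {self.contig}:{self.pos}")
        if self.genotype is not None:
            object.__setattr__(self, "genotype", norm_genotype(*self.genotype))
        object.__setattr__(self, "alts", tuple(a.upper() for a in self.alts))
        object.__setattr__(self, "ref", self.ref.upper())

    @property
    def vtype(self) -> str:
        if len(self.ref) == 1 and all(len(a) == 1 for a in self.alts):
            return "snp"
        return "indel"

    @property
    def is_het(self) -> bool:
        return self.genotype is not None and self.genotype[0] != self.genotype[1]

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open reference span: the consumed bases for deletions,
        the single anchor base for insertions and SNPs."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))


@dataclass
class FilterReport:
    n_input: int
    n_pass: int
    n_fail_depth: int = 0
    n_fail_quality: int = 0
    n_fail_het_no_ref: int = 0
    pass_set: list[VariantCall] = field(default_factory=list)
    fail_reasons: list[tuple[VariantCall, str]] = field(default_factory=list)

    def __post_init__(self):
        total = self.n_pass + self.n_fail_depth + self.n_fail_quality + self.n_fail_het_no_ref
        if total != self.n_input:
            raise ValueError(f"fail counts + passes ({total}) != n_input ({self.n_input})")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_pass": self.n_pass,
            "n_fail_depth": self.n_fail_depth,
            "n_fail_quality": self.n_fail_quality,
            "n_fail_het_no_ref": self.n_fail_het_no_ref,
        }


def _first_fail(
    call: VariantCall,
    depth_min: int,
    depth_max: int,
    qual_min: float,
    mito_contig: str | None,
    reference: dict[str, str] | None,
) -> str | None:
    depth_exempt = mito_contig is not None and call.contig == mito_contig
    if not depth_exempt and not (depth_min <= call.depth <= depth_max):
        return FAIL_DEPTH
    if call.quality < qual_min:
        return FAIL_QUALITY
    if reference is not None and _het_without_ref(call, reference):
        return FAIL_HET_NO_REF
    return None


def _het_without_ref(call: VariantCall, reference: dict[str, str]) -> bool:
    if not call.is_het:
        return False
    contig_seq = reference.get(call.contig)
    if contig_seq is None or call.pos > len(contig_seq):
        raise ValueError(
            f"call {call.contig}:{call.pos} lies beyond the reference contig"
        )
    ref_allele = call.ref
    return ref_allele not in call.genotype


def filter_variants(
    calls: list[VariantCall],
    depth_min: int = 5,
    depth_max: int = 60,
    qual_min: float = 30,
    mito_contig: str | None = None,
    reference: dict[str, str] | None = None,
) -> FilterReport:
    """Apply the depth/quality (and optionally het-no-ref) filters.

    Depth bounds are inclusive and waived entirely on ``mito_contig``.  A call
    failing several rules is attributed to the first failing rule in the order
    depth -> quality -> het-no-ref, so the report counts are additive.
    Passing ``reference`` enables the het-no-ref rule in the same sweep.
    """
    if depth_min < 0 or qual_min < 0:
        raise ValueError("thresholds must be non-negative")
    if depth_min > depth_max:
        raise ValueError(f"depth_min ({depth_min}) > depth_max ({depth_max})")
    if mito_contig is not None and not any(c.contig == mito_contig for c in calls):
        warnings.warn(
            f"mito contig {mito_contig!r} not seen in calls; depth rule applies everywhere",
            stacklevel=2,
        )
    counts = {FAIL_DEPTH: 0, FAIL_QUALITY: 0, FAIL_HET_NO_REF: 0}
    passed, reasons = [], []
    for call in calls:
        why = _first_fail(call, depth_min, depth_max, qual_min, mito_contig, reference)
        if why is None:
            passed.append(call)
        else:
            counts[why] += 1
            reasons.append((call, why))
    return FilterReport(
        n_input=len(calls),
        n_pass=len(passed),
        n_fail_depth=counts[FAIL_DEPTH],
        n_fail_quality=counts[FAIL_QUALITY],
        n_fail_het_no_ref=counts[FAIL_HET_NO_REF],
        pass_set=passed,
        fail_reasons=reasons,
    )


def exclude_het_without_ref_allele(
    calls: list[VariantCall], reference: dict[str, str]
) -> FilterReport:
    """Drop heterozygous calls whose two alleles both differ from the reference.

    Homozygous calls (including homozygous non-reference) pass this rule.
    """
    passed, reasons = [], []
    for call in calls:
        if _het_without_ref(call, reference):
            reasons.append((call, FAIL_HET_NO_REF))
        else:
            passed.append(call)
    return FilterReport(
        n_input=len(calls),
        n_pass=len(passed),
        n_fail_het_no_ref=len(reasons),
        pass_set=passed,
        fail_reasons=reasons,
    )


def concordance_pct(n_concordant: int, n_sites: int) -> float:
    """Concordance percentage at the customary one-decimal precision."""
    if n_sites == 0:
        raise ValueError("no sites to compare")
    return round_half_up(100.0 * n_concordant / n_sites, 1)


def array_concordance(
    seq_genotypes: dict[tuple[str, int], tuple[str, ...] | None],
    array_genotypes: dict[tuple[str, int], tuple[str, ...] | None],
) -> dict:
    """Genotype concordance between sequencing calls and array genotypes.

    Compared over the intersection of (contig, pos) keys; sites where either
    genotype is missing are excluded from the denominator.  Comparison is
    unordered (A/G == G/A).  Symmetric in its two inputs.
    """
    shared = seq_genotypes.keys() & array_genotypes.keys()
    n_sites = n_conc = 0
    for key in shared:
        a, b = seq_genotypes[key], array_genotypes[key]
        if a is None or b is None:
            continue
        n_sites += 1
        if norm_genotype(*a) == norm_genotype(*b):
            n_conc += 1
    if n_sites == 0:
        raise ValueError("no overlapping sites with genotypes on both sides")
    return {"n_sites": n_sites, "n_concordant": n_conc, "pct": concordance_pct(n_conc, n_sites)}


@dataclass
class CoverageWindow:
    contig: str
    start: int  # 0-based
    end: int
    gc_fraction: float
    mean_depth: float
    partial: bool


@dataclass
class CoverageProfile:
    histogram: np.ndarray  # fraction of non-N bases at each depth
    mean_depth: float
    frac_ge1: float
    frac_ge5: float
    windows: list[CoverageWindow]
    poisson_ref: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "depth": np.arange(len(self.histogram)),
                "fraction": self.histogram,
                "poisson": self.poisson_ref,
            }
        )


def coverage_profile(
    depths: np.ndarray,
    reference: str,
    window: int = 50_000,
    contig: str = "chr1",
) -> CoverageProfile:
    """Depth histogram, summary fractions and 50-kb GC/depth windows.

    ``depths`` is per-base depth over one contig; N bases are excluded from
    every denominator.  The returned Poisson pmf has the same mean as the
    observed distribution, for tail comparison.  The final partial window is
    emitted with its true length and flagged.
    """
    depths = np.asarray(depths)
    if len(depths) != len(reference):
        raise ValueError("depths length must equal reference length")
    ref = np.frombuffer(reference.upper().encode(), dtype="S1")
    non_n = ref != b"N"
    n_eff = int(non_n.sum())
    if n_eff == 0:
        raise ValueError("reference is all N")
    d = depths[non_n]
    hist = np.bincount(d) / n_eff
    mean_depth = float(d.sum() / n_eff)
    frac_ge1 = float((d >= 1).mean())
    frac_ge5 = float((d >= 5).mean())
    pois = stats.poisson.pmf(np.arange(len(hist)), mean_depth)
    windows = []
    gc = (ref == b"G") | (ref == b"C")
    for start in range(0, len(reference), window):
        end = min(start + window, len(reference))
        w_non_n = non_n[start:end]
        n_w = int(w_non_n.sum())
        gc_frac = float(gc[start:end].sum() / n_w) if n_w else float("nan")
        mean_w = float(depths[start:end][w_non_n].mean()) if n_w else float("nan")
        windows.append(
            CoverageWindow(contig, start, end, gc_frac, mean_w, partial=(end - start) < window)
        )
    return CoverageProfile(hist, mean_depth, frac_ge1, frac_ge5, windows, pois)
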