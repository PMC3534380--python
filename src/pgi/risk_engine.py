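"""Likelihood-ratio genetic risk assessment.

The procedure mirrors diagnostic-test reasoning on the odds scale: a disease
prevalence stratified by age, sex and ethnicity gives the pre-test
probability p0; each disease-associated SNP carries genotype-specific
likelihood ratios LR(g) = P(g | disease) / P(g | no disease); SNPs in mutual
linkage disequilibrium (r^2 above a threshold) are pruned down to the one
with the strongest evidence; the retained, approximately independent LRs are
multiplied into a combined ratio L; and the post-test probability follows
from odds(p1) = L * odds(p0).  The subject's combined L is ranked against a
reference population panel, and a cumulative "riskogram" series records p1
as each SNP is folded in, in decreasing order of supporting studies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from ._util import genotype_key

logger = logging.getLogger(__name__)

LR_CAP = 1000.0  # cap for zero-denominator LRs; keeps products finite


@dataclass(frozen=True)
class AssociationRecord:
    """One disease-associated SNP with genotype-specific likelihood ratios."""

    rsid: str
    contig: str
    pos: int
    disease: str
    lr_by_genotype: dict[str, float]
    n_studies: int
    n_samples: int
    population_freq: float | None = None

    def __post_init__(self):
        if not self.lr_by_genotype:
            raise ValueError(f"{self.rsid}: empty LR map")
        if self.n_studies < 1:
            raise ValueError(f"{self.rsid}: n_studies must be >= 1")
        norm = {genotype_key(g): float(lr) for g, lr in self.lr_by_genotype.items()}
        for g, lr in norm.items():
            if lr <= 0:
                raise ValueError(f"{self.rsid}: LR({g}) = {lr} must be > 0")
        object.__setattr__(self, "lr_by_genotype", norm)


@dataclass(frozen=True)
class LDRecord:
    rsid_a: str
    rsid_b: str
    r2: float

    def __post_init__(self):
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"r2 must be in [0,1], got {self.r2}")


@dataclass(frozen=True)
class PrevalenceRecord:
    disease: str
    age_lo: int
    age_hi: int
    sex: str
    ethnicity: str
    pretest_prob: float

    def __post_init__(self):
        if not 0.0 < self.pretest_prob < 1.0:
            raise ValueError(f"pretest probability must be in (0,1), got {self.pretest_prob}")


@dataclass(frozen=True)
class PGxRecord:
    rsid: str
    gene: str
    genotype: str
    drug: str
    outcome_text: str

    def __post_init__(self):
        if not self.genotype:
            raise ValueError("genotype must be nonempty")
        object.__setattr__(self, "genotype", genotype_key(self.genotype))


@dataclass
class RiskAssessment:
    disease: str
    pretest: float
    kept: list[AssociationRecord]
    contributions: list[dict]  # rsid, n_studies, n_samples, genotype, lr, cum_p1
    combined_lr: float
    posttest: float
    percentile: float | None = None

    def riskogram_series(self) -> list[float]:
        return [c["cum_p1"] for c in self.contributions]


# ---------------------------------------------------------------------------


def pretest_probability(
    disease: str,
    age: int,
    sex: str,
    ethnicity: str,
    table: list[PrevalenceRecord],
) -> float:
    """Pre-test probability from the prevalence stratum matching the subject.

    Requires exactly one matching stratum (disease, age in [lo, hi], sex,
    ethnicity); zero or several matches is an error.
    """
    matches = [
        r
        for r in table
        if r.disease == disease
        and r.age_lo <= age <= r.age_hi
        and r.sex == sex
        and r.ethnicity == ethnicity
    ]
    if not matches:
        strata = sorted(
            {(r.disease, r.age_lo, r.age_hi, r.sex, r.ethnicity) for r in table}
        )
        raise LookupError(
            f"no prevalence stratum for ({disease}, {age}, {sex}, {ethnicity}); "
            f"available: {strata}"
        )
    if len(matches) > 1:
        raise LookupError(f"ambiguous prevalence strata for {disease}: {matches}")
    return matches[0].pretest_prob


def evidence_order(records: list[AssociationRecord]) -> list[AssociationRecord]:
    """Strongest evidence first: n_studies desc, n_samples desc, rsid asc."""
    return sorted(records, key=lambda r: (-r.n_studies, -r.n_samples, r.rsid))


def ld_prune(
    records: list[AssociationRecord],
    ld: list[LDRecord],
    r2_max: float = 0.3,
) -> list[AssociationRecord]:
    """Greedy LD pruning: keep the strongest-evidence SNP of each LD clump.

    Records are visited strongest-evidence first; one is kept iff its r^2
    against every already-kept record is <= r2_max.  The result never
    contains a pair with r^2 > r2_max.
    """
    r2map: dict[frozenset[str], float] = {}
    for rec in ld:
        key = frozenset((rec.rsid_a, rec.rsid_b))
        r2map[key] = max(r2map.get(key, 0.0), rec.r2)

    def r2(a: str, b: str) -> float:
        return r2map.get(frozenset((a, b)), 0.0)

    kept: list[AssociationRecord] = []
    for rec in evidence_order(records):
        if all(r2(rec.rsid, k.rsid) <= r2_max for k in kept):
            kept.append(rec)
    return kept


def lr_contributions(
    genotypes: dict[str, str],
    kept: list[AssociationRecord],
) -> list[tuple[AssociationRecord, str | None, float]]:
    """Per-record (genotype used, LR) with the missing-data convention.

    A missing subject genotype, or one absent from a record's LR map,
    contributes LR = 1 (no information) and is logged.
    """
    out = []
    for rec in kept:
        g = genotypes.get(rec.rsid)
        g = genotype_key(g) if g is not None else None
        if g is None or g not in rec.lr_by_genotype:
            logger.info("no usable genotype for %s (%s); LR = 1", rec.rsid, g)
            out.append((rec, g, 1.0))
        else:
            out.append((rec, g, rec.lr_by_genotype[g]))
    return out


def combined_lr(genotypes: dict[str, str], kept: list[AssociationRecord]) -> float:
    """Product of per-SNP likelihood ratios (accumulated in log space)."""
    log_sum = 0.0
    for _, _, lr in lr_contributions(genotypes, kept):
        if lr <= 0:
            raise ValueError("likelihood ratios must be > 0")
        log_sum += math.log(lr)
    return math.exp(log_sum)


def posttest_probability(p0: float, lr: float) -> float:
    """Post-test probability via the odds form: odds1 = lr * odds0."""
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"pre-test probability must be in (0,1), got {p0}")
    if lr <= 0:
        raise ValueError(f"likelihood ratio must be > 0, got {lr}")
    odds = lr * p0 / (1.0 - p0)
    return odds / (1.0 + odds)


def risk_percentile(
    subject_lr: float,
    panel_genotypes: dict[str, dict[str, str]],
    kept: list[AssociationRecord],
) -> float:
    """Percent of panel individuals with strictly smaller combined LR.

    Ties are excluded (a subject equal to the whole panel sits at 0%).
    Missing panel genotypes contribute LR = 1, as for the subject.
    """
    if not panel_genotypes:
        raise ValueError("empty population panel")
    panel_lrs = [combined_lr(g, kept) for g in panel_genotypes.values()]
    n_below = sum(1 for lr in panel_lrs if lr < subject_lr)
    return 100.0 * n_below / len(panel_lrs)


def riskogram(
    p0: float,
    genotypes: dict[str, str],
    kept: list[AssociationRecord],
) -> list[dict]:
    """Cumulative post-test probabilities, strongest-studied SNPs first.

    Row k reports the post-test probability after multiplying the first k
    likelihood ratios in (n_studies desc, n_samples desc, rsid asc) order.
    With no kept records the series is empty and the summary p1 equals p0.
    """
    ordered = evidence_order(kept)
    rows = []
    log_sum = 0.0
    for rec, g, lr in lr_contributions(genotypes, ordered):
        log_sum += math.log(lr)
        rows.append(
            {
                "rsid": rec.rsid,
                "n_studies": rec.n_studies,
                "n_samples": rec.n_samples,
                "genotype": g,
                "lr": lr,
                "cum_lr": math.exp(log_sum),
                "cum_p1": posttest_probability(p0, math.exp(log_sum)),
            }
        )
    return rows


def assess_disease(
    disease: str,
    p0: float,
    records: list[AssociationRecord],
    ld: list[LDRecord],
    genotypes: dict[str, str],
    panel_genotypes: dict[str, dict[str, str]] | None = None,
    r2_max: float = 0.3,
) -> RiskAssessment:
    """Full per-disease assessment: prune, combine, post-test, percentile."""
    kept = ld_prune([r for r in records if r.disease == disease], ld, r2_max)
    rows = riskogram(p0, genotypes, kept)
    lam = rows[-1]["cum_lr"] if rows else 1.0
    p1 = rows[-1]["cum_p1"] if rows else p0
    pct = (
        risk_percentile(lam, panel_genotypes, kept)
        if panel_genotypes is not None
        else None
    )
    return RiskAssessment(
        disease=disease,
        pretest=p0,
        kept=kept,
        contributions=rows,
        combined_lr=lam,
        posttest=p1,
        percentile=pct,
    )


def pgx_lookup(genotypes: dict[str, str], table: list[PGxRecord]) -> list[PGxRecord]:
    """Records whose (rsid, genotype) exactly matches the subject (unordered)."""
    matched = []
    for rec in table:
        g = genotypes.get(rec.rsid)
        if g is not None and genotype_key(g) == rec.genotype:
            matched.append(rec)
    return matched
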