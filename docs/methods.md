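# Methods

This note documents the models behind `pgi`, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the design
choices made where the design was genuinely open.

## Variant quality control

Calls are filtered by three conjunctive rules, applied in the fixed order
**depth → quality → het-no-ref**:

* depth of coverage d with 5 ≤ d ≤ 60 (both bounds inclusive). On the
  mitochondrial contig both bounds are waived, since mtDNA copy number puts
  its depth far above any nuclear cap. We waive the floor as well as the
  ceiling: a mito call with nuclear-scale low depth is vanishingly unlikely,
  and a one-sided exemption would silently change the rule's meaning per
  contig. The quality rule still applies everywhere.
* phred-scaled variant quality Q ≥ 30;
* heterozygous calls whose two alleles both differ from the reference base
  are removed (alignment-artifact guard); homozygous non-reference calls are
  untouched by this rule.

A call failing several rules is counted once, under the first failing rule.
This makes the report additive (n_input = n_pass + Σ failures) and means the
retained set is order-independent even though the attribution is not.

Array concordance compares unordered genotypes over the intersection of
(contig, position) keys; missing genotypes are excluded from the
denominator, and an empty intersection is an error rather than 0%.
Percentages are rounded half-up at one decimal (two for mean depth),
matching how such figures are conventionally printed; Python's built-in
banker's rounding would differ on exact ties.

Coverage profiles exclude N bases from every denominator, report the depth
histogram next to a Poisson pmf of matched mean for tail comparison, and
summarize GC fraction and mean depth in non-overlapping 50-kb windows. The
final partial window is emitted with its true length and flagged, so that
window-GC totals conserve the genome-wide GC count exactly.

## Functional annotation

All interval arithmetic is 0-based half-open internally; VCF/GFF3 (1-based
inclusive) and BED (0-based half-open) are converted at the I/O boundary so
overlap logic exists in exactly one convention.

Region labels {coding_exon, utr5, utr3, noncoding_exon, intron, intergenic}
partition every variant. Across overlapping transcripts the most severe
label wins (precedence in the order listed); the per-transcript labels are
retained alongside. A variant's footprint is the reference-consumed span for
deletions and the single anchor base for insertions and SNPs.

Codon effects are computed on the CDS concatenated in translation order
(reverse-complemented on the minus strand). For frameshifts the mutated CDS
is translated codon-by-codon and the 1-based index of the first stop is
reported (None if the shifted frame runs off the CDS end without a stop).
Deletions straddling a CDS boundary are flagged and their frame computed
from the in-CDS bases only.

Repeat overlap counts a variant once per overlapped repeat *class* but once
in the variants-in-repeats denominator. Because the published shares of
variants in LINE/SINE elements are quoted without defining the denominator,
both are reported: percentage of variants-in-repeats and of all variants.

TSS metaprofiles use a ±2 kb window in 50-bp bins (both configurable; the
window resolves features tens of bases from the start site). Position is
strand-oriented: negative upstream of transcription, minus-strand
transcripts mirrored. The profile value is total variants per bin divided by
the number of transcripts. TFBS overlap is restricted to variants that also
lie within the 5-kb strand-aware upstream window of some gene; enhancer
overlap is genome-wide.

Gene-set enrichment is a one-sided hypergeometric tail P(X ≥ k) with
Benjamini–Hochberg FDR (enriched iff q ≤ 0.05). This deliberately replaces
the EASE-adjusted score used by DAVID-style tools; the plain tail is exact,
has no ad-hoc offset, and its BH q-values are monotone in the p-ranking.

## Genome comparison

Sharing between catalogs, by default, requires the same (contig, position)
*and* an overlapping alternate allele; position-only sharing is available by
flag, since published shared percentages mix the two rules. Novel sites are
those shared with no panel and no catalog. Indel representations are
normalized before keying (shared-suffix then shared-prefix trimming with
position adjustment); without this, representation differences masquerade as
novelty. Novel sites partition into gene-only / repeat-only / both / other
by transcript-span and repeat-interval membership; an empty novel set
reports zero percentages with an explicit flag rather than NaNs.

## Risk engine

The engine is diagnostic-test reasoning on the odds scale. Pre-test
probability p₀ comes from an exact prevalence-stratum lookup (disease, age
range, sex, ethnicity); zero or multiple matching strata are errors, not
guesses. LD pruning is greedy in "strongest evidence" order —
n_studies desc, n_samples desc, rsid asc as the deterministic tiebreak — and
keeps a SNP iff its r² to every already-kept SNP is ≤ 0.3. The kept,
approximately independent LRs multiply into Λ (accumulated in log space;
the contract is the product), and

    p₁ = Λ·odds₀ / (1 + Λ·odds₀),  odds₀ = p₀/(1−p₀).

A missing subject or panel genotype at a kept SNP contributes LR = 1 (no
information) and is logged. The population percentile counts panel
individuals with strictly smaller Λ; ties are excluded, so a subject equal
to the whole panel ranks at 0%. Riskogram rows fold SNPs in most-studied
first and record the cumulative p₁; with no kept SNPs the series is empty
and p₁ = p₀. Pharmacogenomic lookup is an exact unordered (rsid, genotype)
join — no fuzzy matching.

## Mitochondrial genome

The subject and reference mt sequences must be equal length (substitutions
only; alignment is out of scope). Regions are 1-based inclusive intervals on
the circular molecule and may wrap the origin; wrapped arithmetic uses an
unrolled doubled sequence. Each variant is assigned one region category
(control / noncoding / rna / protein_coding; first containing region wins),
and coding variants are split synonymous/non-synonymous under the vertebrate
mitochondrial code — TGA is Trp and AGA/AGG are stops, so the nuclear code
would misclassify exactly those codons. Classification is invariant to
rotating the circular origin together with the region coordinates.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions of a deeply sequenced
personal genome:

| parameter | default | rationale |
|---|---|---|
| depth model | gamma-Poisson, mean 34.94, overdispersion 0.08 | var = μ + 0.08 μ² puts extra weight on both tails relative to Poisson, as real short-read coverage shows; mean matches the target genome |
| exonic SNP fraction | 0.056 | share of intragenic SNPs falling in exons |
| array discordance | 0.013 | complements the 98.7% sequencing/array concordance |
| novel site fraction | 0.026 | share of subject SNPs absent from panels and catalogs |
| reference panel | 101 individuals | size of the population used for risk percentiles |
| diseases × SNPs | 49 × 8 | breadth of the risk screen |
| mt variants | 35: 9 control / 1 noncoding / 5 RNA / 20 coding (16 syn / 4 non-syn) | the mitochondrial comparison being emulated |
| quality model | N(60, 18²) clipped to [1, 99] | leaves a few percent of calls under the Q30 floor |

Association LRs are derived from simulated case/control genotype
frequencies: controls are Hardy–Weinberg with MAF ~ U(0.1, 0.5); cases tilt
the control frequencies by a per-allele relative risk rr ~ U(0.7, 2.2);
LR(g) is the frequency ratio, capped at 1000 when a control frequency is
zero (keeps products finite without changing ordering). The generative
frequencies are stored as the bundle's truth, which is what makes the
calibration test meaningful.

Deliberately **not** emulated: reads and alignments, realistic human LD
block structure (LD is a planted r² table, not a haplotype model), realistic
allele-frequency spectra, mutation-rate heterogeneity, and sequencing-error
profiles. Passing tests therefore demonstrate the *correctness of the
pipeline's arithmetic and bookkeeping* under a known generative model — not
robustness to the artifacts of real data.

All randomness flows from one integer seed through named generator streams;
regenerating with the same seed reproduces byte-identical files, and the
orchestrated pipeline is idempotent for a fixed seed and config.

## Numerical choices and problem sizes

* LR products in log space; percentages rounded half-up at printed
  precision; genotypes canonicalized as sorted unordered pairs.
* Calibration of the risk machinery is checked on a 2,000-individual cohort
  generated from the bundle's truth, binned by Λ-decile. The criterion is
  the **mean** absolute gap between predicted p₁ and empirical case
  fraction across deciles (≤ 3 percentage points): with ~200 individuals
  per bin the empirical case fraction alone carries ~2.8 pp of binomial
  noise, so a per-bin maximum would fail under perfect calibration; the
  mean-gap statistic (~0.9 pp noise) tests the same property at the stated
  tolerance.
* Default test/demo problem sizes — 100–200 kb contigs, 2,000–10,000 SNPs,
  500–5,000 variants in oracle comparisons, 101-individual panels — are
  chosen so each synthetic experiment is statistically decisive for the
  quantity under test (binomial bounds at 4σ) while the full suite remains
  a desk-scale computation.

## Known limitations

* UTR assignment assumes UTRs flank the CDS within the transcript (no
  coding exons downstream of a 3'UTR exon, as in unusual isoforms).
* Indel normalization trims shared affixes but does not left-align through
  repeat tracts against the reference; catalogs built by this package key
  consistently, but externally supplied representations could still differ.
* The mt comparison handles substitutions only; an indel-bearing subject
  sequence must be aligned upstream.
* The LD-pruning "strongest evidence" order is a deterministic convention;
  other reasonable orders (e.g. by effect size) would keep different SNPs.
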