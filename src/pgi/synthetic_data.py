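"""Synthetic inputs for the whole pipeline, with planted ground truth.

Everything downstream consumes files this module can emit: a small diploid
reference with gene / repeat / regulatory structure, a circular mitochondrial
genome with region annotations, variant calls with overdispersed-Poisson
depths and phred-like qualities, array genotypes with a planted discordance
rate, panel/catalog variant sets with a planted novel fraction, and a
disease-association bundle with genotype-specific likelihood ratios derived
from simulated case/control genotype frequencies.

Planted truth is recorded in a manifest so that every downstream count can be
checked against an independent scan of the emitted files.  All randomness
flows from one integer seed through named generator streams; regenerating
with the same seed reproduces identical output.

Default parameters are chosen to emulate the study conditions of a deeply
sequenced personal genome: mean depth 34.94 with heavier-than-Poisson tails,
5.6% of SNPs exonic, 1.3% array discordance, a 2.6% novel fraction, a
reference panel of 101 individuals and 49 diseases, and 35 mitochondrial
substitutions split 9/1/5/20 across regions with a 16/4 syn/nonsyn ratio in
coding genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import genotype_key, rng_from_seed
from .functional_annotation import (
    RegulatoryFeature,
    RepeatFeature,
    TranscriptModel,
)
from .mtdna import MtRegion, mt_codon_effect
from .risk_engine import (
    LR_CAP,
    AssociationRecord,
    LDRecord,
    PGxRecord,
    PrevalenceRecord,
)
from .variant_qc import VariantCall

BASES = np.array(list("ACGT"))

REPEAT_MENU = (
    # (class, family, weight, length range) — LINE/SINE dominated, like a
    # mammalian repeat landscape
    ("LINE", "L1", 0.41, (400, 900)),
    ("SINE", "Alu", 0.30, (150, 350)),
    ("LTR", "ERVL", 0.12, (200, 500)),
    ("DNA", "hAT-Charlie", 0.09, (100, 300)),
    ("Simple_repeat", "(AT)n", 0.08, (40, 120)),
)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GenomeConfig:
    contig_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 200_000})
    n_genes: int = 20
    n_repeats: int = 80
    n_tfbs: int = 30
    n_enhancers: int = 15
    tfbs_upstream_fraction: float = 0.6  # TFBSs placed in 5-kb upstream windows
    mt_length: int = 16_569
    mt_n_control: int = 9
    mt_n_noncoding: int = 1
    mt_n_rna: int = 5
    mt_n_syn: int = 16
    mt_n_nonsyn: int = 4

    def validate(self):
        for name, ln in self.contig_lengths.items():
            if ln < 10_000:
                raise ValueError(f"contig {name} shorter than 10 kb")
        for f in (self.tfbs_upstream_fraction,):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {f} outside [0,1]")


@dataclass
class VariantConfig:
    n_snp: int = 10_000
    n_indel: int = 1_000
    exonic_fraction: float = 0.056
    repeat_fraction: float = 0.30
    depth_mean: float = 34.94
    depth_overdispersion: float = 0.08  # var = mean + od * mean^2
    qual_mean: float = 60.0
    qual_sd: float = 18.0
    het_fraction: float = 0.6
    n_coding_inframe: int = 17
    n_coding_frameshift: int = 20
    n_force_low_depth: int = 50
    n_force_high_depth: int = 20
    n_force_low_qual: int = 50
    n_het_no_ref: int = 30

    def validate(self):
        if self.n_snp < 0 or self.n_indel < 0:
            raise ValueError("variant counts must be >= 0")
        if self.depth_mean <= 0:
            raise ValueError("depth mean must be > 0")
        for f in (self.exonic_fraction, self.repeat_fraction, self.het_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {f} outside [0,1]")


@dataclass
class RiskConfig:
    n_diseases: int = 49
    snps_per_disease: int = 8
    panel_n: int = 101
    subject_age: int = 48
    subject_sex: str = "F"
    subject_ethnicity: str = "SA"
    maf_range: tuple[float, float] = (0.1, 0.5)
    rr_range: tuple[float, float] = (0.7, 2.2)
    ld_high_pairs: int = 2  # per disease, pairs planted with r2 > 0.3
    n_pgx: int = 20


# ---------------------------------------------------------------------------
# bundles


@dataclass
class GenomeBundle:
    reference: dict[str, str]
    transcripts: list[TranscriptModel]
    repeats: list[RepeatFeature]
    regulatory: list[RegulatoryFeature]
    mt_reference: str
    mt_regions: list[MtRegion]
    mt_subject: str
    manifest: dict


@dataclass
class CallSet:
    calls: list[VariantCall]
    manifest: dict


@dataclass
class RiskBundle:
    association_records: list[AssociationRecord]
    ld_table: list[LDRecord]
    prevalence: list[PrevalenceRecord]
    population_panel: dict[str, dict[str, str]]  # individual -> rsid -> genotype
    subject_genotypes: dict[str, str]
    pgx_table: list[PGxRecord]
    truth: dict  # generative model: per-rsid case/control genotype frequencies
    manifest: dict


# ---------------------------------------------------------------------------
# reference genome with gene / repeat / regulatory structure


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    # mild GC gradient along the contig so GC/depth windows show structure
    third = max(length // 3, 1)
    parts = []
    for i, p_gc in enumerate((0.38, 0.46, 0.54)):
        n = length - 2 * third if i == 2 else third
        w = np.array([(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2])
        parts.append("".join(rng.choice(BASES, size=n, p=w)))
    return "".join(parts)[:length]


def _build_gene(
    rng: np.random.Generator, contig: str, start: int, idx: int
) -> TranscriptModel:
    n_ex = int(rng.integers(2, 5))
    exon_lens = rng.integers(200, 600, size=n_ex)
    intron_lens = rng.integers(300, 900, size=n_ex - 1)
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if i < n_ex - 1:
            pos += int(intron_lens[i])
    strand = "+" if rng.random() < 0.5 else "-"
    # UTRs live at the transcript ends; trim them off the exon chain to get CDS
    utr_left = int(rng.integers(60, min(150, exon_lens[0] - 60)))
    utr_right = int(rng.integers(60, min(150, exon_lens[-1] - 60)))
    cds = [list(iv) for iv in exons]
    cds[0][0] += utr_left
    cds[-1][1] -= utr_right
    total = sum(e - s for s, e in cds)
    cds[-1][1] -= total % 3  # make CDS length a multiple of 3
    cds = [tuple(iv) for iv in cds]
    tss = exons[0][0] if strand == "+" else exons[-1][1] - 1
    return TranscriptModel(
        id=f"t{idx}",
        gene_id=f"gene{idx}",
        contig=contig,
        strand=strand,
        exons=tuple(exons),
        cds=tuple(cds),
        tss=tss,
    )


def generate_genome_bundle(config: GenomeConfig | None = None, seed: int = 0) -> GenomeBundle:
    """Reference contigs, gene models, repeat/regulatory tracks, mt genome.

    Deterministic for a fixed seed.  Genes never overlap each other; repeats
    and enhancers are placed strictly intergenic (recorded in the manifest),
    so planted exonic / repeat variant counts partition cleanly.
    """
    config = config or GenomeConfig()
    config.validate()
    rng = rng_from_seed(seed, "genome")
    reference = {
        name: _random_sequence(rng, ln) for name, ln in sorted(config.contig_lengths.items())
    }

    # genes: walk each contig left to right, leaving intergenic gaps
    transcripts: list[TranscriptModel] = []
    contigs = sorted(config.contig_lengths)
    per_contig = {
        c: config.n_genes // len(contigs) + (1 if i < config.n_genes % len(contigs) else 0)
        for i, c in enumerate(contigs)
    }
    idx = 1
    gene_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    for contig in contigs:
        length = config.contig_lengths[contig]
        cursor = 6000  # keep the 5-kb upstream window of the first gene on-contig
        for _ in range(per_contig[contig]):
            cursor += int(rng.integers(1500, 4000))
            t = _build_gene(rng, contig, cursor, idx)
            if t.span[1] + 1000 >= length:
                break
            transcripts.append(t)
            gene_spans[contig].append(t.span)
            cursor = t.span[1]
            idx += 1

    # repeats: intergenic, mutually non-overlapping
    repeats: list[RepeatFeature] = []
    weights = np.array([m[2] for m in REPEAT_MENU])
    taken: dict[str, list[tuple[int, int]]] = {c: list(gene_spans[c]) for c in contigs}
    attempts = 0
    while len(repeats) < config.n_repeats and attempts < config.n_repeats * 60:
        attempts += 1
        contig = contigs[int(rng.integers(len(contigs)))]
        mi = int(rng.choice(len(REPEAT_MENU), p=weights))
        rclass, family, _, (lo, hi) = REPEAT_MENU[mi]
        ln = int(rng.integers(lo, hi))
        start = int(rng.integers(0, config.contig_lengths[contig] - ln))
        iv = (start, start + ln)
        if any(iv[0] < e and s < iv[1] for s, e in taken[contig]):
            continue
        taken[contig].append(iv)
        repeats.append(
            RepeatFeature(contig, iv[0], iv[1], f"{family}_{len(repeats) + 1}", rclass, family)
        )
    repeats.sort(key=lambda r: (r.contig, r.start))

    # regulatory: TFBSs mostly promoter-proximal, enhancers intergenic
    regulatory: list[RegulatoryFeature] = []
    from .functional_annotation import upstream_window

    for i in range(config.n_tfbs):
        if transcripts and rng.random() < config.tfbs_upstream_fraction:
            t = transcripts[int(rng.integers(len(transcripts)))]
            lo, hi = upstream_window(t, 5000)
            hi = min(hi, config.contig_lengths[t.contig] - 30)
            if hi - lo < 40:
                continue
            start = int(rng.integers(lo, hi - 25))
            contig = t.contig
        else:
            contig = contigs[int(rng.integers(len(contigs)))]
            start = int(rng.integers(0, config.contig_lengths[contig] - 30))
        ln = int(rng.integers(8, 25))
        regulatory.append(RegulatoryFeature(contig, start, start + ln, "tfbs", f"TF{i + 1}"))
    for i in range(config.n_enhancers):
        contig = contigs[int(rng.integers(len(contigs)))]
        ln = int(rng.integers(200, 800))
        for _ in range(40):
            start = int(rng.integers(0, config.contig_lengths[contig] - ln))
            if not any(start < e and s < start + ln for s, e in gene_spans[contig]):
                break
        regulatory.append(
            RegulatoryFeature(contig, start, start + ln, "enhancer", f"ENH{i + 1}")
        )
    regulatory.sort(key=lambda f: (f.contig, f.start, f.kind, f.label))

    mt_reference, mt_regions = _build_mt_reference(rng, config)
    mt_subject, mt_truth = _plant_mt_variants(rng, mt_reference, mt_regions, config)

    manifest = {
        "seed": seed,
        "contig_lengths": dict(sorted(config.contig_lengths.items())),
        "n_transcripts": len(transcripts),
        "n_repeats": len(repeats),
        "n_tfbs": sum(1 for f in regulatory if f.kind == "tfbs"),
        "n_enhancers": sum(1 for f in regulatory if f.kind == "enhancer"),
        "repeats_avoid_genes": True,
        "mt": mt_truth,
    }
    return GenomeBundle(
        reference=reference,
        transcripts=transcripts,
        repeats=repeats,
        regulatory=regulatory,
        mt_reference=mt_reference,
        mt_regions=mt_regions,
        mt_subject=mt_subject,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# mitochondrial genome


def _build_mt_reference(
    rng: np.random.Generator, config: GenomeConfig
) -> tuple[str, list[MtRegion]]:
    L = config.mt_length
    seq = "".join(rng.choice(BASES, size=L, p=[0.31, 0.31, 0.13, 0.25]))
    regions = [MtRegion(L - 545, 576, "control")]  # wraps the origin, D-loop style
    cursor = 577
    regions.append(MtRegion(cursor, cursor + 99, "noncoding"))
    cursor += 100
    for _ in range(3):  # rRNA/tRNA blocks
        ln = int(rng.integers(800, 1600))
        regions.append(MtRegion(cursor, cursor + ln - 1, "rna"))
        cursor += ln
    # protein-coding genes tile most of the rest; one on the minus strand
    gene_i = 0
    while L - 545 - cursor > 2200:
        ln = int(rng.integers(900, 1800)) // 3 * 3
        strand = "-" if gene_i == 2 else "+"
        frame_start = cursor if strand == "+" else cursor + ln - 1
        regions.append(
            MtRegion(cursor, cursor + ln - 1, "protein_coding", strand, frame_start)
        )
        cursor += ln
        gene_i += 1
        if gene_i % 3 == 0:  # short intergenic spacer
            sp = int(rng.integers(20, 60))
            regions.append(MtRegion(cursor, cursor + sp - 1, "noncoding"))
            cursor += sp
    regions.append(MtRegion(cursor, L - 546, "noncoding"))
    return seq, regions


def _plant_mt_variants(
    rng: np.random.Generator,
    mt_ref: str,
    regions: list[MtRegion],
    config: GenomeConfig,
) -> tuple[str, dict]:
    L = len(mt_ref)

    def region_positions(cat: str) -> list[int]:
        out = []
        for r in regions:
            if r.category != cat:
                continue
            if r.wraps():
                out.extend(range(r.start, L + 1))
                out.extend(range(1, r.end + 1))
            else:
                out.extend(range(r.start, r.end + 1))
        return out

    planted: list[tuple[int, str, str]] = []
    used: set[int] = set()

    def plant(cat: str, n: int):
        pool = [p for p in region_positions(cat) if p not in used]
        for p in rng.choice(len(pool), size=n, replace=False):
            pos = pool[int(p)]
            ref = mt_ref[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            planted.append((pos, ref, alt))
            used.add(pos)

    plant("control", config.mt_n_control)
    plant("noncoding", config.mt_n_noncoding)
    plant("rna", config.mt_n_rna)

    # protein-coding: plant exact synonymous / non-synonymous counts
    coding = [r for r in regions if r.category == "protein_coding"]
    want = {"synonymous": config.mt_n_syn, "nonsynonymous": config.mt_n_nonsyn}
    got = {"synonymous": 0, "nonsynonymous": 0}
    guard = 0
    while (got["synonymous"] < want["synonymous"] or got["nonsynonymous"] < want["nonsynonymous"]) and guard < 200_000:
        guard += 1
        region = coding[int(rng.integers(len(coding)))]
        pos = int(rng.integers(region.start, region.end + 1))
        if pos in used:
            continue
        ref = mt_ref[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        effect = mt_codon_effect(pos, alt, region, mt_ref)
        if got[effect] < want[effect]:
            got[effect] += 1
            planted.append((pos, ref, alt))
            used.add(pos)
    if got != want:
        raise RuntimeError("failed to plant the requested mt syn/nonsyn counts")

    subject = list(mt_ref)
    for pos, _, alt in planted:
        subject[pos - 1] = alt
    truth = {
        "n_total": len(planted),
        "counts": {
            "control": config.mt_n_control,
            "noncoding": config.mt_n_noncoding,
            "rna": config.mt_n_rna,
            "protein_coding": config.mt_n_syn + config.mt_n_nonsyn,
        },
        "syn": config.mt_n_syn,
        "nonsyn": config.mt_n_nonsyn,
        "planted": sorted(planted),
    }
    return "".join(subject), truth


# ---------------------------------------------------------------------------
# variant calls


def _position_pools(bundle: GenomeBundle) -> dict[str, dict[str, np.ndarray]]:
    """Per-contig pools of 0-based positions: exonic, repeat, other."""
    pools: dict[str, dict[str, np.ndarray]] = {}
    for contig, seq in bundle.reference.items():
        length = len(seq)
        exonic = np.zeros(length, dtype=bool)
        for t in bundle.transcripts:
            if t.contig != contig:
                continue
            for s, e in t.exons:
                exonic[s:e] = True
        in_repeat = np.zeros(length, dtype=bool)
        for r in bundle.repeats:
            if r.contig == contig:
                in_repeat[r.start : r.end] = True
        in_gene = np.zeros(length, dtype=bool)
        for t in bundle.transcripts:
            if t.contig == contig:
                s, e = t.span
                in_gene[s:e] = True
        other = ~(in_gene | in_repeat)
        pools[contig] = {
            "exonic": np.flatnonzero(exonic),
            "repeat": np.flatnonzero(in_repeat & ~exonic),
            "other": np.flatnonzero(other),
        }
    return pools


def _sample_depths(rng: np.random.Generator, n: int, mean: float, od: float) -> np.ndarray:
    """Poisson mixed over a gamma mean: var = mean + od * mean^2.

    od = 0 degenerates to plain Poisson.  The gamma mixing produces the extra
    weight on both tails seen in real short-read coverage.
    """
    if od <= 0:
        return rng.poisson(mean, size=n)
    shape = 1.0 / od
    lam = rng.gamma(shape, mean / shape, size=n)
    return rng.poisson(lam)


def generate_variant_calls(
    bundle: GenomeBundle,
    config: VariantConfig | None = None,
    seed: int = 0,
) -> CallSet:
    """Variant calls with planted region fractions and filter outcomes.

    SNP positions are drawn from three disjoint pools (exons, repeats,
    everything else) in the configured proportions; a subset of calls is
    forced to fail each filter rule (low/high depth, low quality, het with no
    reference allele) and the manifest records the resulting pass/fail
    attribution under the canonical thresholds (depth in [5, 60], quality
    >= 30), along with the planted pool counts.
    """
    config = config or VariantConfig()
    config.validate()
    rng = rng_from_seed(seed, "calls")
    pools = _position_pools(bundle)
    contigs = sorted(bundle.reference)

    # apportion SNPs over contigs by length, then over pools by fraction
    lengths = np.array([len(bundle.reference[c]) for c in contigs], dtype=float)
    contig_p = lengths / lengths.sum()

    n_exonic = round(config.n_snp * config.exonic_fraction)
    n_repeat = round(config.n_snp * config.repeat_fraction)
    n_other = config.n_snp - n_exonic - n_repeat

    chosen: list[tuple[str, int, str]] = []  # (contig, pos0, pool)
    for pool_name, n_pool in (("exonic", n_exonic), ("repeat", n_repeat), ("other", n_other)):
        if n_pool == 0:
            continue
        counts = rng.multinomial(n_pool, contig_p)
        for contig, k in zip(contigs, counts):
            avail = pools[contig][pool_name]
            if k > len(avail):
                raise ValueError(
                    f"pool {pool_name} on {contig} has only {len(avail)} positions, need {k}"
                )
            sel = rng.choice(avail, size=k, replace=False)
            chosen.extend((contig, int(p), pool_name) for p in sel)
    # de-duplicate across pools is unnecessary (pools are disjoint) but a
    # position could repeat within a pool draw only if choice replaced, which
    # it does not.
    chosen.sort()

    depths = _sample_depths(rng, len(chosen), config.depth_mean, config.depth_overdispersion)
    quals = np.clip(rng.normal(config.qual_mean, config.qual_sd, size=len(chosen)), 1, 99)

    calls: list[VariantCall] = []
    pool_of: list[str] = []
    for i, (contig, p0, pool_name) in enumerate(chosen):
        ref = bundle.reference[contig][p0]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        het = rng.random() < config.het_fraction
        gt = (ref, alt) if het else (alt, alt)
        calls.append(
            VariantCall(
                contig=contig,
                pos=p0 + 1,
                ref=ref,
                alts=(alt,),
                genotype=gt,
                depth=int(depths[i]),
                quality=float(round(quals[i], 1)),
            )
        )
        pool_of.append(pool_name)

    # force filter failures on disjoint call subsets
    n_forced = config.n_force_low_depth + config.n_force_high_depth + config.n_force_low_qual + config.n_het_no_ref
    if n_forced > len(calls):
        raise ValueError("more forced failures than calls")
    forced_idx = rng.choice(len(calls), size=n_forced, replace=False)
    it = iter(forced_idx)

    def _replace(i: int, **kw):
        c = calls[i]
        d = dict(
            contig=c.contig, pos=c.pos, ref=c.ref, alts=c.alts,
            genotype=c.genotype, depth=c.depth, quality=c.quality,
        )
        d.update(kw)
        calls[i] = VariantCall(**d)

    for _ in range(config.n_force_low_depth):
        _replace(next(it), depth=int(rng.integers(0, 5)))
    for _ in range(config.n_force_high_depth):
        _replace(next(it), depth=int(rng.integers(61, 120)))
    for _ in range(config.n_force_low_qual):
        # depth forced into range so the failure is attributed to quality
        _replace(next(it), depth=30, quality=float(int(rng.integers(0, 30))))
    for _ in range(config.n_het_no_ref):
        i = next(it)
        c = calls[i]
        alt1 = c.alts[0]
        alt2 = str(rng.choice([b for b in "ACGT" if b not in (c.ref, alt1)]))
        _replace(i, alts=(alt1, alt2), genotype=(alt1, alt2), depth=30, quality=60.0)

    # indels
    cds_ivs = [
        (t.contig, s, e) for t in bundle.transcripts for s, e in t.cds
    ]
    indels: list[VariantCall] = []
    used_anchors: set[tuple[str, int]] = {(c.contig, c.pos) for c in calls}

    def _plant_indel(contig: str, p0: int, net: int):
        seq = bundle.reference[contig]
        if net < 0:
            ref = seq[p0 : p0 + 1 - net]
            alt = seq[p0]
        else:
            ref = seq[p0]
            alt = ref + "".join(rng.choice(BASES, size=net))
        het = rng.random() < config.het_fraction
        gt = (ref, alt) if het else (alt, alt)
        indels.append(
            VariantCall(
                contig=contig,
                pos=p0 + 1,
                ref=ref,
                alts=(alt,),
                genotype=gt,
                depth=int(_sample_depths(rng, 1, config.depth_mean, config.depth_overdispersion)[0]),
                quality=float(round(np.clip(rng.normal(config.qual_mean, config.qual_sd), 1, 99), 1)),
            )
        )
        used_anchors.add((contig, p0 + 1))

    def _cds_anchor(margin: int) -> tuple[str, int]:
        for _ in range(10_000):
            contig, s, e = cds_ivs[int(rng.integers(len(cds_ivs)))]
            if e - s < 2 * margin + 2:
                continue
            p0 = int(rng.integers(s + 1, e - margin - 1))
            if (contig, p0 + 1) not in used_anchors:
                return contig, p0
        raise RuntimeError("could not place a coding indel")

    n_plain = config.n_indel - config.n_coding_inframe - config.n_coding_frameshift
    if n_plain < 0:
        raise ValueError("coding indel counts exceed n_indel")
    for _ in range(config.n_coding_inframe):
        contig, p0 = _cds_anchor(margin=6)
        _plant_indel(contig, p0, -3 if rng.random() < 0.5 else 3)
    for _ in range(config.n_coding_frameshift):
        contig, p0 = _cds_anchor(margin=6)
        net = int(rng.choice([-2, -1, 1, 2]))
        _plant_indel(contig, p0, net)
    for _ in range(n_plain):
        for _ in range(1000):
            contig = contigs[int(rng.integers(len(contigs)))]
            avail = pools[contig]["other"]
            p0 = int(avail[int(rng.integers(len(avail)))])
            if p0 + 6 < len(bundle.reference[contig]) and (contig, p0 + 1) not in used_anchors:
                break
        net = int(rng.choice([-3, -2, -1, 1, 2, 3]))
        _plant_indel(contig, p0, net)

    all_calls = sorted(calls + indels, key=lambda c: (c.contig, c.pos))

    # record planted pass/fail status under the canonical filter rules
    from .variant_qc import filter_variants

    report = filter_variants(all_calls, reference=bundle.reference)
    manifest = {
        "seed": seed,
        "n_snp": len(calls),
        "n_indel": len(indels),
        "planted_pools": {"exonic": n_exonic, "repeat": n_repeat, "other": n_other},
        "planted_coding_indels": {
            "inframe": config.n_coding_inframe,
            "frameshift": config.n_coding_frameshift,
        },
        "filter_truth": report.to_dict(),
        "forced": {
            "low_depth": config.n_force_low_depth,
            "high_depth": config.n_force_high_depth,
            "low_qual": config.n_force_low_qual,
            "het_no_ref": config.n_het_no_ref,
        },
        "depth_model": {"mean": config.depth_mean, "overdispersion": config.depth_overdispersion},
    }
    return CallSet(calls=all_calls, manifest=manifest)


def simulate_depth_array(
    reference: str,
    mean: float = 34.94,
    overdispersion: float = 0.08,
    gc_slope: float = 0.8,
    window: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Per-base depths with gamma-Poisson noise and a GC-coverage trend.

    Local mean decreases linearly with window GC fraction (slope in units of
    the global mean per unit GC), mimicking GC bias in short-read coverage.
    """
    rng = rng_from_seed(seed, "depth")
    L = len(reference)
    ref = np.frombuffer(reference.upper().encode(), dtype="S1")
    gc = ((ref == b"G") | (ref == b"C")).astype(float)
    local = np.array(
        [gc[i : i + window].mean() for i in range(0, L, window)]
    )
    lam_win = mean * (1.0 - gc_slope * (local - local.mean()))
    lam = np.repeat(lam_win, window)[:L]
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        lam = rng.gamma(shape, lam / shape)
    return rng.poisson(np.clip(lam, 0.1, None))


def generate_tss_enriched_variants(
    bundle: GenomeBundle,
    n: int = 5000,
    enrichment: float = 3.0,
    core_half: int = 50,
    half_window: int = 2000,
    seed: int = 0,
) -> list[VariantCall]:
    """Variants around TSSs with a planted central enrichment.

    Positions are drawn within +/- half_window of a random transcript's TSS
    (strand-oriented) with density ``enrichment``-fold higher inside the
    central +/- core_half band than outside it.
    """
    rng = rng_from_seed(seed, "tss")
    w_core = 2 * core_half * enrichment
    w_out = (2 * half_window - 2 * core_half) * 1.0
    p_core = w_core / (w_core + w_out)
    calls = []
    transcripts = bundle.transcripts
    while len(calls) < n:
        t = transcripts[int(rng.integers(len(transcripts)))]
        if rng.random() < p_core:
            rel = int(rng.integers(-core_half, core_half))
        else:
            rel = int(rng.integers(-half_window, half_window))
            if -core_half <= rel < core_half:
                continue  # rejection keeps the outside band uniform
        p0 = t.tss + rel if t.strand == "+" else t.tss - rel
        seq = bundle.reference[t.contig]
        if not 0 <= p0 < len(seq):
            continue
        ref = seq[p0]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        calls.append(
            VariantCall(t.contig, p0 + 1, ref, (alt,), (ref, alt), 30, 60.0)
        )
    return calls


# ---------------------------------------------------------------------------
# array genotypes and comparison catalogs


def generate_array_genotypes(
    calls: list[VariantCall],
    n_sites: int = 5000,
    discordance: float = 0.013,
    seed: int = 0,
) -> tuple[dict[tuple[str, int], tuple[str, str]], dict]:
    """Array genotypes at a subset of SNP sites with planted discordance.

    Each selected site receives the sequencing genotype, replaced with
    probability ``discordance`` by a different genotype over {ref, alt}.
    """
    if not 0.0 <= discordance <= 1.0:
        raise ValueError("discordance must be in [0,1]")
    rng = rng_from_seed(seed, "array")
    snps = [c for c in calls if c.vtype == "snp" and c.genotype is not None]
    if n_sites > len(snps):
        raise ValueError(f"only {len(snps)} SNP calls available for {n_sites} array sites")
    sel = rng.choice(len(snps), size=n_sites, replace=False)
    genotypes: dict[tuple[str, int], tuple[str, str]] = {}
    n_flipped = 0
    for i in sel:
        c = snps[int(i)]
        gt = c.genotype
        if rng.random() < discordance:
            alleles = [c.ref, c.alts[0]]
            options = [
                g
                for g in [(alleles[0], alleles[0]), tuple(sorted(alleles)), (alleles[1], alleles[1])]
                if tuple(sorted(g)) != gt
            ]
            gt = options[int(rng.integers(len(options)))]
            n_flipped += 1
        genotypes[(c.contig, c.pos)] = tuple(sorted(gt))
    manifest = {
        "seed": seed,
        "n_sites": n_sites,
        "planted_discordance": discordance,
        "n_discordant": n_flipped,
    }
    return genotypes, manifest


def generate_variant_catalogs(
    calls: list[VariantCall],
    novel_fraction: float = 0.026,
    n_panels: int = 3,
    panel_share: float = 0.5,
    seed: int = 0,
):
    """Panel genomes and a catch-all catalog with a planted novel fraction.

    A ``novel_fraction`` of subject SNP sites is withheld from every panel
    and catalog; each panel additionally carries ``panel_share`` of the
    remaining subject sites plus private sites of its own, and the catch-all
    catalog (dbSNP-like) carries every non-novel subject site.
    """
    if not 0.0 <= novel_fraction <= 1.0:
        raise ValueError("novel_fraction must be in [0,1]")
    from .genome_comparison import VariantCatalog

    rng = rng_from_seed(seed, "catalogs")
    snps = [c for c in calls if c.vtype == "snp"]
    subject = VariantCatalog.from_calls("subject", snps)
    keys = sorted(subject.sites)
    n_novel = round(novel_fraction * len(keys))
    novel_idx = set(map(int, rng.choice(len(keys), size=n_novel, replace=False)))
    novel_keys = {keys[i] for i in novel_idx}
    shared_keys = [k for i, k in enumerate(keys) if i not in novel_idx]

    panels = []
    for p in range(n_panels):
        mask = rng.random(len(shared_keys)) < panel_share
        sites = {k: subject.sites[k] for k, m in zip(shared_keys, mask) if m}
        # private panel sites, absent from the subject
        for _ in range(len(sites) // 5):
            contig, pos = shared_keys[int(rng.integers(len(shared_keys)))]
            shifted = (contig, pos + 1_000_000)
            sites[shifted] = frozenset(str(rng.choice(BASES)))
        panels.append(VariantCatalog(f"panel{p + 1}", sites))
    catchall = VariantCatalog("dbsnp_like", {k: subject.sites[k] for k in shared_keys})
    manifest = {
        "seed": seed,
        "n_subject_sites": len(keys),
        "planted_novel_fraction": novel_fraction,
        "n_novel": n_novel,
        "novel_sites": sorted(novel_keys),
    }
    return subject, panels, [catchall], manifest


# ---------------------------------------------------------------------------
# risk bundle


def _hwe_freqs(a: str, b: str, maf: float) -> dict[str, float]:
    """Hardy-Weinberg genotype frequencies; ``b`` is the minor/risk allele."""
    p, q = 1.0 - maf, maf
    return {
        genotype_key((a, a)): p * p,
        genotype_key((a, b)): 2 * p * q,
        genotype_key((b, b)): q * q,
    }


def _case_freqs(control: dict[str, float], risk_hom: str, risk_het: str, rr: float) -> dict[str, float]:
    """Case genotype frequencies: control tilted by rr per risk allele."""
    w = {}
    for g, f in control.items():
        n_risk = 2 if g == risk_hom else (1 if g == risk_het else 0)
        w[g] = f * rr**n_risk
    z = sum(w.values())
    return {g: v / z for g, v in w.items()}


def lr_from_freqs(case: dict[str, float], control: dict[str, float]) -> dict[str, float]:
    """LR(g) = case frequency / control frequency, capped when control = 0."""
    out = {}
    for g in case:
        c = control.get(g, 0.0)
        if c == 0.0:
            out[g] = LR_CAP if case[g] > 0 else 1.0
        else:
            out[g] = case[g] / c
    return out


def generate_risk_bundle(config: RiskConfig | None = None, seed: int = 0) -> RiskBundle:
    """Association records, LD, prevalence, panel and PGx tables.

    Each SNP's genotype likelihood ratios are derived from simulated
    case/control genotype frequencies (HWE controls tilted by a per-allele
    relative risk); the generative frequencies are recorded as the bundle's
    truth.  Subject and panel genotypes are drawn from the control
    (population) frequencies.
    """
    config = config or RiskConfig()
    rng = rng_from_seed(seed, "risk")
    alleles = ("A", "C", "G", "T")
    records: list[AssociationRecord] = []
    ld: list[LDRecord] = []
    prevalence: list[PrevalenceRecord] = []
    truth: dict[str, dict] = {}
    rs_counter = 1

    for d in range(config.n_diseases):
        disease = f"disease_{d + 1:02d}"
        p0 = float(rng.uniform(0.01, 0.30))
        prevalence.append(
            PrevalenceRecord(disease, 40, 60, config.subject_sex, config.subject_ethnicity, round(p0, 4))
        )
        # a non-matching stratum, so lookups must key on the full stratum
        prevalence.append(
            PrevalenceRecord(disease, 20, 39, "M", "EU", round(float(rng.uniform(0.005, 0.2)), 4))
        )
        rsids = []
        for _ in range(config.snps_per_disease):
            rsid = f"rs{rs_counter:06d}"
            rs_counter += 1
            a, b = rng.choice(alleles, size=2, replace=False)
            maf = float(rng.uniform(*config.maf_range))
            rr = float(rng.uniform(*config.rr_range))
            control = _hwe_freqs(a, b, maf)
            case = _case_freqs(control, genotype_key((b, b)), genotype_key((a, b)), rr)
            records.append(
                AssociationRecord(
                    rsid=rsid,
                    contig=f"chr{int(rng.integers(1, 23))}",
                    pos=int(rng.integers(1, 100_000_000)),
                    disease=disease,
                    lr_by_genotype=lr_from_freqs(case, control),
                    n_studies=int(rng.integers(1, 13)),
                    n_samples=int(rng.integers(200, 20_000)),
                    population_freq=maf,
                )
            )
            truth[rsid] = {
                "disease": disease,
                "case": case,
                "control": control,
                "rr": rr,
                "risk_allele": b,
            }
            rsids.append(rsid)
        # LD: a few high-r2 pairs (must be pruned) and a few low-r2 pairs
        for _ in range(config.ld_high_pairs):
            i, j = rng.choice(len(rsids), size=2, replace=False)
            ld.append(LDRecord(rsids[int(i)], rsids[int(j)], float(rng.uniform(0.4, 0.95))))
        for _ in range(config.ld_high_pairs):
            i, j = rng.choice(len(rsids), size=2, replace=False)
            ld.append(LDRecord(rsids[int(i)], rsids[int(j)], float(rng.uniform(0.0, 0.25))))

    def draw_genotype(rsid: str, r: np.random.Generator) -> str:
        control = truth[rsid]["control"]
        gts = sorted(control)
        probs = np.array([control[g] for g in gts])
        return gts[int(r.choice(len(gts), p=probs / probs.sum()))]

    subject_genotypes = {r.rsid: draw_genotype(r.rsid, rng) for r in records}
    panel = {
        f"ind{i + 1:03d}": {r.rsid: draw_genotype(r.rsid, rng) for r in records}
        for i in range(config.panel_n)
    }

    drugs = [
        "metformin", "warfarin", "simvastatin", "interferon-beta", "clopidogrel",
        "fluorouracil", "amitriptyline", "ribavirin", "bucindolol", "lumiracoxib",
    ]
    pgx = []
    for i in range(config.n_pgx):
        rsid = f"rs9{i + 1:05d}"
        a, b = rng.choice(alleles, size=2, replace=False)
        gt = genotype_key((a, b)) if rng.random() < 0.5 else genotype_key((b, b))
        pgx.append(
            PGxRecord(
                rsid=rsid,
                gene=f"GENE{i + 1}",
                genotype=gt,
                drug=drugs[i % len(drugs)],
                outcome_text=f"altered response to {drugs[i % len(drugs)]}",
            )
        )
        # subject matches roughly half of the PGx rows
        if rng.random() < 0.5:
            subject_genotypes[rsid] = gt
        else:
            subject_genotypes[rsid] = genotype_key((a, a))

    manifest = {
        "seed": seed,
        "n_diseases": config.n_diseases,
        "snps_per_disease": config.snps_per_disease,
        "panel_n": config.panel_n,
        "n_pgx": config.n_pgx,
        "n_pgx_matching": sum(
            1 for p in pgx if subject_genotypes.get(p.rsid) == p.genotype
        ),
        "subject": {
            "age": config.subject_age,
            "sex": config.subject_sex,
            "ethnicity": config.subject_ethnicity,
        },
    }
    return RiskBundle(
        association_records=records,
        ld_table=ld,
        prevalence=prevalence,
        population_panel=panel,
        subject_genotypes=subject_genotypes,
        pgx_table=pgx,
        truth=truth,
        manifest=manifest,
    )


def simulate_cohort(
    records: list[AssociationRecord],
    truth: dict[str, dict],
    p0: float,
    n: int = 2000,
    seed: int = 0,
) -> tuple[list[dict[str, str]], np.ndarray]:
    """Cohort drawn from the generative case/control model.

    Each individual is a case with probability p0; genotypes at each record's
    SNP are drawn independently from the case or control frequencies.
    Returns (genotype dicts, case indicator array).
    """
    rng = rng_from_seed(seed, "cohort")
    status = rng.random(n) < p0
    cohort = []
    for i in range(n):
        key = "case" if status[i] else "control"
        g: dict[str, str] = {}
        for rec in records:
            freqs = truth[rec.rsid][key]
            gts = sorted(freqs)
            probs = np.array([freqs[x] for x in gts])
            g[rec.rsid] = gts[int(rng.choice(len(gts), p=probs / probs.sum()))]
        cohort.append(g)
    return cohort, status
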