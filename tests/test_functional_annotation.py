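"""Region classification, codon effects, repeat/regulatory overlap, TSS
profiles and gene-set enrichment, each checked against an independent
brute-force oracle."""

import numpy as np
import pytest
from Bio.Seq import Seq

from pgi._util import revcomp, rng_from_seed
from pgi.functional_annotation import (
    REGION_CODING,
    REGION_INTERGENIC,
    REGION_INTRON,
    REGION_NC_EXON,
    REGION_ORDER,
    REGION_UTR3,
    REGION_UTR5,
    RegulatoryFeature,
    RepeatFeature,
    TranscriptModel,
    classify_region,
    coding_effect_indel,
    coding_effect_snp,
    geneset_enrichment,
    regulatory_overlap,
    repeat_overlap,
    tss_profile,
    upstream_window,
)
from pgi.variant_qc import VariantCall


def snp(contig, pos, ref="A", alt="G"):
    return VariantCall(contig, pos, ref, (alt,), (ref, alt), 30, 60.0)


def simple_transcript(contig="chr1", strand="+", start=1000):
    """Two-exon transcript with UTRs: exons [start, +300) and [+600, +900),
    CDS from start+100 to second exon end-100 (length adjusted to %3)."""
    e1 = (start, start + 300)
    e2 = (start + 600, start + 900)
    c1 = (start + 100, start + 300)
    c2 = (start + 600, start + 800)
    total = (c1[1] - c1[0]) + (c2[1] - c2[0])
    c2 = (c2[0], c2[1] - total % 3)
    tss = e1[0] if strand == "+" else e2[1] - 1
    return TranscriptModel("t1", "g1", contig, strand, (e1, e2), (c1, c2), tss)


# ---------------------------------------------------------------------------
# region classification


class TestClassifyRegion:
    def test_no_transcripts_is_intergenic(self):
        region, tid, _ = classify_region(snp("chr1", 5), [])
        assert region == REGION_INTERGENIC and tid is None

    def test_cds_position_is_coding(self):
        t = simple_transcript()
        region, tid, _ = classify_region(snp("chr1", 1200), [t])  # 0-based 1199 in CDS
        assert region == REGION_CODING and tid == "t1"

    @pytest.mark.parametrize(
        "strand,pos,expect",
        [
            ("+", 1050, REGION_UTR5),   # left UTR on + is 5'
            ("+", 1850, REGION_UTR3),
            ("-", 1050, REGION_UTR3),   # mirrored on -
            ("-", 1850, REGION_UTR5),
            ("+", 1400, REGION_INTRON),
        ],
    )
    def test_utr_strand_awareness(self, strand, pos, expect):
        t = simple_transcript(strand=strand)
        region, _, _ = classify_region(snp("chr1", pos), [t])
        assert region == expect

    def test_noncoding_transcript_exon(self):
        t = TranscriptModel("nc", "g", "chr1", "+", ((100, 200),), (), tss=100)
        assert classify_region(snp("chr1", 150), [t])[0] == REGION_NC_EXON

    def test_severity_precedence_across_transcripts(self):
        coding = simple_transcript()
        nc = TranscriptModel("nc", "g2", "chr1", "+", ((1100, 1300),), (), tss=1100)
        region, tid, per_t = classify_region(snp("chr1", 1200), [nc, coding])
        assert region == REGION_CODING and tid == "t1"
        assert per_t == {"t1": REGION_CODING, "nc": REGION_NC_EXON}

    def test_random_variants_match_exhaustive_scan(self, bundle):
        """Labels from the interval index equal a linear scan over every
        transcript interval, independently re-deriving the label."""
        rng = rng_from_seed(21, "scan")
        contigs = sorted(bundle.reference)
        variants = []
        for _ in range(500):
            contig = contigs[int(rng.integers(len(contigs)))]
            pos = int(rng.integers(1, len(bundle.reference[contig])))
            ref = bundle.reference[contig][pos - 1]
            alt = "A" if ref != "A" else "G"
            variants.append(snp(contig, pos, ref, alt))

        def oracle(v):
            labels = []
            p0 = v.pos - 1
            for t in bundle.transcripts:
                if t.contig != v.contig or not (t.span[0] <= p0 < t.span[1]):
                    continue
                if any(s <= p0 < e for s, e in t.cds):
                    labels.append(REGION_CODING)
                elif any(s <= p0 < e for s, e in t.exons):
                    if not t.cds:
                        labels.append(REGION_NC_EXON)
                    else:
                        lo, hi = t.cds_span
                        left = p0 < lo
                        five = (t.strand == "+") == left
                        labels.append(REGION_UTR5 if five else REGION_UTR3)
                else:
                    labels.append(REGION_INTRON)
            if not labels:
                return REGION_INTERGENIC
            return min(labels, key=REGION_ORDER.index)

        for v in variants:
            assert classify_region(v, bundle.transcripts)[0] == oracle(v)

    def test_labels_partition_all_variants(self, bundle, callset):
        for c in callset.calls[:800]:
            region, _, _ = classify_region(c, bundle.transcripts)
            assert region in REGION_ORDER


# ---------------------------------------------------------------------------
# coding effects


def make_cds_transcript(cds_seq, contig="chr1", strand="+", start=100):
    """Single-exon transcript whose CDS (in translation orientation) is
    cds_seq; returns (transcript, reference dict)."""
    genomic = cds_seq if strand == "+" else revcomp(cds_seq)
    pad = "T" * start
    ref = {contig: pad + genomic + "T" * 50}
    n = len(cds_seq)
    t = TranscriptModel(
        "t", "g", contig, strand, ((start, start + n),), ((start, start + n),),
        tss=start if strand == "+" else start + n - 1,
    )
    return t, ref


class TestCodingEffectSnp:
    def test_third_base_wobble_is_synonymous(self):
        t, ref = make_cds_transcript("GCTAAATAA")  # Ala Lys stop
        v = snp("chr1", 103, "T", "C")  # GCT -> GCC, Ala -> Ala
        assert coding_effect_snp(v, t, ref) == "synonymous"

    def test_cga_to_tga_is_nonsense(self):
        t, ref = make_cds_transcript("CGAAAATAA")
        v = snp("chr1", 101, "C", "T")  # CGA -> TGA (stop)
        assert coding_effect_snp(v, t, ref) == "nonsense"

    def test_all_nine_changes_of_aaa_match_translation_table(self):
        t, ref = make_cds_transcript("AAATTTTAA")
        for i in range(3):
            for alt in "CGT":
                v = snp("chr1", 101 + i, "A", alt)
                codon = list("AAA")
                codon[i] = alt
                expect_aa = str(Seq("".join(codon)).translate())
                expect = (
                    "synonymous" if expect_aa == "K"
                    else "nonsense" if expect_aa == "*"
                    else "missense"
                )
                assert coding_effect_snp(v, t, ref) == expect

    def test_minus_strand_uses_reverse_complement(self):
        t, ref = make_cds_transcript("ATGGCTTAA", strand="-")
        # CDS base 4 (the G of GCT) sits at genomic position start+len-1-3
        genomic_pos = 100 + 9 - 1 - 3  # 0-based 104 -> 1-based 106
        base = ref["chr1"][genomic_pos]
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[base]
        effect = coding_effect_snp(snp("chr1", genomic_pos + 1, base, alt), t, ref)
        mutated = "ATG" + revcomp(alt) + "CTTAA"
        expect_aa = str(Seq(mutated[3:6]).translate())
        expect = "synonymous" if expect_aa == "A" else ("nonsense" if expect_aa == "*" else "missense")
        assert effect == expect

    def test_strand_flip_invariance(self):
        """Reverse-complementing the whole locus leaves effects unchanged."""
        cds = "ATGCGATCGGCTTGGAAGTAA"
        t_fwd, ref_fwd = make_cds_transcript(cds, strand="+")
        t_rev, ref_rev = make_cds_transcript(cds, strand="-")
        L = len(cds)
        for off in range(L):
            pos_fwd = 100 + off
            base_f = ref_fwd["chr1"][pos_fwd]
            for alt_f in "ACGT":
                if alt_f == base_f:
                    continue
                e_fwd = coding_effect_snp(snp("chr1", pos_fwd + 1, base_f, alt_f), t_fwd, ref_fwd)
                # same CDS base on the flipped locus
                pos_rev = 100 + (L - 1 - off)
                base_r = ref_rev["chr1"][pos_rev]
                alt_r = revcomp(alt_f)
                e_rev = coding_effect_snp(snp("chr1", pos_rev + 1, base_r, alt_r), t_rev, ref_rev)
                assert e_fwd == e_rev

    def test_non_cds_position_is_error(self):
        t, ref = make_cds_transcript("ATGTAA")
        with pytest.raises(ValueError, match="not inside the CDS"):
            coding_effect_snp(snp("chr1", 99, ref["chr1"][98], "A" if ref["chr1"][98] != "A" else "C"), t, ref)

    def test_indel_rejected(self):
        t, ref = make_cds_transcript("ATGTAA")
        v = VariantCall("chr1", 101, "AT", ("A",), ("A", "AT"), 30, 60.0)
        with pytest.raises(ValueError):
            coding_effect_snp(v, t, ref)


class TestCodingEffectIndel:
    def test_three_bp_deletion_is_inframe(self):
        t, ref = make_cds_transcript("ATG" + "GCT" * 20 + "TAA")
        seq = ref["chr1"]
        v = VariantCall("chr1", 104, seq[103:107], (seq[103],), None, 30, 60.0)
        kind, stop, boundary = coding_effect_indel(v, t, ref)
        assert kind == "inframe" and not boundary

    def test_two_bp_deletion_is_frameshift(self):
        t, ref = make_cds_transcript("ATG" + "GCT" * 20 + "TAA")
        seq = ref["chr1"]
        v = VariantCall("chr1", 104, seq[103:106], (seq[103],), None, 30, 60.0)
        kind, stop, _ = coding_effect_indel(v, t, ref)
        assert kind == "frameshift"

    def test_planted_premature_stop_at_codon_179(self):
        """A 1-bp insertion in codon 147 of a designed CDS creates the first
        downstream stop at codon 179."""
        rng = rng_from_seed(5, "mmp")
        non_stop = [
            c for c in ("".join(x) for x in __import__("itertools").product("ACGT", repeat=3))
            if c not in ("TAA", "TAG", "TGA")
        ]
        # build the MUTATED sequence first: 178 non-stop codons, stop at 179
        mut_codons = [non_stop[int(rng.integers(len(non_stop)))] for _ in range(178)]
        mut = "".join(mut_codons) + "TAA" + "G"  # 538 bases
        inserted_at = 146 * 3  # 0-based offset where one base was inserted
        orig = mut[:inserted_at] + mut[inserted_at + 1 :]  # 537 bases, 179 codons
        t, ref = make_cds_transcript(orig)
        anchor_off = inserted_at - 1  # insertion goes after this CDS base
        pos = 100 + anchor_off + 1  # 1-based anchor
        inserted_base = mut[inserted_at]
        v = VariantCall("chr1", pos, orig[anchor_off], (orig[anchor_off] + inserted_base,), None, 30, 60.0)
        kind, stop_at, _ = coding_effect_indel(v, t, ref)
        assert kind == "frameshift"
        assert stop_at == 179

    def test_frameshift_stop_matches_brute_force_translation(self):
        rng = rng_from_seed(9, "fs")
        non_stop = [
            c for c in ("".join(x) for x in __import__("itertools").product("ACGT", repeat=3))
            if c not in ("TAA", "TAG", "TGA")
        ]
        for trial in range(20):
            n_codons = int(rng.integers(30, 80))
            cds = "".join(non_stop[int(rng.integers(len(non_stop)))] for _ in range(n_codons))
            strand = "+" if trial % 2 == 0 else "-"
            t, ref = make_cds_transcript(cds, strand=strand)
            # random 1- or 2-bp insertion at a random CDS anchor (genomic)
            s, e = t.cds[0]
            anchor = int(rng.integers(s, e - 3))
            ins = "".join("ACGT"[int(rng.integers(4))] for _ in range(int(rng.integers(1, 3))))
            seq = ref["chr1"]
            v = VariantCall("chr1", anchor + 1, seq[anchor], (seq[anchor] + ins,), None, 30, 60.0)
            kind, stop_at, _ = coding_effect_indel(v, t, ref)
            assert kind == "frameshift"
            # oracle: splice the insertion into the genomic sequence, rebuild
            # the CDS in translation orientation, translate codon by codon
            mut_genomic = seq[: anchor + 1] + ins + seq[anchor + 1 :]
            mut_cds = mut_genomic[s : e + len(ins)]
            if strand == "-":
                mut_cds = revcomp(mut_cds)
            expect = None
            for ci in range(len(mut_cds) // 3):
                if str(Seq(mut_cds[3 * ci : 3 * ci + 3]).translate()) == "*":
                    expect = ci + 1
                    break
            assert stop_at == expect

    def test_indel_outside_cds_is_error(self):
        t, ref = make_cds_transcript("ATGGCTTAA")
        v = VariantCall("chr1", 50, ref["chr1"][49:52], (ref["chr1"][49],), None, 30, 60.0)
        with pytest.raises(ValueError):
            coding_effect_indel(v, t, ref)

    def test_boundary_spanning_deletion_flagged(self):
        t, ref = make_cds_transcript("ATG" + "GCT" * 10 + "TAA")
        seq = ref["chr1"]
        e = t.cds[0][1]
        # deletion starting inside the CDS, running past its end
        v = VariantCall("chr1", e - 2, seq[e - 3 : e + 3], (seq[e - 3],), None, 30, 60.0)
        kind, _, boundary = coding_effect_indel(v, t, ref)
        assert boundary
        # only the 2 in-CDS deleted bases count toward frame
        assert kind == "frameshift"


# ---------------------------------------------------------------------------
# repeats / regulatory / TSS


class TestRepeatOverlap:
    def test_empty_repeat_track(self, callset):
        res = repeat_overlap(callset.calls[:100], [])
        assert res["n_in_repeat"] == 0

    def test_multi_class_variant_counts_once_in_denominator(self):
        reps = [
            RepeatFeature("chr1", 100, 200, "L1_1", "LINE", "L1"),
            RepeatFeature("chr1", 150, 160, "AT_1", "Simple_repeat", "(AT)n"),
        ]
        res = repeat_overlap([snp("chr1", 155)], reps)
        assert res["n_in_repeat"] == 1
        assert res["class_counts"] == {"LINE": 1, "Simple_repeat": 1}

    def test_random_layout_matches_pairwise_scan(self):
        rng = rng_from_seed(14, "rep")
        classes = ["LINE", "SINE", "LTR", "Simple_repeat"]
        reps = []
        for i in range(60):
            s = int(rng.integers(0, 9_000))
            reps.append(
                RepeatFeature("chr1", s, s + int(rng.integers(20, 400)),
                              f"r{i}", classes[int(rng.integers(4))], "fam")
            )
        variants = [snp("chr1", int(rng.integers(1, 10_000))) for _ in range(300)]
        res = repeat_overlap(variants, reps)
        # O(n*m) oracle
        n_in = 0
        cls = {c: 0 for c in classes}
        for v in variants:
            p0 = v.pos - 1
            hit = {r.rclass for r in reps if r.start <= p0 < r.end}
            if hit:
                n_in += 1
                for c in hit:
                    cls[c] += 1
        assert res["n_in_repeat"] == n_in
        assert res["class_counts"] == {c: n for c, n in cls.items() if n}


class TestTssProfile:
    def test_zero_variants_all_zero(self, bundle):
        prof = tss_profile([], bundle.transcripts)
        assert not prof["profile"].any()

    def test_minus_strand_mirroring(self):
        t = TranscriptModel("t", "g", "chr1", "-", ((9000, 10_001),), (), tss=10_000)
        prof = tss_profile([snp("chr1", 10_101)], [t], half_window=2000, bin_size=50)
        # genomic 10,100 (0-based) is 100 bases right of the TSS: upstream on '-'
        rel = -100
        idx = (rel + 2000) // 50
        assert prof["profile"][idx] == 1.0

    def test_half_window_must_be_bin_multiple(self):
        with pytest.raises(ValueError):
            tss_profile([], [], half_window=2000, bin_size=60)

    def test_planted_enrichment_recovered(self, bundle):
        from pgi.synthetic_data import generate_tss_enriched_variants

        calls = generate_tss_enriched_variants(bundle, n=5000, enrichment=3.0, seed=8)
        prof = tss_profile(calls, bundle.transcripts)["profile"]
        n_bins = len(prof)
        core = prof[n_bins // 2 - 1 : n_bins // 2 + 1].mean()
        flank = np.concatenate([prof[: n_bins // 2 - 1], prof[n_bins // 2 + 1 :]]).mean()
        ratio = core / flank
        assert 2.4 < ratio < 3.6


class TestRegulatoryOverlap:
    def test_tfbs_beyond_upstream_window_not_counted(self):
        t = TranscriptModel("t", "g", "chr1", "+", ((20_000, 21_000),), (), tss=20_000)
        tfbs = RegulatoryFeature("chr1", 13_900, 13_960, "tfbs", "TF1")  # 6 kb upstream
        v = snp("chr1", 13_930)
        res = regulatory_overlap([v], [tfbs], [t])
        assert res["counts"]["tfbs"]["snp"] == 0

    def test_no_variants_all_zero(self, bundle):
        res = regulatory_overlap([], bundle.regulatory, bundle.transcripts)
        assert all(v == 0 for d in res["counts"].values() for v in d.values())

    def test_random_layout_matches_triple_scan(self, bundle, callset):
        res = regulatory_overlap(
            callset.calls, bundle.regulatory, bundle.transcripts, upstream=5000
        )
        ups = [(t.contig, *upstream_window(t, 5000)) for t in bundle.transcripts]
        expect = {"tfbs": {"snp": 0, "indel": 0}, "enhancer": {"snp": 0, "indel": 0}}
        for v in callset.calls:
            s, e = v.span
            kinds = set()
            in_up = any(c == v.contig and s < ue and us < e for c, us, ue in ups)
            for f in bundle.regulatory:
                if f.contig != v.contig or not (s < f.end and f.start < e):
                    continue
                if f.kind == "enhancer":
                    kinds.add("enhancer")
                elif in_up:
                    kinds.add("tfbs")
            for k in kinds:
                expect[k][v.vtype] += 1
        assert res["counts"] == expect


class TestEnrichment:
    def test_geneset_equals_universe_gives_p_one(self):
        uni = {f"g{i}" for i in range(50)}
        hits = {f"g{i}" for i in range(10)}
        df = geneset_enrichment(hits, uni, {"all": set(uni)})
        assert df.loc[0, "p"] == pytest.approx(1.0)

    def test_hypergeometric_tail_matches_direct_summation(self):
        from math import comb

        N, K, n, k = 100, 10, 20, 5
        uni = {f"g{i}" for i in range(N)}
        members = {f"g{i}" for i in range(K)}
        hits = {f"g{i}" for i in range(k)} | {f"g{i}" for i in range(K, K + n - k)}
        df = geneset_enrichment(hits, uni, {"s": members})
        expect = sum(
            comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1)
        ) / comb(N, n)
        assert df.loc[0, "p"] == pytest.approx(expect, rel=1e-10)

    def test_zero_hits_gives_p_one(self):
        uni = {f"g{i}" for i in range(30)}
        df = geneset_enrichment({"g20"}, uni, {"s": {"g1", "g2"}})
        assert df.loc[0, "p"] == pytest.approx(1.0)

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError):
            geneset_enrichment(set(), set(), {})

    def test_bh_q_monotone_in_p_ranking(self):
        rng = rng_from_seed(3, "bh")
        uni = {f"g{i}" for i in range(200)}
        hits = set(list(uni)[:40])
        sets = {
            f"s{j}": {f"g{int(i)}" for i in rng.integers(0, 200, size=rng.integers(5, 40))}
            for j in range(12)
        }
        df = geneset_enrichment(hits, uni, sets).sort_values("p")
        assert (df["q"].diff().dropna() >= -1e-12).all()
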