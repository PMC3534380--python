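"""Readers and writers for the pipeline's file formats.

Coordinate conventions are reconciled here and nowhere else: VCF and GFF3
are 1-based inclusive on disk, BED is 0-based half-open, and everything
in memory uses 0-based half-open intervals (VariantCall.pos stays 1-based,
matching VCF).  Writers emit deterministic byte-identical output for
identical inputs: fixed column orders, fixed float formats, no timestamps.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .functional_annotation import RegulatoryFeature, RepeatFeature, TranscriptModel
from .mtdna import MtRegion
from .risk_engine import AssociationRecord, LDRecord, PGxRecord, PrevalenceRecord
from .variant_qc import VariantCall

# ---------------------------------------------------------------------------
# FASTA


def write_fasta(path, sequences: dict[str, str]):
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# VCF


def write_vcf(path, calls: list[VariantCall], contig_lengths: dict[str, int]):
    """Minimal VCF 4.2 with QUAL, GT and DP for one sample."""
    lines = ["##fileformat=VCFv4.2"]
    for name, ln in sorted(contig_lengths.items()):
        lines.append(f"##contig=<ID={name},length={ln}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE")
    for c in sorted(calls, key=lambda c: (c.contig, c.pos, c.ref)):
        alleles = [c.ref, *c.alts]
        if c.genotype is None:
            gt = "./."
        else:
            gt = "/".join(str(alleles.index(a)) for a in c.genotype)
        lines.append(
            "\t".join(
                [
                    c.contig,
                    str(c.pos),
                    ".",
                    c.ref,
                    ",".join(c.alts),
                    f"{c.quality:.1f}",
                    ".",
                    ".",
                    "GT:DP",
                    f"{gt}:{c.depth}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> list[VariantCall]:
    from cyvcf2 import VCF

    calls = []
    vcf = VCF(str(path))
    for v in vcf:
        alleles = [v.REF, *v.ALT]
        gt = None
        if v.genotypes:
            g = v.genotypes[0]
            idx = [i for i in g[:-1] if i is not None and i >= 0]
            if len(idx) == 2:
                gt = (alleles[idx[0]], alleles[idx[1]])
        dp = v.format("DP")
        depth = int(dp[0][0]) if dp is not None else 0
        calls.append(
            VariantCall(
                contig=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                genotype=gt,
                depth=depth,
                quality=float(v.QUAL) if v.QUAL is not None else 0.0,
            )
        )
    vcf.close()
    return calls


# ---------------------------------------------------------------------------
# GFF3 gene models


def write_gff3(path, transcripts: list[TranscriptModel]):
    lines = ["##gff-version 3"]
    for t in sorted(transcripts, key=lambda t: (t.contig, t.span[0], t.id)):
        s, e = t.span
        common = [t.contig, "pgi", None, None, None, ".", t.strand, None, None]

        def row(ftype, start0, end0, attrs, frame="."):
            r = list(common)
            r[2], r[3], r[4], r[7], r[8] = ftype, str(start0 + 1), str(end0), frame, attrs
            return "\t".join(r)

        lines.append(row("gene", s, e, f"ID={t.gene_id}"))
        lines.append(row("mRNA", s, e, f"ID={t.id};Parent={t.gene_id}"))
        for xs, xe in t.exons:
            lines.append(row("exon", xs, xe, f"Parent={t.id}"))
        # UTRs: exonic minus CDS, split by side of the CDS span
        if t.cds:
            clo, chi = t.cds_span
            for xs, xe in t.exons:
                left = (xs, min(xe, clo))
                right = (max(xs, chi), xe)
                for (us, ue) in (left, right):
                    if ue > us:
                        is_left = ue <= clo
                        five = (t.strand == "+") == is_left
                        ftype = "five_prime_UTR" if five else "three_prime_UTR"
                        lines.append(row(ftype, us, ue, f"Parent={t.id}"))
            phase = 0
            cds_order = t.cds if t.strand == "+" else tuple(reversed(t.cds))
            for cs, ce in cds_order:
                lines.append(row("CDS", cs, ce, f"Parent={t.id}", frame=str(phase)))
                phase = (3 - ((ce - cs) - phase) % 3) % 3
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> list[TranscriptModel]:
    cols = ["contig", "source", "type", "start", "end", "score", "strand", "frame", "attrs"]
    df = pd.read_csv(str(path), sep="\t", comment="#", names=cols, dtype={"contig": str})

    def attr(s: str, key: str) -> str | None:
        for part in s.split(";"):
            k, _, v = part.partition("=")
            if k == key:
                return v
        return None

    mrnas = df[df["type"] == "mRNA"]
    out = []
    for _, m in mrnas.iterrows():
        tid = attr(m["attrs"], "ID")
        gid = attr(m["attrs"], "Parent") or tid
        children = df[df["attrs"].apply(lambda a: attr(a, "Parent") == tid)]
        exons = [
            (int(r["start"]) - 1, int(r["end"]))
            for _, r in children[children["type"] == "exon"].iterrows()
        ]
        cds = [
            (int(r["start"]) - 1, int(r["end"]))
            for _, r in children[children["type"] == "CDS"].iterrows()
        ]
        exons.sort()
        strand = m["strand"]
        tss = exons[0][0] if strand == "+" else exons[-1][1] - 1
        out.append(
            TranscriptModel(
                id=tid,
                gene_id=gid,
                contig=m["contig"],
                strand=strand,
                exons=tuple(exons),
                cds=tuple(sorted(cds)),
                tss=tss,
            )
        )
    return out


# ---------------------------------------------------------------------------
# BED tracks


def write_repeats_bed(path, repeats: list[RepeatFeature]):
    rows = [
        f"{r.contig}\t{r.start}\t{r.end}\t{r.name}\t0\t+\t{r.rclass}\t{r.family}"
        for r in sorted(repeats, key=lambda r: (r.contig, r.start, r.name))
    ]
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


def read_repeats_bed(path) -> list[RepeatFeature]:
    text = Path(path).read_text().strip()
    if not text:
        return []
    out = []
    for line in text.splitlines():
        contig, start, end, name, _, _, rclass, family = line.split("\t")
        out.append(RepeatFeature(contig, int(start), int(end), name, rclass, family))
    return out


def write_regulatory_bed(path, features: list[RegulatoryFeature]):
    rows = [
        f"{f.contig}\t{f.start}\t{f.end}\t{f.kind}:{f.label}\t0\t+"
        for f in sorted(features, key=lambda f: (f.contig, f.start, f.kind, f.label))
    ]
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


def read_regulatory_bed(path) -> list[RegulatoryFeature]:
    text = Path(path).read_text().strip()
    if not text:
        return []
    out = []
    for line in text.splitlines():
        contig, start, end, name, _, _ = line.split("\t")
        kind, _, label = name.partition(":")
        out.append(RegulatoryFeature(contig, int(start), int(end), kind, label))
    return out


# ---------------------------------------------------------------------------
# TSV tables


def write_mt_regions(path, regions: list[MtRegion]):
    df = pd.DataFrame(
        [
            {
                "start": r.start,
                "end": r.end,
                "category": r.category,
                "strand": r.strand,
                "frame_start": r.frame_start if r.frame_start is not None else "",
            }
            for r in regions
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_mt_regions(path) -> list[MtRegion]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        fs = r["frame_start"]
        out.append(
            MtRegion(
                start=int(r["start"]),
                end=int(r["end"]),
                category=r["category"],
                strand=r["strand"],
                frame_start=int(fs) if pd.notna(fs) and fs != "" else None,
            )
        )
    return out


def write_associations(path, records: list[AssociationRecord]):
    rows = []
    for r in sorted(records, key=lambda r: r.rsid):
        for g, lr in sorted(r.lr_by_genotype.items()):
            rows.append(
                {
                    "rsid": r.rsid,
                    "chrom": r.contig,
                    "pos": r.pos,
                    "disease": r.disease,
                    "genotype": g,
                    "LR": f"{lr:.10g}",
                    "n_studies": r.n_studies,
                    "n_samples": r.n_samples,
                    "population_freq": "" if r.population_freq is None else f"{r.population_freq:.6g}",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_associations(path) -> list[AssociationRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (rsid, chrom, pos, disease, n_st, n_sa), grp in df.groupby(
        ["rsid", "chrom", "pos", "disease", "n_studies", "n_samples"], sort=True
    ):
        pf = grp["population_freq"].iloc[0]
        out.append(
            AssociationRecord(
                rsid=rsid,
                contig=chrom,
                pos=int(pos),
                disease=disease,
                lr_by_genotype={g: float(lr) for g, lr in zip(grp["genotype"], grp["LR"])},
                n_studies=int(n_st),
                n_samples=int(n_sa),
                population_freq=float(pf) if pd.notna(pf) else None,
            )
        )
    return out


def write_ld(path, ld: list[LDRecord]):
    rows = [
        {"rsid_a": r.rsid_a, "rsid_b": r.rsid_b, "r2": f"{r.r2:.6g}"}
        for r in sorted(ld, key=lambda r: (r.rsid_a, r.rsid_b))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ld(path) -> list[LDRecord]:
    df = pd.read_csv(path, sep="\t")
    return [LDRecord(r["rsid_a"], r["rsid_b"], float(r["r2"])) for _, r in df.iterrows()]


def write_prevalence(path, table: list[PrevalenceRecord]):
    rows = [
        {
            "disease": r.disease,
            "age_lo": r.age_lo,
            "age_hi": r.age_hi,
            "sex": r.sex,
            "ethnicity": r.ethnicity,
            "pretest_prob": f"{r.pretest_prob:.6g}",
        }
        for r in sorted(table, key=lambda r: (r.disease, r.age_lo, r.sex, r.ethnicity))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_prevalence(path) -> list[PrevalenceRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        PrevalenceRecord(
            r["disease"], int(r["age_lo"]), int(r["age_hi"]), r["sex"], r["ethnicity"],
            float(r["pretest_prob"]),
        )
        for _, r in df.iterrows()
    ]


def write_array_genotypes(path, genotypes: dict[tuple[str, int], tuple[str, str]]):
    rows = [
        {"rsid": f"site_{c}_{p}", "chrom": c, "pos": p, "genotype": "".join(g)}
        for (c, p), g in sorted(genotypes.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_array_genotypes(path) -> dict[tuple[str, int], tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return {
        (r["chrom"], int(r["pos"])): tuple(sorted(r["genotype"]))
        for _, r in df.iterrows()
    }


def write_pgx(path, table: list[PGxRecord]):
    rows = [
        {
            "rsid": r.rsid,
            "gene": r.gene,
            "genotype": r.genotype,
            "drug": r.drug,
            "outcome_text": r.outcome_text,
        }
        for r in sorted(table, key=lambda r: r.rsid)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pgx(path) -> list[PGxRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        PGxRecord(r["rsid"], r["gene"], r["genotype"], r["drug"], r["outcome_text"])
        for _, r in df.iterrows()
    ]


def write_panel(path, panel: dict[str, dict[str, str]]):
    df = pd.DataFrame(panel).sort_index()
    df = df[sorted(df.columns)]
    df.index.name = "rsid"
    df.to_csv(path, sep="\t")


def read_panel(path) -> dict[str, dict[str, str]]:
    df = pd.read_csv(path, sep="\t", index_col="rsid")
    return {ind: df[ind].dropna().to_dict() for ind in df.columns}


def write_genotypes_tsv(path, genotypes: dict[str, str]):
    rows = [{"rsid": k, "genotype": v} for k, v in sorted(genotypes.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["rsid"], df["genotype"]))


def write_manifest(path, manifest: dict):
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# bundle emission


def write_genome_bundle(bundle, outdir) -> dict[str, Path]:
    """Emit every file of a GenomeBundle; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fa",
        "genes": outdir / "genes.gff3",
        "repeats": outdir / "repeats.bed",
        "regulatory": outdir / "regulatory.bed",
        "mt_reference": outdir / "mt_reference.fa",
        "mt_subject": outdir / "mt_subject.fa",
        "mt_regions": outdir / "mt_regions.tsv",
        "manifest": outdir / "genome_manifest.json",
    }
    write_fasta(paths["reference"], bundle.reference)
    write_gff3(paths["genes"], bundle.transcripts)
    write_repeats_bed(paths["repeats"], bundle.repeats)
    write_regulatory_bed(paths["regulatory"], bundle.regulatory)
    write_fasta(paths["mt_reference"], {"chrM": bundle.mt_reference})
    write_fasta(paths["mt_subject"], {"chrM": bundle.mt_subject})
    write_mt_regions(paths["mt_regions"], bundle.mt_regions)
    write_manifest(paths["manifest"], bundle.manifest)
    return paths
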