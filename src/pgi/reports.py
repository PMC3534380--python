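"""Pipeline orchestration and summary statistics.

run_pipeline drives the stages qc -> annotate -> compare -> risk -> mtdna ->
summary over a synthetic bundle on disk; summary_table assembles the
headline sequencing/analysis statistics at the precision such tables are
customarily printed (mean depth to two decimals, percentages to one or two).
All outputs are tab-delimited or JSON and contain no timestamps, so a rerun
with the same seed and config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from ._util import round_half_up
from . import synthetic_data as sd
from .functional_annotation import (
    TranscriptIndex,
    classify_region,
    geneset_enrichment,
    regulatory_overlap,
    repeat_overlap,
    tss_profile,
)
from .genome_comparison import comparison_report
from .mtdna import mt_classify, mt_variants
from .risk_engine import assess_disease, pgx_lookup, pretest_probability
from .variant_qc import array_concordance, coverage_profile, filter_variants

logger = logging.getLogger("pgi")

GB = 1e9  # 1 Gb = 10^9 bases


@dataclass
class RunConfig:
    """Flat, file-round-trippable pipeline configuration."""

    outdir: str = "pgi_run"
    seed: int = 1
    depth_min: int = 5
    depth_max: int = 60
    qual_min: float = 30.0
    mito_contig: str = "chrM"
    r2_max: float = 0.3
    fdr: float = 0.05
    tss_half_window: int = 2000
    tss_bin: int = 50
    upstream_window: int = 5000
    contig_length: int = 100_000
    n_genes: int = 12
    n_snp: int = 2000
    n_indel: int = 200

    def validate(self):
        if self.depth_min > self.depth_max:
            raise ValueError("depth_min > depth_max")
        if self.depth_min < 0 or self.qual_min < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 <= self.r2_max <= 1.0:
            raise ValueError("r2_max outside [0,1]")
        if not 0.0 < self.fdr <= 1.0:
            raise ValueError("fdr outside (0,1]")
        if self.tss_half_window % self.tss_bin:
            raise ValueError("tss_half_window must be a multiple of tss_bin")

    def to_file(self, path):
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            k, v = k.strip(), v.strip()
            t = types.get(k, "str")
            if t == "int":
                kwargs[k] = int(v)
            elif t == "float":
                kwargs[k] = float(v)
            else:
                kwargs[k] = v
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# summary statistics


def mean_depth_from_totals(mapped_bases: float, non_n_bases: int) -> float:
    """Mean mapped depth = mapped bases / non-N reference bases (2 dp)."""
    if non_n_bases <= 0:
        raise ValueError("non_n_bases must be positive")
    return round_half_up(mapped_bases / non_n_bases, 2)


def raw_gigabases(n_reads_million: float, read_length: int) -> float:
    """Total raw bases in Gb (10^9 bases), two decimals."""
    return round_half_up(n_reads_million * 1e6 * read_length / GB, 2)


def mean_contig_length(total_bases: int, n_contigs: int) -> float:
    """Mean length of assembled contigs, to the nearest base."""
    if n_contigs <= 0:
        raise ValueError("n_contigs must be positive")
    return round_half_up(total_bases / n_contigs, 0)


def summary_table(
    filter_report=None,
    coverage=None,
    comparison=None,
    mt_summary=None,
) -> dict:
    """Key-value sequencing/analysis summary from stage reports.

    Raises KeyError naming the missing stage when a requested figure's
    upstream report is absent; an empty variant set gives zero totals.
    """
    out: dict[str, object] = {}
    if filter_report is not None:
        d = filter_report.to_dict() if hasattr(filter_report, "to_dict") else dict(filter_report)
        out["Total variant calls"] = d["n_input"]
        out["Calls passing filters"] = d["n_pass"]
        out["Failed depth filter"] = d["n_fail_depth"]
        out["Failed quality filter"] = d["n_fail_quality"]
        out["Failed het-no-ref rule"] = d["n_fail_het_no_ref"]
    if coverage is not None:
        out["Mean mapped depth (x)"] = round_half_up(coverage.mean_depth, 2)
        out["Bases accessed (% of genome)"] = round_half_up(100 * coverage.frac_ge1, 2)
        out["Covered by >= 5 reads (%)"] = round_half_up(100 * coverage.frac_ge5, 2)
    if comparison is not None:
        out["Novel SNPs"] = comparison["n_novel"]
        out["Novel SNPs (% of subject)"] = comparison["novel_pct"]
    if mt_summary is not None:
        out["mtDNA variants"] = mt_summary["n_total"]
    return out


def require_stage(reports: dict, stage: str):
    if stage not in reports or reports[stage] is None:
        raise KeyError(f"missing upstream report for stage {stage!r}")
    return reports[stage]


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig) -> dict:
    """Simulate inputs, run every stage in order, write versioned artifacts.

    Returns the summary dict.  Any stage failure raises with the stage name;
    the CLI maps that to a nonzero exit status.
    """
    config.validate()
    out = Path(config.outdir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    (out / "reports").mkdir(exist_ok=True)
    seed = config.seed

    logger.info("simulate: genome bundle (seed=%d)", seed)
    gcfg = sd.GenomeConfig(
        contig_lengths={"chr1": config.contig_length}, n_genes=config.n_genes
    )
    bundle = sd.generate_genome_bundle(gcfg, seed=seed)
    paths = pio.write_genome_bundle(bundle, out / "inputs")

    vcfg = sd.VariantConfig(n_snp=config.n_snp, n_indel=config.n_indel)
    callset = sd.generate_variant_calls(bundle, vcfg, seed=seed)
    vcf_path = out / "inputs" / "calls.vcf"
    pio.write_vcf(vcf_path, callset.calls, {c: len(s) for c, s in bundle.reference.items()})
    pio.write_manifest(out / "inputs" / "calls_manifest.json", callset.manifest)

    n_array = min(1000, max(1, callset.manifest["n_snp"] // 2))
    array_gt, array_manifest = sd.generate_array_genotypes(
        callset.calls, n_sites=n_array, seed=seed
    )
    pio.write_array_genotypes(out / "inputs" / "array.tsv", array_gt)

    risk_bundle = sd.generate_risk_bundle(sd.RiskConfig(n_diseases=8), seed=seed)
    pio.write_associations(out / "inputs" / "associations.tsv", risk_bundle.association_records)
    pio.write_ld(out / "inputs" / "ld.tsv", risk_bundle.ld_table)
    pio.write_prevalence(out / "inputs" / "prevalence.tsv", risk_bundle.prevalence)
    pio.write_panel(out / "inputs" / "panel.tsv", risk_bundle.population_panel)
    pio.write_pgx(out / "inputs" / "pgx.tsv", risk_bundle.pgx_table)
    pio.write_genotypes_tsv(out / "inputs" / "subject_genotypes.tsv", risk_bundle.subject_genotypes)

    # --- qc ------------------------------------------------------------
    logger.info("qc: filters (depth [%d,%d], qual >= %g)", config.depth_min, config.depth_max, config.qual_min)
    calls = pio.read_vcf(vcf_path)
    report = filter_variants(
        calls,
        depth_min=config.depth_min,
        depth_max=config.depth_max,
        qual_min=config.qual_min,
        mito_contig=None,
        reference=bundle.reference,
    )
    conc = array_concordance(
        {(c.contig, c.pos): c.genotype for c in calls if c.vtype == "snp"},
        pio.read_array_genotypes(out / "inputs" / "array.tsv"),
    )
    depths = sd.simulate_depth_array(bundle.reference["chr1"], seed=seed)
    cov = coverage_profile(depths, bundle.reference["chr1"], window=50_000)
    qc_out = {
        "filter": report.to_dict(),
        "concordance": conc,
        "coverage": {
            "mean_depth": round_half_up(cov.mean_depth, 2),
            "frac_ge1": cov.frac_ge1,
            "frac_ge5": cov.frac_ge5,
        },
        "array_manifest": array_manifest,
    }
    _write_json(out / "reports" / "qc.json", qc_out)
    cov.to_frame().to_csv(out / "reports" / "coverage_hist.tsv", sep="\t", index=False)

    # --- annotate -------------------------------------------------------
    logger.info("annotate: regions, effects, repeats, regulatory, TSS")
    transcripts = pio.read_gff3(paths["genes"])
    repeats = pio.read_repeats_bed(paths["repeats"])
    regulatory = pio.read_regulatory_bed(paths["regulatory"])
    index = TranscriptIndex(transcripts)
    pass_calls = report.pass_set
    regions = [classify_region(c, index)[0] for c in pass_calls]
    region_counts = pd.Series(regions).value_counts().to_dict()
    rep = repeat_overlap(pass_calls, repeats)
    reg = regulatory_overlap(pass_calls, regulatory, transcripts, config.upstream_window)
    prof = tss_profile(pass_calls, transcripts, config.tss_half_window, config.tss_bin)
    pd.DataFrame(
        {"bin_left": prof["bin_left"], "bin_right": prof["bin_right"], "mean_variants": prof["profile"]}
    ).to_csv(out / "reports" / "tss_profile.tsv", sep="\t", index=False)
    ann_out = {
        "region_counts": region_counts,
        "repeat": {k: rep[k] for k in ("n_variants", "n_in_repeat", "class_counts")},
        "regulatory": reg["counts"],
    }
    _write_json(out / "reports" / "annotation.json", ann_out)

    # --- compare --------------------------------------------------------
    logger.info("compare: panels and catalogs")
    subject, panels, catalogs, cat_manifest = sd.generate_variant_catalogs(
        calls, seed=seed
    )
    comp = comparison_report(subject, panels, catalogs, transcripts, repeats)
    _write_json(
        out / "reports" / "comparison.json",
        {k: comp[k] for k in ("shared_pct", "n_novel", "novel_pct", "novel_partition")},
    )

    # --- risk -----------------------------------------------------------
    logger.info("risk: %d diseases", len({r.disease for r in risk_bundle.association_records}))
    subj = risk_bundle.manifest["subject"]
    assessments = []
    for disease in sorted({r.disease for r in risk_bundle.association_records}):
        p0 = pretest_probability(
            disease, subj["age"], subj["sex"], subj["ethnicity"], risk_bundle.prevalence
        )
        a = assess_disease(
            disease,
            p0,
            risk_bundle.association_records,
            risk_bundle.ld_table,
            risk_bundle.subject_genotypes,
            risk_bundle.population_panel,
            r2_max=config.r2_max,
        )
        assessments.append(a)
    risk_rows = [
        {
            "disease": a.disease,
            "pretest": a.pretest,
            "combined_lr": a.combined_lr,
            "posttest": a.posttest,
            "percentile_vs_panel": a.percentile,
            "n_kept_snps": len(a.kept),
        }
        for a in assessments
    ]
    pd.DataFrame(risk_rows).to_csv(out / "reports" / "risk.tsv", sep="\t", index=False)
    riskogram_rows = []
    for a in assessments:
        for step in a.contributions:
            riskogram_rows.append({"disease": a.disease, **step})
    pd.DataFrame(riskogram_rows).to_csv(out / "reports" / "riskogram.tsv", sep="\t", index=False)
    pgx_hits = pgx_lookup(risk_bundle.subject_genotypes, risk_bundle.pgx_table)
    pd.DataFrame(
        [
            {"rsid": p.rsid, "gene": p.gene, "genotype": p.genotype, "drug": p.drug, "outcome": p.outcome_text}
            for p in pgx_hits
        ]
    ).to_csv(out / "reports" / "pgx.tsv", sep="\t", index=False)

    # --- mtdna ----------------------------------------------------------
    logger.info("mtdna: subject vs circular reference")
    mt_vars = mt_variants(
        pio.read_fasta(paths["mt_subject"])["chrM"],
        pio.read_fasta(paths["mt_reference"])["chrM"],
    )
    mt_sum = mt_classify(mt_vars, pio.read_mt_regions(paths["mt_regions"]), bundle.mt_reference)
    _write_json(
        out / "reports" / "mtdna.json",
        {k: mt_sum[k] for k in ("n_total", "counts", "syn", "nonsyn")},
    )

    # --- summary --------------------------------------------------------
    summary = summary_table(report, cov, comp, mt_sum)
    summary["Array concordance (%)"] = conc["pct"]
    _write_json(out / "reports" / "summary.json", summary)
    config.to_file(out / "run_config.txt")

    # every summary figure must be reproducible from stage artifacts alone
    truth = {
        "filter_truth": callset.manifest["filter_truth"],
        "catalog_truth": {"n_novel": cat_manifest["n_novel"]},
        "mt_truth": bundle.manifest["mt"],
    }
    _write_json(out / "reports" / "planted_truth.json", truth)
    return summary


def _write_json(path, obj):
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.ndarray,)):
        return o.tolist()
    return str(o)
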