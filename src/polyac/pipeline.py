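"""End-to-end orchestration of the poly(A)-cluster pipeline.

Stages mirror the classic 3'-end workflow and can be run independently:

* **P** — preprocess raw FASTQ (orient, trim tails, filter).
* **M** — mapping; delegated to an external aligner (minimap2 when on
  PATH) or skipped entirely when the metadata already points at SAM/BAM.
* **C** — pooled poly(A)-site calling, internal-priming masking,
  clustering, annotation, naming; writes the cluster BED.
* **A** — adopt and re-name an external cluster database instead of de
  novo discovery.
* **B** — per-sample coverage and site bedGraphs.
* **D** — per-sample counting, collapse to exon and gene tables, NB
  differential testing of all three tables, gene classification and the
  final compiled report.

Inputs are declared in a tab-delimited metadata file with columns
``sample``, ``path``, ``condition`` (two condition levels).
"""

from __future__ import annotations

import logging
import os
import shutil
import subprocess
from dataclasses import dataclass, field

import pandas as pd
import pyfaidx

from . import annotation, classify, clustering, counting, differential, pas, preprocess

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    preprocess: preprocess.PreprocessConfig = field(default_factory=preprocess.PreprocessConfig)
    pas: pas.PasConfig = field(default_factory=pas.PasConfig)
    cluster: clustering.ClusterConfig = field(default_factory=clustering.ClusterConfig)
    annotation: annotation.AnnotationConfig = field(default_factory=annotation.AnnotationConfig)
    count: counting.CountConfig = field(default_factory=counting.CountConfig)
    diff: differential.DiffConfig = field(default_factory=differential.DiffConfig)
    classify: classify.ClassifyConfig = field(default_factory=classify.ClassifyConfig)


@dataclass
class PipelineResult:
    pac_db: list | None = None
    pac_bed: str | None = None
    counts: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    report: pd.DataFrame | None = None
    report_path: str | None = None
    paths: dict = field(default_factory=dict)


def read_metadata(path: str) -> pd.DataFrame:
    """Sample sheet: TSV with sample, path, condition columns (header optional)."""
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    if "sample" not in cols:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["sample", "path", "condition"])
    else:
        df.columns = cols
    need = {"sample", "path", "condition"}
    if not need <= set(df.columns):
        raise ValueError(f"metadata must provide columns {sorted(need)}")
    return df[["sample", "path", "condition"]]


def _map_sample(fastq: str, genome_fa: str, out_sam: str) -> str:
    """Shell out to minimap2 (short-read preset) for the mapping stage."""
    aligner = shutil.which("minimap2")
    if aligner is None:
        raise RuntimeError(
            "no aligner found on PATH; provide pre-aligned SAM/BAM in the metadata"
        )
    with open(out_sam, "w") as out:
        subprocess.run(
            [aligner, "-ax", "sr", "--sam-hit-only", genome_fa, fastq],
            stdout=out, check=True,
        )
    return out_sam


def run_pipeline(
    metadata_path: str,
    genome_fasta: str,
    exon_bed: str,
    intron_bed: str,
    outdir: str,
    stages: str = "PMCD",
    config: PipelineConfig | None = None,
    external_pac_bed: str | None = None,
) -> PipelineResult:
    """Run the requested stages and return tables, calls and output paths."""
    config = config or PipelineConfig()
    os.makedirs(outdir, exist_ok=True)
    meta = read_metadata(metadata_path)
    result = PipelineResult()
    sample_paths = dict(zip(meta["sample"], meta["path"]))

    if "P" in stages:
        for sample, path in list(sample_paths.items()):
            if path.endswith((".sam", ".bam")):
                continue
            out = os.path.join(outdir, f"{sample}.trimmed.fastq")
            summary = preprocess.process_fastq(path, out, config.preprocess)
            logger.info("preprocess %s: %s", sample, summary.counts)
            result.paths[f"trimmed/{sample}"] = out
            sample_paths[sample] = out

    if "M" in stages:
        for sample, path in list(sample_paths.items()):
            if path.endswith((".sam", ".bam")):
                continue
            sam = os.path.join(outdir, f"{sample}.sam")
            sample_paths[sample] = _map_sample(path, genome_fasta, sam)

    exons = annotation.read_feature_bed(exon_bed)
    introns = annotation.read_feature_bed(intron_bed)

    if "A" in stages and external_pac_bed:
        result.pac_db = annotation.adopt_external_db(
            external_pac_bed, exons, introns, config.annotation
        )
    elif "C" in stages:
        sams = list(sample_paths.values())
        sites = pas.collect_pas(sams, config.pas)
        genome = pyfaidx.Fasta(genome_fasta)
        kept, masked = pas.apply_internal_priming_mask(sites, genome, config.pas)
        if masked:
            pas.write_pas_bedgraph(masked, os.path.join(outdir, "masked_sites"))
        pacs = clustering.cluster_all(kept, config.cluster)
        result.pac_db = annotation.annotate_pacs(pacs, exons, introns, config.annotation)
    if result.pac_db is not None:
        result.pac_bed = clustering.write_pac_bed(
            result.pac_db, os.path.join(outdir, "pac_db.bed"),
            names=[p.name for p in result.pac_db],
        )

    if "B" in stages:
        per_sample_cfg = config.pas
        for sample, path in sample_paths.items():
            pas.write_coverage_bedgraph(
                path, os.path.join(outdir, f"{sample}.coverage.bedgraph")
            )
            counts = pas.site_counts_per_sample(path, per_sample_cfg)
            sample_sites = [
                pas.PolyASite(c, p, s, total_reads=n, qualified_reads=n)
                for (c, p, s), n in counts.items()
            ]
            pas.write_pas_bedgraph(sample_sites, os.path.join(outdir, f"{sample}.pas"))

    if "D" in stages:
        if result.pac_db is None:
            raise ValueError("stage D requires a cluster database (run C or A first)")
        design = differential.DesignSpec(
            sample_ids=list(meta["sample"]),
            conditions=list(meta["condition"]),
            reference=sorted(set(meta["condition"]))[0],
        )
        pac_counts, _ = counting.build_count_matrix(
            {s: sample_paths[s] for s in meta["sample"]}, result.pac_db, config.count
        )
        drop = None
        if config.count.repeat_mask_path:
            repeats = annotation.read_feature_bed(config.count.repeat_mask_path)
            drop = counting.repeat_overlapping_names(result.pac_db, repeats)
        exon_counts = counting.collapse_counts(pac_counts, "exon", config.count, drop)
        gene_counts = counting.collapse_counts(pac_counts, "gene", config.count, drop)
        result.counts = {"pac": pac_counts, "exon": exon_counts, "gene": gene_counts}

        for level, cm in result.counts.items():
            res = differential.run_differential(cm, design, config.diff)
            res.to_csv(os.path.join(outdir, f"{level}_results.csv"), index_label="feature")
            result.results[level] = res
            result.paths[f"results/{level}"] = os.path.join(outdir, f"{level}_results.csv")
            cm.to_csv(os.path.join(outdir, f"{level}_counts.csv"))

        sf = differential.size_factors(pac_counts)
        occ = classify.occupancy(pac_counts, design, sf, config.classify)
        calls = classify.classify_genes(
            result.results["gene"], result.results["pac"], occ, config.classify
        )
        result.report = classify.compile_report(
            result.results["gene"], result.results["exon"], result.results["pac"],
            calls, config.classify,
        )
        result.report_path = os.path.join(outdir, "final_report.csv")
        result.report.to_csv(result.report_path, index=False)
    return result
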