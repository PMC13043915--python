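"""End-to-end orchestration: simulate -> preprocess -> dedup -> filter -> quantify."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pysam

from . import preprocess, quantify, sitefilter
from .simulate import GenomeRef, SimConfig, SimulatedLibrary, simulate_reads

logger = logging.getLogger(__name__)


def contig_read_counts(path: str | Path) -> dict[str, int]:
    """Unique mapped reads per contig in a SAM/BAM file."""
    path = str(path)
    mode = "rb" if path.endswith(".bam") else "r"
    counts: dict[str, int] = {}
    with pysam.AlignmentFile(path, mode) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            counts[aln.reference_name] = counts.get(aln.reference_name, 0) + 1
    return counts


@dataclass
class ConditionResult:
    """Everything produced for one condition's library."""

    condition: str
    library: SimulatedLibrary
    preprocess_stats: dict
    dedup_stats: dict
    filter_records: list
    filter_summary: sitefilter.FilterSummary
    counts: quantify.CountSet


def run_condition(
    ref: GenomeRef,
    cfg: SimConfig,
    condition: str,
    workdir: str | Path,
    *,
    dedup_method: str = "exact",
    window: sitefilter.WindowSpec | None = None,
) -> ConditionResult:
    """Simulate one library and push it through the full pipeline.

    The FASTQ branch (trim + UMI extraction) is run for its stage counts
    and id consistency; classification consumes the simulator's
    ground-truth alignments after UMI deduplication.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    window = window or ref.binding_window

    library = simulate_reads(ref, cfg)
    paths = library.write(workdir, prefix=condition)
    ref.write_fasta(workdir / "reference.fa")

    trim_cfg = preprocess.TrimConfig(adapter=cfg.adapter)
    umi_cfg = preprocess.UmiConfig(umi_length=cfg.umi_length)
    processed, pre_stats = preprocess.preprocess_reads(
        preprocess.read_fastq(paths["fastq"]), trim_cfg, umi_cfg
    )
    preprocess.write_fastq(processed, workdir / f"{condition}.trimmed.fastq")
    logger.info("%s preprocess: %s", condition, pre_stats)

    dedup_sam = workdir / f"{condition}.dedup.sam"
    dd_stats = preprocess.dedup_sam(paths["sam"], dedup_sam, method=dedup_method)

    records, summary = sitefilter.filter_region(
        dedup_sam,
        window,
        out_bam=workdir / f"{condition}.peak.sam",
        out_tsv=workdir / f"{condition}.peak.tsv",
    )
    counts = quantify.counts_from_library(
        records,
        contig_read_counts(dedup_sam),
        minigene_contig=window.contig,
        condition=condition,
    )
    return ConditionResult(
        condition=condition,
        library=library,
        preprocess_stats=pre_stats,
        dedup_stats=dd_stats,
        filter_records=records,
        filter_summary=summary,
        counts=counts,
    )


def run_pair(
    ref: GenomeRef,
    base_cfg: SimConfig,
    workdir: str | Path,
    *,
    wt_occupancy: float = 1.0,
    mutant_occupancy: float = 0.4,
    quant_cfg: quantify.QuantConfig = quantify.QuantConfig(),
    dedup_method: str = "exact",
    mutant_seed_offset: int = 10_000,
) -> tuple["ConditionResult", "ConditionResult", "object"]:
    """Run matched WT and mutant conditions and build the comparison report."""
    from dataclasses import replace

    wt_cfg = replace(base_cfg, occupancy=wt_occupancy)
    mut_cfg = replace(
        base_cfg,
        occupancy=mutant_occupancy,
        seed=base_cfg.seed + mutant_seed_offset,
    )
    wt = run_condition(ref, wt_cfg, quant_cfg.reference_condition, workdir,
                       dedup_method=dedup_method)
    mut_label = "mutant" if quant_cfg.reference_condition != "mutant" else "mut2"
    mut = run_condition(ref, mut_cfg, mut_label, workdir, dedup_method=dedup_method)
    report = quantify.compare_conditions(wt.counts, mut.counts, quant_cfg)
    quantify.write_report(report, Path(workdir) / "report.tsv")
    return wt, mut, report
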