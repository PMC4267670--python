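"""End-to-end analysis pipeline: demux -> filter -> translate -> correct ->
rank -> (formats, diversity, clustering, motif search, comparisons).

Every stage logs how many reads enter and leave, and the run manifest
records versions, parameters and seeds, so that read counts are conserved
and any run is reproducible from its output directory alone.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

from bicypep.config import PipelineConfig
from bicypep.dataset_ops import compare_datasets
from bicypep.diversity import diversity_report
from bicypep.fastq_io import BarcodeSpec, demultiplex, read_fastq, write_demux_fastq
from bicypep.motif_analysis import cluster_top, clusters_to_text, find_motif
from bicypep.peptide_formats import format_statistics_to_tsv
from bicypep.preprocess import (
    AbundanceTable,
    ExtractionWindow,
    FilterPolicy,
    build_abundance_table,
    correct_errors,
    quality_filter,
    extract_region,
    translate_region,
)

__all__ = ["run_pipeline", "process_label", "LabelResult"]

logger = logging.getLogger("bicypep")


def _package_version() -> str:
    import bicypep

    return bicypep.__version__


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and context."""


@dataclass
class LabelResult:
    """Per-selection outcome: stage counters, tables and derived reports."""

    label: str
    n_assigned: int
    n_passed_filter: int
    n_unparseable: int
    n_translated: int
    table: AbundanceTable
    table_raw: Optional[AbundanceTable] = None  # before error correction
    reports: dict = field(default_factory=dict)


def process_label(
    label: str,
    reads,
    config: PipelineConfig,
) -> tuple[LabelResult, list[str]]:
    """Filter, extract, translate and tabulate the reads of one selection.

    Returns the result plus the per-read nucleotide stream (one entry per
    read that survived filtering and translation), used for rarefaction.
    """
    policy = FilterPolicy(config.q_threshold, config.max_below)
    window = ExtractionWindow(
        config.left_flank, config.right_flank, config.min_len, config.max_len
    )
    n_assigned = n_passed = n_unparseable = 0
    pairs: list[tuple[str, str]] = []
    nt_stream: list[str] = []
    for read in reads:
        n_assigned += 1
        if not quality_filter(read, policy):
            continue
        n_passed += 1
        region = extract_region(read, window)
        aa = None
        if region is not None:
            aa = translate_region(region, config.amber_as_gln)
        if aa is None:
            n_unparseable += 1
            continue
        pairs.append((aa, region))
        nt_stream.append(region)
    table_raw = build_abundance_table(pairs, validate=False)
    if config.correct:
        table = correct_errors(
            table_raw, config.max_mismatch, config.min_ratio, config.amber_as_gln
        )
    else:
        table = table_raw
    result = LabelResult(
        label=label,
        n_assigned=n_assigned,
        n_passed_filter=n_passed,
        n_unparseable=n_unparseable,
        n_translated=len(pairs),
        table=table,
        table_raw=table_raw,
    )
    return result, nt_stream


def _analyze_label(
    result: LabelResult, nt_stream: list[str], config: PipelineConfig, outdir: str
) -> None:
    label_dir = os.path.join(outdir, result.label)
    os.makedirs(label_dir, exist_ok=True)
    table = result.table
    table.to_tsv(os.path.join(label_dir, "abundance.tsv"))
    table.variants_to_tsv(os.path.join(label_dir, "nt_variants.tsv"))
    if len(table):
        format_statistics_to_tsv(table, os.path.join(label_dir, "formats.tsv"))
    if config.rarefaction and nt_stream:
        report = diversity_report(
            result.table_raw,
            None,
            nt_stream,
            seed=config.seed,
            n_points=config.n_points,
            repeats=config.repeats,
            max_mismatch=config.max_mismatch,
            min_ratio=config.min_ratio,
        )
        report["curve_before"].to_csv(os.path.join(label_dir, "rarefaction.csv"))
        report["curve_after"].to_csv(
            os.path.join(label_dir, "rarefaction_corrected.csv")
        )
        with open(os.path.join(label_dir, "fit.json"), "w") as handle:
            json.dump(
                {
                    "before": report["before"],
                    "after": report["after"],
                    "b_reduction": report["b_reduction"],
                    "seed": config.seed,
                },
                handle,
                indent=2,
            )
        result.reports["diversity"] = report
    if len(table) >= config.min_size:
        groups, singletons = cluster_top(
            table, config.top_n, config.cut_height, config.min_size
        )
        with open(os.path.join(label_dir, "clusters.txt"), "w") as handle:
            handle.write(clusters_to_text(groups, singletons))
        result.reports["clusters"] = (groups, singletons)
    for motif in config.motifs:
        hits = find_motif(table, motif)
        safe = motif.replace("[", "(").replace("]", ")")
        with open(os.path.join(label_dir, f"motif_{safe}.tsv"), "w") as handle:
            handle.write("aa_seq\tcount\tfraction\n")
            total = table.total_reads
            for seq, count in hits:
                handle.write(f"{seq}\t{count}\t{count / total:.6f}\n")
        result.reports.setdefault("motifs", {})[motif] = hits


def run_pipeline(
    config: PipelineConfig,
    fastq_paths: Sequence[str],
    outdir: str,
) -> dict[str, LabelResult]:
    """Run the full analysis on one or more FASTQ files.

    All FASTQ inputs are pooled and demultiplexed with the configured
    barcodes; each label is then filtered, translated, corrected, ranked
    and analyzed per the config.  Outputs (TSV/CSV/JSON and the run
    manifest) land under ``outdir``; per-label results are also returned.
    """
    os.makedirs(outdir, exist_ok=True)
    specs = [
        BarcodeSpec(b.label, b.barcode, b.expected_offset) for b in config.barcodes
    ]
    stage = "demultiplex"
    try:
        reads = [r for path in fastq_paths for r in read_fastq(path)]
        demux = demultiplex(reads, specs, rescue=config.rescue)
        write_demux_fastq(demux, outdir)
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc
    n_input = len(reads)
    unassigned_frac = len(demux.unassigned) / n_input if n_input else 0.0
    if unassigned_frac > 0.5:
        logger.warning(
            "%.0f%% of reads unassigned; check barcode configuration",
            100 * unassigned_frac,
        )

    results: dict[str, LabelResult] = {}
    manifest = {
        "version": _package_version(),
        "config": json.loads(config.model_dump_json()),
        "n_input_reads": n_input,
        "n_unassigned": len(demux.unassigned),
        "labels": {},
    }
    for label, label_reads in demux.assigned.items():
        stage = f"process[{label}]"
        try:
            result, nt_stream = process_label(label, label_reads, config)
            _analyze_label(result, nt_stream, config, outdir)
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc
        results[label] = result
        manifest["labels"][label] = {
            "assigned": result.n_assigned,
            "passed_filter": result.n_passed_filter,
            "unparseable": result.n_unparseable,
            "translated": result.n_translated,
            "table_reads": result.table.total_reads,
            "distinct_peptides": len(result.table),
            "distinct_peptides_raw": len(result.table_raw),
        }
        logger.info(
            "%s: %d assigned, %d passed filter, %d unparseable, "
            "%d in table (%d distinct)",
            label,
            result.n_assigned,
            result.n_passed_filter,
            result.n_unparseable,
            result.table.total_reads,
            len(result.table),
        )

    for group in config.compare:
        stage = f"compare{group}"
        try:
            tables = [results[label].table for label in group]
            comparison = compare_datasets(tables)
            comparison.write_tsv(
                os.path.join(outdir, "compare_" + "_vs_".join(group))
            )
        except KeyError as exc:
            raise PipelineError(f"stage {stage}: unknown label {exc}") from exc

    with open(os.path.join(outdir, "manifest.json"), "w") as handle:
        json.dump(manifest, handle, indent=2)
    return results
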