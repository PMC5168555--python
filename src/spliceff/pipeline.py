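"""End-to-end workflow: annotation -> filtering -> junctions -> coverage ->
efficiency tables and plots.

Outputs mirror the conventional folder layout::

    transreads/splice_junctions_coverage.known.csv   (.novel.csv alongside)
    introns/introns_known_5ss.bed, introns_known_3ss.bed and *.counts.csv
    efficiency/splicing_efficiency_{5ss,3ss}_{conf,all}.csv
    efficiency/relative_splicing_efficiency_{5ss,3ss}_conf.csv
    images/<pair>_{5ss,3ss}.pdf
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import alignments as aln_mod
from .alignments import FilterStats, filter_alignments
from .annotation import (
    FIVE_PRIME,
    THREE_PRIME,
    IntronRecord,
    TerminalBase,
    intron_terminal_bases,
    parse_gene_annotation,
    split_by_end,
    write_terminal_bases_bed,
)
from .coverage import terminal_base_coverage, write_coverage_counts
from .efficiency import (
    EfficiencyRecord,
    RelativeEfficiencyRecord,
    WorkflowConfig,
    efficiency_records,
    efficiency_scatterplot,
    pool_samples,
    relative_efficiency,
    write_efficiency_tables,
    write_relative_table,
)
from .junctions import (
    JunctionRecord,
    annotate_junctions,
    extract_junctions,
    write_junction_counts,
)

log = logging.getLogger(__name__)

_SITE_TAG = {FIVE_PRIME: "5ss", THREE_PRIME: "3ss"}


@dataclass
class WorkflowResult:
    """In-memory handles on everything the workflow wrote."""

    introns: list[IntronRecord]
    filter_stats: dict[str, FilterStats]
    junctions: dict[str, list[JunctionRecord]]
    known_junctions: pd.DataFrame
    novel_junctions: pd.DataFrame
    coverage: dict[str, dict[str, dict[TerminalBase, int]]]  # site -> sample -> counts
    efficiencies: dict[str, list[EfficiencyRecord]]  # site -> records
    relative: dict[str, list[RelativeEfficiencyRecord]]  # site -> records
    output_dir: Optional[Path] = None


def _transread_counts(records: list[JunctionRecord]) -> dict[tuple[str, int, int], int]:
    return {r.key: r.transread_count for r in records}


def run_workflow(config: WorkflowConfig) -> WorkflowResult:
    """Run the complete splicing-efficiency workflow for all samples.

    Requires ``config.annotation`` (GTF path) and ``config.samples``
    (sample id -> SAM/BAM path).  When ``config.output_dir`` is set, all
    tables, BED files and plots are written there; otherwise the results
    stay in memory only.
    """
    if not config.annotation:
        raise ValueError("config.annotation (GTF path) is required")
    if not config.samples:
        raise ValueError("config.samples must declare at least one sample")

    introns = parse_gene_annotation(config.annotation)
    log.info("annotation: %d known introns", len(introns))
    terminal_bases = intron_terminal_bases(introns)
    five_bases, three_bases = split_by_end(terminal_bases)
    site_bases = {FIVE_PRIME: five_bases, THREE_PRIME: three_bases}

    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        (outdir / "introns").mkdir(parents=True, exist_ok=True)
        (outdir / "transreads").mkdir(exist_ok=True)
        (outdir / "efficiency").mkdir(exist_ok=True)
        (outdir / "images").mkdir(exist_ok=True)
        write_terminal_bases_bed(five_bases, outdir / "introns" / "introns_known_5ss.bed")
        write_terminal_bases_bed(three_bases, outdir / "introns" / "introns_known_3ss.bed")

    filter_stats: dict[str, FilterStats] = {}
    junctions_by_sample: dict[str, list[JunctionRecord]] = {}
    coverage: dict[str, dict[str, dict[TerminalBase, int]]] = {
        FIVE_PRIME: {},
        THREE_PRIME: {},
    }
    for sample, path in config.samples.items():
        stats = FilterStats()
        alns = list(filter_alignments(path, config.min_mapq, stats))
        filter_stats[sample] = stats
        log.info(
            "%s: %d records, %d kept (unmapped %d, secondary %d, "
            "supplementary %d, MAPQ<%d %d, malformed %d)",
            sample, stats.total, stats.kept, stats.unmapped, stats.secondary,
            stats.supplementary, config.min_mapq, stats.low_mapq,
            stats.malformed_cigar,
        )
        records = extract_junctions(
            alns,
            min_intron=config.min_intron,
            max_intron=config.max_intron,
            min_anchor=config.min_anchor,
        )
        junctions_by_sample[sample] = annotate_junctions(records, introns)
        refs = aln_mod.reference_names(path)
        for site, bases in site_bases.items():
            coverage[site][sample] = terminal_base_coverage(
                alns, bases, config.strandedness, reference_names=refs
            )

    if outdir:
        known_df, novel_df = write_junction_counts(
            junctions_by_sample,
            outdir / "transreads" / "splice_junctions_coverage.known.csv",
            outdir / "transreads" / "splice_junctions_coverage.novel.csv",
        )
        write_coverage_counts(
            coverage[FIVE_PRIME],
            outdir / "introns" / "introns_known_5ss.bed.counts.csv",
        )
        write_coverage_counts(
            coverage[THREE_PRIME],
            outdir / "introns" / "introns_known_3ss.bed.counts.csv",
        )
    else:
        from .junctions import junction_count_table, KNOWN

        table = junction_count_table(junctions_by_sample)
        known_df = table[table["annotation_class"] == KNOWN].reset_index(drop=True)
        novel_df = table[table["annotation_class"] != KNOWN].reset_index(drop=True)

    # efficiency per sample and per pooled group, both sites
    trans_by_sample = {
        s: _transread_counts(recs) for s, recs in junctions_by_sample.items()
    }
    units: dict[str, tuple[dict, dict, dict]] = {}
    for sample in config.samples:
        units[sample] = (
            trans_by_sample[sample],
            coverage[FIVE_PRIME][sample],
            coverage[THREE_PRIME][sample],
        )
    for group, members in config.sample_groups.items():
        units[group] = (
            pool_samples(trans_by_sample, members),
            pool_samples(coverage[FIVE_PRIME], members),
            pool_samples(coverage[THREE_PRIME], members),
        )

    efficiencies: dict[str, list[EfficiencyRecord]] = {}
    for site in (FIVE_PRIME, THREE_PRIME):
        records: list[EfficiencyRecord] = []
        for unit, (trans, cov5, cov3) in units.items():
            cov = cov5 if site == FIVE_PRIME else cov3
            records.extend(
                efficiency_records(
                    introns, trans, cov, unit, site,
                    min_transreads=config.min_transreads,
                    min_coverage=config.min_coverage,
                )
            )
        efficiencies[site] = records
        if outdir:
            tag = _SITE_TAG[site]
            write_efficiency_tables(
                records,
                outdir / "efficiency" / f"splicing_efficiency_{tag}_conf.csv",
                outdir / "efficiency" / f"splicing_efficiency_{tag}_all.csv",
            )

    relative: dict[str, list[RelativeEfficiencyRecord]] = {}
    for site in (FIVE_PRIME, THREE_PRIME):
        by_unit: dict[str, dict] = {}
        for rec in efficiencies[site]:
            by_unit.setdefault(rec.sample_or_group, {})[rec.intron_key] = rec
        rel_records: list[RelativeEfficiencyRecord] = []
        for test, ref in config.sample_pairs:
            for key, test_rec in by_unit.get(test, {}).items():
                ref_rec = by_unit.get(ref, {}).get(key)
                if ref_rec is not None:
                    rel_records.append(relative_efficiency(test_rec, ref_rec))
            if outdir:
                tag = _SITE_TAG[site]
                efficiency_scatterplot(
                    [r for r in efficiencies[site] if r.sample_or_group == test],
                    [r for r in efficiencies[site] if r.sample_or_group == ref],
                    site,
                    outdir / "images" / f"{test}_vs_{ref}_{tag}.pdf",
                    test_label=test,
                    reference_label=ref,
                )
        relative[site] = rel_records
        if outdir and config.sample_pairs:
            tag = _SITE_TAG[site]
            write_relative_table(
                rel_records,
                outdir / "efficiency" / f"relative_splicing_efficiency_{tag}_conf.csv",
            )

    return WorkflowResult(
        introns=introns,
        filter_stats=filter_stats,
        junctions=junctions_by_sample,
        known_junctions=known_df,
        novel_junctions=novel_df,
        coverage=coverage,
        efficiencies=efficiencies,
        relative=relative,
        output_dir=outdir,
    )
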