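"""Splice-junction (transread) detection, counting and annotation.

A *transread* is a read spanning an exon-exon junction of a spliced mRNA;
in its alignment the excised intron appears as an N gap.  Each N gap whose
length falls within plausible intron bounds and whose flanking blocks each
anchor a minimum number of aligned bases counts as one observation of that
junction.  Junctions are then classified against the annotated introns:
``known`` (exact coordinate match), ``novel_donor`` / ``novel_acceptor``
(one end matches an annotated splice site), ``novel_pair`` (both ends match
annotated sites of different introns) or ``novel``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .alignments import SplicedAlignment
from .annotation import IntronRecord

log = logging.getLogger(__name__)

KNOWN = "known"
NOVEL_DONOR = "novel_donor"
NOVEL_ACCEPTOR = "novel_acceptor"
NOVEL_PAIR = "novel_pair"
NOVEL = "novel"
AMBIGUOUS = "ambiguous"  # annotated introns on both strands share the coords

UNKNOWN_STRAND = "unknown"

JunctionKey = tuple[str, int, int]


@dataclass
class JunctionRecord:
    """One observed intron gap in one sample.

    ``start``/``end`` delimit the intronic gap, 0-based half-open.
    ``max_left_anchor``/``max_right_anchor`` are the largest flanking-block
    lengths seen among supporting reads (a diagnostic for alignment trust).
    """

    chrom: str
    start: int
    end: int
    transread_count: int = 0
    strand: str = UNKNOWN_STRAND
    annotation_class: Optional[str] = None
    max_left_anchor: int = 0
    max_right_anchor: int = 0
    gene_id: Optional[str] = None

    @property
    def key(self) -> JunctionKey:
        return (self.chrom, self.start, self.end)


@dataclass
class GapDiagnostics:
    """Counts of gaps that did not qualify as junction evidence."""

    qualifying: int = 0
    too_short: int = 0
    too_long: int = 0
    short_anchor: int = 0


def extract_junctions(
    alignments: Iterable[SplicedAlignment],
    min_intron: int = 20,
    max_intron: int = 10000,
    min_anchor: int = 8,
    diagnostics: Optional[GapDiagnostics] = None,
) -> list[JunctionRecord]:
    """Count transreads per junction from N-gapped alignments.

    Every gap of every read whose length lies in ``[min_intron,
    max_intron]`` and whose two flanking blocks each contribute at least
    ``min_anchor`` aligned reference bases increments that junction's
    transread count.  A read with several qualifying gaps supports each of
    them independently.

    Returns records sorted by (chrom, start, end); only junctions with at
    least one supporting read are reported.
    """
    if diagnostics is None:
        diagnostics = GapDiagnostics()
    acc: dict[JunctionKey, list[int]] = {}
    for aln in alignments:
        for i, (gap_start, gap_end) in enumerate(aln.gaps):
            gap_len = gap_end - gap_start
            if gap_len < min_intron:
                diagnostics.too_short += 1
                continue
            if gap_len > max_intron:
                diagnostics.too_long += 1
                continue
            left = aln.blocks[i][1] - aln.blocks[i][0]
            right = aln.blocks[i + 1][1] - aln.blocks[i + 1][0]
            if left < min_anchor or right < min_anchor:
                diagnostics.short_anchor += 1
                continue
            diagnostics.qualifying += 1
            entry = acc.setdefault((aln.chrom, gap_start, gap_end), [0, 0, 0])
            entry[0] += 1
            entry[1] = max(entry[1], left)
            entry[2] = max(entry[2], right)
    return [
        JunctionRecord(
            chrom=chrom,
            start=start,
            end=end,
            transread_count=count,
            max_left_anchor=max_l,
            max_right_anchor=max_r,
        )
        for (chrom, start, end), (count, max_l, max_r) in sorted(acc.items())
    ]


def annotate_junctions(
    junctions: Iterable[JunctionRecord],
    introns: Sequence[IntronRecord],
) -> list[JunctionRecord]:
    """Classify junctions against annotated introns; fills strand in place.

    A junction exactly matching one annotated intron is ``known`` and
    inherits its strand and gene.  If only one boundary coincides with an
    annotated splice site, the class names the *unannotated* side
    (``novel_acceptor`` when the donor is the known one, and vice versa);
    note that on the ``-`` strand the donor is the high-coordinate boundary.
    A junction matching annotated introns on both strands at identical
    coordinates is flagged ``ambiguous`` and excluded from the known set.
    """
    exact: dict[JunctionKey, list[IntronRecord]] = {}
    by_start: dict[tuple[str, int], list[IntronRecord]] = {}
    by_end: dict[tuple[str, int], list[IntronRecord]] = {}
    for intron in introns:
        exact.setdefault((intron.chrom, intron.start, intron.end), []).append(intron)
        by_start.setdefault((intron.chrom, intron.start), []).append(intron)
        by_end.setdefault((intron.chrom, intron.end), []).append(intron)

    out = []
    for j in junctions:
        matches = exact.get(j.key, [])
        if len({m.strand for m in matches}) > 1:
            log.warning(
                "junction %s:%d-%d matches annotated introns on both strands; "
                "excluded from the known set",
                j.chrom,
                j.start,
                j.end,
            )
            j.annotation_class = AMBIGUOUS
            j.strand = UNKNOWN_STRAND
        elif matches:
            j.annotation_class = KNOWN
            j.strand = matches[0].strand
            j.gene_id = matches[0].gene_id
        else:
            start_hits = by_start.get((j.chrom, j.start), [])
            end_hits = by_end.get((j.chrom, j.end), [])
            if start_hits and end_hits:
                j.annotation_class = NOVEL_PAIR
                strands = {m.strand for m in start_hits + end_hits}
                j.strand = strands.pop() if len(strands) == 1 else UNKNOWN_STRAND
            elif start_hits:
                hit = start_hits[0]
                # '+': low boundary is the donor -> acceptor side is novel
                j.annotation_class = (
                    NOVEL_ACCEPTOR if hit.strand == "+" else NOVEL_DONOR
                )
                j.strand = hit.strand
                j.gene_id = hit.gene_id
            elif end_hits:
                hit = end_hits[0]
                j.annotation_class = (
                    NOVEL_DONOR if hit.strand == "+" else NOVEL_ACCEPTOR
                )
                j.strand = hit.strand
                j.gene_id = hit.gene_id
            else:
                j.annotation_class = NOVEL
                j.strand = UNKNOWN_STRAND
        out.append(j)
    return out


def junction_count_table(
    per_sample: Mapping[str, Sequence[JunctionRecord]],
) -> pd.DataFrame:
    """Collate annotated per-sample junction records into one wide table.

    One row per junction observed in at least one sample; columns ``chrom,
    start, end, strand, annotation_class, gene_id`` followed by one
    transread-count column per sample (absent samples filled with 0).
    """
    meta: dict[JunctionKey, JunctionRecord] = {}
    counts: dict[JunctionKey, dict[str, int]] = {}
    for sample, records in per_sample.items():
        for rec in records:
            meta.setdefault(rec.key, rec)
            counts.setdefault(rec.key, {})[sample] = rec.transread_count
    samples = list(per_sample)
    rows = []
    for key in sorted(meta):
        rec = meta[key]
        row = {
            "chrom": rec.chrom,
            "start": rec.start,
            "end": rec.end,
            "strand": rec.strand,
            "annotation_class": rec.annotation_class,
            "gene_id": rec.gene_id,
        }
        for sample in samples:
            row[sample] = counts[key].get(sample, 0)
        rows.append(row)
    columns = ["chrom", "start", "end", "strand", "annotation_class", "gene_id"]
    return pd.DataFrame(rows, columns=columns + samples)


def write_junction_counts(
    per_sample: Mapping[str, Sequence[JunctionRecord]],
    known_path: Union[str, Path],
    novel_path: Union[str, Path],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write known and novel junction count CSVs; returns both tables.

    The ``known`` table holds exactly the junctions matching an annotated
    intron; everything else (including ambiguous-strand junctions) goes to
    the ``novel`` table.
    """
    table = junction_count_table(per_sample)
    known = table[table["annotation_class"] == KNOWN].reset_index(drop=True)
    novel = table[table["annotation_class"] != KNOWN].reset_index(drop=True)
    known.to_csv(known_path, index=False)
    novel.to_csv(novel_path, index=False)
    return known, novel
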