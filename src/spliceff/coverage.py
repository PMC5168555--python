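"""Strand-specific single-base coverage of intron terminal bases.

For each known intron the pre-mRNA (unspliced) signal is the number of
sense-strand reads whose aligned blocks cover the very first (5' site) or
very last (3' site) intronic base.  Split reads are honoured: a transread
whose N gap spans the base contributes nothing, so spliced evidence never
leaks into the unspliced denominator.

Strandedness must be stated explicitly.  ``forward`` means a sense read
aligns on the transcript's strand; ``reverse`` means it aligns on the
opposite strand (typical of dUTP protocols).  A wrong setting silently
counts antisense transcription instead, so there is no default.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .alignments import SplicedAlignment
from .annotation import TerminalBase

log = logging.getLogger(__name__)

FORWARD = "forward"
REVERSE = "reverse"

_FLIP = {"+": "-", "-": "+"}


@dataclass(frozen=True)
class CoverageRecord:
    """Sense-strand read count at one terminal base in one sample."""

    terminal_base: TerminalBase
    sample_id: str
    count: int


def sense_read_strand(feature_strand: str, strandedness: str) -> str:
    """Read strand that counts as 'sense' for a feature under a protocol."""
    if strandedness == FORWARD:
        return feature_strand
    if strandedness == REVERSE:
        return _FLIP[feature_strand]
    raise ValueError(
        f"strandedness must be {FORWARD!r} or {REVERSE!r}, got {strandedness!r}"
    )


def terminal_base_coverage(
    alignments: Iterable[SplicedAlignment],
    terminal_bases: Sequence[TerminalBase],
    strandedness: str,
    reference_names: Iterable[str] | None = None,
) -> dict[TerminalBase, int]:
    """Count sense-strand reads with an aligned block over each base.

    A read is counted once per terminal base when any of its blocks
    contains the base's position (half-open intervals, so a block ending
    exactly at the base does not cover it); N gaps never count.  Overlapping
    introns sharing a coordinate are counted independently.

    ``reference_names``, when given (e.g. from the SAM header), triggers a
    warning for terminal bases on chromosomes the alignments cannot
    mention; their counts stay 0.
    """
    counts: dict[TerminalBase, int] = {tb: 0 for tb in terminal_bases}
    if reference_names is not None:
        missing = {tb.chrom for tb in terminal_bases} - set(reference_names)
        for chrom in sorted(missing):
            log.warning(
                "chromosome %s absent from the alignment header; "
                "its terminal-base counts stay 0",
                chrom,
            )

    by_chrom: dict[str, tuple[list[int], list[list[tuple[TerminalBase, str]]]]] = {}
    for tb in terminal_bases:
        positions, payload = by_chrom.setdefault(tb.chrom, ([], []))
        required = sense_read_strand(tb.strand, strandedness)
        idx = bisect_left(positions, tb.pos)
        if idx < len(positions) and positions[idx] == tb.pos:
            payload[idx].append((tb, required))
        else:
            positions.insert(idx, tb.pos)
            payload.insert(idx, [(tb, required)])

    for aln in alignments:
        entry = by_chrom.get(aln.chrom)
        if entry is None:
            continue
        positions, payload = entry
        for block_start, block_end in aln.blocks:
            lo = bisect_left(positions, block_start)
            hi = bisect_right(positions, block_end - 1)
            for i in range(lo, hi):
                for tb, required in payload[i]:
                    if aln.read_strand == required:
                        counts[tb] += 1
    return counts


def coverage_table(
    per_sample: Mapping[str, Mapping[TerminalBase, int]],
) -> pd.DataFrame:
    """One row per terminal base, one count column per sample."""
    samples = list(per_sample)
    bases: list[TerminalBase] = []
    seen = set()
    for sample_counts in per_sample.values():
        for tb in sample_counts:
            if tb not in seen:
                seen.add(tb)
                bases.append(tb)
    bases.sort(key=lambda tb: (tb.chrom, tb.pos, tb.intron_key, tb.which_end))
    rows = []
    for tb in bases:
        c, s, e, st = tb.intron_key
        row = {
            "chrom": tb.chrom,
            "start": tb.pos,
            "end": tb.pos + 1,
            "strand": tb.strand,
            "which_end": tb.which_end,
            "intron": f"{c}:{s}-{e}:{st}",
        }
        for sample in samples:
            row[sample] = per_sample[sample].get(tb, 0)
        rows.append(row)
    columns = ["chrom", "start", "end", "strand", "which_end", "intron"]
    return pd.DataFrame(rows, columns=columns + samples)


def write_coverage_counts(
    per_sample: Mapping[str, Mapping[TerminalBase, int]],
    path: Union[str, Path],
) -> pd.DataFrame:
    """Write a terminal-base count table as CSV; returns the table."""
    table = coverage_table(per_sample)
    table.to_csv(path, index=False)
    return table
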