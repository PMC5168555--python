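"""Alignment filtering and split-read block decomposition.

Reads SAM/BAM records (via pysam), keeps only primary alignments mapped
unambiguously (MAPQ above a threshold), and decomposes each survivor into
ordered reference-interval *blocks* separated by the *gaps* that N CIGAR
operations skip.  Gaps are the raw evidence for splice junctions; blocks are
what may cover an intron terminal base.  Deletions (D) stay inside a block:
a read deleted over a position still spans it on the reference.

The pipeline is single-end by design: mate flags are ignored and every
record is treated independently.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import pysam

log = logging.getLogger(__name__)

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")
_CIGAR_FULL = re.compile(r"(?:\d+[MIDNSHP=X])+$")

#: CIGAR operations that consume reference within a block.
_BLOCK_OPS = frozenset("M=XD")


class MalformedCigarError(ValueError):
    """CIGAR string that cannot be decomposed into blocks and gaps."""


@dataclass
class SplicedAlignment:
    """A filtered read as reference blocks split on N gaps.

    ``blocks`` are sorted, non-overlapping 0-based half-open intervals;
    ``gaps`` are the skipped intervals between consecutive blocks, so
    ``len(gaps) == len(blocks) - 1`` always holds.
    """

    read_id: str
    chrom: str
    blocks: list[tuple[int, int]]
    gaps: list[tuple[int, int]]
    mapq: int
    read_strand: str  # '+' or '-', from the reverse-complement flag
    flags: int = 0


@dataclass
class FilterStats:
    """Counters accumulated while filtering an alignment stream."""

    total: int = 0
    unmapped: int = 0
    secondary: int = 0
    supplementary: int = 0
    low_mapq: int = 0
    malformed_cigar: int = 0
    kept: int = 0


def aligned_blocks(
    cigar: str, pos: int
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Decompose a CIGAR at reference position ``pos`` into blocks and gaps.

    M, ``=``, X and D extend the current block; N closes it and records a
    gap; I, S, H and P consume no reference.  ``pos`` is the 0-based
    leftmost reference coordinate of the alignment.

    Raises
    ------
    MalformedCigarError
        If the string cannot be tokenised, consumes no reference at all, or
        has an N as its first or last reference-consuming operation.
    """
    if not cigar or not _CIGAR_FULL.match(cigar):
        raise MalformedCigarError(f"unparsable CIGAR {cigar!r}")
    blocks: list[tuple[int, int]] = []
    gaps: list[tuple[int, int]] = []
    block_start = cur = pos
    for length_s, op in _CIGAR_TOKEN.findall(cigar):
        length = int(length_s)
        if op in _BLOCK_OPS:
            cur += length
        elif op == "N":
            if cur == block_start:
                raise MalformedCigarError(
                    f"CIGAR {cigar!r}: N not flanked by aligned bases"
                )
            blocks.append((block_start, cur))
            gaps.append((cur, cur + length))
            cur += length
            block_start = cur
        # I, S, H, P: no reference consumed
    if cur == block_start:
        raise MalformedCigarError(
            f"CIGAR {cigar!r}: no aligned bases after final N"
            if gaps
            else f"CIGAR {cigar!r}: consumes no reference"
        )
    blocks.append((block_start, cur))
    return blocks, gaps


AlignmentSource = Union[str, Path, pysam.AlignmentFile, Iterable[pysam.AlignedSegment]]


def filter_alignments(
    source: AlignmentSource,
    min_mapq: int = 10,
    stats: Optional[FilterStats] = None,
) -> Iterator[SplicedAlignment]:
    """Yield MAPQ-filtered primary alignments as :class:`SplicedAlignment`.

    Unmapped, secondary (0x100) and supplementary (0x800) records are
    dropped before the MAPQ test, so only reads mapped unambiguously to a
    single locus survive.  Duplicates are deliberately not removed.  Records
    with an unparsable CIGAR are skipped with a warning and counted in
    ``stats.malformed_cigar``.

    Parameters
    ----------
    source:
        Path to a SAM/BAM file, an open ``pysam.AlignmentFile``, or an
        iterable of ``pysam.AlignedSegment``.
    min_mapq:
        Minimum mapping quality kept (inclusive); 10 keeps only reads the
        aligner considers unambiguous.
    stats:
        Optional :class:`FilterStats` to accumulate counters into.
    """
    if stats is None:
        stats = FilterStats()
    own_handle = None
    if isinstance(source, (str, Path)):
        own_handle = pysam.AlignmentFile(str(source), check_sq=False)
        records: Iterable[pysam.AlignedSegment] = own_handle
    else:
        records = source
    try:
        for rec in records:
            stats.total += 1
            if rec.is_unmapped:
                stats.unmapped += 1
                continue
            if rec.is_secondary:
                stats.secondary += 1
                continue
            if rec.is_supplementary:
                stats.supplementary += 1
                continue
            if rec.mapping_quality < min_mapq:
                stats.low_mapq += 1
                continue
            try:
                blocks, gaps = aligned_blocks(rec.cigarstring, rec.reference_start)
            except MalformedCigarError as exc:
                stats.malformed_cigar += 1
                log.warning("read %s skipped: %s", rec.query_name, exc)
                continue
            stats.kept += 1
            yield SplicedAlignment(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                blocks=blocks,
                gaps=gaps,
                mapq=rec.mapping_quality,
                read_strand="-" if rec.is_reverse else "+",
                flags=rec.flag,
            )
    finally:
        if own_handle is not None:
            own_handle.close()


def reference_names(path: Union[str, Path]) -> list[str]:
    """Chromosome names declared in the SAM/BAM header."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        return list(fh.references)
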