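"""Known-intron derivation from a GTF gene annotation.

Budding-yeast introns are not always present as explicit ``intron`` features
in public annotations, but exon features are universal.  This module infers
the set of known introns as the gaps between consecutive exons of each
annotated transcript, deduplicates them across transcripts, and derives the
strand-aware 5' and 3' *terminal bases* of each intron -- the single first
and last intronic nucleotides whose read coverage serves as the pre-mRNA
(unspliced) signal in the splicing-efficiency ratio.

Coordinate conventions
----------------------
GTF input is 1-based inclusive; everything in memory is 0-based half-open
(``[start, end)``), the convention BED uses natively.  On the ``+`` strand
the 5' terminal base of an intron ``[start, end)`` is ``start`` and the 3'
terminal base is ``end - 1``; on the ``-`` strand the two are swapped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO, Union

log = logging.getLogger(__name__)

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

#: (chrom, start, end, strand) -- the identity of an intron after
#: deduplication across transcripts.
IntronKey = tuple[str, int, int, str]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """A GTF line that cannot be interpreted; the message names the line."""


@dataclass
class IntronRecord:
    """One annotated intron, deduplicated across transcripts.

    ``start``/``end`` are 0-based half-open reference coordinates of the
    intronic interval.  ``gene_id`` is the lexicographically smallest gene
    identifier among contributing transcripts (introns are almost always
    private to one gene; the tie-break only matters for annotation
    oddities).
    """

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(f"intron must span >= 1 base: {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-': {self.strand!r}")

    @property
    def key(self) -> IntronKey:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class TerminalBase:
    """A single intron-end nucleotide, strand-aware.

    ``pos`` is the 0-based coordinate of the base; ``which_end`` is
    ``"five_prime"`` (donor end) or ``"three_prime"`` (acceptor end).
    """

    chrom: str
    pos: int
    strand: str
    which_end: str
    intron_key: IntronKey


def _open_lines(source: Union[str, Path, TextIO, Iterable[str]]) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from fh
    else:
        yield from source


def _parse_attributes(attrs: str, lineno: int) -> tuple[str, str]:
    found = dict(_ATTR_RE.findall(attrs))
    try:
        return found["gene_id"], found["transcript_id"]
    except KeyError as exc:
        raise GtfParseError(
            f"GTF line {lineno}: exon feature lacks {exc.args[0]} attribute"
        ) from None


def parse_gene_annotation(
    gtf: Union[str, Path, TextIO, Iterable[str]],
) -> list[IntronRecord]:
    """Infer known introns from the exon features of a GTF annotation.

    For every transcript with at least two exons, the gaps between
    consecutive exons (in reference order) become introns.  Introns with
    identical ``(chrom, start, end, strand)`` across transcripts are merged
    into a single :class:`IntronRecord` carrying all supporting transcript
    ids.  Transcripts whose exons lie on multiple chromosomes or strands are
    skipped with a warning.

    Parameters
    ----------
    gtf:
        Path to a GTF file, or an iterable of GTF lines.

    Returns
    -------
    list of IntronRecord, sorted by (chrom, start, end, strand).

    Raises
    ------
    GtfParseError
        On a malformed exon line; the message names the offending line
        number.
    """
    exons: dict[str, list[tuple[str, int, int, str]]] = {}
    genes: dict[str, str] = {}
    for lineno, line in enumerate(_open_lines(gtf), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise GtfParseError(
                f"GTF line {lineno}: expected 9 tab-separated fields, "
                f"got {len(fields)}"
            )
        chrom, _source, feature, start_s, end_s, _score, strand, _frame = fields[:8]
        if feature != "exon":
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise GtfParseError(
                f"GTF line {lineno}: non-integer coordinates "
                f"{start_s!r}/{end_s!r}"
            ) from None
        if start < 1 or end < start:
            raise GtfParseError(
                f"GTF line {lineno}: invalid 1-based interval {start}..{end}"
            )
        if strand not in ("+", "-"):
            raise GtfParseError(f"GTF line {lineno}: invalid strand {strand!r}")
        gene_id, transcript_id = _parse_attributes(fields[8], lineno)
        # GTF 1-based inclusive -> 0-based half-open
        exons.setdefault(transcript_id, []).append((chrom, start - 1, end, strand))
        genes.setdefault(transcript_id, gene_id)

    merged: dict[IntronKey, tuple[set[str], set[str]]] = {}
    for transcript_id, tx_exons in exons.items():
        chroms = {e[0] for e in tx_exons}
        strands = {e[3] for e in tx_exons}
        if len(chroms) > 1 or len(strands) > 1:
            log.warning(
                "transcript %s has exons on multiple chromosomes/strands; skipped",
                transcript_id,
            )
            continue
        if len(tx_exons) < 2:
            continue
        chrom, strand = tx_exons[0][0], tx_exons[0][3]
        ordered = sorted(tx_exons, key=lambda e: e[1])
        for (_, _, prev_end, _), (_, next_start, _, _) in zip(ordered, ordered[1:]):
            if next_start <= prev_end:
                continue  # abutting or overlapping exons leave no intron
            key = (chrom, prev_end, next_start, strand)
            gene_ids, tx_ids = merged.setdefault(key, (set(), set()))
            gene_ids.add(genes[transcript_id])
            tx_ids.add(transcript_id)

    records = [
        IntronRecord(
            chrom=key[0],
            start=key[1],
            end=key[2],
            strand=key[3],
            gene_id=min(gene_ids),
            transcript_ids=frozenset(tx_ids),
        )
        for key, (gene_ids, tx_ids) in merged.items()
    ]
    records.sort(key=lambda r: r.key)
    return records


def intron_terminal_bases(introns: Iterable[IntronRecord]) -> list[TerminalBase]:
    """Return the two terminal bases (5' then 3') of every intron.

    Strand-aware: on ``+`` the 5' base is ``start`` and the 3' base is
    ``end - 1``; on ``-`` the assignment is swapped.  A length-1 intron
    yields both terminal bases at the same coordinate.
    """
    out: list[TerminalBase] = []
    for intron in introns:
        if intron.strand == "+":
            five, three = intron.start, intron.end - 1
        else:
            five, three = intron.end - 1, intron.start
        out.append(
            TerminalBase(intron.chrom, five, intron.strand, FIVE_PRIME, intron.key)
        )
        out.append(
            TerminalBase(intron.chrom, three, intron.strand, THREE_PRIME, intron.key)
        )
    return out


def _bed_name(tb: TerminalBase) -> str:
    c, s, e, st = tb.intron_key
    tag = "5ss" if tb.which_end == FIVE_PRIME else "3ss"
    return f"{c}:{s}-{e}:{st}:{tag}"


def _parse_bed_name(name: str) -> tuple[IntronKey, str]:
    chrom, span, strand, tag = name.rsplit(":", 3)
    start_s, end_s = span.split("-")
    which = FIVE_PRIME if tag == "5ss" else THREE_PRIME
    return (chrom, int(start_s), int(end_s), strand), which


def write_terminal_bases_bed(
    terminal_bases: Iterable[TerminalBase], path: Union[str, Path]
) -> None:
    """Write terminal bases as BED6 single-base intervals (0-based half-open)."""
    with open(path, "w") as fh:
        for tb in terminal_bases:
            fh.write(
                f"{tb.chrom}\t{tb.pos}\t{tb.pos + 1}\t{_bed_name(tb)}\t0\t{tb.strand}\n"
            )


def read_terminal_bases_bed(path: Union[str, Path]) -> list[TerminalBase]:
    """Read a BED6 file written by :func:`write_terminal_bases_bed`."""
    out: list[TerminalBase] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, _end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            intron_key, which = _parse_bed_name(name)
            out.append(TerminalBase(chrom, int(start), strand, which, intron_key))
    return out


def split_by_end(
    terminal_bases: Sequence[TerminalBase],
) -> tuple[list[TerminalBase], list[TerminalBase]]:
    """Partition terminal bases into (5' list, 3' list)."""
    five = [tb for tb in terminal_bases if tb.which_end == FIVE_PRIME]
    three = [tb for tb in terminal_bases if tb.which_end == THREE_PRIME]
    return five, three
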