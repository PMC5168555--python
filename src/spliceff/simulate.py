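"""Synthetic genome, annotation and spliced/unspliced read alignments.

The simulator emulates a strand-specific single-end RNA-seq experiment on
intron-containing yeast genes with a *known* per-gene spliced fraction
``p``: each read is drawn from the spliced mRNA with probability ``p``
(reads crossing an exon-exon junction get an N-gapped CIGAR with the exact
intron length) or from the unspliced pre-mRNA with probability ``1 - p``
(contiguous M CIGAR).  Read starts are uniform along the chosen template
and reads are error-free: the pipeline only inspects coordinates and CIGAR,
never base identities, although canonical GT..AG intron ends are written to
the genome FASTA for realism.

Sampling model and closed-form expectation
------------------------------------------
The number of reads starting at any given position of a template is
Poisson with rate ``(depth / L) * p`` on the mRNA and ``(depth / L) *
(1 - p)`` on the pre-mRNA, where ``L`` is the read length and ``depth`` the
expected per-base coverage a fraction-1 gene would receive.  A junction
collects transreads from the ``L - 2a + 1`` start positions that leave at
least ``a`` anchoring bases on each side; an intron terminal base is
covered by pre-mRNA reads from exactly ``L`` start positions (exons at
least ``L`` long guarantee no edge truncation).  The measured efficiency
therefore converges to::

    p * (L - 2a + 1) / ((1 - p) * L)

which :func:`expected_efficiency` returns and the recovery tests check.
"""

from __future__ import annotations

import math
import textwrap
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_SPACER = 100  # bases between genes and at chromosome edges


@dataclass
class GeneSpec:
    """One simulated intron-containing gene.

    ``exon_lengths`` and ``intron_lengths`` interleave along the gene
    (two exons and one intron by default); ``spliced_fraction`` is the
    probability a read comes from the spliced isoform.
    """

    name: str
    spliced_fraction: float
    exon_lengths: tuple[int, ...] = (300, 300)
    intron_lengths: tuple[int, ...] = (150,)
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0.0 <= self.spliced_fraction <= 1.0:
            raise ValueError("spliced_fraction must lie in [0, 1]")
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need exactly one intron between consecutive exons")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass
class SimSpec:
    """Parameters of one simulated dataset.

    ``depth`` is the expected per-base read coverage a gene would receive
    if all reads came from a single template; ``decoy_low_mapq_fraction``
    adds ambiguous-alignment decoys (MAPQ 3) that the MAPQ filter must
    remove.
    """

    genes: list[GeneSpec]
    read_length: int = 100
    depth: float = 500.0
    strandedness: str = "reverse"
    decoy_low_mapq_fraction: float = 0.02
    decoy_mapq: int = 3
    chrom: str = "chrSim"

    def __post_init__(self) -> None:
        if self.strandedness not in ("forward", "reverse"):
            raise ValueError("strandedness must be 'forward' or 'reverse'")
        for gene in self.genes:
            span = sum(gene.exon_lengths) + sum(gene.intron_lengths)
            if self.read_length > span:
                raise ValueError(
                    f"read length {self.read_length} exceeds gene {gene.name} "
                    f"span {span}"
                )
            if self.read_length > sum(gene.exon_lengths):
                raise ValueError(
                    f"read length {self.read_length} exceeds spliced length "
                    f"of gene {gene.name}"
                )


@dataclass
class SimPaths:
    fasta: Path
    gtf: Path
    sam: Path
    truth: Path


def default_spec(
    spliced_fractions: Sequence[float],
    read_length: int = 100,
    depth: float = 500.0,
    strandedness: str = "reverse",
    intron_length: int = 150,
    exon_length: int = 300,
) -> SimSpec:
    """A SimSpec with one two-exon gene per spliced fraction, strands alternating."""
    genes = [
        GeneSpec(
            name=f"gene{i + 1:03d}",
            spliced_fraction=p,
            exon_lengths=(exon_length, exon_length),
            intron_lengths=(intron_length,),
            strand="+" if i % 2 == 0 else "-",
        )
        for i, p in enumerate(spliced_fractions)
    ]
    return SimSpec(
        genes=genes,
        read_length=read_length,
        depth=depth,
        strandedness=strandedness,
    )


def expected_efficiency(
    spliced_fraction: float, read_length: int, min_anchor: int
) -> float:
    """Closed-form splicing efficiency the pipeline converges to.

    ``p * (L - 2a + 1) / ((1 - p) * L)`` for spliced fraction ``p`` < 1,
    read length ``L`` and junction anchor ``a``; NaN for ``p`` = 1 (no
    pre-mRNA reads, so the ratio is undefined).  Assumes flanking exons at
    least ``L`` long and ``L > 2a``.
    """
    if read_length <= 2 * min_anchor:
        raise ValueError("read length must exceed twice the anchor")
    p = spliced_fraction
    if p >= 1.0:
        return math.nan
    return p * (read_length - 2 * min_anchor + 1) / ((1.0 - p) * read_length)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class _GeneLayout:
    spec: GeneSpec
    gene_start: int  # genomic, 0-based
    exons: list[tuple[int, int]]  # genomic order, 0-based half-open
    introns: list[tuple[int, int]]

    @property
    def gene_end(self) -> int:
        return self.exons[-1][1]


def _layout_genes(spec: SimSpec) -> list[_GeneLayout]:
    layouts = []
    cursor = _SPACER
    for gene in spec.genes:
        exons: list[tuple[int, int]] = []
        introns: list[tuple[int, int]] = []
        pos = cursor
        for i, exon_len in enumerate(gene.exon_lengths):
            exons.append((pos, pos + exon_len))
            pos += exon_len
            if i < len(gene.intron_lengths):
                introns.append((pos, pos + gene.intron_lengths[i]))
                pos += gene.intron_lengths[i]
        layouts.append(_GeneLayout(gene, cursor, exons, introns))
        cursor = pos + _SPACER
    return layouts


def _genome_sequence(spec: SimSpec, layouts: list[_GeneLayout], rng) -> str:
    length = layouts[-1].gene_end + _SPACER if layouts else 2 * _SPACER
    bases = rng.choice(np.array(list("ACGT")), size=length)
    seq = list(map(str, bases))
    # canonical splice motifs: GT..AG on the transcribed strand
    for layout in layouts:
        for intron_start, intron_end in layout.introns:
            if layout.spec.strand == "+":
                seq[intron_start:intron_start + 2] = ["G", "T"]
                seq[intron_end - 2:intron_end] = ["A", "G"]
            else:  # reverse complement of GT..AG read on the genome forward strand
                seq[intron_start:intron_start + 2] = ["C", "T"]
                seq[intron_end - 2:intron_end] = ["A", "C"]
    return "".join(seq)


def _template_blocks(layout: _GeneLayout, spliced: bool) -> list[tuple[int, int]]:
    if spliced:
        return list(layout.exons)
    return [(layout.gene_start, layout.gene_end)]


def _read_alignment(
    blocks: Sequence[tuple[int, int]], offset: int, read_length: int
) -> tuple[int, str, list[tuple[int, int]]]:
    """Map a template offset to (genomic start, CIGAR, aligned blocks)."""
    remaining = read_length
    skip = offset
    out_blocks: list[tuple[int, int]] = []
    for b_start, b_end in blocks:
        b_len = b_end - b_start
        if skip >= b_len:
            skip -= b_len
            continue
        take = min(b_len - skip, remaining)
        out_blocks.append((b_start + skip, b_start + skip + take))
        remaining -= take
        skip = 0
        if remaining == 0:
            break
    if remaining:
        raise ValueError("read extends past template end")
    cigar_parts = []
    for i, (s, e) in enumerate(out_blocks):
        if i:
            cigar_parts.append(f"{s - out_blocks[i - 1][1]}N")
        cigar_parts.append(f"{e - s}M")
    return out_blocks[0][0], "".join(cigar_parts), out_blocks


def simulate_dataset(
    spec: SimSpec,
    seed: int,
    outdir: Union[str, Path],
    prefix: str = "sim",
) -> SimPaths:
    """Write a deterministic (FASTA, GTF, SAM, truth CSV) quartet.

    Given the same spec and seed the SAM is byte-identical across runs.
    Read counts per template are Poisson as described in the module
    docstring; decoy low-MAPQ reads are unspliced reads placed uniformly on
    the gene span.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    layouts = _layout_genes(spec)
    genome = _genome_sequence(spec, layouts, rng)
    L = spec.read_length
    rate = spec.depth / L  # expected reads starting per template position

    fasta_path = outdir / f"{prefix}.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{spec.chrom}\n")
        fh.write("\n".join(textwrap.wrap(genome, 60)) + "\n")

    gtf_path = outdir / f"{prefix}.gtf"
    with open(gtf_path, "w") as fh:
        for layout in layouts:
            gene = layout.spec
            for exon_start, exon_end in layout.exons:
                attrs = (
                    f'gene_id "{gene.name}"; transcript_id "{gene.name}.t1";'
                )
                fh.write(
                    "\t".join(
                        [
                            spec.chrom,
                            "sim",
                            "exon",
                            str(exon_start + 1),  # 1-based inclusive
                            str(exon_end),
                            ".",
                            gene.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )

    sam_path = outdir / f"{prefix}.sam"
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{spec.chrom}\tLN:{len(genome)}\n")
        for layout in layouts:
            gene = layout.spec
            p = gene.spliced_fraction
            if spec.strandedness == "forward":
                read_strand = gene.strand
            else:
                read_strand = "-" if gene.strand == "+" else "+"
            flag = 16 if read_strand == "-" else 0
            serial = 0
            for spliced in (True, False):
                template = _template_blocks(layout, spliced)
                template_len = sum(e - s for s, e in template)
                n_starts = template_len - L + 1
                weight = p if spliced else 1.0 - p
                n_reads = rng.poisson(rate * weight * n_starts)
                offsets = rng.integers(0, n_starts, size=n_reads)
                kind = "m" if spliced else "p"
                for offset in offsets:
                    start, cigar, blocks = _read_alignment(template, int(offset), L)
                    seq = "".join(genome[s:e] for s, e in blocks)
                    serial += 1
                    fh.write(
                        "\t".join(
                            [
                                f"{gene.name}_{kind}{serial:06d}",
                                str(flag),
                                spec.chrom,
                                str(start + 1),  # SAM is 1-based
                                "60",
                                cigar,
                                "*",
                                "0",
                                "0",
                                seq,
                                "*",
                            ]
                        )
                        + "\n"
                    )
            # decoys: ambiguous placements the MAPQ filter must drop
            span = layout.gene_end - layout.gene_start
            n_decoy = rng.poisson(
                spec.decoy_low_mapq_fraction * rate * span
            )
            offsets = rng.integers(0, span - L + 1, size=n_decoy)
            for i, offset in enumerate(offsets, start=1):
                start = layout.gene_start + int(offset)
                seq = genome[start:start + L]
                fh.write(
                    "\t".join(
                        [
                            f"{gene.name}_d{i:06d}",
                            str(flag),
                            spec.chrom,
                            str(start + 1),
                            str(spec.decoy_mapq),
                            f"{L}M",
                            "*",
                            "0",
                            "0",
                            seq,
                            "*",
                        ]
                    )
                    + "\n"
                )

    truth_path = outdir / f"{prefix}.truth.csv"
    with open(truth_path, "w") as fh:
        fh.write(
            "gene_id,chrom,intron_start,intron_end,strand,spliced_fraction\n"
        )
        for layout in layouts:
            for intron_start, intron_end in layout.introns:
                fh.write(
                    f"{layout.spec.name},{spec.chrom},{intron_start},"
                    f"{intron_end},{layout.spec.strand},"
                    f"{layout.spec.spliced_fraction}\n"
                )
    return SimPaths(fasta=fasta_path, gtf=gtf_path, sam=sam_path, truth=truth_path)
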