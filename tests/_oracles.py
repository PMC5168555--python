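"""Independent brute-force oracles used to cross-check the pipeline.

Everything here re-derives counts from raw SAM text by walking each CIGAR
one base at a time, deliberately sharing no code with the package.
"""

from __future__ import annotations

from collections import Counter
from fractions import Fraction

_REF_OPS = "MDN=X"


def _tokenize(cigar):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def per_base_walk(cigar, pos):
    """Return (covered reference positions set, gap list, flank lengths).

    ``gaps`` is a list of (start, end, left_aligned, right_aligned) where
    the flanks count the aligned reference bases in the segments adjacent
    to each N gap.
    """
    covered = set()
    segments = [0]  # aligned reference bases per inter-N segment
    gap_bounds = []
    ref = pos
    for n, op in _tokenize(cigar):
        if op == "N":
            gap_bounds.append((ref, ref + n))
            ref += n
            segments.append(0)
        elif op in "MDX=":
            for i in range(n):
                covered.add(ref + i)
            segments[-1] += n
            ref += n
        # I, S, H, P consume no reference
    gaps = [
        (start, end, segments[i], segments[i + 1])
        for i, (start, end) in enumerate(gap_bounds)
    ]
    return covered, gaps


def iter_sam_records(sam_text, min_mapq=10):
    """Yield (chrom, pos0, strand, cigar) for records passing the filters."""
    for line in sam_text.splitlines():
        if not line or line.startswith("@"):
            continue
        fields = line.split("\t")
        flag = int(fields[1])
        if flag & (0x4 | 0x100 | 0x800):
            continue
        if int(fields[4]) < min_mapq:
            continue
        strand = "-" if flag & 0x10 else "+"
        yield fields[2], int(fields[3]) - 1, strand, fields[5]


def brute_force_junctions(
    sam_text, min_mapq=10, min_intron=20, max_intron=10000, min_anchor=8
):
    """Counter of (chrom, start, end) -> transread count."""
    counts = Counter()
    for chrom, pos, _strand, cigar in iter_sam_records(sam_text, min_mapq):
        _covered, gaps = per_base_walk(cigar, pos)
        for start, end, left, right in gaps:
            if (
                min_intron <= end - start <= max_intron
                and left >= min_anchor
                and right >= min_anchor
            ):
                counts[(chrom, start, end)] += 1
    return counts


def brute_force_coverage(sam_text, bases, strandedness, min_mapq=10):
    """Counter of (chrom, pos, strand) -> sense-strand covering reads.

    ``bases`` is an iterable of (chrom, pos, feature_strand).
    """
    flip = {"+": "-", "-": "+"}
    counts = Counter({b: 0 for b in bases})
    for chrom, pos, read_strand, cigar in iter_sam_records(sam_text, min_mapq):
        covered, _gaps = per_base_walk(cigar, pos)
        for base in counts:
            b_chrom, b_pos, b_strand = base
            sense = b_strand if strandedness == "forward" else flip[b_strand]
            if b_chrom == chrom and read_strand == sense and b_pos in covered:
                counts[base] += 1
    return counts


def enumerate_expected_efficiency(exon1, exon2, intron, read_length, min_anchor, p):
    """Efficiency expectation by enumerating every read start position.

    Reads start at each position of a template at a rate proportional to
    the template's sampling weight (p for the spliced mRNA, 1 - p for the
    pre-mRNA).  Returns the exact transread / terminal-base-coverage ratio
    at the 5' site as a Fraction-backed float; the 3' site is symmetric.
    """
    p = Fraction(p).limit_denominator(10**6)
    L, a = read_length, min_anchor
    junction = exon1  # mRNA coordinate of the first base of exon 2
    # spliced template: exon1 + exon2 joined
    m_len = exon1 + exon2
    trans = sum(
        1
        for s in range(m_len - L + 1)
        if (junction - s) >= a and (s + L - junction) >= a
    )
    # unspliced template: first intron base at offset exon1
    p_len = exon1 + intron + exon2
    base = exon1
    cov = sum(1 for s in range(p_len - L + 1) if s <= base <= s + L - 1)
    if (1 - p) * cov == 0:
        return float("nan")
    return float(p * trans / ((1 - p) * cov))
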