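from __future__ import annotations

import pytest

import pysam


def make_sam_text(records, chrom_lengths=None):
    """Build a minimal SAM document from (qname, flag, chrom, pos1, mapq, cigar).

    ``pos1`` is 1-based as in SAM.  SEQ/QUAL are omitted ('*'): the
    pipeline never inspects base identities.
    """
    if chrom_lengths is None:
        chrom_lengths = {}
        for rec in records:
            chrom_lengths[rec[2]] = 100000
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom, length in chrom_lengths.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")
    for qname, flag, chrom, pos1, mapq, cigar in records:
        lines.append(
            f"{qname}\t{flag}\t{chrom}\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0\t*\t*"
        )
    return "\n".join(lines) + "\n"


@pytest.fixture
def write_sam(tmp_path):
    def _write(records, chrom_lengths=None, name="reads.sam"):
        path = tmp_path / name
        path.write_text(make_sam_text(records, chrom_lengths))
        return path

    return _write


def parse_sam_records(path):
    """Open a SAM file as a list of pysam records (for in-memory streams)."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        return list(fh)


@pytest.fixture
def two_exon_gtf(tmp_path):
    """One + strand gene: exons 1..100 and 201..300 (intron [100, 200))."""
    text = (
        'chrI\ttest\texon\t1\t100\t.\t+\t.\tgene_id "YAL001C"; transcript_id "YAL001C.t1";\n'
        'chrI\ttest\texon\t201\t300\t.\t+\t.\tgene_id "YAL001C"; transcript_id "YAL001C.t1";\n'
    )
    path = tmp_path / "genes.gtf"
    path.write_text(text)
    return path
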