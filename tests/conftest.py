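"""Shared fixtures and independent oracles for the test suite.

The padded-alignment oracle reconstructs, from the reference sequence and
the CIGAR alone (never the MD string), which read offsets sit on masked
reference Ns — the implementation recovers the same set from the MD string
alone (never the reference), so the two routes are independent.
"""
from __future__ import annotations

import pysam
import pytest

from allelesort.model import AlignmentView

# SAM numeric op codes used in test data.
M, I, D, N, S = 0, 1, 2, 3, 4


def padded_alignment(ref_seq: str, pos: int, cigar) -> list:
    """Aligned columns as (read_offset, ref_pos, ref_base) for M bases.

    Brute-force reconstruction by walking the CIGAR against the actual
    reference sequence; ``pos`` is 1-based.
    """
    columns = []
    qoff = 0
    rpos = pos
    for op, length in cigar:
        if op in (0, 7, 8):
            for _ in range(length):
                columns.append((qoff, rpos, ref_seq[rpos - 1]))
                qoff += 1
                rpos += 1
        elif op == 1:
            qoff += length
        elif op in (2, 3):
            rpos += length
        else:
            raise ValueError(f"oracle cannot handle op {op}")
    return columns


def oracle_masked_offsets(ref_seq: str, pos: int, cigar) -> list:
    """Read offsets over reference Ns, by direct reference inspection."""
    return [q for q, _r, base in padded_alignment(ref_seq, pos, cigar)
            if base == "N"]


def make_view(
    pos: int = 1,
    cigar=((0, 10),),
    sequence: str = "A" * 10,
    md: str = None,
    chrom: str = "chr1",
    name: str = "r1",
    conversion_strand: str = None,
    is_reverse: bool = False,
) -> AlignmentView:
    """Hand-build an AlignmentView without going through a SAM file."""
    return AlignmentView(
        name=name,
        is_paired=False,
        is_first=True,
        is_reverse=is_reverse,
        is_unmapped=False,
        chrom=chrom,
        pos=pos,
        cigar=[tuple(c) for c in cigar],
        sequence=sequence,
        md=md,
        conversion_strand=conversion_strand,
        raw=None,
    )


def write_sam(path, records, references=("chr1",), lengths=(100000,)):
    """Write AlignedSegment-describing dicts as a SAM file.

    Each record dict may carry: name, flag, chrom, pos (1-based), cigar
    (list of (op, len)), seq, md, tags (list of (tag, value)).
    """
    header = pysam.AlignmentHeader.from_references(
        list(references), list(lengths)
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for desc in records:
            rec = pysam.AlignedSegment(header)
            rec.query_name = desc.get("name", "r")
            rec.flag = desc.get("flag", 0)
            if not rec.is_unmapped:
                rec.reference_name = desc.get("chrom", references[0])
                rec.reference_start = desc.get("pos", 1) - 1
                rec.cigartuples = desc.get("cigar", [(0, len(desc.get("seq", "A")))])
                rec.mapping_quality = 40
            rec.query_sequence = desc.get("seq", "A" * 10)
            if "md" in desc:
                rec.set_tag("MD", desc["md"], value_type="Z")
            for tag, value in desc.get("tags", []):
                rec.set_tag(tag, value, value_type="Z")
            if desc.get("pnext") is not None:
                rec.next_reference_name = desc.get("rnext", rec.reference_name)
                rec.next_reference_start = desc["pnext"] - 1
            out.write(rec)
    return path


def read_tags(path) -> list:
    """(name, XX-tag) pairs of a tagged alignment file, in file order."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        return [(rec.query_name, rec.get_tag("XX")) for rec in fh]


def read_names(path) -> list:
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        return [rec.query_name for rec in fh]


@pytest.fixture()
def tiny_genome():
    return {"chr1": "ACGTACGTACGTACGTACGT", "chr2": "TTTTCCCCGGGGAAAATTTT"}
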