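"""Stage I: determine each read's allelic origin and append the XX:Z: tag.

Reads aligned to an N-masked genome carry the masked reference base N in
their MD:Z: field wherever they cross a SNP.  The tagger walks the CIGAR
and MD strings together to recover, without the reference in hand, the read
offsets sitting on masked positions, maps them to genomic coordinates,
looks them up in the SNP annotation and classifies the read:

    UA  unassignable (no informative SNP overlap)
    G1  genome-1-specific evidence only
    G2  genome-2-specific evidence only
    CF  conflicting (evidence for both genomes in one read)

CIGAR operations M, I, D and N (splices) are supported; soft-clipped,
hard-clipped or padded alignments are rejected and reported.  In bisulfite
mode, SNPs indistinguishable from bisulfite conversion on the aligned
strand (C/T on the forward, G/A on the reverse conversion strand) are
skipped, and at remaining C- or G-containing SNPs both methylation states
of the base are accepted as a match.
"""
from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass
from bisect import bisect_left, bisect_right
from typing import Iterable, Optional

from . import io as asio
from .model import AlignmentView, AlleleSortError, SnpRecord, TagReport

log = logging.getLogger(__name__)

# SAM numeric CIGAR operation codes.
_OP_M, _OP_I, _OP_D, _OP_N = 0, 1, 2, 3
_OP_EQ, _OP_X = 7, 8
_MATCH_OPS = (_OP_M, _OP_EQ, _OP_X)

_TAGS = ("UA", "G1", "G2", "CF")


class TaggerError(AlleleSortError):
    pass


class UnsupportedCigar(TaggerError):
    """Alignment uses a CIGAR operation outside {M, I, D, N, =, X}."""


class MdMismatch(TaggerError):
    """MD string inconsistent with the CIGAR's aligned-base count."""


class MissingMd(TaggerError):
    """Record lacks the MD:Z: field the tagger depends on."""


class SnpIndex:
    """Point and range lookup of SNP records by chromosome and position."""

    def __init__(self, records: Iterable[SnpRecord]):
        self._by_chrom: dict = {}
        self.genome_names: Optional[tuple] = None
        n = 0
        for rec in records:
            chrom = self._by_chrom.setdefault(rec.chrom, {})
            if rec.pos in chrom:
                raise TaggerError(
                    f"duplicate SNP at {rec.chrom}:{rec.pos} in annotation"
                )
            chrom[rec.pos] = rec
            n += 1
        self._positions = {
            chrom: sorted(posmap) for chrom, posmap in self._by_chrom.items()
        }
        self._count = n

    @classmethod
    def from_file(cls, path) -> "SnpIndex":
        index = cls(asio.read_snp_file(path))
        index.genome_names = asio.snp_file_genome_names(path)
        return index

    def __len__(self) -> int:
        return self._count

    def lookup(self, chrom: str, pos: int) -> Optional[SnpRecord]:
        return self._by_chrom.get(chrom, {}).get(pos)

    def overlap(self, chrom: str, start: int, end: int) -> list:
        """All SNPs with start <= position <= end, in position order."""
        positions = self._positions.get(chrom)
        if not positions:
            return []
        lo = bisect_left(positions, start)
        hi = bisect_right(positions, end)
        posmap = self._by_chrom[chrom]
        return [posmap[p] for p in positions[lo:hi]]


@dataclass(frozen=True, slots=True)
class BaseObservation:
    """One read base sitting on a known SNP, with its allele verdict."""

    pos: int  # genomic, 1-based
    read_base: str
    snp: SnpRecord
    verdict: str  # "allele1" | "allele2" | "neither" | "skipped_bisulfite"


def cigar_map(view: AlignmentView) -> list:
    """Map every aligned read base to its genomic position.

    Returns a list of ``(read_offset_0based, genomic_pos_1based)`` pairs,
    strictly increasing in both coordinates.  M/=/X consume read and
    genome, I consumes the read only, D and N the genome only; any other
    operation raises :class:`UnsupportedCigar`.
    """
    if not view.cigar:
        raise UnsupportedCigar("empty CIGAR")
    pairs = []
    qoff = 0
    rpos = view.pos
    for op, length in view.cigar:
        if op in _MATCH_OPS:
            pairs.extend(zip(range(qoff, qoff + length), range(rpos, rpos + length)))
            qoff += length
            rpos += length
        elif op == _OP_I:
            qoff += length
        elif op in (_OP_D, _OP_N):
            rpos += length
        else:
            raise UnsupportedCigar(f"CIGAR operation code {op} not supported")
    if view.sequence is not None and qoff != len(view.sequence):
        raise MdMismatch(
            f"CIGAR consumes {qoff} query bases but sequence is "
            f"{len(view.sequence)} bp"
        )
    return pairs


_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


def masked_positions_from_md(view: AlignmentView, pairs: Optional[list] = None) -> list:
    """Read offsets whose stored reference base is the mask base N.

    Walks the MD string in lock-step with the CIGAR's aligned-base list so
    insertions (absent from MD) and deletions (present but consuming no
    read base) are accounted for.
    """
    if view.md is None:
        raise MissingMd(
            f"read {view.name!r} has no MD:Z: field; the aligner must be "
            "configured to emit MD tags"
        )
    if pairs is None:
        pairs = cigar_map(view)
    offsets = []
    idx = 0  # index into the aligned-base list
    consumed = 0
    for m in _MD_TOKEN.finditer(view.md):
        consumed += len(m.group(0))
        if m.group(1) is not None:
            idx += int(m.group(1))
        elif m.group(2) is not None:
            pass  # deleted reference bases: no read base to examine
        else:
            if idx >= len(pairs):
                raise MdMismatch(
                    f"MD string {view.md!r} longer than aligned bases"
                )
            if m.group(3).upper() == "N":
                offsets.append(pairs[idx][0])
            idx += 1
    if consumed != len(view.md):
        raise MdMismatch(f"unparseable MD string {view.md!r}")
    if idx != len(pairs):
        raise MdMismatch(
            f"MD string {view.md!r} covers {idx} aligned bases, CIGAR has "
            f"{len(pairs)}"
        )
    return offsets


# ---------------------------------------------------------------------------
# Bisulfite rules

def bisulfite_usable(snp: SnpRecord, strand: str) -> bool:
    """Whether a SNP is informative on the given conversion strand.

    C/T (in either orientation) is indistinguishable from bisulfite
    conversion on the forward strand, G/A on the reverse strand; such
    positions are skipped rather than risking methylation-state
    misclassification.  They remain usable for the opposing strand.
    """
    alleles = {snp.allele1, snp.allele2}
    if strand == "forward" and alleles == {"C", "T"}:
        return False
    if strand == "reverse" and alleles == {"G", "A"}:
        return False
    return True


def bisulfite_match(read_base: str, allele_base: str, strand: str) -> bool:
    """Allele matching that tolerates the conversion of unmethylated bases.

    On the forward conversion strand both methylation states of C (read C
    or T) match an allele C; on the reverse strand read G or A matches an
    allele G.  Every other combination requires identity.
    """
    if strand == "forward" and allele_base == "C":
        return read_base in ("C", "T")
    if strand == "reverse" and allele_base == "G":
        return read_base in ("G", "A")
    return read_base == allele_base


def _strand_of(view: AlignmentView) -> str:
    if view.conversion_strand == "CT":
        return "forward"
    if view.conversion_strand == "GA":
        return "reverse"
    raise TaggerError(
        f"read {view.name!r} carries no genome-conversion tag; bisulfite "
        "mode expects Bismark-style alignments"
    )


def observe(
    view: AlignmentView,
    index: SnpIndex,
    bisulfite: bool = False,
) -> list:
    """Collect allele evidence for one read at its masked SNP positions.

    Masked positions not present in the annotation are ignored (masked but
    unknown to this strain pair).
    """
    pairs = cigar_map(view)
    offsets = masked_positions_from_md(view, pairs)
    if not offsets:
        return []
    pos_by_offset = dict(pairs)
    strand = _strand_of(view) if bisulfite else None
    seq = view.sequence or ""
    observations = []
    for off in offsets:
        gpos = pos_by_offset[off]
        snp = index.lookup(view.chrom, gpos)
        if snp is None:
            continue
        base = seq[off].upper()
        if bisulfite:
            if not bisulfite_usable(snp, strand):
                verdict = "skipped_bisulfite"
            else:
                m1 = bisulfite_match(base, snp.allele1, strand)
                m2 = bisulfite_match(base, snp.allele2, strand)
                if m1 and m2:
                    verdict = "neither"  # uninformative: matches both
                elif m1:
                    verdict = "allele1"
                elif m2:
                    verdict = "allele2"
                else:
                    verdict = "neither"
        else:
            if base == snp.allele1:
                verdict = "allele1"
            elif base == snp.allele2:
                verdict = "allele2"
            else:
                verdict = "neither"  # sequencing error or read-base N
        observations.append(BaseObservation(gpos, base, snp, verdict))
    return observations


def classify(observations: Iterable[BaseObservation]) -> str:
    """Reduce per-base verdicts to the read's allele tag.

    Evidence for both genomes in one read is conflicting; bases matching
    neither allele carry no information and cannot create conflicts.
    """
    a1 = sum(1 for o in observations if o.verdict == "allele1")
    a2 = sum(1 for o in observations if o.verdict == "allele2")
    if a1 > 0 and a2 > 0:
        return "CF"
    if a1 > 0:
        return "G1"
    if a2 > 0:
        return "G2"
    return "UA"


# ---------------------------------------------------------------------------
# File-level tagging

_DETECT_WINDOW = 100


def tag_file(
    input_path,
    index: SnpIndex,
    output_path,
    bisulfite: bool = False,
    hic: bool = False,
    paired: Optional[bool] = None,
    conversion_tag: str = "XG",
) -> TagReport:
    """Tag every record of an alignment file with its allelic origin.

    Records are re-emitted in input order, each with exactly one ``XX:Z:``
    tag.  Unmapped reads and reads with unsupported CIGARs are emitted as
    UA but counted in their own report buckets.  If the first records look
    like Bismark output (genome-conversion tags present), bisulfite mode
    and pairedness are switched on automatically.
    """
    if len(index) == 0:
        raise TaggerError("SNP annotation is empty")
    report = TagReport()
    infile = asio.open_alignments(input_path)
    with infile:
        head = list(itertools.islice(infile, _DETECT_WINDOW))
        if not bisulfite and any(r.has_tag(conversion_tag) for r in head):
            bisulfite = True
            log.info("genome-conversion tags detected: enabling bisulfite mode")
        if paired is None:
            paired = any(r.is_paired for r in head)
            if paired:
                log.info("paired flags detected: enabling paired mode")
        if hic:
            paired = True
        report.bisulfite_mode = bisulfite
        report.paired_mode = paired
        if not head:
            log.warning("input %s contains no alignment records", input_path)
        outfile = asio.open_alignment_writer(output_path, template=infile)
        with outfile:
            for rec in itertools.chain(head, infile):
                report.reads_seen += 1
                view = AlignmentView.from_pysam(rec, conversion_tag=conversion_tag)
                if view.is_unmapped:
                    report.unmapped_skipped += 1
                    asio.emit(view, "UA", outfile)
                    continue
                try:
                    observations = observe(view, index, bisulfite=bisulfite)
                except (UnsupportedCigar, MdMismatch):
                    report.cigar_unsupported += 1
                    asio.emit(view, "UA", outfile)
                    continue
                report.snp_positions_examined += len(observations)
                report.bisulfite_positions_skipped += sum(
                    1 for o in observations if o.verdict == "skipped_bisulfite"
                )
                report.neither_allele_basecalls += sum(
                    1 for o in observations if o.verdict == "neither"
                )
                tag = classify(observations)
                if tag == "G1":
                    report.genome1 += 1
                elif tag == "G2":
                    report.genome2 += 1
                elif tag == "CF":
                    report.conflicting += 1
                else:
                    report.unassignable += 1
                asio.emit(view, tag, outfile)
    report.check()
    return report
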