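"""Core value types shared across the package.

Coordinates are 1-based and fully closed everywhere in the public API,
matching the native conventions of VCF and SAM.  Any half-open arithmetic
is internal and never serialised.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Unambiguous DNA alphabet.
DNA = frozenset("ACGT")

#: Genome container: ordered mapping chromosome name -> uppercase sequence
#: over {A,C,G,T,N}.  Plain dicts preserve insertion order.
GenomeMap = dict


class AlleleSortError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(AlleleSortError):
    """A file did not conform to its expected format."""


@dataclass(frozen=True, slots=True)
class SnpRecord:
    """One SNP that is heterozygous between the two genomes of a hybrid.

    ``allele1`` is the base carried by genome 1 (the reference strain for a
    single hybrid, strain 1 for a dual hybrid); ``allele2`` the base carried
    by genome 2.
    """

    id: str
    chrom: str
    pos: int  # 1-based
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP position must be >= 1, got {self.pos}")
        if self.allele1 not in DNA or self.allele2 not in DNA:
            raise ValueError(
                f"SNP alleles must be single bases in ACGT, got "
                f"{self.allele1!r}/{self.allele2!r}"
            )
        if self.allele1 == self.allele2:
            raise ValueError(
                f"SNP alleles must differ, got {self.allele1}/{self.allele2} "
                f"at {self.chrom}:{self.pos}"
            )


@dataclass(frozen=True, slots=True)
class SampleCall:
    """Per-sample genotype plus its confidence flag (pass/fail/absent)."""

    genotype: tuple
    confidence: str  # "pass" | "fail" | "absent"


@dataclass(slots=True)
class VcfCall:
    """Minimal view of one VCF data line, restricted to requested samples."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple
    per_sample: dict
    id: Optional[str] = None


@dataclass(slots=True)
class AlignmentView:
    """The subset of a SAM record the tagger needs.

    ``cigar`` is a list of ``(operation_code, length)`` pairs using the
    numeric SAM operation codes (M=0, I=1, D=2, N=3, S=4, H=5, P=6, ==7,
    X=8).  ``raw`` is an opaque pass-through handle to the underlying
    record so it can be re-emitted untouched apart from the added tag.
    """

    name: str
    is_paired: bool
    is_first: bool
    is_reverse: bool
    is_unmapped: bool
    chrom: Optional[str]
    pos: int  # 1-based leftmost mapped position
    cigar: Optional[list]
    sequence: Optional[str]
    md: Optional[str]
    conversion_strand: Optional[str]  # "CT" | "GA" | None
    raw: object = None

    @classmethod
    def from_pysam(cls, rec, conversion_tag: str = "XG") -> "AlignmentView":
        md = rec.get_tag("MD") if rec.has_tag("MD") else None
        strand = None
        if rec.has_tag(conversion_tag):
            value = str(rec.get_tag(conversion_tag))
            if value in ("CT", "GA"):
                strand = value
        return cls(
            name=rec.query_name,
            is_paired=rec.is_paired,
            is_first=rec.is_read1 if rec.is_paired else True,
            is_reverse=rec.is_reverse,
            is_unmapped=rec.is_unmapped,
            chrom=rec.reference_name if not rec.is_unmapped else None,
            pos=(rec.reference_start + 1) if not rec.is_unmapped else 0,
            cigar=list(rec.cigartuples) if rec.cigartuples else None,
            sequence=rec.query_sequence,
            md=md,
            conversion_strand=strand,
            raw=rec,
        )


@dataclass(slots=True)
class FilterSummary:
    """Counters for one pass of VCF genotype filtering."""

    total_seen: int = 0
    retained: int = 0
    skipped_low_confidence: int = 0
    skipped_heterozygous: int = 0
    skipped_homozygous_ref: int = 0
    skipped_not_snp: int = 0
    skipped_ref_mismatch: int = 0
    skipped_missing_genotype: int = 0

    def skipped_total(self) -> int:
        return (
            self.skipped_low_confidence
            + self.skipped_heterozygous
            + self.skipped_homozygous_ref
            + self.skipped_not_snp
            + self.skipped_ref_mismatch
            + self.skipped_missing_genotype
        )

    def check(self) -> None:
        if self.total_seen != self.retained + self.skipped_total():
            raise AlleleSortError(
                f"filter summary does not balance: seen={self.total_seen} "
                f"retained={self.retained} skipped={self.skipped_total()}"
            )


@dataclass(slots=True)
class DualHybridSummary:
    """Counters for the strain-1 vs strain-2 annotation comparison."""

    total_seen: int = 0
    retained: int = 0
    strain1_only: int = 0
    strain2_only: int = 0
    shared_different: int = 0
    shared_identical_excluded: int = 0

    def check(self) -> None:
        if self.retained != (
            self.strain1_only + self.strain2_only + self.shared_different
        ):
            raise AlleleSortError("dual-hybrid summary does not balance")
        if self.total_seen != self.retained + self.shared_identical_excluded:
            raise AlleleSortError("dual-hybrid summary does not balance")


@dataclass(slots=True)
class MaskReport:
    """What apply_mask did to the genome."""

    per_chrom: dict = field(default_factory=dict)
    total: int = 0
    #: (chrom, pos) where the genome base matched neither allele.
    disagreements: list = field(default_factory=list)

    def check(self) -> None:
        if self.total != sum(self.per_chrom.values()):
            raise AlleleSortError("mask report does not balance")


@dataclass(slots=True)
class TagReport:
    """Counters for one tagging run (Stage I)."""

    reads_seen: int = 0
    unassignable: int = 0
    genome1: int = 0
    genome2: int = 0
    conflicting: int = 0
    unmapped_skipped: int = 0
    cigar_unsupported: int = 0
    snp_positions_examined: int = 0
    bisulfite_positions_skipped: int = 0
    neither_allele_basecalls: int = 0
    bisulfite_mode: bool = False
    paired_mode: bool = False

    def check(self) -> None:
        categorised = (
            self.unassignable
            + self.genome1
            + self.genome2
            + self.conflicting
            + self.unmapped_skipped
            + self.cigar_unsupported
        )
        if self.reads_seen != categorised:
            raise AlleleSortError(
                f"tag report does not balance: seen={self.reads_seen} "
                f"categorised={categorised}"
            )


@dataclass(slots=True)
class SortReport:
    """Counters for one sorting run (Stage II).

    ``written`` maps output category name to the number of *records*
    written there; ``conflicting_suppressed`` counts records withheld
    because conflicting output was not enabled.
    """

    reads_seen: int = 0
    pairs_seen: int = 0
    singletons_seen: int = 0
    written: dict = field(default_factory=dict)
    conflicting_suppressed: int = 0

    def check(self) -> None:
        if self.reads_seen != sum(self.written.values()) + self.conflicting_suppressed:
            raise AlleleSortError(
                f"sort report does not balance: seen={self.reads_seen} "
                f"written={sum(self.written.values())} "
                f"suppressed={self.conflicting_suppressed}"
            )
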