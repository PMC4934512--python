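"""Readers and writers for the formats the pipeline touches.

FASTA and VCF parsing are delegated to pysam (htslib); the SNP annotation
file is this package's own five-column tab-delimited format (always written
gzip-compressed, auto-detected on read); SAM/BAM streaming goes through
pysam.AlignmentFile and is exposed as :class:`~allelesort.model.AlignmentView`
values.
"""
from __future__ import annotations

import gzip
import logging
import re
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pysam

from .model import (
    DNA,
    AlignmentView,
    FormatError,
    GenomeMap,
    SampleCall,
    SnpRecord,
    VcfCall,
)

log = logging.getLogger(__name__)

# IUPAC ambiguity codes other than N are collapsed to N during
# normalisation so downstream masking arithmetic only ever sees ACGTN.
_NORMALISE = str.maketrans("RYSWKMBDHVU", "NNNNNNNNNNT")
_VALID_BASES = DNA | {"N"}


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> GenomeMap:
    """Read a (possibly gzipped) FASTA file into a genome mapping.

    Sequences are uppercased and non-ACGTN ambiguity codes collapsed to N;
    the part of the header after the first whitespace is dropped.
    """
    genome: GenomeMap = {}
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            name = entry.name
            if not name:
                raise FormatError(f"{path}: empty sequence name")
            if name in genome:
                raise FormatError(f"{path}: duplicate chromosome name {name!r}")
            seq = entry.sequence.upper().translate(_NORMALISE)
            if not seq:
                raise FormatError(f"{path}: empty sequence for {name!r}")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(
                    f"{path}: invalid characters {sorted(bad)} in {name!r}"
                )
            genome[name] = seq
    if not genome:
        raise FormatError(f"{path}: no FASTA records found")
    return genome


def write_fasta(genome: GenomeMap, path, line_width: int = 60) -> None:
    """Write a genome mapping as wrapped FASTA (gzipped if path ends .gz)."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    if not genome:
        log.warning("writing empty FASTA file to %s", path)
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as out:
        for name, seq in genome.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                out.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# VCF

def parse_vcf(
    path,
    samples: list,
    confidence_field: str = "FI",
) -> Iterator[VcfCall]:
    """Stream genotype calls for the requested samples from a VCF file.

    The confidence flag is a per-sample integer FORMAT field (default
    ``FI``, as in the Mouse Genomes Project VCFs): value 1 means pass, any
    other value fail; a missing field yields the tri-state ``"absent"``.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"{path}: cannot read VCF: {exc}") from exc
    with vcf:
        header_samples = set(vcf.header.samples)
        for sample in samples:
            if sample not in header_samples:
                raise FormatError(
                    f"{path}: sample {sample!r} not present in VCF header "
                    f"(available: {sorted(header_samples)})"
                )
        line_no = 0
        try:
            for rec in vcf:
                line_no += 1
                per_sample = {}
                for sample in samples:
                    s = rec.samples[sample]
                    try:
                        genotype = tuple(s["GT"])
                    except KeyError:
                        genotype = (None, None)
                    try:
                        flag = s[confidence_field]
                    except KeyError:
                        flag = None
                    if isinstance(flag, tuple):
                        flag = flag[0] if flag else None
                    if flag is None:
                        confidence = "absent"
                    elif flag == 1:
                        confidence = "pass"
                    else:
                        confidence = "fail"
                    per_sample[sample] = SampleCall(genotype, confidence)
                yield VcfCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts) if rec.alts else (),
                    per_sample=per_sample,
                    id=rec.id,
                )
        except (OSError, ValueError) as exc:
            raise FormatError(
                f"{path}: malformed VCF near data line {line_no + 1}: {exc}"
            ) from exc


# ---------------------------------------------------------------------------
# SNP annotation file

_ALLELE_RE = re.compile(r"^([ACGT])/([ACGT])$")
_GZIP_MAGIC = b"\x1f\x8b"


def _open_maybe_gzip(path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def write_snp_file(
    snps: Iterable[SnpRecord],
    path,
    genome_names: Optional[tuple] = None,
) -> int:
    """Write SNP records as the gzipped five-column annotation file.

    Columns: ID, chromosome, 1-based position, strand placeholder "1",
    alleles as "allele1/allele2".  An optional comment header records the
    two genome names for use in downstream reports.  Returns the number of
    records written.
    """
    n = 0
    with gzip.open(path, "wt") as out:
        if genome_names is not None:
            out.write(f"#genome1={genome_names[0]}\tgenome2={genome_names[1]}\n")
        for snp in snps:
            out.write(
                f"{snp.id}\t{snp.chrom}\t{snp.pos}\t1\t"
                f"{snp.allele1}/{snp.allele2}\n"
            )
            n += 1
    return n


def read_snp_file(path) -> Iterator[SnpRecord]:
    """Stream SNP records from an annotation file (gzip auto-detected)."""
    with _open_maybe_gzip(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(
                    f"{path}:{line_no}: expected 5 tab-separated columns, "
                    f"got {len(fields)}"
                )
            snp_id, chrom, pos_s, _strand, alleles = fields
            m = _ALLELE_RE.match(alleles)
            if not m:
                raise FormatError(
                    f"{path}:{line_no}: malformed allele column {alleles!r}"
                )
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(
                    f"{path}:{line_no}: non-integer position {pos_s!r}"
                ) from None
            try:
                yield SnpRecord(snp_id, chrom, pos, m.group(1), m.group(2))
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: {exc}") from exc


def snp_file_genome_names(path) -> Optional[tuple]:
    """Return the (genome1, genome2) names from the file header, if any."""
    with _open_maybe_gzip(path) as fh:
        first = fh.readline()
    m = re.match(r"^#genome1=(.*)\tgenome2=(.*)$", first.rstrip("\n"))
    if m:
        return (m.group(1), m.group(2))
    return None


# ---------------------------------------------------------------------------
# SAM/BAM

def open_alignments(path) -> pysam.AlignmentFile:
    """Open a SAM/BAM file for streaming (headers required)."""
    try:
        return pysam.AlignmentFile(str(path), check_sq=False)
    except (OSError, ValueError) as exc:
        raise FormatError(f"{path}: cannot read alignments: {exc}") from exc


def alignments(path, conversion_tag: str = "XG") -> Iterator[AlignmentView]:
    """Stream alignment records as AlignmentView values in file order."""
    with open_alignments(path) as fh:
        for rec in fh:
            yield AlignmentView.from_pysam(rec, conversion_tag=conversion_tag)


def open_alignment_writer(path, template: pysam.AlignmentFile) -> pysam.AlignmentFile:
    """Open a SAM or BAM writer (chosen by extension) sharing a header."""
    mode = "wb" if str(path).endswith(".bam") else "wh"
    return pysam.AlignmentFile(str(path), mode, template=template)


def emit(view: AlignmentView, tag: Optional[str], sink: pysam.AlignmentFile) -> None:
    """Write the original record, adding an XX:Z: allele tag if given.

    All other fields pass through untouched.
    """
    rec = view.raw
    if tag is not None:
        rec.set_tag("XX", tag, value_type="Z")
    sink.write(rec)
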