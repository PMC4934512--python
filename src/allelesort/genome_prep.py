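"""Build N-masked or personalised genomes from strain genotype calls.

Two preparation flavours exist.  A *single hybrid* crosses the reference
strain with one alternative strain: genome 1 is the reference, genome 2 the
strain, and every retained SNP is masked (or substituted) directly in the
reference.  A *dual hybrid* crosses two non-reference strains: both strains
are filtered against the reference, strain 1's variants are substituted
into the reference to make a new strain-1 coordinate frame, and a fresh
annotation is built whose allele 1/allele 2 are strain 1/strain 2.
Positions where both strains carry the same variant are no longer
polymorphic between the hybrids' genomes and are dropped from the new
annotation.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

from . import io as asio
from . import reports
from .model import (
    DNA,
    AlleleSortError,
    DualHybridSummary,
    FilterSummary,
    GenomeMap,
    MaskReport,
    SnpRecord,
)

log = logging.getLogger(__name__)


class GenomePrepError(AlleleSortError):
    pass


def filter_strain_snps(
    calls: Iterable,
    strain: str,
    genome: GenomeMap,
    accept_unflagged: bool = False,
) -> tuple:
    """Select high-confidence homozygous-alternative SNPs for one strain.

    A call is retained iff the strain's genotype is homozygous for a
    non-reference allele, its confidence flag passes (an absent flag is
    rejected unless ``accept_unflagged``), both REF and the genotype's ALT
    are single ACGT bases, and the genome carries the REF base at the
    position.  Retained calls become ``SnpRecord(allele1=REF,
    allele2=ALT)``.

    Returns ``(snps, FilterSummary)``.
    """
    summary = FilterSummary()
    snps: list = []
    for call in calls:
        summary.total_seen += 1
        sample = call.per_sample[strain]
        gt = sample.genotype
        if len(gt) == 0 or any(a is None for a in gt):
            summary.skipped_missing_genotype += 1
            continue
        if len(set(gt)) != 1:
            summary.skipped_heterozygous += 1
            continue
        allele_idx = gt[0]
        if allele_idx == 0:
            summary.skipped_homozygous_ref += 1
            continue
        if sample.confidence == "fail" or (
            sample.confidence == "absent" and not accept_unflagged
        ):
            summary.skipped_low_confidence += 1
            continue
        alleles = (call.ref,) + call.alts
        if allele_idx >= len(alleles):
            summary.skipped_missing_genotype += 1
            continue
        ref = call.ref.upper()
        alt = alleles[allele_idx].upper()
        if len(ref) != 1 or ref not in DNA or len(alt) != 1 or alt not in DNA:
            summary.skipped_not_snp += 1
            continue
        seq = genome.get(call.chrom)
        if seq is None:
            log.warning(
                "VCF chromosome %s absent from genome; skipping %s:%d",
                call.chrom, call.chrom, call.pos,
            )
            summary.skipped_ref_mismatch += 1
            continue
        if call.pos > len(seq) or seq[call.pos - 1] != ref:
            summary.skipped_ref_mismatch += 1
            continue
        snp_id = call.id if call.id not in (None, ".") else f"{call.chrom}_{call.pos}"
        snps.append(SnpRecord(snp_id, call.chrom, call.pos, ref, alt))
        summary.retained += 1
    summary.check()
    return snps, summary


def apply_mask(
    genome: GenomeMap,
    snps: Iterable[SnpRecord],
    mode: str = "n_mask",
    which_allele: int = 2,
) -> tuple:
    """Substitute SNP positions in a genome, in place of nothing else.

    ``n_mask`` writes the ambiguity base N at each SNP position;
    ``full_sequence`` writes the base of the requested allele (1 or 2).
    Chromosome lengths never change.  Positions whose current base matches
    neither allele (and is not a previous mask) are substituted anyway but
    recorded in the report's disagreement list.

    Returns ``(new_genome, MaskReport)``.
    """
    if mode not in ("n_mask", "full_sequence"):
        raise ValueError(f"unknown mask mode {mode!r}")
    if which_allele not in (1, 2):
        raise ValueError("which_allele must be 1 or 2")
    buffers = {name: bytearray(seq, "ascii") for name, seq in genome.items()}
    report = MaskReport()
    for snp in sorted(snps, key=lambda s: (s.chrom, s.pos)):
        buf = buffers.get(snp.chrom)
        if buf is None:
            raise GenomePrepError(
                f"SNP chromosome {snp.chrom!r} not present in genome"
            )
        if snp.pos > len(buf):
            raise GenomePrepError(
                f"SNP position {snp.chrom}:{snp.pos} beyond chromosome end "
                f"({len(buf)} bp): annotation/genome mismatch"
            )
        current = chr(buf[snp.pos - 1])
        if current not in (snp.allele1, snp.allele2, "N"):
            report.disagreements.append((snp.chrom, snp.pos))
        new_base = "N" if mode == "n_mask" else (
            snp.allele1 if which_allele == 1 else snp.allele2
        )
        buf[snp.pos - 1] = ord(new_base)
        report.per_chrom[snp.chrom] = report.per_chrom.get(snp.chrom, 0) + 1
        report.total += 1
    report.check()
    masked = {name: buf.decode("ascii") for name, buf in buffers.items()}
    return masked, report


def build_dual_hybrid_annotation(
    snps1: Iterable[SnpRecord],
    snps2: Iterable[SnpRecord],
    genome1: GenomeMap,
) -> tuple:
    """Re-reference two strains' SNP sets so allele 1/2 = strain 1/strain 2.

    Both inputs are expressed against the common reference (allele1=REF,
    allele2=strain ALT); ``genome1`` is the full-sequence strain-1 genome.
    Per position: strain-1-only sites flip to (strain1 alt, reference);
    strain-2-only sites keep (reference, strain2 alt); sites where both
    strains differ from the reference in different ways become
    (strain1 alt, strain2 alt); sites where both strains carry the same
    variant are no longer polymorphic between the two hybrid genomes and
    are excluded.

    Returns ``(snps, DualHybridSummary)``.
    """
    by_pos1 = {(s.chrom, s.pos): s for s in snps1}
    by_pos2 = {(s.chrom, s.pos): s for s in snps2}
    summary = DualHybridSummary()
    out: list = []
    for key in sorted(set(by_pos1) | set(by_pos2)):
        summary.total_seen += 1
        chrom, pos = key
        s1 = by_pos1.get(key)
        s2 = by_pos2.get(key)
        if s1 is not None and s2 is not None:
            if s1.allele2 == s2.allele2:
                summary.shared_identical_excluded += 1
                continue
            new = SnpRecord(s1.id, chrom, pos, s1.allele2, s2.allele2)
            summary.shared_different += 1
        elif s1 is not None:
            new = SnpRecord(s1.id, chrom, pos, s1.allele2, s1.allele1)
            summary.strain1_only += 1
        else:
            new = SnpRecord(s2.id, chrom, pos, s2.allele1, s2.allele2)
            summary.strain2_only += 1
        genome_base = genome1[chrom][pos - 1]
        if genome_base != new.allele1:
            raise GenomePrepError(
                f"dual-hybrid allele1 {new.allele1} disagrees with strain-1 "
                f"genome base {genome_base} at {chrom}:{pos}"
            )
        out.append(new)
        summary.retained += 1
    summary.check()
    return out, summary


def _write_genome(genome: GenomeMap, out_dir: Path, label: str) -> Path:
    d = out_dir / label
    d.mkdir(parents=True, exist_ok=True)
    path = d / "genome.fa"
    asio.write_fasta(genome, path)
    return path


def prepare_single_hybrid(
    vcf_path,
    strain: str,
    reference_path,
    out_dir,
    n_masking: bool = True,
    full_sequence: bool = False,
    chromosomes: Optional[list] = None,
    accept_unflagged: bool = False,
    confidence_field: str = "FI",
    build: str = "build",
) -> dict:
    """Filter one strain's SNPs and emit masked/personalised genomes.

    Genome 1 is the reference strain, genome 2 the requested strain.
    Writes the SNP annotation file, the requested genome flavours and a
    filtering report into ``out_dir``; returns their paths plus the
    in-memory summaries.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = asio.read_fasta(reference_path)
    if chromosomes:
        missing = [c for c in chromosomes if c not in genome]
        if missing:
            raise GenomePrepError(f"chromosomes not in reference: {missing}")
        genome = {c: genome[c] for c in chromosomes}
    calls = asio.parse_vcf(vcf_path, [strain], confidence_field=confidence_field)
    snps, summary = filter_strain_snps(
        calls, strain, genome, accept_unflagged=accept_unflagged
    )
    if not snps:
        raise GenomePrepError(
            f"zero SNPs retained for strain {strain!r}; filtering summary: "
            f"{summary}"
        )
    snp_path = out_dir / f"all_SNPs_{strain}_{build}.txt.gz"
    asio.write_snp_file(snps, snp_path, genome_names=("REF", strain))
    result = {"snp_file": snp_path, "filter_summary": summary, "snps": snps}
    if n_masking:
        masked, mask_report = apply_mask(genome, snps, mode="n_mask")
        result["n_masked"] = _write_genome(masked, out_dir, f"{strain}_N-masked")
        result["mask_report"] = mask_report
    if full_sequence:
        full, _ = apply_mask(genome, snps, mode="full_sequence", which_allele=2)
        result["full_sequence"] = _write_genome(
            full, out_dir, f"{strain}_full_sequence"
        )
    report_path = out_dir / "SNP_filtering_report.txt"
    reports.render_report(summary, report_path, title=f"SNP filtering: {strain}")
    result["report"] = report_path
    return result


def prepare_dual_hybrid(
    vcf_path,
    strain1: str,
    strain2: str,
    reference_path,
    out_dir,
    n_masking: bool = True,
    full_sequence: bool = False,
    chromosomes: Optional[list] = None,
    accept_unflagged: bool = False,
    confidence_field: str = "FI",
    build: str = "build",
) -> dict:
    """Build a dual-hybrid annotation and genome for two non-reference strains.

    Strain 1's variants are substituted into the reference to form the new
    coordinate frame's sequence; the re-referenced annotation (allele 1 =
    strain 1, allele 2 = strain 2) is then N-masked into that sequence.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = asio.read_fasta(reference_path)
    if chromosomes:
        missing = [c for c in chromosomes if c not in genome]
        if missing:
            raise GenomePrepError(f"chromosomes not in reference: {missing}")
        genome = {c: genome[c] for c in chromosomes}

    snps1, summary1 = filter_strain_snps(
        asio.parse_vcf(vcf_path, [strain1], confidence_field=confidence_field),
        strain1, genome, accept_unflagged=accept_unflagged,
    )
    snps2, summary2 = filter_strain_snps(
        asio.parse_vcf(vcf_path, [strain2], confidence_field=confidence_field),
        strain2, genome, accept_unflagged=accept_unflagged,
    )
    genome1_full, _ = apply_mask(genome, snps1, mode="full_sequence", which_allele=2)
    dual_snps, dual_summary = build_dual_hybrid_annotation(
        snps1, snps2, genome1_full
    )
    if not dual_snps:
        raise GenomePrepError(
            f"zero SNPs distinguish {strain1!r} from {strain2!r}; "
            f"shared-identical excluded: {dual_summary.shared_identical_excluded}"
        )
    pair = f"{strain1}_{strain2}"
    snp_path = out_dir / f"all_SNPs_{pair}_{build}.txt.gz"
    asio.write_snp_file(dual_snps, snp_path, genome_names=(strain1, strain2))
    result = {
        "snp_file": snp_path,
        "filter_summary_strain1": summary1,
        "filter_summary_strain2": summary2,
        "dual_summary": dual_summary,
        "snps": dual_snps,
    }
    if n_masking:
        masked, mask_report = apply_mask(genome1_full, dual_snps, mode="n_mask")
        result["n_masked"] = _write_genome(masked, out_dir, f"{pair}_N-masked")
        result["mask_report"] = mask_report
    if full_sequence:
        result["full_sequence_strain1"] = _write_genome(
            genome1_full, out_dir, f"{strain1}_full_sequence"
        )
        genome2_full, _ = apply_mask(
            genome, snps2, mode="full_sequence", which_allele=2
        )
        result["full_sequence_strain2"] = _write_genome(
            genome2_full, out_dir, f"{strain2}_full_sequence"
        )
    report_path = out_dir / "SNP_filtering_report.txt"
    reports.render_dual_report(
        summary1, summary2, dual_summary, report_path, strain1, strain2
    )
    result["report"] = report_path
    return result
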