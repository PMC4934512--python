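"""Deterministic synthetic diploid fixtures: genome, VCF, reads with truth.

The simulator builds a toy hybrid system end to end: a random reference
genome, strain variant calls (including deliberate negatives that the
genotype filter must reject), the two full-sequence allele genomes, and
reads of known allelic origin written as SAM records against the N-masked
reference — with CIGAR strings that may contain insertions, deletions and
splice gaps, and MD strings computed against the masked reference so that
every SNP crossing appears as a reference N.

Everything is driven by one integer seed; the same seed yields
byte-identical output files.  Separate child generators are used per file
type so, e.g., adding read simulation does not perturb the genome.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pysam

from . import genome_prep
from . import io as asio
from .model import AlleleSortError, GenomeMap, SnpRecord

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class SimulationError(AlleleSortError):
    pass


@dataclass(slots=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe the standard benchmark system: two 100 kb
    chromosomes, candidate variant sites at 1 per 300 bp of which three
    quarters pass genotype filtering (~500 usable SNPs genome-wide), and
    10,000 error-free 50 bp single-end reads drawn alternately from the
    two alleles.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 100_000
    snp_density: float = 1 / 300
    read_length: int = 50
    n_reads: int = 10_000
    error_rate: float = 0.0
    indel_rate: float = 0.0
    splice_rate: float = 0.0
    bisulfite: bool = False
    methylation_rate: float = 0.0  # per CpG cytosine
    hic: bool = False
    paired: bool = False
    #: "require": every read overlaps >= 1 SNP; "avoid": none does; "any".
    snp_overlap: str = "require"
    # Proportions of deliberate filter negatives among VCF lines.
    frac_het: float = 0.1
    frac_low_confidence: float = 0.1
    frac_indel: float = 0.05
    # Dual-strain only: fraction of sites where both strains share one variant.
    frac_shared_identical: float = 0.1
    frac_strain2_only: float = 0.2
    frac_shared_different: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "snp_density", "error_rate", "indel_rate", "splice_rate",
            "methylation_rate", "frac_het", "frac_low_confidence",
            "frac_indel", "frac_shared_identical", "frac_strain2_only",
            "frac_shared_different",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.chromosome_length < self.read_length:
            raise ValueError("chromosome_length must be >= read_length")
        if self.snp_overlap not in ("require", "avoid", "any"):
            raise ValueError(f"invalid snp_overlap {self.snp_overlap!r}")


@dataclass(slots=True)
class TruthRecord:
    """Ground truth for one simulated read (or read pair)."""

    allele: int  # 1 or 2
    snps_covered: int


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# Reference genome

def simulate_reference(config: SimConfig) -> GenomeMap:
    """Uniform-random ACGT chromosomes, reproducible under the seed."""
    rng = _rng(config, 0)
    genome: GenomeMap = {}
    for i in range(config.n_chromosomes):
        draws = rng.integers(0, 4, size=config.chromosome_length)
        genome[f"chr{i + 1}"] = _BASES[draws].tobytes().decode("ascii")
    return genome


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=FI,Number=1,Type=Integer,Description='
    '"High confidence (1) or low confidence (0)">\n'
)


@dataclass(slots=True)
class VcfEntry:
    """One data line to be written; genotypes per sample as VCF strings."""

    chrom: str
    pos: int
    ref: str
    alts: tuple
    samples: dict  # sample -> "GT:FI" string, e.g. "1/1:1"
    id: str = "."


def write_vcf(entries: Iterable[VcfEntry], samples: list, path) -> None:
    """Write a minimal VCF (plain text) from explicit entries."""
    entries = sorted(entries, key=lambda e: (e.chrom, e.pos))
    contigs = sorted({e.chrom for e in entries})
    with open(path, "w") as out:
        out.write(_VCF_HEADER)
        for c in contigs:
            out.write(f"##contig=<ID={c}>\n")
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for e in entries:
            cells = [e.samples.get(s, "0/0:1") for s in samples]
            out.write(
                f"{e.chrom}\t{e.pos}\t{e.id}\t{e.ref}\t{','.join(e.alts)}\t"
                f".\tPASS\t.\tGT:FI\t" + "\t".join(cells) + "\n"
            )


def _other_base(rng, ref: str, exclude: tuple = ()) -> str:
    choices = [b for b in "ACGT" if b != ref and b not in exclude]
    return choices[int(rng.integers(0, len(choices)))]


def simulate_vcf(
    genome: GenomeMap,
    config: SimConfig,
    strains: list,
    path,
) -> dict:
    """Sample SNP sites and write a VCF with retainables plus negatives.

    Negatives (heterozygous calls, low-confidence calls, indel ALTs) are
    interleaved in the configured proportions; in dual-strain mode sites
    are additionally split between strain-1-only, strain-2-only,
    shared-different and shared-identical variants.  Returns the truth:
    ``{strain: [SnpRecord, ...]}`` containing only calls the genotype
    filter should retain (allele1=REF, allele2=ALT).
    """
    if not 1 <= len(strains) <= 2:
        raise SimulationError("one or two strains supported")
    rng = _rng(config, 1)
    truth: dict = {s: [] for s in strains}
    entries: list = []
    dual = len(strains) == 2
    for chrom, seq in genome.items():
        hits = np.flatnonzero(rng.random(len(seq)) < config.snp_density)
        for idx in hits:
            pos = int(idx) + 1
            ref = seq[idx]
            if ref == "N":
                continue
            u = rng.random()
            snp_id = f"sim_{chrom}_{pos}"
            if u < config.frac_het:
                alt = _other_base(rng, ref)
                entries.append(VcfEntry(chrom, pos, ref, (alt,),
                                        {strains[0]: "0/1:1"}, snp_id))
                continue
            u -= config.frac_het
            if u < config.frac_low_confidence:
                alt = _other_base(rng, ref)
                entries.append(VcfEntry(chrom, pos, ref, (alt,),
                                        {strains[0]: "1/1:0"}, snp_id))
                continue
            u -= config.frac_low_confidence
            if u < config.frac_indel:
                alt = ref + _other_base(rng, ref)
                entries.append(VcfEntry(chrom, pos, ref, (alt,),
                                        {strains[0]: "1/1:1"}, snp_id))
                continue
            # Retainable site.
            alt = _other_base(rng, ref)
            if not dual:
                entries.append(VcfEntry(chrom, pos, ref, (alt,),
                                        {strains[0]: "1/1:1"}, snp_id))
                truth[strains[0]].append(SnpRecord(snp_id, chrom, pos, ref, alt))
                continue
            v = rng.random()
            if v < config.frac_shared_identical:
                entries.append(VcfEntry(
                    chrom, pos, ref, (alt,),
                    {strains[0]: "1/1:1", strains[1]: "1/1:1"}, snp_id))
                truth[strains[0]].append(SnpRecord(snp_id, chrom, pos, ref, alt))
                truth[strains[1]].append(SnpRecord(snp_id, chrom, pos, ref, alt))
            elif v < config.frac_shared_identical + config.frac_shared_different:
                alt2 = _other_base(rng, ref, exclude=(alt,))
                entries.append(VcfEntry(
                    chrom, pos, ref, (alt, alt2),
                    {strains[0]: "1/1:1", strains[1]: "2/2:1"}, snp_id))
                truth[strains[0]].append(SnpRecord(snp_id, chrom, pos, ref, alt))
                truth[strains[1]].append(SnpRecord(snp_id, chrom, pos, ref, alt2))
            elif v < (config.frac_shared_identical
                      + config.frac_shared_different
                      + config.frac_strain2_only):
                entries.append(VcfEntry(
                    chrom, pos, ref, (alt,),
                    {strains[0]: "0/0:1", strains[1]: "1/1:1"}, snp_id))
                truth[strains[1]].append(SnpRecord(snp_id, chrom, pos, ref, alt))
            else:
                entries.append(VcfEntry(
                    chrom, pos, ref, (alt,),
                    {strains[0]: "1/1:1", strains[1]: "0/0:1"}, snp_id))
                truth[strains[0]].append(SnpRecord(snp_id, chrom, pos, ref, alt))
    write_vcf(entries, strains, path)
    return truth


# ---------------------------------------------------------------------------
# Reads

def _random_cigar(rng, read_length: int, config: SimConfig) -> list:
    """A CIGAR over M plus at most one indel and one splice gap.

    Returned as ``[(op_code, length), ...]`` whose query-consuming lengths
    sum to ``read_length``.
    """
    events = []
    if config.indel_rate and rng.random() < config.indel_rate:
        kind = 1 if rng.random() < 0.5 else 2  # I or D
        events.append((kind, int(rng.integers(1, 4))))
    if config.splice_rate and rng.random() < config.splice_rate:
        events.append((3, int(rng.integers(50, 501))))
    if not events:
        return [(0, read_length)]
    rng.shuffle(events)
    # Query bases consumed by M segments (insertions consume query too).
    q_insert = sum(l for op, l in events if op == 1)
    m_total = read_length - q_insert
    if m_total < len(events) + 1:
        return [(0, read_length)]
    cuts = sorted(rng.choice(np.arange(1, m_total), size=len(events),
                             replace=False))
    cigar = []
    prev = 0
    for cut, event in zip(cuts, events):
        cigar.append((0, int(cut) - prev))
        cigar.append(event)
        prev = int(cut)
    cigar.append((0, m_total - prev))
    return cigar


def _ref_span(cigar) -> int:
    return sum(l for op, l in cigar if op in (0, 2, 3))


def _build_read(allele_seq: str, masked_seq: str, start: int, cigar, rng,
                config: SimConfig) -> tuple:
    """Construct the read sequence and its MD string.

    The read is copied from the allele genome along the CIGAR's reference
    walk; the MD string is computed against the N-masked reference, so
    masked SNP positions appear as reference-N mismatches.  Returns
    ``(sequence, md, aligned_ref_positions)``.
    """
    seq_parts = []
    aligned_positions = []  # 1-based reference positions of M bases
    rpos = start  # 1-based
    for op, length in cigar:
        if op == 0:
            seq_parts.append(allele_seq[rpos - 1 : rpos - 1 + length])
            aligned_positions.extend(range(rpos, rpos + length))
            rpos += length
        elif op == 1:
            ins = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
            seq_parts.append(ins)
        else:  # D or N consume reference only
            rpos += length
    seq = list("".join(seq_parts))
    # Sequencing errors, uniformly per base.
    if config.error_rate:
        for i in np.flatnonzero(rng.random(len(seq)) < config.error_rate):
            seq[i] = _other_base(rng, seq[i])
    # MD against the masked reference.
    md_parts = []
    match_run = 0
    qoff = 0
    rpos = start
    for op, length in cigar:
        if op == 0:
            for _ in range(length):
                ref_base = masked_seq[rpos - 1]
                if seq[qoff] == ref_base:
                    match_run += 1
                else:
                    md_parts.append(f"{match_run}{ref_base}")
                    match_run = 0
                qoff += 1
                rpos += 1
        elif op == 1:
            qoff += length
        elif op == 2:
            md_parts.append(f"{match_run}^{masked_seq[rpos - 1 : rpos - 1 + length]}")
            match_run = 0
            rpos += length
        else:  # N: skipped region, absent from MD
            rpos += length
    md_parts.append(str(match_run))
    return "".join(seq), "".join(md_parts), aligned_positions


def _bisulfite_convert(seq: str, strand: str, rng, config: SimConfig) -> str:
    """Convert unmethylated C (forward) or G (reverse) bases.

    Methylation protection is drawn per CpG cytosine at
    ``methylation_rate``; all other convertible bases always convert.
    """
    out = list(seq)
    for i, base in enumerate(out):
        if strand == "CT" and base == "C":
            in_cpg = i + 1 < len(out) and out[i + 1] == "G"
            if not (in_cpg and rng.random() < config.methylation_rate):
                out[i] = "T"
        elif strand == "GA" and base == "G":
            in_cpg = i > 0 and seq[i - 1] == "C"
            if not (in_cpg and rng.random() < config.methylation_rate):
                out[i] = "A"
    return "".join(out)


def _count_snps(snp_positions_by_chrom: dict, chrom: str, positions) -> int:
    snp_set = snp_positions_by_chrom.get(chrom, frozenset())
    return sum(1 for p in positions if p in snp_set)


def _pick_start(rng, chrom_len: int, span: int, snp_positions,
                mode: str) -> Optional[int]:
    """A 1-based start for a read of reference span ``span``."""
    max_start = chrom_len - span + 1
    if max_start < 1:
        return None
    if mode == "require" and snp_positions is not None and len(snp_positions):
        # Anchor the window on a random SNP so overlap is likely; the
        # caller still verifies against the aligned (M) positions.
        pos = int(snp_positions[int(rng.integers(0, len(snp_positions)))])
        lo = max(1, pos - span + 1)
        hi = min(pos, max_start)
        if hi < lo:
            return None
        return int(rng.integers(lo, hi + 1))
    return int(rng.integers(1, max_start + 1))


def simulate_reads(
    masked_genome: GenomeMap,
    allele_genomes: tuple,
    snps: list,
    config: SimConfig,
    out_sam,
) -> dict:
    """Write SAM records of known allelic origin against the masked genome.

    Reads alternate between allele 1 and allele 2.  Paired and Hi-C modes
    emit name-adjacent mates drawn from the same allele; bisulfite mode
    converts unmethylated bases and sets the genome-conversion tag (both
    mates of a pair are placed on the same conversion strand).  Returns
    ``{read_name: TruthRecord}``.
    """
    rng = _rng(config, 2)
    paired = config.paired or config.hic
    chroms = list(masked_genome)
    snp_positions_by_chrom: dict = {}
    for s in snps:
        snp_positions_by_chrom.setdefault(s.chrom, []).append(s.pos)
    snp_arrays = {c: np.array(sorted(p)) for c, p in snp_positions_by_chrom.items()}
    snp_sets = {c: frozenset(p) for c, p in snp_positions_by_chrom.items()}
    if config.snp_overlap == "require" and not snps:
        raise SimulationError("snp_overlap='require' needs a non-empty SNP list")

    header = pysam.AlignmentHeader.from_references(
        chroms, [len(masked_genome[c]) for c in chroms]
    )
    truth: dict = {}
    n_units = config.n_reads // 2 if paired else config.n_reads
    mode = "wb" if str(out_sam).endswith(".bam") else "wh"
    with pysam.AlignmentFile(str(out_sam), mode, header=header) as out:
        for i in range(n_units):
            allele = 1 if i % 2 == 0 else 2
            name = f"read{i}"
            strand = None
            if config.bisulfite:
                strand = "CT" if rng.random() < 0.5 else "GA"
            mates = []
            attempts = 0
            n_mates = 2 if paired else 1
            while len(mates) < n_mates:
                attempts += 1
                if attempts > 1000:
                    raise SimulationError(
                        "could not place a read satisfying the SNP-overlap "
                        "constraint; SNP density too low?"
                    )
                if config.hic or not mates:
                    chrom = chroms[int(rng.integers(0, len(chroms)))]
                cigar = _random_cigar(rng, config.read_length, config)
                span = _ref_span(cigar)
                if len(masked_genome[chrom]) < span + config.read_length:
                    continue
                start = _pick_start(
                    rng, len(masked_genome[chrom]), span,
                    snp_arrays.get(chrom), config.snp_overlap,
                )
                if start is None:
                    continue
                seq, md, aligned = _build_read(
                    allele_genomes[allele - 1][chrom],
                    masked_genome[chrom], start, cigar, rng, config,
                )
                covered = _count_snps(snp_sets, chrom, aligned)
                if config.snp_overlap == "require" and covered == 0:
                    continue
                if config.snp_overlap == "avoid" and covered > 0:
                    continue
                if config.bisulfite:
                    seq = _bisulfite_convert(seq, strand, rng, config)
                    # MD must reflect the converted read against the
                    # masked reference, so recompute mismatches.
                    md = _recompute_md(seq, masked_genome[chrom], start, cigar)
                mates.append((chrom, start, cigar, seq, md, covered))
            total_covered = sum(m[5] for m in mates)
            truth[name] = TruthRecord(allele=allele, snps_covered=total_covered)
            for j, (chrom, start, cigar, seq, md, _c) in enumerate(mates):
                rec = pysam.AlignedSegment(header)
                rec.query_name = name
                rec.query_sequence = seq
                rec.reference_name = chrom
                rec.reference_start = start - 1
                rec.cigartuples = cigar
                rec.mapping_quality = 40
                flag = 0
                if paired:
                    flag |= 0x1 | (0x40 if j == 0 else 0x80)
                    other = mates[1 - j]
                    rec.next_reference_name = other[0]
                    rec.next_reference_start = other[1] - 1
                if config.bisulfite and strand == "GA":
                    flag |= 0x10
                rec.flag = flag
                rec.set_tag("MD", md, value_type="Z")
                if config.bisulfite:
                    rec.set_tag("XG", strand, value_type="Z")
                out.write(rec)
    return truth


def _recompute_md(seq: str, masked_seq: str, start: int, cigar) -> str:
    md_parts = []
    match_run = 0
    qoff = 0
    rpos = start
    for op, length in cigar:
        if op == 0:
            for _ in range(length):
                ref_base = masked_seq[rpos - 1]
                if seq[qoff] == ref_base:
                    match_run += 1
                else:
                    md_parts.append(f"{match_run}{ref_base}")
                    match_run = 0
                qoff += 1
                rpos += 1
        elif op == 1:
            qoff += length
        elif op == 2:
            md_parts.append(f"{match_run}^{masked_seq[rpos - 1 : rpos - 1 + length]}")
            match_run = 0
            rpos += length
        else:
            rpos += length
    md_parts.append(str(match_run))
    return "".join(md_parts)


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as out:
        out.write("read\tallele\tsnps_covered\n")
        for name, rec in truth.items():
            out.write(f"{name}\t{rec.allele}\t{rec.snps_covered}\n")


def read_truth(path) -> dict:
    truth = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            name, allele, covered = line.rstrip("\n").split("\t")
            truth[name] = TruthRecord(int(allele), int(covered))
    return truth


# ---------------------------------------------------------------------------
# End-to-end dataset

def simulate_dataset(config: SimConfig, out_dir, strains: Optional[list] = None) -> dict:
    """Generate a complete fixture set under one seed.

    Emits ``ref.fa``, ``strain.vcf``, ``masked.fa``, ``snps.txt.gz``,
    ``reads.sam`` and ``truth.tsv`` in ``out_dir`` and returns the paths
    plus the in-memory objects (genomes, SNPs, truth).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    strains = strains or ["STRAIN1"]
    reference = simulate_reference(config)
    ref_path = out_dir / "ref.fa"
    asio.write_fasta(reference, ref_path)
    vcf_path = out_dir / "strain.vcf"
    truth_snps = simulate_vcf(reference, config, strains, vcf_path)

    if len(strains) == 1:
        snps = truth_snps[strains[0]]
        allele1 = reference
        allele2, _ = genome_prep.apply_mask(
            reference, snps, mode="full_sequence", which_allele=2
        )
    else:
        snps1 = truth_snps[strains[0]]
        snps2 = truth_snps[strains[1]]
        allele1, _ = genome_prep.apply_mask(
            reference, snps1, mode="full_sequence", which_allele=2
        )
        allele2, _ = genome_prep.apply_mask(
            reference, snps2, mode="full_sequence", which_allele=2
        )
        snps, _ = genome_prep.build_dual_hybrid_annotation(snps1, snps2, allele1)
    masked, _ = genome_prep.apply_mask(allele1, snps, mode="n_mask")
    masked_path = out_dir / "masked.fa"
    asio.write_fasta(masked, masked_path)
    snp_path = out_dir / "snps.txt.gz"
    genome_names = ("REF", strains[0]) if len(strains) == 1 else tuple(strains)
    asio.write_snp_file(snps, snp_path, genome_names=genome_names)

    sam_path = out_dir / "reads.sam"
    truth = simulate_reads(masked, (allele1, allele2), snps, config, sam_path)
    truth_path = out_dir / "truth.tsv"
    write_truth(truth, truth_path)
    return {
        "reference": ref_path,
        "vcf": vcf_path,
        "masked": masked_path,
        "snp_file": snp_path,
        "reads": sam_path,
        "truth_file": truth_path,
        "genome": reference,
        "masked_genome": masked,
        "allele_genomes": (allele1, allele2),
        "snps": snps,
        "truth_snps": truth_snps,
        "truth": truth,
    }
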