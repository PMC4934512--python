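# Methods

## The assignment model

A hybrid (F1) diploid genome differs from its two parental haplotypes at a
known set of single-base substitutions. After alignment to an N-masked
reference — the reference with every such position replaced by `N` — each
read's bases at masked positions are the only evidence of its allelic
origin. The tagger never sees the reference: it reconstructs which read
offsets sit over reference Ns from two fields the aligner already wrote,
the CIGAR (alignment structure) and the MD:Z: string (reference bases at
mismatch and deletion positions). The walk is:

1. Expand the CIGAR into the ordered list of aligned columns
   `(read_offset, genomic_position)` — M/=/X consume read and genome, I
   the read only, D and N the genome only.
2. Walk the MD string over that list: match-run numbers advance the
   column index, `^`-prefixed deletions advance nothing on the read side,
   and each substituted-reference letter consumes one column; letters equal
   to `N` mark masked columns.
3. Look each masked genomic position up in the SNP annotation; positions
   masked but absent from the annotation (e.g. masked for another strain
   pair) are ignored.
4. Compare the read base to the two alleles. With `a1`/`a2` the counts of
   allele-1/allele-2 matches, the read's tag is `CF` if both are positive,
   `G1`/`G2` if only one is, else `UA`.

Bases matching neither allele (sequencing errors, read-base `N`) are
counted but carry no weight: error should not manufacture conflicts, and a
conflict is defined strictly as evidence for both genomes.

Reads whose CIGAR contains soft/hard clips or padding cannot be walked
end-to-end and are rejected; they are still emitted (as `UA`) and counted
in a dedicated report bucket so the output remains an order-preserving
superset of the input — silently dropping records would break downstream
mate pairing. An absent MD tag aborts the run (the aligner must be
configured to emit it); an MD string inconsistent with the CIGAR rejects
only that read.

## Genome preparation

Genotype filtering retains a VCF call iff the strain's genotype is
homozygous for a non-reference allele, the per-sample confidence flag
passes (integer FORMAT field, default name `FI`, 1 = pass; an absent flag
is rejected unless `accept_unflagged` — the conservative reading of
"high-confidence"), both REF and the genotype-selected ALT are single
ACGT bases, and the reference genome actually carries REF at the position.
Each rejection increments exactly one counter, checked in precedence order
(missing genotype, heterozygous, homozygous-reference, confidence, not a
SNP, reference mismatch), so `total = retained + Σ skipped` always holds.

Masking substitutes `N` (or, for personalised genomes, the requested
allele's base) at each SNP position; chromosome lengths never change.
A genome base matching neither allele is substituted anyway but recorded —
assembly-patch drift is common and loud failure here would block whole
runs; a prior `N` (re-masking) is not counted as a disagreement, which
makes masking idempotent.

For dual hybrids the two strains' filtered sets are compared per position:
strain-1-only sites flip orientation to (strain1 alt, reference),
strain-2-only sites keep (reference, strain2 alt), sites with two
different alts become (alt1, alt2), and sites where both strains carry the
same variant are excluded — they no longer distinguish the two genomes.
Every output record's allele 1 is verified against the strain-1
full-sequence genome; a mismatch is a hard error, not a warning.

## Bisulfite and Hi-C handling

Bisulfite conversion turns unmethylated C into T (read on the reverse
conversion strand: G into A), so a C/T SNP on the forward strand, or a G/A
SNP on the reverse strand, is indistinguishable from conversion. Such
positions are skipped and counted (`skipped_bisulfite`); they stay usable
on the opposing strand. At remaining SNPs an allele C on the forward
strand is matched by read C *or* T (both methylation states), and an
allele G on the reverse strand by G or A; everything else requires
identity. A read base that would match both alleles this way is treated as
uninformative — in practice the usability filter already removes every
pair where that can occur, so the branch is defensive. The strand comes
from the Bismark-style genome-conversion tag (`XG:Z:CT`/`GA`); bisulfite
mode without the tag is a hard error rather than a guess from the reverse
flag. Masked positions receive no methylation call upstream (Bismark
writes `.`), and the tagger reads only sequence and MD, so SNP positions
can never leak into methylation evidence.

Pair combination for standard paired-end data: CF in either mate, or G1
and G2 across the two mates, makes the pair conflicting; otherwise a
single genome's evidence assigns the pair; two UA mates stay UA. This
maximises assignable pairs while never mixing alleles, and is consistent
with Hi-C's mixed categories. Hi-C pairs (HiCUP-style, mates adjacent by
contract — violations are fatal) map to six unordered categories;
(G2, G1) normalises to `G1_G2` because ligation junctions have no
directionality. Conflicting reads/pairs are suppressed by default in every
mode and materialise only under the `conflicting` option; re-sorting a
tagged file with different options never re-tags.

Paired-end sorting requires name-adjacent mates; if the input is not
name-adjacent a stable name-sort is applied first (stable so equal-named
records keep their relative order). Dangling mates are routed as
singletons by their own tag, into separate `.st` files when requested.

## The simulator

`simulate_dataset` builds the whole study system from one integer seed,
with one child generator per file type (genome, VCF, reads) so adding one
artefact never perturbs another; the same seed yields byte-identical
files. It emulates: uniform-random chromosomes; a VCF containing
retainable homozygous-alt pass calls plus deliberate negatives
(heterozygous, low-confidence, indel ALTs — 10%/10%/5% of sites) and, in
dual-strain mode, strain-private, shared-different and shared-identical
sites; and reads copied from the appropriate full-sequence allele genome
with optional single indels (1–3 bp), splice gaps (50–500 bp, as one
internal N operation), uniform base errors, bisulfite conversion and
paired/Hi-C layout. MD strings are computed against the masked reference,
so masked SNP crossings appear exactly as an aligner would report them.

Defaults are the benchmark conditions: 2 chromosomes × 100 kb, candidate
variant sites at 1/300 bp (≈500 retained SNPs after the 25% negatives),
10,000 error-free 50 bp reads drawn alternately from the two alleles, each
required to cover ≥1 SNP (`snp_overlap="require"`; `"avoid"` inverts the
constraint for negative controls). Placement under `"require"` anchors a
window on a random SNP and then verifies coverage against the aligned
columns, so indel/splice reads are also guaranteed informative.

What the simulator does *not* emulate — and hence what passing tests do
not show about real data: quality-dependent error profiles, PCR
duplicates, mapping ambiguity and aligner-specific soft-clipping, real
Hi-C fragment/ligation geometry, and context-dependent methylation beyond
a flat per-CpG rate. Both mates of a simulated bisulfite pair are placed
on the same conversion strand (one shared `XG` tag), a simplification of
Bismark's four-strand read-2 chemistry; the tagger itself is per-mate and
strand-general. Allelic recovery being 100% here reflects the absence of
those artefacts, not a claim about real libraries.

## Numerical and format choices

Coordinates are 1-based closed throughout (VCF/SAM native). The SNP
annotation file is five tab-separated columns (ID, chromosome, position,
strand placeholder `1`, `allele1/allele2`), gzip-written, gzip-auto-
detected, with an optional `#genome1=…\tgenome2=…` header carrying strain
names into reports. Duplicate SNP positions are fatal at index build
(annotation corruption). IUPAC ambiguity codes other than N are collapsed
to N on FASTA read. `=`/`X` CIGAR operators are treated as M. Report
percentages are rendered to two decimals against the run's total; a report
whose counters violate their conservation law refuses to render (that is
an internal-bug signal, never user error).

## Known limitations

Streaming is single-pass and the SNP index and genome are held in memory
(a few GB for mouse-scale data); paired-end sorting loads the file into
memory to allow the name-sort fallback. No CRAM, no VCF writing, no
indexed BAM access, no InDel alleles (SNP-only keeps a common coordinate
frame). The Hi-C sorter trusts the upstream pipeline's pair ordering
rather than repairing it.
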