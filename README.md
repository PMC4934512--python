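# allelesort

Allele-specific sorting of sequencing reads aligned to N-masked genomes.

Most functional sequencing experiments on diploid organisms average the
signal from the two alleles. When the parental genotypes are known — as in
F1 crosses of inbred mouse strains — reads covering heterozygous SNPs can
instead be assigned to their allele of origin, enabling allele-specific
expression (ASE), binding (ASB) and methylation (ASM) analyses. Aligning
directly to the reference biases mapping toward the reference allele; the
approach implemented here avoids that by replacing every known SNP position
in the reference with the ambiguity base `N` (*N-masking*), so both alleles
of a read map equally well, and then recovering the base each read carries
under the masked positions.

`allelesort` covers the full workflow:

1. **Genome preparation** — filter a strain's variant calls (VCF with
   per-sample genotype `GT` and confidence flag `FI`) down to
   high-confidence homozygous single-base substitutions, and write an
   N-masked (or personalised full-sequence) genome plus a SNP annotation
   file. Single hybrids (reference × strain) and dual hybrids
   (strain 1 × strain 2, neither the reference) are supported; for dual
   hybrids the annotation is re-referenced so allele 1/allele 2 means
   strain 1/strain 2, and positions where both strains carry the same
   variant are dropped.
2. **Tagging (stage I)** — for each aligned read, recover the read offsets
   sitting on masked reference Ns *from the CIGAR and MD:Z: fields alone*
   (no reference needed), look them up in the SNP annotation and append an
   `XX:Z:` tag: `G1`/`G2` (genome-specific), `UA` (unassignable), or `CF`
   (conflicting — evidence for both genomes in one read). CIGAR operations
   M, I, D and N (splices) are handled; soft-clipped alignments are
   rejected. Bisulfite mode skips SNPs confounded with C→T (forward
   strand) or G→A (reverse strand) conversion and accepts both methylation
   states at remaining C/G-containing SNPs.
3. **Sorting (stage II)** — partition the tagged file into
   genome-specific outputs. Paired-end mates are combined (conflict wins,
   genome evidence beats UA); Hi-C pairs are kept in six symmetric
   categories (`G1_G1`, `G2_G2`, `G1_UA`, `G2_UA`, `G1_G2`, `UA_UA`).
   Conflicting reads/pairs are counted but not written unless requested.
4. **Simulation** — a deterministic generator builds a complete synthetic
   hybrid system (reference, VCF with deliberate filter negatives, masked
   genome, reads with correct CIGAR/MD and known allelic origin) so the
   whole pipeline is testable without any downloads.

## Worked example

```python
from allelesort import SimConfig, simulate_dataset, SnpIndex, tag_file, sort_single_end

res = simulate_dataset(SimConfig(seed=1, n_reads=2000, chromosome_length=50000), "demo")
index = SnpIndex.from_file(res["snp_file"])
report = tag_file(res["reads"], index, "demo/tagged.sam")
print(f"G1 {report.genome1}  G2 {report.genome2}  UA {report.unassignable}  CF {report.conflicting}")
paths, sort_report = sort_single_end("demo/tagged.sam", "demo/sorted")
print({cat: n for cat, n in sort_report.written.items()})
```

prints

```
G1 1000  G2 1000  UA 0  CF 0
{'genome1': 1000, 'genome2': 1000}
```

Every simulated read was drawn from a known allele and covers at least one
SNP, so tagging recovers the origin of all 2,000 reads (1,000 per allele)
with no conflicts, and sorting writes each read to its genome's file.

The same pipeline is available from the shell:

```bash
allelesort simulate --seed 1 --n-reads 2000 -o demo
allelesort split demo/reads.sam --snp-file demo/snps.txt.gz -o demo/out
allelesort prepare --vcf calls.vcf --reference ref.fa --strain CAST_EiJ -o genome_out
```

`examples/` contains short narrative scripts, one per capability.

## Scope

Alignment itself is upstream (Bowtie2/STAR/HISAT2/Bismark/HiCUP or any
aligner that supports `N` bases and emits MD tags). InDel-based allele
discrimination, CRAM, methylation extraction and downstream quantitation
are out of scope.
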