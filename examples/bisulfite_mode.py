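"""Allele-sort bisulfite-converted reads, respecting conversion ambiguity.

Simulates fully unmethylated Bismark-style reads (every unmethylated C
reads as T on the forward conversion strand, G as A on the reverse) and
shows how conversion-confounded SNPs are skipped while the rest remain
informative.
"""
from pathlib import Path
from tempfile import TemporaryDirectory

from allelesort import SimConfig, SnpIndex, simulate_dataset, tag_file

with TemporaryDirectory() as tmp:
    work = Path(tmp)
    res = simulate_dataset(
        SimConfig(seed=11, n_reads=1000, chromosome_length=40_000,
                  bisulfite=True, methylation_rate=0.0),
        work,
    )
    index = SnpIndex.from_file(res["snp_file"])
    report = tag_file(res["reads"], index, work / "tagged.sam")
    # bisulfite mode is auto-detected from the XG conversion tags
    print(f"bisulfite mode auto-detected: {report.bisulfite_mode}")
    print(
        f"G1={report.genome1} G2={report.genome2} "
        f"UA={report.unassignable} CF={report.conflicting}"
    )
    print(
        f"SNP positions examined: {report.snp_positions_examined}, "
        f"skipped as conversion-ambiguous: {report.bisulfite_positions_skipped}"
    )

print(
    "\nC/T SNPs on the forward strand (and G/A on the reverse) cannot be"
    "\ntold apart from conversion and are skipped, so some reads fall back"
    "\nto UA - but no read is ever assigned to the wrong allele, and zero"
    "\nconflicts arise from methylation state."
)
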