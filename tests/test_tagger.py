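"""CIGAR/MD walking, allele classification and file-level tagging."""
from __future__ import annotations

import itertools

import pysam
import pytest

from allelesort import io as asio
from allelesort.model import SnpRecord
from allelesort.simulate import SimConfig, simulate_dataset
from allelesort.tagger import (
    BaseObservation,
    MdMismatch,
    MissingMd,
    SnpIndex,
    TaggerError,
    UnsupportedCigar,
    bisulfite_match,
    bisulfite_usable,
    cigar_map,
    classify,
    masked_positions_from_md,
    observe,
    tag_file,
)
from conftest import (
    M, I, D, N, S,
    make_view,
    oracle_masked_offsets,
    read_tags,
    write_sam,
)


class TestCigarMap:
    @pytest.mark.parametrize("pos, cigar, expected", [
        (10, [(M, 5)], [(0, 10), (1, 11), (2, 12), (3, 13), (4, 14)]),
        (10, [(M, 2), (D, 2), (M, 3)],
         [(0, 10), (1, 11), (2, 14), (3, 15), (4, 16)]),
        (10, [(M, 2), (N, 3), (M, 2), (I, 2), (M, 1)],
         [(0, 10), (1, 11), (2, 15), (3, 16), (6, 17)]),
    ])
    def test_coordinate_walk(self, pos, cigar, expected):
        qlen = sum(l for op, l in cigar if op in (M, I))
        view = make_view(pos=pos, cigar=cigar, sequence="A" * qlen)
        assert cigar_map(view) == expected

    @pytest.mark.parametrize("cigar", [
        [(S, 3), (M, 5)],   # soft clip
        [(5, 2), (M, 5)],   # hard clip
        [(6, 1), (M, 5)],   # pad
    ])
    def test_clipped_or_padded_alignments_rejected(self, cigar):
        qlen = sum(l for op, l in cigar if op in (M, I, S))
        view = make_view(cigar=cigar, sequence="A" * qlen)
        with pytest.raises(UnsupportedCigar):
            cigar_map(view)

    def test_eq_and_x_operators_treated_as_match(self):
        view = make_view(pos=5, cigar=[(7, 2), (8, 1)], sequence="ACG")
        assert cigar_map(view) == [(0, 5), (1, 6), (2, 7)]

    def test_query_length_mismatch_rejected(self):
        view = make_view(cigar=[(M, 5)], sequence="ACGTACGT")
        with pytest.raises(MdMismatch):
            cigar_map(view)


class TestMaskedPositionsFromMd:
    @pytest.mark.parametrize("cigar, md, expected", [
        ([(M, 10)], "4N5", [4]),
        ([(M, 4), (I, 2), (M, 4)], "3N4", [3]),
        ([(M, 10)], "10", []),
        ([(M, 3), (D, 2), (M, 3)], "3^AC1N1", [4]),
        ([(M, 10)], "0N4N4", [0, 5]),          # leading zero run
        ([(M, 4), (I, 2), (M, 6)], "7N2", [9]),  # ref-N after the insertion
    ])
    def test_md_walk(self, cigar, md, expected):
        qlen = sum(l for op, l in cigar if op in (M, I))
        view = make_view(cigar=cigar, sequence="A" * qlen, md=md)
        assert masked_positions_from_md(view) == expected

    def test_md_absent_is_fatal(self):
        view = make_view(cigar=[(M, 4)], sequence="ACGT", md=None)
        with pytest.raises(MissingMd):
            masked_positions_from_md(view)

    @pytest.mark.parametrize("md", ["12", "3N", "4N5X5", "4!5"])
    def test_md_inconsistent_with_cigar_rejected(self, md):
        view = make_view(cigar=[(M, 10)], sequence="A" * 10, md=md)
        with pytest.raises(MdMismatch):
            masked_positions_from_md(view)


class TestClassify:
    def obs(self, verdict):
        snp = SnpRecord("s", "chr1", 1, "C", "T")
        return BaseObservation(1, "C", snp, verdict)

    def test_rule_agrees_with_brute_force_enumeration(self):
        # Independent oracle: enumerate all verdict multisets up to size 3
        # and apply the definitions verbatim — evidence for both genomes
        # conflicts; one genome's evidence assigns; nothing else assigns.
        verdicts = ["allele1", "allele2", "neither", "skipped_bisulfite"]
        for size in range(4):
            for combo in itertools.product(verdicts, repeat=size):
                a1 = combo.count("allele1")
                a2 = combo.count("allele2")
                if a1 and a2:
                    expected = "CF"
                elif a1:
                    expected = "G1"
                elif a2:
                    expected = "G2"
                else:
                    expected = "UA"
                got = classify([self.obs(v) for v in combo])
                assert got == expected, combo

    def test_no_observations_is_unassignable(self):
        assert classify([]) == "UA"


class TestBisulfiteRules:
    # Frozen usability table: C/T-type SNPs are confounded with conversion
    # on the forward strand, G/A-type on the reverse strand.
    UNUSABLE = {("C", "T"): "forward", ("T", "C"): "forward",
                ("G", "A"): "reverse", ("A", "G"): "reverse"}

    @pytest.mark.parametrize("a1, a2", [p for p in itertools.permutations("ACGT", 2)])
    @pytest.mark.parametrize("strand", ["forward", "reverse"])
    def test_usability_over_all_ordered_pairs_and_strands(self, a1, a2, strand):
        snp = SnpRecord("s", "chr1", 1, a1, a2)
        expected = self.UNUSABLE.get((a1, a2)) != strand
        assert bisulfite_usable(snp, strand) is expected

    @pytest.mark.parametrize("read, allele, strand, expected", [
        ("T", "C", "forward", True),   # unmethylated converted C
        ("C", "C", "forward", True),   # methylated C
        ("T", "C", "reverse", False),  # conversion is strand-specific
        ("A", "G", "reverse", True),
        ("G", "G", "reverse", True),
        ("A", "G", "forward", False),
        ("T", "A", "forward", False),  # non-C alleles need identity
        ("A", "A", "forward", True),
    ])
    def test_dual_state_matching(self, read, allele, strand, expected):
        assert bisulfite_match(read, allele, strand) is expected

    def test_unusable_snp_produces_skipped_verdict(self):
        index = SnpIndex([SnpRecord("s", "chr1", 15, "C", "T")])
        view = make_view(pos=11, cigar=[(M, 10)], sequence="AAAATAAAAA",
                         md="4N5", conversion_strand="CT")
        obs = observe(view, index, bisulfite=True)
        assert [o.verdict for o in obs] == ["skipped_bisulfite"]

    def test_converted_read_still_matches_c_allele_at_usable_snp(self):
        # SNP C/A on the forward strand: read T matches the C allele.
        index = SnpIndex([SnpRecord("s", "chr1", 15, "C", "A")])
        view = make_view(pos=11, cigar=[(M, 10)], sequence="AAAATAAAAA",
                         md="4N5", conversion_strand="CT")
        obs = observe(view, index, bisulfite=True)
        assert [o.verdict for o in obs] == ["allele1"]

    def test_missing_conversion_tag_in_bisulfite_mode_fatal(self):
        index = SnpIndex([SnpRecord("s", "chr1", 15, "C", "A")])
        view = make_view(pos=11, cigar=[(M, 10)], sequence="AAAATAAAAA",
                         md="4N5")
        with pytest.raises(TaggerError, match="conversion"):
            observe(view, index, bisulfite=True)


class TestObserve:
    INDEX = SnpIndex([SnpRecord("s", "chr1", 15, "C", "T")])

    @pytest.mark.parametrize("base, verdict", [
        ("T", "allele2"), ("C", "allele1"), ("G", "neither"), ("N", "neither"),
    ])
    def test_verdict_per_read_base(self, base, verdict):
        view = make_view(pos=11, cigar=[(M, 10)],
                         sequence="AAAA" + base + "AAAAA", md="4N5")
        obs = observe(view, self.INDEX)
        assert [(o.pos, o.verdict) for o in obs] == [(15, verdict)]

    def test_masked_position_unknown_to_annotation_is_ignored(self):
        view = make_view(pos=50, cigar=[(M, 10)], sequence="A" * 10, md="4N5")
        assert observe(view, self.INDEX) == []

    def test_duplicate_snp_positions_fatal_on_index_build(self):
        records = [SnpRecord("a", "chr1", 5, "C", "T"),
                   SnpRecord("b", "chr1", 5, "C", "G")]
        with pytest.raises(TaggerError, match="duplicate"):
            SnpIndex(records)

    def test_range_query_returns_exact_interval(self):
        index = SnpIndex([SnpRecord(f"s{p}", "chr1", p, "C", "T")
                          for p in (5, 10, 15, 20)])
        assert [s.pos for s in index.overlap("chr1", 10, 15)] == [10, 15]
        assert index.overlap("chr1", 21, 30) == []
        assert index.overlap("chrX", 1, 100) == []


class TestOracleEquivalence:
    def test_md_discovery_matches_padded_alignment_oracle(self, tmp_path):
        """MD-only masked-position recovery equals reference inspection.

        1,000+ randomised alignments with insertions, deletions, splices
        and base errors; the oracle sees only the masked reference and the
        CIGAR, the implementation only the MD string.
        """
        config = SimConfig(seed=11, n_reads=1200, chromosome_length=30000,
                           indel_rate=0.4, splice_rate=0.3, error_rate=0.03,
                           snp_overlap="any", snp_density=1 / 150)
        res = simulate_dataset(config, tmp_path)
        masked = res["masked_genome"]
        n_checked = 0
        for view in asio.alignments(res["reads"]):
            expected = oracle_masked_offsets(masked[view.chrom], view.pos,
                                             view.cigar)
            assert masked_positions_from_md(view) == expected
            n_checked += 1
        assert n_checked >= 1000


class TestTagFile:
    def make_fixture(self, tmp_path, names=("r1", "r2", "r3", "r4", "r5", "r6")):
        # chr1 SNPs at 15 (C/T) and 35 (G/A); read windows hand-placed.
        index = SnpIndex([SnpRecord("a", "chr1", 15, "C", "T"),
                          SnpRecord("b", "chr1", 35, "G", "A")])
        recs = [
            # two G1 reads (allele-1 bases C / G at the SNPs)
            {"name": names[0], "pos": 11, "cigar": [(M, 10)],
             "seq": "AAAACAAAAA", "md": "4N5"},
            {"name": names[1], "pos": 31, "cigar": [(M, 10)],
             "seq": "AAAAGAAAAA", "md": "4N5"},
            # two G2 reads
            {"name": names[2], "pos": 11, "cigar": [(M, 10)],
             "seq": "AAAATAAAAA", "md": "4N5"},
            {"name": names[3], "pos": 31, "cigar": [(M, 10)],
             "seq": "AAAAAAAAAA", "md": "4N5"},
            # no SNP overlap
            {"name": names[4], "pos": 50, "cigar": [(M, 10)],
             "seq": "AAAAAAAAAA", "md": "10"},
            # spans both SNPs with opposite-allele bases -> conflicting
            {"name": names[5], "pos": 11, "cigar": [(M, 30)],
             "seq": "AAAACAAAAAAAAAAAAAAAAAAAAAAAA" + "A", "md": "4N19N5"},
        ]
        path = write_sam(tmp_path / "in.sam", recs)
        return path, index

    def test_known_truth_fixture_counts(self, tmp_path):
        path, index = self.make_fixture(tmp_path)
        report = tag_file(path, index, tmp_path / "out.sam")
        assert (report.genome1, report.genome2,
                report.unassignable, report.conflicting) == (2, 2, 1, 1)
        report.check()
        assert report.reads_seen == 6

    def test_output_preserves_input_order(self, tmp_path):
        names = ("r3", "r1", "r2", "r6", "r5", "r4")
        path, index = self.make_fixture(tmp_path, names=names)
        tag_file(path, index, tmp_path / "out.sam")
        assert [n for n, _ in read_tags(tmp_path / "out.sam")] == list(names)

    def test_every_output_record_carries_exactly_one_tag(self, tmp_path):
        path, index = self.make_fixture(tmp_path)
        tag_file(path, index, tmp_path / "out.sam")
        for _, tag in read_tags(tmp_path / "out.sam"):
            assert tag in ("UA", "G1", "G2", "CF")

    def test_unmapped_and_clipped_reads_emitted_ua_and_counted(self, tmp_path):
        index = SnpIndex([SnpRecord("a", "chr1", 15, "C", "T")])
        recs = [
            {"name": "u1", "flag": 0x4, "seq": "ACGT"},
            {"name": "c1", "pos": 11, "cigar": [(S, 2), (M, 8)],
             "seq": "AAAACAAAAA", "md": "8"},
        ]
        path = write_sam(tmp_path / "in.sam", recs)
        report = tag_file(path, index, tmp_path / "out.sam")
        assert report.unmapped_skipped == 1
        assert report.cigar_unsupported == 1
        assert [t for _, t in read_tags(tmp_path / "out.sam")] == ["UA", "UA"]
        report.check()

    def test_missing_md_is_fatal_for_the_run(self, tmp_path):
        index = SnpIndex([SnpRecord("a", "chr1", 15, "C", "T")])
        path = write_sam(tmp_path / "in.sam",
                         [{"name": "r", "pos": 11, "cigar": [(M, 4)],
                           "seq": "ACGT"}])
        with pytest.raises(MissingMd):
            tag_file(path, index, tmp_path / "out.sam")

    def test_bismark_style_input_autodetected(self, tmp_path):
        index = SnpIndex([SnpRecord("a", "chr1", 15, "C", "T")])
        path = write_sam(tmp_path / "in.sam",
                         [{"name": "r", "pos": 11, "cigar": [(M, 10)],
                           "seq": "AAAATAAAAA", "md": "4N5",
                           "tags": [("XG", "CT")]}])
        report = tag_file(path, index, tmp_path / "out.sam")
        assert report.bisulfite_mode
        # the C/T SNP is confounded on the forward strand -> skipped, UA
        assert report.bisulfite_positions_skipped == 1
        assert report.unassignable == 1

    def test_empty_input_warns_and_writes_empty_output(self, tmp_path):
        index = SnpIndex([SnpRecord("a", "chr1", 15, "C", "T")])
        path = write_sam(tmp_path / "in.sam", [])
        report = tag_file(path, index, tmp_path / "out.sam")
        assert report.reads_seen == 0
        assert read_tags(tmp_path / "out.sam") == []

    def test_empty_snp_index_rejected(self, tmp_path):
        path = write_sam(tmp_path / "in.sam", [])
        with pytest.raises(TaggerError, match="empty"):
            tag_file(path, SnpIndex([]), tmp_path / "out.sam")
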