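"""Plain-text report rendering: stable key/value lines with percentages."""
from __future__ import annotations

from pathlib import Path

from .model import (
    AlleleSortError,
    DualHybridSummary,
    FilterSummary,
    MaskReport,
    SortReport,
    TagReport,
)


class ReportError(AlleleSortError):
    pass


def _pct(value: int, total: int) -> str:
    if total <= 0:
        return "0.00%"
    return f"{100.0 * value / total:.2f}%"


def _counter_lines(rows, total: int) -> list:
    return [f"{key}: {value} ({_pct(value, total)})" for key, value in rows]


def _tag_rows(r: TagReport):
    return [
        ("reads_seen", r.reads_seen),
        ("unassignable", r.unassignable),
        ("genome1", r.genome1),
        ("genome2", r.genome2),
        ("conflicting", r.conflicting),
        ("unmapped_skipped", r.unmapped_skipped),
        ("cigar_unsupported", r.cigar_unsupported),
    ]


def _filter_rows(r: FilterSummary):
    return [
        ("total_seen", r.total_seen),
        ("retained", r.retained),
        ("skipped_low_confidence", r.skipped_low_confidence),
        ("skipped_heterozygous", r.skipped_heterozygous),
        ("skipped_homozygous_ref", r.skipped_homozygous_ref),
        ("skipped_not_snp", r.skipped_not_snp),
        ("skipped_ref_mismatch", r.skipped_ref_mismatch),
        ("skipped_missing_genotype", r.skipped_missing_genotype),
    ]


def render_lines(report, genome_names=None) -> list:
    """Render any report object to machine-parsable key/value lines.

    Raises :class:`ReportError` if the report's conservation invariant is
    violated (that indicates an internal bug, never bad user input).
    """
    try:
        report.check()
    except AlleleSortError as exc:
        raise ReportError(str(exc)) from exc
    if isinstance(report, TagReport):
        lines = _counter_lines(_tag_rows(report)[1:], report.reads_seen)
        lines.insert(0, f"reads_seen: {report.reads_seen}")
        lines.append(f"snp_positions_examined: {report.snp_positions_examined}")
        lines.append(
            f"bisulfite_positions_skipped: {report.bisulfite_positions_skipped}"
        )
        lines.append(
            f"neither_allele_basecalls: {report.neither_allele_basecalls}"
        )
        lines.append(f"bisulfite_mode: {str(report.bisulfite_mode).lower()}")
        lines.append(f"paired_mode: {str(report.paired_mode).lower()}")
    elif isinstance(report, FilterSummary):
        lines = _counter_lines(_filter_rows(report)[1:], report.total_seen)
        lines.insert(0, f"total_seen: {report.total_seen}")
    elif isinstance(report, SortReport):
        lines = [
            f"reads_seen: {report.reads_seen}",
            f"pairs_seen: {report.pairs_seen}",
            f"singletons_seen: {report.singletons_seen}",
        ]
        for cat in sorted(report.written):
            lines.append(
                f"written_{cat}: {report.written[cat]} "
                f"({_pct(report.written[cat], report.reads_seen)})"
            )
        lines.append(
            f"conflicting_suppressed: {report.conflicting_suppressed} "
            f"({_pct(report.conflicting_suppressed, report.reads_seen)})"
        )
    elif isinstance(report, MaskReport):
        lines = [f"total_masked: {report.total}"]
        for chrom in sorted(report.per_chrom):
            lines.append(f"masked_{chrom}: {report.per_chrom[chrom]}")
        lines.append(f"genome_base_disagreements: {len(report.disagreements)}")
    elif isinstance(report, DualHybridSummary):
        lines = _counter_lines(
            [
                ("retained", report.retained),
                ("strain1_only", report.strain1_only),
                ("strain2_only", report.strain2_only),
                ("shared_different", report.shared_different),
                ("shared_identical_excluded", report.shared_identical_excluded),
            ],
            report.total_seen,
        )
        lines.insert(0, f"total_seen: {report.total_seen}")
    else:
        raise ReportError(f"cannot render report of type {type(report).__name__}")
    if genome_names:
        lines.insert(0, f"genome2_name: {genome_names[1]}")
        lines.insert(0, f"genome1_name: {genome_names[0]}")
    return lines


def render_report(report, path, title: str = "", genome_names=None) -> Path:
    """Write a report to a text file, one counter per line."""
    path = Path(path)
    lines = render_lines(report, genome_names=genome_names)
    with open(path, "w") as out:
        if title:
            out.write(f"# {title}\n")
        out.write("\n".join(lines) + "\n")
    return path


def render_dual_report(
    summary1: FilterSummary,
    summary2: FilterSummary,
    dual: DualHybridSummary,
    path,
    strain1: str,
    strain2: str,
) -> Path:
    """Combined filtering + comparison report for a dual-hybrid run."""
    path = Path(path)
    with open(path, "w") as out:
        out.write(f"# SNP filtering: {strain1}\n")
        out.write("\n".join(render_lines(summary1)) + "\n")
        out.write(f"# SNP filtering: {strain2}\n")
        out.write("\n".join(render_lines(summary2)) + "\n")
        out.write(f"# Dual-hybrid annotation ({strain1} vs {strain2})\n")
        out.write("\n".join(render_lines(dual)) + "\n")
    return path
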