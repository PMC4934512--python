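"""Stage II: partition a tagged alignment file into allele-specific outputs.

Single-end records are routed straight by their ``XX:Z:`` tag.  For
paired-end input the two mates' tags are combined: conflicting evidence in
either mate, or opposite-genome evidence across the pair, makes the pair
conflicting; otherwise any genome-specific evidence wins over UA.
Conflicting reads and pairs are suppressed (counted but not written) unless
explicitly enabled.  Hi-C input keeps the pair structure in six symmetric
categories (G1-G1, G2-G2, G1-UA, G2-UA, G1-G2, UA-UA) because ligation
junctions have no directionality.
"""
from __future__ import annotations

import logging
from pathlib import Path

import pysam

from . import io as asio
from .model import AlleleSortError, SortReport

log = logging.getLogger(__name__)

_TAGS = ("UA", "G1", "G2", "CF")

#: Canonical tag order used to normalise unordered Hi-C pairs.
_HIC_ORDER = {"G1": 0, "G2": 1, "UA": 2}

HIC_CATEGORIES = ("G1_G1", "G1_G2", "G1_UA", "G2_G2", "G2_UA", "UA_UA")


class SorterError(AlleleSortError):
    pass


def _tag_of(rec) -> str:
    if not rec.has_tag("XX"):
        raise SorterError(
            f"record {rec.query_name!r} carries no XX:Z: tag; the file was "
            "not tagged (run the tagging stage first)"
        )
    tag = rec.get_tag("XX")
    if tag not in _TAGS:
        raise SorterError(f"record {rec.query_name!r} has invalid tag {tag!r}")
    return tag


def combine_pair_tags(tag1: str, tag2: str) -> str:
    """Combine the two mates' tags into a pair category.

    Symmetric in its arguments.  CF is absorbing; evidence for both
    genomes across the pair is conflicting; genome evidence beats UA.
    """
    tags = {tag1, tag2}
    if "CF" in tags or {"G1", "G2"} <= tags:
        return "CF"
    if "G1" in tags:
        return "G1"
    if "G2" in tags:
        return "G2"
    return "UA"


def classify_hic_pair(tag1: str, tag2: str) -> str:
    """Map an unordered Hi-C mate-tag pair to its category.

    Mixed-genome categories are reported once (G2,G1 normalises to
    G1_G2); pairs containing a conflicting mate map to "conflicting".
    """
    if tag1 == "CF" or tag2 == "CF":
        return "conflicting"
    a, b = sorted((tag1, tag2), key=_HIC_ORDER.__getitem__)
    return f"{a}_{b}"


def _out_path(input_path, out_dir, category: str) -> Path:
    p = Path(input_path)
    out_dir = Path(out_dir) if out_dir else p.parent
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".bam" if p.suffix == ".bam" else ".sam"
    stem = p.name[: -len(p.suffix)] if p.suffix else p.name
    return out_dir / f"{stem}.{category}{ext}"


class _Sinks:
    """Lazily-opened category writers sharing the input header."""

    def __init__(self, input_path, out_dir, template):
        self._input_path = input_path
        self._out_dir = out_dir
        self._template = template
        self._open: dict = {}
        self.paths: dict = {}

    def ensure(self, category: str) -> None:
        if category not in self._open:
            path = _out_path(self._input_path, self._out_dir, category)
            self._open[category] = asio.open_alignment_writer(
                path, template=self._template
            )
            self.paths[category] = path

    def write(self, category: str, *recs) -> int:
        self.ensure(category)
        for rec in recs:
            self._open[category].write(rec)
        return len(recs)

    def close(self) -> None:
        for fh in self._open.values():
            fh.close()


_CATEGORY_FILE = {"G1": "genome1", "G2": "genome2", "UA": "unassigned", "CF": "conflicting"}


def sort_single_end(
    input_path,
    out_dir=None,
    conflicting: bool = False,
) -> tuple:
    """Route single-end records into genome1/genome2/unassigned files.

    Conflicting reads are suppressed (counted only) unless ``conflicting``
    is set.  Returns ``({category: path}, SortReport)``.
    """
    report = SortReport()
    infile = asio.open_alignments(input_path)
    sinks = _Sinks(input_path, out_dir, infile)
    for cat in ("genome1", "genome2", "unassigned"):
        sinks.ensure(cat)
    if conflicting:
        sinks.ensure("conflicting")
    try:
        with infile:
            for rec in infile:
                report.reads_seen += 1
                tag = _tag_of(rec)
                if tag == "CF" and not conflicting:
                    report.conflicting_suppressed += 1
                    continue
                cat = _CATEGORY_FILE[tag]
                n = sinks.write(cat, rec)
                report.written[cat] = report.written.get(cat, 0) + n
    finally:
        sinks.close()
    report.check()
    return sinks.paths, report


def _load_tagged(input_path) -> tuple:
    infile = asio.open_alignments(input_path)
    with infile:
        header = infile.header
        records = [(rec, _tag_of(rec)) for rec in infile]
    return records, header


def _pair_up(records) -> tuple:
    """Group name-adjacent records into pairs; leftovers are singletons."""
    pairs, singletons = [], []
    i = 0
    n = len(records)
    while i < n:
        rec, tag = records[i]
        if (
            i + 1 < n
            and rec.is_paired
            and records[i + 1][0].is_paired
            and records[i + 1][0].query_name == rec.query_name
        ):
            pairs.append((records[i], records[i + 1]))
            i += 2
        else:
            singletons.append(records[i])
            i += 1
    return pairs, singletons


def _is_name_adjacent(records) -> bool:
    paired = [r for r, _ in records if r.is_paired]
    for i in range(0, len(paired) - 1, 2):
        if paired[i].query_name != paired[i + 1].query_name:
            return False
    return True


def sort_paired_end(
    input_path,
    out_dir=None,
    singletons: bool = False,
    conflicting: bool = False,
) -> tuple:
    """Route read pairs by the combination of both mates' tags.

    Mates are expected name-adjacent; if they are not, the records are
    stably name-sorted first (and this is logged).  Both mates of a pair
    are written to the same file.  Mate-less records are routed by their
    own tag — into separate ``.st`` outputs when ``singletons`` is set,
    else into the main files.
    """
    records, _header = _load_tagged(input_path)
    infile = asio.open_alignments(input_path)  # template for writers
    if not _is_name_adjacent(records):
        log.info("mates not adjacent in %s: name-sorting first", input_path)
        records.sort(key=lambda item: item[0].query_name)
    pairs, single = _pair_up(records)
    report = SortReport()
    report.reads_seen = len(records)
    report.pairs_seen = len(pairs)
    report.singletons_seen = len(single)
    sinks = _Sinks(input_path, out_dir, infile)
    for cat in ("genome1", "genome2", "unassigned"):
        sinks.ensure(cat)
    if conflicting:
        sinks.ensure("conflicting")
    try:
        for (rec1, tag1), (rec2, tag2) in pairs:
            combined = combine_pair_tags(tag1, tag2)
            if combined == "CF" and not conflicting:
                report.conflicting_suppressed += 2
                continue
            cat = _CATEGORY_FILE[combined]
            n = sinks.write(cat, rec1, rec2)
            report.written[cat] = report.written.get(cat, 0) + n
        for rec, tag in single:
            if rec.is_paired:
                log.warning("dangling mate %r treated as singleton", rec.query_name)
            if tag == "CF" and not conflicting:
                report.conflicting_suppressed += 1
                continue
            cat = _CATEGORY_FILE[tag]
            if singletons:
                cat = f"{cat}.st"
            n = sinks.write(cat, rec)
            report.written[cat] = report.written.get(cat, 0) + n
    finally:
        sinks.close()
        infile.close()
    report.check()
    return sinks.paths, report


def sort_hic(
    input_path,
    out_dir=None,
    conflicting: bool = False,
) -> tuple:
    """Route Hi-C pairs into the six symmetric allele categories.

    Hi-C input is paired by definition with read 1 and read 2 adjacent;
    anything else violates the format contract and is fatal.  Pairs with a
    conflicting mate are suppressed unless ``conflicting`` is set.
    """
    records, _header = _load_tagged(input_path)
    infile = asio.open_alignments(input_path)
    report = SortReport()
    report.reads_seen = len(records)
    if len(records) % 2 != 0:
        infile.close()
        raise SorterError("Hi-C input has an odd number of records")
    sinks = _Sinks(input_path, out_dir, infile)
    for cat in HIC_CATEGORIES:
        sinks.ensure(cat)
    if conflicting:
        sinks.ensure("conflicting")
    try:
        for i in range(0, len(records), 2):
            (rec1, tag1), (rec2, tag2) = records[i], records[i + 1]
            if not (rec1.is_paired and rec2.is_paired):
                raise SorterError(
                    f"unpaired record {rec1.query_name!r} in Hi-C mode"
                )
            if rec1.query_name != rec2.query_name:
                raise SorterError(
                    f"Hi-C mates not adjacent: {rec1.query_name!r} followed "
                    f"by {rec2.query_name!r}"
                )
            report.pairs_seen += 1
            cat = classify_hic_pair(tag1, tag2)
            if cat == "conflicting" and not conflicting:
                report.conflicting_suppressed += 2
                continue
            n = sinks.write(cat, rec1, rec2)
            report.written[cat] = report.written.get(cat, 0) + n
    finally:
        sinks.close()
        infile.close()
    report.check()
    return sinks.paths, report


def resort(input_path, out_dir=None, mode: str = "single", **options) -> tuple:
    """Re-run sorting on an already-tagged file with different options.

    No re-tagging is performed; the outcome is identical to sorting the
    original tagged output with the new options.
    """
    if mode == "single":
        return sort_single_end(input_path, out_dir, **options)
    if mode == "paired":
        return sort_paired_end(input_path, out_dir, **options)
    if mode == "hic":
        return sort_hic(input_path, out_dir, **options)
    raise ValueError(f"unknown sort mode {mode!r}")
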