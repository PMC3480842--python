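"""Reading aligned-read BED files and writing peak calls.

Input reads are BED6 (0-based half-open, strand in column 6); anything past
column 6 is ignored so BED6+ exports work unchanged.  Peak output comes in
two flavours: a tab-delimited table with 1-based inclusive coordinates
(columns CHR, START, END, PEAK.LOC, PEAK.NLP, FORM, LAG, ER) and standard
BED6 with the peak score in the score column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "ReadAlignment",
    "BedParseError",
    "read_bed_reads",
    "group_reads",
    "read_chrom_sizes",
    "write_reads_bed",
    "write_peaks",
    "read_peak_table",
    "write_run_metadata",
]

FORWARD = "+"
REVERSE = "-"
STRANDS = (FORWARD, REVERSE)

PEAK_TABLE_COLUMNS = ("CHR", "START", "END", "PEAK.LOC", "PEAK.NLP",
                      "FORM", "LAG", "ER")


@dataclass(frozen=True, slots=True)
class ReadAlignment:
    """One aligned read in BED-native coordinates.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive, and
    ``strand`` is ``"+"`` or ``"-"``.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"read interval must be non-empty: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


class BedParseError(ValueError):
    """A malformed line in a BED input, with its 1-based line number."""

    def __init__(self, path, lineno, message):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


_HEADER_PREFIXES = ("track", "browser", "#")


def read_bed_reads(path) -> list[ReadAlignment]:
    """Read aligned reads from a BED6(+) file.

    Returns records grouped by (chromosome, strand) and sorted by start
    within each group.  An empty file yields an empty list.  Malformed
    coordinates, empty intervals or unknown strand codes raise
    :class:`BedParseError` naming the offending line.
    """
    reads: list[ReadAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_HEADER_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedParseError(
                    path, lineno,
                    f"expected >= 6 tab-separated fields, got {len(fields)}")
            chrom, s, e = fields[0], fields[1], fields[2]
            strand = fields[5]
            try:
                start, end = int(s), int(e)
            except ValueError:
                raise BedParseError(
                    path, lineno, f"non-integer coordinates {s!r}, {e!r}") from None
            if start >= end:
                raise BedParseError(path, lineno,
                                    f"start {start} >= end {end}")
            if strand not in STRANDS:
                raise BedParseError(path, lineno,
                                    f"unknown strand code {strand!r}")
            reads.append(ReadAlignment(chrom, start, end, strand))
    reads.sort(key=lambda r: (r.chrom, r.strand, r.start, r.end))
    return reads


def group_reads(reads: Iterable[ReadAlignment]):
    """Group reads into a dict keyed by (chrom, strand), start-sorted."""
    groups: dict[tuple[str, str], list[ReadAlignment]] = {}
    for read in reads:
        groups.setdefault((read.chrom, read.strand), []).append(read)
    for grp in groups.values():
        grp.sort(key=lambda r: (r.start, r.end))
    return groups


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column whitespace-separated chromosome-sizes file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            chrom = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer length {fields[1]!r}") from None
            if length <= 0:
                raise ValueError(
                    f"{path}:{lineno}: non-positive length {length} for {chrom}")
            if chrom in sizes:
                raise ValueError(
                    f"{path}:{lineno}: duplicate chromosome {chrom!r}")
            sizes[chrom] = length
    return sizes


def write_reads_bed(reads: Iterable[ReadAlignment], path, name_prefix="r"):
    """Write reads as BED6 (name = prefix + index, score 0)."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"{read.chrom}\t{read.start}\t{read.end}"
                     f"\t{name_prefix}{i}\t0\t{read.strand}\n")


def _peak_sort_key(peak):
    return (-peak.peak_nlp, peak.chrom, peak.start)


def write_peaks(peaks, path, format="table"):
    """Write peak calls sorted by descending PEAK.NLP.

    ``format="table"``: tab-delimited with header, 1-based inclusive
    START/END, floats at 6 significant digits.  ``format="bed"``: BED6 with
    0-based half-open coordinates, the form label as name and PEAK.NLP in
    the score column.
    """
    peaks = sorted(peaks, key=_peak_sort_key)
    with open(path, "w") as fh:
        if format == "table":
            fh.write("\t".join(PEAK_TABLE_COLUMNS) + "\n")
            for p in peaks:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_loc}"
                         f"\t{p.peak_nlp:.6g}\t{p.form}\t{p.lag}"
                         f"\t{p.er:.6g}\n")
        elif format == "bed":
            for p in peaks:
                fh.write(f"{p.chrom}\t{p.start - 1}\t{p.end}"
                         f"\tform{p.form}\t{p.peak_nlp:.6g}\t.\n")
        else:
            raise ValueError(f"unknown peak output format {format!r}")


def read_peak_table(path):
    """Parse a peak table written by :func:`write_peaks` back into calls."""
    from .detect import PeakCall  # local import avoids a module cycle

    peaks = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PEAK_TABLE_COLUMNS:
            raise ValueError(f"unexpected peak table header {header}")
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, loc, nlp, form, lag, er = line.rstrip("\n").split("\t")
            peaks.append(PeakCall(
                chrom=chrom, start=int(start), end=int(end),
                peak_loc=int(loc), peak_nlp=float(nlp), form=int(form),
                lag=int(lag), er=float(er)))
    return peaks


def write_run_metadata(path, metadata: Mapping):
    """Dump the run-metadata block (parameters, r, min.er, stage counts)."""
    Path(path).write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")
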