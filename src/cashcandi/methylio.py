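"""Readers and writers for methylation count tables, read-level calls and regions.

All *internal* coordinates are 1-based inclusive: a region ``chr6:391824-393789``
has length ``393789 - 391824 + 1 = 1966``.  On-disk BED is the usual 0-based
half-open convention; :func:`read_bed` / :func:`write_bed` translate.

Three input dialects are supported:

* cytosine reports -- per-CpG TSV with columns
  ``chrom  pos  strand  count_methylated  count_unmethylated  context``
  (the style emitted by common bisulfite/EM-seq extractors); only CpG-context
  rows are retained;
* SAM/BAM with per-base methylation call strings in the ``XM`` tag
  (``Z`` = methylated CpG, ``z`` = unmethylated CpG, other symbols ignored);
* a plain-text read dialect (``chrom  start  end  calls  offsets``) so the
  whole pipeline is testable without binary alignments -- see README for a
  worked example.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Sequence, Union

import pandas as pd

__all__ = [
    "ParseError",
    "GenomicRegion",
    "MethRead",
    "parse_cytosine_report",
    "write_cytosine_report",
    "collapse_strands",
    "read_bed",
    "write_bed",
    "parse_read_calls",
    "write_read_calls",
]

#: column order of a parsed cytosine-report count table
COUNT_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth"]

#: contexts accepted as a CpG row in a cytosine report
_CPG_CONTEXTS = {"CpG", "CG"}


class ParseError(ValueError):
    """Malformed input; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True, slots=True)
class GenomicRegion:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(
                f"start > end ({self.chrom}:{self.start}-{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, start: int, end: int) -> bool:
        """True when [start, end] lies completely inside this region."""
        return self.start <= start and end <= self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(slots=True)
class MethRead:
    """One aligned read (or mate) with its ordered per-CpG methylation calls.

    ``cpg_calls`` is a tuple of ``(pos, methylated)`` pairs, strictly
    increasing in ``pos``; every position lies within the aligned span.
    Mates of a pair are independent MethReads.
    """

    chrom: str
    start: int
    end: int
    sample_id: str = ""
    cpg_calls: tuple[tuple[int, bool], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"read start {self.start} > end {self.end}")
        prev = self.start - 1
        for pos, _ in self.cpg_calls:
            if pos <= prev:
                raise ValueError(
                    f"CpG call positions must be strictly increasing and "
                    f"within [{self.start}, {self.end}]"
                )
            prev = pos
        if prev > self.end:
            raise ValueError(
                f"CpG call at {prev} outside aligned span "
                f"[{self.start}, {self.end}]"
            )

    @property
    def n_calls(self) -> int:
        return len(self.cpg_calls)

    @property
    def n_methylated(self) -> int:
        return sum(1 for _, m in self.cpg_calls if m)


# ---------------------------------------------------------------------------
# cytosine report I/O
# ---------------------------------------------------------------------------


def _lines(stream: Union[str, IO[str], Iterable[str]]) -> Iterator[str]:
    if isinstance(stream, str):
        with open(stream) as fh:
            yield from fh
    else:
        yield from stream


def parse_cytosine_report(
    stream: Union[str, IO[str], Iterable[str]], sample_id: str = ""
) -> pd.DataFrame:
    """Parse a cytosine-report TSV into a per-CpG count table.

    Parameters
    ----------
    stream
        Path, open text handle, or iterable of lines.  Each data line has six
        tab-separated fields: chrom, 1-based pos, strand (``+``/``-``),
        methylated count, unmethylated count, context.  Rows whose context is
        not CpG are skipped.
    sample_id
        Recorded in ``DataFrame.attrs['sample_id']``.

    Returns
    -------
    pandas.DataFrame
        Columns ``chrom, pos, strand, meth, unmeth``; one row per CpG-context
        input row, positions preserved verbatim.

    Raises
    ------
    ParseError
        On a malformed line (wrong column count, non-integer or negative
        counts, pos < 1, bad strand), naming the line number.
    """
    rows = []
    for lineno, raw in enumerate(_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ParseError(
                f"expected 6 tab-separated fields, got {len(parts)}", lineno
            )
        chrom, pos_s, strand, meth_s, unmeth_s, context = parts
        if context not in _CPG_CONTEXTS:
            continue
        if strand not in ("+", "-"):
            raise ParseError(f"bad strand {strand!r}", lineno)
        try:
            pos = int(pos_s)
            meth = int(meth_s)
            unmeth = int(unmeth_s)
        except ValueError:
            raise ParseError(
                f"non-integer position or count in {parts[1:5]!r}", lineno
            ) from None
        if pos < 1:
            raise ParseError(f"position must be >= 1, got {pos}", lineno)
        if meth < 0 or unmeth < 0:
            raise ParseError(
                f"negative count ({meth}, {unmeth})", lineno
            )
        rows.append((chrom, pos, strand, meth, unmeth))
    table = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    table.attrs["sample_id"] = sample_id
    return table


def write_cytosine_report(table: pd.DataFrame, stream: Union[str, IO[str]]) -> None:
    """Write a count table back to 6-column cytosine-report TSV (context CpG)."""
    close = False
    if isinstance(stream, str):
        stream = open(stream, "w")
        close = True
    try:
        strand = table["strand"] if "strand" in table.columns else None
        for i, row in enumerate(table.itertuples(index=False)):
            s = strand.iloc[i] if strand is not None else "+"
            stream.write(
                f"{row.chrom}\t{row.pos}\t{s}\t{row.meth}\t{row.unmeth}\tCpG\n"
            )
    finally:
        if close:
            stream.close()


def collapse_strands(table: pd.DataFrame) -> pd.DataFrame:
    """Sum plus- and minus-strand counts onto the plus-strand C position.

    The minus-strand C of a CpG dinucleotide sits one base downstream of the
    plus-strand C, so a ``-`` row at pos ``p`` is folded onto ``p - 1``.
    Chromosomes are never merged.  Output has unique ``(chrom, pos)`` and no
    strand column; total methylated/unmethylated counts are conserved.
    """
    if table.empty:
        return pd.DataFrame(columns=["chrom", "pos", "meth", "unmeth"])
    work = table[["chrom", "pos", "meth", "unmeth"]].copy()
    if "strand" in table.columns:
        minus = (table["strand"] == "-").to_numpy()
        work.loc[minus, "pos"] = work.loc[minus, "pos"] - 1
    out = (
        work.groupby(["chrom", "pos"], as_index=False, sort=True)[["meth", "unmeth"]]
        .sum()
    )
    out.attrs["sample_id"] = table.attrs.get("sample_id", "")
    return out


# ---------------------------------------------------------------------------
# BED I/O  (0-based half-open on disk <-> 1-based inclusive internally)
# ---------------------------------------------------------------------------


def read_bed(stream: Union[str, IO[str], Iterable[str]]) -> list[GenomicRegion]:
    """Read BED3(+) into internal 1-based inclusive regions."""
    regions = []
    for lineno, raw in enumerate(_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError("BED line needs at least 3 fields", lineno)
        chrom = parts[0]
        try:
            start0 = int(parts[1])
            end0 = int(parts[2])
        except ValueError:
            raise ParseError(f"non-integer BED coordinates {parts[1:3]!r}", lineno) from None
        if start0 < 0:
            raise ParseError(f"negative BED start {start0}", lineno)
        if start0 >= end0:
            raise ParseError(
                f"BED start {start0} >= end {end0} (empty interval)", lineno
            )
        regions.append(GenomicRegion(chrom, start0 + 1, end0))
    return regions


def write_bed(
    regions: Sequence[GenomicRegion], stream: Union[str, IO[str]], names: Sequence[str] | None = None
) -> None:
    """Write internal regions as BED3 (or BED4 when ``names`` is given)."""
    close = False
    if isinstance(stream, str):
        stream = open(stream, "w")
        close = True
    try:
        for i, r in enumerate(regions):
            line = f"{r.chrom}\t{r.start - 1}\t{r.end}"
            if names is not None:
                line += f"\t{names[i]}"
            stream.write(line + "\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# read-call I/O
# ---------------------------------------------------------------------------


def _parse_tsv_reads(
    stream: Union[str, IO[str], Iterable[str]], sample_id: str
) -> list[MethRead]:
    reads = []
    for lineno, raw in enumerate(_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ParseError(
                f"read line needs 5 tab-separated fields, got {len(parts)}", lineno
            )
        chrom, start_s, end_s, calls_s, offsets_s = parts
        try:
            start = int(start_s)
            end = int(end_s)
        except ValueError:
            raise ParseError(f"non-integer read span {parts[1:3]!r}", lineno) from None
        if calls_s == ".":
            calls: tuple[tuple[int, bool], ...] = ()
        else:
            try:
                offsets = [int(o) for o in offsets_s.split(",")]
            except ValueError:
                raise ParseError(f"bad offsets {offsets_s!r}", lineno) from None
            if len(offsets) != len(calls_s):
                raise ParseError(
                    f"{len(calls_s)} calls but {len(offsets)} offsets", lineno
                )
            if any(c not in "Mu" for c in calls_s):
                raise ParseError(f"call string must be M/u, got {calls_s!r}", lineno)
            calls = tuple((start + o, c == "M") for o, c in zip(offsets, calls_s))
        try:
            reads.append(MethRead(chrom, start, end, sample_id, calls))
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from None
    return reads


def _parse_sam_reads(path: str, sample_id: str) -> list[MethRead]:
    import pysam

    reads = []
    with pysam.AlignmentFile(path, check_sq=False) as af:
        for aln in af:
            if aln.is_unmapped or aln.reference_name is None:
                continue
            try:
                xm = aln.get_tag("XM")
            except KeyError:
                continue
            calls = []
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                c = xm[qpos]
                if c == "Z":
                    calls.append((rpos + 1, True))
                elif c == "z":
                    calls.append((rpos + 1, False))
            calls.sort(key=lambda t: t[0])
            start = aln.reference_start + 1
            end = aln.reference_end  # pysam end is exclusive 0-based == inclusive 1-based
            reads.append(
                MethRead(aln.reference_name, start, end, sample_id, tuple(calls))
            )
    return reads


def parse_read_calls(
    stream: Union[str, IO[str], Iterable[str]],
    dialect: str = "tsv",
    sample_id: str = "",
) -> list[MethRead]:
    """Parse aligned reads carrying per-CpG methylation calls.

    ``dialect='tsv'`` reads the plain-text dialect
    (``chrom  start  end  calls  offsets``; calls a string of ``M``/``u``,
    offsets comma-separated 0-based distances from ``start``; ``.  .`` for a
    read without CpG calls).  ``dialect='sam'`` reads SAM/BAM with XM-style
    call strings via pysam (``stream`` must then be a path).
    """
    if dialect == "tsv":
        return _parse_tsv_reads(stream, sample_id)
    if dialect in ("sam", "bam"):
        if not isinstance(stream, str):
            raise ValueError("SAM/BAM parsing requires a file path")
        return _parse_sam_reads(stream, sample_id)
    raise ValueError(f"unknown read dialect {dialect!r}")


def write_read_calls(reads: Iterable[MethRead], stream: Union[str, IO[str]]) -> None:
    """Serialize reads to the plain-text dialect (lossless round trip)."""
    close = False
    if isinstance(stream, str):
        stream = open(stream, "w")
        close = True
    try:
        for r in reads:
            if r.cpg_calls:
                calls = "".join("M" if m else "u" for _, m in r.cpg_calls)
                offsets = ",".join(str(p - r.start) for p, _ in r.cpg_calls)
            else:
                calls = offsets = "."
            stream.write(f"{r.chrom}\t{r.start}\t{r.end}\t{calls}\t{offsets}\n")
    finally:
        if close:
            stream.close()
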