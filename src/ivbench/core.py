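"""Core interval types and BED input/output.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  Two intervals overlap iff they share at least one base,
which means book-ended (touching) intervals do *not* overlap — the property
that makes gap-derived queries return empty results by construction.
Strand is ignored everywhere.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

#: Hard ceiling on any coordinate: chromosomes never exceed two billion bases.
MAX_COORD = 2_000_000_000


class BedParseError(ValueError):
    """Raised when a BED line cannot be interpreted as an interval."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """One half-open genomic span ``[start, end)`` on a named chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome (or scaffold) name.
    start : int
        0-based inclusive start position.
    end : int
        Exclusive end position; must satisfy ``start < end <= 2e9``.
    id : str
        Record identifier (BED column 4).  May be empty for ad-hoc probes,
        but every record emitted by the simulator carries a unique id.
    extra : tuple of str
        BED columns 5+ preserved verbatim on round-trip; ignored semantically.
    """

    chrom: str
    start: int
    end: int
    id: str = ""
    extra: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.end > MAX_COORD:
            raise ValueError(f"end {self.end} exceeds chromosome capacity {MAX_COORD}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.id)

    def __str__(self) -> str:  # pragma: no cover - convenience only
        return f"{self.chrom}:{self.start}-{self.end}" + (f"({self.id})" if self.id else "")


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff *a* and *b* share at least one base (half-open semantics).

    Equivalent to ``max(a.start, b.start) < min(a.end, b.end)`` on the same
    chromosome; adjacency (``a.end == b.start``) is not overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def _open_text(path: str | Path, compressed: bool | None, mode: str):
    path = Path(path)
    if compressed is None:
        compressed = path.suffix == ".gz"
    if compressed:
        return gzip.open(path, mode + "t")
    return open(path, mode)


_HEADER_PREFIXES = ("#", "track", "browser")


def read_bed(path: str | Path, compressed: bool | None = None) -> list[GenomicInterval]:
    """Read a BED3+ file into a list of :class:`GenomicInterval`.

    Column 4, when present, becomes the record id; otherwise the id is
    ``line<k>`` for 1-based file line number *k*.  Columns 5+ are kept in
    ``extra``.  Gzip input is used when ``compressed`` is true or the path
    ends in ``.gz``.

    Raises
    ------
    BedParseError
        On non-integer coordinates, ``start >= end``, or fewer than three
        columns; the message names the offending line number.
    """
    out: list[GenomicInterval] = []
    with _open_text(path, compressed, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_HEADER_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r}/{fields[2]!r}"
                ) from None
            name = fields[3] if len(fields) > 3 else f"line{lineno}"
            try:
                iv = GenomicInterval(chrom, start, end, name, tuple(fields[4:]))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
            out.append(iv)
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    compressed: bool | None = None,
) -> None:
    """Write intervals as tab-separated BED, preserving order and extra columns.

    Round-trips with :func:`read_bed`.  Ids containing field separators are
    rejected rather than silently corrupting the file.
    """
    with _open_text(path, compressed, "w") as fh:
        for iv in intervals:
            if "\t" in iv.id or "\n" in iv.id:
                raise ValueError(f"interval id {iv.id!r} contains a field separator")
            if not iv.id:
                raise ValueError("cannot write an interval with an empty id")
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.id, *iv.extra]
            fh.write("\t".join(cols) + "\n")


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Total, stable order: lexicographic chrom, then start, end, id.

    Note the chromosome order is plain lexicographic (``chr10`` < ``chr2``);
    no karyotype order is imposed.
    """
    return sorted(intervals, key=GenomicInterval.sort_key)
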