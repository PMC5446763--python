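"""Coordinate primitives shared by every stage of the pipeline.

All coordinates inside the package are 0-based half-open ``[start, end)``
on the forward genomic strand.  Formats that use other conventions (GTF,
STAR junction tables) are converted at the I/O boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with optional strand."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must be > start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Gap in bases between two non-overlapping intervals (0 if they touch
        or overlap; intervals on different contigs are infinitely far apart)."""
        if self.contig != other.contig:
            raise ValueError("gap undefined across contigs")
        return max(self.start, other.start) - min(self.end, other.end)

    def intersection(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return replace(
            self, start=max(self.start, other.start), end=min(self.end, other.end)
        )

    def padded(self, pad: int, contig_length: int | None = None) -> "GenomicInterval":
        """Interval extended by ``pad`` on both sides, clipped at contig bounds."""
        start = max(0, self.start - pad)
        end = self.end + pad
        if contig_length is not None:
            end = min(end, contig_length)
        return replace(self, start=start, end=end)


@dataclass(frozen=True)
class SpliceJunction:
    """An intron observed in spliced alignments.

    ``donor_end`` is the 0-based exclusive end of the upstream exonic block
    (== first intronic base), ``acceptor_start`` the 0-based inclusive start
    of the downstream exonic block (== first base after the intron).  The
    names refer to genomic left/right order, not transcript orientation.
    """

    contig: str
    donor_end: int
    acceptor_start: int
    strand: str = "."
    unique_read_count: int = 0
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.acceptor_start <= self.donor_end:
            raise ValueError(
                f"acceptor_start ({self.acceptor_start}) must be > donor_end "
                f"({self.donor_end})"
            )
        if self.unique_read_count < 0:
            raise ValueError("unique_read_count must be >= 0")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def intron(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.donor_end, self.acceptor_start, self.strand)

    def same_coords(self, other: "SpliceJunction") -> bool:
        return (
            self.contig == other.contig
            and self.donor_end == other.donor_end
            and self.acceptor_start == other.acceptor_start
        )


def merge_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Single-linkage merge of intervals whose gap is <= ``max_gap``.

    Strand is dropped on merged products unless all members agree.
    """
    per_contig: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        per_contig.setdefault(iv.contig, []).append(iv)
    out: list[GenomicInterval] = []
    for contig in sorted(per_contig):
        ivs = sorted(per_contig[contig], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        strands = {ivs[0].strand}
        for iv in ivs[1:]:
            if iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
                strands.add(iv.strand)
            else:
                out.append(
                    GenomicInterval(
                        contig, cur_start, cur_end,
                        strands.pop() if len(strands) == 1 else ".",
                    )
                )
                cur_start, cur_end = iv.start, iv.end
                strands = {iv.strand}
        out.append(
            GenomicInterval(
                contig, cur_start, cur_end,
                strands.pop() if len(strands) == 1 else ".",
            )
        )
    return out


def subtract_intervals(
    span: GenomicInterval, blocks: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """``span`` minus the union of ``blocks`` (used to derive introns)."""
    merged = merge_intervals([b for b in blocks if b.overlaps(span)]) if blocks else []
    out = []
    cursor = span.start
    for b in merged:
        lo, hi = max(b.start, span.start), min(b.end, span.end)
        if lo > cursor:
            out.append(replace(span, start=cursor, end=lo))
        cursor = max(cursor, hi)
    if cursor < span.end:
        out.append(replace(span, start=cursor, end=span.end))
    return out
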