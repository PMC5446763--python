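"""Readers, writers and annotation flattening.

Everything that touches an external file format lives here: GTF gene models
(Ensembl dialect, 1-based closed, converted on read), SAM/BAM alignments,
STAR ``SJ.out.tab`` junction tables, BED/narrowPeak peak intervals, UCSC
RepeatMasker tables, bedGraph (or bigWig) conservation tracks and indexed
FASTA.  Internally every coordinate is 0-based half-open.

The flattener reproduces the DEXSeq convention: the exons of all transcripts
of a gene are partitioned at every distinct exon boundary into disjoint
counting bins, genes whose exons overlap on the same strand are merged into
``+``-joined aggregates, and introns are derived as the within-gene
complement of the bins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .intervals import (
    GenomicInterval,
    SpliceJunction,
    reverse_complement,
    subtract_intervals,
)

logger = logging.getLogger(__name__)

REPEAT_FAMILIES = (
    "LINE", "SINE", "Alu", "LTR", "DNA", "Simple_repeat", "Low_complexity", "other",
)


# ---------------------------------------------------------------------------
# annotation model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExonBin:
    """One disjoint counting bin of a flattened gene."""

    interval: GenomicInterval
    gene_id: str
    bin_index: int

    @property
    def bin_id(self) -> str:
        return f"{self.gene_id}:E{self.bin_index:03d}"


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    strand: str
    exons: list[GenomicInterval]           # genomic order
    cds_start: int | None = None           # genomic span of the CDS
    cds_end: int | None = None

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def cds_length(self) -> int:
        """Spliced CDS length in nucleotides (0 for non-coding)."""
        if not self.is_coding:
            return 0
        return sum(
            max(0, min(e.end, self.cds_end) - max(e.start, self.cds_start))
            for e in self.exons
        )


@dataclass
class FlattenedAnnotation:
    """Disjoint exon bins and derived introns per (aggregate) gene."""

    genes: dict[str, list[ExonBin]]
    introns: dict[str, list[GenomicInterval]]
    transcripts: dict[str, TranscriptModel]
    strands: dict[str, str] = field(default_factory=dict)

    def gene_span(self, gene_id: str) -> GenomicInterval:
        bins = self.genes[gene_id]
        first, last = bins[0].interval, bins[-1].interval
        return GenomicInterval(first.contig, first.start, last.end, first.strand)

    def gene_ids(self) -> list[str]:
        return sorted(self.genes)

    def bins_on(self, contig: str) -> list[ExonBin]:
        return [
            b for bins in self.genes.values() for b in bins
            if b.interval.contig == contig
        ]

    def host_intron(self, gene_id: str, interval: GenomicInterval) -> GenomicInterval | None:
        """The gene intron containing ``interval`` entirely, if any."""
        for intron in self.introns.get(gene_id, []):
            if intron.contains(interval):
                return intron
        return None

    def transcripts_of(self, gene_id: str) -> list[TranscriptModel]:
        members = set(gene_id.split("+"))
        return [
            t for t in self.transcripts.values()
            if t.gene_id in members or t.gene_id == gene_id
        ]


def read_gtf(path: str | Path) -> pd.DataFrame:
    """Read a GTF into a DataFrame with 0-based half-open coordinates.

    Raises a parse error naming the first malformed line; exon records
    without a gene_id are rejected with a warning.
    """
    import pyranges as pr

    path = Path(path)
    try:
        df = pr.read_gtf(str(path)).df
    except Exception as exc:  # locate the offending line for the message
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.startswith("#") or not line.strip():
                    continue
                if len(line.rstrip("\n").split("\t")) != 9:
                    raise ValueError(
                        f"{path}: malformed GTF line {lineno}: expected 9 "
                        f"tab-separated fields"
                    ) from exc
        raise ValueError(f"{path}: failed to parse GTF: {exc}") from exc
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: GTF records carry no gene_id attribute")
    bad = df["gene_id"].isna() | (df["gene_id"] == "")
    if bad.any():
        warnings.warn(
            f"{path}: rejected {int(bad.sum())} record(s) without gene_id"
        )
        df = df[~bad]
    logger.info("read %d GTF records from %s", len(df), path)
    return df


def _aggregate_genes(exons: pd.DataFrame) -> dict[str, str]:
    """Map each gene_id to its aggregate id (genes overlapping on the same
    contig+strand are merged, DEXSeq-style)."""
    mapping: dict[str, str] = {}
    spans = (
        exons.groupby("gene_id")
        .agg(
            Chromosome=("Chromosome", "first"),
            Strand=("Strand", "first"),
            Start=("Start", "min"),
            End=("End", "max"),
        )
        .reset_index()
    )
    for (_, _), grp in spans.groupby(["Chromosome", "Strand"], observed=True):
        grp = grp.sort_values(["Start", "End"])
        cluster: list[str] = []
        cluster_end = -1
        for row in grp.itertuples():
            if cluster and row.Start < cluster_end:
                cluster.append(row.gene_id)
                cluster_end = max(cluster_end, row.End)
            else:
                if cluster:
                    agg = "+".join(sorted(cluster))
                    for g in cluster:
                        mapping[g] = agg
                cluster = [row.gene_id]
                cluster_end = row.End
        if cluster:
            agg = "+".join(sorted(cluster))
            for g in cluster:
                mapping[g] = agg
    return mapping


def flatten_annotation(gtf: pd.DataFrame | str | Path) -> FlattenedAnnotation:
    """Partition transcript exons into disjoint bins and derive introns.

    Accepts a path or a DataFrame as returned by :func:`read_gtf`.
    """
    if not isinstance(gtf, pd.DataFrame):
        gtf = read_gtf(gtf)
    exons = gtf[gtf["Feature"] == "exon"].copy()
    if exons.empty:
        raise ValueError("annotation contains no exon records")
    strand = exons.get("Strand")
    if strand is None:
        exons["Strand"] = "."
    agg_of = _aggregate_genes(exons)
    exons["aggregate"] = exons["gene_id"].map(agg_of)

    genes: dict[str, list[ExonBin]] = {}
    introns: dict[str, list[GenomicInterval]] = {}
    strands: dict[str, str] = {}
    for agg, grp in exons.groupby("aggregate"):
        contig = str(grp["Chromosome"].iloc[0])
        gstrand = str(grp["Strand"].iloc[0])
        if grp["Strand"].nunique() > 1:
            gstrand = "."
        strands[agg] = gstrand
        # partition at every distinct exon boundary
        starts = grp["Start"].to_numpy()
        ends = grp["End"].to_numpy()
        bounds = np.unique(np.concatenate([starts, ends]))
        bins: list[ExonBin] = []
        idx = 1
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if ((starts < hi) & (ends > lo)).any():      # segment covered by >=1 exon
                bins.append(
                    ExonBin(GenomicInterval(contig, int(lo), int(hi), gstrand), agg, idx)
                )
                idx += 1
        genes[agg] = bins
        span = GenomicInterval(contig, int(bounds[0]), int(bounds[-1]), gstrand)
        introns[agg] = subtract_intervals(span, [b.interval for b in bins])

    transcripts: dict[str, TranscriptModel] = {}
    if "transcript_id" in gtf.columns:
        tx_exons = exons.dropna(subset=["transcript_id"])
        cds = gtf[gtf["Feature"] == "CDS"]
        cds_span = (
            cds.groupby("transcript_id").agg(cs=("Start", "min"), ce=("End", "max"))
            if not cds.empty and "transcript_id" in cds.columns
            else pd.DataFrame(columns=["cs", "ce"])
        )
        for tid, grp in tx_exons.groupby("transcript_id"):
            grp = grp.sort_values("Start")
            contig = str(grp["Chromosome"].iloc[0])
            tstrand = str(grp["Strand"].iloc[0])
            exs = [
                GenomicInterval(contig, int(r.Start), int(r.End), tstrand)
                for r in grp.itertuples()
            ]
            cs = ce = None
            if tid in cds_span.index:
                cs, ce = int(cds_span.loc[tid, "cs"]), int(cds_span.loc[tid, "ce"])
            gid = str(grp["gene_id"].iloc[0])
            transcripts[str(tid)] = TranscriptModel(
                str(tid), gid, tstrand, exs, cs, ce
            )
    return FlattenedAnnotation(genes, introns, transcripts, strands)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitRead:
    """A primary spliced alignment decomposed into aligned blocks."""

    query_name: str
    contig: str
    blocks: tuple[GenomicInterval, ...]
    junctions: tuple[SpliceJunction, ...]
    is_duplicate: bool = False
    mapq: int = 255
    sample_id: str = ""


def _cigar_blocks(pos: int, cigartuples) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Aligned reference blocks and (donor_end, acceptor_start) junctions."""
    blocks: list[tuple[int, int]] = []
    junctions: list[tuple[int, int]] = []
    ref = pos
    block_start = pos
    in_block = False
    for op, length in cigartuples:
        if op in (0, 7, 8):          # M, =, X consume reference and read
            if not in_block:
                block_start = ref
                in_block = True
            ref += length
        elif op == 2:                # D consumes reference, stays in block
            ref += length
        elif op == 3:                # N: splice junction
            if in_block:
                blocks.append((block_start, ref))
                in_block = False
            junctions.append((ref, ref + length))
            ref += length
        # I, S, H, P consume no reference
    if in_block:
        blocks.append((block_start, ref))
    return blocks, junctions


def extract_spliced_reads(
    path: str | Path,
    sample_id: str = "",
    min_mapq: int = 0,
    require_sorted: bool = True,
) -> list[SplitRead]:
    """All primary spliced alignments of a SAM/BAM file.

    Secondary and supplementary alignments are excluded; duplicate-marked
    reads are kept here (their flag is preserved for the counting step to
    honour).  Reads without a CIGAR are skipped and counted.
    """
    path = Path(path)
    mode = "rb" if path.suffix == ".bam" else "r"
    out: list[SplitRead] = []
    skipped_no_cigar = 0
    with pysam.AlignmentFile(str(path), mode) as af:
        so = (af.header.get("HD") or {}).get("SO", "unknown")
        if require_sorted and so != "coordinate":
            raise ValueError(
                f"{path}: alignments are not coordinate-sorted (SO={so}); "
                "sort the file first (e.g. samtools sort)"
            )
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            if read.cigartuples is None:
                skipped_no_cigar += 1
                continue
            if not any(op == 3 for op, _ in read.cigartuples):
                continue
            blocks, juncs = _cigar_blocks(read.reference_start, read.cigartuples)
            contig = read.reference_name
            out.append(
                SplitRead(
                    read.query_name,
                    contig,
                    tuple(GenomicInterval(contig, s, e) for s, e in blocks),
                    tuple(
                        SpliceJunction(contig, d, a, ".", 1, sample_id)
                        for d, a in juncs
                    ),
                    bool(read.is_duplicate),
                    read.mapping_quality,
                    sample_id,
                )
            )
    if skipped_no_cigar:
        logger.warning("%s: skipped %d reads without CIGAR", path, skipped_no_cigar)
    logger.info("extracted %d spliced reads from %s", len(out), path)
    return out


def extract_all_reads(
    path: str | Path, sample_id: str = "", min_mapq: int = 0
) -> list[SplitRead]:
    """All primary alignments (spliced or not) as block records.

    Used by the counting steps, which need every read; spliced reads carry
    their junctions, unspliced ones a single block.
    """
    path = Path(path)
    mode = "rb" if path.suffix == ".bam" else "r"
    out: list[SplitRead] = []
    with pysam.AlignmentFile(str(path), mode) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq or read.cigartuples is None:
                continue
            blocks, juncs = _cigar_blocks(read.reference_start, read.cigartuples)
            contig = read.reference_name
            out.append(
                SplitRead(
                    read.query_name,
                    contig,
                    tuple(GenomicInterval(contig, s, e) for s, e in blocks),
                    tuple(
                        SpliceJunction(contig, d, a, ".", 1, sample_id)
                        for d, a in juncs
                    ),
                    bool(read.is_duplicate),
                    read.mapping_quality,
                    sample_id,
                )
            )
    return out


# ---------------------------------------------------------------------------
# junction tables (STAR SJ.out.tab dialect)
# ---------------------------------------------------------------------------

_SJ_STRAND = {0: ".", 1: "+", 2: "-"}
_SJ_STRAND_INV = {".": 0, "+": 1, "-": 2}


def read_junction_table(
    path: str | Path, dialect: str = "star", sample_id: str = ""
) -> list[SpliceJunction]:
    """Read a STAR ``SJ.out.tab`` file.

    STAR reports 1-based inclusive intron coordinates; these convert to the
    internal convention as ``donor_end = start - 1`` and ``acceptor_start =
    end``.  Zero-unique-read junctions are retained.
    """
    if dialect != "star":
        raise ValueError(f"unknown junction table dialect: {dialect}")
    out: list[SpliceJunction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 columns, got {len(fields)}"
                )
            contig = fields[0]
            start, end, strand_code = int(fields[1]), int(fields[2]), int(fields[3])
            n_unique = int(fields[6])
            if n_unique < 0:
                warnings.warn(f"{path}: line {lineno}: negative count, record rejected")
                continue
            out.append(
                SpliceJunction(
                    contig, start - 1, end, _SJ_STRAND[strand_code], n_unique, sample_id
                )
            )
    return out


def write_junction_table(
    junctions: Iterable[SpliceJunction], path: str | Path
) -> None:
    """Write junctions back to the STAR dialect (inverse of the reader)."""
    with open(path, "w") as fh:
        for j in sorted(junctions, key=lambda x: (x.contig, x.donor_end, x.acceptor_start)):
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            j.contig, j.donor_end + 1, j.acceptor_start,
                            _SJ_STRAND_INV[j.strand], 0, 0,
                            j.unique_read_count, 0, 50,
                        ],
                    )
                )
                + "\n"
            )


def junctions_from_split_reads(
    split_reads: Iterable[SplitRead], sample_id: str = ""
) -> list[SpliceJunction]:
    """Collapse per-read junctions into a counted junction table."""
    counts: dict[tuple[str, int, int], int] = {}
    for sr in split_reads:
        for j in sr.junctions:
            key = (j.contig, j.donor_end, j.acceptor_start)
            counts[key] = counts.get(key, 0) + 1
    return [
        SpliceJunction(c, d, a, ".", n, sample_id)
        for (c, d, a), n in sorted(counts.items())
    ]


# ---------------------------------------------------------------------------
# peaks, repeats
# ---------------------------------------------------------------------------

@dataclass
class PeakSet:
    """Binding peaks of one RBP experiment (one replicate)."""

    name: str
    replicate: str
    peaks: list[GenomicInterval]
    peak_points: list[int] = field(default_factory=list)   # narrowPeak summit/first nt

    def __post_init__(self) -> None:
        order = sorted(range(len(self.peaks)), key=lambda i: (self.peaks[i].contig, self.peaks[i].start))
        self.peaks = [self.peaks[i] for i in order]
        if self.peak_points:
            self.peak_points = [self.peak_points[i] for i in order]


def read_peaks(path: str | Path, name: str = "", replicate: str = "1") -> PeakSet:
    """Read BED or narrowPeak peak intervals (0-based half-open)."""
    peaks: list[GenomicInterval] = []
    points: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            start, end = int(f[1]), int(f[2])
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
            peaks.append(GenomicInterval(f[0], start, end, strand))
            # narrowPeak column 10 is the summit offset; -1 means first nt
            if len(f) >= 10:
                offset = int(f[9])
                points.append(start + (offset if offset >= 0 else 0))
            else:
                points.append(start)
    name = name or Path(path).stem
    logger.info("read %d peaks from %s", len(peaks), path)
    return PeakSet(name, replicate, peaks, points)


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            nm = names[i] if names else f"iv{i}"
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{nm}\t0\t{iv.strand}\n")


@dataclass(frozen=True)
class RepeatElement:
    interval: GenomicInterval
    family: str
    element_name: str
    element_strand: str

    def __post_init__(self) -> None:
        if self.family not in REPEAT_FAMILIES:
            raise ValueError(f"unknown repeat family {self.family!r}")


def _repeat_family(rep_class: str, rep_family: str, rep_name: str) -> str:
    """Controlled-vocabulary family; Alu is split out of SINE because of its
    special role in exonisation."""
    if rep_family == "Alu" or rep_name.startswith("Alu"):
        return "Alu"
    base = rep_class.split("?")[0]
    return base if base in REPEAT_FAMILIES else "other"


def read_repeats(path: str | Path) -> list[RepeatElement]:
    """Read a UCSC RepeatMasker (rmsk) table.

    Accepts the full 17-column dump (leading ``bin`` column) or the
    16-column variant without it.  RepeatMasker strand ``C`` means the
    element is on the reverse strand.
    """
    out: list[RepeatElement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) == 17:
                f = f[1:]
            if len(f) != 16:
                raise ValueError(
                    f"{path}: line {lineno}: expected 16/17 rmsk columns, got {len(f)}"
                )
            contig, start, end = f[4], int(f[5]), int(f[6])
            strand = "-" if f[8] in ("C", "-") else "+"
            rep_name, rep_class, rep_family = f[9], f[10], f[11]
            out.append(
                RepeatElement(
                    GenomicInterval(contig, start, end),
                    _repeat_family(rep_class, rep_family, rep_name),
                    rep_name,
                    strand,
                )
            )
    return out


def write_repeats(repeats: Iterable[RepeatElement], path: str | Path) -> None:
    """Write elements in the 16-column rmsk layout read by :func:`read_repeats`."""
    with open(path, "w") as fh:
        for r in repeats:
            cls = "SINE" if r.family == "Alu" else r.family
            fam = "Alu" if r.family == "Alu" else cls
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            0, 0, 0, 0,
                            r.interval.contig, r.interval.start, r.interval.end, 0,
                            "C" if r.element_strand == "-" else "+",
                            r.element_name, cls, fam, 0, 0, 0, 0,
                        ],
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# conservation tracks
# ---------------------------------------------------------------------------

class ConservationTrack:
    """Per-base score accessor over a (possibly sparse) bedGraph track.

    Means are computed over covered bases only; fully unscored intervals
    yield ``nan``.  Results are invariant to how runs are split into rows.
    """

    def __init__(self, rows: Iterable[tuple[str, int, int, float]]):
        per: dict[str, list[tuple[int, int, float]]] = {}
        for contig, start, end, value in rows:
            per.setdefault(contig, []).append((start, end, value))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        for contig, rs in per.items():
            rs.sort()
            for (s1, e1, _), (s2, _, _) in zip(rs[:-1], rs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping track rows on {contig} at {s2} < {e1}; "
                        "bedGraph rows must be disjoint"
                    )
            self._starts[contig] = np.array([r[0] for r in rs])
            self._ends[contig] = np.array([r[1] for r in rs])
            self._values[contig] = np.array([r[2] for r in rs], dtype=float)

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "ConservationTrack":
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.split()
                rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
        return cls(rows)

    @classmethod
    def from_file(cls, path: str | Path) -> "ConservationTrack":
        path = Path(path)
        if path.suffix.lower() in (".bw", ".bigwig"):
            import pyBigWig

            rows = []
            with pyBigWig.open(str(path)) as bw:
                for contig in bw.chroms():
                    for start, end, value in bw.intervals(contig) or []:
                        rows.append((contig, start, end, value))
            return cls(rows)
        return cls.from_bedgraph(path)

    def mean(self, interval: GenomicInterval) -> float:
        """Arithmetic per-base mean over covered bases; nan if none covered."""
        starts = self._starts.get(interval.contig)
        if starts is None:
            return float("nan")
        ends = self._ends[interval.contig]
        vals = self._values[interval.contig]
        lo = np.searchsorted(ends, interval.start, side="right")
        hi = np.searchsorted(starts, interval.end, side="left")
        if hi <= lo:
            return float("nan")
        s = np.maximum(starts[lo:hi], interval.start)
        e = np.minimum(ends[lo:hi], interval.end)
        cov = (e - s).astype(float)
        covered = cov.sum()
        if covered <= 0:
            return float("nan")
        return float((vals[lo:hi] * cov).sum() / covered)


# ---------------------------------------------------------------------------
# genome sequence
# ---------------------------------------------------------------------------

class GenomeSequence:
    """Strand-aware sequence fetch over an indexed FASTA."""

    def __init__(self, path: str | Path):
        import pyfaidx

        self._fasta = pyfaidx.Fasta(str(path), sequence_always_upper=True)

    def contig_length(self, contig: str) -> int:
        return len(self._fasta[contig])

    def fetch(self, interval: GenomicInterval, rna: bool = False) -> str:
        """Sequence of ``interval`` on its own strand.

        Minus-strand intervals return the reverse complement of the forward
        slice.  Intervals running past the contig end are clipped with a
        warning; unknown contigs raise ``KeyError``.
        """
        if interval.contig not in self._fasta:
            raise KeyError(f"unknown contig {interval.contig!r}")
        clen = self.contig_length(interval.contig)
        end = interval.end
        if end > clen:
            warnings.warn(
                f"interval {interval} extends past contig end ({clen}); clipped"
            )
            end = clen
        seq = str(self._fasta[interval.contig][interval.start:end])
        if interval.strand == "-":
            seq = reverse_complement(seq)
        if rna:
            seq = seq.replace("T", "U")
        return seq
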