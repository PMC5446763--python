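"""Fully synthetic reference, reads and annotation tracks with known truth.

The generator emulates the data layout of a replicated depletion/control
splicing study: multi-exon genes with valid GT/AG introns and a coding
sequence, cryptic cassette exons and exon extensions spiked into introns
at controlled inclusion (PSI) per condition, junction-spanning spliced
reads plus plain exonic coverage written as coordinate-sorted SAM with
matching STAR-style junction tables, and optional peak, repeat and
conservation tracks spiked at the cryptic loci.  Reads are generated at
the junction level — spliced reads uniformly placed across each junction —
because every downstream statistic consumes junctions and bin counts.

Everything is deterministic under the configuration seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .annotation_io import PeakSet, RepeatElement, write_junction_table
from .classification import CrypticExon
from .intervals import GenomicInterval, SpliceJunction, reverse_complement

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_STOP = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOP
]


@dataclass(frozen=True)
class CrypticSpike:
    """One planted cryptic event (class named in transcript orientation)."""

    gene_index: int
    exon_class: str                  # cassette | five_prime_extension | three_prime_extension
    intron_index: int                # transcript-order intron hosting the event
    delta_psi: float
    length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta_psi <= 1.0:
            raise ValueError("delta_psi must lie in [0, 1]")
        if self.length <= 0:
            raise ValueError("length must be positive")


@dataclass
class SimulationConfig:
    seed: int
    n_genes: int = 60
    exons_per_gene: int = 4
    exon_length: tuple[int, int] = (120, 180)
    intron_length: tuple[int, int] = (1500, 2500)
    spikes: list[CrypticSpike] = field(default_factory=list)
    replicates: int = 3
    junction_depth: int = 100
    exon_depth: int = 20
    read_anchor: int = 50
    control_psi: float = 0.02        # baseline cryptic inclusion in controls
    null_background_psi: float = 0.02  # equal-inclusion events in unspiked genes
    minus_strand_fraction: float = 0.3
    inject_duplicates: bool = True
    inject_secondary: bool = True
    ug_spike: bool = False           # embed UG runs in cryptic exons
    contig: str = "chr1"
    gene_padding: int = 400

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")


def standard_config(seed: int = 1) -> SimulationConfig:
    """The benchmark layout: 60 genes, 20 cassette spikes at ΔPSI
    {0.4, 0.6, 0.8}, 10 extension spikes, 30 unspiked genes, 3v3
    replicates at junction depth 100."""
    rng = np.random.default_rng(seed)
    spikes: list[CrypticSpike] = []
    dpsis = [0.4, 0.6, 0.8]
    for i in range(20):
        spikes.append(
            CrypticSpike(i, "cassette", 1, dpsis[i % 3], int(rng.integers(81, 150)))
        )
    for i in range(10):
        cls = "five_prime_extension" if i % 2 == 0 else "three_prime_extension"
        spikes.append(
            CrypticSpike(20 + i, cls, 1, dpsis[i % 3], int(rng.integers(30, 61)))
        )
    return SimulationConfig(seed=seed, n_genes=60, spikes=spikes)


@dataclass
class SimulatedGene:
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]         # genomic order, absolute coords
    cds_start: int
    cds_end: int
    block: tuple[int, int]


@dataclass
class SpikeTruth:
    spike_id: str
    gene_id: str
    contig: str
    start: int
    end: int
    exon_class: str                      # transcript orientation
    strand: str
    intron: tuple[int, int]
    psi_control: float
    psi_depletion: float
    is_null_background: bool = False

    @property
    def delta_psi(self) -> float:
        return self.psi_depletion - self.psi_control

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.start, self.end, self.strand)


@dataclass
class SimulatedReference:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[SimulatedGene]
    truths: list[SpikeTruth]
    fasta_path: Path | None = None
    gtf_path: Path | None = None

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "spike_id": t.spike_id, "gene_id": t.gene_id, "contig": t.contig,
                    "start": t.start, "end": t.end, "class": t.exon_class,
                    "strand": t.strand, "psi_control": t.psi_control,
                    "psi_depletion": t.psi_depletion, "delta_psi": t.delta_psi,
                    "null_background": t.is_null_background,
                }
                for t in self.truths
            ]
        )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _donor_head(rng: np.random.Generator) -> str:
    """First 6 intronic nt of an annotated donor: GT + consensus-like AAGT."""
    tail = list("AAGT")
    for i in range(4):
        if rng.random() < 0.15:
            tail[i] = str(rng.choice(_BASES))
    return "GT" + "".join(tail)


def _acceptor_tail(rng: np.random.Generator) -> str:
    """Last 20 intronic nt of an annotated acceptor: polypyrimidine + AG."""
    py = "".join(
        rng.choice(np.array(list("CT"))) if rng.random() < 0.85 else str(rng.choice(_BASES))
        for _ in range(17)
    )
    return py + str(rng.choice(_BASES)) + "AG"


def _mirror(coord: int, block_len: int) -> int:
    return block_len - coord


def simulate_reference(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedReference:
    """Build the genome and annotation; write FASTA/GTF when a directory is
    given.  Re-running with the same seed gives byte-identical outputs."""
    rng = np.random.default_rng(config.seed)
    spikes_by_gene: dict[int, list[CrypticSpike]] = {}
    for sp in config.spikes:
        spikes_by_gene.setdefault(sp.gene_index, []).append(sp)

    contig_parts: list[str] = []
    cursor = 0
    genes: list[SimulatedGene] = []
    truths: list[SpikeTruth] = []
    for g in range(config.n_genes):
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        n_ex = config.exons_per_gene
        el = [int(rng.integers(*config.exon_length)) for _ in range(n_ex)]
        il = [int(rng.integers(*config.intron_length)) for _ in range(n_ex - 1)]
        pad = config.gene_padding

        # local layout, transcript orientation treated as plus
        exons_local: list[tuple[int, int]] = []
        pos = pad
        for i in range(n_ex):
            exons_local.append((pos, pos + el[i]))
            pos += el[i]
            if i < n_ex - 1:
                pos += il[i]
        block_len = pos + pad

        seq = np.array(list(_random_seq(rng, block_len)))
        # mRNA: 5'UTR + stop-free CDS + stop codon + 3'UTR
        total_exonic = sum(el)
        utr5, utr3 = 60, 90
        cds_len = total_exonic - utr5 - utr3
        cds_len -= cds_len % 3
        utr3 = total_exonic - utr5 - cds_len
        codons = list(rng.choice(_NONSTOP_CODONS, size=cds_len // 3 - 1))
        mrna = _random_seq(rng, utr5) + "".join(codons) + "TAA" + _random_seq(rng, utr3)
        offset = 0
        for (s, e) in exons_local:
            seq[s:e] = list(mrna[offset : offset + (e - s)])
            offset += e - s
        # annotated splice motifs at every intron boundary
        for i in range(n_ex - 1):
            istart = exons_local[i][1]
            iend = exons_local[i + 1][0]
            seq[istart : istart + 6] = list(_donor_head(rng))
            seq[iend - 20 : iend] = list(_acceptor_tail(rng))

        # cryptic spikes (local coordinates, transcript orientation)
        local_truths: list[tuple[CrypticSpike, int, int, int, int, bool]] = []
        gene_spikes = list(spikes_by_gene.get(g, []))
        is_null = not gene_spikes
        if is_null and config.null_background_psi > 0:
            gene_spikes = [
                CrypticSpike(g, "cassette", 1, 0.0, int(rng.integers(81, 150)))
            ]
        for sp in gene_spikes:
            istart = exons_local[sp.intron_index][1]
            iend = exons_local[sp.intron_index + 1][0]
            if sp.exon_class == "cassette":
                c0 = istart + ((iend - istart) - sp.length) // 2
                c1 = c0 + sp.length
                seq[c0 - 2 : c0] = ["A", "G"]
                seq[c1 : c1 + 2] = ["G", "T"]
                if config.ug_spike:
                    run = "TG" * 10
                    mid = c0 + (sp.length - len(run)) // 2
                    seq[mid : mid + len(run)] = list(run)
            elif sp.exon_class == "five_prime_extension":
                c1 = iend
                c0 = iend - sp.length
                seq[c0 - 2 : c0] = ["A", "G"]
            elif sp.exon_class == "three_prime_extension":
                c0 = istart
                c1 = istart + sp.length
                seq[c1 : c1 + 2] = ["G", "T"]
            else:
                raise ValueError(f"unknown spike class {sp.exon_class}")
            local_truths.append((sp, c0, c1, istart, iend, is_null))

        cds_lo = exons_local[0][0] + utr5
        cds_hi = exons_local[-1][1] - utr3

        if strand == "-":
            seq = np.array(list(reverse_complement("".join(seq))))
            exons_abs = [
                (_mirror(e, block_len), _mirror(s, block_len)) for s, e in exons_local
            ][::-1]
            cds_lo, cds_hi = _mirror(cds_hi, block_len), _mirror(cds_lo, block_len)
            local_truths = [
                (sp, _mirror(c1, block_len), _mirror(c0, block_len),
                 _mirror(ie, block_len), _mirror(is_, block_len), null)
                for sp, c0, c1, is_, ie, null in local_truths
            ]
        else:
            exons_abs = exons_local

        gene_id = f"g{g:03d}"
        base = cursor
        genes.append(
            SimulatedGene(
                gene_id, config.contig, strand,
                [(base + s, base + e) for s, e in exons_abs],
                base + cds_lo, base + cds_hi,
                (base, base + block_len),
            )
        )
        for j, (sp, c0, c1, is_, ie, null) in enumerate(local_truths):
            psi_ctl = config.control_psi if not null else config.null_background_psi
            psi_dep = min(psi_ctl + sp.delta_psi, 1.0)
            truths.append(
                SpikeTruth(
                    f"{gene_id}.s{j}", gene_id, config.contig,
                    base + c0, base + c1, sp.exon_class, strand,
                    (base + is_, base + ie), psi_ctl, psi_dep, null,
                )
            )
        contig_parts.append("".join(seq))
        cursor += block_len

    genome = {config.contig: "".join(contig_parts)}
    ref = SimulatedReference(config, genome, genes, truths)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ref.fasta_path = out_dir / "genome.fa"
        with open(ref.fasta_path, "w") as fh:
            for contig, s in genome.items():
                fh.write(f">{contig}\n")
                for i in range(0, len(s), 80):
                    fh.write(s[i : i + 80] + "\n")
        ref.gtf_path = out_dir / "annotation.gtf"
        write_gtf(ref, ref.gtf_path)
    return ref


def write_gtf(ref: SimulatedReference, path: str | Path) -> None:
    """One transcript per gene; CDS spans include the stop codon."""
    with open(path, "w") as fh:
        for gene in ref.genes:
            tid = gene.gene_id.replace("g", "t", 1)
            attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tid}";'
            span = (gene.exons[0][0] + 1, gene.exons[-1][1])
            rows = [("gene", span[0], span[1], f'gene_id "{gene.gene_id}";')]
            rows.append(("transcript", span[0], span[1], attrs))
            for s, e in gene.exons:
                rows.append(("exon", s + 1, e, attrs))
                cs, ce = max(s, gene.cds_start), min(e, gene.cds_end)
                if ce > cs:
                    rows.append(("CDS", cs + 1, ce, attrs))
            for feat, s1, e1, a in rows:
                fh.write(
                    f"{gene.contig}\tsim\t{feat}\t{s1}\t{e1}\t.\t{gene.strand}\t.\t{a}\n"
                )


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass
class _Read:
    name: str
    pos: int
    cigar: str
    flag: int = 0


def _spliced_cigar(blocks: list[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        parts.append(f"{e - s}M")
        if i + 1 < len(blocks):
            parts.append(f"{blocks[i + 1][0] - e}N")
    return "".join(parts)


def sample_names(config: SimulationConfig) -> tuple[list[str], dict[str, str]]:
    samples = [f"ctl_{i + 1}" for i in range(config.replicates)] + [
        f"dep_{i + 1}" for i in range(config.replicates)
    ]
    condition_of = {
        s: ("control" if s.startswith("ctl") else "depletion") for s in samples
    }
    return samples, condition_of


def simulate_reads(
    ref: SimulatedReference, out_dir: str | Path
) -> tuple[dict[str, Path], dict[str, Path], Path]:
    """Per-sample SAM and SJ.out.tab plus the truth table.

    Returns (sam paths, junction-table paths, truth path), all keyed by
    sample id.
    """
    config = ref.config
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)
    samples, condition_of = sample_names(config)
    contig = config.contig
    genome = ref.genome[contig]
    anchor = config.read_anchor

    truth_by_intron: dict[tuple[int, int], SpikeTruth] = {
        t.intron: t for t in ref.truths
    }

    sam_paths: dict[str, Path] = {}
    sj_paths: dict[str, Path] = {}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": contig, "LN": len(genome)}],
        }
    )
    for sample in samples:
        condition = condition_of[sample]
        reads: list[_Read] = []
        junction_counts: dict[tuple[int, int], int] = {}
        rid = 0

        def add_junction_read(blocks: list[tuple[int, int]], flag: int = 0) -> None:
            nonlocal rid
            reads.append(_Read(f"{sample}.r{rid}", blocks[0][0], _spliced_cigar(blocks), flag))
            rid += 1
            if flag & 0x100 == 0:
                for (s1, e1), (s2, _) in zip(blocks[:-1], blocks[1:]):
                    key = (e1, s2)
                    junction_counts[key] = junction_counts.get(key, 0) + 1

        for gene in ref.genes:
            exs = gene.exons
            for i in range(len(exs) - 1):
                intron = (exs[i][1], exs[i + 1][0])
                depth = config.junction_depth
                truth = truth_by_intron.get(intron)
                k = 0
                if truth is not None:
                    psi = truth.psi_depletion if condition == "depletion" else truth.psi_control
                    k = int(rng.binomial(depth, psi))
                for _ in range(depth - k):
                    a = int(rng.integers(20, anchor + 1))
                    add_junction_read(
                        [
                            (intron[0] - a, intron[0]),
                            (intron[1], intron[1] + (2 * anchor - a)),
                        ]
                    )
                if truth is not None and k > 0:
                    c0, c1 = truth.start, truth.end
                    left_end, right_start = intron
                    if c0 > left_end and c1 < right_start:      # cassette, mid-intron
                        for _ in range(k):
                            a = int(rng.integers(20, anchor + 1))
                            add_junction_read(
                                [(left_end - a, left_end), (c0, c0 + (2 * anchor - a))]
                            )
                            add_junction_read(
                                [(c1 - a, c1), (right_start, right_start + (2 * anchor - a))]
                            )
                    elif c1 == right_start:                     # right-abutting extension
                        for _ in range(k):
                            a = int(rng.integers(20, anchor + 1))
                            add_junction_read(
                                [(left_end - a, left_end), (c0, c0 + (c1 - c0) + 30)]
                            )
                    elif c0 == left_end:                        # left-abutting extension
                        for _ in range(k):
                            add_junction_read(
                                [(c0 - 30, c1), (right_start, right_start + anchor)]
                            )
                if config.inject_secondary and gene.gene_id.endswith("0"):
                    add_junction_read(
                        [(intron[0] - anchor, intron[0]), (intron[1], intron[1] + anchor)],
                        flag=0x100,
                    )
            for s, e in exs:
                for _ in range(config.exon_depth):
                    pos = int(rng.integers(s, max(e - 100, s) + 1))
                    reads.append(_Read(f"{sample}.r{rid}", pos, f"{min(100, e - pos)}M"))
                    rid += 1
                if config.inject_duplicates:
                    reads.append(_Read(f"{sample}.r{rid}", s, f"{min(100, e - s)}M", 0x400))
                    rid += 1

        reads.sort(key=lambda r: r.pos)
        sam_path = out_dir / f"{sample}.sam"
        with pysam.AlignmentFile(str(sam_path), "wh", header=header) as af:
            for r in reads:
                seg = pysam.AlignedSegment(header)
                seg.query_name = r.name
                seg.flag = r.flag
                seg.reference_id = 0
                seg.reference_start = r.pos
                seg.mapping_quality = 255
                seg.cigarstring = r.cigar
                blocks, _ = _aligned_blocks(r.pos, r.cigar)
                seg.query_sequence = "".join(genome[s:e] for s, e in blocks)
                af.write(seg)
        sam_paths[sample] = sam_path

        sj_path = out_dir / f"{sample}.SJ.out.tab"
        junctions = [
            SpliceJunction(contig, d, a, _junction_strand(ref, d, a), n, sample)
            for (d, a), n in sorted(junction_counts.items())
        ]
        write_junction_table(junctions, sj_path)
        sj_paths[sample] = sj_path

    truth_path = out_dir / "truth.tsv"
    ref.truth_frame().to_csv(truth_path, sep="\t", index=False)
    return sam_paths, sj_paths, truth_path


def _aligned_blocks(pos: int, cigar: str) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    import re

    blocks, juncs = [], []
    ref = pos
    start = pos
    for length, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        length = int(length)
        if op in "M=X":
            ref += length
        elif op == "D":
            ref += length
        elif op == "N":
            blocks.append((start, ref))
            juncs.append((ref, ref + length))
            ref += length
            start = ref
    blocks.append((start, ref))
    return blocks, juncs


def _junction_strand(ref: SimulatedReference, donor_end: int, acceptor_start: int) -> str:
    for gene in ref.genes:
        if gene.block[0] <= donor_end < gene.block[1]:
            return gene.strand
    return "."


# ---------------------------------------------------------------------------
# auxiliary tracks
# ---------------------------------------------------------------------------

def simulate_peaks(
    ref: SimulatedReference,
    spiked_rbp: str = "RBP_SPIKED",
    n_uniform_rbps: int = 5,
    spike_fraction: float = 0.5,
    uniform_density: float = 1e-3,
    peak_width: int = 30,
    replicates: int = 2,
    seed: int | None = None,
) -> dict[str, list[PeakSet]]:
    """eCLIP-style peak sets: one RBP spiked onto a fraction of the true
    cryptic exons, the rest uniform over gene bodies."""
    rng = np.random.default_rng(seed if seed is not None else ref.config.seed + 2)
    contig = ref.config.contig
    out: dict[str, list[PeakSet]] = {}
    real = [t for t in ref.truths if not t.is_null_background]
    for rep in range(1, replicates + 1):
        chosen = rng.random(len(real)) < spike_fraction
        peaks = [
            GenomicInterval(contig, max(0, t.start - 10), t.start - 10 + peak_width)
            for t, c in zip(real, chosen)
            if c
        ]
        out.setdefault(spiked_rbp, []).append(
            PeakSet(spiked_rbp, str(rep), peaks, [p.start for p in peaks])
        )
    for i in range(n_uniform_rbps):
        name = f"RBP_{i:02d}"
        for rep in range(1, replicates + 1):
            n_peaks = rng.poisson(
                uniform_density * sum(g.block[1] - g.block[0] for g in ref.genes)
            )
            starts = []
            for _ in range(int(n_peaks)):
                g = ref.genes[int(rng.integers(len(ref.genes)))]
                starts.append(int(rng.integers(g.block[0], g.block[1] - peak_width)))
            peaks = [GenomicInterval(contig, s, s + peak_width) for s in sorted(starts)]
            out.setdefault(name, []).append(PeakSet(name, str(rep), peaks, [p.start for p in peaks]))
    return out


def simulate_repeats(
    ref: SimulatedReference,
    spike_family: str = "SINE",
    spike_orientation: str = "antisense",
    spike_fraction: float = 0.8,
    background_per_intron: float = 0.3,
    element_length: int = 120,
    seed: int | None = None,
) -> list[RepeatElement]:
    """Repeat elements spiked at cryptic loci plus a uniform background."""
    rng = np.random.default_rng(seed if seed is not None else ref.config.seed + 3)
    contig = ref.config.contig
    out: list[RepeatElement] = []
    for t in ref.truths:
        if t.is_null_background or rng.random() > spike_fraction:
            continue
        gene_strand = t.strand
        if spike_orientation == "antisense":
            es = "-" if gene_strand == "+" else "+"
        else:
            es = gene_strand
        mid = (t.start + t.end) // 2
        out.append(
            RepeatElement(
                GenomicInterval(contig, mid - element_length // 2, mid + element_length // 2),
                spike_family, f"{spike_family}_spike", es,
            )
        )
    families = ["LINE", "LTR", "DNA"]
    for gene in ref.genes:
        for i in range(len(gene.exons) - 1):
            if rng.random() < background_per_intron:
                lo, hi = gene.exons[i][1], gene.exons[i + 1][0]
                if hi - lo < element_length + 40:
                    continue
                s = int(rng.integers(lo + 20, hi - element_length - 20))
                fam = families[int(rng.integers(len(families)))]
                out.append(
                    RepeatElement(
                        GenomicInterval(contig, s, s + element_length),
                        fam, f"{fam}_bg", "+" if rng.random() < 0.5 else "-",
                    )
                )
    return out


def simulate_conservation(
    ref: SimulatedReference,
    exon_score: float = 2.0,
    background_score: float = 0.0,
    noise_sd: float = 0.1,
    bin_size: int = 25,
    seed: int | None = None,
) -> list[tuple[str, int, int, float]]:
    """bedGraph rows: high score over annotated exons, low elsewhere."""
    rng = np.random.default_rng(seed if seed is not None else ref.config.seed + 4)
    contig = ref.config.contig
    exonic = np.zeros(len(ref.genome[contig]), dtype=bool)
    for gene in ref.genes:
        for s, e in gene.exons:
            exonic[s:e] = True
    rows = []
    n = len(exonic)
    for s in range(0, n, bin_size):
        e = min(s + bin_size, n)
        base = exon_score if exonic[s:e].mean() > 0.5 else background_score
        rows.append((contig, s, e, float(base + rng.normal(0, noise_sd))))
    return rows


def write_bedgraph(rows: list[tuple[str, int, int, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, s, e, v in rows:
            fh.write(f"{contig}\t{s}\t{e}\t{v:.4f}\n")


# ---------------------------------------------------------------------------
# truth evaluation
# ---------------------------------------------------------------------------

def end_to_end_truth_eval(
    final_exons: list[CrypticExon],
    truth: pd.DataFrame,
) -> dict:
    """Precision/recall/ΔPSI-error of a pipeline run against planted truth.

    A discovered exon matches a planted one when their intervals overlap
    and the class agrees.  Null-background events count as false positives
    if called.
    """
    spiked = truth[~truth["null_background"]]
    matches: dict[str, CrypticExon] = {}
    false_positives: list[CrypticExon] = []
    for ex in final_exons:
        iv = ex.tag.interval
        hits = [
            d for d in spiked.to_dict("records")
            if d["contig"] == iv.contig and d["start"] < iv.end and d["end"] > iv.start
        ]
        matched_id = None
        for d in hits:
            if d["class"] == ex.exon_class and d["spike_id"] not in matches:
                matched_id = d["spike_id"]
                break
        if matched_id is not None:
            matches[matched_id] = ex
        else:
            false_positives.append(ex)
    dpsi_errors = []
    for spike_id, ex in matches.items():
        true_dpsi = float(spiked.set_index("spike_id").loc[spike_id, "delta_psi"])
        measured = ex.headline_delta_psi()
        if np.isfinite(measured):
            dpsi_errors.append(abs(measured - true_dpsi))
    n_true = len(spiked)
    recall = len(matches) / n_true if n_true else float("nan")
    return {
        "n_true": n_true,
        "n_detected": len(final_exons),
        "n_matched": len(matches),
        "recall": recall,
        "false_positives": len(false_positives),
        "false_positive_ids": [ex.exon_id for ex in false_positives],
        "mean_abs_delta_psi_error": float(np.mean(dpsi_errors)) if dpsi_errors else float("nan"),
    }
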