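"""Predicted consequence of cassette cryptic-exon inclusion on coding.

For each cassette exon falling inside the coding sequence of a transcript,
the transcript is rebuilt with and without the cryptic sequence and
translated in silico.  The cryptic exon can shift the downstream reading
frame (length not a multiple of 3), introduce a premature termination
codon (PTC: a stop upstream of the annotated stop), and either trigger
nonsense-mediated decay or escape it — a PTC within 50 nt of the final
exon-exon junction (inclusive), or downstream of it, escapes NMD and
yields a truncated protein.  Seven mutually exclusive outcome categories
cover the combinations; a random-sequence null with the same length
distribution calibrates how surprising the observed category mix is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .annotation_io import FlattenedAnnotation, GenomeSequence, TranscriptModel
from .classification import CrypticExon
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

CATEGORIES = (
    "frameshift_only",
    "frameshift_and_ptc",
    "ptc_only",
    "frameshift_ptc_escape_truncated_novel",
    "ptc_escape_truncated",
    "frameshift_no_ptc_novel_protein",
    "benign_cassette",
)

NMD_ESCAPE_WINDOW = 50  # nt upstream of the final exon-exon junction, inclusive

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class CassetteContext:
    """Everything needed to classify one cassette exon's inclusion variant.

    Sequences are in transcript (mRNA, 5'->3') orientation, DNA alphabet.
    The cryptic sequence is inserted between ``prefix`` and ``suffix``.
    """

    exon_id: str
    transcript_id: str
    prefix: str                 # mRNA upstream of the insertion point
    suffix: str                 # mRNA downstream of it
    cryptic_seq: str
    cds_offset: int             # index of the CDS start in the mRNA
    last_exon_length: int       # of the annotated transcript
    insertion_phase: int        # codon phase at the insertion point

    @property
    def cryptic_length(self) -> int:
        return len(self.cryptic_seq)


@dataclass
class OutcomeCall:
    exon_id: str
    category: str
    ptc_positions: list[int] = field(default_factory=list)  # mRNA codon starts
    first_ptc_to_last_junction: float = float("nan")        # nt, + = upstream
    frameshift: bool = False
    has_ptc: bool = False
    nmd_escape: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def resolve_flanking_exons(
    exon: CrypticExon, flattened: FlattenedAnnotation
) -> tuple[TranscriptModel, GenomicInterval, GenomicInterval, int] | None:
    """Match the cryptic exon to a coding transcript and insertion frame.

    The host intron must sit between two consecutive exons of a coding
    transcript and inside its CDS span; among several matching transcripts
    the one with the longest CDS wins.  Returns (transcript, genomically
    left exon, right exon, codon phase at the insertion point) or None for
    a non-coding context.
    """
    intron = exon.host_intron
    best: tuple[int, TranscriptModel, GenomicInterval, GenomicInterval] | None = None
    for tx in flattened.transcripts_of(exon.tag.gene_id):
        if not tx.is_coding:
            continue
        if not (tx.cds_start <= intron.start and intron.end <= tx.cds_end):
            continue
        for left, right in zip(tx.exons[:-1], tx.exons[1:]):
            if left.end == intron.start and right.start == intron.end:
                cds_len = tx.cds_length()
                if best is None or cds_len > best[0]:
                    best = (cds_len, tx, left, right)
                break
    if best is None:
        logger.info("%s: non-coding context, omitted", exon.exon_id)
        return None
    _, tx, left, right = best
    # codon phase at the insertion point: CDS nucleotides 5' of the intron
    if tx.strand == "-":
        cds_before = sum(
            max(0, min(e.end, tx.cds_end) - max(e.start, tx.cds_start))
            for e in tx.exons
            if e.start >= intron.end
        )
    else:
        cds_before = sum(
            max(0, min(e.end, tx.cds_end) - max(e.start, tx.cds_start))
            for e in tx.exons
            if e.end <= intron.start
        )
    return tx, left, right, cds_before % 3


def build_context(
    exon: CrypticExon,
    tx: TranscriptModel,
    genome: GenomeSequence,
    phase: int,
) -> CassetteContext:
    """Assemble the transcript-orientation sequence pieces for one exon."""
    strand = tx.strand
    order = list(tx.exons) if strand != "-" else list(reversed(tx.exons))
    intron = exon.host_intron
    # transcript-order index of the exon 5' of the insertion point
    idx = None
    for i, e in enumerate(order):
        if (strand != "-" and e.end == intron.start) or (
            strand == "-" and e.start == intron.end
        ):
            idx = i
            break
    if idx is None:
        raise ValueError("host intron does not adjoin the transcript's exons")

    def seq_of(iv: GenomicInterval) -> str:
        return genome.fetch(GenomicInterval(iv.contig, iv.start, iv.end, strand))

    prefix = "".join(seq_of(e) for e in order[: idx + 1])
    suffix = "".join(seq_of(e) for e in order[idx + 1 :])
    cryptic_seq = genome.fetch(
        GenomicInterval(
            exon.tag.interval.contig, exon.tag.interval.start, exon.tag.interval.end, strand
        )
    )
    # CDS start offset in mRNA coordinates
    cds_offset = 0
    for e in order:
        if strand != "-":
            if e.end <= tx.cds_start:
                cds_offset += len(e)
            elif e.start <= tx.cds_start:
                cds_offset += tx.cds_start - e.start
                break
            else:
                break
        else:
            if e.start >= tx.cds_end:
                cds_offset += len(e)
            elif e.end >= tx.cds_end:
                cds_offset += e.end - tx.cds_end
                break
            else:
                break
    return CassetteContext(
        exon.exon_id, tx.transcript_id, prefix, suffix, cryptic_seq,
        cds_offset, len(order[-1]), phase,
    )


def _stop_scan(mrna: str, cds_offset: int) -> list[int]:
    """Codon-start positions of every in-frame stop, via Biopython."""
    coding = mrna[cds_offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    protein = str(Seq(coding).translate())
    return [cds_offset + 3 * i for i, aa in enumerate(protein) if aa == "*"]


def classify_outcome(ctx: CassetteContext, cryptic_seq: str | None = None) -> OutcomeCall:
    """Assign one of the seven outcome categories to an inclusion variant.

    ``cryptic_seq`` overrides the context's own sequence (used by the
    random-sequence null).  A PTC located within the cryptic exon itself
    distinguishes ``frameshift_and_ptc`` from plain ``frameshift_only``
    (where the shift creates the stop downstream).
    """
    seq = (cryptic_seq if cryptic_seq is not None else ctx.cryptic_seq).upper()
    frameshift = len(seq) % 3 != 0
    excl = ctx.prefix + ctx.suffix
    incl = ctx.prefix + seq + ctx.suffix

    excl_stops = _stop_scan(excl, ctx.cds_offset)
    annotated_stop_excl = excl_stops[0] if excl_stops else len(excl)
    annotated_stop_incl = annotated_stop_excl + len(seq)

    incl_stops = _stop_scan(incl, ctx.cds_offset)
    ptcs = [s for s in incl_stops if s < annotated_stop_incl]
    has_ptc = bool(ptcs)

    last_junction_incl = len(incl) - ctx.last_exon_length
    escape = False
    dist = float("nan")
    if has_ptc:
        dist = last_junction_incl - ptcs[0]
        escape = dist <= NMD_ESCAPE_WINDOW

    cryptic_span = (len(ctx.prefix), len(ctx.prefix) + len(seq))
    if not frameshift:
        if not has_ptc:
            cat = "benign_cassette"
        elif escape:
            cat = "ptc_escape_truncated"
        else:
            cat = "ptc_only"
    else:
        if not has_ptc:
            cat = "frameshift_no_ptc_novel_protein"
        elif escape:
            cat = "frameshift_ptc_escape_truncated_novel"
        elif ptcs[0] < cryptic_span[1] and ptcs[0] + 3 > cryptic_span[0]:
            cat = "frameshift_and_ptc"
        else:
            cat = "frameshift_only"
    return OutcomeCall(ctx.exon_id, cat, ptcs, dist, frameshift, has_ptc, escape)


def null_outcome_distribution(
    contexts: list[CassetteContext],
    reps: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Category proportions for random cryptic sequences, per replicate.

    Each replicate replaces every real cryptic sequence with uniform random
    nucleotides of identical length and re-classifies, preserving the
    observed length distribution exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    bases = np.array(list("ACGT"))
    for rep in range(reps):
        tally = {c: 0 for c in CATEGORIES}
        for ctx in contexts:
            rand = "".join(rng.choice(bases, size=ctx.cryptic_length))
            tally[classify_outcome(ctx, rand).category] += 1
        n = max(len(contexts), 1)
        rows.append({c: tally[c] / n for c in CATEGORIES} | {"rep": rep})
    return pd.DataFrame(rows).set_index("rep")


# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------

def _brute_force_category(ctx: CassetteContext, cryptic_seq: str) -> str:
    """Category via a plain codon-by-codon scan, independent of Biopython."""
    seq = cryptic_seq.upper()
    excl = (ctx.prefix + ctx.suffix).upper()
    incl = (ctx.prefix + seq + ctx.suffix).upper()

    def first_stop(mrna: str) -> int | None:
        for pos in range(ctx.cds_offset, len(mrna) - 2, 3):
            if mrna[pos : pos + 3] in STOP_CODONS:
                return pos
        return None

    def all_stops(mrna: str) -> list[int]:
        return [
            pos
            for pos in range(ctx.cds_offset, len(mrna) - 2, 3)
            if mrna[pos : pos + 3] in STOP_CODONS
        ]

    s0 = first_stop(excl)
    annotated = (s0 if s0 is not None else len(excl)) + len(seq)
    ptcs = [s for s in all_stops(incl) if s < annotated]
    frameshift = len(seq) % 3 != 0
    if not ptcs:
        return "frameshift_no_ptc_novel_protein" if frameshift else "benign_cassette"
    last_junction = len(incl) - ctx.last_exon_length
    escape = last_junction - ptcs[0] <= NMD_ESCAPE_WINDOW
    if not frameshift:
        return "ptc_escape_truncated" if escape else "ptc_only"
    if escape:
        return "frameshift_ptc_escape_truncated_novel"
    lo, hi = len(ctx.prefix), len(ctx.prefix) + len(seq)
    if ptcs[0] < hi and ptcs[0] + 3 > lo:
        return "frameshift_and_ptc"
    return "frameshift_only"


def oracle_check(
    contexts: list[CassetteContext],
    sequences: list[str] | None = None,
) -> pd.DataFrame:
    """Compare the classifier against the brute-force translator.

    Raises ``AssertionError`` on any disagreement; returns the per-input
    agreement report otherwise.
    """
    rows = []
    for i, ctx in enumerate(contexts):
        seq = sequences[i] if sequences is not None else ctx.cryptic_seq
        a = classify_outcome(ctx, seq).category
        b = _brute_force_category(ctx, seq)
        rows.append({"exon_id": ctx.exon_id, "classifier": a, "oracle": b, "agree": a == b})
    report = pd.DataFrame(rows)
    if not report.empty and not report["agree"].all():
        bad = report[~report["agree"]]
        raise AssertionError(
            f"classifier disagrees with brute-force oracle on {len(bad)} input(s):\n{bad}"
        )
    return report
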