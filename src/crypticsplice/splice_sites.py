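"""Splice-site extraction and strength scoring.

A 5' (donor) site is the last 3 exonic nucleotides plus the first 6
intronic ones — a 9-mer whose intronic positions 4-5 are the invariant GT.
A 3' (acceptor) site is the last 20 intronic nucleotides (ending in the
invariant AG) plus the first 3 exonic ones — a 23-mer.  Sites are scored
with a position log-odds model (a PWM with pseudocount 1 against a uniform
background, log2 units) trained on annotated sites.  The absolute scores
are model-specific and not comparable to maximum-entropy scorers; an
adapter accepts externally computed score tables for parity runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation_io import FlattenedAnnotation, GenomeSequence
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

DONOR_LENGTH = 9        # 3 exonic + 6 intronic, GT at positions 4-5 (1-based)
ACCEPTOR_LENGTH = 23    # 20 intronic + 3 exonic, AG at positions 19-20
KINDS = ("donor_9mer", "acceptor_23mer")
_LEN = {"donor_9mer": DONOR_LENGTH, "acceptor_23mer": ACCEPTOR_LENGTH}
_BASES = "ACGT"


@dataclass(frozen=True)
class SpliceSiteSeq:
    kind: str
    sequence: str          # DNA alphabet, gene-strand orientation
    origin: str            # cryptic | canonical | random
    site_id: str = ""

    @property
    def is_consensus(self) -> bool:
        s = self.sequence.upper()
        if self.kind == "donor_9mer":
            return len(s) == DONOR_LENGTH and s[3:5] == "GT"
        return len(s) == ACCEPTOR_LENGTH and s[18:20] == "AG"


@dataclass(frozen=True)
class SiteScore:
    site: SpliceSiteSeq
    score: float           # log2 odds vs uniform background
    model_id: str


@dataclass
class PositionLogOddsModel:
    kind: str
    log_odds: np.ndarray   # 4 x L, log2(freq / 0.25)
    model_id: str = "pwm"
    n_training: int = 0

    def score(self, site: SpliceSiteSeq) -> SiteScore:
        s = site.sequence.upper()
        if site.kind != self.kind or len(s) != self.log_odds.shape[1]:
            raise ValueError(
                f"model {self.kind} cannot score a {site.kind} of length {len(s)}"
            )
        total = 0.0
        for i, base in enumerate(s):
            j = _BASES.find(base)
            if j >= 0:
                total += self.log_odds[j, i]
        return SiteScore(site, float(total), self.model_id)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.log_odds, index=list(_BASES))
        df.attrs["kind"] = self.kind
        return df


def extract_donor_site(
    genome: GenomeSequence, contig: str, exon_end: int, strand: str
) -> SpliceSiteSeq:
    """Donor 9-mer at an exon/intron boundary (genomic-left exon for +)."""
    if strand == "-":
        iv = GenomicInterval(contig, exon_end - 6, exon_end + 3, "-")
    else:
        iv = GenomicInterval(contig, exon_end - 3, exon_end + 6, "+")
    return SpliceSiteSeq("donor_9mer", genome.fetch(iv), "canonical")


def extract_acceptor_site(
    genome: GenomeSequence, contig: str, exon_start: int, strand: str
) -> SpliceSiteSeq:
    """Acceptor 23-mer at an intron/exon boundary."""
    if strand == "-":
        iv = GenomicInterval(contig, exon_start - 3, exon_start + 20, "-")
    else:
        iv = GenomicInterval(contig, exon_start - 20, exon_start + 3, "+")
    return SpliceSiteSeq("acceptor_23mer", genome.fetch(iv), "canonical")


def extract_sites(
    genome: GenomeSequence,
    exon: GenomicInterval,
    strand: str,
    origin: str = "cryptic",
) -> dict[str, SpliceSiteSeq]:
    """Both splice sites of an exon, transcript-orientation aware.

    The exon's 5' (acceptor) side is its genomic start on + genes and its
    genomic end on - genes.
    """
    contig = exon.contig
    if strand == "-":
        donor = extract_donor_site(genome, contig, exon.start, "-")
        acceptor = extract_acceptor_site(genome, contig, exon.end, "-")
    else:
        donor = extract_donor_site(genome, contig, exon.end, "+")
        acceptor = extract_acceptor_site(genome, contig, exon.start, "+")
    return {
        "donor_9mer": SpliceSiteSeq("donor_9mer", donor.sequence, origin),
        "acceptor_23mer": SpliceSiteSeq("acceptor_23mer", acceptor.sequence, origin),
    }


def train_site_model(
    sites: list[SpliceSiteSeq], kind: str, min_sites: int = 50
) -> PositionLogOddsModel:
    """Per-position log2 odds against a uniform background, pseudocount 1.

    Non-consensus sites (missing the invariant GT/AG) are excluded from
    training with a log message.
    """
    usable = [s for s in sites if s.kind == kind and s.is_consensus]
    dropped = sum(1 for s in sites if s.kind == kind) - len(usable)
    if dropped:
        logger.info("excluded %d non-consensus %s training sites", dropped, kind)
    if len(usable) < min_sites:
        raise ValueError(
            f"need >= {min_sites} consensus-valid {kind} training sites, got {len(usable)}"
        )
    L = _LEN[kind]
    counts = np.ones((4, L))  # pseudocount 1
    for s in usable:
        for i, base in enumerate(s.sequence.upper()):
            j = _BASES.find(base)
            if j >= 0:
                counts[j, i] += 1
    freqs = counts / counts.sum(axis=0, keepdims=True)
    return PositionLogOddsModel(kind, np.log2(freqs / 0.25), n_training=len(usable))


def score_site(model: PositionLogOddsModel, site: SpliceSiteSeq) -> SiteScore:
    return model.score(site)


def random_baseline(
    kind: str, n: int, rng: np.random.Generator | int | None = None
) -> list[SpliceSiteSeq]:
    """Uniform random sites with the invariant GT/AG dinucleotide fixed."""
    rng = np.random.default_rng(rng)
    L = _LEN[kind]
    bases = np.array(list(_BASES))
    out = []
    for i in range(n):
        s = list(rng.choice(bases, size=L))
        if kind == "donor_9mer":
            s[3:5] = ["G", "T"]
        else:
            s[18:20] = ["A", "G"]
        out.append(SpliceSiteSeq(kind, "".join(s), "random", f"random{i}"))
    return out


@dataclass
class PairedComparison:
    exon_class: str
    side: str
    n_pairs: int
    n_dropped: int
    t_statistic: float
    p_value: float
    direction: str      # "canonical_stronger" | "cryptic_stronger" | "none"
    degenerate: bool = False


def paired_comparison(
    pairs: list[tuple[float, float]],
    exon_class: str,
    side: str,
    n_dropped: int = 0,
) -> PairedComparison:
    """Paired t-test of cryptic vs matched canonical site scores.

    ``pairs`` holds (cryptic score, canonical score) per exon; pairs with a
    missing partner should be dropped by the caller and counted via
    ``n_dropped``.  Zero-variance differences are reported as degenerate
    rather than crashing.
    """
    if not pairs:
        return PairedComparison(exon_class, side, 0, n_dropped, float("nan"), float("nan"), "none", True)
    cryptic = np.array([a for a, _ in pairs], dtype=float)
    canonical = np.array([b for _, b in pairs], dtype=float)
    diff = cryptic - canonical
    if len(pairs) < 2 or np.allclose(diff.std(ddof=1), 0.0):
        direction = (
            "canonical_stronger" if diff.mean() < 0
            else "cryptic_stronger" if diff.mean() > 0 else "none"
        )
        p = 1.0 if np.allclose(diff, 0.0) else float("nan")
        return PairedComparison(exon_class, side, len(pairs), n_dropped, float("nan"), p, direction, True)
    t = sps.ttest_rel(cryptic, canonical)
    direction = (
        "canonical_stronger" if diff.mean() < 0
        else "cryptic_stronger" if diff.mean() > 0 else "none"
    )
    return PairedComparison(
        exon_class, side, len(pairs), n_dropped, float(t.statistic), float(t.pvalue), direction
    )


def annotated_internal_sites(
    flattened: FlattenedAnnotation, genome: GenomeSequence
) -> dict[str, list[SpliceSiteSeq]]:
    """Donor and acceptor sites of all internal exons of coding transcripts.

    This is the default training and positive-control set for the scorer.
    """
    donors: list[SpliceSiteSeq] = []
    acceptors: list[SpliceSiteSeq] = []
    seen: set[tuple[str, str, int]] = set()
    for tx in flattened.transcripts.values():
        if len(tx.exons) < 3:
            continue
        internal = tx.exons[1:-1]
        for e in internal:
            sites = extract_sites(genome, e, tx.strand, origin="canonical")
            for key_pos, site in (
                ((tx.strand, e.contig, e.start), sites["acceptor_23mer"]),
                ((tx.strand, e.contig, e.end), sites["donor_9mer"]),
            ):
                key = (site.kind,) + key_pos[1:]
                if key not in seen:
                    seen.add(key)
                    (donors if site.kind == "donor_9mer" else acceptors).append(site)
    return {"donor_9mer": donors, "acceptor_23mer": acceptors}


def import_site_scores(path: str | Path) -> pd.DataFrame:
    """Adapter for externally computed splice-site scores.

    Expects a TSV with columns ``site_id``, ``kind``, ``origin``,
    ``score``; returned verbatim for use in the paired comparisons.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"site_id", "kind", "origin", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"imported scores must carry columns {sorted(required)}")
    return df
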