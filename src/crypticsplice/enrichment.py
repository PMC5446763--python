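"""Binding, repeat and sequence-composition enrichment of cryptic exons.

The central design is the length-matched null: each cryptic exon, flanked
by 100 nt to capture binding around its splice sites, is compared against
random intervals of identical length drawn either from the remainder of
its host intron or from an adjacent intron of the same gene (100 draws per
exon per mode).  Enrichment is a two-proportion test of "overlaps at least
one peak/element", Bonferroni-corrected across the tests of a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .annotation_io import GenomeSequence, PeakSet, RepeatElement
from .classification import CrypticExon
from .intervals import GenomicInterval
from .stats import bonferroni, significance_tier, two_proportion_test

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 100
DEFAULT_N_NULL = 100
NULL_MODES = ("same_intron", "adjacent_intron")


@dataclass(frozen=True)
class NullExonDraw:
    source_exon_id: str
    mode: str
    interval: GenomicInterval
    draw_index: int


@dataclass
class EnrichmentResult:
    label: str
    cryptic_proportion: float
    null_proportions: dict[str, float]
    fold_changes: dict[str, float]
    p_values: dict[str, float]
    adjusted_p: dict[str, float] = field(default_factory=dict)
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def tier(self, mode: str) -> str:
        return significance_tier(self.adjusted_p.get(mode, 1.0))


def flank(
    intervals: list[GenomicInterval],
    pad: int = DEFAULT_FLANK,
    contig_lengths: dict[str, int] | None = None,
) -> list[GenomicInterval]:
    """Pad each interval by ``pad`` nt on both sides, clipped at contig bounds."""
    out = []
    for iv in intervals:
        clen = contig_lengths.get(iv.contig) if contig_lengths else None
        out.append(iv.padded(pad, clen))
    return out


def _admissible_starts(
    region: GenomicInterval, length: int, exclude: GenomicInterval | None
) -> list[tuple[int, int]]:
    """Half-open ranges of admissible draw start positions."""
    lo, hi = region.start, region.end - length + 1
    if hi <= lo:
        return []
    if exclude is None or exclude.contig != region.contig:
        return [(lo, hi)]
    ranges = []
    # start early enough that the draw ends before the excluded interval
    a_hi = min(hi, exclude.start - length + 1)
    if a_hi > lo:
        ranges.append((lo, a_hi))
    b_lo = max(lo, exclude.end)
    if hi > b_lo:
        ranges.append((b_lo, hi))
    return ranges


def sample_null(
    exon_id: str,
    flanked: GenomicInterval,
    host_intron: GenomicInterval,
    adjacent_introns: list[GenomicInterval],
    n: int = DEFAULT_N_NULL,
    rng: np.random.Generator | int | None = None,
) -> list[NullExonDraw]:
    """Length-matched null draws for one flanked exon, both modes.

    ``same_intron`` draws come from the host intron and never overlap the
    flanked exon; ``adjacent_intron`` draws pick a fitting adjacent intron
    uniformly per draw.  Exons whose length cannot fit yield fewer draws
    (the deficit is logged); absent adjacent introns skip that mode.
    """
    rng = np.random.default_rng(rng)
    length = len(flanked)
    draws: list[NullExonDraw] = []

    ranges = _admissible_starts(host_intron, length, flanked)
    total = sum(b - a for a, b in ranges)
    if total > 0:
        offsets = rng.integers(0, total, size=n)
        for i, off in enumerate(offsets, 1):
            for a, b in ranges:
                if off < b - a:
                    s = a + int(off)
                    break
                off -= b - a
            draws.append(
                NullExonDraw(
                    exon_id, "same_intron",
                    GenomicInterval(host_intron.contig, s, s + length, flanked.strand),
                    i,
                )
            )
    else:
        logger.info("%s: no room for same-intron nulls (length %d)", exon_id, length)

    fitting = [a for a in adjacent_introns if len(a) >= length]
    if fitting:
        which = rng.integers(0, len(fitting), size=n)
        for i, w in enumerate(which, 1):
            a = fitting[int(w)]
            s = int(rng.integers(a.start, a.end - length + 1))
            draws.append(
                NullExonDraw(
                    exon_id, "adjacent_intron",
                    GenomicInterval(a.contig, s, s + length, flanked.strand),
                    i,
                )
            )
    elif adjacent_introns:
        logger.info("%s: adjacent introns too short for length %d", exon_id, length)
    return draws


def _peak_tree(peaks: PeakSet, use_point: bool = False) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    items = (
        [GenomicInterval(p.contig, pt, pt + 1) for p, pt in zip(peaks.peaks, peaks.peak_points)]
        if use_point
        else peaks.peaks
    )
    for iv in items:
        trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _overlap_fraction(
    intervals: list[GenomicInterval], trees: dict[str, IntervalTree]
) -> tuple[int, int]:
    k = sum(
        1 for iv in intervals
        if iv.contig in trees and trees[iv.contig].overlap(iv.start, iv.end)
    )
    return k, len(intervals)


def overlap_test(
    flanked_exons: list[GenomicInterval],
    null_draws: list[NullExonDraw],
    peaks: PeakSet,
    label: str | None = None,
    use_peak_point: bool = False,
) -> EnrichmentResult:
    """Proportion of exons overlapping >=1 peak versus both null modes."""
    trees = _peak_tree(peaks, use_peak_point)
    k_c, n_c = _overlap_fraction(flanked_exons, trees)
    prop_c = k_c / n_c if n_c else 0.0
    null_props, folds, ps, counts = {}, {}, {}, {"cryptic": (k_c, n_c)}
    for mode in NULL_MODES:
        dr = [d.interval for d in null_draws if d.mode == mode]
        if not dr:
            continue
        k_n, n_n = _overlap_fraction(dr, trees)
        prop_n = k_n / n_n
        null_props[mode] = prop_n
        folds[mode] = prop_c / prop_n if prop_n > 0 else float("inf") if prop_c > 0 else 1.0
        counts[mode] = (k_n, n_n)
        if not peaks.peaks:
            continue
        ps[mode] = two_proportion_test(k_c, n_c, k_n, n_n).p_value
    return EnrichmentResult(label or peaks.name, prop_c, null_props, folds, ps, counts=counts)


def eclip_screen(
    flanked_exons: list[GenomicInterval],
    null_draws: list[NullExonDraw],
    peaksets_by_rbp: dict[str, list[PeakSet]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Worst-case per-RBP screen over replicates and null modes.

    For each RBP the *highest* p-value over (replicates x null modes) is
    kept and Bonferroni-corrected across RBPs; only a protein whose every
    test is significant can pass.  Returns one row per RBP with the max p,
    the adjusted p and a ``passes`` flag at ``alpha``.
    """
    rows = []
    for rbp, replicates in sorted(peaksets_by_rbp.items()):
        worst = 0.0
        details = {}
        for ps in replicates:
            res = overlap_test(flanked_exons, null_draws, ps, label=rbp)
            for mode, p in res.p_values.items():
                details[f"{ps.replicate}:{mode}"] = p
                worst = max(worst, p)
            if not res.p_values:
                worst = 1.0
        rows.append({"rbp": rbp, "max_p": worst, "n_tests": len(details)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(adjusted_p=[], passes=[])
    df["adjusted_p"] = bonferroni(df["max_p"], m=len(df))
    df["passes"] = df["adjusted_p"] < alpha
    return df.sort_values("adjusted_p").reset_index(drop=True)


def cluster_rbps(overlap_matrix: pd.DataFrame):
    """Hierarchical clustering of RBPs by their exon-overlap profiles.

    Rows are RBPs, columns exons, entries {0,1}.  Jaccard distance with
    complete linkage; returns (linkage matrix, leaf-ordered RBP labels,
    reordered matrix).  Leaf order is deterministic for a given input.
    """
    if overlap_matrix.shape[0] < 2:
        raise ValueError("need at least two RBPs to cluster")
    x = overlap_matrix.to_numpy(dtype=bool)
    dist = pdist(x, metric="jaccard")
    z = hierarchy.linkage(dist, method="complete")
    order = hierarchy.leaves_list(z)
    labels = [overlap_matrix.index[i] for i in order]
    return z, labels, overlap_matrix.iloc[order]


def binary_overlap_matrix(
    flanked_exons: list[GenomicInterval],
    exon_ids: list[str],
    peaksets_by_rbp: dict[str, list[PeakSet]],
) -> pd.DataFrame:
    """Exon x RBP 0/1 overlap matrix (any replicate counts), RBPs as rows."""
    data = {}
    for rbp, replicates in sorted(peaksets_by_rbp.items()):
        hit = np.zeros(len(flanked_exons), dtype=int)
        for ps in replicates:
            trees = _peak_tree(ps)
            for i, iv in enumerate(flanked_exons):
                if iv.contig in trees and trees[iv.contig].overlap(iv.start, iv.end):
                    hit[i] = 1
        data[rbp] = hit
    return pd.DataFrame(data, index=exon_ids).T


DINUCLEOTIDES = [a + b for a in "ACGU" for b in "ACGU"]


def _dinucleotide_counts(seqs: list[str]) -> tuple[dict[str, int], int]:
    counts = {d: 0 for d in DINUCLEOTIDES}
    total = 0
    for s in seqs:
        s = s.upper().replace("T", "U")
        for i in range(len(s) - 1):
            d = s[i : i + 2]
            if d in counts:
                counts[d] += 1
                total += 1
    return counts, total


def dinucleotide_enrichment(
    cryptic_seqs: list[str], background_seqs: list[str]
) -> list[EnrichmentResult]:
    """Overlapping-window dinucleotide frequencies, cryptic vs background.

    The background is meant to be the adjacent-intron sequence of the same
    genes.  Frequencies are counts over all dinucleotide positions of each
    set; each of the 16 dinucleotides gets a two-proportion test and a
    Bonferroni x16 adjustment.
    """
    c_counts, c_tot = _dinucleotide_counts(cryptic_seqs)
    b_counts, b_tot = _dinucleotide_counts(background_seqs)
    results = []
    raw_ps = []
    for d in DINUCLEOTIDES:
        fc = c_counts[d] / c_tot if c_tot else 0.0
        fb = b_counts[d] / b_tot if b_tot else 0.0
        fold = fc / fb if fb > 0 else float("inf") if fc > 0 else 1.0
        p = (
            two_proportion_test(c_counts[d], c_tot, b_counts[d], b_tot, exact_fallback=False).p_value
            if c_tot and b_tot
            else 1.0
        )
        raw_ps.append(p)
        results.append(
            EnrichmentResult(
                d, fc, {"background": fb}, {"background": fold}, {"background": p},
                counts={"cryptic": (c_counts[d], c_tot), "background": (b_counts[d], b_tot)},
            )
        )
    adj = bonferroni(raw_ps, m=16)
    for r, a in zip(results, adj):
        r.adjusted_p["background"] = float(a)
    return results


def repeat_overlap(
    flanked_exons: list[GenomicInterval],
    gene_strands: list[str],
    null_draws: list[NullExonDraw],
    null_strands: dict[str, str],
    repeats: list[RepeatElement],
) -> list[EnrichmentResult]:
    """Per repeat family x orientation enrichment against both null modes.

    Orientation is sense when the element strand equals the gene strand,
    antisense otherwise, and "unoriented" for unstranded genes.  Families
    are disjoint: Alu elements are excluded from the SINE tally.
    """
    trees: dict[tuple[str, str], dict[str, IntervalTree]] = {}
    for r in repeats:
        key = (r.family, r.element_strand)
        trees.setdefault(key, {}).setdefault(r.interval.contig, IntervalTree()).addi(
            r.interval.start, r.interval.end
        )

    def orientation(gene_strand: str, element_strand: str) -> str:
        if gene_strand not in "+-":
            return "unoriented"
        return "sense" if gene_strand == element_strand else "antisense"

    def hit_fraction(ivs: list[GenomicInterval], strands: list[str], family: str, orient: str):
        k = 0
        for iv, gs in zip(ivs, strands):
            found = False
            for es in "+-":
                if orientation(gs, es) != orient:
                    continue
                t = trees.get((family, es), {}).get(iv.contig)
                if t is not None and t.overlap(iv.start, iv.end):
                    found = True
                    break
            k += found
        return k, len(ivs)

    families = [f for f in ("LINE", "SINE", "Alu", "LTR", "DNA", "Simple_repeat", "Low_complexity")]
    orients = ["sense", "antisense"]
    if any(s not in "+-" for s in gene_strands):
        orients.append("unoriented")
    results = []
    raw = []
    for fam in families:
        for orient in orients:
            k_c, n_c = hit_fraction(flanked_exons, gene_strands, fam, orient)
            prop_c = k_c / n_c if n_c else 0.0
            null_props, folds, ps = {}, {}, {}
            counts = {"cryptic": (k_c, n_c)}
            for mode in NULL_MODES:
                dr = [d for d in null_draws if d.mode == mode]
                if not dr:
                    continue
                ivs = [d.interval for d in dr]
                sts = [null_strands.get(d.source_exon_id, ".") for d in dr]
                k_n, n_n = hit_fraction(ivs, sts, fam, orient)
                prop_n = k_n / n_n if n_n else 0.0
                null_props[mode] = prop_n
                folds[mode] = prop_c / prop_n if prop_n > 0 else float("inf") if prop_c > 0 else 1.0
                counts[mode] = (k_n, n_n)
                ps[mode] = two_proportion_test(k_c, n_c, k_n, n_n).p_value
            res = EnrichmentResult(f"{fam}:{orient}", prop_c, null_props, folds, ps, counts=counts)
            results.append(res)
            raw.extend((res, m, p) for m, p in ps.items())
    m = len(raw)
    for res, mode, p in raw:
        res.adjusted_p[mode] = float(min(p * m, 1.0))
    return results


def export_flanked_fasta(
    exons: list[CrypticExon],
    genome: GenomeSequence,
    path: str | Path,
    pad: int = DEFAULT_FLANK,
) -> None:
    """Write gene-strand sequences of flanked exons for external motif tools.

    Headers carry id, class and coordinates and parse back to an interval:
    ``>{exon_id}|{class}|{contig}:{start}-{end}({strand})``.
    """
    with open(path, "w") as fh:
        for ex in exons:
            iv = ex.tag.interval.padded(pad, genome.contig_length(ex.tag.interval.contig))
            strand = ex.host_intron.strand if ex.host_intron.strand in "+-" else "+"
            siv = GenomicInterval(iv.contig, iv.start, iv.end, strand)
            seq = genome.fetch(siv)
            fh.write(
                f">{ex.exon_id}|{ex.exon_class}|{iv.contig}:{iv.start}-{iv.end}({strand})\n"
            )
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def parse_flanked_header(header: str) -> tuple[str, str, GenomicInterval]:
    """Inverse of the FASTA header written by :func:`export_flanked_fasta`."""
    import re

    exon_id, cls, loc = header.lstrip(">").split("|")
    m = re.fullmatch(r"(.+):(\d+)-(\d+)\(([+-.])\)", loc)
    if m is None:
        raise ValueError(f"unparseable flanked-FASTA header: {header!r}")
    return exon_id, cls, GenomicInterval(m[1], int(m[2]), int(m[3]), m[4])
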