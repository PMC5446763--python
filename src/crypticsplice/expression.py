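"""Gene-level expression analysis around cryptic-exon genes.

The bespoke statistic here is the expression-matched hypergeometric
enrichment: among genes expressed at least as highly as the least-expressed
cryptic-exon gene, is the cryptic set over-represented among down- (or up-)
regulated genes?  A deliberately minimal negative-binomial Wald test backs
the differential-expression call for self-contained runs; externally
produced result tables can be imported verbatim for parity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .annotation_io import FlattenedAnnotation
from .stats import benjamini_hochberg, binomial_ci, bonferroni, hypergeometric_upper_tail

logger = logging.getLogger(__name__)

DEFAULT_DE_FDR = 0.10
MIN_DISPERSION = 1e-8


@dataclass
class GeneCountTable:
    counts: pd.DataFrame               # genes x samples, non-negative ints
    condition_of: dict[str, str]
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts < 0).any().any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ValueError("gene ids must be unique")
        if self.size_factors is None:
            self.size_factors = median_of_ratios(self.counts)
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")

    def normalized(self) -> pd.DataFrame:
        return self.counts / self.size_factors


def median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: median ratio to the geometric-mean gene."""
    log_counts = np.log(counts.replace(0, np.nan))
    log_geo = log_counts.mean(axis=1)
    usable = np.isfinite(log_geo)
    if usable.sum() == 0:
        return pd.Series(1.0, index=counts.columns)
    ratios = log_counts.loc[usable].sub(log_geo[usable], axis=0)
    sf = np.exp(ratios.median(axis=0))
    return sf.fillna(1.0)


def count_genes(
    reads_by_sample: dict[str, list],
    flattened: FlattenedAnnotation,
    condition_of: dict[str, str],
) -> GeneCountTable:
    """Union-mode gene counting over flattened exon bins.

    A primary non-duplicate read counts once for the single gene whose
    bins it touches; reads overlapping bins of two gene aggregates are
    ambiguous and contribute nothing.
    """
    tree: dict[str, IntervalTree] = {}
    for gene_id, bins in flattened.genes.items():
        for b in bins:
            tree.setdefault(b.interval.contig, IntervalTree()).addi(
                b.interval.start, b.interval.end, gene_id
            )
    genes = sorted(flattened.genes)
    table = pd.DataFrame(0, index=genes, columns=sorted(reads_by_sample), dtype=int)
    for sample, reads in reads_by_sample.items():
        col = dict.fromkeys(genes, 0)
        for read in reads:
            if getattr(read, "is_duplicate", False):
                continue
            hits = set()
            for b in read.blocks:
                t = tree.get(b.contig)
                if t is not None:
                    hits.update(h.data for h in t.overlap(b.start, b.end))
            if len(hits) == 1:
                col[hits.pop()] += 1
        table[sample] = pd.Series(col)
    return GeneCountTable(table, dict(condition_of))


@dataclass
class DEResult:
    gene_id: str
    log2_fold_change: float
    p_value: float
    adjusted_p: float
    direction: str            # up | down | ns
    mean_normalized: float
    tested: bool = True


def de_test(
    table: GeneCountTable,
    fdr: float = DEFAULT_DE_FDR,
    depletion_label: str = "depletion",
    control_label: str = "control",
) -> list[DEResult]:
    """Minimal per-gene negative-binomial Wald test (depletion vs control).

    Median-of-ratios normalization, per-gene moment dispersion with a
    floor, Wald test on the log ratio of condition means, BH adjustment.
    Not a reimplementation of any moderated framework — no shrinkage, no
    trended dispersion — and labelled accordingly.  All-zero genes are
    reported untested.
    """
    samples = list(table.counts.columns)
    dep = [s for s in samples if table.condition_of.get(s) == depletion_label]
    ctl = [s for s in samples if table.condition_of.get(s) == control_label]
    if len(dep) < 2 or len(ctl) < 2:
        raise ValueError("built-in DE test requires >=2 replicates per condition")
    norm = table.normalized()
    results: list[DEResult] = []
    pvals, idx = [], []
    for gene in norm.index:
        x = norm.loc[gene]
        mu_d, mu_c = float(x[dep].mean()), float(x[ctl].mean())
        mean_all = float(x.mean())
        if mu_d == 0 and mu_c == 0:
            results.append(DEResult(gene, np.nan, np.nan, np.nan, "ns", 0.0, tested=False))
            continue
        # pooled moment dispersion: var = mu + alpha mu^2
        resid = np.concatenate(
            [x[dep].to_numpy() - mu_d, x[ctl].to_numpy() - mu_c]
        )
        var = float((resid**2).sum() / max(len(resid) - 2, 1))
        mu_bar = (mu_d + mu_c) / 2
        alpha = max((var - mu_bar) / mu_bar**2 if mu_bar > 0 else 0.0, MIN_DISPERSION)
        pc = 0.5
        lfc = float(np.log2((mu_d + pc) / (mu_c + pc)))
        v_d = (1 / max(mu_d, pc) + alpha) / len(dep)
        v_c = (1 / max(mu_c, pc) + alpha) / len(ctl)
        z = np.log((mu_d + pc) / (mu_c + pc)) / np.sqrt(v_d + v_c)
        p = float(2 * sps.norm.sf(abs(z)))
        results.append(DEResult(gene, lfc, p, np.nan, "ns", mean_all))
        pvals.append(p)
        idx.append(len(results) - 1)
    adj = benjamini_hochberg(pvals)
    for i, a in zip(idx, adj):
        r = results[i]
        r.adjusted_p = float(a)
        if a < fdr:
            r.direction = "up" if r.log2_fold_change > 0 else "down"
    return results


def import_de(path: str | Path, fdr: float = DEFAULT_DE_FDR) -> list[DEResult]:
    """Verbatim import of an external DE results table.

    TSV columns: ``gene_id``, ``log2_fold_change``, ``adjusted_p`` and
    optionally ``p_value`` and ``mean_normalized``.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2_fold_change", "adjusted_p"}
    if not required.issubset(df.columns):
        raise ValueError(f"imported DE table must carry columns {sorted(required)}")
    out = []
    for r in df.itertuples():
        a = float(r.adjusted_p)
        lfc = float(r.log2_fold_change)
        direction = ("up" if lfc > 0 else "down") if a < fdr else "ns"
        out.append(
            DEResult(
                str(r.gene_id), lfc, float(getattr(r, "p_value", np.nan)), a,
                direction, float(getattr(r, "mean_normalized", np.nan)),
            )
        )
    return out


@dataclass
class EnrichmentReport:
    direction: str
    background_size: int
    n_de_in_background: int
    n_cryptic_in_background: int
    overlap: int
    p_value: float
    adjusted_p: float
    background_proportion: float
    cryptic_proportion: float
    background_ci: tuple[float, float]
    cryptic_ci: tuple[float, float]
    expression_floor: float


def enrichment_of_cryptic_genes(
    de_results: list[DEResult],
    cryptic_genes: set[str] | list[str],
    directions: tuple[str, ...] = ("down", "up"),
    bonferroni_m: int | None = None,
) -> list[EnrichmentReport]:
    """Expression-matched hypergeometric enrichment of cryptic-exon genes.

    The background is every tested gene whose mean normalized expression is
    at or above the least-expressed cryptic-exon gene.  For each direction
    the upper-tail hypergeometric p of the overlap between the cryptic set
    and that direction's DE genes is computed; Bonferroni is applied over
    the directions tested in this invocation (or an explicit family size).
    """
    cryptic = set(cryptic_genes)
    tested = [r for r in de_results if r.tested]
    in_set = [r for r in tested if r.gene_id in cryptic]
    if not in_set:
        warnings.warn("no cryptic gene present among tested genes; empty report")
        return []
    floor = min(r.mean_normalized for r in in_set)
    background = [r for r in tested if r.mean_normalized >= floor]
    bg_ids = {r.gene_id for r in background}
    cryptic_bg = cryptic & bg_ids
    reports = []
    for direction in directions:
        de_genes = {r.gene_id for r in background if r.direction == direction}
        overlap = len(de_genes & cryptic_bg)
        p = hypergeometric_upper_tail(
            overlap, len(background), len(de_genes), len(cryptic_bg)
        )
        bp = len(de_genes) / len(background)
        cp = overlap / len(cryptic_bg) if cryptic_bg else 0.0
        reports.append(
            EnrichmentReport(
                direction, len(background), len(de_genes), len(cryptic_bg), overlap,
                p, np.nan, bp, cp,
                binomial_ci(len(de_genes), len(background)),
                binomial_ci(overlap, len(cryptic_bg)),
                floor,
            )
        )
    m = bonferroni_m if bonferroni_m is not None else len(reports)
    adj = bonferroni([r.p_value for r in reports], m=m)
    for r, a in zip(reports, adj):
        r.adjusted_p = float(a)
    return reports


def cross_set_enrichment(
    de_results: list[DEResult],
    external_cryptic_genes: set[str] | list[str],
    directions: tuple[str, ...] = ("down", "up"),
    bonferroni_m: int | None = None,
) -> list[EnrichmentReport]:
    """Same computation with a cryptic gene list from another dataset."""
    ext = set(external_cryptic_genes)
    tested_ids = {r.gene_id for r in de_results if r.tested}
    if not ext & tested_ids:
        warnings.warn("external cryptic gene list is disjoint from tested genes")
        return []
    return enrichment_of_cryptic_genes(de_results, ext, directions, bonferroni_m)
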