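"""Cryptic tag discovery and differential usage testing.

Spliced reads that jump from an annotated exon into an intron are the raw
signal of cryptic splicing.  Their intronic blocks, pooled across all
samples irrespective of condition, are merged into *tags* (clusters within
500 bp of each other).  Tags are counted per sample against the flattened
exon bins of their gene, and relative usage — the proportion of a gene's
reads falling on the tag — is compared between depletion and control
samples with a beta-binomial likelihood-ratio test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps
from scipy.optimize import minimize_scalar

from .annotation_io import FlattenedAnnotation, SplitRead
from .intervals import GenomicInterval, merge_intervals
from .stats import benjamini_hochberg

logger = logging.getLogger(__name__)

DEFAULT_MERGE_DISTANCE = 500
DEFAULT_FDR = 0.05
DEFAULT_MIN_ABS_LOG2FC = 0.6


@dataclass
class IntronicFragment:
    """The intronic portion of one spliced read's aligned block."""

    interval: GenomicInterval
    gene_id: str
    sample_id: str
    query_name: str = ""


@dataclass
class CrypticTag:
    """A merged cluster of intronic split-read fragments within one intron."""

    tag_id: str
    interval: GenomicInterval
    gene_id: str
    n_fragments: int
    counts: dict[str, int] = field(default_factory=dict)            # per sample
    gene_remainder: dict[str, int] = field(default_factory=dict)    # per sample


@dataclass
class UsageTestResult:
    tag_id: str
    log2_fold_change: float
    p_value: float
    adjusted_p: float
    mean_normalized_count: float
    tested: bool = True
    reason: str = ""


def _bin_trees(flattened: FlattenedAnnotation) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gene_id, bins in flattened.genes.items():
        for b in bins:
            trees.setdefault(b.interval.contig, IntervalTree()).addi(
                b.interval.start, b.interval.end, (gene_id, b.bin_index)
            )
    return trees


def _intron_trees(flattened: FlattenedAnnotation) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gene_id, introns in flattened.introns.items():
        for iv in introns:
            trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end, gene_id)
    return trees


def select_intronic_split_reads(
    split_reads: list[SplitRead], flattened: FlattenedAnnotation
) -> list[IntronicFragment]:
    """Intronic blocks of exon-anchored spliced reads.

    A read is kept when at least one of its blocks overlaps an annotated
    exon bin but its blocks do not all land in annotated bins (reads merely
    bridging two annotated exons carry no cryptic signal).  Only the
    intronic part of each kept read's blocks is returned.
    """
    bin_tree = _bin_trees(flattened)
    intron_tree = _intron_trees(flattened)
    out: list[IntronicFragment] = []
    for sr in split_reads:
        btree = bin_tree.get(sr.contig)
        itree = intron_tree.get(sr.contig)
        if btree is None:
            continue
        touches_exon = any(btree.overlap(b.start, b.end) for b in sr.blocks)
        if not touches_exon:
            continue
        # intronic sections of each block
        frags: list[tuple[GenomicInterval, str]] = []
        if itree is not None:
            for b in sr.blocks:
                for hit in itree.overlap(b.start, b.end):
                    lo, hi = max(b.start, hit.begin), min(b.end, hit.end)
                    if hi > lo:
                        frags.append(
                            (GenomicInterval(sr.contig, lo, hi), hit.data)
                        )
        if not frags:
            continue  # all blocks exonic: read bridges annotated exons
        for iv, gene_id in frags:
            out.append(IntronicFragment(iv, gene_id, sr.sample_id, sr.query_name))
    logger.info(
        "retained %d intronic fragments from %d spliced reads", len(out), len(split_reads)
    )
    return out


def cluster_tags(
    fragments: list[IntronicFragment],
    flattened: FlattenedAnnotation,
    merge_distance: int = DEFAULT_MERGE_DISTANCE,
) -> list[CrypticTag]:
    """Merge intronic fragments within ``merge_distance`` bp into tags.

    Fragments are pooled across samples and conditions; tags are clipped to
    the intron list so only events splicing within the gene body survive.
    """
    by_gene: dict[str, list[IntronicFragment]] = {}
    for f in fragments:
        by_gene.setdefault(f.gene_id, []).append(f)
    tags: list[CrypticTag] = []
    for gene_id in sorted(by_gene):
        frs = by_gene[gene_id]
        merged = merge_intervals([f.interval for f in frs], max_gap=merge_distance)
        introns = flattened.introns.get(gene_id, [])
        for m in merged:
            for intron in introns:
                clipped = m.intersection(intron)
                if clipped is None:
                    continue
                n_frag = sum(1 for f in frs if f.interval.overlaps(clipped))
                tags.append(
                    CrypticTag(
                        f"{gene_id}:{clipped.contig}:{clipped.start}-{clipped.end}",
                        clipped,
                        gene_id,
                        n_frag,
                    )
                )
    logger.info("clustered %d fragments into %d tags", len(fragments), len(tags))
    return tags


def count_bins(
    split_or_all_reads: dict[str, list],
    flattened: FlattenedAnnotation,
    tags: list[CrypticTag],
) -> pd.DataFrame:
    """Per-sample counts over exon bins and tags (HTSeq-like union rule).

    ``split_or_all_reads`` maps sample_id to any objects with ``blocks``
    (GenomicInterval tuples) and ``is_duplicate``; duplicate-marked reads
    are ignored.  A read adds one count to every bin/tag it overlaps inside
    a single gene aggregate; reads touching two aggregates are ambiguous
    and counted for none.  Rows are bin/tag ids, columns sample ids.
    """
    feature_tree: dict[str, IntervalTree] = {}
    for gene_id, bins in flattened.genes.items():
        for b in bins:
            feature_tree.setdefault(b.interval.contig, IntervalTree()).addi(
                b.interval.start, b.interval.end, (gene_id, b.bin_id)
            )
    for t in tags:
        feature_tree.setdefault(t.interval.contig, IntervalTree()).addi(
            t.interval.start, t.interval.end, (t.gene_id, t.tag_id)
        )
    rows = [b.bin_id for bins in flattened.genes.values() for b in bins]
    rows += [t.tag_id for t in tags]
    counts = pd.DataFrame(
        0, index=sorted(set(rows)), columns=sorted(split_or_all_reads), dtype=int
    )
    no_feature = 0
    for sample_id, reads in split_or_all_reads.items():
        col = counts[sample_id].to_dict()
        for read in reads:
            if getattr(read, "is_duplicate", False):
                continue
            tree = feature_tree.get(read.blocks[0].contig if read.blocks else "", None)
            if tree is None:
                no_feature += 1
                continue
            hits = set()
            for b in read.blocks:
                for h in tree.overlap(b.start, b.end):
                    hits.add(h.data)
            genes = {g for g, _ in hits}
            if len(genes) != 1:
                continue  # no_feature or ambiguous across aggregates
            for _, fid in hits:
                col[fid] += 1
        counts[sample_id] = pd.Series(col)
    if no_feature:
        logger.info("%d reads on contigs absent from the annotation (no_feature)", no_feature)
    return counts


def attach_tag_counts(
    tags: list[CrypticTag], counts: pd.DataFrame, flattened: FlattenedAnnotation
) -> None:
    """Fill each tag's per-sample count and gene-remainder count from the
    bin count table (remainder = annotated bins of the same gene)."""
    gene_bin_ids: dict[str, list[str]] = {
        g: [b.bin_id for b in bins] for g, bins in flattened.genes.items()
    }
    for t in tags:
        tag_row = counts.loc[t.tag_id]
        remainder = counts.loc[[i for i in gene_bin_ids[t.gene_id] if i in counts.index]].sum(axis=0)
        t.counts = {s: int(tag_row[s]) for s in counts.columns}
        t.gene_remainder = {s: int(remainder[s]) for s in counts.columns}


# ---------------------------------------------------------------------------
# beta-binomial likelihood-ratio test
# ---------------------------------------------------------------------------

def _bb_loglik(k: np.ndarray, n: np.ndarray, p: float, rho: float) -> float:
    """Beta-binomial log-likelihood in the (p, rho) parameterization."""
    from scipy.special import betaln, gammaln

    if rho < 1e-12:
        return float(sps.binom.logpmf(k, n, p).sum())
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    log_choose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return float((log_choose + betaln(k + a, n - k + b) - betaln(a, b)).sum())


def _bb_fit_p(k: np.ndarray, n: np.ndarray, rho: float) -> tuple[float, float]:
    """MLE of the beta-binomial proportion at fixed overdispersion rho."""
    if n.sum() == 0:
        return 0.0, 0.0
    res = minimize_scalar(
        lambda p: -_bb_loglik(k, n, p, rho),
        bounds=(1e-9, 1 - 1e-9),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), float(-res.fun)


def _moment_rho(k: np.ndarray, n: np.ndarray) -> float:
    """Moment estimate of beta-binomial overdispersion from one tag.

    Uses the Pearson dispersion of the pooled-proportion fit:
    phi = chi2/(m-1); rho = (phi-1)/(mean(n)-1), clipped to [0, 0.99].
    """
    mask = n > 0
    k, n = k[mask], n[mask]
    if len(k) < 2 or n.sum() == 0:
        return 0.0
    p = k.sum() / n.sum()
    if p <= 0 or p >= 1:
        return 0.0
    chi2 = float((((k - n * p) ** 2) / (n * p * (1 - p))).sum())
    phi = chi2 / (len(k) - 1)
    nbar = float(n.mean())
    if nbar <= 1:
        return 0.0
    return float(np.clip((phi - 1) / (nbar - 1), 0.0, 0.99))


RHO_FLOOR = 1e-6
SHRINKAGE_RAW_WEIGHT = 0.25


def test_differential_usage(
    tags: list[CrypticTag],
    condition_of: dict[str, str],
    depletion_label: str = "depletion",
    control_label: str = "control",
) -> list[UsageTestResult]:
    """Beta-binomial LRT on tag vs gene-remainder proportions per condition.

    Per tag the proportion tag/(tag + remainder) is fitted once jointly and
    once per condition; twice the log-likelihood gain is referred to a
    chi-square with one degree of freedom.  Overdispersion is a per-tag
    moment estimate shrunk toward a count-trended mean across tags, with a
    floor of 1e-6.  The fold change is the ratio of the pooled per-condition
    proportions with a 0.5 pseudocount on every count.  BH adjustment is
    applied across all tested tags.
    """
    samples = sorted(condition_of)
    dep = [s for s in samples if condition_of[s] == depletion_label]
    ctl = [s for s in samples if condition_of[s] == control_label]
    if len(dep) < 2 or len(ctl) < 2:
        raise ValueError(
            "the built-in usage test requires >=2 replicates per condition; "
            "use the imported-results path for single-replicate designs"
        )

    # per-tag data and raw moment dispersions
    data = []
    rho_raw = np.zeros(len(tags))
    mean_tot = np.zeros(len(tags))
    for i, t in enumerate(tags):
        k = np.array([t.counts.get(s, 0) for s in samples], dtype=float)
        rem = np.array([t.gene_remainder.get(s, 0) for s in samples], dtype=float)
        n = k + rem
        data.append((k, n))
        rho_raw[i] = _moment_rho(k, n)
        mean_tot[i] = n.mean()

    # trended mean: running mean of raw rho over tags ordered by depth
    if len(tags) >= 10:
        order = np.argsort(mean_tot)
        window = max(10, len(tags) // 20)
        trend_sorted = (
            pd.Series(rho_raw[order]).rolling(window, center=True, min_periods=1).mean().to_numpy()
        )
        trend = np.empty_like(trend_sorted)
        trend[order] = trend_sorted
    else:
        trend = np.full(len(tags), rho_raw.mean() if len(tags) else 0.0)

    # strong shrinkage toward the trend: the raw per-tag moment estimate is
    # unbiased but noisy, and its noise is correlated with the test
    # statistic, which deflates the LRT; 25% raw weight keeps per-tag
    # adaptivity while preserving type-I calibration
    rho = np.maximum(SHRINKAGE_RAW_WEIGHT * rho_raw + (1 - SHRINKAGE_RAW_WEIGHT) * trend, RHO_FLOOR)

    dep_idx = np.array([samples.index(s) for s in dep])
    ctl_idx = np.array([samples.index(s) for s in ctl])
    results: list[UsageTestResult] = []
    for i, t in enumerate(tags):
        k, n = data[i]
        if n[dep_idx].sum() == 0 or n[ctl_idx].sum() == 0:
            results.append(
                UsageTestResult(t.tag_id, np.nan, np.nan, np.nan, float(n.mean()),
                                tested=False, reason="zero total counts in a condition")
            )
            continue
        _, ll0 = _bb_fit_p(k, n, rho[i])
        _, ll_dep = _bb_fit_p(k[dep_idx], n[dep_idx], rho[i])
        _, ll_ctl = _bb_fit_p(k[ctl_idx], n[ctl_idx], rho[i])
        lrt = max(0.0, 2.0 * (ll_dep + ll_ctl - ll0))
        p = float(sps.chi2.sf(lrt, df=1))
        # pseudocounted pooled proportions for the fold change
        p_dep = (k[dep_idx] + 0.5).sum() / (n[dep_idx] + 1.0).sum()
        p_ctl = (k[ctl_idx] + 0.5).sum() / (n[ctl_idx] + 1.0).sum()
        lfc = float(np.log2(p_dep / p_ctl))
        results.append(UsageTestResult(t.tag_id, lfc, p, np.nan, float(n.mean())))

    tested = [r for r in results if r.tested]
    if tested:
        adj = benjamini_hochberg([r.p_value for r in tested])
        for r, a in zip(tested, adj):
            r.adjusted_p = float(a)
    return results


def select_candidates(
    results: list[UsageTestResult],
    tags: list[CrypticTag],
    fdr: float = DEFAULT_FDR,
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
) -> list[CrypticTag]:
    """Tags passing adjusted p < ``fdr`` and |log2FC| > ``min_abs_log2fc``."""
    by_id = {t.tag_id: t for t in tags}
    out = []
    for r in results:
        if not r.tested:
            continue
        if r.adjusted_p < fdr and abs(r.log2_fold_change) > min_abs_log2fc:
            out.append(by_id[r.tag_id])
    return out


def import_usage_results(path: str | Path) -> list[UsageTestResult]:
    """Import an externally produced per-tag results table.

    Expected TSV columns: ``tag_id``, ``log2_fold_change``, ``adjusted_p``
    (and optionally ``p_value``, ``mean_normalized_count``).  This is the
    parity route for results computed with an external differential-usage
    framework.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"tag_id", "log2_fold_change", "adjusted_p"}
    if not required.issubset(df.columns):
        raise ValueError(f"imported results must carry columns {sorted(required)}")
    return [
        UsageTestResult(
            str(r.tag_id),
            float(r.log2_fold_change),
            float(getattr(r, "p_value", np.nan)),
            float(r.adjusted_p),
            float(getattr(r, "mean_normalized_count", np.nan)),
        )
        for r in df.itertuples()
    ]
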