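"""Evolutionary conservation of cryptic exons versus annotated neighbours.

Cryptic exons that arose recently from intronic sequence are expected to
score like random intron on a per-base conservation track (phyloP-like
units), far below the adjacent annotated exons.  This module summarises
per-interval mean scores for three groups — cryptic, adjacent annotated,
random intronic — and compares them with rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .annotation_io import ConservationTrack, FlattenedAnnotation
from .classification import CrypticExon
from .enrichment import sample_null
from .intervals import GenomicInterval
from .stats import bonferroni

GROUPS = ("cryptic", "annotated_adjacent", "random_intronic")


@dataclass(frozen=True)
class ConservationSummary:
    interval_id: str
    group: str
    mean_score: float  # nan when no base of the interval is covered


def mean_conservation(interval: GenomicInterval, track: ConservationTrack) -> float:
    """Arithmetic mean of per-base scores over covered bases (nan if none)."""
    return track.mean(interval)


def _adjacent_annotated_exons(
    exon: CrypticExon, flattened: FlattenedAnnotation
) -> list[GenomicInterval]:
    """The annotated exon bins flanking the host intron (junction-defined)."""
    out = []
    for b in flattened.genes[exon.tag.gene_id]:
        if b.interval.end == exon.host_intron.start or b.interval.start == exon.host_intron.end:
            out.append(b.interval)
    return out


def conservation_comparison(
    exons: list[CrypticExon],
    flattened: FlattenedAnnotation,
    track: ConservationTrack,
    seed: int | None = None,
    n_random_per_exon: int = 10,
) -> tuple[list[ConservationSummary], dict]:
    """Grouped per-interval mean scores plus rank-based group comparisons.

    Random intronic controls reuse the length-matched same-intron null
    sampler.  Tests are Mann-Whitney (cryptic vs random, cryptic vs
    adjacent) with Bonferroni over the two; both are skipped with a warning
    flag when a group has fewer than two scored intervals.
    """
    rng = np.random.default_rng(seed)
    summaries: list[ConservationSummary] = []
    for ex in exons:
        summaries.append(
            ConservationSummary(ex.exon_id, "cryptic", mean_conservation(ex.tag.interval, track))
        )
        for adj in _adjacent_annotated_exons(ex, flattened):
            summaries.append(
                ConservationSummary(
                    f"{ex.exon_id}|adj:{adj.start}-{adj.end}",
                    "annotated_adjacent",
                    mean_conservation(adj, track),
                )
            )
        draws = sample_null(
            ex.exon_id, ex.tag.interval, ex.host_intron, [], n=n_random_per_exon, rng=rng
        )
        for d in draws:
            summaries.append(
                ConservationSummary(
                    f"{ex.exon_id}|null:{d.draw_index}",
                    "random_intronic",
                    mean_conservation(d.interval, track),
                )
            )

    def scores(group: str) -> np.ndarray:
        v = np.array([s.mean_score for s in summaries if s.group == group])
        return v[np.isfinite(v)]

    stats: dict = {g: {"n": len(scores(g)), "mean": float(np.mean(scores(g))) if len(scores(g)) else float("nan")} for g in GROUPS}
    cr, ad, rd = scores("cryptic"), scores("annotated_adjacent"), scores("random_intronic")
    tests = {}
    if len(cr) >= 2 and len(rd) >= 2 and (np.ptp(np.concatenate([cr, rd])) > 0):
        tests["cryptic_vs_random"] = float(sps.mannwhitneyu(cr, rd).pvalue)
    if len(cr) >= 2 and len(ad) >= 2 and (np.ptp(np.concatenate([cr, ad])) > 0):
        tests["cryptic_vs_adjacent"] = float(sps.mannwhitneyu(cr, ad).pvalue)
    if tests:
        adj = bonferroni(list(tests.values()), m=2)
        stats["tests"] = {k: {"p": v, "adjusted_p": float(a)} for (k, v), a in zip(tests.items(), adj)}
    else:
        stats["tests"] = {}
        stats["warning"] = "too few scored intervals; tests skipped"
    return summaries, stats
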