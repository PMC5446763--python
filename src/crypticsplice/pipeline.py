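"""End-to-end orchestration: alignments in, classified cryptic exons out."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotation_io, classification, discovery
from .annotation_io import FlattenedAnnotation, SplitRead
from .classification import CrypticExon
from .discovery import CrypticTag, UsageTestResult
from .intervals import SpliceJunction

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    flattened: FlattenedAnnotation
    tags: list[CrypticTag]
    usage_results: list[UsageTestResult]
    candidates: list[CrypticTag]
    classified: list[CrypticExon]
    final_exons: list[CrypticExon]
    counts: pd.DataFrame | None = None
    junctions_by_sample: dict[str, list[SpliceJunction]] = field(default_factory=dict)

    def final_table(self) -> pd.DataFrame:
        rows = []
        for ex in self.final_exons:
            iv = ex.tag.interval
            rows.append(
                {
                    "exon_id": ex.exon_id,
                    "gene_id": ex.tag.gene_id,
                    "contig": iv.contig,
                    "start": iv.start,
                    "end": iv.end,
                    "class": ex.exon_class,
                    "delta_psi_upstream": ex.delta_psi_upstream,
                    "delta_psi_downstream": ex.delta_psi_downstream,
                    "delta_psi": ex.headline_delta_psi(),
                }
            )
        return pd.DataFrame(rows)


def run_pipeline(
    sam_by_sample: dict[str, str | Path],
    sj_by_sample: dict[str, str | Path],
    gtf: str | Path,
    condition_of: dict[str, str],
    merge_distance: int = discovery.DEFAULT_MERGE_DISTANCE,
    fdr: float = discovery.DEFAULT_FDR,
    min_abs_log2fc: float = discovery.DEFAULT_MIN_ABS_LOG2FC,
    min_canonical: int = classification.DEFAULT_MIN_CANONICAL,
    min_dpsi: float = classification.DEFAULT_MIN_DPSI,
    min_mapq: int = 0,
) -> PipelineResult:
    """Discovery, differential usage and classification in one call.

    The stages are exactly the library functions; this wrapper only wires
    their inputs together and keeps every intermediate for inspection.
    """
    flattened = annotation_io.flatten_annotation(gtf)
    reads_by_sample: dict[str, list[SplitRead]] = {}
    for sample, path in sam_by_sample.items():
        reads_by_sample[sample] = annotation_io.extract_all_reads(
            path, sample_id=sample, min_mapq=min_mapq
        )
    split_reads = [
        r for reads in reads_by_sample.values() for r in reads if r.junctions
    ]
    fragments = discovery.select_intronic_split_reads(split_reads, flattened)
    tags = discovery.cluster_tags(fragments, flattened, merge_distance)
    counts = discovery.count_bins(reads_by_sample, flattened, tags)
    discovery.attach_tag_counts(tags, counts, flattened)
    usage = discovery.test_differential_usage(tags, condition_of)
    candidates = discovery.select_candidates(usage, tags, fdr, min_abs_log2fc)

    junctions_by_sample = {
        sample: annotation_io.read_junction_table(path, sample_id=sample)
        for sample, path in sj_by_sample.items()
    }
    classified = classification.quantify_and_classify(
        candidates, junctions_by_sample, flattened, condition_of
    )
    final = classification.apply_filters(
        classified, condition_of, min_canonical=min_canonical, min_dpsi=min_dpsi
    )
    return PipelineResult(
        flattened, tags, usage, candidates, classified, final,
        counts, junctions_by_sample,
    )
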