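"""Classification and quantification of candidate cryptic tags.

A candidate tag becomes a cryptic exon by rediscovering, in the per-sample
splice-junction tables, the junctions that connect it to its neighbouring
annotated exons.  Three classes are distinguished:

* **cassette** — novel donor *and* acceptor inside the intron; the tag is
  spliced on both sides;
* **5' extension** — a novel acceptor upstream of an annotated exon start
  (transcript orientation); the tag is contiguous with that exon;
* **3' extension** — a novel donor downstream of an annotated exon end.

Percent spliced in (PSI) is cryptic/(cryptic + canonical) junction reads per
sample and side; ΔPSI is the depletion-minus-control difference of the
per-condition mean PSI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .annotation_io import FlattenedAnnotation
from .discovery import CrypticTag
from .intervals import GenomicInterval, SpliceJunction

logger = logging.getLogger(__name__)

CLASSES = ("cassette", "five_prime_extension", "three_prime_extension")

DEFAULT_MIN_CANONICAL = 10
DEFAULT_MIN_DPSI = 0.05


@dataclass
class CrypticExon:
    tag: CrypticTag
    exon_class: str
    host_intron: GenomicInterval
    canonical_junction: SpliceJunction
    canonical_counts: dict[str, int]
    upstream_counts: dict[str, int]        # junctions left-exon -> tag
    downstream_counts: dict[str, int]      # junctions tag -> right-exon
    psi_upstream: dict[str, float] = field(default_factory=dict)
    psi_downstream: dict[str, float] = field(default_factory=dict)
    mean_psi: dict[tuple[str, str], float] = field(default_factory=dict)  # (side, condition)
    delta_psi_upstream: float = float("nan")
    delta_psi_downstream: float = float("nan")
    flags: list[str] = field(default_factory=list)

    @property
    def exon_id(self) -> str:
        return self.tag.tag_id

    @property
    def has_upstream(self) -> bool:
        return any(v > 0 for v in self.upstream_counts.values())

    @property
    def has_downstream(self) -> bool:
        return any(v > 0 for v in self.downstream_counts.values())

    def headline_delta_psi(self) -> float:
        """Mean of the existing sides' ΔPSI (both sides for cassettes)."""
        sides = []
        if self.has_upstream and np.isfinite(self.delta_psi_upstream):
            sides.append(self.delta_psi_upstream)
        if self.has_downstream and np.isfinite(self.delta_psi_downstream):
            sides.append(self.delta_psi_downstream)
        return float(np.mean(sides)) if sides else float("nan")


def _junction_index(junctions: list[SpliceJunction]) -> dict[tuple[str, int, int], int]:
    idx: dict[tuple[str, int, int], int] = {}
    for j in junctions:
        key = (j.contig, j.donor_end, j.acceptor_start)
        idx[key] = idx.get(key, 0) + j.unique_read_count
    return idx


def find_canonical_junction(
    tag: CrypticTag,
    junctions_by_sample: dict[str, list[SpliceJunction]],
    flattened: FlattenedAnnotation,
    condition_of: dict[str, str] | None = None,
    control_label: str = "control",
) -> tuple[SpliceJunction | None, dict[str, int], GenomicInterval | None]:
    """The junction spanning the host intron, with per-sample counts.

    Candidates must span the tag; the one matching the flattened intron
    boundaries exactly is preferred, ties broken by higher control count.
    Returns (junction, per-sample counts, host intron); junction is None
    when no spanning junction exists in any sample (the exon is then
    flagged and removed by the canonical-count filter downstream).
    """
    intron = flattened.host_intron(tag.gene_id, tag.interval)
    if intron is None:
        raise ValueError(
            f"tag {tag.tag_id} does not lie within an intron of {tag.gene_id}"
        )
    candidates: dict[tuple[int, int], dict[str, int]] = {}
    for sample, juncs in junctions_by_sample.items():
        for j in juncs:
            if (
                j.contig == tag.interval.contig
                and j.donor_end <= tag.interval.start
                and j.acceptor_start >= tag.interval.end
            ):
                candidates.setdefault((j.donor_end, j.acceptor_start), {})
                candidates[(j.donor_end, j.acceptor_start)][sample] = (
                    candidates[(j.donor_end, j.acceptor_start)].get(sample, 0)
                    + j.unique_read_count
                )
    if not candidates:
        return None, {}, intron

    exact = (intron.start, intron.end)
    if exact in candidates:
        chosen = exact
    else:
        def control_count(coords: tuple[int, int]) -> int:
            counts = candidates[coords]
            if condition_of is None:
                return sum(counts.values())
            return sum(
                v for s, v in counts.items() if condition_of.get(s) == control_label
            )
        chosen = max(candidates, key=lambda c: (control_count(c), -(c[1] - c[0])))
    counts = candidates[chosen]
    junction = SpliceJunction(
        tag.interval.contig, chosen[0], chosen[1],
        tag.interval.strand, sum(counts.values()),
    )
    return junction, counts, intron


def find_cryptic_junctions(
    tag: CrypticTag,
    host_intron: GenomicInterval,
    junctions_by_sample: dict[str, list[SpliceJunction]],
) -> tuple[dict[str, int], dict[str, int]]:
    """Per-sample counts of the junctions linking the tag to its neighbours.

    Upstream junctions run from the genomically-left annotated exon boundary
    (the intron start) to an acceptor within ``[tag.start, tag.end)``;
    downstream junctions run from a donor within ``(tag.start, tag.end]`` to
    the right exon boundary (the intron end).  Junctions wholly inside the
    tag are ignored.
    """
    up: dict[str, int] = {}
    down: dict[str, int] = {}
    t = tag.interval
    for sample, juncs in junctions_by_sample.items():
        for j in juncs:
            if j.contig != t.contig:
                continue
            if j.donor_end == host_intron.start and t.start <= j.acceptor_start < t.end:
                up[sample] = up.get(sample, 0) + j.unique_read_count
            elif j.acceptor_start == host_intron.end and t.start < j.donor_end <= t.end:
                down[sample] = down.get(sample, 0) + j.unique_read_count
    return up, down


def classify(
    tag: CrypticTag,
    host_intron: GenomicInterval,
    upstream_counts: dict[str, int],
    downstream_counts: dict[str, int],
    flattened: FlattenedAnnotation,
) -> str | None:
    """Assign the three-way class, or None when unclassifiable.

    Extension contiguity requires the tag to touch the annotated exon
    boundary exactly (0 bp gap).  5'/3' naming follows transcript
    orientation, so a minus-strand gene flips the genomic left/right sense.
    """
    has_up = any(v > 0 for v in upstream_counts.values())
    has_down = any(v > 0 for v in downstream_counts.values())
    strand = flattened.strands.get(tag.gene_id, tag.interval.strand)
    t = tag.interval
    if has_up and has_down:
        disjoint = all(
            not t.overlaps(b.interval) for b in flattened.genes[tag.gene_id]
        )
        if disjoint:
            return "cassette"
        return None
    if has_up and not has_down and t.end == host_intron.end:
        # genomically-right exon extended leftwards
        return "five_prime_extension" if strand != "-" else "three_prime_extension"
    if has_down and not has_up and t.start == host_intron.start:
        # genomically-left exon extended rightwards
        return "three_prime_extension" if strand != "-" else "five_prime_extension"
    return None


def compute_psi(cryptic: int, canonical: int) -> float:
    """PSI = cryptic/(cryptic + canonical); 0 when both are zero."""
    if cryptic < 0 or canonical < 0:
        raise ValueError("counts must be non-negative")
    total = cryptic + canonical
    if total == 0:
        return 0.0
    return cryptic / total


def aggregate_delta_psi(
    psi_by_sample: dict[str, float],
    condition_of: dict[str, str],
    depletion_label: str = "depletion",
    control_label: str = "control",
) -> tuple[float, float, float]:
    """(mean depletion PSI, mean control PSI, ΔPSI = depletion - control)."""
    dep = [v for s, v in psi_by_sample.items() if condition_of.get(s) == depletion_label]
    ctl = [v for s, v in psi_by_sample.items() if condition_of.get(s) == control_label]
    m_dep = float(np.mean(dep)) if dep else float("nan")
    m_ctl = float(np.mean(ctl)) if ctl else float("nan")
    return m_dep, m_ctl, m_dep - m_ctl


def quantify_and_classify(
    candidates: list[CrypticTag],
    junctions_by_sample: dict[str, list[SpliceJunction]],
    flattened: FlattenedAnnotation,
    condition_of: dict[str, str],
    depletion_label: str = "depletion",
    control_label: str = "control",
) -> list[CrypticExon]:
    """Classify candidate tags and compute per-sample PSI and ΔPSI.

    Cryptic junctions are rediscovered from the depletion samples' tables
    (the class is defined by what emerges under depletion); PSI is then
    quantified in every sample.
    """
    depletion_junctions = {
        s: j for s, j in junctions_by_sample.items()
        if condition_of.get(s) == depletion_label
    }
    exons: list[CrypticExon] = []
    for tag in candidates:
        canon, canon_counts, intron = find_canonical_junction(
            tag, junctions_by_sample, flattened, condition_of, control_label
        )
        up, down = find_cryptic_junctions(tag, intron, depletion_junctions)
        cls = classify(tag, intron, up, down, flattened)
        if cls is None:
            logger.info("tag %s unclassifiable; dropped", tag.tag_id)
            continue
        flags = []
        if canon is None:
            flags.append("no_canonical_junction")
            canon = SpliceJunction(
                tag.interval.contig, intron.start, intron.end, tag.interval.strand, 0
            )
        # quantify both sides in *all* samples
        up_all, down_all = find_cryptic_junctions(tag, intron, junctions_by_sample)
        samples = sorted(junctions_by_sample)
        psi_up = {
            s: compute_psi(up_all.get(s, 0), canon_counts.get(s, 0)) for s in samples
        }
        psi_down = {
            s: compute_psi(down_all.get(s, 0), canon_counts.get(s, 0)) for s in samples
        }
        ex = CrypticExon(
            tag, cls, intron, canon, canon_counts,
            {s: up_all.get(s, 0) for s in samples},
            {s: down_all.get(s, 0) for s in samples},
            psi_up, psi_down, flags=flags,
        )
        for side, psis in (("upstream", psi_up), ("downstream", psi_down)):
            m_dep, m_ctl, dpsi = aggregate_delta_psi(
                psis, condition_of, depletion_label, control_label
            )
            ex.mean_psi[(side, depletion_label)] = m_dep
            ex.mean_psi[(side, control_label)] = m_ctl
            if side == "upstream":
                ex.delta_psi_upstream = dpsi
            else:
                ex.delta_psi_downstream = dpsi
        exons.append(ex)
    return exons


def apply_filters(
    exons: list[CrypticExon],
    condition_of: dict[str, str],
    depletion_label: str = "depletion",
    min_canonical: int = DEFAULT_MIN_CANONICAL,
    min_dpsi: float = DEFAULT_MIN_DPSI,
) -> list[CrypticExon]:
    """Junction-support and effect-size filters on classified exons.

    An exon is removed when (i) any depletion sample lacks a cryptic
    junction read on both sides, (ii) canonical junction reads summed over
    all samples fall below ``min_canonical``, or (iii) any side the exon
    actually uses has ΔPSI below ``min_dpsi``.
    """
    dep_samples = [s for s, c in condition_of.items() if c == depletion_label]
    kept: list[CrypticExon] = []
    for ex in exons:
        if any(
            ex.upstream_counts.get(s, 0) + ex.downstream_counts.get(s, 0) < 1
            for s in dep_samples
        ):
            ex.flags.append("missing_depletion_junction")
            continue
        if sum(ex.canonical_counts.values()) < min_canonical:
            ex.flags.append("low_canonical_support")
            continue
        sides = []
        if ex.has_upstream:
            sides.append(ex.delta_psi_upstream)
        if ex.has_downstream:
            sides.append(ex.delta_psi_downstream)
        if any(not np.isfinite(d) or d < min_dpsi for d in sides):
            ex.flags.append("low_delta_psi")
            continue
        kept.append(ex)
    logger.info("filters kept %d of %d classified exons", len(kept), len(exons))
    return kept


def inclusion_ratio_screen(
    exons: list[CrypticExon],
    panel_junctions: dict[str, list[SpliceJunction]],
    group_of: dict[str, str],
) -> dict[str, dict]:
    """Baseline-inclusion screen of final exons across an external panel.

    Per sample, the upstream and downstream junction counts are each
    divided by the canonical junction count to give inclusion ratios; per
    group, the mean and standard deviation of the per-sample mean ratio are
    reported.  Samples with zero canonical reads are skipped and flagged.
    """
    report: dict[str, dict] = {}
    for ex in exons:
        per_sample: dict[str, dict] = {}
        skipped: list[str] = []
        for sample, juncs in panel_junctions.items():
            idx = _junction_index(juncs)
            key = (
                ex.canonical_junction.contig,
                ex.canonical_junction.donor_end,
                ex.canonical_junction.acceptor_start,
            )
            canon = idx.get(key, 0)
            up, down = find_cryptic_junctions(ex.tag, ex.host_intron, {sample: juncs})
            if canon == 0:
                skipped.append(sample)
                continue
            r_up = up.get(sample, 0) / canon
            r_down = down.get(sample, 0) / canon
            per_sample[sample] = {
                "upstream_ratio": r_up,
                "downstream_ratio": r_down,
                "mean_ratio": (r_up + r_down) / 2,
            }
        groups: dict[str, dict] = {}
        for grp in sorted(set(group_of.values())):
            vals = [
                d["mean_ratio"] for s, d in per_sample.items()
                if group_of.get(s) == grp
            ]
            if vals:
                groups[grp] = {
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    "n": len(vals),
                }
        report[ex.exon_id] = {
            "samples": per_sample,
            "groups": groups,
            "skipped_zero_canonical": skipped,
        }
    return report
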