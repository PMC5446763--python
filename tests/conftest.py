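"""Shared fixtures: small synthetic studies and toy annotations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from crypticsplice import annotation_io, simulate as sim

def make_gtf_df(genes: dict) -> pd.DataFrame:
    """Build a GTF-like DataFrame from {gene_id: {tx_id: [(s,e),...]}} specs.

    Optional per-transcript CDS span via key ``(tx_id, "cds")`` -> (s, e).
    Coordinates are 0-based half-open, as after read_gtf.
    """
    rows = []
    for gene_id, txs in genes.items():
        strand = txs.get("strand", "+")
        for tx_id, exons in txs.items():
            if tx_id == "strand" or (isinstance(tx_id, tuple)):
                continue
            for s, e in exons:
                rows.append(
                    dict(Chromosome="chr1", Feature="exon", Start=s, End=e,
                         Strand=strand, gene_id=gene_id, transcript_id=tx_id)
                )
            cds = txs.get((tx_id, "cds"))
            if cds:
                rows.append(
                    dict(Chromosome="chr1", Feature="CDS", Start=cds[0], End=cds[1],
                         Strand=strand, gene_id=gene_id, transcript_id=tx_id)
                )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_reference(tmp_path_factory):
    """A compact synthetic study: 12 genes, 4 cassette + 2 extension spikes."""
    out = tmp_path_factory.mktemp("smallsim")
    spikes = [
        sim.CrypticSpike(0, "cassette", 1, 0.6, 100),
        sim.CrypticSpike(1, "cassette", 1, 0.4, 90),
        sim.CrypticSpike(2, "cassette", 1, 0.8, 123),
        sim.CrypticSpike(3, "cassette", 1, 0.6, 141),
        sim.CrypticSpike(4, "five_prime_extension", 1, 0.6, 40),
        sim.CrypticSpike(5, "three_prime_extension", 1, 0.6, 45),
    ]
    config = sim.SimulationConfig(seed=7, n_genes=12, spikes=spikes)
    ref = sim.simulate_reference(config, out)
    sam_paths, sj_paths, truth_path = sim.simulate_reads(ref, out)
    return {
        "ref": ref,
        "dir": out,
        "sam": sam_paths,
        "sj": sj_paths,
        "truth": pd.read_csv(truth_path, sep="\t"),
        "conditions": sim.sample_names(config)[1],
    }


@pytest.fixture(scope="session")
def small_flattened(small_reference):
    return annotation_io.flatten_annotation(small_reference["ref"].gtf_path)


@pytest.fixture(scope="session")
def small_genome(small_reference):
    return annotation_io.GenomeSequence(small_reference["ref"].fasta_path)


@pytest.fixture(scope="session")
def small_pipeline(small_reference):
    from crypticsplice.pipeline import run_pipeline

    return run_pipeline(
        small_reference["sam"],
        small_reference["sj"],
        small_reference["ref"].gtf_path,
        small_reference["conditions"],
    )


def per_base_members(intervals) -> set[int]:
    out: set[int] = set()
    for iv in intervals:
        out.update(range(iv.start, iv.end))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(42)
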