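import numpy as np
import pysam
import pytest

from conftest import make_gtf_df, per_base_members
from crypticsplice import annotation_io as aio
from crypticsplice.intervals import GenomicInterval, SpliceJunction


class TestFlatten:
    def test_single_transcript_bins_equal_exons(self):
        df = make_gtf_df({"g1": {"t1": [(100, 200), (300, 400)]}})
        flat = aio.flatten_annotation(df)
        bins = [b.interval for b in flat.genes["g1"]]
        assert [(b.start, b.end) for b in bins] == [(100, 200), (300, 400)]
        assert [(i.start, i.end) for i in flat.introns["g1"]] == [(200, 300)]

    def test_overlapping_transcripts_partition_at_boundaries(self):
        # brute-force partition of [100,200) u [150,250) at {100,150,200,250}
        df = make_gtf_df({"g1": {"t1": [(100, 200)], "t2": [(150, 250)]}})
        flat = aio.flatten_annotation(df)
        got = [(b.interval.start, b.interval.end) for b in flat.genes["g1"]]
        assert got == [(100, 150), (150, 200), (200, 250)]
        assert per_base_members(b.interval for b in flat.genes["g1"]) == set(range(100, 250))

    def test_overlapping_genes_merged_into_aggregate(self):
        df = make_gtf_df(
            {"gA": {"tA": [(100, 300)]}, "gB": {"tB": [(250, 400)]}}
        )
        flat = aio.flatten_annotation(df)
        assert list(flat.genes) == ["gA+gB"]

    def test_intron_complement_per_base_oracle(self, rng):
        genes = {}
        for g in range(10):
            base = g * 10_000
            n_tx = int(rng.integers(1, 4))
            txs = {}
            for t in range(n_tx):
                pos = base + int(rng.integers(0, 200))
                exons = []
                for _ in range(int(rng.integers(2, 5))):
                    w = int(rng.integers(50, 200))
                    exons.append((pos, pos + w))
                    pos += w + int(rng.integers(100, 500))
                txs[f"t{g}_{t}"] = exons
            genes[f"g{g}"] = txs
        flat = aio.flatten_annotation(make_gtf_df(genes))
        for gid, bins in flat.genes.items():
            span = flat.gene_span(gid)
            bin_bases = per_base_members(b.interval for b in bins)
            intron_bases = per_base_members(flat.introns[gid])
            assert bin_bases | intron_bases == set(range(span.start, span.end))
            assert not bin_bases & intron_bases

    def test_flattening_is_idempotent(self):
        df = make_gtf_df(
            {"g1": {"t1": [(100, 200), (300, 400)], "t2": [(150, 250), (300, 450)]}}
        )
        flat1 = aio.flatten_annotation(df)
        refeed = make_gtf_df(
            {"g1": {"t1": [(b.interval.start, b.interval.end) for b in flat1.genes["g1"]]}}
        )
        flat2 = aio.flatten_annotation(refeed)
        assert [
            (b.interval.start, b.interval.end) for b in flat1.genes["g1"]
        ] == [(b.interval.start, b.interval.end) for b in flat2.genes["g1"]]

    def test_malformed_gtf_names_line(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text('chr1\tsim\texon\t100\t200\t.\t+\n')  # 7 fields
        with pytest.raises(ValueError, match="line 1"):
            aio.read_gtf(p)


class TestSplicedReads:
    def _write_sam(self, path, records, sorted_flag="coordinate"):
        header = {"HD": {"VN": "1.6", "SO": sorted_flag}, "SQ": [{"SN": "chr1", "LN": 100000}]}
        h = pysam.AlignmentHeader.from_dict(header)
        with pysam.AlignmentFile(str(path), "wh", header=h) as af:
            for name, pos, cigar, flag in records:
                seg = pysam.AlignedSegment(h)
                seg.query_name = name
                seg.flag = flag
                seg.reference_id = 0
                seg.reference_start = pos
                seg.mapping_quality = 255
                seg.cigarstring = cigar
                seg.query_sequence = "A" * sum(
                    int(n) for n, op in __import__("re").findall(r"(\d+)([MIS=X])", cigar)
                )
                af.write(seg)

    def test_cigar_block_arithmetic(self, tmp_path):
        p = tmp_path / "a.sam"
        self._write_sam(p, [("r1", 1000, "50M100N50M", 0)])
        reads = aio.extract_spliced_reads(p)
        assert len(reads) == 1
        assert [(b.start, b.end) for b in reads[0].blocks] == [(1000, 1050), (1150, 1200)]
        j = reads[0].junctions[0]
        assert (j.donor_end, j.acceptor_start) == (1050, 1150)

    def test_unspliced_and_secondary_excluded(self, tmp_path):
        p = tmp_path / "a.sam"
        self._write_sam(
            p,
            [("plain", 10, "100M", 0), ("sec", 1000, "50M100N50M", 256),
             ("dup", 2000, "50M100N50M", 1024)],
        )
        reads = aio.extract_spliced_reads(p)
        assert [r.query_name for r in reads] == ["dup"]
        assert reads[0].is_duplicate  # flag preserved for counting policy

    def test_unsorted_input_rejected(self, tmp_path):
        p = tmp_path / "a.sam"
        self._write_sam(p, [("r1", 1000, "50M100N50M", 0)], sorted_flag="unsorted")
        with pytest.raises(ValueError, match="sort"):
            aio.extract_spliced_reads(p)


class TestJunctionTable:
    def test_star_dialect_conversion(self, tmp_path):
        p = tmp_path / "SJ.out.tab"
        p.write_text("chr1\t1051\t1150\t1\t1\t1\t42\t0\t20\n")
        (j,) = aio.read_junction_table(p)
        assert (j.donor_end, j.acceptor_start, j.unique_read_count, j.strand) == (
            1050, 1150, 42, "+",
        )

    def test_strand_code_zero_is_unstranded(self, tmp_path):
        p = tmp_path / "SJ.out.tab"
        p.write_text("chr1\t10\t20\t0\t0\t0\t5\t0\t10\n")
        assert aio.read_junction_table(p)[0].strand == "."

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "SJ.out.tab"
        p.write_text("")
        assert aio.read_junction_table(p) == []

    def test_column_mismatch_raises(self, tmp_path):
        p = tmp_path / "SJ.out.tab"
        p.write_text("chr1\t10\t20\t1\n")
        with pytest.raises(ValueError, match="columns"):
            aio.read_junction_table(p)

    def test_round_trip(self, tmp_path):
        juncs = [
            SpliceJunction("chr1", 1050, 1150, "+", 42),
            SpliceJunction("chr2", 5, 500, "-", 0),
            SpliceJunction("chr1", 99, 200, ".", 7),
        ]
        p = tmp_path / "SJ.out.tab"
        aio.write_junction_table(juncs, p)
        back = aio.read_junction_table(p)
        assert {(j.contig, j.donor_end, j.acceptor_start, j.strand, j.unique_read_count)
                for j in juncs} == \
               {(j.contig, j.donor_end, j.acceptor_start, j.strand, j.unique_read_count)
                for j in back}


class TestPeaksRepeatsTracks:
    def test_bed_convention(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t10\t20\tpeak1\n")
        ps = aio.read_peaks(p, "X")
        assert ps.peaks[0] == GenomicInterval("chr1", 10, 20)

    def test_bed_round_trip(self, tmp_path):
        ivs = [GenomicInterval("chr1", 10, 20, "+"), GenomicInterval("chr2", 5, 9, "-")]
        p = tmp_path / "p.bed"
        aio.write_bed(ivs, p)
        back = aio.read_peaks(p)
        assert back.peaks == sorted(ivs, key=lambda x: (x.contig, x.start))

    def test_rmsk_parse_and_alu_partition(self, tmp_path):
        rows = [
            ["0"] * 4 + ["chr1", "100", "220", "0", "C", "AluY", "SINE", "Alu"] + ["0"] * 4,
            ["0"] * 4 + ["chr1", "400", "520", "0", "+", "B2_Mm2", "SINE", "B2"] + ["0"] * 4,
            ["0"] * 4 + ["chr1", "700", "820", "0", "+", "L1Md", "LINE", "L1"] + ["0"] * 4,
        ]
        p = tmp_path / "rmsk.tsv"
        p.write_text("\n".join("\t".join(r) for r in rows) + "\n")
        reps = aio.read_repeats(p)
        assert [r.family for r in reps] == ["Alu", "SINE", "LINE"]
        assert reps[0].element_strand == "-"  # rmsk 'C' convention

    def test_repeats_round_trip(self, tmp_path):
        reps = [
            aio.RepeatElement(GenomicInterval("chr1", 10, 100), "Alu", "AluY", "-"),
            aio.RepeatElement(GenomicInterval("chr1", 300, 500), "LINE", "L1", "+"),
        ]
        p = tmp_path / "rmsk.tsv"
        aio.write_repeats(reps, p)
        back = aio.read_repeats(p)
        assert [(r.interval, r.family, r.element_strand) for r in back] == [
            (r.interval, r.family, r.element_strand) for r in reps
        ]

    def test_bedgraph_mean(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t10\t2.0\n")
        track = aio.ConservationTrack.from_bedgraph(p)
        assert track.mean(GenomicInterval("chr1", 0, 10)) == pytest.approx(2.0)

    def test_mean_invariant_to_row_splitting(self):
        a = aio.ConservationTrack([("chr1", 0, 100, 1.5), ("chr1", 100, 200, 3.0)])
        b = aio.ConservationTrack(
            [("chr1", 0, 40, 1.5), ("chr1", 40, 100, 1.5),
             ("chr1", 100, 130, 3.0), ("chr1", 130, 200, 3.0)]
        )
        for iv in [GenomicInterval("chr1", 0, 200), GenomicInterval("chr1", 50, 150)]:
            assert a.mean(iv) == pytest.approx(b.mean(iv))

    def test_uncovered_interval_is_nan(self):
        t = aio.ConservationTrack([("chr1", 100, 200, 1.0)])
        assert np.isnan(t.mean(GenomicInterval("chr1", 300, 400)))
        assert np.isnan(t.mean(GenomicInterval("chr9", 0, 10)))


class TestGenomeSequence:
    @pytest.fixture()
    def genome(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">c1\nACGTA\n")
        return aio.GenomeSequence(fa)

    def test_forward_fetch(self, genome):
        assert genome.fetch(GenomicInterval("c1", 0, 4)) == "ACGT"

    def test_minus_strand_is_reverse_complement(self, genome):
        assert genome.fetch(GenomicInterval("c1", 0, 4, "-")) == "ACGT"[::-1].translate(
            str.maketrans("ACGT", "TGCA")
        )

    def test_rna_flag(self, genome):
        assert genome.fetch(GenomicInterval("c1", 0, 4), rna=True) == "ACGU"

    def test_clip_and_unknown_contig(self, genome):
        with pytest.warns(UserWarning, match="clipped"):
            assert genome.fetch(GenomicInterval("c1", 3, 10)) == "TA"
        with pytest.raises(KeyError):
            genome.fetch(GenomicInterval("nope", 0, 2))
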