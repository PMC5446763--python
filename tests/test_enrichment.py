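import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from crypticsplice import enrichment as enr
from crypticsplice.annotation_io import PeakSet, RepeatElement
from crypticsplice.intervals import GenomicInterval
from crypticsplice.stats import two_proportion_test


class TestFlank:
    def test_pad_both_sides(self):
        (f,) = enr.flank([GenomicInterval("chr1", 500, 600)], 100)
        assert (f.start, f.end) == (400, 700)

    def test_clip_at_contig_start(self):
        (f,) = enr.flank([GenomicInterval("chr1", 50, 80)], 100)
        assert (f.start, f.end) == (0, 180)

    def test_pad_zero_is_identity(self):
        iv = GenomicInterval("chr1", 500, 600)
        assert enr.flank([iv], 0) == [iv]


class TestSampleNull:
    INTRON = GenomicInterval("chr1", 10_000, 20_000)
    FLANKED = GenomicInterval("chr1", 14_000, 14_300)

    def test_draw_count_length_and_exclusion(self):
        draws = enr.sample_null("e1", self.FLANKED, self.INTRON, [], n=100, rng=3)
        same = [d for d in draws if d.mode == "same_intron"]
        assert len(same) == 100
        for d in same:
            assert len(d.interval) == 300
            assert not d.interval.overlaps(self.FLANKED)
            assert self.INTRON.contains(d.interval)

    def test_adjacent_mode_uses_adjacent_introns(self):
        adj = [GenomicInterval("chr1", 30_000, 33_000), GenomicInterval("chr1", 40_000, 45_000)]
        draws = enr.sample_null("e1", self.FLANKED, self.INTRON, adj, n=50, rng=3)
        ad = [d for d in draws if d.mode == "adjacent_intron"]
        assert len(ad) == 50
        assert all(any(a.contains(d.interval) for a in adj) for d in ad)

    def test_no_adjacent_intron_skips_mode(self):
        draws = enr.sample_null("e1", self.FLANKED, self.INTRON, [], n=10, rng=0)
        assert all(d.mode == "same_intron" for d in draws)

    def test_same_seed_reproducible(self):
        a = enr.sample_null("e1", self.FLANKED, self.INTRON, [], n=20, rng=11)
        b = enr.sample_null("e1", self.FLANKED, self.INTRON, [], n=20, rng=11)
        assert [d.interval for d in a] == [d.interval for d in b]

    def test_no_room_gives_zero_draws(self):
        tight = GenomicInterval("chr1", 14_000 - 50, 14_300 + 50)
        draws = enr.sample_null("e1", self.FLANKED, tight, [], n=10, rng=0)
        assert [d for d in draws if d.mode == "same_intron"] == []

    def test_draws_uniform_over_admissible_starts(self):
        # chi-square goodness of fit over start positions of 10k draws
        intron = GenomicInterval("chr1", 0, 1100)
        flanked = GenomicInterval("chr1", 500, 600)
        draws = enr.sample_null("e1", flanked, intron, [], n=10_000, rng=5)
        starts = np.array([d.interval.start for d in draws])
        admissible = list(range(0, 401)) + list(range(600, 1001))
        assert set(starts) <= set(admissible)
        bins = np.linspace(0, len(admissible), 20)
        ranks = np.searchsorted(np.array(admissible), starts)
        obs, _ = np.histogram(ranks, bins=bins)
        p = sps.chisquare(obs).pvalue
        assert p > 0.001


def peakset(intervals, name="RBP", rep="1"):
    ivs = [GenomicInterval("chr1", s, e) for s, e in intervals]
    return PeakSet(name, rep, ivs, [iv.start for iv in ivs])


class TestOverlapTest:
    def test_maximal_separation(self):
        exons = [GenomicInterval("chr1", i * 1000, i * 1000 + 100) for i in range(10)]
        draws = [
            enr.NullExonDraw(f"e{i}", "same_intron", GenomicInterval("chr1", 500_000 + i * 1000, 500_100 + i * 1000), 1)
            for i in range(100)
        ]
        peaks = peakset([(i * 1000, i * 1000 + 100) for i in range(10)])
        res = enr.overlap_test(exons, draws, peaks)
        assert res.cryptic_proportion == 1.0
        assert res.null_proportions["same_intron"] == 0.0
        assert res.p_values["same_intron"] < 1e-10

    def test_chi_square_matches_hand_formula(self):
        # 8/10 vs 20/100, Yates-corrected chi-square computed by hand
        res = two_proportion_test(8, 10, 20, 100, exact_fallback=False)
        table = np.array([[8, 2], [20, 80]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2 = ((np.abs(table - expected) - 0.5) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(chi2)
        assert res.chi2_p == pytest.approx(sps.chi2.sf(chi2, 1))

    def test_small_cell_uses_fisher_and_flags(self):
        res = two_proportion_test(8, 10, 20, 100)
        assert res.method == "fisher"
        _, fp = sps.fisher_exact([[8, 2], [20, 80]])
        assert res.p_value == pytest.approx(fp)

    def test_uniform_peaks_mostly_non_significant(self):
        rng = np.random.default_rng(9)
        n_sig = 0
        runs = 100
        for _ in range(runs):
            exons = [GenomicInterval("chr1", int(s), int(s) + 100) for s in rng.integers(0, 900_000, 20)]
            draws = [
                enr.NullExonDraw(f"e{i}", "same_intron",
                                 GenomicInterval("chr1", int(s), int(s) + 100), 1)
                for i, s in enumerate(rng.integers(0, 900_000, 2000))
            ]
            peaks = peakset([(int(s), int(s) + 30) for s in sorted(rng.integers(0, 900_000, 2000))])
            res = enr.overlap_test(exons, draws, peaks)
            if res.p_values["same_intron"] < 0.05:
                n_sig += 1
        assert n_sig <= 5  # >= 95% of runs non-significant


class TestEclipScreen:
    def _setup(self, rng, spike_fraction=0.5):
        exons = [GenomicInterval("chr1", (i + 1) * 10_000, (i + 1) * 10_000 + 100) for i in range(40)]
        draws = [
            enr.NullExonDraw(f"e{i}", mode, GenomicInterval("chr1", int(s), int(s) + 100), j)
            for mode in enr.NULL_MODES
            for j, (i, s) in enumerate(
                zip(itertools.cycle(range(40)), rng.integers(500_000, 900_000, 1000))
            )
        ]
        spiked = [
            peakset([(e.start - 10, e.start + 20) for e in exons if rng.random() < spike_fraction],
                    "SPIKED", rep)
            for rep in "12"
        ]
        uniform = {
            f"U{k}": [
                peakset([(int(s), int(s) + 30) for s in sorted(rng.integers(0, 900_000, 300))], f"U{k}", rep)
                for rep in "12"
            ]
            for k in range(4)
        }
        return exons, draws, {"SPIKED": spiked, **uniform}

    def test_only_spiked_rbp_passes(self, rng):
        exons, draws, sets = self._setup(rng)
        df = enr.eclip_screen(exons, draws, sets)
        passing = set(df[df["passes"]]["rbp"])
        assert passing == {"SPIKED"}

    def test_one_weak_replicate_excludes_rbp(self, rng):
        exons, draws, sets = self._setup(rng)
        # replace one spiked replicate with uniform peaks -> max-p rule kills it
        sets["SPIKED"][1] = peakset(
            [(int(s), int(s) + 30) for s in sorted(rng.integers(500_000, 900_000, 50))],
            "SPIKED", "2",
        )
        df = enr.eclip_screen(exons, draws, sets)
        assert not df[df["rbp"] == "SPIKED"]["passes"].iloc[0]

    def test_single_rbp_reduces_to_overlap_test(self, rng):
        exons, draws, sets = self._setup(rng)
        only = {"SPIKED": sets["SPIKED"][:1]}
        df = enr.eclip_screen(exons, draws, only)
        res = enr.overlap_test(exons, draws, sets["SPIKED"][0])
        assert df["max_p"].iloc[0] == pytest.approx(max(res.p_values.values()))
        assert df["adjusted_p"].iloc[0] == pytest.approx(min(1.0, df["max_p"].iloc[0] * 1))


class TestClusterRbps:
    def test_identical_rows_merge_first_disjoint_distance_one(self):
        m = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]],
            index=["a", "b", "c"],
        )
        z, labels, ordered = enr.cluster_rbps(m)
        assert z[0, 2] == 0.0          # identical rows at distance 0
        assert z[-1, 2] == 1.0         # disjoint clusters at Jaccard 1
        assert set(labels) == {"a", "b", "c"}

    def test_merge_tree_matches_brute_force_agglomeration(self, rng):
        m = pd.DataFrame(rng.integers(0, 2, size=(5, 8)), index=list("abcde"))
        z, _, _ = enr.cluster_rbps(m)

        def jac(u, v):
            union = np.logical_or(u, v).sum()
            return 0.0 if union == 0 else np.logical_xor(u, v).sum() / union

        # brute-force complete-linkage agglomeration
        clusters = {i: [i] for i in range(5)}
        rows = {i: m.to_numpy()[i].astype(bool) for i in range(5)}
        heights = []
        next_id = 5
        while len(clusters) > 1:
            best = None
            for i in sorted(clusters):
                for j in sorted(clusters):
                    if i >= j:
                        continue
                    d = max(jac(rows[a], rows[b]) for a in clusters[i] for b in clusters[j])
                    if best is None or d < best[0]:
                        best = (d, i, j)
            d, i, j = best
            heights.append(d)
            clusters[next_id] = clusters.pop(i) + clusters.pop(j)
            next_id += 1
        assert np.allclose(sorted(z[:, 2]), sorted(heights))


class TestDinucleotides:
    def test_sliding_window_hand_count(self):
        counts, total = enr._dinucleotide_counts(["UGUGUG"])
        assert counts["UG"] == 3 and counts["GU"] == 2 and total == 5

    def test_identical_sets_fold_one(self):
        seqs = ["ACGUACGUAC", "GGGUUUACAC"]
        res = enr.dinucleotide_enrichment(seqs, list(seqs))
        assert all(r.fold_changes["background"] == pytest.approx(1.0) for r in res)
        assert all(r.adjusted_p["background"] >= r.p_values["background"] for r in res)

    def test_ug_doubled_density_significant(self, rng):
        bases = np.array(list("ACGU"))
        background = ["".join(rng.choice(bases, size=400)) for _ in range(40)]
        cryptic = [
            "".join("UG" if rng.random() < 0.25 else str(rng.choice(bases)) for _ in range(200))
            for _ in range(40)
        ]
        res = {r.label: r for r in enr.dinucleotide_enrichment(cryptic, background)}
        assert res["UG"].fold_changes["background"] > 1
        assert res["GU"].fold_changes["background"] > 1
        assert res["UG"].adjusted_p["background"] < 0.05


class TestRepeatOverlap:
    def _draws(self, rng, n=300):
        return [
            enr.NullExonDraw(f"e{i % 10}", mode, GenomicInterval("chr1", int(s), int(s) + 100), i)
            for mode in enr.NULL_MODES
            for i, s in enumerate(rng.integers(500_000, 900_000, n))
        ]

    def test_orientation_rule(self):
        exons = [GenomicInterval("chr1", 1000, 1100)]
        reps = [RepeatElement(GenomicInterval("chr1", 1020, 1060), "SINE", "B2", "-")]
        res = enr.repeat_overlap(exons, ["+"], [], {}, reps)
        by = {r.label: r for r in res}
        assert by["SINE:antisense"].cryptic_proportion == 1.0
        assert by["SINE:sense"].cryptic_proportion == 0.0

    def test_alu_excluded_from_sine(self):
        exons = [GenomicInterval("chr1", 1000, 1100)]
        reps = [RepeatElement(GenomicInterval("chr1", 1020, 1060), "Alu", "AluY", "-")]
        res = {r.label: r for r in enr.repeat_overlap(exons, ["+"], [], {}, reps)}
        assert res["Alu:antisense"].cryptic_proportion == 1.0
        assert res["SINE:antisense"].cryptic_proportion == 0.0

    def test_antisense_sine_spike_only_that_cell_significant(self, rng):
        exons = [GenomicInterval("chr1", i * 10_000, i * 10_000 + 100) for i in range(10)]
        strands = ["+"] * 10
        reps = [
            RepeatElement(GenomicInterval("chr1", e.start + 10, e.start + 90), "SINE", "B2", "-")
            for e in exons
        ]
        draws = self._draws(rng)
        null_strands = {f"e{i}": "+" for i in range(10)}
        res = enr.repeat_overlap(exons, strands, draws, null_strands, reps)
        sig = {r.label for r in res if any(v < 0.05 for v in r.adjusted_p.values())}
        assert sig == {"SINE:antisense"}


class TestFlankedFasta:
    def test_round_trip_and_minus_strand(self, small_pipeline, small_genome, tmp_path):
        final = small_pipeline.final_exons
        path = tmp_path / "flanked.fa"
        enr.export_flanked_fasta(final, small_genome, path, pad=100)
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        assert len(records) == len(final)
        for rec, ex in zip(records, final):
            exon_id, cls_, iv = enr.parse_flanked_header(">" + rec.description)
            assert exon_id == ex.exon_id and cls_ == ex.exon_class
            fetched = small_genome.fetch(
                GenomicInterval(iv.contig, iv.start, iv.end, iv.strand)
            )
            assert str(rec.seq) == fetched
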