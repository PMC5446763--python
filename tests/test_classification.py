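import numpy as np
import pytest

from conftest import make_gtf_df
from crypticsplice import annotation_io as aio
from crypticsplice import classification as cls
from crypticsplice.discovery import CrypticTag
from crypticsplice.intervals import GenomicInterval, SpliceJunction


@pytest.fixture()
def flat():
    # gene with exons [1000,1200), [2000,2200), [3000,3200): introns
    # [1200,2000) and [2200,3000)
    return aio.flatten_annotation(
        make_gtf_df({"g1": {"t1": [(1000, 1200), (2000, 2200), (3000, 3200)]}})
    )


def tag(start, end):
    return CrypticTag(
        f"g1:chr1:{start}-{end}", GenomicInterval("chr1", start, end), "g1", 1
    )


def J(d, a, n, sample=""):
    return SpliceJunction("chr1", d, a, ".", n, sample)


COND = {"c1": "control", "c2": "control", "d1": "depletion", "d2": "depletion"}


class TestCanonicalJunction:
    def test_exact_intron_match(self, flat):
        t = tag(1400, 1500)
        juncs = {"c1": [J(1200, 2000, 30)], "d1": [J(1200, 2000, 10)]}
        junction, counts, intron = cls.find_canonical_junction(t, juncs, flat)
        assert (junction.donor_end, junction.acceptor_start) == (1200, 2000)
        assert counts == {"c1": 30, "d1": 10}
        assert (intron.start, intron.end) == (1200, 2000)

    def test_ambiguous_spanning_ties_broken_by_control_count(self, flat):
        t = tag(1400, 1500)
        # no junction matches the flattened intron exactly; two span the tag
        juncs = {
            "c1": [J(1250, 1900, 5), J(1300, 1950, 40)],
            "d1": [J(1250, 1900, 50)],
        }
        junction, _, _ = cls.find_canonical_junction(t, juncs, flat, COND, "control")
        assert (junction.donor_end, junction.acceptor_start) == (1300, 1950)

    def test_tag_outside_intron_guarded(self, flat):
        with pytest.raises(ValueError, match="intron"):
            cls.find_canonical_junction(tag(1100, 1150), {}, flat)

    def test_no_spanning_junction_flagged(self, flat):
        junction, counts, intron = cls.find_canonical_junction(tag(1400, 1500), {"c1": []}, flat)
        assert junction is None and counts == {}


class TestCrypticJunctions:
    def test_placement_rules(self, flat):
        t = tag(1400, 1500)
        intron = GenomicInterval("chr1", 1200, 2000)
        juncs = {
            "d1": [
                J(1200, 1400, 7),   # upstream: donor at exon end, acceptor in tag
                J(1500, 2000, 9),   # downstream: donor at tag end, acceptor at exon
                J(1420, 1480, 99),  # wholly inside the tag: ignored
                J(1200, 2000, 5),   # canonical: neither
            ]
        }
        up, down = cls.find_cryptic_junctions(t, intron, juncs)
        assert up == {"d1": 7}
        assert down == {"d1": 9}

    def test_all_interior_placements_ignored(self, flat):
        t = tag(1400, 1500)
        intron = GenomicInterval("chr1", 1200, 2000)
        interior = [J(a, b, 1) for a in (1410, 1450) for b in (1460, 1490) if b > a]
        up, down = cls.find_cryptic_junctions(t, intron, {"d1": interior})
        assert up == {} and down == {}


class TestClassify:
    def test_mid_intron_both_sides_is_cassette(self, flat):
        intron = GenomicInterval("chr1", 1200, 2000)
        got = cls.classify(tag(1400, 1500), intron, {"d1": 5}, {"d1": 5}, flat)
        assert got == "cassette"

    def test_right_abutting_single_acceptor_is_five_prime_extension(self, flat):
        intron = GenomicInterval("chr1", 1200, 2000)
        got = cls.classify(tag(1950, 2000), intron, {"d1": 5}, {}, flat)
        assert got == "five_prime_extension"

    def test_left_abutting_single_donor_is_three_prime_extension(self, flat):
        intron = GenomicInterval("chr1", 1200, 2000)
        got = cls.classify(tag(1200, 1250), intron, {}, {"d1": 5}, flat)
        assert got == "three_prime_extension"

    def test_minus_strand_flips_extension_naming(self):
        flat = aio.flatten_annotation(
            make_gtf_df({"g1": {"strand": "-", "t1": [(1000, 1200), (2000, 2200)]}})
        )
        intron = GenomicInterval("chr1", 1200, 2000)
        assert cls.classify(tag(1950, 2000), intron, {"d1": 5}, {}, flat) == \
            "three_prime_extension"
        assert cls.classify(tag(1200, 1250), intron, {}, {"d1": 5}, flat) == \
            "five_prime_extension"

    def test_mid_intron_single_side_unclassified(self, flat):
        intron = GenomicInterval("chr1", 1200, 2000)
        assert cls.classify(tag(1400, 1500), intron, {"d1": 5}, {}, flat) is None


class TestPsi:
    @pytest.mark.parametrize("c,k,expected", [(10, 30, 0.25), (0, 50, 0.0), (0, 0, 0.0)])
    def test_ratio(self, c, k, expected):
        assert cls.compute_psi(c, k) == pytest.approx(expected)

    def test_delta_psi_hand_mean_difference(self):
        psis = {"c1": 0.0, "c2": 0.1, "d1": 0.5, "d2": 0.7}
        m_dep, m_ctl, dpsi = cls.aggregate_delta_psi(psis, COND)
        assert dpsi == pytest.approx(0.55)

    def test_delta_psi_antisymmetric_under_label_swap(self):
        psis = {"c1": 0.1, "c2": 0.2, "d1": 0.6, "d2": 0.9}
        _, _, d1 = cls.aggregate_delta_psi(psis, COND)
        swapped = {s: ("depletion" if c == "control" else "control") for s, c in COND.items()}
        _, _, d2 = cls.aggregate_delta_psi(psis, swapped)
        assert d1 == pytest.approx(-d2)


def make_exon(flat, up, down, canon, dpsi_up=0.2, dpsi_down=0.2, start=1400, end=1500):
    t = tag(start, end)
    ex = cls.CrypticExon(
        t, "cassette", GenomicInterval("chr1", 1200, 2000),
        SpliceJunction("chr1", 1200, 2000, ".", sum(canon.values())),
        canon, up, down,
    )
    ex.delta_psi_upstream = dpsi_up
    ex.delta_psi_downstream = dpsi_down
    return ex


class TestFilters:
    def test_low_side_delta_psi_removed(self, flat):
        ex = make_exon(
            flat, {"d1": 5, "d2": 5}, {"d1": 5, "d2": 5},
            {"c1": 30, "c2": 30}, dpsi_up=0.04, dpsi_down=0.20,
        )
        assert cls.apply_filters([ex], COND) == []
        assert "low_delta_psi" in ex.flags

    def test_canonical_nine_removed_ten_kept(self, flat):
        for total, kept in [(9, False), (10, True)]:
            ex = make_exon(
                flat, {"d1": 5, "d2": 5}, {"d1": 5, "d2": 5},
                {"c1": total - 4, "c2": 4}, dpsi_up=0.2, dpsi_down=0.2,
            )
            assert (cls.apply_filters([ex], COND) == [ex]) is kept

    def test_depletion_sample_without_junction_removed(self, flat):
        ex = make_exon(
            flat, {"d1": 5, "d2": 0}, {"d1": 5, "d2": 0}, {"c1": 30, "c2": 30}
        )
        assert cls.apply_filters([ex], COND) == []
        assert "missing_depletion_junction" in ex.flags

    def test_extension_single_side_passes_all_gates(self, flat):
        ex = make_exon(
            flat, {"d1": 3, "d2": 4}, {}, {"c1": 25, "c2": 25},
            dpsi_up=0.06, dpsi_down=float("nan"), start=1950, end=2000,
        )
        ex.exon_class = "five_prime_extension"
        assert cls.apply_filters([ex], COND) == [ex]

    @pytest.mark.parametrize("dpsi,kept", [(0.04, False), (0.06, True)])
    def test_delta_psi_boundary(self, flat, dpsi, kept):
        ex = make_exon(
            flat, {"d1": 5, "d2": 5}, {"d1": 5, "d2": 5},
            {"c1": 30, "c2": 30}, dpsi_up=dpsi, dpsi_down=dpsi,
        )
        assert (len(cls.apply_filters([ex], COND)) == 1) is kept


class TestInclusionRatio:
    def test_hand_ratios(self, flat):
        ex = make_exon(flat, {"d1": 5}, {"d1": 5}, {"c1": 100})
        panel = {"s1": [J(1200, 2000, 100), J(1200, 1400, 5), J(1500, 2000, 5)]}
        rep = cls.inclusion_ratio_screen([ex], panel, {"s1": "liver"})
        s = rep[ex.exon_id]["samples"]["s1"]
        assert s["upstream_ratio"] == pytest.approx(0.05)
        assert s["downstream_ratio"] == pytest.approx(0.05)
        assert rep[ex.exon_id]["groups"]["liver"]["mean"] == pytest.approx(0.05)

    def test_zero_cryptic_everywhere_gives_zero_ratios(self, flat):
        ex = make_exon(flat, {"d1": 5}, {"d1": 5}, {"c1": 100})
        panel = {"s1": [J(1200, 2000, 40)], "s2": [J(1200, 2000, 60)]}
        rep = cls.inclusion_ratio_screen([ex], panel, {"s1": "a", "s2": "a"})
        assert all(
            v["mean_ratio"] == 0 for v in rep[ex.exon_id]["samples"].values()
        )

    def test_zero_canonical_sample_skipped(self, flat):
        ex = make_exon(flat, {"d1": 5}, {"d1": 5}, {"c1": 100})
        panel = {"s1": [J(1200, 1400, 3)]}
        rep = cls.inclusion_ratio_screen([ex], panel, {"s1": "a"})
        assert rep[ex.exon_id]["skipped_zero_canonical"] == ["s1"]

    def test_known_inclusion_recovered_from_binomial_panel(self, flat, rng):
        ex = make_exon(flat, {"d1": 5}, {"d1": 5}, {"c1": 100})
        panel, groups = {}, {}
        for i in range(30):
            canon = 200
            up = int(rng.binomial(canon, 0.10))
            down = int(rng.binomial(canon, 0.10))
            panel[f"s{i}"] = [J(1200, 2000, canon), J(1200, 1400, up), J(1500, 2000, down)]
            groups[f"s{i}"] = "brain"
        rep = cls.inclusion_ratio_screen([ex], panel, groups)
        assert rep[ex.exon_id]["groups"]["brain"]["mean"] == pytest.approx(0.10, abs=0.02)


class TestQuantifyAndClassify:
    def test_end_to_end_small_fixture(self, flat):
        t = tag(1400, 1500)
        juncs = {
            "c1": [J(1200, 2000, 50)],
            "c2": [J(1200, 2000, 50)],
            "d1": [J(1200, 2000, 20), J(1200, 1400, 20), J(1500, 2000, 20)],
            "d2": [J(1200, 2000, 20), J(1200, 1400, 20), J(1500, 2000, 20)],
        }
        (ex,) = cls.quantify_and_classify([t], juncs, flat, COND)
        assert ex.exon_class == "cassette"
        assert ex.psi_upstream["d1"] == pytest.approx(0.5)
        assert ex.psi_upstream["c1"] == pytest.approx(0.0)
        assert ex.delta_psi_upstream == pytest.approx(0.5)
        final = cls.apply_filters([ex], COND)
        assert final == [ex]
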