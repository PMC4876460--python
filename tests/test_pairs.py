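import random
from dataclasses import replace

import pytest

import guideseek as gs
from guideseek.offtarget import AlignmentCounts, OffTargetSite
from guideseek.pairs import PairGeometryError

PL = "TACTATCATGATACTAGTCA"
PR = "ATGATACGTATCATGCATAT"


def site(strand, start, end, contig="chr1", counts=AlignmentCounts()):
    length = end - start + 1
    return OffTargetSite(
        contig_id=contig,
        strand=strand,
        start=start,
        end=end,
        site_seq="A" * length,
        pam_seq="TGG",
        counts=counts,
    )


def pam_out_query(spacer: int) -> str:
    return "TTATT" + gs.reverse_complement(PL + "TGG") + "T" * spacer + PR + "TGG" + "TTATT"


class TestSpacerLength:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((101, 120), (135, 154), 14),
            ((1, 20), (21, 40), 0),
            ((1, 20), (38, 57), 17),
        ],
    )
    def test_between_region_arithmetic(self, a, b, expected):
        left = site("-", *a)
        right = site("+", *b)
        assert gs.spacer_length(left, right) == expected
        assert gs.spacer_length(right, left) == expected  # order-insensitive

    def test_same_strand_rejected(self):
        with pytest.raises(PairGeometryError):
            gs.spacer_length(site("+", 1, 20), site("+", 40, 59))

    def test_overlap_rejected(self):
        with pytest.raises(PairGeometryError):
            gs.spacer_length(site("-", 1, 20), site("+", 15, 34))

    def test_pam_in_rejected(self):
        # forward site upstream of reverse site means the PAMs face inward
        with pytest.raises(PairGeometryError):
            gs.spacer_length(site("+", 1, 20), site("-", 40, 59))


class TestEnumeratePairs:
    def test_rfn_window_accepts_spacer_15(self):
        settings = gs.default_settings("rfn")
        cands = gs.enumerate_guides(pam_out_query(15), settings)
        pairs = gs.enumerate_pairs(cands, settings)
        assert len(pairs) == 1
        assert pairs[0].spacer_len == 15
        assert (pairs[0].left.strand, pairs[0].right.strand) == ("-", "+")

    def test_rfn_window_rejects_spacer_13(self):
        settings = gs.default_settings("rfn")
        cands = gs.enumerate_guides(pam_out_query(13), settings)
        assert gs.enumerate_pairs(cands, settings) == []

    def test_cas9n_accepts_wide_spacer(self):
        settings = gs.default_settings("cas9n")
        cands = gs.enumerate_guides(pam_out_query(500), settings)
        pairs = gs.enumerate_pairs(cands, settings)
        assert len(pairs) == 1 and pairs[0].spacer_len == 500

    def test_mode_defaults(self):
        rfn = gs.default_settings("rfn")
        assert (rfn.spacer_min, rfn.spacer_max) == (14, 17)
        cas9n = gs.default_settings("cas9n")
        assert (cas9n.spacer_min, cas9n.spacer_max) == (0, 1000)

    def test_single_guide_mode_rejected(self):
        with pytest.raises(Exception):
            gs.enumerate_pairs([], gs.default_settings("cas9"))


class TestPairSites:
    def make_settings(self, max_bulged=0, smin=14, smax=17):
        return replace(
            gs.default_settings("rfn"),
            spacer_min=smin,
            spacer_max=smax,
            max_bulged_strands=max_bulged,
        )

    def test_pam_out_pair_within_spacer(self):
        s = self.make_settings()
        left = [site("-", 101, 120)]
        right = [site("+", 137, 156)]  # spacer 16
        (pair,) = gs.pair_sites(left, right, s)
        assert (pair.spacer_len, pair.bulged_strands) == (16, 0)

    def test_bulged_strand_budget(self):
        bulged = site("-", 101, 120, counts=AlignmentCounts(nonseed_ins=1))
        right = [site("+", 137, 156)]
        assert gs.pair_sites([bulged], right, self.make_settings(max_bulged=0)) == []
        (pair,) = gs.pair_sites([bulged], right, self.make_settings(max_bulged=1))
        assert pair.bulged_strands == 1
        assert gs.bulged_strand_count(pair) == 1

    def test_two_bulged_members(self):
        a = site("-", 101, 120, counts=AlignmentCounts(seed_del=1))
        b = site("+", 137, 156, counts=AlignmentCounts(nonseed_ins=1))
        (pair,) = gs.pair_sites([a], [b], self.make_settings(max_bulged=2))
        assert pair.bulged_strands == 2

    def test_same_strand_sites_never_pair(self):
        s = self.make_settings()
        assert gs.pair_sites([site("+", 101, 120)], [site("+", 137, 156)], s) == []

    def test_symmetric_in_member_lists(self):
        rng = random.Random(5)
        s = self.make_settings(smin=0, smax=60)
        a, b = [], []
        for _ in range(25):
            strand = rng.choice("+-")
            start = rng.randint(1, 900)
            (a if rng.random() < 0.5 else b).append(site(strand, start, start + 19))
        keys_ab = {
            (p.site_a.start, p.site_b.start) for p in gs.pair_sites(a, b, s)
        }
        keys_ba = {
            (p.site_a.start, p.site_b.start) for p in gs.pair_sites(b, a, s)
        }
        assert keys_ab == keys_ba

    def test_widening_spacer_range_only_adds_pairs(self):
        rng = random.Random(6)
        a = [site("-", p, p + 19) for p in rng.sample(range(1, 2000), 12)]
        b = [site("+", p, p + 19) for p in rng.sample(range(1, 2000), 12)]
        narrow = {
            (p.site_a.start, p.site_b.start)
            for p in gs.pair_sites(a, b, self.make_settings(smin=10, smax=40))
        }
        wide = {
            (p.site_a.start, p.site_b.start)
            for p in gs.pair_sites(a, b, self.make_settings(smin=0, smax=120))
        }
        assert narrow <= wide
        for p in gs.pair_sites(a, b, self.make_settings(smin=10, smax=40)):
            assert 10 <= p.spacer_len <= 40

    @pytest.mark.parametrize("trial", range(8))
    def test_agrees_with_brute_force_pairing(self, trial):
        rng = random.Random(40 + trial)
        s = self.make_settings(
            max_bulged=rng.randint(0, 2),
            smin=rng.randint(0, 20),
            smax=rng.randint(20, 80),
        )
        def random_sites(n):
            out = []
            for _ in range(n):
                start = rng.randint(1, 1500)
                counts = AlignmentCounts(nonseed_ins=rng.randint(0, 1))
                out.append(
                    site(rng.choice("+-"), start, start + 19,
                         contig=rng.choice(["chr1", "chr2"]), counts=counts)
                )
            return out
        a, b = random_sites(15), random_sites(15)
        got = {
            (p.site_a.contig_id, p.site_a.start, p.site_b.start, p.bulged_strands)
            for p in gs.pair_sites(a, b, s)
        }
        want = {
            (p.site_a.contig_id, p.site_a.start, p.site_b.start, p.bulged_strands)
            for p in gs.brute_force_pairs(a, b, s)
        }
        assert got == want

    def test_count_pair_targets_on_planted_pair(self):
        sc = gs.scenario("rfn-spacer-sweep", seed=2)
        cands = gs.enumerate_guides(sc.query, sc.settings)
        (gp,) = gs.enumerate_pairs(cands, sc.settings)
        count, flag = gs.count_pair_targets(gp, sc.genome, sc.settings)
        assert count == len(sc.truth_pairs)
        assert flag is (count == 1)
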