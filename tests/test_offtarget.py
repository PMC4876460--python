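import random
from dataclasses import replace

import pytest

import guideseek as gs
from guideseek.offtarget import AlignmentCounts
from guideseek.settings import BasicBudgets, RegionBudgets, SpecificBudgets

from conftest import random_protospacer, random_search_settings, site_signature

PROTO = "TACATGATCGTATCAGTACT"


def specific(seed_mm=0, seed_ins=0, seed_del=0, non_mm=0, non_ins=0, non_del=0):
    return replace(
        gs.default_settings("cas9"),
        filter_form="specific",
        specific=SpecificBudgets(
            RegionBudgets(seed_mm, seed_ins, seed_del),
            RegionBudgets(non_mm, non_ins, non_del),
        ),
    )


class TestAlignWindow:
    def test_identity_is_all_zero(self, cas9_defaults):
        counts = gs.align_window(PROTO, PROTO, cas9_defaults)
        assert counts == AlignmentCounts()
        assert counts.is_perfect

    def test_pam_distal_mismatch_is_nonseed(self, cas9_defaults):
        window = "G" + PROTO[1:]
        counts = gs.align_window(PROTO, window, cas9_defaults)
        assert counts.as_tuple() == (0, 0, 0, 1, 0, 0)

    def test_seed_deletion_attributed_to_seed(self):
        # window = protospacer with one seed base removed (gRNA bulge in the seed)
        s = specific(seed_ins=1)
        window = PROTO[:15] + PROTO[16:]
        counts = gs.align_window(PROTO, window, s)
        assert counts.as_tuple() == (0, 1, 0, 0, 0, 0)

    def test_extra_genomic_base_is_a_deletion(self):
        s = specific(non_del=1)
        window = PROTO[:3] + "G" + PROTO[3:]
        counts = gs.align_window(PROTO, window, s)
        assert counts.as_tuple() == (0, 0, 0, 0, 0, 1)

    def test_over_budget_returns_none(self, zero_budget_settings):
        window = "G" + PROTO[1:]
        assert gs.align_window(PROTO, window, zero_budget_settings) is None

    def test_n_in_genome_scores_as_mismatch(self, cas9_defaults):
        window = PROTO[:5] + "N" + PROTO[6:]
        counts = gs.align_window(PROTO, window, cas9_defaults)
        assert counts.as_tuple() == (0, 0, 0, 1, 0, 0)


class TestFilters:
    def test_all_zero_passes_any_budgets(self, cas9_defaults, zero_budget_settings):
        z = AlignmentCounts()
        assert gs.passes_basic(z, cas9_defaults)
        assert gs.passes_basic(z, zero_budget_settings)
        assert gs.passes_specific(z, specific())

    def test_basic_seed_cap_binds_before_total(self):
        s = replace(
            gs.default_settings("cas9"),
            basic=BasicBudgets(max_mm_total=3, max_gap_total=0, max_mm_seed=1, max_gap_seed=0),
        )
        assert not gs.passes_basic(AlignmentCounts(seed_mm=2), s)
        assert gs.passes_basic(AlignmentCounts(nonseed_mm=3), s)

    def test_specific_caps_are_independent(self):
        s = specific(seed_ins=0, non_del=1)
        assert not gs.passes_specific(AlignmentCounts(seed_ins=1), s)
        assert gs.passes_specific(AlignmentCounts(nonseed_del=1), s)


class TestFindSites:
    def test_planted_exact_site_found_once(self, zero_budget_settings):
        genome = gs.random_genome(2000, 0.5, seed=9)
        genome, _ = gs.plant(
            genome, gs.PlantSpec("chr1", 700, "+", PROTO, "AGG"), zero_budget_settings
        )
        sites = gs.find_sites(PROTO, genome, zero_budget_settings)
        assert site_signature(sites) == [("chr1", "+", 701, 720, (0, 0, 0, 0, 0, 0))]
        assert sites[0].is_perfect

    def test_seed_mismatch_budget_toggles_variant(self):
        genome = gs.random_genome(2000, 0.5, seed=10)
        s0 = specific(seed_mm=0)
        genome, _ = gs.plant(
            genome, gs.PlantSpec("chr1", 400, "+", PROTO, "TGG"), s0
        )
        genome, _ = gs.plant(
            genome, gs.PlantSpec("chr1", 900, "-", PROTO, "TGG", edits=(("mm", 13),)), s0
        )
        strict_sites = gs.find_sites(PROTO, genome, s0)
        assert [(x.start, x.strand) for x in strict_sites] == [(401, "+")]
        s1 = specific(seed_mm=1)
        tolerant_sites = gs.find_sites(PROTO, genome, s1)
        assert [(x.start, x.strand) for x in tolerant_sites] == [(401, "+"), (901, "-")]
        assert tolerant_sites[1].counts.as_tuple() == (1, 0, 0, 0, 0, 0)

    def test_nag_pam_reported_only_under_nrg(self, zero_budget_settings):
        genome = gs.random_genome(1200, 0.5, seed=12)
        genome, _ = gs.plant(
            genome, gs.PlantSpec("chr1", 300, "+", PROTO, "AAG"), zero_budget_settings
        )
        under_ngg = gs.find_sites(
            PROTO, genome, replace(zero_budget_settings, off_pam=gs.PamPattern("NGG"))
        )
        under_nrg = gs.find_sites(
            PROTO, genome, replace(zero_budget_settings, off_pam=gs.PamPattern("NRG"))
        )
        assert under_ngg == []
        assert [(x.start, x.pam_seq) for x in under_nrg] == [(301, "AAG")]

    def test_count_genome_targets_highlight_rule(self, zero_budget_settings):
        genome = gs.random_genome(1500, 0.5, seed=13)
        genome, _ = gs.plant(
            genome, gs.PlantSpec("chr1", 200, "+", PROTO, "TGG"), zero_budget_settings
        )
        assert gs.count_genome_targets(PROTO, genome, zero_budget_settings) == (1, True)
        genome, _ = gs.plant(
            genome, gs.PlantSpec("chr1", 800, "+", PROTO, "TGG"), zero_budget_settings
        )
        assert gs.count_genome_targets(PROTO, genome, zero_budget_settings) == (2, False)
        absent = "ACTATGCATACGATCAGTAT"
        assert gs.count_genome_targets(absent, genome, zero_budget_settings) == (0, False)


class TestOracleAgreement:
    @pytest.mark.parametrize("trial", range(12))
    def test_random_instances_match_brute_force(self, trial):
        rng = random.Random(100 + trial)
        settings = random_search_settings(rng)
        genome = gs.random_genome(rng.randint(150, 450), rng.uniform(0.3, 0.7), seed=trial)
        proto = random_protospacer(rng, genome, settings.grna_len)
        assert site_signature(gs.find_sites(proto, genome, settings)) == site_signature(
            gs.brute_force_sites(proto, genome, settings)
        )

    def test_oracle_guard_bound(self, cas9_defaults):
        genome = gs.random_genome(60_000, 0.5, seed=1)
        with pytest.raises(ValueError, match="guard"):
            gs.brute_force_sites(PROTO, genome, cas9_defaults)
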