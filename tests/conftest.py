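import random
from dataclasses import replace

import pytest
from hypothesis import settings as hyp_settings

import guideseek as gs
from guideseek.settings import BasicBudgets, RegionBudgets, SpecificBudgets

hyp_settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
hyp_settings.load_profile("ci")


@pytest.fixture
def cas9_defaults():
    return gs.default_settings("cas9")


@pytest.fixture
def zero_budget_settings():
    """Cas9 defaults with every mismatch/gap budget at zero (exact matches only)."""
    return replace(
        gs.default_settings("cas9"),
        basic=BasicBudgets(max_mm_total=0, max_gap_total=0, max_mm_seed=0, max_gap_seed=0),
    )


def random_search_settings(rng: random.Random, mode: str = "cas9") -> gs.SearchSettings:
    """Small random budget/geometry draws for randomized equivalence checks."""
    form = rng.choice(["basic", "specific"])
    kw = dict(
        grna_len=rng.choice([17, 18, 20]),
        seed_len=rng.choice([8, 10, 12]),
        filter_form=form,
        off_pam=gs.PamPattern(rng.choice(["NRG", "NGG", "NAG"])),
    )
    if form == "basic":
        kw["basic"] = BasicBudgets(
            rng.randint(0, 3), rng.randint(0, 2), rng.randint(0, 2), rng.randint(0, 1)
        )
    else:
        kw["specific"] = SpecificBudgets(
            RegionBudgets(rng.randint(0, 1), rng.randint(0, 1), rng.randint(0, 1)),
            RegionBudgets(rng.randint(0, 2), rng.randint(0, 1), rng.randint(0, 1)),
        )
    return replace(gs.default_settings(mode), **kw)


def random_protospacer(rng: random.Random, genome: gs.Genome, length: int) -> str:
    """Half the time sample the protospacer from the genome so near-matches exist."""
    seq = genome.contigs[0].residues
    if rng.random() < 0.6 and len(seq) > length + 4:
        st = rng.randint(0, len(seq) - length - 4)
        window = seq[st : st + length]
        if "N" not in window:
            return window
    return "".join(rng.choice("ACGT") for _ in range(length))


def site_signature(sites):
    return [(s.contig_id, s.strand, s.start, s.end, s.counts.as_tuple()) for s in sites]
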