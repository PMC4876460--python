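"""Synthetic genomes and queries with planted sites and exhaustive truth sets.

Every planted site is written into a reproducible random background together
with a machine-checkable expectation (coordinates, strand, per-region edit
counts, pair spacer).  Scenario builders assemble complete test instances —
genome + query + settings + truth — for one pipeline aspect each, and verify
by exhaustive enumeration that the truth set is *complete* for the scenario's
genome under its settings; a background that happens to contain an unplanned
within-budget site is re-rolled deterministically (seed+1, seed+2, ...).

When a scenario's edit budgets admit gaps, a perfectly planted site also
matches at shifted intervals sharing its PAM (one bulge against the same
PAM); those shadow records are part of the constructed truth, not an
artefact of the oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .offtarget import AlignmentCounts
from .oracle import brute_force_pairs, brute_force_sites
from .sequence import Contig, Genome, PamPattern, reverse_complement
from .settings import BasicBudgets, RegionBudgets, SearchSettings, SpecificBudgets, default_settings

SCENARIO_NAMES = (
    "cas9-basic",
    "cas9-specific-budgets",
    "cas9n-spacer-sweep",
    "rfn-spacer-sweep",
    "bulge-tolerance",
    "pam-nag",
)

_MAX_REROLLS = 32

# fixed guides used by the scenario catalogue: no GG/CC dinucleotides, so the
# only PAM contexts in engineered queries are the ones placed on purpose
GUIDE_A = "TACATGATCGTATCAGTACT"
GUIDE_B = "ACTATGCATACGATCAGTAT"
GUIDE_L = "TACTATCATGATACTAGTCA"
GUIDE_R = "ATGATACGTATCATGCATAT"


class PlantError(ValueError):
    """A plant does not fit the genome or collides with a prior plant."""


@dataclass(frozen=True)
class PlantSpec:
    """One site to write into a background genome.

    ``position`` is the 0-based forward-strand start of the protospacer
    region; for reverse-strand plants the PAM is written immediately to its
    left (reverse-complemented).  ``edits`` are (op, protospacer position[,
    base]) with op in {"mm", "ins", "del"}: "ins" removes the base at that
    protospacer position from the genomic copy (gRNA bulge), "del" inserts an
    extra genomic base before it (DNA bulge).
    """

    contig_id: str
    position: int
    strand: str
    protospacer: str
    pam: str
    edits: tuple = ()
    partner: Optional["PlantSpec"] = None
    spacer_len: Optional[int] = None


@dataclass(frozen=True)
class TruthRecord:
    """Expected site for one planted guide occurrence."""

    guide: str
    contig_id: str
    strand: str
    start: int  # 1-based inclusive, forward strand
    end: int
    counts: AlignmentCounts

    @property
    def key(self) -> tuple:
        return (self.contig_id, self.strand, self.start, self.end, self.counts.as_tuple())


@dataclass(frozen=True)
class PairTruth:
    """Expected retained PAM-out site pair."""

    left: TruthRecord
    right: TruthRecord
    spacer_len: int

    @property
    def key(self) -> tuple:
        return (self.left.contig_id, self.left.start, self.left.end, self.right.start, self.right.end)


@dataclass(frozen=True)
class Scenario:
    """A complete reproducible test instance for one pipeline aspect."""

    name: str
    genome: Genome
    query: str
    settings: SearchSettings
    truth_sites: tuple[TruthRecord, ...]
    truth_pairs: tuple[PairTruth, ...]
    background_seed: int


def random_genome(
    total_len: int,
    gc_fraction: float = 0.5,
    seed: int = 0,
    n_contigs: int = 1,
    contig_prefix: str = "chr",
) -> Genome:
    """Reproducible i.i.d. random genome with the requested GC fraction."""
    if total_len <= 0:
        raise ValueError("total_len must be positive")
    if not (0.0 <= gc_fraction <= 1.0):
        raise ValueError("gc_fraction must lie in [0, 1]")
    if not (1 <= n_contigs <= total_len):
        raise ValueError("n_contigs must lie in [1, total_len]")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    bases = np.array(list("ACGT"))
    per = total_len // n_contigs
    contigs = []
    for k in range(n_contigs):
        n = per if k < n_contigs - 1 else total_len - per * (n_contigs - 1)
        contigs.append(
            Contig(f"{contig_prefix}{k + 1}", "".join(rng.choice(bases, size=n, p=p)))
        )
    return Genome(tuple(contigs))


def _apply_edits(
    protospacer: str, edits: Sequence[tuple], seed_start: int
) -> tuple[str, AlignmentCounts]:
    """Derive the genomic site sequence and the expected per-region counts."""
    L = len(protospacer)
    site = list(protospacer)
    c = [0, 0, 0, 0, 0, 0]  # seed_mm, seed_ins, seed_del, nonseed_mm, nonseed_ins, nonseed_del

    def idx(kind: int, pos: int) -> int:
        return kind if pos >= seed_start else kind + 3

    for edit in sorted(edits, key=lambda e: -e[1]):
        op, pos = edit[0], edit[1]
        base = edit[2] if len(edit) > 2 else None
        if not (0 <= pos < L):
            raise PlantError(f"edit position {pos} outside protospacer of length {L}")
        if op == "mm":
            if base is None:
                base = "ACGT"[("ACGT".index(protospacer[pos]) + 1) % 4]
            site[pos] = base
            c[idx(0, pos)] += 1
        elif op == "ins":
            del site[pos]
            c[idx(1, pos)] += 1
        elif op == "del":
            if base is None:
                avoid = {protospacer[pos]}
                if pos > 0:
                    avoid.add(protospacer[pos - 1])
                base = next(b for b in "ACGT" if b not in avoid)
            site.insert(pos, base)
            c[idx(2, pos)] += 1
        else:
            raise PlantError(f"unknown edit op {op!r}")
    return "".join(site), AlignmentCounts.from_tuple(tuple(c))


def plant(
    genome: Genome,
    spec: PlantSpec,
    settings: SearchSettings,
    occupied: Optional[list] = None,
) -> tuple[Genome, tuple[TruthRecord, ...]]:
    """Write a (possibly edited) protospacer+PAM into the genome.

    Returns the edited genome and the truth record(s); a partner spec, if
    present, is planted too.  ``occupied`` is a mutable registry of
    (contig_id, start0, end0) extents used to reject overlapping plants.
    """
    contig = genome.get(spec.contig_id)
    site_seq, counts = _apply_edits(spec.protospacer, spec.edits, settings.seed_start)
    if spec.strand == "+":
        insert = site_seq + spec.pam
        start0 = spec.position
    elif spec.strand == "-":
        insert = reverse_complement(site_seq + spec.pam)
        start0 = spec.position - len(spec.pam)
    else:
        raise PlantError(f"strand must be '+' or '-', got {spec.strand!r}")
    end0 = start0 + len(insert)  # half-open extent of the written bases
    if start0 < 0 or end0 > len(contig):
        raise PlantError(
            f"plant at {spec.contig_id}:{spec.position} ({spec.strand}) exceeds contig bounds"
        )
    if occupied is not None:
        for cid, s, e in occupied:
            if cid == spec.contig_id and start0 < e and s < end0:
                raise PlantError(f"plant at {spec.contig_id}:{spec.position} overlaps a prior plant")
        occupied.append((spec.contig_id, start0, end0))
    residues = contig.residues[:start0] + insert + contig.residues[end0:]
    new_contigs = tuple(
        Contig(c.id, residues) if c.id == contig.id else c for c in genome
    )
    new_genome = Genome(new_contigs)
    record = TruthRecord(
        guide=spec.protospacer,
        contig_id=spec.contig_id,
        strand=spec.strand,
        start=spec.position + 1,
        end=spec.position + len(site_seq),
        counts=counts,
    )
    records = (record,)
    if spec.partner is not None:
        new_genome, partner_records = plant(new_genome, spec.partner, settings, occupied)
        records = records + partner_records
    return new_genome, records


def _shadow_records(rec: TruthRecord, settings: SearchSettings) -> list[TruthRecord]:
    """Bulge-shifted intervals a *perfectly edited region end* also matches.

    Under gap budgets, a planted site additionally aligns at intervals whose
    PAM-distal edge is shifted by one bulge: one extra gRNA-bulge (interval
    one base shorter) and/or one extra DNA-bulge (one base longer), each
    attributed to the non-seed region (the distal edge).  Only single-shift
    shadows are generated; scenario budgets are chosen so deeper shifts are
    infeasible.
    """
    out = []
    c = rec.counts
    gaps_left = (
        settings.basic.max_gap_total - c.total_gaps
        if settings.filter_form == "basic"
        else None
    )
    # one more gRNA bulge (shorter interval)
    ins_ok = (
        (gaps_left or 0) >= 1
        if settings.filter_form == "basic"
        else c.nonseed_ins < settings.specific.nonseed.max_ins
    )
    del_ok = (
        (gaps_left or 0) >= 1
        if settings.filter_form == "basic"
        else c.nonseed_del < settings.specific.nonseed.max_del
    )
    if ins_ok:
        shifted = replace(
            rec,
            counts=replace(c, nonseed_ins=c.nonseed_ins + 1),
            **(
                {"start": rec.start + 1}
                if rec.strand == "+"
                else {"end": rec.end - 1}
            ),
        )
        out.append(shifted)
    if del_ok:
        shifted = replace(
            rec,
            counts=replace(c, nonseed_del=c.nonseed_del + 1),
            **(
                {"start": rec.start - 1}
                if rec.strand == "+"
                else {"end": rec.end + 1}
            ),
        )
        out.append(shifted)
    return out


def scenario(name: str, seed: int = 0) -> Scenario:
    """Build a named scenario; deterministic in (name, seed)."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; known: {', '.join(SCENARIO_NAMES)}"
        ) from None
    last_err: Optional[str] = None
    for attempt in range(_MAX_REROLLS):
        bg_seed = seed + attempt
        built = builder(bg_seed)
        ok, last_err = _verify(built)
        if ok:
            return built
    raise RuntimeError(
        f"could not build scenario {name!r} with a clean background after "
        f"{_MAX_REROLLS} attempts (seed {seed}): {last_err}"
    )


def _verify(sc: Scenario) -> tuple[bool, Optional[str]]:
    """Exhaustively check that the constructed truth is complete and exact."""
    guides = sorted({r.guide for r in sc.truth_sites})
    brute_by_guide = {}
    for g in guides:
        actual = brute_force_sites(g, sc.genome, sc.settings)
        brute_by_guide[g] = actual
        actual_keys = {(s.contig_id, s.strand, s.start, s.end, s.counts.as_tuple()) for s in actual}
        expected_keys = {r.key for r in sc.truth_sites if r.guide == g}
        if actual_keys != expected_keys:
            return False, (
                f"guide {g}: oracle found {sorted(actual_keys - expected_keys)} beyond truth, "
                f"missing {sorted(expected_keys - actual_keys)}"
            )
    if sc.truth_pairs:
        gl = sc.truth_pairs[0].left.guide
        gr = sc.truth_pairs[0].right.guide
        actual_pairs = brute_force_pairs(
            brute_by_guide[gl], brute_by_guide[gr], sc.settings
        )
        actual_keys = {
            (p.site_a.contig_id, p.site_a.start, p.site_a.end, p.site_b.start, p.site_b.end)
            for p in actual_pairs
        }
        expected_keys = {p.key for p in sc.truth_pairs}
        if actual_keys != expected_keys:
            return False, f"pairs: oracle {sorted(actual_keys)} != truth {sorted(expected_keys)}"
    return True, None


# ---------------------------------------------------------------------------
# scenario builders
# ---------------------------------------------------------------------------

_PAD = "TTATT"


def _single_guide_query(guide: str, pam: str = "TGG") -> str:
    return _PAD + guide + pam + _PAD


def _build_cas9_basic(bg_seed: int) -> Scenario:
    """Basic-form filtering: total/seed mismatch caps with a one-gap allowance."""
    settings = default_settings("cas9")  # basic (3, 1, 1, 0)
    genome = random_genome(2000, 0.5, seed=bg_seed)
    occupied: list = []
    truth: list[TruthRecord] = []
    plants = [
        ((), True),                                   # exact
        ((("mm", 4),), True),                         # 1 non-seed mismatch
        ((("mm", 13),), True),                        # 1 seed mismatch (cap is 1)
        ((("mm", 11), ("mm", 14)), False),            # 2 seed mismatches: excluded
        ((("mm", 2), ("mm", 4), ("mm", 6)), True),    # 3 non-seed mismatches (total cap 3)
        ((("mm", 2), ("mm", 5), ("mm", 9), ("mm", 15)), False),  # 4 mismatches: excluded
    ]
    pos = 100
    for k, (edits, retained) in enumerate(plants):
        strand = "+" if k % 2 == 0 else "-"
        position = pos if strand == "+" else pos + 3
        spec = PlantSpec("chr1", position, strand, GUIDE_A, "TGG", edits=tuple(edits))
        genome, recs = plant(genome, spec, settings, occupied)
        if retained:
            truth.extend(recs)
            for rec in recs:
                truth.extend(_shadow_records(rec, settings))
        pos += 300
    return Scenario(
        name="cas9-basic",
        genome=genome,
        query=_single_guide_query(GUIDE_A),
        settings=settings,
        truth_sites=tuple(truth),
        truth_pairs=(),
        background_seed=bg_seed,
    )


def _build_cas9_specific(bg_seed: int) -> Scenario:
    """Specific-form filtering: independent per-region mismatch caps, no gaps."""
    settings = replace(
        default_settings("cas9"),
        filter_form="specific",
        specific=SpecificBudgets(
            seed=RegionBudgets(max_mm=1, max_ins=0, max_del=0),
            nonseed=RegionBudgets(max_mm=2, max_ins=0, max_del=0),
        ),
    )
    genome = random_genome(2000, 0.5, seed=bg_seed)
    occupied: list = []
    truth: list[TruthRecord] = []
    plants = [
        ((), True),                                    # exact
        ((("mm", 13),), True),                         # seed mm 1 <= 1
        ((("mm", 9), ("mm", 13)), False),              # seed mm 2: excluded
        ((("mm", 2), ("mm", 5)), True),                # non-seed mm 2 <= 2
        ((("mm", 1), ("mm", 3), ("mm", 5)), False),    # non-seed mm 3: excluded
        ((("mm", 12), ("mm", 2), ("mm", 5)), True),    # seed 1 + non-seed 2: retained
    ]
    pos = 100
    for k, (edits, retained) in enumerate(plants):
        strand = "+" if k % 2 == 0 else "-"
        position = pos if strand == "+" else pos + 3
        spec = PlantSpec("chr1", position, strand, GUIDE_A, "TGG", edits=tuple(edits))
        genome, recs = plant(genome, spec, settings, occupied)
        if retained:
            truth.extend(recs)
        pos += 300
    return Scenario(
        name="cas9-specific-budgets",
        genome=genome,
        query=_single_guide_query(GUIDE_A),
        settings=settings,
        truth_sites=tuple(truth),
        truth_pairs=(),
        background_seed=bg_seed,
    )


def _build_bulge_tolerance(bg_seed: int) -> Scenario:
    """Single non-seed bulges tolerated, seed bulges rejected."""
    settings = replace(
        default_settings("cas9"),
        filter_form="specific",
        specific=SpecificBudgets(
            seed=RegionBudgets(max_mm=0, max_ins=0, max_del=0),
            nonseed=RegionBudgets(max_mm=0, max_ins=1, max_del=1),
        ),
        off_pam=PamPattern("NGG"),
    )
    genome = random_genome(2000, 0.5, seed=bg_seed)
    occupied: list = []
    truth: list[TruthRecord] = []
    plants = [
        ((), True),                    # exact: perfect + two shadow intervals
        ((("ins", 3),), True),         # non-seed gRNA bulge: tolerated
        ((("del", 3),), True),         # non-seed DNA bulge: tolerated
        ((("ins", 15),), False),       # seed bulge: excluded outright
    ]
    pos = 100
    for k, (edits, retained) in enumerate(plants):
        strand = "+" if k % 2 == 0 else "-"
        position = pos if strand == "+" else pos + 3
        spec = PlantSpec("chr1", position, strand, GUIDE_A, "TGG", edits=tuple(edits))
        genome, recs = plant(genome, spec, settings, occupied)
        if retained:
            truth.extend(recs)
            for rec in recs:
                truth.extend(_shadow_records(rec, settings))
        pos += 300
    return Scenario(
        name="bulge-tolerance",
        genome=genome,
        query=_single_guide_query(GUIDE_A),
        settings=settings,
        truth_sites=tuple(truth),
        truth_pairs=(),
        background_seed=bg_seed,
    )


def _build_pam_nag(bg_seed: int) -> Scenario:
    """NAG is a valid off-target PAM under NRG but never an on-target PAM."""
    settings = replace(
        default_settings("cas9"),
        basic=BasicBudgets(max_mm_total=0, max_gap_total=0, max_mm_seed=0, max_gap_seed=0),
    )
    genome = random_genome(1500, 0.5, seed=bg_seed)
    occupied: list = []
    truth: list[TruthRecord] = []
    genome, recs = plant(
        genome, PlantSpec("chr1", 200, "+", GUIDE_A, "TGG"), settings, occupied
    )
    truth.extend(recs)
    genome, recs = plant(
        genome, PlantSpec("chr1", 600, "+", GUIDE_A, "TAG"), settings, occupied
    )
    truth.extend(recs)
    # a query region carrying a NAG context must never be enumerated on-target
    query = _PAD + GUIDE_A + "TGG" + "TATTT" + GUIDE_B + "TAG" + _PAD
    return Scenario(
        name="pam-nag",
        genome=genome,
        query=query,
        settings=settings,
        truth_sites=tuple(truth),
        truth_pairs=(),
        background_seed=bg_seed,
    )


def _zero_budgets(settings: SearchSettings) -> SearchSettings:
    return replace(
        settings,
        basic=BasicBudgets(max_mm_total=0, max_gap_total=0, max_mm_seed=0, max_gap_seed=0),
    )


def _build_sweep(
    name: str,
    mode: str,
    spacers: Sequence[int],
    separation: int,
    query_spacer: int,
    bg_seed: int,
) -> Scenario:
    settings = _zero_budgets(default_settings(mode))
    smin, smax = settings.spacer_min, settings.spacer_max
    lead = 60
    total = lead + sum(46 + s + separation for s in spacers) + lead
    genome = random_genome(total, 0.5, seed=bg_seed)
    occupied: list = []
    truth: list[TruthRecord] = []
    pairs: list[PairTruth] = []
    cursor = lead
    for s in spacers:
        left_pos = cursor + 3  # room for the left (reverse-strand) PAM
        right_pos = left_pos + len(GUIDE_L) + s
        genome, (lrec,) = plant(
            genome, PlantSpec("chr1", left_pos, "-", GUIDE_L, "TGG"), settings, occupied
        )
        genome, (rrec,) = plant(
            genome, PlantSpec("chr1", right_pos, "+", GUIDE_R, "TGG"), settings, occupied
        )
        truth.extend([lrec, rrec])
        if smin <= s <= smax:
            pairs.append(PairTruth(left=lrec, right=rrec, spacer_len=s))
        cursor = right_pos + len(GUIDE_R) + 3 + separation
    query = (
        _PAD
        + reverse_complement(GUIDE_L + "TGG")
        + "T" * query_spacer
        + GUIDE_R
        + "TGG"
        + _PAD
    )
    return Scenario(
        name=name,
        genome=genome,
        query=query,
        settings=settings,
        truth_sites=tuple(truth),
        truth_pairs=tuple(pairs),
        background_seed=bg_seed,
    )


def _build_rfn_sweep(bg_seed: int) -> Scenario:
    """PAM-out pairs at spacers 10..20; RFN defaults retain exactly 14..17."""
    return _build_sweep(
        "rfn-spacer-sweep", "rfn", list(range(10, 21)), separation=120, query_spacer=15, bg_seed=bg_seed
    )


def _build_cas9n_sweep(bg_seed: int) -> Scenario:
    """Pairs spanning and exceeding the Cas9n 0-1000 nt spacer ceiling."""
    return _build_sweep(
        "cas9n-spacer-sweep",
        "cas9n",
        [0, 1, 500, 999, 1000, 1001, 1100],
        separation=1200,
        query_spacer=20,
        bg_seed=bg_seed,
    )


_BUILDERS = {
    "cas9-basic": _build_cas9_basic,
    "cas9-specific-budgets": _build_cas9_specific,
    "cas9n-spacer-sweep": _build_cas9n_sweep,
    "rfn-spacer-sweep": _build_rfn_sweep,
    "bulge-tolerance": _build_bulge_tolerance,
    "pam-nag": _build_pam_nag,
}
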