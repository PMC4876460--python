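"""PAM-anchored off-target search with per-region edit accounting.

The search natively replaces a read-aligner stage: for every off-target PAM
occurrence on either genome strand, the adjacent window is globally aligned
to the candidate protospacer, anchored at the PAM-proximal end, and the
mismatch / insertion / deletion counts are attributed to the seed
(PAM-proximal) or non-seed region by the protospacer coordinate at which
each operation occurs.  The PAM itself is matched positionally — an
alignment can never place an indel inside the PAM.

Edit orientation: an *insertion* is a protospacer (gRNA) base absent from
the genomic site (gRNA bulge); a *deletion* is an extra genomic base
(DNA bulge).

Among the alignments of one genomic interval that satisfy the active
budgets, the reported counts are the feasible count vector minimising
(total gaps, total mismatches, then the vector
(seed_mm, seed_ins, seed_del, nonseed_mm, nonseed_ins, nonseed_del)
lexicographically), which deterministically prefers seed-sparing
attributions.  One site is reported per (contig, strand, interval).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .guides import GuideCandidate
from .sequence import Genome, iupac_match, pam_match_positions, reverse_complement
from .settings import SearchSettings

# count vectors are handled internally as 6-tuples in this fixed order
_FIELDS = ("seed_mm", "seed_ins", "seed_del", "nonseed_mm", "nonseed_ins", "nonseed_del")
_ZERO = (0, 0, 0, 0, 0, 0)


@dataclass(frozen=True)
class AlignmentCounts:
    """Mismatch/insertion/deletion counts split into seed and non-seed regions."""

    seed_mm: int = 0
    seed_ins: int = 0
    seed_del: int = 0
    nonseed_mm: int = 0
    nonseed_ins: int = 0
    nonseed_del: int = 0

    @property
    def total_mm(self) -> int:
        return self.seed_mm + self.nonseed_mm

    @property
    def total_ins(self) -> int:
        return self.seed_ins + self.nonseed_ins

    @property
    def total_del(self) -> int:
        return self.seed_del + self.nonseed_del

    @property
    def total_gaps(self) -> int:
        return self.total_ins + self.total_del

    @property
    def is_perfect(self) -> bool:
        return self.total_mm == 0 and self.total_gaps == 0

    def as_tuple(self) -> tuple[int, int, int, int, int, int]:
        return (
            self.seed_mm,
            self.seed_ins,
            self.seed_del,
            self.nonseed_mm,
            self.nonseed_ins,
            self.nonseed_del,
        )

    @classmethod
    def from_tuple(cls, t: tuple[int, int, int, int, int, int]) -> "AlignmentCounts":
        return cls(*t)


@dataclass(frozen=True)
class OffTargetSite:
    """A genomic interval matched to a candidate within the edit budgets.

    ``start``/``end`` are 1-based inclusive forward-strand coordinates of the
    matched protospacer region.  ``site_seq`` and ``pam_seq`` are given on the
    site's own strand (protospacer orientation, PAM 3' of the region).
    """

    contig_id: str
    strand: str
    start: int
    end: int
    site_seq: str
    pam_seq: str
    counts: AlignmentCounts

    @property
    def is_perfect(self) -> bool:
        return self.counts.is_perfect

    @property
    def interval_key(self) -> tuple[str, str, int, int]:
        return (self.contig_id, self.strand, self.start, self.end)


def counts_order_key(t: tuple[int, int, int, int, int, int]) -> tuple:
    """Deterministic order on count vectors: gaps, then mismatches, then the vector."""
    seed_mm, seed_ins, seed_del, nonseed_mm, nonseed_ins, nonseed_del = t
    gaps = seed_ins + seed_del + nonseed_ins + nonseed_del
    mm = seed_mm + nonseed_mm
    return (gaps, mm, t)


def counts_within_budget(t: tuple[int, int, int, int, int, int], settings: SearchSettings) -> bool:
    """Budget predicate on a (possibly partial) count vector; monotone, so usable for pruning."""
    seed_mm, seed_ins, seed_del, nonseed_mm, nonseed_ins, nonseed_del = t
    if settings.filter_form == "basic":
        b = settings.basic
        return (
            seed_mm + nonseed_mm <= b.max_mm_total
            and seed_ins + seed_del + nonseed_ins + nonseed_del <= b.max_gap_total
            and seed_mm <= b.max_mm_seed
            and seed_ins + seed_del <= b.max_gap_seed
        )
    sp = settings.specific
    return (
        seed_mm <= sp.seed.max_mm
        and seed_ins <= sp.seed.max_ins
        and seed_del <= sp.seed.max_del
        and nonseed_mm <= sp.nonseed.max_mm
        and nonseed_ins <= sp.nonseed.max_ins
        and nonseed_del <= sp.nonseed.max_del
    )


def passes_basic(counts: AlignmentCounts, settings: SearchSettings) -> bool:
    """Basic-form filter: total and seed-region caps on mismatches and gaps."""
    b = settings.basic
    return (
        counts.total_mm <= b.max_mm_total
        and counts.total_gaps <= b.max_gap_total
        and counts.seed_mm <= b.max_mm_seed
        and counts.seed_ins + counts.seed_del <= b.max_gap_seed
    )


def passes_specific(counts: AlignmentCounts, settings: SearchSettings) -> bool:
    """Specific-form filter: each of the six counts capped independently."""
    sp = settings.specific
    return (
        counts.seed_mm <= sp.seed.max_mm
        and counts.seed_ins <= sp.seed.max_ins
        and counts.seed_del <= sp.seed.max_del
        and counts.nonseed_mm <= sp.nonseed.max_mm
        and counts.nonseed_ins <= sp.nonseed.max_ins
        and counts.nonseed_del <= sp.nonseed.max_del
    )


def passes_filter(counts: AlignmentCounts, settings: SearchSettings) -> bool:
    if settings.filter_form == "basic":
        return passes_basic(counts, settings)
    return passes_specific(counts, settings)


def _bases_match(a: str, b: str) -> bool:
    # N never matches inside the protospacer alignment, not even another N
    return a == b and a in "ACGT"


def align_window(
    protospacer: str, window: str, settings: SearchSettings
) -> Optional[AlignmentCounts]:
    """Best within-budget global alignment of the protospacer to a genomic window.

    Both ends are anchored: the window is the exact candidate protospacer
    region, its 3' edge abutting the PAM.  The dynamic programme propagates
    the *set* of budget-feasible count vectors per cell (budgets are small,
    so these sets stay tiny), which makes region-wise feasibility exact; the
    reported vector is the feasible minimum under ``counts_order_key``.
    Returns None when no alignment satisfies the budgets.
    """
    L, W = len(protospacer), len(window)
    seed_start = settings.seed_start

    def is_seed(i: int) -> bool:
        # an op at the protospacer coordinate where it occurs/opens; i == L
        # (a trailing DNA bulge against the PAM edge) is PAM-proximal => seed
        return i >= seed_start

    cells: list[list[set]] = [[set() for _ in range(W + 1)] for _ in range(L + 1)]
    cells[0][0].add(_ZERO)
    for i in range(L + 1):
        for j in range(W + 1):
            here = cells[i][j]
            if not here:
                continue
            for t in here:
                if i < L and j < W:
                    if _bases_match(protospacer[i], window[j]):
                        nt = t
                    else:
                        idx = 0 if is_seed(i) else 3
                        nt = t[:idx] + (t[idx] + 1,) + t[idx + 1 :]
                    if counts_within_budget(nt, settings):
                        cells[i + 1][j + 1].add(nt)
                if i < L:  # gRNA bulge: protospacer base i unmatched
                    idx = 1 if is_seed(i) else 4
                    nt = t[:idx] + (t[idx] + 1,) + t[idx + 1 :]
                    if counts_within_budget(nt, settings):
                        cells[i + 1][j].add(nt)
                if j < W:  # DNA bulge: window base j unmatched, opens at coordinate i
                    idx = 2 if is_seed(i) else 5
                    nt = t[:idx] + (t[idx] + 1,) + t[idx + 1 :]
                    if counts_within_budget(nt, settings):
                        cells[i][j + 1].add(nt)
    final = cells[L][W]
    if not final:
        return None
    return AlignmentCounts.from_tuple(min(final, key=counts_order_key))


def _protospacer_of(candidate: Union[GuideCandidate, str]) -> str:
    return getattr(candidate, "protospacer", candidate)


def find_sites(
    candidate: Union[GuideCandidate, str], genome: Genome, settings: SearchSettings
) -> list[OffTargetSite]:
    """All genomic sites matching the candidate within the active budgets.

    Scans both strands of every contig for off-PAM occurrences, then aligns
    each PAM-adjacent window of every admissible length.  A site is reported
    iff its PAM matches positionally, the alignment passes the active filter,
    and its (contig, strand, interval) has not been reported already.
    Output is sorted by (contig order, start, strand, end).
    """
    P = _protospacer_of(candidate)
    L = len(P)
    pl = settings.off_pam.length
    w_lo = max(1, L - settings.max_ins_total)
    w_hi = L + settings.max_del_total
    sites: list[OffTargetSite] = []
    contig_rank = {c.id: k for k, c in enumerate(genome)}
    for contig in genome:
        for strand in "+-":
            seq = contig.residues if strand == "+" else reverse_complement(contig.residues)
            M = len(seq)
            for p in pam_match_positions(seq, settings.off_pam):
                p = int(p)
                for W in range(w_lo, w_hi + 1):
                    s0 = p - W
                    if s0 < 0:
                        continue
                    counts = align_window(P, seq[s0:p], settings)
                    if counts is None:
                        continue
                    if strand == "+":
                        start, end = s0 + 1, p
                    else:
                        start, end = M - p + 1, M - s0
                    sites.append(
                        OffTargetSite(
                            contig_id=contig.id,
                            strand=strand,
                            start=start,
                            end=end,
                            site_seq=seq[s0:p],
                            pam_seq=seq[p : p + pl],
                            counts=counts,
                        )
                    )
    sites.sort(key=lambda s: (contig_rank[s.contig_id], s.start, s.strand, s.end))
    return sites


def count_genome_targets(
    candidate: Union[GuideCandidate, str], genome: Genome, settings: SearchSettings
) -> tuple[int, bool]:
    """Genome-wide target count for a single-guide candidate, and the count==1 flag.

    A count of 1 marks a uniquely targetable (highly specific) candidate; the
    on-target site itself is included in the count.  Paired modes count site
    pairs instead — see :func:`guideseek.pairs.count_pair_targets`.
    """
    n = len(find_sites(candidate, genome, settings))
    return n, n == 1
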