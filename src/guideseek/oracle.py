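"""Exhaustive-enumeration oracles for the off-target search and site pairing.

These deliberately naive routines define ground truth on small genomes: every
(contig, strand, window, alignment) combination is enumerated by plain
recursion and filtered with the same budget predicates the production search
uses.  They share only the filter/tie-break *contract* with the production
code (``counts_within_budget`` / ``counts_order_key``), not its algorithms.
"""

from __future__ import annotations

from itertools import product
from typing import Union

from .guides import GuideCandidate
from .offtarget import (
    AlignmentCounts,
    OffTargetSite,
    counts_order_key,
    counts_within_budget,
)
from .pairs import OffTargetPair, bulged_strand_count
from .sequence import Genome, IUPAC_SETS, reverse_complement
from .settings import SearchSettings

#: refuse genomes larger than this (the oracle is quadratic-ish by design)
GUARD_BOUND = 50_000

_ZERO = (0, 0, 0, 0, 0, 0)


def _all_feasible_alignments(
    protospacer: str, window: str, settings: SearchSettings
) -> list[tuple[int, int, int, int, int, int]]:
    """Every complete alignment's count vector that satisfies the budgets."""
    L, W = len(protospacer), len(window)
    seed_start = settings.seed_start
    out: list[tuple[int, int, int, int, int, int]] = []

    def bump(t, idx):
        return t[:idx] + (t[idx] + 1,) + t[idx + 1 :]

    def rec(i: int, j: int, t) -> None:
        if not counts_within_budget(t, settings):
            return
        if i == L and j == W:
            out.append(t)
            return
        if i < L and j < W:
            a, b = protospacer[i], window[j]
            if a == b and a in "ACGT":
                rec(i + 1, j + 1, t)
            else:
                rec(i + 1, j + 1, bump(t, 0 if i >= seed_start else 3))
        if i < L:
            rec(i + 1, j, bump(t, 1 if i >= seed_start else 4))
        if j < W:
            rec(i, j + 1, bump(t, 2 if i >= seed_start else 5))

    rec(0, 0, _ZERO)
    return out


def _pam_ok(seq: str, p: int, settings: SearchSettings) -> bool:
    code = settings.off_pam.code
    if p + len(code) > len(seq):
        return False
    return all(IUPAC_SETS[seq[p + k]] <= IUPAC_SETS[ch] for k, ch in enumerate(code))


def brute_force_sites(
    candidate: Union[GuideCandidate, str], genome: Genome, settings: SearchSettings
) -> list[OffTargetSite]:
    """Ground-truth site list by exhaustive enumeration; guard-bounded genome size."""
    if genome.total_length > GUARD_BOUND:
        raise ValueError(
            f"genome of {genome.total_length} nt exceeds the oracle guard bound ({GUARD_BOUND})"
        )
    P = getattr(candidate, "protospacer", candidate)
    L = len(P)
    pl = settings.off_pam.length
    sites: list[OffTargetSite] = []
    order: list[tuple] = []
    for rank, contig in enumerate(genome):
        for strand in "+-":
            seq = contig.residues if strand == "+" else reverse_complement(contig.residues)
            M = len(seq)
            for p in range(M):  # p = position right after the protospacer region
                if not _pam_ok(seq, p, settings):
                    continue
                for W in range(1, L + settings.max_del_total + 1):
                    s0 = p - W
                    if s0 < 0:
                        continue
                    feasible = _all_feasible_alignments(P, seq[s0:p], settings)
                    if not feasible:
                        continue
                    counts = AlignmentCounts.from_tuple(min(feasible, key=counts_order_key))
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
                    order.append((rank, start, strand, end))
    sites = [s for _, s in sorted(zip(order, sites), key=lambda x: x[0])]
    return sites


def brute_force_pairs(
    sites_a: list[OffTargetSite],
    sites_b: list[OffTargetSite],
    settings: SearchSettings,
) -> list[OffTargetPair]:
    """Ground-truth PAM-out pairing by checking every cross combination."""
    smin, smax = settings.spacer_min, settings.spacer_max
    if smin is None or smax is None:
        raise ValueError("pairing requires spacer_min and spacer_max")
    seen: set[tuple] = set()
    pairs: list[OffTargetPair] = []
    for u, v in list(product(sites_a, sites_b)) + list(product(sites_b, sites_a)):
        if u.contig_id != v.contig_id:
            continue
        if not (u.strand == "-" and v.strand == "+"):
            continue
        if u.end >= v.start:  # overlap or PAM-in geometry
            continue
        spacer = v.start - u.end - 1
        if not (smin <= spacer <= smax):
            continue
        pair = OffTargetPair(site_a=u, site_b=v, spacer_len=spacer)
        if bulged_strand_count(pair) > settings.max_bulged_strands:
            continue
        key = (u.contig_id, u.start, u.end, v.start, v.end)
        if key in seen:
            continue
        seen.add(key)
        pairs.append(pair)
    pairs.sort(key=lambda p: (p.site_a.contig_id, p.site_a.start, p.site_b.start))
    return pairs
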