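"""Paired-guide construction for Cas9 nickase and dimeric FokI (RFN) modes.

Both paired systems cut only when two guides bind nearby on opposite strands
in PAM-out orientation: the left member's protospacer sits on the reverse
strand (its PAM pointing left/outward on forward coordinates) and the right
member's on the forward strand (PAM pointing right/outward).  The *spacer* is
the count of genomic bases strictly between the two protospacer regions; the
PAMs face outward and never lie inside it.  Specificity for a paired system
is a property of the pair: the genome-wide target count is the number of
valid site *pairs*, not of individual sites.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Union

from .guides import GuideCandidate
from .offtarget import OffTargetSite, find_sites
from .sequence import Genome
from .settings import PAIRED_MODES, SearchSettings, SettingsError


class PairGeometryError(ValueError):
    """Inputs violate the PAM-out paired geometry."""


@dataclass(frozen=True)
class GuidePair:
    """A PAM-out pair of query candidates: left on '-', right on '+'."""

    left: GuideCandidate
    right: GuideCandidate
    spacer_len: int

    def __post_init__(self) -> None:
        if self.left.strand != "-" or self.right.strand != "+":
            raise PairGeometryError(
                "PAM-out pair requires left candidate on '-' and right candidate on '+'"
            )


@dataclass(frozen=True)
class OffTargetPair:
    """Two off-target sites on one contig in PAM-out orientation.

    ``bulged_strands`` counts the member sites whose alignment carries at
    least one insertion or deletion (0, 1 or 2).
    """

    site_a: OffTargetSite  # left member, '-' strand
    site_b: OffTargetSite  # right member, '+' strand
    spacer_len: int
    bulged_strands: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "bulged_strands",
            sum(1 for s in (self.site_a, self.site_b) if s.counts.total_gaps >= 1),
        )


def bulged_strand_count(pair: OffTargetPair) -> int:
    """Number of member sites tolerating a bulge (>=1 insertion or deletion)."""
    return pair.bulged_strands


def spacer_length(a, b) -> int:
    """Genomic bases strictly between two PAM-out protospacer regions.

    ``a`` and ``b`` carry ``strand``/``start``/``end`` (1-based inclusive) and
    may be given in either order; errors on same-strand, overlapping, or
    PAM-in arrangements.
    """
    ca, cb = getattr(a, "contig_id", None), getattr(b, "contig_id", None)
    if ca is not None and cb is not None and ca != cb:
        raise PairGeometryError("spacer is undefined across contigs")
    if a.strand == b.strand:
        raise PairGeometryError("paired members must lie on opposite strands")
    rev, fwd = (a, b) if a.strand == "-" else (b, a)
    if rev.end >= fwd.start and fwd.end >= rev.start:
        raise PairGeometryError("protospacer regions overlap")
    if rev.start > fwd.end:
        raise PairGeometryError("PAM-in arrangement: reverse-strand member must lie upstream")
    return fwd.start - rev.end - 1


def enumerate_pairs(
    candidates: list[GuideCandidate], settings: SearchSettings
) -> list[GuidePair]:
    """All PAM-out candidate pairs with spacer in the configured range."""
    if settings.mode not in PAIRED_MODES:
        raise SettingsError(f"paired enumeration requires mode in {PAIRED_MODES}, got {settings.mode!r}")
    smin, smax = settings.spacer_min, settings.spacer_max
    rev = [c for c in candidates if c.strand == "-"]
    fwd = [c for c in candidates if c.strand == "+"]
    out = []
    for left in rev:
        for right in fwd:
            if left.end >= right.start:
                continue
            spacer = right.start - left.end - 1
            if smin <= spacer <= smax:
                out.append(GuidePair(left=left, right=right, spacer_len=spacer))
    out.sort(key=lambda p: (p.left.start, p.right.start))
    return out


def pair_sites(
    sites_a: list[OffTargetSite],
    sites_b: list[OffTargetSite],
    settings: SearchSettings,
) -> list[OffTargetPair]:
    """PAM-out cross-strand pairings of the two members' genome-wide sites.

    Per contig, every combination of a reverse-strand site from one member
    with a forward-strand site from the other is kept when the spacer lies in
    [spacer_min, spacer_max] and at most ``max_bulged_strands`` members carry
    a bulge.  Symmetric in the two site lists; identical (contig, intervals)
    pairs are deduplicated.
    """
    smin, smax = settings.spacer_min, settings.spacer_max
    if smin is None or smax is None:
        raise SettingsError("pairing requires spacer_min and spacer_max")
    fwd_a = defaultdict(list)
    fwd_b = defaultdict(list)
    rev_a = [s for s in sites_a if s.strand == "-"]
    rev_b = [s for s in sites_b if s.strand == "-"]
    for s in sites_a:
        if s.strand == "+":
            fwd_a[s.contig_id].append(s)
    for s in sites_b:
        if s.strand == "+":
            fwd_b[s.contig_id].append(s)
    for pool in fwd_a.values():
        pool.sort(key=lambda s: s.start)
    for pool in fwd_b.values():
        pool.sort(key=lambda s: s.start)

    seen: set[tuple] = set()
    out: list[OffTargetPair] = []

    def scan(rev_sites: list[OffTargetSite], fwd_pools: dict[str, list[OffTargetSite]]) -> None:
        for left in rev_sites:
            pool = fwd_pools.get(left.contig_id)
            if not pool:
                continue
            starts = [s.start for s in pool]
            lo = bisect_left(starts, left.end + 1 + smin)
            for right in pool[lo:]:
                spacer = right.start - left.end - 1
                if spacer > smax:
                    break
                if spacer < smin:
                    continue
                pair = OffTargetPair(site_a=left, site_b=right, spacer_len=spacer)
                if pair.bulged_strands > settings.max_bulged_strands:
                    continue
                key = (left.contig_id, left.start, left.end, right.start, right.end)
                if key in seen:
                    continue
                seen.add(key)
                out.append(pair)

    scan(rev_a, fwd_b)
    scan(rev_b, fwd_a)
    out.sort(key=lambda p: (p.site_a.contig_id, p.site_a.start, p.site_b.start))
    return out


def count_pair_targets(
    pair: GuidePair, genome: Genome, settings: SearchSettings
) -> tuple[int, bool]:
    """Genome-wide count of valid site pairs for a guide pair, and the count==1 flag."""
    sl = find_sites(pair.left, genome, settings)
    sr = find_sites(pair.right, genome, settings)
    n = len(pair_sites(sl, sr, settings))
    return n, n == 1
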