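"""Enumerate protospacer+PAM guide candidates in a query sequence.

Both strands of the query are scanned for windows of the configured gRNA
length immediately followed (3' side) by the on-target PAM.  Reverse-strand
candidates report the reverse-complement protospacer with coordinates mapped
back to the forward strand.  Two GC-based efficiency measures accompany each
candidate: total GC percent of the protospacer (PAM excluded) and the G/C
count of the 6 PAM-proximal protospacer bases, flagged when >= 4 — high GC
in that window is a strong positive predictor of guide efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sequence import (
    SequenceError,
    normalize_sequence,
    pam_match_positions,
    reverse_complement,
)
from .settings import SearchSettings


@dataclass(frozen=True)
class GuideCandidate:
    """A protospacer+PAM occurrence in the query.

    ``start``/``end`` are 1-based inclusive forward-strand query coordinates
    of the protospacer region (the PAM lies outside them, 3' of the
    protospacer on the candidate's own strand).
    """

    strand: str  # "+" or "-" relative to the query
    start: int
    end: int
    protospacer: str
    pam: str
    gc_total_pct: float
    prox6_gc_count: int
    prox6_flag: bool


def gc_total(protospacer: str) -> float:
    """Percent G+C of the protospacer (PAM excluded); N counts as non-GC."""
    if not protospacer:
        raise SequenceError("cannot compute GC content of an empty sequence")
    gc = sum(1 for b in protospacer if b in "GC")
    return 100.0 * gc / len(protospacer)


def prox6_metrics(protospacer: str) -> tuple[int, bool]:
    """G/C count among the 6 PAM-proximal (3'-terminal) bases, and the >=4 flag."""
    if len(protospacer) < 6:
        raise SequenceError("protospacer shorter than 6 nt has no PAM-proximal hexamer")
    count = sum(1 for b in protospacer[-6:] if b in "GC")
    return count, count >= 4


def make_candidate(strand: str, start: int, end: int, protospacer: str, pam: str) -> GuideCandidate:
    count, flag = prox6_metrics(protospacer)
    return GuideCandidate(
        strand=strand,
        start=start,
        end=end,
        protospacer=protospacer,
        pam=pam,
        gc_total_pct=gc_total(protospacer),
        prox6_gc_count=count,
        prox6_flag=flag,
    )


def enumerate_guides(query: str, settings: SearchSettings) -> list[GuideCandidate]:
    """All protospacer+on-PAM candidates on both strands of the query.

    Overlapping candidates are all reported; output is sorted by
    (start, strand).  Candidates whose protospacer or PAM would run past the
    query ends are dropped, not padded.
    """
    q = normalize_sequence(query, what="query")
    L, pl = settings.grna_len, settings.on_pam.length
    if len(q) < L + pl:
        raise SequenceError(
            f"query of length {len(q)} is shorter than protospacer+PAM ({L + pl} nt)"
        )
    n = len(q)
    out: list[GuideCandidate] = []
    for strand, seq in (("+", q), ("-", reverse_complement(q))):
        for p in pam_match_positions(seq, settings.on_pam):
            p = int(p)
            if p < L:
                continue
            proto = seq[p - L : p]
            pam = seq[p : p + pl]
            if strand == "+":
                start, end = p - L + 1, p
            else:
                start, end = n - p + 1, n - p + L
            out.append(make_candidate(strand, start, end, proto, pam))
    out.sort(key=lambda c: (c.start, c.strand))
    return out
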