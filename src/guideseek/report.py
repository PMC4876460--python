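"""Result tables and genome-browser tracks.

The candidate table mirrors a result-table view: strand, 1-based inclusive
start/end, GC measures, the genome-wide target count and a boolean
specificity flag that marks uniquely targetable candidates (count == 1).
Site tables carry the per-region mismatch/insertion/deletion breakdown.
Tracks are emitted as BED6 (0-based half-open, score = total edits) and GFF3
(1-based inclusive, type ``nucleotide_match``) so any standard genome
browser can load them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import pandas as pd

from .guides import GuideCandidate, enumerate_guides
from .offtarget import OffTargetSite, find_sites
from .pairs import GuidePair, OffTargetPair, enumerate_pairs, pair_sites
from .sequence import Genome
from .settings import SearchSettings

_SINGLE_COLUMNS = [
    "id",
    "strand",
    "start",
    "end",
    "protospacer",
    "pam",
    "gc_total_pct",
    "prox6_gc_count",
    "prox6_flag",
    "spacer_len",
    "target_count",
    "specific_flag",
]

_PAIR_COLUMNS = (
    ["id"]
    + [f"{c}_left" for c in ("strand", "start", "end", "protospacer", "pam", "gc_total_pct", "prox6_gc_count", "prox6_flag")]
    + [f"{c}_right" for c in ("strand", "start", "end", "protospacer", "pam", "gc_total_pct", "prox6_gc_count", "prox6_flag")]
    + ["spacer_len", "target_count", "specific_flag"]
)

_SITE_COLUMNS = [
    "candidate_id",
    "pair_member",
    "contig",
    "strand",
    "start",
    "end",
    "site_seq",
    "pam",
    "seed_mm",
    "seed_ins",
    "seed_del",
    "nonseed_mm",
    "nonseed_ins",
    "nonseed_del",
    "total_mm",
    "total_gaps",
    "spacer_len",
]


@dataclass(frozen=True)
class CandidateReport:
    """One candidate (or pair) with its genome-wide sites and specificity count."""

    id: str
    item: Union[GuideCandidate, GuidePair]
    sites: tuple
    target_count: int
    specific_flag: bool


def run_pipeline(query: str, genome: Genome, settings: SearchSettings) -> list[CandidateReport]:
    """Enumerate -> search -> (pair) -> report, for any mode."""
    candidates = enumerate_guides(query, settings)
    reports: list[CandidateReport] = []
    if settings.mode == "cas9":
        for k, cand in enumerate(candidates, 1):
            sites = tuple(find_sites(cand, genome, settings))
            reports.append(
                CandidateReport(
                    id=f"g{k}",
                    item=cand,
                    sites=sites,
                    target_count=len(sites),
                    specific_flag=len(sites) == 1,
                )
            )
        return reports
    guide_pairs = enumerate_pairs(candidates, settings)
    site_cache: dict[GuideCandidate, list[OffTargetSite]] = {}

    def member_sites(c: GuideCandidate) -> list[OffTargetSite]:
        if c not in site_cache:
            site_cache[c] = find_sites(c, genome, settings)
        return site_cache[c]

    for k, gp in enumerate(guide_pairs, 1):
        pairs = tuple(
            pair_sites(member_sites(gp.left), member_sites(gp.right), settings)
        )
        reports.append(
            CandidateReport(
                id=f"p{k}",
                item=gp,
                sites=pairs,
                target_count=len(pairs),
                specific_flag=len(pairs) == 1,
            )
        )
    return reports


def _candidate_row(c: GuideCandidate, suffix: str = "") -> dict:
    return {
        f"strand{suffix}": c.strand,
        f"start{suffix}": c.start,
        f"end{suffix}": c.end,
        f"protospacer{suffix}": c.protospacer,
        f"pam{suffix}": c.pam,
        f"gc_total_pct{suffix}": round(c.gc_total_pct, 2),
        f"prox6_gc_count{suffix}": c.prox6_gc_count,
        f"prox6_flag{suffix}": c.prox6_flag,
    }


def candidate_table(reports: list[CandidateReport], paired: bool = None) -> pd.DataFrame:
    """One row per candidate/pair; deterministic ordering follows the reports."""
    if paired is None:
        paired = bool(reports) and isinstance(reports[0].item, GuidePair)
    rows = []
    for r in reports:
        if paired:
            gp: GuidePair = r.item
            row = {"id": r.id}
            row.update(_candidate_row(gp.left, "_left"))
            row.update(_candidate_row(gp.right, "_right"))
            row["spacer_len"] = gp.spacer_len
        else:
            row = {"id": r.id}
            row.update(_candidate_row(r.item))
            row["spacer_len"] = ""
        row["target_count"] = r.target_count
        row["specific_flag"] = r.specific_flag
        rows.append(row)
    columns = _PAIR_COLUMNS if paired else _SINGLE_COLUMNS
    return pd.DataFrame(rows, columns=columns)


def _site_row(candidate_id: str, member: str, site: OffTargetSite, spacer) -> dict:
    c = site.counts
    return {
        "candidate_id": candidate_id,
        "pair_member": member,
        "contig": site.contig_id,
        "strand": site.strand,
        "start": site.start,
        "end": site.end,
        "site_seq": site.site_seq,
        "pam": site.pam_seq,
        "seed_mm": c.seed_mm,
        "seed_ins": c.seed_ins,
        "seed_del": c.seed_del,
        "nonseed_mm": c.nonseed_mm,
        "nonseed_ins": c.nonseed_ins,
        "nonseed_del": c.nonseed_del,
        "total_mm": c.total_mm,
        "total_gaps": c.total_gaps,
        "spacer_len": spacer,
    }


def site_table(reports: list[CandidateReport]) -> pd.DataFrame:
    """One row per site (or per pair member, sharing the pair's id)."""
    rows = []
    for r in reports:
        for entry in r.sites:
            if isinstance(entry, OffTargetPair):
                rows.append(_site_row(r.id, "left", entry.site_a, entry.spacer_len))
                rows.append(_site_row(r.id, "right", entry.site_b, entry.spacer_len))
            else:
                rows.append(_site_row(r.id, "", entry, ""))
    return pd.DataFrame(rows, columns=_SITE_COLUMNS)


def _iter_track_sites(reports):
    for r in reports:
        for entry in r.sites:
            if isinstance(entry, OffTargetPair):
                yield r.id, "left", entry.site_a, entry
                yield r.id, "right", entry.site_b, entry
            else:
                yield r.id, "", entry, None


def export_tracks(
    reports: list[CandidateReport],
    bed_path: Union[str, Path],
    gff_path: Union[str, Path],
    source: str = "guideseek",
) -> None:
    """Write BED6 and GFF3 tracks for all reported sites/pair members.

    BED is 0-based half-open with score = total edits; GFF3 is 1-based
    inclusive with ``nucleotide_match`` features carrying the per-region
    counts as attributes.
    """
    bed_lines = []
    gff_lines = ["##gff-version 3"]
    feature_no = 0
    for cand_id, member, site, pair in _iter_track_sites(reports):
        feature_no += 1
        c = site.counts
        name = f"{cand_id}.{feature_no}" + (f".{member}" if member else "")
        bed_lines.append(
            "\t".join(
                [
                    site.contig_id,
                    str(site.start - 1),
                    str(site.end),
                    name,
                    str(c.total_mm + c.total_gaps),
                    site.strand,
                ]
            )
        )
        attrs = [
            f"ID={name}",
            f"candidate={cand_id}",
            f"seed_mm={c.seed_mm}",
            f"seed_ins={c.seed_ins}",
            f"seed_del={c.seed_del}",
            f"nonseed_mm={c.nonseed_mm}",
            f"nonseed_ins={c.nonseed_ins}",
            f"nonseed_del={c.nonseed_del}",
        ]
        if pair is not None:
            attrs.append(f"pair_member={member}")
            attrs.append(f"spacer_len={pair.spacer_len}")
        gff_lines.append(
            "\t".join(
                [
                    site.contig_id,
                    source,
                    "nucleotide_match",
                    str(site.start),
                    str(site.end),
                    ".",
                    site.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
        )
    Path(bed_path).write_text("\n".join(bed_lines) + ("\n" if bed_lines else ""))
    Path(gff_path).write_text("\n".join(gff_lines) + "\n")
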