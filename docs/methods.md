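# Methods

## Candidate enumeration

The query is scanned on both strands for windows of the configured gRNA
length whose 3' neighbour matches the on-target PAM under IUPAC degeneracy.
Matching uses the subset rule — a (possibly degenerate) sequence letter
satisfies a pattern position iff its base set is contained in the pattern
letter's set — so a genomic N satisfies only a pattern N. Reverse-strand
candidates carry the reverse-complement protospacer with coordinates mapped
to the forward strand. All overlapping candidates are reported; candidates
whose protospacer or PAM would run past the query ends are dropped.
Internally all coordinates are 0-based half-open; every user-facing record
is 1-based inclusive, matching genome-browser display.

Efficiency metrics per candidate: total GC percent of the protospacer (PAM
excluded; N counts as non-GC) and the G/C count of the protospacer's
3'-terminal 6 bases — the PAM-proximal hexamer, which never overlaps the
PAM — flagged when the count is ≥ 4. No multivariable efficiency score is
computed: there is insufficient experimental evidence to weight mismatch,
gap and position effects against each other, so the tool reports the
ingredients and ranks by predicted specificity only.

## Off-target search

The production path is PAM-anchored: off-target PAM occurrences are located
on both strands of every contig (vectorised lookup-table scan), and for
each occurrence every admissible window length
`W ∈ [L − max_ins, L + max_del]` ending flush against the PAM is aligned to
the protospacer. The alignment is a banded global alignment anchored at
both ends whose dynamic programme propagates the *set* of budget-feasible
count vectors per cell rather than a scalar score. Budgets are small in
practice (≤ 3 mismatches, ≤ 2 gaps), so these sets stay tiny, and the
approach makes region-wise feasibility exact: an alignment that is globally
minimal but violates a seed cap cannot mask a feasible alternative.

Conventions, fixed once:

* **Seed region** = the `seed_len` PAM-proximal protospacer positions
  (default 12 of 20, the convention for SpCas9). A mismatch belongs to the
  region of its protospacer position; an indel to the region of the
  protospacer coordinate at which it opens, with an indel opening exactly at
  the seed boundary counted as seed. A DNA bulge opening past the last
  protospacer base (against the PAM edge) is seed.
* **Insertion** = gRNA bulge (protospacer base missing from the genome);
  **deletion** = DNA bulge (extra genomic base).
* **No indels in the PAM**: the PAM is matched positionally at a fixed
  offset; loci that a free read-aligner would rescue by bulging the PAM are
  simply not sites.
* **N policy**: inside the protospacer alignment N never matches (scored as
  a mismatch), and in PAM matching a genomic N satisfies only a pattern N.
  Ambiguous bases must not create spurious "uniquely targetable" calls.
* **Tie-break**: among feasible alignments of one (contig, strand, interval)
  the reported vector minimises (total gaps, total mismatches, then the
  vector (seed_mm, seed_ins, seed_del, nonseed_mm, nonseed_ins, nonseed_del)
  lexicographically — i.e. seed-sparing attributions win). One site per
  interval; output ordering (contig, start, strand, end) is total, so runs
  are byte-reproducible.
* Distinct intervals are distinct sites: under a gap budget a perfectly
  matching locus is also reported at the one-bulge-shifted intervals sharing
  its PAM. The exhaustive oracle has the same semantics, and the per-site
  edit columns make the relationship explicit.

Default budgets (basic form) are mm_total 3, gap_total 1, mm_seed 1,
gap_seed 0: three or more interspersed mismatches largely abolish SpCas9
activity, seed mismatches are markedly less tolerated than distal ones, and
single-bulge tolerance is documented; all caps are user-settable, including
the fully independent per-region "specific" form.

## Paired modes

Cas9n and RFN both require two guides on opposite strands in PAM-out
orientation (both published geometries): the left member's protospacer on
the reverse strand, PAM pointing left, the right member's on the forward
strand, PAM pointing right. The spacer is the number of genomic bases
strictly between the two protospacer regions; because the PAMs face
outward they can never lie inside it, and the spacer is measured exclusive
of PAM bases. Default spacer ranges: 14–17 nt for RFN (the effective FokI
dimerisation window) and 0–1000 nt for Cas9n. Genome-wide specificity of a
pair is the number of valid *site pairs* (same contig, PAM-out, spacer in
range, at most `max_bulged_strands` members carrying ≥ 1 indel); the
default `max_bulged_strands` is 0, the most conservative of the three
allowed values, since no canonical default exists. Pairing is symmetric in
the two members' site lists and deduplicates identical interval pairs.

## Oracles

`brute_force_sites` re-derives the site list by enumerating every end
position, window length and alignment operation sequence recursively, with
no banding, memoisation or PAM-first indexing, and `brute_force_pairs`
checks every cross combination of two site lists. They share only the
budget predicates and the tie-break key with the production code (that
triple is the reporting contract) and are guard-bounded at 50 kb of genome.
The acceptance-level tests assert exact set equality between the production
search and these oracles on hundreds of randomised (genome, settings,
protospacer) instances, alongside strand-symmetry and budget-monotonicity
properties.

## Synthetic fixtures

`random_genome` draws i.i.d. bases at a requested GC fraction from a seeded
generator. `plant` overwrites a background interval with an edited
protospacer+PAM (reverse-complemented for reverse-strand plants) and
returns the expected record — coordinates, strand and per-region counts —
by construction. Scenario builders assemble one instance per pipeline
aspect (basic budgets, specific budgets, bulge tolerance, NAG PAM
semantics, RFN and Cas9n spacer sweeps) and then *prove* the truth set
complete by running the exhaustive oracle over the scenario genome; a
background that happens to contain an unplanned within-budget hit is
re-rolled deterministically (seed+1, seed+2, ...). When a scenario's
budgets admit gaps, the constructed truth includes the one-bulge shadow
intervals described above.

The spacer-sweep scenarios keep each mode's default spacer range — the
variable under test — but set the mismatch/gap budgets to zero so that the
planted pairs are the only sites and the retained-spacer set is exactly
readable from the construction. Cluster separations (120 nt for the RFN
sweep, 1200 nt for the Cas9n sweep) exceed the respective spacer ceilings
so no cross-cluster pairings arise.

What the fixtures do *not* emulate: real-genome repeat structure, biased
base composition, or assembly gaps. Passing tests therefore demonstrate
correctness of the search semantics, not off-target recall on a real
genome, where repeat-driven near-matches dominate.

## Problem sizes and numerics

Scenario genomes are 1.5–2 kb (single-guide scenarios), ~2 kb (RFN sweep)
and ~13 kb (Cas9n sweep, whose spacers reach 1100 nt); randomised oracle
instances use 150–500 bp genomes, which already exercise every code path
(multi-contig, both strands, all budget forms). All computation is exact
integer arithmetic — there are no tolerances to tune; GC percentages are
reported to two decimals.

## Known limitations

* The search is desk-scale by design: scanning is linear per contig with
  a small constant, with no FM-index; whole mammalian genomes are out of
  scope.
* Only PAM-out pair geometry is modelled; PAM-in and tandem layouts are not.
* Off-target *likelihood* is not scored; the tool enumerates and counts
  sites under hard budgets.
* The treatment of genomic N as a guaranteed mismatch is a deliberate
  conservative policy, not an empirical model of ambiguous bases.
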