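# guideseek

CRISPR guide design with a seed-aware off-target search, for the single-guide
Cas9 system and the two specificity-enhancing paired-guide systems: Cas9 D10A
nickases (Cas9n) and dimeric RNA-guided FokI nucleases (RFN).

`guideseek` is for researchers choosing guide RNAs who care about predicted
specificity above all else. Given a query sequence and a reference genome, it

* enumerates every protospacer candidate on both strands of the query that is
  immediately followed by the on-target PAM (default `NGG`, configurable in
  IUPAC code);
* searches the whole genome for off-target sites under the off-target PAM
  (default `NRG`, i.e. `NGG` + `NAG`), with **separate mismatch, insertion and
  deletion budgets for the seed and non-seed regions** of the protospacer;
* in the paired modes, builds PAM-out guide pairs and counts genome-wide
  *site pairs* within a spacer range — 14–17 nt for RFN, 0–1000 nt for Cas9n —
  with a cap on how many members may carry a bulge (0, 1 or 2);
* reports GC-efficiency metrics per candidate: total GC% of the protospacer
  (PAM excluded) and the G/C count of the 6 PAM-proximal bases, flagged when
  ≥ 4 (GC > 50% in that window is a strong positive predictor of activity);
* writes TSV tables plus genome-browser-ready BED6 and GFF3 tracks.

A candidate whose genome-wide target (or pair) count is exactly 1 is flagged
as uniquely targetable.

## The search model

For a protospacer $P$ of length $L$ (default 20) with seed = the $s$
PAM-proximal positions (default $s = 12$), a genomic locus is an off-target
site when its PAM matches the off-target pattern *positionally* (no indels
are ever allowed inside the PAM) and the adjacent window admits a global
alignment to $P$, anchored at the PAM-proximal end, whose operation counts
$(mm_{seed}, ins_{seed}, del_{seed}, mm_{non}, ins_{non}, del_{non})$ satisfy
the active budget filter:

* **basic** form: $mm_{tot} \le M$, $gaps_{tot} \le G$,
  $mm_{seed} \le M_s$, $gaps_{seed} \le G_s$ (defaults 3, 1, 1, 0);
* **specific** form: each of the six counts capped independently.

An insertion is a gRNA bulge (protospacer base absent from the genome); a
deletion is a DNA bulge (extra genomic base). Each indel is attributed to
the seed or non-seed region by the protospacer coordinate at which it opens.
An exhaustive-enumeration oracle (`brute_force_sites`, `brute_force_pairs`)
independently defines ground truth on small genomes and backs the test
suite; no multivariable efficiency score is computed.

## Worked example

The built-in fixtures generate a synthetic 2 kb genome with planted variants
of one guide (exact, 1 non-seed mismatch, 1 seed mismatch, 3 non-seed
mismatches, plus over-budget decoys):

```python
import guideseek as gs
sc = gs.scenario("cas9-basic", seed=1)
gs.write_fasta(sc.genome, "demo_genome.fa")
open("demo_query.fa", "w").write(">query\n" + sc.query + "\n")
```

```
$ guideseek --mode cas9 --query demo_query.fa --genome demo_genome.fa --out demo_out
1 candidates, 0 uniquely targetable; results in demo_out
```

`demo_out/candidates.tsv`:

```
id  strand  start  end  protospacer           pam  gc_total_pct  prox6_gc_count  prox6_flag  spacer_len  target_count  specific_flag
g1  +       6      25   TACATGATCGTATCAGTACT  TGG  35.0          2               False                   12            False
```

The single query candidate (protospacer at query positions 6–25, GC 35%,
only 2 G/C in the PAM-proximal hexamer so the efficiency flag is off) has 12
genome-wide sites under the default budgets, so it is not uniquely
targetable. `demo_out/sites.tsv` breaks them down — e.g. the planted
seed-mismatch variant on the reverse strand:

```
candidate_id  contig  strand  start  end  site_seq              pam  seed_mm  ...  total_mm  total_gaps
g1            chr1    -       404    423  TACAAGATCGTATCAGTACT  TGG  1             1         0
```

Each planted site appears three times because the default gap budget of 1
also admits the two single-bulge alignments of the neighbouring intervals
sharing the same PAM (score column = total edits in `sites.bed`). Re-running
with `--max-gap-total 0` reports exactly the four planted loci.

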