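# endbind

Analysis toolkit for transcription-factor binding at **gene ends** — in
particular MYC/MAX-style binding near transcriptional end sites (TESs) —
and its downstream correlates: read-through transcription, TSS–TES
chromatin contacts, co-occupancy with other factors, and the co-regulation
of closely spaced gene pairs from a single shared intergenic site.

It is written for computational genomicists who have per-factor ChIP peak
calls (narrowPeak), a gene annotation (GTF), strand-specific coverage
(bedGraph), loop calls (BEDPE) and expression tables, and who want the
full end-binding analysis as a tested, importable Python library rather
than a one-off script.

## The analysis in brief

* **Window assignment.** A gene's 5′ and 3′ ends are the TSS/TES anchors
  of each annotated transcript. A peak belongs to a gene end when its
  summit lies within ±2.5 kb of an anchor (±1 kb preset for compact
  genomes); a peak inside the windows of two genes is assigned to both,
  and peaks readable as either TES binding of one gene or TSS binding of
  its head-to-tail neighbour are flagged ambiguous.
* **16 binding categories.** Each gene end is in one of four states —
  unbound, factor A only, factor B only, both — and the (5′ state,
  3′ state) pair maps to categories 1–16 (16 = fully unbound; 9 = A/B at
  the 5′ end only; 2/6/13 = TES-only binding).
* **Read-through (DoG) fraction.** With `d` the read count in the 500 bp
  window just past the TES on the gene's own strand and `u` the count in
  the 500 bp window just before it, the read-through fraction is `d/u` —
  depth-scale invariant because the windows are equal length. Groups are
  compared by Wilcoxon rank-sum.
* **Loop groups A–H.** Loop anchors are assigned to end windows by their
  midpoints; each gene is classified by (direct TSS–TES loop?, TSS–other
  contact?, TES–other contact?) into eight groups and cross-tabulated
  with the 16 binding categories.
* **Co-occupancy z-profiles.** Around reference-factor-bound positions in
  four region classes (TSS, TES, intragenic enhancer, distal enhancer),
  the per-250-bp-bin percentage of regions overlapped by each co-factor's
  peaks is z-scored per factor.
* **Dyads.** Head-to-tail pairs whose *only* binding is one intergenic
  site within 2.5 kb of both facing anchors; each flank's expression
  response to induction is classed positive/none/negative at a 1.5-fold
  threshold, split by site affinity (baseline-occupied vs induced).

A fully seeded synthetic-data generator (`endbind.simulate`) lays out
genes in head-to-head / head-to-tail / tail-to-tail arrangements, plants
every one of the structures above with recorded ground truth, and writes
standard GTF / narrowPeak / bedGraph / BEDPE / TSV fixtures, so the whole
pipeline is testable end to end without external downloads.

## Worked example

```sh
python examples/02_readthrough.py
```

builds a 200-gene synthetic chromosome, measures per-gene DoG fractions
and compares TES-bound with TES-unbound genes:

```
gene_id  downstream_count  upstream_count  fraction flags
  G0000              2.00          102.00  0.019608
  G0001             43.00          104.80  0.410305
  ...

median DoG fraction, TES-bound genes:   0.278 (n=42)
median DoG fraction, TES-unbound genes: 0.086 (n=158)
Wilcoxon rank-sum p = 7.74e-13 (larger in the TES_bound group)
```

`G0001` reads through heavily (41% of its terminal density continues past
the TES); the group comparison shows that genes with MYC/MAX near their
TES have roughly three-fold higher median read-through in this cohort,
recovering the planted effect. The other scripts in `examples/` cover the
16-category classification, loop groups, co-occupancy profiles, dyads and
retention kinetics, each printing a short annotated result.

There is also a thin CLI over the same library code:

```sh
endbind all --outdir run1 --seed 42        # simulate + every analysis stage
endbind classify --outdir run1 --seed 42   # one stage, reading run1/fixtures
```

Every output TSV carries a provenance header with the configuration hash,
and a rerun with the same configuration is byte-identical.

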