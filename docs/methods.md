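# Methods

## Scope and model

`endbind` implements a window-based model of transcription-factor binding
at gene ends. Genes are interval models carrying per-transcript anchor
sets: each annotated transcript contributes one TSS and one TES anchor
(by strand), and anchors within 10 bp on the same gene end are collapsed
to the most upstream (TSS) or most downstream (TES) survivor to avoid
double-counting near-identical transcript ends. All coordinates are
1-based and closed in memory; BED-dialect files are converted at
ingestion and every emitted table states the convention in its header.

A peak is represented by its summit. Membership in an end window is
`|summit − anchor| ≤ radius` with radius 2500 bp by default (a 1000 bp
preset is provided for compact genomes, where intergenic spacing makes
the wide window ambiguous). Summit-based membership was chosen over
interval overlap because distances of binding sites from TSS/TES are the
quantity of interest throughout; an interval-overlap mode is available.
A peak inside the windows of two genes is assigned to both. When several
anchors of the *same* gene end are in range, only the nearest is kept, so
a gene contributes at most one assignment row per (peak, end).

**Ambiguity.** In closely spaced head-to-tail pairs a single peak can be
read as TES binding of the upstream gene or TSS binding of the downstream
one. Such peaks are flagged on both assignment rows. The flag is applied
or ignored per analysis: category classification keeps ambiguous peaks
(the categories draw no TES/TSS distinction for them to corrupt), while
signal-level and TES-specific analyses drop them. Both behaviours are
exposed as a pipeline switch.

**Categories.** Each gene end is summarised as unbound / A only / B only
/ both, and the (5′, 3′) state pair is mapped to an integer category 1–16.
Only part of the numbering is externally anchored (9 = both factors at 5′
only; 7 = B at both ends; 10/11/12 all have both factors at 5′;
12 = both/both; 3 = A/A and 4 = A/B; 2, 6, 13 are the TES-only cells;
16 = unbound). The remaining cells are completed to a bijection as a
package convention, validated at run time, and overridable through a
16-row map; downstream code keys on the state pair, never the integer, so
a different numbering cannot change any result.

**Region classes.** Peaks partition into TSS, TES, intragenic and distal
classes with precedence TSS > TES > intragenic > distal. Intragenic means
inside a gene span, more than one radius downstream of every TSS anchor
and upstream of every TES anchor of that gene (this region is sometimes
loosely called "intergenic" in the literature; it lies inside genes and
is named accordingly here). Distal means outside all spans and windows.

**Retention kinetics.** Sites are matched across timepoints by the
(gene, end, anchor, factor) key rather than peak-interval identity, since
summit jitter between timepoints would break interval matching. The
bound fraction is presence/absence of any peak at the site; relative
signal is the mean signal over retained sites divided by the mean
baseline signal over all baseline sites, so both are exactly 1 at
baseline. Affinity tiers split baseline signals at a configurable
quantile (default: median, within each factor × end).

**Read-through.** The DoG fraction is `downstream/upstream` over equal
500 bp windows flanking the most-downstream TES anchor, on the gene's
own strand, with coverage intervals prorated by overlap length. Genes
with fewer than 10 upstream counts are flagged `low_expression`, and
genes whose downstream window overlaps another same-strand gene are
flagged `masked_overlap`; both have undefined fractions. Condition
deltas are per-gene log2 ratios of pseudocounted (0.5) fractions.
Unstranded data is supported by passing one coverage table under both
strand keys, with the caller choosing the wider unstranded boundaries.

**Loops.** Anchor membership uses the anchor-interval midpoint with the
same radius convention as peaks. A gene's profile has three flags:
direct TSS–TES loop, TSS–other and TES–other contacts, where "other"
requires the partner anchor to lie outside the same gene's opposite end
window (self-loops within one window are discarded). Groups A–D have the
direct loop (A: extra contacts at both ends, B: TSS only, C: TES only,
D: neither); E–H mirror them without it. The B-vs-C orientation is a
package convention with a config override, and is excluded from
external-truth claims. Looping frequency per category is reported with
both defensible denominators (all genes; genes with ≥1 contact). The
RNAPII gate restricts the universe to genes with RNAPII assigned at both
ends and emits the four-way TES split (both factors / A / B / neither).

**Co-occupancy.** Regions are ±halfwidth windows (default 2500, narrow
preset 500) around reference-factor summits in the four classes. For
each queried factor, per-250-bp signed-distance bin, the percentage of
regions whose bin interval touches ≥1 peak is computed and z-scored per
factor across all bins of all classes (per-bin rather than per-region
percentages preserve the profile shape). Zero-variance rows are emitted
as zeros and flagged. The 250 bp bin is a package choice; published
heatmaps of this kind are continuous and state no bin width.

**Dyads.** Candidates are head-to-tail relations whose facing anchors
share at least one factor-A peak (summit within radius of both). The
exclusivity rule — no other binding for either gene at any timepoint —
defaults to scanning each gene's span extended by one radius
(`span_plus_radius`), with a `windows` mode that only considers window
assignments. Affinity is high if a shared peak exists at baseline, low
if it appears only later. Responses use per-timepoint log2 fold changes
versus baseline; the summary timepoint is the max-|log2FC| one (a full
induction trajectory is a curve; the extreme point is its natural scalar
summary, and the full matrix is also returned). The threshold is 1.5-fold
by default.

**Statistics.** Expression is compared on log2(value + 1) with Welch
t-tests or Wilcoxon rank-sum tests as selected per analysis;
2×2 binding-fraction comparisons use chi-squared with continuity
correction, falling back to Fisher's exact test (flagged) on zero cells.
Benjamini–Hochberg FDR columns accompany every multi-comparison table.
Ridge-style distribution plots are replaced by per-group quantile tables.

## Synthetic data

The generator builds one synthetic chromosome. Units (an isolated gene or
an oriented pair) are drawn from an orientation mix of 40% isolated, 15%
head-to-head, 30% head-to-tail, 15% tail-to-tail; gene lengths are
uniform on 8–30 kb, facing-anchor gaps uniform on 6–12 kb for ordinary
pairs and 1.2–3.8 kb for dyad pairs (half of head-to-tail pairs by
default), inter-unit gaps 25–40 kb. A quarter of genes get a second
transcript with slightly inset anchors. The geometry guarantees that a
planted peak's jittered summit (normal, sd 300 bp, truncated to the
window) can reach only its intended window, so planted truth is exact by
construction rather than approximately recovered.

Per-gene binding categories are drawn from a default mix set to the
marginal structure reported for human/mouse ChIP compendia: ~52% of
genes bound at either end, ~17.5% with 3′-end binding, category 9 the
modal bound configuration, categories 3 and 4 together below 0.5% of
bound genes, and solitary factor-A binding several-fold rarer than
solitary factor-B. lncRNA genes (20% of genes, vs 70% protein-coding)
draw TES-bound categories at 1.5× weight, reflecting their reported
3′-end bias. Signals are lognormal in two affinity tiers (log-means 3.4
and 2.1, sigma 0.5). RNAPII is planted at both ends of 70% of genes.
Additional reference-factor sites are planted mid-gene (15% of genes)
and in a gene-free distal region, giving all four co-occupancy classes;
twenty stand-in co-factors are planted at 80% of their home-class
regions plus a small uniform background.

Coverage is Poisson per 50-bp tile at 100 reads per 500 bp window, on
the gene's strand, with tiles truncated at the TES so body coverage
never bleeds into the downstream window. Read-through extends past the
TES at `fraction × depth` for 600 bp plus an exponential tail (mean
2 kb, capped at 15 kb) — the floor guarantees the 500 bp measurement
window carries the planted fraction in full. Fractions are Beta(3,7)
(mean 0.3) for TES-bound genes and Beta(1,9) (mean 0.1) for unbound
ones, or a fixed cycled list for estimator-calibration runs. Loops place
anchors (±500 bp jitter, 400 bp width) per a planted A–H group; genes in
dyad pairs are forced to group H so loop anchors cannot enter the narrow
shared window of an unrelated analysis. Dyad sites sit at the intergenic
midpoint, are co-bound by factor B half the time (so dyad flanks land in
the four single-end categories), appear at baseline only when planted
high-affinity, and drive planted flank responses of ±4-fold (threshold
comfortably above the 1.5-fold call) with 0.05-log2 noise. Expression is
lognormal with log2-mean increments for 5′ and 3′ binding and 0.8-log2
spread.

All randomness flows through a single seeded generator and every
container is iterated in deterministic order, so a seed fixes every
output byte. `perturb` derives depleted bundles (independent peak drops,
global signal decay, noise loops) with an explicit truth delta.

What the generator does **not** emulate: mappability and GC structure,
replicate variability and peak-calling noise, overlapping gene models,
antisense transcription, distance-dependent loop frequencies, and any
sequence-level features (motifs are out of scope). Passing tests
therefore demonstrate the correctness of the interval logic,
classification rules, estimators and statistics under the stated
stochastic model — not robustness to the full messiness of real ChIP
data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the study at 500 genes
(~1500 peaks, ~100k coverage tiles, ~450 loops), with 200-replicate
power and 500-replicate null simulations for the read-through group
test; these sizes give stable recovery percentages (binomial s.e. below
a percentage point on the main rates) while keeping a full run in tens
of seconds. Equidistant anchor ties assign to both genes with
deterministic gene-id ordering; empty region classes are reported with
n = 0 rather than dropped; degenerate z-rows are zeroed and flagged;
BH FDR uses the step-up procedure clipped to [0, 1]. Pipeline outputs
carry a configuration hash (output paths excluded) and no timestamps, so
reruns are checksum-identical.

## Known limitations

Peak-to-end assignment is summit-based by default, so very broad peaks
whose summit falls just outside a window are not assigned (use the
interval-overlap mode if that matters). The read-through estimator is a
ratio of Poisson-distributed window counts and is slightly biased upward
at low expression (≈1% at 100 upstream counts); the `min_upstream`
threshold bounds this. Dyad exclusivity in `span_plus_radius` mode uses
raw peak positions, so factor peaks on unannotated neighbours do not
disqualify a pair. The co-occupancy module reports profiles, not the
unsupervised factor grouping sometimes drawn alongside such heatmaps.
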