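# Methods

This note documents the statistical model behind each pipeline stage,
the generator that the validation suite runs against, the numerical
choices, and the known limitations.

## Coordinate conventions

All internal coordinates are 0-based half-open `[start, end)`; a tag is
a single genomic coordinate (the mapped 5′ position of a sequenced
fragment), counted inside an interval iff `start <= pos < end`.
Conversions happen only at file boundaries: RepeatMasker `.out` query
coordinates (1-based inclusive) are converted on read/write, so an
element whose `.out` end column is E covers position E−1 but not E.
Fragment extension of tags is not modelled: counts are of tag positions,
not of extended fragments. RepeatMasker class/family strings are mapped
to the six analysed family groups by an editable data table
(`SINE/Alu → Alu`, `SINE/MIR → MIR`, `LINE/L1 → L1`, `LINE/L2 → L2`,
`LTR/* → LTR`, `DNA/* → DNA`); rows of any other class are skipped and
counted. Each `.out` row is treated as an independent insertion —
fragments of one interrupted element are not merged.

## Promoter presence/absence calls

Promoters are `[tss−1000, tss+200)` on the + strand and mirrored on the
− strand, clipped at chromosome ends (clipping flagged). For a library
of N tags on a genome of length G, a promoter of length L has
background expectation λ = (N/G)·L. The presence threshold is the
smallest integer k with P(X ≥ k | Poisson(λ)) **strictly below** the
Bonferroni level α/m — the strict inequality and the maximal test count
m = (genes × modifications) both push the caller toward conservatism.
Because the Poisson tail is discrete, the attained per-test level is
typically well below α/m; the measured family-wise false-present rate
under a homogeneous null (10,000 promoters × 5 libraries) is therefore
essentially zero rather than near α. Calls are monotone in counts by
construction. An empty library yields all-absent calls with a warning.

## Active/repressive classification

A modification's expression enrichment is
`mean expression(present) / mean expression(absent)` on the linear
scale; fold > 1 labels the mark active, fold < 1 repressive. A fold of
exactly 1 has no direction; it is labelled repressive and flagged
`fold-boundary`, so every modification with a defined fold lands in
exactly one class. Significance (reported, not required for the label)
is a classical pooled-variance Student's t-test. A `log_scale` switch
replaces arithmetic by geometric means (t-test on log values).

The bundled demo uses the log-scale switch. The reason is structural:
the demo plants 38 simultaneous expression effects, each multiplying
the expression of an independently drawn 20% of genes by 3 (active
marks) or 1/3 (repressive marks). Multiplicative compounding across
marks gives log-expression a standard deviation near 3, and the sample
mean of such a heavy-tailed linear-scale variable does not stabilise at
600 genes, whereas the geometric-mean fold recovers every planted
direction. With a single planted mark (as in the dedicated recovery
study, which uses the default linear scale) the two estimators agree.

## Family enrichment

For family f with merged intervals of total length L_f carrying c_f
tags, the log2 enrichment is `log2((c_f/L_f)/b)`. Intervals are merged
per family before counting, so a tag is never double-counted within a
family; a tag overlapping two families' annotations counts in both.
With `c_f = 0` the log2 value is undefined and the record flagged.

Two backgrounds:

* **global** — b = N/G, the library's total tag count over the genome
  length. Tags inside TEs are *not* excluded, so a strongly enriched
  family slightly inflates its own background; this dilutes log2 values
  toward zero (by about `log2(1 + Σ L_f(fold_f − 1)/G)`) without
  changing rank order. A config switch (`exclude_te_tags`) subtracts
  all TE tags and TE length from the background; the parameter-recovery
  study uses it so the planted fold is the estimand.
* **local** — for each element, one non-TE segment of the element's
  length is sampled from the 1 Mb window centred on the element, and
  the background is the pooled rate Σcounts/Σlengths over all sampled
  segments of the family (the maximum-likelihood rate; an unweighted
  per-element mean is available by flag). Sampling is exact rather than
  retry-based: the window's non-TE gaps are enumerated and a start
  position is drawn uniformly over all placements that fit, which
  targets the same distribution as rejection sampling but cannot fail
  when a feasible placement exists. Elements with no feasible gap are
  skipped and counted; estimates with >10% skipped are flagged
  unreliable.

Significance is a 2-cell goodness-of-fit G-test — observed (tags in
family, tags in background region) against expectations proportional to
the two region lengths — with G = 2·Σ o·ln(o/e) (0·ln 0 = 0), df = 1,
p from the χ² upper tail, and a Bonferroni-corrected level
α/(families × modifications) per background kind, recorded in every
record. G is asymptotically equivalent to Pearson's X²; the relative
difference grows like |o−e|/(3·min e), so the two agree within 5% in
the bulk of null fluctuations at expected counts ≥ 50 but can diverge
further in the far tail.

Class records (active/repressive) sum tag counts within the class
*before* the enrichment formula, equivalent to concatenating the
libraries; duplicating a library in a class leaves log2 unchanged and
increases G. Family-age correlations use Spearman's ρ against the fixed
young-to-old ranking Alu < L1 < LTR < DNA < L2 < MIR.

## Age and distance analyses

The subfamily age table groups elements by (family, subfamily): the age
proxy is the **unweighted** mean percent divergence over elements
(element-wise, not length-weighted), the density is class tags over the
subfamily's merged length, so splitting an element into adjacent
records changes nothing. Correlations (divergence vs. density) are
Spearman over subfamilies, separately per class, requiring ≥ 3
subfamilies.

Distance is boundary-to-boundary between the element and the nearest
gene *span* (not TSS): 0 with `inside_gene=True` for overlap, otherwise
the smaller flanking gap, ties broken toward the lower gene start for
determinism; elements on gene-less chromosomes get NaN and are dropped
from profiles. Counting uses uniquely mapped tags by default — the
generator assigns the non-unique flag at random, emulating repetitively
mapping tags whose placement carries no positional information —
with `unique_only=False` as the sensitivity variant. Bins are
`[i·10kb, (i+1)·10kb)` up to a 200 kb cap plus an overflow bin;
inside-gene elements share bin 0 with 0–10 kb elements but are
separated by a flag (aggregate the two rows for the pooled view). The
reported correlation is always Spearman on the unbinned per-element
(distance, count/length) pairs; an all-constant distance vector leaves
it undefined and flagged.

## Statistical primitives

* Correlations: Spearman uses average ranks for ties; both methods get
  `t = c·√((n−2)/(1−c²))` and a two-sided p from Student's t with n−2
  df. `method="auto"` applies a Q-Q-correlation normality heuristic
  (correlation of sorted data against standard-normal quantiles at
  plotting positions (i+0.5)/n; cutoff 0.99, affine-invariant) to both
  vectors and picks Pearson only if both pass; every result records the
  method actually used. Coefficients within 1e−12 of ±1 are snapped to
  ±1 (exact monotone agreement otherwise lost to rounding), giving
  t = ±∞, p = 0. Constant input raises.
* Student's (pooled) t-test, not Welch; a zero pooled variance raises.
* Bonferroni is plain α/m; no FDR.

## The generator and what it does not emulate

Tags are drawn segment-wise: the genome is partitioned at every
feature boundary into constant-rate segments with rate
`background_rate × fold`, counts are Poisson per segment, positions
uniform within segments. Folds multiply: a TE's family (or subfamily)
fold × its gene-proximity factor `1 + (max_fold−1)·e^(−d/scale)` ×
any overlapping regional bias. Expected totals therefore satisfy rate
conservation: E[N] = rate·Σ(length × fold). Genes are placed first
with a one-promoter-window margin; TEs are placed by bounded rejection
sampling avoiding other TEs and all promoter windows (so planted
promoter and TE folds are identifiable) but may fall inside gene
bodies, which feeds the inside-gene distance bin. Placement failure
after the attempt budget raises with a clear message. Marked genes per
modification are a seeded sample without replacement; their expression
is multiplied by the modification's `expression_effect`, compounding
across modifications. All randomness flows from
`(seed, stage name, library name)` substreams, so runs are reproducible
and adding a library does not perturb the others.

Deliberately not emulated: nucleotide sequence (no FASTA, no read
errors, no aligner), real chromosome-scale TE density or GC/isochore
structure, fragment-length effects, correlated placement of marks
across modifications, and the concentration of non-uniquely mapping
tags inside repeats (the non-unique flag is independent of position).
Consequently, passing tests demonstrate that the estimators recover
planted structure from data generated under the model's assumptions —
not that real tag data satisfy those assumptions.

## Demo study conditions

Two 4 Mb chromosomes; 600 genes (log-normal expression, meanlog 3,
sdlog 1); six families with 2–6 subfamilies each (Alu and L1 carry six
subfamilies spanning divergences ~1–20%); 38 libraries at background
rate 0.004 tags/bp (~40k tags each, ~1.5M total), non-unique fraction
0.39. Planted structure: family folds increase log-linearly with age
rank (0.3 log2 units per rank) with a fixed per-(family, modification)
fold variation of ±0.8 log2 units — without which the across-
modification spread of enrichments within a family would be pure
sampling noise and the global-vs-local agreement check would be
meaningless; Alu subfamily folds rise with divergence for both classes
while L1 active folds rise and L1 repressive folds fall; all TE rates
decay with gene distance (max fold 3, scale 20 kb); 20% of genes per
modification are promoter-marked (fold 6) with expression effects 3
(active) or 1/3 (repressive). These sizes keep a full run under half a
minute while every planted pattern is recovered with wide margins.

Validation studies use their own smaller conditions (documented in
`temark.validation` docstrings): e.g. the null calibration uses a
deterministic grid of 10,000 promoters so the layout itself contributes
no variance, and fold recovery uses 200 × 300 bp elements per family,
giving delta-method standard errors of 0.03–0.10 log2 units against
which recovery within three standard errors is checked.

## Known limitations

* The G-test's 2-cell layout treats the background count as a second
  multinomial cell; for the local background this conditions on the
  sampled segments as if they were a fixed region.
* Expression enrichment assumes one TSS and one expression value per
  gene; multi-TSS genes are out of scope.
* The local background shares one sampled segment set per family
  across modifications (statistically valid — segments are independent
  of tag placement — and much cheaper than resampling per
  modification).
* At fold exactly 1 the active/repressive partition is a labelling
  convention, flagged rather than resolved.
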