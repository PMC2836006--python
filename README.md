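# temark

Histone-modification enrichment analysis of transposable element (TE)
families from mapped ChIP-Seq tag libraries — with a synthetic-data
generator that plants known structure so every stage of the analysis can
be validated against ground truth.

## The scientific problem

Transposable elements make up a large fraction of mammalian genomes, and
how host chromatin treats them discriminates between two evolutionary
accounts: under a *genome defense* view, potentially active (young) TEs
should be wrapped in repressive histone modifications; under an
*exaptation* view, older elements — those most likely to have been
co-opted as regulatory sequence — should carry more marks of both kinds,
especially near genes. Distinguishing these views requires quantifying,
family by family, how strongly dozens of histone modifications are
enriched or depleted over TE sequence relative to a genomic background.

`temark` implements that quantification pipeline for anyone working with
tag-level ChIP-Seq data and repeat annotations:

1. **Promoter calling** — each gene's promoter (1,000 bp upstream to
   200 bp downstream of the TSS) gets a binary presence/absence call per
   modification: with a library of *N* tags on a genome of length *G*, a
   promoter of length *L* has background expectation λ = (*N*/*G*)·*L*,
   and the call threshold is the smallest *k* with
   P(X ≥ *k* | Poisson(λ)) < α/*m*, Bonferroni-corrected over all *m*
   promoter tests.
2. **Active/repressive classification** — a modification's expression
   enrichment is mean expression of present-marked genes over mean
   expression of unmarked genes (linear scale by default, geometric
   means by option); fold > 1 ⇒ active, fold < 1 ⇒ repressive, with a
   pooled two-sample t-test for the group difference.
3. **Family enrichment** — for each TE family *f* and modification, the
   length-normalised tag density over the family's merged intervals is
   compared to a background density *b*:

   log2E(f) = log2[ (tags_f / length_f) / b ]

   with *b* either **global** (*N*/*G*) or **local** (tag density in a
   randomly sampled non-TE segment of matched length within a 1 Mb
   window around each element, pooled over elements). Significance is a
   2-cell goodness-of-fit G-test, G = 2·Σ o·ln(o/e), against χ²(1),
   Bonferroni-corrected over all family × modification cells.
4. **Age and distance analyses** — class-summed tag densities are
   correlated (Spearman, p from t = ρ·√((n−2)/(1−ρ²)) with n−2 df)
   with subfamily consensus divergence (an insertion-age proxy) and with
   distance to the nearest gene (10 kb bins for presentation; the
   correlation is always computed on unbinned per-element data, using
   uniquely mapped tags only).

The synthetic-data generator draws tag libraries as a
piecewise-homogeneous Poisson point process with configurable fold
enrichments inside TE families and subfamilies, inside promoters of
"marked" genes (whose expression is shifted to emulate active or
repressive marks), with optional gene-proximity decay and regional
biases, and a configurable fraction of non-uniquely-mapped tags.

## Worked example

Run the bundled demo study — 2 × 4 Mb chromosomes, six TE families with
subfamily-structured divergence, 600 genes, and 38 modification
libraries (28 with a planted activating expression effect, 10
repressive) totalling ~1.5 M tags:

```bash
temark demo --seed 1 --outdir results/demo
```

or stage by stage with the numbered drivers:

```bash
python analysis/01_simulate.py
python analysis/02_call_promoters.py
...
python analysis/06_distance_analysis.py
```

which prints, among other things:

```
28 active / 10 repressive modifications
global: 228 records, 213 significant after Bonferroni
global vs local log2 agreement per family (Pearson r): {'Alu': 0.989, 'DNA': 0.973,
 'L1': 0.989, 'L2': 0.984, 'LTR': 0.983, 'MIR': 0.968}
family age vs active enrichment (global): rho = +1.00 (p = 0)
Alu active: divergence-density rho = +1.00 over 6 subfamilies (p = 0)
L1 repressive: divergence-density rho = -1.00 over 6 subfamilies (p = 0)
Alu active: distance-density rho = -0.176 over 360 elements (p = 0.0008)
```

Reading these numbers: all 38 planted expression effects are recovered
as the correct active/repressive labels; the 6 × 38 = 228 enrichment
grid is emitted for each background kind and the two backgrounds agree
closely (r ≈ 0.97–0.99 per family); the planted increase of enrichment
with family age, the within-Alu rise of both mark classes with
subfamily divergence, the opposing L1 repressive gradient, and the decay
of tag density with distance from genes all come back with the planted
signs and significant p-values.

Each stage writes plain TSV tables (`enrichment_global.tsv` with one row
per family × modification, `subfamily_age.tsv`, `distance_bins.tsv`, …)
plus a `manifest.json` recording the config hash, seed and per-stage row
counts; identical config and seed reproduce identical files.

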