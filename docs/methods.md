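# Methods

This note records the statistical model behind each component, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions a user auditing results will want.

## Coordinates and the overlap kernel

All intervals are 0-based half-open (`[start, end)`, BED convention), and a
peak's center is `floor((start + end) / 2)`.  Every distance the package
reports is between two single positions (a center and a TSS), so the
half-open convention affects results by at most 1 bp.  Windowed overlap
copies `bedtools window -w`: the query interval is expanded by `w` bp on both
sides and a pair is reported iff the expanded query shares ≥ 1 bp with the
subject.  Chromosome names are matched by exact string equality;
`IntervalSet.validate_chromosomes()` reports names absent from the genome
table instead of silently dropping them, because silent `chr1` vs `1`
mismatches are the dominant failure mode of interval analyses.

## Consensus sites

Replicate peaks are co-clustered by transitive ≥ 1 bp overlap (the most
permissive deterministic criterion; a stricter minimum-overlap is exposed as
`min_overlap_bp`).  A cluster's *support* is the number of distinct
replicates contributing; clusters with support ≥ `min_support` (default 2 of
3) become consensus sites spanning the union of their members — the merged
span is what the `Merged-<chrom>-<center>-<k>` name encodes, with `k`
disambiguating exact center ties.  Control subtraction removes any site
sharing ≥ 1 bp with a control peak.  Two orders are supported: the default
subtracts control peaks from each replicate *before* clustering (per-sample
background cleaning); `post-consensus` removes finished consensus sites
instead.  The two differ only for sites whose replicate peaks partially
escape the control footprint.

## Context classification and gene assignment

Context is decided by the peak *center* — this keeps the context unique and
matches the center-based distances used everywhere else — with precedence
promoter > exonic > intronic > intergenic.  The promoter window is
−1000/+300 bp around the TSS, oriented by gene strand.  Promoter and exonic
peaks are assigned to their single host gene (overlapping candidates broken
by closest TSS, then symbol).  Intronic and intergenic peaks are assigned
bidirectionally: the closest gene by TSS on each genomic side of the center
(at most two assignments; equidistant genes on one side are all kept and
flagged `tied` rather than silently dropped).  Distances are unsigned
`|center − TSS|` to the closest transcript TSS of the assigned gene; for
multi-transcript genes no isoform is privileged.  "Upstream/downstream"
means genomic left/right of the center, not strand-relative — the rule is
about flanking genes.

A useful audit property follows: two peaks assigned to the same gene on the
same side must show distances differing by exactly their center difference.
The test suite exercises this on the published direct-target table, where
both double-peak genes satisfy it (Δ = 458 bp and 1085 bp).

## Co-occupancy statistics

*Profiles.*  For each feature midpoint within ±20 kb (default) of a
reference center, the bin (default 500 bp) of the signed offset is
incremented.  Fold-enrichment divides the per-bin pair density by the
genome-average feature-midpoint density, so uniformly scattered features
give ≈ 1 in every bin and the profile integrates back to the raw pair count.
Midpoint counting is the aggregation-server convention; any-overlap counting
would double-count wide features across bins.

*Random-interval null.*  `n` intervals with lengths resampled (with
replacement) from the reference set's length multiset, chromosome chosen
with probability proportional to length among chromosomes long enough, start
uniform.  Length-matching is the conservative choice; a fixed-length null is
available by passing a degenerate multiset.  No assembly-gap or blacklist
masking is applied (none is available for a synthetic genome); a masking
hook would slot into the sampler.

*Fisher's exact test.*  Two-sided, on
`[[n_overlap, n_ref − n_overlap], [n_overlap_random, n_random − n_overlap_random]]`.
The p-value is the standard sum of hypergeometric probabilities ≤ the
observed one; the reported odds ratio is the sample ratio with a Haldane 0.5
correction applied only when a cell is zero (the p-value is never modified).
p-values below 2.2e−16 are printed as `< 2.2e-16` by `format_p` while the
raw float is kept in tables.  The suite verifies agreement with an
exact-rational enumeration oracle to 1e−12 relative error.

*F-score.*  precision = fraction of feature intervals with ≥ 1 reference
peak within the window, recall = fraction of reference peaks with ≥ 1
feature; F = 2PR/(P + R), 0 when both are 0.  Which set counts as the
"prediction" is a convention; `return_components=True` exposes both
directions, and swapping the sets swaps P and R while leaving F unchanged.

*Panels.*  Every feature set in a panel is tested against the *same* seeded
random set, and a Benjamini–Hochberg adjusted p column is appended (multiple
features are tested; raw p-values are kept alongside).  Per-feature failures
are flagged rows, not aborts.

## ChIA-PET direct targets

An interaction maps iff one anchor overlaps ≥ 1 consensus site and the other
overlaps ≥ 1 promoter window (both orientations tried; anchor window default
0 bp, i.e. direct overlap, consistent with the overlap kernel elsewhere).
An optional promoter-filter interval set restricts qualifying promoters
(e.g. to RNAPII-occupied ones when such evidence accompanies the interaction
data); absent a filter, all annotated promoters qualify.  Intra-chromosomal
links report `|peak center − gene TSS|` — peak-to-TSS rather than
anchor-to-anchor, since the table's purpose is peak-gene attribution — and
inter-chromosomal links the label `Inter (<geneChrom>-<peakChrom>)` with the
gene's chromosome first.  No cap is applied to intra-chromosomal distances.
The direct-target table keeps one row per (gene, peak) link whose gene
passes `fdr < 0.05` in the supplied differential-expression table; genes
linked to several peaks appear on several rows, sorted by symbol.

## Expression and GSEA

RPKM = `count · 1e9 / (gene_length · library_size)` with library size the
column sum of raw counts and gene length the exon-model length.  Ranking
uses `log2((mean RPKM_a + ε) / (mean RPKM_b + ε))` with ε = 0.1 RPKM to
stabilize lowly expressed genes (configurable); ties break lexicographically
for determinism.

The GSEA running sum adds `|score|^p / Σ_hits |score|^p` at each gene-set
hit and subtracts `1/(N − |S|)` at each miss; ES is the deviation of maximal
magnitude (ties between equal positive and negative peaks resolve to the
positive one, deterministically).  Default weight p = 1 (hit scores weighted,
the common modern default); p = 0 gives the classic Kolmogorov–Smirnov-style
statistic whose running sum provably returns to 0 and whose ES the suite
checks against a brute-force enumeration oracle.  Significance uses
*gene-set* permutation — random sets of size |S| drawn from the ranked
list — because with 3-vs-3 designs phenotype permutation has only 20
distinct relabelings and is degenerate; this is a documented divergence from
phenotype-permuting implementations.  The permutation p is
`(1 + #{|ES_null| ≥ |ES_obs|}) / (1 + m)`, so its floor is `1/(m+1)`.  The
null is computed vectorized by evaluating the running sum only at the 2k
positions (just before / just after each hit) where its extrema can occur.

Differential-expression *testing* on real data is consumed as an input table
(gene, log2 fold change, FDR) from whatever caller produced it; it is not
reimplemented here.

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes, at
about 1/10 the scale of a typical mammalian ChIP study so the full test
suite runs in seconds: 5 chromosomes × 2 Mb, 1,500 single-transcript genes
of 0.6–3 kb with 1–5 exons (2,000 genes on a 5 Mb genome cannot be placed
without overlap, so the genome is 10 Mb), 120 true binding sites of mean
length 400 bp spaced ≥ 5 kb apart.  Site contexts are *planted*
(57% intergenic, 37% intronic, 2.6% promoter, 2.4% exonic, matching the
empirical distribution such factors show) by rejection sampling against the
package's own classifier, so truth labels are self-consistent with the
pipeline's definitions.

Replicates detect each true site with probability 0.9/0.85/0.4 — a
strong/strong/weak sensitivity spread — jittered by N(0, 20 bp), plus
130/110/15 uniform noise peaks; 10% of sites are planted into the control
set as artifacts, plus 40 control noise peaks.  The exact consensus
sensitivity P(detected in ≥ 2 replicates) = 0.853 is computed in closed form
and used as the recovery benchmark.  Co-factor sets plant a peak at a
fraction ρ of true sites (defaults 0.82/0.462/0.4475 for the three
pluripotency factors, the observed co-localization levels in the motivating
system) with N(0, 30 bp) jitter, padded with uniform background to 200 peaks.
Loops connect consensus-survivable sites (detected ≥ 2×, not contaminated —
mirroring a design where loops are read off the consensus list) to gene
promoters: 27.8% inter-chromosomal, 63% of intra-chromosomal loops under
100 kb.  Expression is negative-binomial (dispersion 0.1) in two groups of
3; all loop-target genes receive a +1 log2-unit shift and 12/23 additional
non-looped genes +/−1 shifts.  The emitted DE table comes from a Wald test
on the log ratio of group count sums using the generator's known dispersion
(the moderation an empirical-Bayes caller would otherwise supply), with BH
correction; *ground-truth direct targets* are the looped genes called at
FDR < 0.05 in that table, which is what a pipeline run can be audited
against.

What the generator does **not** emulate: read-level noise and mappability
structure, peak-width/signal correlation, clustered (non-uniform) gene
density, isoform complexity, GC or copy-number biases, and correlated
replicate failures.  Passing tests therefore demonstrate correctness of the
interval arithmetic, the statistics and the bookkeeping under the stated
generative model — not robustness to real-data artifacts such as blacklist
regions or antibody batch effects.

With 3-vs-3 samples and dispersion 0.1, single-gene DE power at a 1 log2
fold change is modest by construction (the log-ratio standard deviation is
≈ 0.39 log2 units regardless of depth once dispersion dominates), so only a
minority of planted genes is called at FDR < 0.05; this mirrors real
small-n designs and is why ground truth is defined through the emitted DE
table rather than through the planted effect list.

## Determinism and the pipeline

All randomness flows from one root seed through named `SeedSequence`
substreams (annotation, sites, replicates, cofactors, interactions,
expression), so identical config + seed give byte-identical output files,
and stages are reproducible independently.  The pipeline writes a manifest
(config hash, seed, per-stage row counts, package version) and a report
whose every number is recomputable from the stage output files alone.  A
stage failure aborts with the stage named; completed outputs are retained.

## Problem sizes used in checks

Oracle-equivalence checks run on random instances of up to 500 intervals
against vectorized all-pairs oracles, and on all 2×2 tables with margins
≤ 12 plus 200 random tables with margins ≤ 200 against an exact-rational
Fisher oracle.  Calibration checks use 200 simulated null overlap tests and
100 null GSEA rankings of 400 genes with 200 permutations each.  Parameter
recovery runs the full default synthetic study.  These sizes make the whole
suite complete in well under a minute while keeping every binomial tolerance
(3 SE or a 99% CI) meaningful.
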