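# regcoloc

Integrative analysis of transcription-factor ChIP-seq peak sets downstream of
peak calling, built around the question: *where does a factor bind, which
genes does it target, and which other factors share its sites?*  The package
was designed for studies of the SIM2 transcription factor in mouse embryonic
stem cells — a factor whose binding sites co-localize with the OCT4 / SOX2 /
NANOG pluripotency network — but every component is generic over BED-style
interval data.

It provides, as a library and a `regcoloc` command-line tool:

- **Replicate-consensus binding sites.** Peaks from ≥ 2 biological replicates
  are clustered by overlap; clusters supported by at least `min_support`
  replicates become merged sites named `Merged-<chrom>-<center>-<k>`, and
  sites found in a control line are removed as artifacts.
- **Genomic-context annotation.** Each site's center is classified with
  precedence promoter > exonic > intronic > intergenic (promoter = −1 kb/+300 bp
  around the TSS, strand-oriented), and assigned candidate target genes:
  the single host gene for promoter/exonic sites, the nearest gene by TSS on
  *each* side of the center for intronic/intergenic sites.
- **Co-occupancy statistics.** Frequency profiles of a second factor's peak
  midpoints around reference centers (40 kb window); windowed overlap
  fractions (`bedtools window` semantics, 100 bp default); a length-matched
  random-interval null; a two-sided Fisher's exact test of observed vs random
  overlap counts; and the interval-overlap F-score
  (F = 2PR/(P+R), 1 = perfect match).
- **ChIA-PET direct targets.** Paired-anchor interactions (BEDPE) are mapped
  so that one anchor hits a consensus site and the other a gene promoter;
  linked genes that are differentially expressed (FDR < 0.05) become the
  direct-target table, with center-to-TSS distances for intra-chromosomal
  links and `Inter (<geneChrom>-<peakChrom>)` labels otherwise.
- **Expression integration.** RPKM normalization
  (count·10⁹ / (length·library size)), log2 fold-change ranking, and GSEA:
  the enrichment score ES is the signed maximal deviation of the
  hit-weighted running sum over the ranked gene list, with a gene-set
  permutation p-value.
- **A synthetic-data generator** that emits every input the pipeline consumes
  with full ground-truth labels, so each stage is testable end to end without
  any external download.

## Worked example

Simulate a study and run the whole pipeline from one seed:

```bash
regcoloc run --seed 7 --out run7
```

This writes the simulated inputs under `run7/simulated/`, the consensus sites
(`consensus.bed`), the annotation and co-localization tables, the
direct-target table and a JSON report.  With the default generator settings
(120 true sites, replicate detection probabilities 0.9/0.85/0.4, co-factor
co-localization fractions 0.82/0.462/0.4475) the run prints a report
containing, e.g.:

```
consensus_sites: 93            # of 120 true sites; P(detected in >= 2 reps) = 0.853
context_counts: {intergenic: 57, intronic: 29, promoter: 4, exonic: 3}
coloc NANOG: fraction 0.796, p 4.9e-34, F 0.51
coloc OCT4:  fraction 0.495, p 8.0e-15, F 0.31
coloc SOX2:  fraction 0.441, p 8.2e-14, F 0.29
chiapet: 40 links (33 intra / 7 inter), 9 direct-target genes
gsea: ES 0.998, fdr_p 0.001
```

Read: the consensus step recovered the expected ~85% of plantable sites; the
observed overlap fractions estimate the planted co-localization fractions;
the Fisher p-values reject the random-placement null for every co-factor; the
planted loop-target genes are strongly enriched among upregulated genes
(positive ES, permutation p at its floor).

The same stages are available individually (`regcoloc simulate`, `consensus`,
`annotate`, `coloc`, `chiapet`, `gsea`) on your own BED/GTF/BEDPE/TSV files —
see `regcoloc <cmd> --help`.

## Layout

```
src/regcoloc/
  intervals.py        interval model, BED I/O, windowed-overlap kernel
  consensus.py        replicate clustering, consensus sites, control subtraction
  annotation.py       GTF gene models, context classification, TSS assignment
  colocalization.py   profiles, random-interval null, Fisher test, F-score
  chiapet.py          BEDPE I/O, anchor mapping, direct-target table
  expression.py       RPKM, fold-change ranking, GSEA
  simulate.py         ground-truth synthetic data generator
  pipeline.py, cli.py orchestration and command-line interface
docs/methods.md       model assumptions, defaults, numerical choices
```
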