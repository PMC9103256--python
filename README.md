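# methtriad

Methylome / small-RNA / transcriptome integration for two-condition plant
experiments: sliding-window DMR calling from bisulfite cytosine reports,
CPM + t-test differential expression, DMR-gene and miRNA-methylation
association, and negative-correlation "key gene" classification — with a
synthetic-data generator that plants recoverable ground truth.

## The analysis

The package targets the common tri-omics design in plant epigenomics: one
pooled whole-genome bisulfite library per condition (e.g. heat-shock
treatment vs control), plus small-RNA and mRNA libraries with three
replicates each. It answers three questions in sequence:

1. **Where does methylation change?** Per cytosine context (CG/CHG/CHH),
   1 kb windows sliding by 500 bp are tested with a two-sided Fisher exact
   test on pooled methylated/unmethylated read counts. A window is a DMR
   candidate when p < 0.05 and BH-adjusted q < 0.05, pooled coverage is
   >= 30 reads in each sample, the methylation difference exceeds 15
   percentage points, and the level fold change is > 2 or < 0.5;
   surviving windows merge into regions (hyper = higher under treatment).
2. **What changes expression?** miRNAs: Welch-type t statistics on
   log2(CPM+1) with empirical-Bayes variance moderation, DER = q < 0.05.
   mRNAs: thresholds |log2FC| > 1 and q < 0.05 applied to an external
   differential-expression table (or a built-in, clearly labelled
   stand-in test for synthetic runs).
3. **Which genes are pinched from both sides?** Each DMR is assigned to
   gene sub-features (promoter thirds, exons/introns, downstream) by
   maximal overlap; triads (gene, DMR direction, targeting miRNA's
   direction) are classified by the directional pattern

   ```
   fully_negative  <=>  (gene up  & DMR hypo  & miRNA down)
                     or (gene down & DMR hyper & miRNA up)
   ```

   Fully negative triads are the *key genes*: expression moves opposite
   to both its promoter/body methylation and its targeting miRNA.
   Hypergeometric term enrichment (Bonferroni-corrected) profiles any
   resulting gene set.

All inputs are plain text: Bismark-CX-like cytosine reports, GFF3 gene
models, BED miRNA loci, TSV count matrices, miRNA-target pairs, and
gene-term maps. See `docs/methods.md` for the full model description,
defaults, and limitations.

## Worked example

Simulate a full dataset (2 chromosomes x 1 Mb, 120 genes, 40 miRNA loci,
20 planted DMRs, planted differential features, 5 planted fully-negative
triads and 5 distractors) and run the whole pipeline:

```
$ methtriad --seed 11 --outdir demo --log-level WARNING run-all
called 19 DMRs, 19 DERs, 27 DEGs; 5 key-gene triads (planted 5)
```

The counts mean: 19 merged DMRs passed all filters (of 20 planted; one
CHG region fell to the fold-change filter), 19 miRNAs and 27 genes were
called differential (planted DE features plus the planted triad/distractor
features), and exactly the 5 planted fully-negative triads — and none of
the 5 distractors — were flagged as key genes:

```
$ column -t demo/results/key_genes.tsv | head -4
gene_id         gene_dir  dmr_dir  dmr_location     mirna_id        mirna_dir  label           is_key_gene
gene_chr1_0037  down      hyper    distal_promoter  mirna_chr1_012  up         fully_negative  True
gene_chr1_0046  up        hypo     distal_promoter  mirna_chr1_009  down       fully_negative  True
```

Each row reads as one triad: `gene_chr1_0037` is downregulated under
treatment, its distal promoter is hypermethylated, and its targeting
miRNA is upregulated — the canonical repressive pattern from both layers.
`demo/results/` also holds the context summaries, regional profiles,
window statistics, DMR BED, DER/DEG tables, DMR-gene links, and the
miRNA-methylation association table; `demo/inputs/` holds the simulated
inputs and the ground-truth JSON.

The same stages run individually (`simulate`, `methylome`, `dmr`,
`diffexpr`, `annotate`, `integrate`, `enrich`) on your own files, and the
library API (`methtriad.dmr.call_dmrs`, `methtriad.diffexpr`,
`methtriad.integration`, ...) is the intended surface for scripted use.

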