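# Methods

`methtriad` re-implements, as a tested library, a tri-omics integration
analysis of a two-condition plant experiment (heat-shock-treated vs
control microspores): whole-genome bisulfite methylation summaries,
sliding-window differential-methylation-region (DMR) calling, differential
expression of miRNAs and mRNAs, DMR-gene and miRNA-methylation
association, and the directional "key gene" classification that joins the
three layers. Because the original sequencing data are not required, a
synthetic-data generator produces all inputs with planted, recoverable
ground truth; the test suite and the acceptance script quantify recovery.

## Coordinate and data conventions

All internal coordinates are 0-based half-open. The cytosine report
(1-based positions) and GFF3 (1-based inclusive) are converted at the I/O
boundary only. Cytosine calls keep their strand, but all window and region
statistics pool both strands. Methylation levels are always
coverage-weighted: the level of any set of cytosines is
(sum of methylated reads) / (sum of total reads), so splitting one site's
reads across records changes nothing.

A site counts as a methylated cytosine (mC) when it has at least one
supporting read (`min_meth_reads`, default 1). An optional stricter rule
additionally requires a one-sided binomial test against a bisulfite
conversion-error rate (default 0.5%) at level 0.05; it is off by default
because no error model is part of the default inputs.

## Methylome summaries

Per context (CG, CHG, CHH), the summary reports site counts, mC counts,
each context's share of all mCs, and the coverage-weighted mean level.
Between-condition comparison uses a two-sided Fisher exact test on the
2x2 table (mC sites, non-mC sites) x (condition A, condition B), per
context and overall. Which 2x2 construction the original analysis used is
not documented anywhere we could find; this one is an explicit assumption
of the package.

Regional profiles average levels over named gene sub-features: the 2 kb
upstream flank cut into near-equal thirds (distal / intermediate /
proximal promoter; 667/666/667 bp at the default flank), the exon/intron
partition in transcription order (first / internal / last; a 2-exon gene
has no internal exon, and its single intron is classed "first intron"),
and the 2 kb downstream flank. Regions without covered cytosines report
NaN, never 0. A metagene curve uses 20 fixed-width bins per flank and 60
proportionally scaled gene-body bins; genes shorter than the bin count
contribute through fractional coordinates.

## DMR calling

Chromosomes are tiled with 1 kb windows sliding by 500 bp (windows
truncated at chromosome ends). Per window and context, methylated /
unmethylated read counts are pooled over cytosines and compared between
conditions with the two-sided Fisher exact test (point-probability
criterion — the sum of all table probabilities not exceeding the observed
table's; mid-p variants differ and are not used). Windows with no covered
cytosine in either sample are dropped. Benjamini-Hochberg q-values are
computed per context across all tested windows.

A window survives when p < 0.05, q < 0.05, pooled coverage >= 30 reads in
each sample, |level difference| > 15 percentage points, and fold change
> 2 or < 0.5. The "more than 15" threshold is interpreted as percentage
points of absolute level difference — the fold-change filter already
covers the ratio reading — but a `level_filter="ratio"` option implements
the other reading. Thresholds written with ">" are strict; the coverage
">= 30" is inclusive. Fold change divides level_A by level_B with a floor
of 0.005 on the denominator; floored records are flagged.

Surviving windows that overlap or touch, and share chromosome, context
and direction, merge into one region. Merged counts are re-pooled from
the call tables over the merged span, so cytosines shared by overlapping
windows are counted once; the merged p is recomputed by Fisher on those
counts, and the merged q is the smallest member-window q (the merged span
is not itself a member of the BH family, so it carries no adjusted value
of its own). Direction is hyper when the treatment level exceeds the
control level. For exact two-sided Fisher p-values at scale the package
uses its own vectorized log-gamma enumeration, verified against
`scipy.stats.fisher_exact` to ~1e-12.

## Differential expression

miRNA counts are CPM-normalized and tested per feature on log2(CPM + 1)
with a two-sided t statistic. By default the pooled per-feature variance
is moderated: log-variances are regressed on average expression
(quadratic trend), the prior degrees of freedom are estimated from the
residual spread by method of moments, and the posterior variance
(d0*s0^2 + d*s^2)/(d0 + d) is used with a t reference on d + d0 degrees
of freedom. With three replicates per condition a raw Welch statistic has
~4 degrees of freedom; its p-values rarely fall far below 1e-3, which
makes FDR control across even a modest feature family discard most true
effects. Variance moderation is the standard remedy for this design and
is what the package defaults to; `moderated=False` restores the plain
Welch test, and both variants hold the nominal type-I level on null
simulations. Differential miRNAs (DERs) are called from q < 0.05 alone —
no fold-change filter — matching the analysis this package reproduces.

mRNA differential expression canonically arrives as an external table
(e.g. from an edgeR/DESeq2 run) with feature_id, log2fc and q; the
package then applies the thresholds |log2FC| > 1 (strict by default,
inclusive as an option) and q < 0.05. For fully synthetic runs a built-in
stand-in — the same moderated t on log2(CPM + 1) plus those thresholds —
is used and labelled `builtin-standin` in the provenance column; it makes
no claim to reproduce a negative-binomial GLM. FPKM
(count x 1e9 / (length x library)) is provided for completeness.

log2 fold changes use a pseudocount of 1 on normalized means to avoid
infinities. Zero-variance features with equal means get p = 1 (p = 0 when
the means differ). The lexicographically first group label is the
treatment, so swapping labels negates every log2fc and preserves p and q.

## Association and integration

A DMR links to every gene whose body +/- 2 kb it overlaps; its feature
class is the sub-feature with maximal base overlap, ties broken in the
order promoter > exon > intron > downstream. A gene linked to DMRs of
both directions is kept as "mixed" and excluded from triad classification
(the directional patterns assume a single direction). A miRNA locus is
"associated with mCs" when at least one methylated cytosine lies inside
it (threshold configurable).

Triads join a differentially expressed gene, its DMR direction, and the
DER direction of a miRNA predicted to target it (target pairs are an
input table). The label is a pure function of the three directions:
fully negative when (gene up, DMR hypo, miRNA down) or (gene down, DMR
hyper, miRNA up); methylation-only or miRNA-only negative when exactly
one layer anti-correlates; non-negative otherwise. "Negative correlation"
is implemented as this direction logic, not a numeric coefficient: with a
single pooled methylome per condition a per-gene correlation coefficient
across samples is undefined. The key-gene table deduplicates to one row
per (gene, miRNA), concatenating DMR locations, and is deterministically
sorted. Reconstructed published direction tuples are frozen in the test
suite; for five of the seven genes the methylation direction was missing
from the available table text and was inferred from the published key-gene
lists (a gene printed up/down with a down/up miRNA can only be absent from
the key list if its methylation direction is non-anticorrelated; one
ambiguous gene, non-key under either reading, was fixed as hyper).

Term enrichment is the upper-tail hypergeometric test with Bonferroni
correction over the tested terms; terms with zero hits in the query set
are not tested and do not inflate the correction denominator. The
background defaults to all annotated genes and is overridable.

## Synthetic data generator

The generator emulates the statistical structure of the study design: two
pooled bisulfite samples (one per condition, no methylation replicates),
three expression replicates per condition, and planted effects at the
stated magnitudes. Defaults: 2 chromosomes x 1 Mb; 120 genes of 1-5 exons
placed with >= 6 kb intergenic gaps (so no gene's 2 kb flank touches
another gene); 40 intergenic miRNA loci of 80-160 bp; cytosine densities
CG 0.02, CHG 0.015, CHH 0.045 per bp; baseline levels CG 0.65, CHG 0.35,
CHH 0.10; coverage ~ Poisson(40) truncated to >= 1.

Methylated counts are beta-binomial: each site draws one latent level
from Beta(mean*c, (1-mean)*c) with concentration c = 30, shared by both
conditions — site-to-site heterogeneity is a property of the locus, not
of the sample — and binomial reads are drawn per condition around it.
Only inside a planted DMR of the matching context does the treatment
condition draw an independent level around baseline +/- 0.4. This keeps
the window Fisher test exactly calibrated under the null while marginal
counts remain overdispersed. Planted DMRs are 2 kb, aligned to the
500 bp window grid, mutually separated, and use CG in the hypo direction
(0.65 -> 0.25) and CHG in the hyper direction (0.35 -> 0.75): a 0.4
shift cannot be planted downward in CHH at all (0.10 - 0.4 < 0, a
configuration error), and an upward 0.4 CHH shift would be far outside
the plausible range for that context.

Expression counts are negative-binomial (variance mu + 0.05 mu^2) with
per-feature baselines log-uniform on [10, 1e4] and library sizes jittered
+/-20% per replicate (so CPM normalization is actually exercised).
Planted differential features shift by 2^(+/-2) in the treatment
condition and draw baselines from [1e2, 1e4]: the integration recovery
checks target robustly expressed features, not detection at the counting
floor. Planted up/down directions alternate so library composition stays
roughly balanced.

Triad planting is coherent: each of the 5 fully negative triads gets a
promoter DMR in its gene (hypo-CG with gene up and miRNA down, or
hyper-CHG mirrored), and each of the 5 distractor triads flips exactly
one of the three directions (cycling through gene, DMR, miRNA), so
classifier specificity is testable. Decoy miRNA-target pairs connect
unplanted miRNAs to unplanted genes. Everything is a deterministic
function of the seed.

What the generator does not emulate: genome sequence composition,
read-level artifacts, bisulfite conversion error, positionally
autocorrelated methylation outside planted regions, and correlated
biological replicate structure. Passing recovery tests therefore
demonstrate the pipeline's statistical correctness under its stated
model, not performance on real libraries.

## Problem sizes and numerical choices

The default synthetic genome (2 x 1 Mb, ~160k cytosines, 12k tested
windows) keeps a full pipeline run at a few seconds and the 10-seed
recovery studies at about a minute each; these sizes were chosen so that
every planted window holds enough cytosines (~15-20 per context) for the
coverage filter and the Fisher test to operate in their intended regime.
BH adjustment is a hand-written step-up (verified against statsmodels);
Fisher tests use SciPy scalar calls and the package's vectorized batch
enumeration; the hypergeometric tail uses `scipy.stats.hypergeom.sf`.
Ties in maximal-overlap classification break by a fixed feature order;
empty inputs yield empty, well-typed outputs rather than errors wherever
a downstream join can still proceed.

## Known limitations

With one pooled methylome per condition, window tests measure read-level
evidence, not biological replication; real designs with replicates would
need a different caller (explicitly out of scope). The CHG-hyper planted
effect sits near the fold-change boundary (0.75/0.35 ~ 2.14 vs > 2), so
a small fraction of planted CHG regions are legitimately filtered out;
recovery rates reflect that. CPM normalization is composition-sensitive
when a large fraction of a small feature family is differential; the
moderated test absorbs most, but not all, of the resulting compression.
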