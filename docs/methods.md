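# Methods

This note documents the models and estimators implemented in `obpdiv`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that a
user re-deriving the outputs needs to know.

## Study design assumed

The toolkit targets a two-lineage supergene system sampled as haploid
individuals: group A ("SB") recombines with the rest of the genome, group B
("Sb") is a non-recombining haplotype, and an outgroup lineage split before
the A/B divergence. Defaults throughout mirror that design: 7 haploids per
group, one pooled outgroup library, ~8× mean coverage, and a supergene
confined to one interval on one linkage group.

## Fixed differences and polarization

A site is a fixed difference when all called samples of group A share one
allele, all called samples of group B share a different allele, and each
group has at least `min_called` calls. `min_called` defaults to the full
group size (7): with only seven haploids per group, "fixed" should mean
fixed among everything observed. Lowering `min_called` trades stringency
for tolerance of missing genotypes; both behaviours are exercised in tests.

Polarization compares the outgroup call at each fixed site: if the outgroup
matches the A allele the substitution is derived on the B lineage, and vice
versa. Missing, polymorphic, or third-allele outgroup states are
`unresolved` — no imputation is attempted, since a single pooled outgroup
library cannot distinguish low coverage from true polymorphism.

## Codon effects and allele-specific CDS

Coordinates are 0-based half-open internally; GFF3 I/O converts to/from
1-based inclusive. User-facing codon positions are 1-based ("codon 16 of
176"). Allele-specific coding sequences are rebuilt by substituting each
lineage's fixed alleles into the reference CDS; insertions and deletions
shift the downstream frame and the net offset is recorded. A stop codon
strictly before the final codon is flagged premature; translation continues
past it so downstream substitutions remain reportable.

Single-nucleotide codon changes are labelled directly from the genetic
code. Codons hit by two or three fixed differences get per-site labels by
substituting each site alone into the A background, with an ambiguity flag
when the B-background label differs; this reconciles per-nucleotide
difference counts with codon-level estimators. Indels are reported as
structural notes and never counted as synonymous/nonsynonymous
substitutions.

## dN/dS (Nei–Gojobori 1986)

Synonymous site content of a codon is the per-position fraction of the
three alternative bases that preserve the amino acid (mutations creating a
stop count as nonsynonymous), so S + N = 3 per codon; sites are averaged
between the two alleles. Substitution counts for multi-hit codons average
over all orderings of the changes with equal weights; orderings that pass
through a stop codon are excluded (if none is stop-free, all orderings are
used). Proportions are corrected with Jukes–Cantor, d = −(3/4)·ln(1−4p/3);
p ≥ 3/4 raises with the raw proportion reported. dS = 0 yields ratio NA
with Nd and Sd still emitted. Genes whose alleles carry an internal stop
are excluded from dN/dS with a warning and surface through structural notes
instead — a ratio over a pseudogenized reading frame is not meaningful.

The estimator name is recorded in output metadata. Other codon estimators
(e.g. Li-style kaks as in seqinR) weight pathways and sites differently and
will not reproduce these numbers exactly; the implementation is validated
against an exhaustive pathway-enumeration oracle rather than against any
particular published gene value.

## Coverage copy-number model

The per-gene statistic is the median per-base depth over the CDS (robust to
local spikes); the background is the mean of per-gene medians over a
background set (default 1000 genes, sampled away from the tested unit).
In multi-sample mode the per-sample ratio r_i = unit depth / mean
background depth of sample i is tested by a one-sample t-test of log2 r_i
against 0 with n−1 df. The log scale is the natural choice because fold
changes are multiplicative; it also makes the back-transformed CI
asymmetric around the fold estimate, as observed for real multi-copy genes.
Single-sample mode (a lone pooled library) compares the unit's normalized
depth against the background units' normalized-depth distribution with
n_background − 1 df.

Deletions are maximal runs of windows with zero depth in every carrier
sample and depth above a presence threshold (default 1 read/base) in every
sample of the other group, annotated with whole CDS exons lost and a
frameshift flag (coding bp removed mod 3). Duplications are called when a
group's fold exceeds 1.75 (rounding to ≥ 2 copies) while the other group's
CI contains 1; if both groups exceed the threshold the call is shared
("both") with copies = rounded mean fold.

## Nucleotide diversity and sweep scan

Per-site π uses the unbiased haploid estimator (n/(n−1))(1 − Σ p_a²);
window π sums sites over non-overlapping windows (default 10 kb) and
divides by the full window length, so windows remain comparable regardless
of callability (a callable-sites denominator is available). The sweep scan
flags windows strictly below a genome-wide quantile (default the lower
quartile) that overlap annotated features, merging adjacent flagged windows
into runs. The scan is applied to the recombining (SB) group only: the
entire non-recombining haplotype carries a sweep-like signature, so a
within-Sb scan is uninformative by construction and is excluded by default.

## Expression statistics

Size factors are median-of-ratios: for every gene expressed in all samples,
count over geometric mean; the sample's factor is the median ratio (taken
on the ratio scale; only factor ratios are identified).

The differential-expression test is a deliberately transparent
simplification of shrinkage-based RNA-Seq packages: normalized group means,
a single pooled method-of-moments NB dispersion (per-gene moments
(var − mean)/(mean² − var/n), averaged across genes), and a Wald test of
the log2 fold change with variance (1/μ + α)/n per group by the delta
method. The Wald statistic is referred to a standard normal: the standard
error comes from the pooled fit over thousands of genes, not a per-gene
sample variance, so no small-sample t correction applies. The cost of the
simplification is that genes whose true dispersion exceeds the pooled value
are anti-conservative; on the generator's constant-dispersion output the
test is calibrated (type-I error ≈ 0.05, checked on a 2000-gene null at
5 vs 5 samples), but on real heterogeneous data a shrinkage method should
be preferred. Benjamini–Hochberg adjustment is applied within each caste,
as queens and workers are tested separately. All-zero genes are reported NA
and excluded from the adjustment.

The three secondary statistics are: a one-proportion goodness-of-fit χ²
(df = 1, no continuity correction — the conventional pairing for printed
values like χ² = 0.05 → p = 0.82) for region enrichment of DE genes; a
one-sided exact binomial tail P(X ≥ k | n, ½) for direction consistency of
significant genes; and a two-sided two-sample Kolmogorov–Smirnov test for a
p-value shift of a target gene set, exact by enumeration when both sets
have n ≤ 10.

## Coexpression

Unsigned adjacency a_ij = |cor(i,j)|^β with β = 6 (the standard
scale-free-topology default for unsigned networks), topological overlap
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), average-linkage
clustering of 1 − TOM, and a static cut at 0.9 of the maximum merge height
(min module size 10; small clusters become "unassigned"). The static cut
replaces dynamic tree cutting; 0.9 was chosen because realistic module
noise puts within-module merges well above half the dendrogram height —
with block correlation 0.8 and noise SD 0.5, within-block merges reach
~0.7 of the maximum, and any cut below that shatters true modules. (A cut
of 0.25 of max corresponds to WGCNA's eigengene-merging threshold, a
different quantity, and fails planted-partition recovery.) Module
eigengenes are first principal components of the standardized module
expression, unit-norm, oriented to correlate non-negatively with the module
mean. Group tests are two-sided two-sample t-tests per eigengene,
Bonferroni-corrected across modules; cross-dataset module correspondence
uses two-sided Fisher exact tests on the shared gene universe, Bonferroni
over all module pairs.

## Synthetic-data generator

The generator plants known truth and emits exactly the formats the
pipeline consumes, so every stage is verifiable without external data.
Defaults (all exposed in `SimulationConfig`):

- three 100 kb scaffolds (one per linkage group); supergene interval
  10–70 kb on one of them; 24 genes, 10 in the supergene, 3 clustered
  inside a designated low-diversity interval;
- 7 + 7 haploids plus one outgroup sample; outgroup divergence 0.02/site
  genome-wide (an order of magnitude above the supergene divergence,
  matching the relative ages of the species split and the supergene split);
  non-coding supergene divergence 0.002/site, derived on Sb;
- within-group diversity 1e-3 (SB) vs 1e-5 (Sb) — the two-orders-of-
  magnitude contrast characteristic of a swept non-recombining haplotype —
  with segregating sites placed at a density calibrated so expected window
  π matches the target, and the low-π interval depressed 50-fold;
- planted coding events with exact counts (rejection-sampled substitutions:
  8+1, 3+2, 1+0, 0+1), a premature stop (single base to TAG at codon 16,
  derived on SB) plus a 17-bp frameshifting insertion (anchor at CDS
  nucleotide 74, derived on Sb) in one gene, a 2600 bp deletion removing
  3 of 5 coding exons (267 coding bp, no frameshift), a two-copy
  Sb-specific duplication and a four-copy shared duplication;
- an unpolarizable fraction of 1/8 of planted differences per event
  (outgroup call set to missing), applied deterministically in planting
  order, so an 8-substitution gene resolves exactly 7 of 8;
- coverage: expected depth = mean depth × copy number × a per-(gene,sample)
  lognormal factor (σ = 0.25 in log2 units, representing mappability and
  library effects that do not cancel in background normalization), then
  per-base Poisson sampling with the gene statistic taken as the median;
  this σ reproduces CI widths of the order reported for real fourfold
  gains. Windows use mean Poisson depth; windows fully inside a planted
  deletion have expectation exactly 0 in carriers;
- expression: NB counts via gamma–Poisson with dispersion 0.1, per-gene
  lognormal baselines (median 200 for focal genes), per-sample lognormal
  size factors (σ = 0.2), and the study's pool sizes (queens 3 multiple-
  vs 2 single-queen; workers 2 vs 3). Planted social-form effects are
  +2 log2 on 14 focal genes in queens (7 supergene + 7 outside) and on 4
  supergene genes in workers — all positive, reproducing the
  direction-consistency structure; 2% of the 2000 background transcripts
  get random-sign effects.

What the generator does **not** emulate: read-level errors and mapping
bias, recombination and demography (variants are placed independently, so
there is no linkage disequilibrium beyond the planted fixed haplotype
structure), overlapping genes, alternative splicing, and
dispersion heterogeneity across expression genes. Passing tests therefore
demonstrate correctness of the estimators under the stated sampling models,
not robustness to alignment artefacts or model misspecification in real
data.

## Problem sizes used in checks

The oracle-agreement checks run 1000 random codon-aligned pairs (≤ 30
codons) for dN/dS and 500 random windows for π, both to |Δ| < 1e-12. The
fold-CI coverage check uses 200 coverage replicates with 100 background
genes per replicate (the per-unit t-test depends on the tested unit's
ratios, not on the background count, which only sets the precision of the
per-sample background mean). The null calibration uses one 2000-gene
negative-binomial matrix at 5 vs 5 samples.

## Known limitations

- The NG86 implementation targets pairwise allele comparisons; no
  branch-model or maximum-likelihood codon tests.
- The DE test's pooled dispersion is a global constant; see above.
- Deletion calling requires strictly zero carrier depth per window, which
  is appropriate for haploid carriers of a true deletion but brittle if
  contamination adds stray reads; the presence threshold for the other
  group is configurable.
- Module detection with a static cut does not adapt to nested module
  structure; module counts are sensitive to the cut and are not a stable
  output of interest — planted-structure recovery is.
- The polarization model assumes no recurrent mutation at fixed-difference
  sites; a third allele in the outgroup is left unresolved rather than
  modelled.
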