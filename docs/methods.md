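# Methods

`ilripe` reimplements, as a tested pipeline, a candidate-gene screen for
fruit-ripening regulators that combines comparative parent
transcriptomics with expression-QTL (eQTL) mapping on an introgression-line
(IL) panel: a set of ~76 lines, each carrying one defined chromosomal
segment from a wild donor (*Solanum pennellii*) in the background of the
cultivated recurrent parent (M82), whose overlapping segments tile the
donor genome.  The real screen ran on external array and RNA-seq
compendia; this package runs the same computations on any conforming
expression matrix and ships a synthetic panel generator with planted
truth so every step is verifiable end to end.

## Parent-expression sorting

Genes are split by the pseudocounted ratio of mean expression between
the parents,

    ratio = (mean_M82 + c) / (mean_Penn + c),    c = 1 abundance unit,

into a Lyco set (ratio > 1), a Penn set (ratio < 1) and exact ties.
The candidate filter keeps genes with ratio >= 5 (inclusive boundary) in
the chosen direction.  The pseudocount stabilizes ratios when the donor
allele is nearly silent (e.g. abundance 31 vs 0.17, where the raw ratio
divides by near-zero); it is shared with every other fold-change
computation in the package.  Replicates are averaged arithmetically by
default (geometric available by flag); the choice is visible only near
the filter boundary.

## eQTL detection and classification

An IL panel reduces eQTL mapping to outlier detection: for a cis-regulated
gene, only the line(s) whose introgression carries the gene's locus
deviate from the recurrent parent.  For each gene, replicates are
collapsed to per-IL means, log2-transformed with the pseudocount, and IL
*i* is called iff

    |z_i| >= z_min   and   |log2(IL_i / parent)| >= min_abs_log2,

where z_i = (x_i − median_j x_j) / (1.4826 · MAD_j x_j) over the IL log2
means.  Defaults z_min = 2.5, min_abs_log2 = 1.  The median/MAD z is
robust to exactly the structure a cis-eQTL creates (one or two outlier
lines among ~76); the ratio floor suppresses calls that are
statistically outlying but biologically negligible.  When the MAD is
zero (noise-free panels, near-constant genes) the z criterion is dropped
with a warning and the ratio floor decides alone — this makes the
noiseless limit exact.

Classification from interval geometry (0-based half-open BED
coordinates, point containment of the gene start):

* **located ILs** — lines whose introgression contains the gene's start
  coordinate; nested sub-lines (an IL4-1-1 inside an IL4-1) can both
  contain it.
* **specific** — a nonempty call set that touches at least one located
  IL and strays into at most `max_extra_ils` (default 0) other lines.
  Nested located lines both calling is still specific.
* **cis / trans / mixed** — every / no / some called IL is located.

Gene-start containment (rather than any-overlap) decides boundary-spanning
genes; with megabase segments and kilobase genes the difference is
negligible and the rule is unambiguous.

## Candidate routes

**eQTL route** — specific-eQTL genes that passed the 5-fold parent
filter and are annotated as transcription regulators, oxidases or
cytochrome P450s (the categories enriched for ripening regulators).

**TF route** — transcription factors more than 5-fold higher in the
cultivated parent that carry at least one eQTL call, ranked by the
pseudocounted ratio of expression at ten days post-breaker (Br+10) to
breaker (Br), top 20 kept.  Curated ortholog/literature knowledge is
accepted as an optional allow-list file, since it is human judgement,
not computation.

**Final narrowing** — both routes merged (eQTL route wins duplicates),
then filtered on tissue specificity and the parent ratio.  Tissue
specificity uses the tau index over per-stage mean expression,

    tau = sum_i (1 − x_i / x_max) / (n − 1),

which is 0 for uniform and 1 for single-stage expression; defaults
tau_min = 0.5, ratio_min = 5.  Each surviving record carries a
per-filter audit trail.

## Co-expression network

Pearson correlation (Spearman by flag) of log2(x+1) expression across
tissues/stages for every unordered pair of a curated target list, with
the exact two-sided P from t = r·sqrt((n−2)/(1−r²)) on n−2 df.  Edges
require |r| > 0.6 and raw P < 0.05, matching common practice for small
curated lists; Benjamini–Hochberg is available behind a flag and off by
default.  |r| = 1 maps to the smallest positive double so perfect
correlations are retained.  Zero-variance genes are skipped with a
warning.  Output (SIF/TSV) is sorted lexicographically and Cytoscape-loadable.

## Differential expression and conserved sets

DEGs per contrast use the dual threshold |log2FC| >= 1 and BH FDR < 0.05.
The fold change is computed on pseudocounted group means of raw
abundances; the test is Welch's t on log2(x+1) replicate values, a
transparent default for abundance matrices (the original DEG lists came
from an RNA-seq pipeline whose test is unstated; count-model dispersion
estimation is out of scope).  A fold-change-only mode serves two-replicate
designs whose variance estimates are uninformative.  Degenerate
variances (noise-free fixtures) use the convention P = 0 when the means
differ and 1 otherwise, shared with the test oracles so exact
comparisons are well defined.

Conserved sets intersect per-contrast direction calls under a required
sign pattern (e.g. up in OE at mature green, down in RNAi at breaker and
pink) and report all exclusive Venn region counts.  External mutant DEG
lists join the intersection under a sign-concordance rule: their sign
must match the direction required of the designated knockdown-like
contrast (loss-of-function mutants are expected to move with the RNAi).
Unsigned lists are accepted with sign checks disabled and a warning.

The qPCR utility implements Livak relative quantification,
2^−ΔΔCt with ΔΔCt = (Ct_target − Ct_reference)_sample − (Ct_target −
Ct_reference)_calibrator; it is invariant under a common Ct shift.

## Synthetic panel generator

The generator emulates the statistical structure the screen assumes, not
any particular dataset:

* **Design** — main segments partition each chromosome into equal spans
  extended 10% into their neighbours (union exactly covers the
  chromosome), plus a `nested_fraction` share of strictly-contained
  sub-lines.  Defaults: 12 chromosomes of 50 Mb, 76 lines, 15% nested.
* **Expression model** — log-normal: log2 abundance ~ Normal(mean,
  noise_sd_log2).  The pipeline consumes ratios, not counts, so a
  negative-binomial read model would add nothing downstream statistics
  can see.  Baseline log2 means are uniform on [0, 10].
* **Planted cis eQTLs** — 150 genes whose donor-allele mean is shifted
  by a magnitude drawn U(2, 4) in log2, random sign; ILs containing the
  gene's locus take the donor mean.  Effects are planted only on genes
  with baseline log2 >= 3: an eQTL on a transcript at the pseudocount
  scale is undetectable by any ratio-based screen and would not model a
  discoverable signal.
* **Donor dropout** — with probability 0.02 a gene's donor allele is
  nearly silent (log2 = −2.5), reproducing the near-zero donor
  expression pattern of the strongest real candidates; these genes are
  genotype-switched in their located ILs like cis genes (a silent donor
  allele is a cis difference) but tracked separately in the truth table.
* **Trans pairs** — 30 regulators drawn from the cis genes, each
  shifting one target by ±1.5 log2 in every IL carrying the regulator.
  Targets are drawn outside all ILs containing their regulator, so a
  trans effect can never be confounded with a cis signal by chance
  collocation; the confounded geometry is undecidable for any method
  and is excluded by design.
* **Stage matrix** — the M82 background across six tissues/stages; a
  seeded 30% of TF genes are ripening-induced (suppressed before
  breaker, +3 log2 at Br+10 over Br), giving the TF route and the tau
  filter real signal.
* **Transgenic experiment** — WT/OE/RNAi at three stages with a planted
  conserved core (up in OE at MG, down in RNAi at Br and Pink, down in
  the rin/nor label sets) and its mirror, plus genotype-private extras,
  effect ±2 log2.
* **Replication and noise** — defaults noise_sd_log2 = 0.4 and 3
  replicates per group, reflecting the limited replication of IL array
  data.  The real panel's replicate count and noise level are unknown;
  these are free parameters, not calibrated to the original data.

Reproducibility: one `numpy.random.default_rng(seed)` stream per
generator with a documented draw order; the noise draw is always made
(sd possibly zero), so the stream position — and therefore every other
draw — is identical between noisy and noiseless runs with the same seed.
Same seed and config give byte-identical files.

What the generator does *not* emulate: cross-platform normalization
differences (each matrix is treated as internally comparable only),
linkage/recombination beyond fixed intervals, count overdispersion,
correlated noise across genes, and partially-silenced alleles.  Passing
tests therefore demonstrate correctness of the computations and
recoverability of planted structure under log-normal noise — not
performance on any real compendium.

## Numerical and determinism choices

* Coordinates 0-based half-open throughout; strand ignored (never used).
* TSV serialization: 9 significant digits for expression, 12 for
  correlation coefficients; round-trip tests compare at those
  precisions.  Missing values are rejected, never imputed.
* Pipeline runs canonicalize gene and sample order (sorted) on entry so
  every floating-point reduction has a fixed summation order: repeated
  runs and permuted input files produce byte-identical outputs.
* Ties in ranked lists break lexicographically by gene id; merged
  candidate duplicates keep the eQTL-route record.

## Problem sizes used by the checks

The planted-recovery experiments run at the emulated design's full size
(5,000 genes × 76 ILs × 3 replicates; seconds on one CPU).  The network
oracle comparison uses 171 genes × 40 samples; the DEG oracle fixture
1,000 genes with 40 planted 4-fold effects; the null calibration 200
simulations of 100 genes at 3 replicates per group.  The conserved-core
recovery experiment uses 6 replicates per group: Welch's t at n = 3 has
~4 degrees of freedom and is dominated by its variance estimate, so an
adequately powered recovery experiment needs more replication; at n = 6
the per-contrast miss probability for a 4-fold effect at noise 0.2 is
far below 1%.

## Known limitations

The specific/nonspecific boundary of the original screen was never
quantified; the robust-z rule here is a defensible formalization, so
class counts are comparable across runs of this package but not to the
original publication's counts.  Headline numbers of the original study
(gene totals, per-class counts, the 0.86 co-expression coefficient)
derive from external datasets and are not reproduction targets.  The
Welch test substitutes for an unstated RNA-seq DEG procedure.  eQTL
significance is thresholded, not permutation-calibrated — the design
lacks the replication to support permutation.
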