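# Methods

This note documents the statistical models, the parameter choices, and the
design decisions behind `methylink`, in the order the pipeline runs them.

## Coordinates and formats

All internal coordinates are 0-based half-open on the forward strand.  GTF
(1-based inclusive) and Bismark-style coverage files (1-based) are converted
once at the I/O boundary; conversions are involutions and are tested as
round-trips.  CpG positions are keyed by the + strand cytosine of the CG
dinucleotide; reverse-strand calls must be collapsed onto it by the caller
(CpG methylation is symmetric, and coverage-file merging tools do this).  A
`destrand` decision is deliberately left to the caller because input files
differ in whether it was already applied.  N bases never participate in CpG
or motif matches.

## Synthetic study generator

The generator emulates the structure of a four-group neuro-epigenomics
study: groups "Attacker", "Parental", "Father", "Mother" with 6/6/5/6
biological replicates, RNA-seq gene counts and RRBS CpG counts from the same
animals.  Defaults, and why:

* **Genome**: 4 contigs x 2.5 Mb of uniform random DNA.  Spontaneous CCGG
  occurrences are destroyed (first C flipped, preserving the internal CpG)
  and motifs are planted at `ccgg_rate = 1.8e-4`/bp, giving roughly 20 000
  digest-capturable CpGs — the scale at which the representation urn and
  multiple-testing behaviour are exercised realistically while a full run
  stays under a minute.  A rate of zero therefore yields an empty
  background, which the tests rely on.
* **Genes**: 5000 non-overlapping genes of 600–1200 bp with 1–3 exons on
  random strands.  Gene density is unrealistically high; this is deliberate
  (promoter/gene-body assignment gets exercised heavily) and documented as a
  difference from real genomes below.
* **Expression**: baseline means log-normal(log 100, 1); per-sample size
  factors log-normal(0, 0.1); counts negative binomial with dispersion 0.1
  (typical biological replicate variability).  10 % of genes are planted
  with |log2FC| ~ |N(1, 0.25)| in one uniformly chosen group, so each
  pairwise comparison sees a subset of the planted genes.
* **Methylation**: only digest-capturable CpGs are simulated, which makes
  the representation test's urn exact by construction.  Baselines are a
  bimodal mixture (40 % Beta(1,9), 40 % Beta(9,1), 20 % Beta(5,5)),
  mimicking the low/high bimodality of real CpG methylation.  Coverage is
  Poisson(30); methylated counts are beta-binomial with overdispersion
  0.05.  5 % of CpGs carry a planted |delta| ~ |N(0.30, 0.05)| in one
  group, clamped to [0.01, 0.99] with a counted warning.
* **Coupling**: optionally, genes that are both expression-planted and have
  promoter CpGs receive promoter methylation deltas anti-monotone with
  their planted log2FC through a Gaussian copula of strength
  `coupling_rho`, mapped monotonically onto (−0.35, 0.35).  A rank-based
  copula is used because the integration stage measures Spearman
  correlations.

One seeded `numpy` Generator is threaded through every draw, so a seed
fixes the study byte-for-byte.

What passing tests on this generator do **not** show: behaviour under
GC-biased coverage, cell-type mixtures, strand-specific artefacts, gene
length/expression correlations, or LD-like spatial correlation of
methylation — none of which the generator emulates.

## Differential expression

Filtering keeps a gene iff in *every* group strictly more than half the
samples have CPM >= 1 ("per group" is ambiguous between any/every; the
strict reading reproduces the removal of a gene missing from half of one
group, and an `any` mode is available).  The CPM floor is configurable
because the original pipelines in this field rarely print it.

TMM normalization follows the standard recipe: reference sample = largest
upper quartile of CPM, gene-wise log ratios double-trimmed (30 % on M, 5 %
on A), inverse-variance weighted, factors normalized to geometric mean 1.

The test is a likelihood-ratio chi-square (1 df) between a two-mean and a
one-mean NB model with log effective library sizes as offsets.  Group means
are fitted by Fisher scoring on the log scale, vectorized across genes.
Dispersion is estimated by Cox–Reid adjusted profile likelihood on a
25-point log-spaced grid (1e-4 to 5): per gene, the profile log-likelihood
at the fitted group means minus half the log Fisher information per fitted
mean, plus an abundance-binned trend curve weighted to be worth 10 prior
observations; the maximizer is refined by quadratic interpolation in log
dispersion.  A method-of-moments alternative (`method="moments"`) is kept
for reference; it is measurably anti-conservative at n = 6 + 6 (type-I
~0.065 at nominal 0.05 versus ~0.055 for the adjusted likelihood), which is
why the adjusted likelihood is the default.

log2FC = log2 of the fitted mean counts at the average effective library
size, with a prior count of 0.125 against zeros.  Sign convention: in a
comparison "X vs Y", positive log2FC means higher expression in X.  DEG
thresholds are strict: |log2FC| > 0.5 AND p < 0.05, on raw p-values; a BH
FDR column is included for information only.

DEG clustering z-scores each gene's normalized log-CPM group means across
the four groups (population SD; constant rows get z = 0) and runs k-means
(k = 8, Euclidean, k-means++, 50 restarts) with clusters relabeled by
descending size so a fixed seed is fully deterministic.

## Differential methylation

A site is tested when at least 2 samples per group have coverage >= 5
(these floors are package defaults, not inherited from any published
analysis).  Group levels are read-pooled proportions over the samples
passing the floor.  Overdispersion is method-of-moments from the
chi-square-type statistic `X2 = sum_j (y_j − n_j p)^2 / (n_j p q)`: since
`E[X2_g] = (m_g − 1)(1 + (n − 1) phi)` — estimating the pooled proportion
removes one sample's worth of the *full* beta-binomial variance — the
denominator carries an (m−1)/m correction; without it the estimator is
biased low by ~m/(m−1) and the test's type-I error exceeds 0.07 at the
study's sample sizes.  Per-site estimates are clipped to [0, 1] and shrunk
toward the genome-wide median with a prior weight of 10 observations.

The Wald statistic divides the group difference by the beta-binomial
standard error; degenerate group proportions (0 or 1) get a continuity
correction `(y+0.5)/(n+1)` in the variance only, so that with `phi = 0` and
non-degenerate counts the test reduces *exactly* to the unpooled
two-proportion z-test.  DMC thresholds are strict on p (< 0.05) and
inclusive on the difference (|delta| >= 0.15).  Delta follows the same sign
convention as expression: positive = higher methylation in the first-named
group ("hyper").

DMRs are greedy merges of consecutive tested CpGs with gaps <= 100 bp whose
significant members share a direction; a region must span >= 50 bp (the
last CpG's dinucleotide included), contain >= 3 CpGs and be >= 50 %
significant — the conventional defaults for this model family, all
configurable.

## Digest background and feature annotation

The in-silico digest finds every motif occurrence (overlaps included; CCGG
is its own reverse complement so a + strand scan covers both strands), puts
the cleavage point after offset 1 (C^CGG), takes ±100 bp windows, merges
overlaps so the urn contains distinct balls, and collects CpGs whose C lies
inside a window (a CG straddling the right edge counts by its C).

Features are assigned with a fixed precedence — promoter > exon > intron >
TTS region > intergenic — so every position gets exactly one label; ties
among genes at equal precedence go to the nearest TSS, then lexicographic
gene id.  The promoter is [TSS − 2000, TSS), excluding the TSS base (the
usual "upstream to the TSS" reading; a flag includes it); the TTS region is
the 1000 bp downstream of the TTS.  For expression pairing, "gene body"
spans TSS to 1000 bp past the TTS by default; because reasonable analysts
disagree about the tail, `body_includes_tail=False` turns it off.

Representation is tested two-sided by default (both depletion and
enrichment are of scientific interest; one-sided is available) with the
doubling rule `2*min(P[X<=k], P[X>=k], 0.5)` and a Haldane-corrected
(+0.5 per cell) log2 odds ratio so zero cells still yield finite effect
sizes, BH-corrected across features.  Note the odds ratio is the 2x2-table
(DMC vs non-DMC) version: a DMC set that is an exactly proportional
subsample of the background gives log2OR = 0, but the degenerate "DMC set =
whole background" case does not (both complement cells vanish).

## RRHO

Metrics are `-log10(p) * sign(log2FC)` with p floored at 1e-300 and
`sign(0) = 0` (such genes join no quadrant).  The stratified scheme
computes each quadrant over only the genes whose metric signs match that
quadrant in both lists, ranks them most-extreme-first (ties by gene id),
and scores every rank-threshold pair on a grid of step `ceil(sqrt(N))`
(grid forced to include the full universe) with the upper hypergeometric
tail.  All pixels of all four quadrants are corrected jointly with
Benjamini–Yekutieli — BY rather than BH because pixel statistics are
strongly positively dependent across thresholds.  The per-quadrant gene
list is the overlap at the most significant pixel (ties toward the smallest
thresholds); this extraction rule is a package convention — the literature
reports such counts without defining the pixel choice — and the counts are
only meaningful when the quadrant actually carries signal.

## Integration

The observation unit is the (gene, DMC) pair, preserving genes with several
DMCs; a gene-mean mode exists (`aggregate_pairs_by_gene`).  Quantile
boundaries are type-7 (linear interpolation) quantiles of the *distinct*
genes' log2FC so multi-DMC genes cannot distort them; a gene exactly on a
boundary falls into the lower quantile.  Gene-body pairs use m = 8
quantiles and promoter pairs m = 4 (promoter observations are scarcer).
Spearman's rho per quantile uses the exact permutation distribution for
n <= 9 pairs and the t approximation otherwise; quantiles with fewer than 3
pairs are flagged rather than tested.  The family-wise threshold is exactly
alpha/m (0.00625 for m = 8, 0.0125 for m = 4 at alpha = 0.05); no other
adjustment is applied.  Coupling recovery is assessed on the Spearman rho
over the full coupled pair set: conditioning on a single quantile strongly
attenuates a global rank coupling (a copula of strength 0.6 drops to ~0.2
within a quartile), so per-quantile signs are reported but the pooled sign
is the recovery criterion.

The joint-change gene list — DEGs with at least one promoter or gene-body
DMC, deduplicated, no quantile segmentation — feeds the ORA stage; distal
intergenic DMCs never link to genes (enhancer-to-gene assignment is out of
scope).

## Pipeline

`run_all` executes: filter/normalize → DE for the four default comparisons
(Attacker vs Parental, Attacker vs Father, Parental vs Father, Father vs
Mother — Mother is compared only to Father, the only other pair-bonded
group) → DM per comparison → digest background → annotation →
representation tests → RRHO of the two Attacker comparisons → DEG-union
clustering → integration per comparison and region → ORA.  If integration
has fewer distinct genes than quantiles it retries with the largest
feasible m and logs the reduction.  Outputs are TSV/BED with fixed float
formatting; the resolved config and seed are written next to them, and
reruns are byte-identical.  The run log is deliberately timestamp-free so
it, too, reproduces exactly.  Warnings (clamped deltas, untestable sites,
unmapped orthologs, reduced quantiles) are counted and summarized, never
silent.

## Problem sizes used in tests

The test suite runs the calibration checks at the design's own scale (5000
genes or 20 000 CpGs, 6 vs 6 samples) and the end-to-end check on the full
default study (5000 genes, ~20 000 capturable CpGs, 6/6/5/6 samples);
smaller fixtures cover the combinatorial oracles exhaustively (all
hypergeometric urns with N <= 25, 20-gene RRHO grids at step 1).  These
sizes were chosen so the complete suite exercises every stage at realistic
multiplicity.

## Known limitations

* The NB dispersion and beta-binomial overdispersion estimators are
  transparent approximations of the heavier empirical-Bayes machinery in
  dedicated DE/DM packages; numerical parity with any of them is not a
  goal — calibration on the stated generative models is the contract, and
  is what the acceptance checks measure.
* The Wald DM test remains slightly anti-conservative (~0.06 at nominal
  0.05 under the study design); this is measured and bounded, not hidden.
* Promoters/gene bodies come from gene spans, not transcript isoforms; UTR
  and CpG-island classes are not modelled.
* RRHO pixel p-values are analytic hypergeometric tails; permutation-based
  pixel nulls are out of scope.
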