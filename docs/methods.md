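# Methods

`srnadisc` re-implements, as a self-contained and fully testable Python
package, the analysis a small RNA-seq biomarker discovery study runs from
raw reads to a report: trimming, hierarchical read classification, mature
miRNA quantification, unsupervised exploration, and negative-binomial
differential expression with FDR-maximizing independent filtering. This
note records the models, the parameters that matter, the numerical
choices, and what the synthetic-data tests do and do not demonstrate.

## Read preprocessing

Each read is processed in three steps.

1. **3' quality trimming** uses the standard running-sum rule: walking from
   the 3' end, the partial sums of `cutoff − q_i` are accumulated and the
   read is cut where the sum is maximal (stopping once it turns negative).
   Default cutoff: Phred 20.
2. **Adapter removal** searches every start position for an ungapped
   occurrence of the 3' adapter, allowing the adapter to run off the read's
   3' end (prefix-only overlap) with at least `min_overlap = 3` aligned
   columns, and admitting a candidate when `errors / overlap ≤ 0.1`.
   Candidates are ranked by matched columns (overlap − errors), then by
   errors, then by the 5'-most start. Ranking by matched columns first is a
   deliberate choice: a genuine full-length adapter occurrence (≈20 matched
   columns) must outrank a chance zero-error 3-nt overhang at the very end
   of the read, while the final 5'-most key keeps the behavior conservative
   against adapter read-through when candidates are otherwise equal.
3. **Length filtering** discards inserts shorter than 17 nt (the lower end
   of the mature miRNA length range) or longer than an optional maximum.

The conservation identity `input = passed + discarded_short +
discarded_long` is asserted per sample.

## Ungapped k-mismatch alignment

The classification cascade needs bowtie1 `-v`-style semantics: ungapped
alignment with at most 0–2 substitutions, both strands, reporting either
all best-stratum hits or one deterministic best hit. The aligner indexes
exact k-mers (k = 10) of both strands and uses pigeonhole seeding — with at
most m mismatches, one of m+1 disjoint seed blocks must match exactly —
when the read is long enough (`len ≥ (m+1)·k`); shorter reads, which at
small RNA lengths is the common case, fall back to a vectorized mismatch
profile over every offset. Both paths end in exact Hamming verification,
so results are identical and are tested against an exhaustive scan.

Choices worth noting:

* `N` never matches any base, in read or reference (conservative).
* Reverse-strand hits are reported at the forward coordinate of the
  alignment start, so one coordinate convention serves both strands.
* "First best hit" is defined reproducibly: among best-stratum hits, the
  smallest (reference id, position, strand with `+` before `-`). An
  index-order-dependent "first" would not be reproducible across runs.

## Hierarchical classification

Each trimmed read receives exactly one class:

1. genome search, 2 mismatches — no hit ⇒ **unmapped**;
2. miRNA quantifier match in precursor context ⇒ **miRNA**;
3. ncRNA search, 1 mismatch, first best hit ⇒ that record's class
   (rRNA, tRNA, piRNA, snRNA, snoRNA, lncRNA, yRNA, other_ncRNA);
4. cDNA search, 1 mismatch ⇒ **mRNA**;
5. otherwise **unknown_genomic**.

miRNA assignment deliberately precedes the generic annotation steps so the
dedicated quantifier claims the primary analyte. The ncRNA step does not
resolve multi-mapping beyond the deterministic first best hit; this is a
known classification blur for similar references and is surfaced in the
report. Class counts are conserved (they sum to the trimmed read total)
and the percent view sums to 100 per sample.

## miRNA quantification and RPM

A read counts toward mature `m` when it aligns sense-strand to `m`'s
precursor, within 1 mismatch, inside the window
`[m.start − 2, m.end + 5)` — canonical reads plus isomiRs with small
templated 5'/3' shifts collapse onto the canonical mature id. The window
defaults (2 nt upstream, 5 nt downstream, 1 mismatch) follow common
quantifier practice. A read admissible for several matures is counted
once, toward the first best-stratum mature in the aligner's deterministic
order; multi-counting would inflate totals.

RPM normalizes to the sample's **total miRNA-assigned reads** (not total
reads) × 10⁶, so each RPM column sums to 10⁶ exactly; a sample with zero
miRNA reads gets an all-NA RPM column and a warning.

## Differential expression

The engine follows the standard quasi-likelihood negative-binomial
workflow, vectorized across features:

* **TMM normalization**: weighted trimmed mean of M-values (30% trim on M,
  5% on A, inverse-variance weights), reference = the sample whose
  upper-quartile count fraction is closest to the mean of those fractions,
  factors scaled to geometric mean 1, all-zero features excluded. This
  step reproduces edgeR's `calcNormFactors` to near machine precision
  (cross-checked in the test suite through Rscript).
* **GLM**: per feature, NB log-linear model with offsets
  `log(library size × TMM factor)`, fitted by IRLS across all features at
  once (max 50 iterations, relative deviance tolerance 1e-8, ridge 1e-6 on
  the information matrix to handle separable cases). The design matrix is
  intercept + contrast indicator + optional additive blocking dummies;
  rank deficiency (e.g. blocking confounded with the contrast) is an
  error. A contrast side may pool several group levels; samples in neither
  side are excluded.
* **Dispersion**: per-feature values solve the Pearson chi-square equation
  `Σ (y−μ)² / (μ + φμ²) = df` (monotone in φ, solved by bracketed root
  finding), then are shrunk toward an abundance-binned median trend with a
  fixed prior weight of 10 residual-df equivalents.
* **Testing**: full and reduced fits at the shrunken dispersions give a
  quasi-likelihood ratio; the denominator is the per-feature quasi-
  dispersion (deviance / residual df) moderated by empirical-Bayes
  squeezing under the scaled-F model (moment matching on log s², with the
  trigamma inverse solved by Newton iteration). The statistic is referred
  to F(1, residual df + prior df). Features with no counts among the
  contrasted samples return NA.

This is a faithful-in-spirit re-implementation, not a numerical clone:
acceptance is by calibration (null type-I error within [0.025, 0.075] at
α = 0.05) and recovery (planted log2 fold changes of 2 estimated within
±0.3), plus the edgeR cross-checks above (logFC median |Δ| < 0.01,
p-value rank correlation > 0.95 on a shared simulated dataset).

## Independent filtering

Low-abundance features mostly contribute noise; removing them before
Benjamini–Hochberg adjustment can increase the number of significant
features. The scan:

* filter statistic: mean RPM across the contrasted samples — abundance
  based and independent of the group labels;
* grid: quantiles θ ∈ {0, 0.01, …, 0.95}; at each θ, features at or above
  the θ-quantile of abundance survive, surviving p-values are BH-adjusted,
  and those ≤ α counted;
* θ\* is the arg-max, ties to the smallest θ (least filtering), with no
  curve smoothing — the raw maximum is taken.

When the maximum does not exceed the unfiltered count the scan is
uninformative (typically: no true positives) and a **fallback RPM rule**
is applied instead: with `T = 10 / L` (L = smallest contrasted library
size in millions — i.e. the RPM at which ~10 reads are expected in the
shallowest library), a feature is dropped when its RPM is below `T` in at
least ⌈n/2⌉ samples of the smaller contrast group. Two edge readings were
settled here: the threshold is the CPM-style `10/L` with L in millions
(the only dimensionally coherent reading; the literal raw-count divisor is
selectable in code), and with equal group sizes — where no smaller group
exists — the condition must hold in both sides, which keeps the mask
invariant under swapping the contrast. BH is re-run on the survivors only;
filtered features carry NA p/FDR and a flag.

## Exploration statistics

* distinct miRNAs per sample at strict thresholds (> 0 and > 10);
* top-50 features by coefficient of variation (sd/mean, n−1 sd, zero-mean
  features excluded, ties by feature id);
* heatmap matrices are unit-variance scaled per feature (constant features
  scale to zeros, not NaN) and clustered by complete linkage on Euclidean
  distances, features and samples separately; a second heatmap covers
  features detected (count > 0) in every sample;
* PCA on log2(RPM + 1), feature-centered, via SVD (equivalently the
  eigendecomposition of the sample covariance), component signs fixed so
  the largest-magnitude loading is positive; t-SNE at perplexity
  min(5, (n−1)/3) with a recorded seed. The pseudo-count 1 and the log2
  scale for ordination are this package's choices and are visible in the
  code/config.

## Synthetic data: what it emulates and what it does not

The generator produces every input the pipeline consumes. Its defaults
describe a modest discovery study: 2 × 4 samples, 1000 reads per sample
with composition 60% miRNA / 20% rRNA / 10% mRNA / 5% unknown-genomic /
5% unmapped, 50 mature miRNAs (10 differentially expressed at log2FC 2),
NB counts at mean 100 with dispersion 0.1, reads of 17–25 nt carrying the
standard small RNA 3' adapter, constant Q37 qualities (optionally with a
low-quality 3' tail to exercise quality trimming).

Two construction guarantees make end-to-end checks exact rather than
statistical:

* **separability**: every embedded reference sequence (precursors, ncRNAs,
  cDNAs), their reverse complements, and the adapter are kept pairwise
  Hamming distance > 2 apart over every window of the minimum read length
  (rejection sampling against a window bank), so every read classifies
  unambiguously; "unmapped" reads are brute-force verified not to hit the
  genome within 2 mismatches, and "unknown genomic" reads are sampled from
  genome regions outside all embedded features;
* **exact apportionment**: per-sample class counts are derived from the
  design fractions by the largest-remainder method, so truth tables hold
  exact integers.

What passing these tests does **not** show about real data: there are no
sequencing errors, PCR duplicates, quality dropoffs, repeat structure, or
cross-mapping families (real miRNA families differ by 1–2 nt, where
single-assignment choices genuinely matter); real genomes are 5–6 orders
of magnitude larger, where the desk-scale aligner would be too slow. The
statistical claims (calibration, recovery, filtering gain) rest on the NB
model being the data-generating process — the same assumption the method
itself makes.

## Problem sizes used in the automated checks

The test suite and the acceptance script run at desk scale, chosen as the
smallest sizes at which each property is meaningfully exercised: 2 kb
genomes and 100-read batches for aligner-vs-oracle equivalence; 8 samples
× 1000 reads for exact classification recovery; 2000 features × 10 or 16
samples for calibration, recovery and filtering simulations; 50 × 8
matrices for the exploration oracles.

## Known limitations

* The aligner is ungapped and unsuitable for genome-scale references.
* ncRNA classification stops at the first best hit (see above).
* One additive blocking factor; no random effects or continuous
  covariates.
* Novel miRNA prediction, spike-in absolute quantification, and BAM input
  are out of scope.
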