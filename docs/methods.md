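# Methods

## Model and pipeline

The package analyses per-SNP log2 copy-number ratios (0 = diploid) from
dense SNP arrays of tumor tissue. Its core assumption is the admixture
model: assayed tissue contains a fraction ρ ∈ (0, 1] of tumor cells, so a
segmental event with integer tumor copy number *c* shifts the expected
log2 ratio of covered SNPs to `log2((ρ·c + (1−ρ)·2)/2)` — attenuated
("partial") gains and losses rather than the pure-tumor values. Because
the observed shift depends on unknown purity, the pipeline avoids hard
per-SNP thresholds and instead accumulates local evidence:

1. **Moving-window t smoothing.** Copy-number events are segmental, so
   neighboring SNPs share the same underlying copy number. Each raw value
   is replaced by the one-sample t-statistic of the 31 SNPs centered on it
   (window confined to the SNP's chromosome), tested against 0. Near a
   chromosome end the window shrinks symmetrically; when the symmetric
   window would fall below 5 SNPs it is instead extended asymmetrically
   within the chromosome. A zero-variance window maps to 0 (zero mean) or
   ±50 (the `zero_variance_cap`, chosen to dominate the ±10 call cutoff
   while staying finite). t-statistics are scale-free, so the smoothed
   profile is invariant to rescaling of the raw ratios.

2. **Cytoband scores.** Per sample, each cytoband's smoothed values are
   summarized by a one-sample t against 0 (default) or by a sign-test z,
   `(n_pos − n/2)/√(n/4)` with n counting nonzero values (zeros carry no
   sign information; an all-zero band scores 0). Positive = gain,
   negative = loss. Bands with fewer than 2 SNPs are merged into their
   neighbor toward the centromere before scoring. The t default makes the
   downstream constants (call cutoff 10, IQR filter 2.5) meaningful for
   bands of tens-to-hundreds of SNPs.

3. **Calls and arm events.** Strict thresholds: score > 10 → gain,
   < −10 → loss, else neutral. An arm's loss (gain) proportion over a
   sample group is the maximum band-level proportion on the arm; the
   direction with the larger proportion is the arm's overall state (ties
   are reported "undecided"). Cross-study pooling sums event and sample
   counts and rounds the percentage half away from zero — the convention
   that reproduces every printed percentage in the packaged six-study
   count table (`cytoscan/data/study_counts.tsv`, 572 tumors in total).

4. **Group statistics.** Box summaries are per-band (q1, median, q3) with
   the linear-interpolation ("type 7") quartile rule — fixed because the
   IQR feeds a hard filter. A band whose whole box is below (above) zero
   means at least 75% of the group shows loss (gain). Two-group
   comparison is Welch's unequal-variance t with Welch–Satterthwaite
   degrees of freedom ("studentized" with the unequal group sizes typical
   of these cohorts); |t| > 2 is flagged significant, with no multiple-
   testing correction (a Benjamini–Hochberg column is emitted for
   reference only). Event correlation uses sign-oriented mean scores over
   band sets and Pearson's r.

5. **Survival scan.** Disease-specific survival runs from first operation
   to disease-caused death; death from other causes censors at the death
   date. Bands with cross-sample score IQR ≤ 2.5 are excluded. For each
   remaining band, 100 univariate Cox models are fitted, each on a random
   80% subset of patients drawn without replacement (resampling, not
   bootstrap), and −log10 of the score-test p-value and the Newton-fitted
   coefficient are averaged over non-degenerate models (`n_models_used`
   reports how many). The Cox machinery uses the Breslow partial
   likelihood; the score statistic U(0)²/I(0) is referred to χ²(1) and
   coincides with the logrank test for binary covariates with untied
   event times (verified against lifelines to 1e−10). One covariate per
   model (the band score); no clinical adjusters. Subsets are drawn from a
   per-band RNG substream keyed by the band *name*, so results are
   invariant to band and sample order.

6. **Clustering.** Agglomerative hierarchical clustering of score-matrix
   rows; Ward linkage on euclidean distance by default (correlation
   distance and average/complete linkage available; Ward requires
   euclidean). Flat labels for a chosen k are renumbered by first
   appearance, making results deterministic. Subtype-recovery accuracy is
   the fraction matched under the best one-to-one cluster→class
   assignment (Hungarian); surplus clusters count their members as errors.

## Synthetic data generator

`simulate_cohort` emulates the structure the analysis assumes: events
snap to cytoband boundaries; each group's events are realized per sample
with a penetrance probability; purity is uniform on a configurable range
(default (0.4, 0.9) — early-stage tumors tend to be less pure, and the
templates use (0.6, 0.9)); i.i.d. Gaussian noise, default sd 0.25 on the
log2 scale, is added everywhere. Survival is exponential with log-hazard
= log(baseline) + Σ coefficients over carried regions, censored uniformly
on (0, T) for a configurable fraction. Everything is reproducible from a
single seed (PCG64). The mixture copy number is floored at 2⁻⁸ before the
log so a homozygous deletion at purity 1 stays finite, mimicking an
array's signal floor.

The default synthetic genome map gives every autosome 4 equal cytobands
per arm with 60 evenly spaced SNPs each (~10.6k loci). The density
matters: cytobands must be several times wider than the 31-SNP smoothing
window, as on a real 100K array, otherwise smoothing autocorrelation
inflates null band scores and the ±10 cutoff loses meaning. Even at this
density a null band's t-score has sd ≈ √window ≈ 6, so isolated calls at
|score| > 10 occur in roughly 10% of null sample-bands; the max-proportion
arm rule at the 50% level absorbs this.

What the generator does *not* emulate: allele-specific states, subclonal
populations beyond the two-component mixture, translocations (only their
copy-number consequence), GC/wave artifacts, probe-specific noise, or
inter-sample correlation. Passing tests therefore demonstrate
correctness of the statistical machinery and recoverability under the
stated admixture model, not performance on raw array data.

Two study templates ship with the package: a four-stage clear-cell
progression template (earliest stage: −3p, +5q, +7, −14; latest adds
−1p, +1q, −6q, −8p, +8q, −9, +12, −13, −18, +20, −22) with penetrance
0.9 — below 1 both on realism grounds and so every planted band has
within-cohort noncarriers for AUC evaluation — and a four-subtype
template (clear cell: −3p, +5q, −8p, −14q; papillary: +7, +12, +3p, +17;
chromophobe: broad whole-chromosome losses; oncocytoma: quiet) with
penetrance 1, since the signatures there are definitional for the
clustering contract. A compact survival testbed (6 chromosomes, 24
bands, 200 samples) plants a single-band gain whose carriers take an
extra 0.5 on the log-hazard.

## Numerical and design choices

- Quartiles: numpy's default linear interpolation everywhere (type 7).
- Zero-variance cases are defined, not left to propagate: smoothing and
  band t use the ±cap rule; Welch t on two zero-variance equal-mean
  groups is 0 with p 1; a constant Cox covariate returns the degenerate
  contract (0, 1, 0).
- Percent rounding: half away from zero.
- The subset fraction of the survival scan (0.8) is a package default;
  only "a fixed number" per model is prescribed by the method. With 80%
  subsets, models within a band share ~64% of samples pairwise, so a
  band's mean −log10 p is unbiased but right-skewed across bands under
  the null: the across-band mean sits at the uniform reference 1/ln 10 ≈
  0.434 (p-value calibration verified by permutation), while the
  across-band median falls somewhat below it. Interpret the scan by
  ranking, not by absolute averaged significances.
- Score-test p-values are floored at the smallest positive double before
  −log10.
- Coordinates are 0-based half-open internally (UCSC dialect); band names
  are "3p25"-style without a "chr" prefix. Chromosomes X and Y are
  excluded from every analysis; sub-bands in a banding file are kept as
  given, never merged to major bands (unless below the 2-SNP minimum).

## Problem sizes

The test suite and the acceptance script run the stage template at 40
samples per group on the default 176-band map, the subtype template at
10 per group, and the survival testbed at 200 samples with 100 models per
band — sizes chosen to match the scale of the cohorts the method targets
while keeping a full run in tens of seconds.

## Known limitations

- The ranking power of the survival scan at a carrier log-hazard of 0.5
  with 200 samples is moderate; the planted band ranks first in most but
  not all random replicates.
- Arm calls inherit the ±10 cutoff's ~10% per-band null call rate; lower
  purity ranges or sparser maps degrade the planted-set recovery.
- The pooled study table mixes detection platforms (banding, qPCR, SNP
  arrays); counts are pooled as exchangeable, with no platform
  correction or heterogeneity model.
- Smoothing windows cross the centromere (within a chromosome), so a
  strong whole-arm event bleeds slightly into the adjacent arm's
  centromeric band.
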