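# Methods

`sunpanel` re-implements, as a tested library, the population-genomic
workflow used to analyse diversity, linkage disequilibrium (LD),
breeding-pool differentiation, marker–trait associations and shared
haplotype structure in a diverse panel of inbred sunflower lines.  Because
panels of this kind are rarely deposited at desk scale, the package ships
a synthetic generator that reproduces the statistical structure every
stage assumes; all guarantees below are demonstrated on that generator.

## Data model

Genotypes are unphased biallelic SNP calls stored as alternate-allele
dosages (0/1/2, missing sentinel −1) in an accessions × markers matrix.
A genetic map assigns each marker to one of the linkage groups with a cM
position; within-group position ties are broken lexicographically by
marker id so map order is deterministic.  Panel metadata assigns each
accession a class label and a breeding pool — HA (maintainer), RHA
(restorer) or other — derived from the label by a documented prefix rule.
All statistics are frequency/dosage based; residual heterozygous calls
enter frequencies through their dosage of 1 (the treatment of residual
heterozygosity in inbred panels is a documented choice, flagged for
users, not a biological claim).

## Synthetic panel generator

The generator is a mosaic-of-founders model, not a coalescent: an elite
inbred panel's signal is shared haplotype blocks descending from a small
number of key ancestors, and founders give exactly the block structure
the graphical-genotype algorithm needs.

* **Founders and mosaics.**  Per panel, `n_founder_haplotypes` (default
  12) binary haplotypes are drawn with per-marker frequencies uniform on
  [0.1, 0.9] (array-ascertained SNPs skew common).  Founder usage is
  Zipf-skewed (weights ∝ 1/rank), mirroring the dominance of a few
  ancestral lines.  Each accession is a per-linkage-group mosaic with
  Poisson recombination breakpoints (default 3 crossovers per Morgan,
  standing in for the few breeding generations separating panel members),
  made fully homozygous before noise injection.
* **Pool divergence.**  Pool-specific target frequencies are obtained by a
  logit-scale offset with variance `pool_divergence` (default 0.5,
  calibrated once so the default panel's genome-wide multilocus F_ST is
  ≈ 0.05, the value typical of maintainer-vs-restorer sunflower pools).
  The offsets are applied at the founder-by-pool level — each pool carries
  its own flipped variant of every founder — so pools differentiate while
  within-pool haplotype sharing is preserved.  Per-cell flips would
  destroy the block structure that both the LD and painting analyses rely
  on.
* **Sweep.**  A localized sweep (default: 10–35 cM on linkage group 10,
  swept pool RHA, carrier frequency 0.95) replaces carriers' genotypes in
  the interval with the swept pool's variant of founder 0, producing the
  joint LD-spike/F_ST-spike/shared-haplotype signature of a recent
  selective sweep in one breeding pool.
* **Noise.**  Residual heterozygosity (panel mean 0.03) is concentrated
  8× in the non-elite pool, reflecting the much lower inbreeding of
  open-pollinated and introgressed material relative to elite lines;
  missing calls are injected i.i.d. at rate 0.01.
* **Phenotypes.**  Plant-level values are intercept + major-locus effect ×
  dosage + polygenic value + location effect + G×E deviation + rep and
  block-within-rep effects + plant noise.  The polygenic value is a
  dosage-weighted sum of random marker effects rescaled so that its share
  of entry-by-location-mean variance equals `polygenic_h2`; the `@sweep`
  sentinel resolves a major locus to the common (MAF ≥ 0.1) marker nearest
  the sweep midpoint, since a major-gene variant segregating between pools
  is by construction a common polymorphism.  Defaults emulate a
  branching-like trait (major sweep locus, moderate polygenic background,
  high heritability) and a flowering-time-like trait (polygenic, strong
  G×E, low heritability) scored on 4 plants × 2 reps × 3 locations.

What the generator does **not** emulate: genotype-calling error modes,
ascertainment correlation between markers, admixed pedigrees, wild
introgression segments, alpha-lattice spatial structure, or selection
acting during the simulated generations.  Passing tests therefore
demonstrate correctness of the statistical machinery under a clean
block-structured model, not robustness to every artefact of real array
data.

## Statistics

* **Diversity.**  Ho is the heterozygote fraction among called genotypes;
  unbiased gene diversity UHe = 2N/(2N−1)·(1−Σp²) with N the called
  diploids.  Sliding windows are half-open [start, start+width) intervals
  anchored at 0 cM, advancing by `step` (defaults 5 cM width, 1 cM step;
  the step and anchoring are configuration since only the width is
  standard), value = unweighted mean over member markers, empty windows
  NA.
* **LD.**  r² is the squared Pearson correlation of dosage vectors over
  pairwise-complete accessions (composite LD — identical to haplotype r²
  for fully homozygous lines, and phasing-free at ~3% heterozygosity);
  pairs with < 4 shared calls or a constant vector are NA.  Decay curves
  use a Nadaraya–Watson box kernel (half-width = bandwidth, default
  2 cM — the smoother's bandwidth is not standardized, so it is logged
  configuration).  The distance at which LD "drops below" a threshold is
  computed per focal marker — the smallest grid distance at which the
  marker's own smoothed profile falls below the threshold, censored at
  its maximum observed pair distance — and summarized per linkage group
  by mean and median.  This per-marker construction is one documented
  interpretation of a per-chromosome average crossing distance.
* **Differentiation.**  Per-SNP F_ST is Nei/Chesser-style: Hs = mean of
  the pools' unbiased expected heterozygosities, Ht = unbiased expected
  heterozygosity at the unweighted pooled-mean frequency, F_ST =
  (Ht−Hs)/Ht; negatives truncated to 0 with a logged count; a
  Weir–Cockerham θ variant is available behind a flag.  The outlier scan
  permutes pool labels; each marker's p-value is
  (1 + #{reference ≥ observed})/(1 + n_permutations) where the reference
  is, by default, the most extreme permuted F_ST within the marker's
  expected-heterozygosity stratum (10 quantile strata).  This
  Westfall–Young-style family correction makes the scan an outlier test
  against loci of comparable diversity: with hundreds of lines, two
  genuinely divergent pools make a per-marker "any differentiation" test
  flag much of the genome, which is not the question a selection scan
  asks.  The per-marker reference remains available
  (`null_reference="marker"`).  Raw (untruncated) estimates are compared
  on both sides so truncation ties cannot distort the null.
  Benjamini–Hochberg FDR across markers yields q-values; outliers are
  q ≤ 0.05 by default.
* **Structure and kinship.**  Nei's standard distance is applied between
  accessions using genotype-implied allele frequencies (0, 0.5, 1);
  pairs with zero shared identity are capped at D = 10 (logged).  PCoA is
  classical metric scaling with negative eigenvalues truncated and
  reported.  The P covariates are scores of a PCA on the centered,
  per-marker mean-imputed dosage matrix (imputation is deterministic and
  standard for structure covariates).  Kinship uses the Loiselle
  estimator as a ratio of sums over loci, with the Σ p̄(1−p̄)/(n−1)
  small-sample correction; the Ritland standardized variant sits behind a
  flag because the program conventionally used for this computation
  offers both and the source analysis does not say which was taken.
  Negative pairwise estimates are set to 0.  Q matrices (admixture
  membership fractions) are only ever read from file — admixture MCMC is
  out of scope — and one column is dropped for identifiability.
* **Phenotype analysis.**  All association inputs are produced separately
  per location (G×E is assumed).  LS-means come from a fixed-effects
  least-squares fit of entry + rep + block-within-rep solved by
  pseudoinverse, predictions averaged over the observed rep×block grid —
  a deterministic surrogate for a random-effects fit whose difference
  vanishes in balanced designs; for traits without significant design
  effects raw means are used (configurable per trait).  Broad-sense H² is
  σ²_G/(σ²_G+σ²_res) from expected mean squares of a one-way
  random-effects decomposition on entry-by-location means, after removing
  location main effects by per-location centering (a crossed
  environmental mean is neither genotypic nor residual variance; leaving
  it in deflates H² arbitrarily).  Negative component estimates truncate
  at 0.  Trait correlations are Pearson on accession-level means with
  Holm step-down adjustment.
* **Association.**  The mixed model is y = Xβ + u + e with
  u ~ N(0, σ²_g·2K) and e ~ N(0, σ²_e·I); the factor 2 converts relative
  kinship to the numerator-relationship scale (supply pre-scaled matrices
  accordingly).  Variance components are estimated once by REML on the
  null model — a grid-plus-Brent 1-D search over the variance ratio after
  a single eigendecomposition of 2K — and reused for every marker
  (population-parameters-previously-determined); per-marker re-estimation
  changes little at desk scale and costs an eigendecomposition per
  marker.  Each marker is then tested by GLS with a two-sided Wald t test
  on its dosage coefficient (missing dosages mean-imputed per marker;
  markers collinear with the design are NA with a reason).  The "naive"
  model is ordinary regression with an intercept only.  The significance
  threshold is α divided by the effective number of independent tests:
  per linkage group, the smallest k such that the top-k eigenvalues of
  the marker correlation matrix reach C = 0.995 of their sum, summed over
  groups (per-group blocks keep the correlation matrices well-conditioned
  and cheap).  q-q diagnostics report −log10 observed vs i/(m+1)
  expected quantiles and λ_GC = median χ²₁ quantile / 0.4549.
* **Graphical genotypes.**  A shared block is a maximal run of ≥ 25
  consecutive map-ordered markers (never crossing a linkage-group
  boundary) at which two accessions are both homozygous, called,
  unmasked and equal; heterozygous or missing calls terminate runs and
  are never painted.  Each of the 25 greedy cycles scores every accession
  by the mean over all *other* accessions of the fraction of their
  genome lying in blocks shared with it (mean-share; union-coverage is
  available behind a flag, and the template's own genome is excluded from
  its score), selects the top scorer as template (ties → input order),
  labels the template's entire unmasked homozygous genome plus all block
  cells shared with it (labelling only block-participating template cells
  is available behind a flag), and masks the labelled cells.  Strict
  identity is required inside blocks — a missing call breaks a run — as
  the lenient alternative is not uniquely defined.  Genome-share
  fractions per accession and label, panel averages and cumulative top-k
  coverage summarize the painting.

## Numerical choices and degenerate inputs

Frequencies, Ho, UHe and F_ST are undefined (NA) below the minimal call
counts stated above rather than extrapolated.  The REML search runs on
log-variance-ratio in [−12, 12] with a 49-point grid before bounded
refinement; estimates at the search edge are flagged, an all-zero
kinship matrix falls back to OLS, and a kinship matrix with eigenvalues
below −10⁻⁶ (relative) is rejected as not PSD.  PCoA and PCA fix sign by
making each axis's largest-magnitude loading positive.  The pipeline
derives one child seed per stage from the global seed through fixed
`SeedSequence` spawn keys, so disabling a stage never shifts another's
randomness, and reruns are hash-identical.

## Problem sizes

The test suite and the reproduction script run the full workflow on
panels of 271 accessions with 17 linkage groups at 40–150 markers per
group (680–2,550 SNPs) — the package's chosen desk scale, dense enough
for every qualitative signature (sweep localization, LD spike, outlier
enrichment, λ contrast, painting recovery) while keeping a complete run
in minutes.  The generator's study-scale default (340 markers per group,
5,780 SNPs) runs the same code unchanged.

## Known limitations

The permutation outlier scan is a surrogate for Bayesian F_ST outlier
machinery: it returns frequency-conditioned empirical p-values, not
posterior selection probabilities or Bayes factors.  LS-means treat
design effects as fixed.  H² uses a single entry-vs-residual
decomposition; multi-environment BLUPs are out of scope.  The painting
algorithm is greedy and order-dependent under score ties, exactly as
specified; it performs identity-by-state matching, not probabilistic
identity-by-descent inference.
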