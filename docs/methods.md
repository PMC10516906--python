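# Methods

This note documents the models, numerical choices and known limitations of
the package. It states nothing the test suite or the acceptance script does
not itself compute.

## βMNTD and βNTI

The between-community β-mean nearest taxon distance is the abundance-
weighted (default) or presence-weighted mean of each taxon's patristic
distance to its closest relative in the partner community, averaged over
both directions. A taxon present in both communities contributes zero (its
nearest taxon is itself), so βMNTD measures the phylogenetic depth of the
*turnover* between two samples, not their overlap.

The null model shuffles taxon labels across the tips of the phylogeny of
all observed taxa. One permutation is drawn per randomization and applied
to **every** sample pair before the next draw, which preserves the
correlation structure between pairs within a randomization; it is
implemented as a symmetric row/column permutation of the patristic matrix.
βNTI is the per-pair z-score of the observed βMNTD in this null ensemble;
values below −2 are read as homogeneous selection, above +2 as variable
selection, in between as stochastic assembly. Default 1000 randomizations
(configurable down to 100 for tests; the Monte-Carlo SE of the null mean
falls with 1/√n_rand and is checked against exhaustive permutation
enumeration in the test suite).

A pair whose null distribution has zero spread (e.g. two taxa, or two
samples with identical support) gets βNTI = NaN and class `undefined`
rather than ±∞; exporting such a result set to a score matrix is an error,
because a silent NaN would propagate into downstream Mantel statistics.

### What the power simulations established

Three properties of the statistic shaped the synthetic worlds (all
reproduced by the test suite):

1. **Occupancy contrast.** If most observed taxa are present in most
   samples, both observed and null nearest-taxon distances collapse toward
   zero and βNTI loses all power. Detectable selection needs per-sample
   richness well below the observed pool size (hundreds of taxa per sample
   against a pool of thousands in real OTU tables).
2. **Clade fidelity of the niche trait.** Under plain Brownian motion on a
   Yule tree roughly half the trait variance accrues on terminal branches,
   so taxa with similar traits sit in many different clades and a Gaussian
   filter on the trait does not phylogenetically cluster the community.
   The default trait model is therefore early-burst Brownian motion (the
   evolutionary rate decays e-fold × 8 from root to tip; `trait_decay=0`
   recovers plain BM), which makes the trait a deep-clade marker.
3. **Drift and immigration.** With one shared optimum and no drift, every
   sample draws the same filtered support: turnover is carried only by
   anti-selected rare taxa and βNTI is non-negative or undefined. The
   selection regimes therefore add ecological drift — per-sample Bernoulli
   local extinction (`occupancy`, default 0.5) and lognormal abundance
   jitter (`drift_sigma`, default 1.0) — plus a small immigration floor
   (`immigration`, default 0.003) inside the filter so that off-optimum
   taxa remain observable at low abundance. Without the floor the observed
   pool itself is clade-restricted and a tip shuffle restricted to observed
   taxa cannot detect the filter at all.

## Synthetic worlds

`simulate_tree` is a true pure-birth (Yule) process: exponential waiting
times at rate (lineages × birth_rate), all pendant edges extended by each
wait, a final stretch after the last split so no branch length is zero.

`simulate_communities` regimes:

* `neutral` — every sample is an independent multinomial draw at the given
  depth from one shared log-normal metacommunity frequency vector
  (σ_log default 1.5). This is the calibration world: abundances carry no
  phylogenetic information, so βNTI should stay inside ±2 for ~95% of
  pairs (the suite asserts ≤ 10% outside at 60 taxa × 10 samples ×
  depth 2000 over 20 seeds).
* `homogeneous_selection` — Gaussian filter exp(−(trait−opt)²/2σ²) with a
  single shared optimum at +1 trait sd (traits z-scored), σ =
  `selection_strength` (default 0.3), plus drift and immigration as above.
* `variable_selection` — the same machinery with `n_blocks` sample blocks
  whose optima sit at ±max(2σ, 1), guaranteeing ≥ 4σ separation.

Power worlds in the acceptance tests use 2000 taxa, 10 samples, depth
3000, σ = 0.3 and metacommunity σ_log = 1.0; at this scale the pooled
median βNTI is ≈ −3 for homogeneous and strongly positive for variable
selection. Magnitude grows with pool size (≈ −1.9 at 1000 taxa, ≈ −3.4 at
3000), which is why desk-scale worlds below ~500 taxa cannot demonstrate
the homogeneous regime even though the statistic is correct — a green
power test establishes the classifier's behaviour at realistic OTU
richness, not at toy sizes.

`simulate_cooccurrence` plants modules through latent Gaussian factors:
log-abundance = baseline + log_sigma·(√ρ·module factor + noise), with
noise sd √(1−ρ) so the within-module log correlation is exactly ρ and the
between-module correlation 0. The default `log_sigma = 0.5` keeps the
exponentiation near-linear so the Pearson correlation of the counts
themselves also tracks ρ.

`simulate_feature_table` draws log-normal features and shifts a flagged
20% subset down (or up) by `effect_size` log-scale standard deviations in
the non-reference groups, returning the truth list for FDR scoring.

What the generators do **not** emulate: sequencing error, chimeras,
compositional library-size artifacts beyond fixed-depth multinomial
sampling, taxonomic structure in names, or phylogenetic signal in the
metacommunity abundances themselves. Green tests therefore establish the
statistics' behaviour under their own model assumptions, not robustness to
real-data artifacts.

## RMT threshold selection

At each grid threshold s (default 0.30–0.95, step 0.01) the correlation
matrix is hard-thresholded (|r| < s zeroed, diagonal kept), rows without
any remaining off-diagonal connection are dropped, and the spectrum of the
remaining symmetric matrix is computed. Unfolding fits a cubic
least-squares spline (15 interior knots at uniform quantiles, reduced
automatically when Schoenberg–Whitney conditions fail) to the empirical
cumulative eigenvalue count; exact duplicate eigenvalues are collapsed
first, since repeated values carry no spacing information. The unfolded
spacings (mean 1 within 5%, asserted) are binned at width 0.1 on [0, 3]
plus an open tail bin and compared by chi-square statistics against the
Poisson and GOE forms.

The per-threshold decision defaults to the **relative** rule — Poisson
fits better than GOE (χ²_Poisson < χ²_GOE) — with persistence required at
≥ 80% of all larger grid values that still yield ≥ 20 eigenvalues. Two
empirical findings forced this design (an absolute rule, p > 0.05 against
Poisson at every larger threshold, is also available via
`criterion="absolute"`): first, even genuinely Poisson spacings fail a 5%
test ~5–7% of the time, so demanding every point of a ~60-value grid tail
pass makes the scan fail by chance alone; second, near-empty networks at
extreme thresholds fragment into near-degenerate dyads and triads whose
spacing distribution is *more* clustered than Poisson (p ≈ 0), which is an
artifact of the regime where the NNSD stops being meaningful, not evidence
against a threshold. A matrix of independent taxa never reaches sustained
Poisson preference and raises an explicit no-structure error.

Known caveat: the default `log_relative` transform (log10 relative
abundance, zeros replaced by 0.01 × the smallest nonzero relative
abundance) introduces compositional coupling — every taxon shares the
−log(total) term — which inflates between-module correlations on strongly
structured tables. Module-recovery validation therefore correlates raw
counts (`transform="none"`); on real tables, where no single module
dominates the total, the compositional term is much weaker.

## Supporting statistics

* Rarefaction is a single multivariate hypergeometric draw per sample
  (without replacement); samples below the target depth are dropped with a
  warning, and an all-dropped table is an error.
* NMDS minimises Kruskal stress-1 by majorization with isotonic regression
  (scikit-learn backend), 20 random restarts, eps 1e-7; coordinates are
  column-centered.
* PERMANOVA and the Mantel test use Anderson's pseudo-F and the
  permutation schemes of scikit-bio; both use the (1 + count)/(1 + n_perm)
  p-value estimator, so p = 0 cannot occur. Note the p-value floor
  1/(n_perm+1) is reachable only when the number of distinct group
  partitions is much larger than n_perm: with two equal groups of six, the
  mirrored partition reproduces the observed F exactly and the minimum
  attainable p is 2/(n_perm+1).
* The Wilcoxon screen uses the exact rank-sum distribution for combined
  n ≤ 12 without ties, otherwise the tie-corrected normal approximation;
  multiplicity is controlled by Benjamini–Hochberg across all features of
  one screen. Direction defaults to one-sided *decrease* against the
  reference group. Constant features get p = 1 and a flag.
* Tukey HSD letters come from the insertion algorithm: start with one
  letter covering all groups, split the cover for each significantly
  different pair, absorb redundant subsets. The property suite checks that
  differing pairs never share a letter and non-differing pairs always do.
* RPKM = count / ((length/1000) × (total_mapped/10⁶)); Z-scores use the
  n−1 standard deviation and refuse constant features.

## Pipeline

`run_all` validates the whole config before any stage executes (a missing
tree with the assembly stage enabled fails fast), derives per-stage seeds
as `global_seed XOR crc32(stage_name) mod 2³¹`, and writes a manifest with
every parameter left open by convention (weighting, correction method,
threshold rule) plus sha256 checksums of all outputs. Stages communicate
only through files and returned objects; nothing mutates another stage's
inputs.

## Limitations

* Raup–Crick (RC_bray) partitioning of the stochastic fraction into
  dispersal processes is not implemented; the classifier stops at βNTI.
* UniFrac, CCA/RDA and plotting are out of scope; coordinates and graphs
  are exported for external tools (e.g. Gephi).
* The homogeneous-selection power margin is intrinsically scale-dependent
  (see above); worlds below ~500 taxa will not show median βNTI < −2.
* The NNSD chi-square uses fixed binning for determinism; with fewer than
  ~40 spacings its absolute p-values are noisy, which is why the threshold
  scan's default decision is relative.
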