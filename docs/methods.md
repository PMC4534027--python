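# Methods

## The reproducibility model

All reproducibility statements in this package reduce to the one-way
random-effects decomposition of a per-sample metric y measured on k
technical replicates of each of G subjects:

    y_ij = mu + b_i + e_ij,    b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_e^2)

The intraclass correlation ICC = sigma_b^2 / (sigma_b^2 + sigma_e^2) is the
fraction of total variance that is stable between-subject signal.  The
estimator is the ANOVA-moment (Searle) form: with between/within mean
squares MSB and MSW,

    ICC_hat     = (MSB - MSW) / (MSB + (k - 1) MSW)
    sigma_e^2_hat = MSW
    sigma_b^2_hat = max(0, (MSB - MSW) / k)

with the unbalanced-design effective group size
k = (N - sum n_g^2 / N) / (G - 1).  The moment estimator was chosen over
REML deliberately: it is closed-form, exactly reproducible, and is the
estimator implemented by the standard R "ICC" package, so cross-language
checks are straightforward.  The raw estimate can leave [0, 1] in small
samples; reports clamp it (`icc_report`) but the raw value is always
retained, and the truncation applies only to the variance-component field,
never to the statistic used in permutation comparisons.

Assumptions worth stating: replicates are exchangeable within subject;
variances are homogeneous across subjects; the metric is approximately
interval-scaled.  Compositional metrics (phylum relative abundances) and
bounded ordination scores violate Gaussianity mildly; the ICC remains a
well-defined variance ratio, and its permutation test does not rely on
normality.

### Permutation inference

* **ICC = 0.** All values in a stratum are shuffled across subjects
  (group sizes preserved); p = (1 + #{perm ICC >= observed}) / (n_perm + 1).
  This is exact-level by construction (the add-one smoothing makes the
  smallest attainable p equal to 1/(n_perm + 1)).  Default n_perm = 999.
* **ICC_a vs ICC_b across media.** The statistic is |ICC_a - ICC_b|; the
  null swaps, per subject independently with probability 1/2, the subject's
  entire replicate set between the two conditions.  This preserves the
  within-subject correlation structure while making condition labels
  exchangeable.  Other schemes are defensible; this one is isolated in
  `icc_difference_test` so it can be swapped wholesale.
* Simulation checks (in the test suite and `scripts/acceptance.py`): the
  null rejection rate at alpha = 0.05 sits at the nominal level, and mean
  ICC estimates over 500 simulated 10-subject x 3-replicate studies land
  within a few hundredths of true ICCs 0.8 / 0.5 / 0.2 (the moment
  estimator has a small O(1/G) downward bias, visible as ~0.02-0.04 at
  ICC = 0.5 with G = 10).

### Temporal stability

For each medium and delay t in {3, 7} days, technical replicates are first
averaged per subject at day t and day 0 separately; each subject then
contributes a 2-value group (average at t, average at 0) and the same
one-way ICC is computed (k = 2).  High values mean the between-subject
ordering survives the freezing delay.

### Other statistics

* **Paired t-tests** (scipy) compare per-subject replicate-averaged phylum
  abundances between no-media and each medium; deliberately uncorrected
  for multiple comparisons (four phyla are few, and the analysis is
  descriptive).  Zero-variance differences degenerate to p = 1 (zero mean
  difference) or p = 0 (constant nonzero shift).
* **Abundance-ICC trend**: OLS of per-taxon ICC on ln(mean relative
  abundance), restricted to taxa whose *median* relative abundance in the
  stratum is at least 0.1% (the floor and the regressor intentionally use
  different summaries: the median floor is robust to single blow-ups, the
  mean regressor reflects the abundance actually driving counting noise).

## Diversity metrics

* **Rarefaction**: each sample is subsampled *without replacement* to a
  fixed depth (default 5000 reads), 20 independent draws, and the metric is
  averaged across draws.  Draws follow the multivariate hypergeometric law
  exactly (numpy's generator).  Samples under depth are excluded with a
  logged warning, never silently subsampled shallower.  The RNG substream
  is keyed by (master seed, CRC32 of sample id, draw index), so a sample's
  values do not depend on table ordering.
* **Observed species / Chao1 / Shannon**: standard forms; Chao1 is the
  bias-corrected estimator S + F1(F1-1)/(2(F2+1)) with singleton/doubleton
  counts taken *after* rarefaction; Shannon uses natural log.
* **Faith's PD** is root-inclusive by default (the subtree connecting the
  present leaves *and the root*), the convention of the QIIME-1 era
  pipelines this analysis models; `include_root=False` (CLI
  `--pd-no-root`) gives the MRCA-subtree variant.
* **UniFrac**: the tree is pruned to the count table's OTU set (collapsed
  paths keep their summed lengths) and flattened to per-edge arrays; a
  single post-order pass gives each sample's presence/abundance flow
  through every edge, and all pairwise distances follow by matrix algebra.
  Weighted UniFrac is the **raw** form, sum_e b_e |P_A(e) - P_B(e)|
  (optionally normalized by its maximum); unweighted is unique/total
  branch length.  Beta diversity uses a *single* rarefaction per sample at
  the same default depth as alpha (one draw, fixed substream) rather than
  a 20-draw average — distances are pairwise and a fresh draw per pair
  would break the metric property; `depth=None` computes on full counts.
* **PCoA**: Gower double-centering of squared distances, dense symmetric
  eigendecomposition.  Negative eigenvalues (non-Euclidean input) are
  dropped, not Lingoes/Cailliez-corrected, and logged;
  proportion-explained is relative to the positive spectrum.  Axis signs
  are fixed by making the largest-|coordinate| sample positive, so runs
  are byte-reproducible.  The study ordination is computed once over all
  samples jointly and strata are sliced from the shared axes — stratum ICCs
  of PCoA scores are therefore comparable across columns.
* **Distance R²**: the one-factor PERMANOVA decomposition
  ss_total = (1/N) sum_{i<j} d_ij^2, ss_within = sum_g (1/n_g)
  sum_{i<j in g} d_ij^2, R² = 1 - ss_within/ss_total.  Singleton groups
  contribute zero within-SS.

## The synthetic study generator

The generator stands in for the unavailable raw sequencing data.  It emits
the reference design exactly — per subject, 3 no-media aliquots at day 0
and 3 replicates x {0, 3, 7} days for each of three RNAlater-based media
(30 samples/subject; default 10 subjects) — with a known variance
structure:

1. **Template**: OTU weights follow a power law (Zipf exponent 1.5) within
   each phylum, rescaled so expected phylum totals match the targets
   (Firmicutes 75.1%, Bacteroidetes 14.6%, Actinobacteria 2.1%,
   Proteobacteria 0.6%, remainder "other"); roughly half the OTUs fall
   below 0.1% relative abundance, which is what makes the abundance-ICC
   trend analysis non-trivial.
2. **Subject effect**: + N(0, sigma_b2) per OTU on the log scale
   (default sigma_b2 = 1.0).
3. **Medium effect**: per-phylum log fold-changes; default: no-media
   depletes Bacteroidetes by 1.6 log-units and Proteobacteria by 0.6,
   with the compensatory rise of other phyla arising from renormalization.
4. **Incubation drift**: + N(0, drift_rate^2 * days) per OTU per aliquot
   (Brownian in time); defaults 0.10 / 0.25 / 0.25 per sqrt(day) for
   RNAlater / +kanamycin / +ciprofloxacin — the antibiotic media are made
   *less* stable, the direction the downstream analysis should detect.
5. **Replicate noise**: + N(0, sigma_e2) per OTU (default 0.05, i.e. a
   latent Gaussian ICC of 1.0/1.05 ≈ 0.95, matching the high day-0
   reproducibility regime the analysis targets).  `rare_noise_scale`
   optionally inflates the noise s.d. of taxa below 1% by that many units
   per decade of rarity, for experiments that need an abundance-dependent
   noise floor.
6. **Counts**: softmax to a composition, multinomial at fixed depth
   (default 20 000 reads).

Because steps 2 and 5 act on the same log scale, the latent
(infinite-depth) ICC of any log-abundance trait is exactly
sigma_b2/(sigma_b2 + sigma_e2) — `GroundTruth.true_gaussian_icc` — which is
what the parameter-recovery tests exploit.  Magnitudes of the medium and
drift effects are illustrative (chosen for direction, not to match any
printed table).  Every random draw is keyed by a master seed with
per-sample substreams derived from (subject, medium, time, replicate), so
outputs are byte-identical under a fixed seed and adding subjects does not
reshuffle existing samples.

What the generator does **not** emulate: sequencing error and chimeras,
PCR amplification bias, overdispersion beyond the log-normal hierarchy
(no explicit Dirichlet-multinomial extra-variance), taxon-taxon
interactions, and phylogenetic signal in abundances (tree topology is
independent of the abundance template).  Passing tests therefore show the
*statistics* behave correctly under a controlled hierarchy, not that any
particular real dataset will reach the same ICC values.

## Numerical and design choices

* All-identical values in a group structure make the ICC degenerate; it is
  reported as 1 with a `degenerate` flag rather than 0/0.
* Permutation counts use a >= comparison with a 1e-12 tolerance so exact
  ties (fully degenerate data) count as extreme.
* Zero-total count rows cannot be normalized; they stay all-zero and are
  flagged, and downstream stages drop them via the NaN/exclusion path.
* Count-table orientation: OTUs-in-rows is the on-disk default (the common
  amplicon convention); the in-memory model is always samples x OTUs.
* Unknown taxonomy maps to "other" instead of erroring, so partial maps
  (only the 4 major phyla) work.
* Strata that lose samples (under-depth exclusion, missing subjects) still
  report an ICC when at least 2 subjects keep at least 2 replicates;
  otherwise the cell is NA and the reason is logged.
* Validation problem sizes: 500 simulations for estimator recovery, 200 x
  199 permutations for test calibration, 100 random trees (<= 16 leaves)
  for the UniFrac oracle, and 50 full synthetic studies per directional
  experiment — sizes at which Monte-Carlo error is well inside the asserted
  tolerances while the whole suite stays interactive.

## Known limitations

* Only the one-way (agreement-free) ICC is implemented; two-way forms
  (ICC(2,1)/ICC(3,1)) and Fisher-transform confidence intervals are out of
  scope.
* Beta diversity covers UniFrac only (no Bray-Curtis/Jaccard/generalized
  UniFrac).
* The ICC-difference permutation scheme is one defensible choice among
  several; its operating characteristics are checked by simulation but no
  optimality is claimed.
* The temporal R² compares pooled day-{0,t} samples by subject; it does not
  isolate the time effect from replicate noise the way the paired temporal
  ICC does.
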