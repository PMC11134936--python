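# Methods

This note documents the statistical models, numerical choices and
limitations behind `nestniche`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Isotopic-niche model

Specimens carry (δ¹³C, δ¹⁵N) coordinates in ‰. All nest-level statistics
are built on *nest centroids*: the per-(nest, group) mean of specimen
coordinates. Species- or lifestyle-level summaries are **unweighted means
of nest centroids** with SEs over nest means, never over pooled
individuals — a nest sampled heavily must not dominate the species mean.
With one specimen per nest the centroid is the specimen and its SE is
undefined (NaN).

### Distance ratio

For every nest holding both a focal group (e.g. host-specialized
silverfish) and host ants, `within_between_ratio` compares the focal
centroid with its own nest's host centroid (d_within) and with the host
centroids of all other eligible nests (d_between, averaged). The reported
statistic is **ratio = d_between / d_within**, so convergence on the host
colony yields values above 1. The opposite orientation is just the
reciprocal; we fix this one so that "larger = more convergent".
Degenerate nests with d_within = 0 (focal and host centroids coincide
exactly) would produce infinite ratios; they are kept in the per-nest
table, flagged, counted, and excluded from the mean/SE summary. An
optional host-taxon restriction limits between-nest comparisons to nests
whose host genus matches the focal nest's host.

The statistic is invariant under rigid rotation and translation of the
whole biplot (it is built from Euclidean distances only); the test suite
checks this property directly.

### 95% ellipses and overlap

Ellipses are maximum-likelihood bivariate-normal coverage regions:
centre = sample mean, shape = unbiased (n−1) sample covariance Σ, boundary
at Mahalanobis radius c = √χ²ₚ(2) with p = 0.95 by default, area
π·χ²ₚ(2)·√det Σ. The small-sample-corrected variant (covariance rescaled
by (n−1)/(n−2)) is exposed as an option but is not the default, matching
the "approximately 95% of the data" reading of the coverage ellipse.
Fewer than 3 points, or a singular covariance (collinear points), is an
error rather than a silent fallback.

Overlap between two ellipses is computed by discretising each boundary
into an n-vertex polygon (default 360) and intersecting the polygons
(shapely). Percent overlap follows a named convention — `union`
(intersection over union; symmetric and bounded, the default), `min`, or
`first` — because field usage varies and the convention is rarely stated.
Polygon areas (not analytic ellipse areas) are used in the denominators so
identical ellipses give exactly 100%. At 360 vertices the error against
the closed-form circular-lens area is below 10⁻³ for unit-scale ellipses,
and accuracy improves monotonically with the vertex count; both facts are
asserted in the tests.

## Sequential PERMANOVA

Given an n×n distance matrix D, the Gower-centred inner-product matrix is
G = J(−½ D∘D)J with J = I − 11ᵀ/n, and SS_total = tr G. For ordered terms
(categorical factors or two-factor interactions, dummy-coded with an
intercept), cumulative design matrices X₁ ⊂ X₂ ⊂ … give orthogonal
projectors H_k (via SVD with a rank tolerance of 10⁻⁸ times the largest
singular value); term k is charged SS_k = tr((H_k − H_{k−1})G) — the
sequential (Type I) convention of the R community-ecology default — with
df_k the rank increment, pseudo-F_k = (SS_k/df_k)/(SS_res/df_res), and
R²_k = SS_k/SS_total. SS additivity (ΣSS + SS_res = SS_total) holds by
construction and is verified to 10⁻⁸ on random inputs; any negative SS
beyond −10⁻⁸·SS_total raises an error as a numerical fault.

Significance uses free permutation of sample labels (equivalently PGPᵀ):

- when n! ≤ n_permutations + 1, the whole permutation group is enumerated
  and p is the exact tail probability (ties counted as ≥, conservative);
- otherwise n_permutations seeded draws are taken and
  p = (1 + #{F* ≥ F}) / (1 + n_permutations), the "observed counts as one
  permutation" convention. Because term order matters under sequential SS,
  the pipelines run and report **both** candidate orders
  (taxon → nest → interaction and nest → taxon → interaction).

Pairwise post hoc comparisons run a one-term PERMANOVA per level pair on
the corresponding sub-matrix and adjust p-values with Benjamini–Hochberg
(statsmodels). Restricted/stratified permutation schemes, marginal
(Type III) tests and dispersion tests are out of scope.

The implementation is validated against three independent oracles: the
classical ANOVA sum-of-squares identity on 1-D data (R² = 100/101 on
{0,1,10,11} with balanced groups), brute-force enumeration of all 720
permutations at n = 6, and scikit-bio's single-factor pseudo-F. A null
simulation (labels independent of the data, 500 replicates of n = 20 with
199 permutations) checks that the rejection rate at α = 0.05 stays within
3 binomial SEs of 0.05.

## Microbiome post-processing

The chain is fixed and auditable: relative abundance → decontamination →
symbiotic designation → endosymbiont subtraction → {density | curation →
composition / strain profiles}. Every filtering step can emit an audit
table listing each zOTU's statistics and decision.

- **Relative abundance**: per-sample proportions excluding the spike-in
  from the denominator (it is a quantification standard, not community).
  The exclusion basis is recorded. Anaplasmataceae reads *are* included at
  this stage; they are only subtracted later for density and composition.
- **Decontamination (tenfold rule)**: a zOTU is retained iff its maximum
  relative abundance across experimental samples is ≥ 10× (configurable)
  its maximum across blanks; zOTUs absent from every blank are always
  retained. Running without blanks is an explicit error, not a silent
  pass. Retention is monotone in the fold factor.
- **Symbiotic designation**: maximum experimental relative abundance
  strictly greater than 0.001 ("higher than" is read strictly; a zOTU at
  exactly 0.001 is not symbiotic).
- **Spike-in density**: density = ((symbiotic reads − subtracted-family
  reads)/spike reads) × spike_copies / template_ng, in 16S rRNA copies per
  ng template DNA, with spike_copies defaulting to 1000. "Symbiotic reads"
  are all non-spike, non-subtracted reads of the designated set; samples
  with zero spike reads are flagged undefined rather than dropped
  silently. Per-sample template mass is a required metadata column — it is
  rarely published, so the simulator records it explicitly.
- **Curation**: mean read count ≥ 20 (inclusive — "threshold of 20" is
  read as attainable at the boundary) AND standard deviation strictly
  above the 10% quantile of the SD distribution of the zOTUs that passed
  the mean filter. "Minimum variance threshold of 10% (based on the
  standard deviation)" admits several readings; dropping the lowest SD
  decile *after* the mean filter is the implemented one, with both the
  fraction and the stage configurable.
- **Composition**: counts aggregate to bacterial order; orders are ranked
  by summed relative abundance across the analysis samples with
  "unassigned"/"Other" never rankable; the top 9 are kept and the rest
  folded into "Other"; rows are proportions summing to 1; nest-lifestyle
  averaging (one row per group) avoids pseudo-replication before the
  lifestyle PERMANOVA.
- **Strain profiles**: binary presence/absence over the flagged target
  (Weissella) zOTUs retained after curation, present at ≥ 1 read by
  default (no detection floor is standard; the threshold is exposed).
  Samples with no detected strain are dropped from the Jaccard analysis
  (an all-zero row has no defined Jaccard distance) and counted in the
  report.

## Synthetic-data generator

The generator's defaults encode the study design the analyses expect:

- **Isotopes**: 12 nests, 6 host workers and 4 silverfish per nest.
  Nest baselines ~ N(−26, 0.6²) ‰ for δ¹³C and N(5.5, 1.5²) ‰ for δ¹⁵N —
  a strong between-colony spread in trophic position over a compact
  carbon range, as seen in granivorous-ant systems; individual noise
  0.4/0.5 ‰; taxon offset (0, 0) is the convergent scenario. Gaussian
  noise is the minimal model; nothing in the downstream statistics
  assumes it.
- **Amplicons**: 12 nests (6 hosting Messor-specialized silverfish, 3
  Aphaenogaster-specialized, 3 obligate generalist), 2 ants + 3 silverfish
  sequenced per nest, 9 blanks (emulating six extraction + three PCR
  blanks). Every reaction receives 1000 spike copies with an expected
  spike read yield of 1000 (per-sample read yield lognormal, σ = 0.3,
  cancelled exactly by the density estimator). Symbiont copy numbers are
  gamma-distributed given presence and reads Poisson given copies, i.e.
  negative-binomial reads; presence is Bernoulli with lifestyle-
  conditional prevalence (e.g. the unplaced Lactobacillales symbiont at
  0.77 in Messor-specialized silverfish vs 0.07 in ants; intracellular
  Anaplasmataceae at 0.36 overall). A ubiquitous unassigned background
  zOTU guarantees every specimen a non-empty microbiome. Each Messor nest
  draws 6 of 18 Weissella strains; all its ants and silverfish share that
  pool minus a 5% per-strain false-negative rate.
- **Contaminants** occupy blanks at stated proportional levels and leak
  into experimental samples at 0.2× their blank relative abundance.
  Because blanks contain essentially nothing but contaminants, blank
  relative abundances renormalise to large proportions, so a leakage
  factor ≥ 1 on the RA scale is arithmetically impossible; 0.2× is a
  realistic low-level carry-over and sits far below the tenfold retention
  bar, so the rule removes every injected contaminant by construction.
  The factor is configurable to create retention cases.
- All randomness flows from the single config seed through one NumPy
  generator; identical configs give byte-identical tables.

What the generator does **not** emulate: sequencing error, chimeras and
denoising artefacts (the pipeline starts from a finished zOTU table),
compositional coupling between taxa (reads are independent given copies),
cross-talk of real taxa into blanks, spatial/temporal baseline gradients
in the isotope data, and unbalanced per-nest sampling. Tests passing on
synthetic data therefore demonstrate the correctness of the computations
and the recoverability of the encoded effects — not robustness to every
artefact of real amplicon or isotope data.

## Problem sizes

The default test and acceptance runs use the design above (60
experimental samples + 9 blanks; 120 isotope specimens), 999 permutations
for reported p-values (199 inside the null-calibration loop), 10⁵ draws
for Monte-Carlo ellipse coverage, and 200 samples for density-recovery
checks — sizes chosen to keep every run comfortably reproducible on a
single CPU while leaving the binomial/Monte-Carlo error well inside the
asserted tolerances.

## Known limitations

- Sequential SS makes reported R² order-dependent; both orders are
  reported but users must still choose which to quote.
- The exhaustive permutation path enumerates n! relabellings and is only
  engaged for tiny n; for n around 7–8 with a large requested
  permutation count it can be slower than sampling.
- Ellipse overlap is polygonal, not analytic; at the default 360 vertices
  the error is negligible for realistic aspect ratios but grows for
  extremely eccentric ellipses.
- Density estimates inherit the spike-in's assumptions: equal
  amplification efficiency of spike and community templates and accurate
  template-mass measurements; neither is checked internally.
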