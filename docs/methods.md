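# Methods

This note documents the models, estimators and numerical choices behind
`landgen`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Sequence diversity and neutrality statistics

An alignment is reduced by *complete deletion*: any column containing a
gap, `N` or another non-`ACGT` character is removed before anything is
counted (this mirrors the default of the standard desktop software for
these statistics).  Pairwise deletion is available and affects only the
per-site nucleotide diversity; haplotype identity and all count-based
statistics always use the complete-deletion matrix, because mixing
deletion schemes inside one statistic makes S, η and π mutually
inconsistent.

* Haplotype diversity: Hd = n/(n−1)·(1 − Σ p_h²) over haplotype
  frequencies.  The effective haplotype number 1/Σ p_h² is the count of
  equally frequent haplotypes that would produce the same diversity;
  evenness divides it by the observed haplotype count, so evenness = 1
  means all haplotypes equally frequent.
* π is reported per site (mean pairwise proportion of differing sites)
  and the mean pairwise difference count k is exposed separately, since
  per-site and per-sequence magnitudes are both used in field tables
  and confusing the two is a classic reading error.
* Watterson's θ = S / a_n per locus, a_n = Σ_{i<n} 1/i.
* Tajima's D uses the 1989 constants; it is an explicit error (not 0)
  at S = 0.
* Fu & Li's D* and F* are the no-outgroup "star" statistics.  Mutations
  are counted per column as (number of alleles − 1); singleton
  mutations as alleles carried by exactly one sequence, capped at the
  column's mutation count.  The variance constants are the corrected
  forms in common use (the originally printed formulas contain typos);
  the test suite pins them against an independently written oracle and
  against neutral-coalescent calibration (mean ≈ 0).
* Fu's Fs: S′ = P(K ≥ k_obs | θ = k) under the Ewens sampling
  distribution, computed with a log-space unsigned-Stirling recursion
  (the test oracle rebuilds the same probabilities by polynomial
  expansion of the rising factorial), and Fs = ln(S′/(1−S′)).
* No p-values are attached to the neutrality tests.  The desktop tools
  attach significance from coalescent beta approximations; that is a
  simulation exercise the user can run with `simulate_haplotypes`.

## Statistical-parsimony networks

Haplotypes collapse by exact string equality after complete deletion;
ordering is deterministic and input-order invariant (count descending,
then lexicographic).

The *connection limit* is the largest mutational distance j at which
two haplotypes differing at j of m sites are, with the stated
confidence, separated by exactly j mutations.  The probability is
derived here from a two-state per-site Poisson model: given a per-site
difference probability q, the expected per-site hit count is
λ = −ln(1−2q)/2; a differing site carries exactly one hit with
probability λe^(−λ)/q and a matching site zero hits with probability
e^(−λ)/(1−q); q is integrated over its Beta(j+1, m−j+1) posterior
(uniform prior) truncated to [0, ½), by trapezoidal quadrature on a
log-scaled integrand.  This reproduces the qualitative behaviour of the
classic TCS limit (non-decreasing in m, ~1–2% of sites at 95%) but is
an independent derivation, typically a little more conservative than
TCS 1.21 (463 bp → 5 steps here).  Single steps are always trusted, so
the limit is at least 1.

The network itself is a deterministic minimum-spanning network: pairs
are connected in increasing mutational distance, and within one
distance level every pair joining components that were distinct at the
level's start is added, so alternative equal-length connections remain
as loops.  TCS's partially undocumented loop-breaking heuristics are
deliberately not imitated; the connection limit is the inferential
content.  Multi-step edges optionally expand into chains of unlabeled
intermediate nodes (both renderings are supported because published
figures are ambiguous on this point).

## Microsatellites

Expected heterozygosity uses Nei's unbiased estimator
(2n/(2n−1))(1 − Σp²); Fis = 1 − Ho/He, undefined for monomorphic
samples.  The Hardy–Weinberg test conditions on allele counts
(Levene's distribution) and sums the probability of tables no more
probable than the observed one: full enumeration for two alleles (any
n) or on request, and a seeded Monte-Carlo permutation of the allele
vector otherwise (default 10,000 shuffles; the seed is a parameter and
is reported).  Full enumeration over ≥3-allele tables grows
combinatorially and is only practical for small samples, which is why
Monte-Carlo is the multi-allelic default.

Pairwise Hedrick's G′ST uses the Nei & Chesser small-sample estimators
of HS and HT per locus (harmonic-mean sample size, observed-
heterozygosity correction), averages HS and HT across loci first, then
takes GST = (HT − HS)/HT and standardizes by GST_max =
(k−1)(1−HS)/(k−1+HS) with k = 2.  Because the unbiased estimators can
dip slightly negative for identical populations, estimates are
truncated into [0, 1]; an all-monomorphic pair is 0 by convention with
a warning.  Pairs with fewer than five typed individuals on a side are
flagged in the matrix metadata rather than suppressed — small samples
were a fact of the study design, not a reason to drop sites.

DAPC encodes individuals as per-allele count vectors (0/1/2), imputes
missing entries by the column mean, centers and scales, runs PCA and
then LDA on the retained components.  The LDA uses the eigen solver
with an empirical covariance carrying a vanishing relative ridge
(1e−12), which keeps the generalized eigenproblem well posed when a
group is clonal; the ridge is orders of magnitude below the numerical
tolerances used anywhere else.  `n_pca` must not exceed the rank of the
centered matrix and `n_da ≤ groups − 1`.  Group labels are
user-supplied (in the motivating study they came from a Bayesian
clustering tool, which is intentionally out of scope).

## Landscape model

* Terrain ruggedness index: mean absolute elevation difference to the
  up-to-8 valid neighbours (edge cells use the neighbours they have);
  the root-sum-of-squares variant is available behind a flag.
* Aggregation: block mean with factor floor(target/cellsize), nodata
  propagating when a block is more than half masked, then bilinear
  resampling if the target is not an integer multiple.
* Monomolecular transforms: input min–max scaled to [0, 1]; base curve
  g(x) = (1 − e^(−x/s)) / (1 − e^(−1/s)); reverse flips the input,
  inverse flips the output; output clipped to [1, m].  Min–max scaling
  (rather than z-scaling) is fixed so that shape and magnitude have a
  stable meaning across rasters.
* Movement is 4-neighbour.  Least-cost edge weight:
  cellsize·(r_i + r_j)/2 (Dijkstra on the sparse grid graph).  Commute
  distance: edge conductance (2/(r_i + r_j))/cellsize, commute =
  volume × effective resistance, with effective resistances from sparse
  LU solves against the grounded Laplacian.  Note that uniformly
  rescaling all resistances leaves commute distances unchanged (volume
  and effective resistance scale inversely), while least-cost distances
  scale linearly — both behaviours are pinned by tests.
* Geographic distances are haversine great circles (R = 6371.0088 km).
  Synthetic grids without lon/lat use straight-line distances between
  cell centres as the geographic stand-in.
* Sites snap to the nearest valid cell; two sites in one cell is an
  error (at coarse grids that would alias distinct populations).
* Raster I/O is the plain-text ESRI ASCII grid; values are
  georeferenced by origin and cellsize and are expected in projected
  coordinates before graph construction.

## MLPE mixed model and model selection

Pairwise differentiation is modelled as
y_ij = β0 + β1·z(x_ij) + u_i + u_j + ε_ij with u ~ N(0, σu²) per
population and ε ~ N(0, σe²) per pair; z is the centered/scaled
predictor so that β1 is per SD of distance and the transform's
magnitude is not confounded with the slope.  The marginal covariance is
σu²·ZZ′ + σe²·I with Z the pair-population incidence matrix.

Fitting is maximum likelihood throughout, never REML: AICc comparisons
across different fixed-effect structures are only valid under ML.  The
likelihood is profiled over λ = σu²/σe² (bounded scalar search on
log λ, plus the λ = 0 boundary).  For a complete pairwise design, Z′Z =
(n−2)I + J has a closed-form inverse and ZZ′ a known spectrum, so each
profile evaluation is O(n_pairs) via Woodbury — this is what makes
10⁴-replicate bootstraps affordable.  Incomplete designs fall back to
dense Cholesky; both paths are cross-checked against each other and
against direct multivariate-normal density evaluation.

AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with n = number of pairs (the
observations entering the likelihood) and k counting every estimated
parameter including the two variance components (null k = 3, predictor
models k = 4).  Akaike weights are the normalized relative likelihoods.
R²m = var(Xβ̂)/(var(Xβ̂) + 2σû² + σê²) and R²c adds 2σû² to the
numerator — each pair carries two independent population effects, hence
the factor 2.  Ranking ties break by fewer parameters, then a fixed
hypothesis order.

The bootstrap keeps floor(frac·n_pops) populations per replicate
(without replacement), restricts every matrix, refits all hypotheses
and ranks by AICc; mean rank and % best are reported and the whole
procedure is bit-reproducible for a fixed seed.  Note that with
near-duplicate predictors the per-dataset split of "best" is highly
variable because subsets share pairs; only the average over datasets is
pinned near 50/50 by the tests.

## GA transform search

Real-coded GA over (family ∈ 4 monomolecular variants, log shape,
magnitude): tournament selection (size 3), BLX-0.5 crossover on the
continuous genes, Gaussian mutation, elitism, stall-based stopping
(no best-objective improvement > 1e−6 for `stall_generations`).  The
objective is the MLPE ML log-likelihood of the induced distances —
all candidates share k, so log-likelihood and AICc order them
identically; AICc enters only when comparing hypotheses.  Default
bounds s ∈ [0.01, 10] (log-uniform init) and m ∈ [1, 2500] span
near-linear to step-like curves and the customary maximum resistance.
The study-fidelity preset is population 250 / stall 200; the `fast`
preset (population 20 / stall 10) is for desk-scale work and tests.
Shape and magnitude are weakly identified from distance matrices alone
(many transforms induce nearly affine-equivalent distances), so
recovery is asserted on the objective — the GA must reach or beat the
generating transform's log-likelihood — not on the raw parameters.

## Synthetic data: what it does and does not emulate

* Elevation: spectral synthesis — white Gaussian noise filtered to a
  power-law spectrum P(f) ∝ f^(−β) and rescaled to the configured
  range.  β defaults to 3 (terrain-like roughness); the periodogram
  slope of generated surfaces recovers β within ±0.5.  Chosen over
  midpoint-displacement schemes for stationarity and clean seeding.
  Default grid 64×64 at 5 km, matching the coarse analysis resolution
  of the motivating study; elevation range 3000 m (coastal plain to
  high range).
* Differentiation matrices are drawn from the MLPE generative model
  itself (the statistical structure the fitting assumes), with the
  distance computed from a known transform.  Defaults β1 = 0.8,
  σ_pop = 0.1, σ_resid = 0.05, 30 populations — the stated
  parameter-recovery conditions.  Clamping to [0, 1] is off by default
  so recovery is exact; it exists because bounded differentiation
  measures truncate while the linear model does not.  There is
  deliberately no forward simulation of gene flow on the surface: the
  generative model matches what the regression assumes, so recovery
  tests validate the fitting machinery, not the biological realism of
  MLPE itself.
* Coalescent haplotypes: hand-written Kingman coalescent (exponential
  waiting times at rate C(k,2) in units of 2N generations), Poisson
  mutations at θ/2 per branch-length unit, infinite sites mapped onto
  distinct positions.  Cross-checked against msprime.  E[S] and E[π]
  match analytic expectations within Monte-Carlo error.
* Microsatellites: island-model (Balding–Nichols Dirichlet) population
  frequencies around common ancestral frequencies, concentration
  (1−F)/F for a target differentiation; genotypes are two independent
  draws (HWE within populations); panel defaults to 11 loci, the
  study's panel size.

Passing the synthetic suite shows the estimators and the
model-selection machinery are correct under the assumed models; it
does not validate null-allele behaviour, genuine linkage, selection,
isolation-by-distance that violates MLPE's covariance structure, or
raster misregistration — all of which real data can exhibit.

## Problem sizes and determinism

The default test and acceptance runs use 40×40 rasters with 30
populations, 1,000-replicate neutral calibrations and 2,000-replicate
bootstraps — sizes at which every check runs comfortably on a single
core while leaving the Monte-Carlo error well inside the asserted
bands.  Every stochastic component takes an integer seed and derives
sub-streams from it; identical seeds give byte-identical outputs.

## Known limitations

* The parsimony probability is an independent derivation, not a
  re-implementation of TCS 1.21's recursion; limits can differ by a
  few steps from that program.
* Fu & Li star statistics and Fu's Fs are sensitive to the singleton
  and mutation counting conventions at multi-allelic sites; the
  conventions used are stated above.
* HWE exact enumeration beyond two alleles is exponential; use the
  Monte-Carlo path for realistic sample sizes.
* MLPE standard errors and p-values for β are not reported (model
  comparison is by information criteria, as in the motivating design).
* No null-allele inference, linkage-disequilibrium testing, Bayesian
  clustering, haplotype phasing, or recombination detection; those are
  upstream/external steps in the intended workflow.
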