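# Methods

This note documents the models and numerical choices behind
`assemblyscape`: what each statistic assumes, what the synthetic-data
generator does and does not emulate, and the decisions made where the
methodology is genuinely open.

## Data model

Community tables are samples-as-rows integer count matrices with opaque
string taxon ids; metadata carries site, depth layer (T/M/S: 0–20, 20–40,
40–100 cm) and grassland type (AM/TG/DG/GD). Distance matrices are
`skbio.DistanceMatrix` objects except for βNTI and RC-bray, which are
returned as labelled square DataFrames because βNTI can be undefined
(NaN) for degenerate phylogenies. Trees are rooted `skbio.TreeNode`
objects with branch lengths; unrooted input is midpoint-rooted with a
loud log message (rooting only affects UniFrac — βMNTD uses patristic
distances, which are rooting-invariant).

Rarefaction is a single multivariate-hypergeometric draw per sample
(subsampling without replacement). Each sample's draw is performed on
taxa sorted by id and mapped back, with per-sample child seeds spawned
from the global seed, so the result is invariant to the order of taxon
columns and each sample is independently reproducible. Zero-count taxa
are retained by the container but dropped (via `drop_empty_taxa`) before
diversity and null-model computations; reports state both counts.

## Synthetic survey generator

The generator emulates the study system the toolkit targets: ~22–66
sites on a ~450 km south–north transect with mean annual precipitation
declining from ~600 to ~150 mm, grassland type following the gradient
(alpine meadow wettest through grasslandization desert driest), three
depth layers per site with nutrient stocks (SOC, TN, TP, TC, AN) scaled
by 1 / 0.6 / 0.35 with depth, and weakly structured values for the other
soil variables (SWC, pH, AP, AK, BD, EC). Coordinates are real
latitude/longitude, so geographic distances are genuine haversine
distances.

The taxon side: a Yule (pure-birth) phylogeny scaled to unit depth;
niche optima evolve by Brownian motion from a root value of 0, so tip
covariance equals shared root-to-node path length times the rate (the
phylogenetic conservatism that βNTI needs in order to detect selection).
Metacommunity abundances are lognormal(0, 1.5), the standard species
abundance distribution.

Assembly regimes:

* **Homogeneous / variable selection.** Selection acts on shallow clades
  (the tree cut at depth 0.8), which are the ecologically coherent units
  under Brownian niches: a clade's weight is its pooled abundance times a
  Gaussian kernel exp(−(opt_c − E*)²/2σ²) at the clade's mean optimum.
  Which member dominates a clade drifts sample-to-sample (lognormal noise,
  sd `within_noise` = 3), and a small mass-effect immigrant fraction
  (`immigration_frac` = 0.05) of reads comes from the raw pool. This
  construction matters: turnover between samples then happens among close
  relatives while the phylogenetic footprint is pinned by selection,
  which is exactly the configuration the tip-shuffle null detects as
  βNTI ≪ −2. A flat per-taxon kernel with independent noise does *not*
  produce that signature — its turnover sits in the phylogenetically
  scattered maladapted tail, and the observed pool collapses onto the
  selected clade, leaving the null nothing to contrast against. Under
  homogeneous selection all samples share E* = 0; under variable
  selection E* tracks each site's standardized MAP (span ±2 niche SD).
* **Neutral drift.** Communities are drawn from the exact stationary law
  of the Sloan source–sink model in its diffusion limit: frequencies
  x ~ Dirichlet(J·m·pool), reads ~ Multinomial(J, x), with J the reads
  per sample and m the per-birth immigration probability. Direct
  stationary sampling is exact, O(taxa), and reduces to an iid
  multinomial from the pool at m = 1. (A sequential urn that copies
  resident reads with probability 1 − m was evaluated and rejected: its
  early immigrants are over-reinforced, so its effective immigration is
  roughly a third of the nominal m and the neutral-model fit cannot
  recover the generating parameter.)
* **Dispersal limitation.** The same stationary sampler with small m
  (≤ 0.05) and spatially autocorrelated local pools — per-taxon Gaussian
  fields with an exponential spatial kernel (length scale one sixth of
  the transect) perturbing the metacommunity lognormally.
* **Mixed** (the survey default): strong homogeneous selection in
  topsoil (σ = 0.3 niche SD), weakened selection in the middle layer
  (kernel 6× wider *and* a drifting clade profile, clade-level lognormal
  sd 1.5 — weak selection no longer pins clade weights), and
  dispersal-limited drift in the subsoil. This builds a monotone
  deterministic-to-stochastic depth gradient with known truth.

What the generator does **not** emulate: sequencing error and chimeras,
compositional biases of PCR, taxonomy mis-annotation (its taxonomy is
defined from tree clades, so genus/phylum structure is perfectly
phylogenetically coherent), temporal dynamics, and realistic
co-occurrence induced by direct biotic interactions (co-occurrence in the
generator arises only through shared environmental tracking). Passing
tests therefore show that the *inference machinery* is correct and
calibrated under the stated generative assumptions, not that any field
data set satisfies those assumptions.

## Null models

**βMNTD / βNTI.** βMNTD is abundance-weighted by default (presence-only
weighting is a flag). The null shuffles taxon labels across the tips of
the tree — equivalently, permutes rows/columns of the patristic distance
matrix — holding every community's composition fixed; one permutation per
iteration is applied to all sample pairs, and βNTI is the per-pair
z-score over 999 iterations (configurable; ≥ 99 enforced). Pairs whose
null standard deviation is zero (e.g. star trees, ≤ 2 taxa) yield NaN
with a warning and are excluded — and counted — by the classifier.
Calibration under the null design (communities drawn iid from the pool)
gives a near-standard-normal βNTI (mean ≈ −0.1, sd ≈ 0.9, ~96% of pairs
within ±2 in the acceptance suite).

**RC-bray.** Each null iteration reassembles every sample: its observed
richness is drawn without replacement with probability proportional to
regional occupancy (Gumbel top-k sampling), each drawn taxon gets one
read, and the remaining reads are multinomial with probability
proportional to regional relative abundance. Null Bray–Curtis values are
compared per pair with the half-weight tie convention
((#null < obs) + ½(#null = obs))/n, rescaled to [−1, 1]. One set of null
communities per iteration serves all pairs; each pair still sees n_null
independent null pairs marginally, at O(n·S) rather than O(n·S²) cost.
Ties use a 1e−9 tolerance because exact Bray–Curtis ties occur on small
integer toys.

**Classification.** Strict inequalities as listed in the README; the
boundary values βNTI = ±2 and |RC| = 0.95 therefore fall to the
stochastic/drift side. Fractions are reported over within-group pairs
(depth layer × grassland type by default; any grouping or all pairs is
available).

## Neutral community model

N defaults to the mean post-rarefaction sample total (overridable); the
detection limit is 1/N. m is estimated by least squares of observed
occurrence frequencies on the Beta-CDF prediction, with a 61-point
log-grid scan on [1e−6, 1] followed by bounded scalar refinement — the
SSE surface is flat in m wherever most taxa are saturated, which defeats
naive local optimization. The 95% band uses binomial quantiles of the
predicted frequency at the number of samples, so a taxon observed in all
samples is classified "within" whenever the prediction makes that outcome
plausible (a Wilson-type interval on the prediction can never contain
f = 1 and would mislabel saturated taxa). R² = 1 − SSE/SST may be
negative. Note the fit inherits the Sloan approximation of ignoring the
read-sampling layer; in recovery simulations this biases m̂ upward by
roughly 20% at m = 0.1, within the accepted recovery band.

## Networks

Taxa are collapsed to genus; genera are kept if their phylum's mean
relative abundance exceeds 1%; the top 200 genera by summed counts are
retained (ties broken lexicographically). Edges use Spearman correlation
on relative abundances with the t-approximation p-value; taxon–taxon
edges require |ρ| > 0.8 and p < 0.05, genus–environment edges p < 0.01.
p-values are deliberately uncorrected by default (an optional
Benjamini–Hochberg flag exists) — the thresholds are used as published.
Constant vectors are excluded with a warning. Topology: average degree
2E/N; mean local clustering over nodes of degree ≥ 2; average path length
on the largest connected component (reported with its size); modularity
by greedy modularity maximization on the unsigned graph. Note that
compositional closure means a fully positive network requires background
taxa to absorb the constraint; no compositionality correction (SparCC
and relatives) is attempted.

## Distance-decay, MRM and PLS-PM

The decay model is fit on dissimilarity (ln C = α + β ln(E/G)) by OLS
over pairs with strictly positive dissimilarity and predictor distance;
zero pairs are excluded and counted, never pseudo-counted. A similarity
option (1 − C) exists. Significance is a Mantel-style permutation of the
community matrix's sample labels — whole rows/columns together — because
pairs sharing a sample are dependent and independent pair-shuffling would
be anticonservative. Geographic distance is haversine on a sphere of
radius 6371.0088 km.

MRM vectorizes lower triangles, fits OLS, and permutes the response
matrix's labels jointly, comparing pseudo-t statistics two-sidedly
(Legendre's convention); NaN response pairs (undefined βNTI) are dropped;
near-collinear predictors (condition number > 1e8) trigger a warning.

PLS-PM uses mode A outer estimation with the centroid inner scheme,
convergence at max weight change < 1e−6 (300 iterations cap), latent
orientation anchored to positive correlation with each block's first
indicator, path coefficients by OLS of each endogenous latent on its
predecessors, indirect effects as products along paths,
GOF = √(mean communality × mean R²) with single-indicator blocks
contributing communality 1, and bootstrap percentile intervals. The
biotic "taxa association" distance — genuinely under-specified in the
field — is implemented as the Euclidean distance between samples'
correlation-weighted relative-abundance profiles (each sample's profile
is its abundance vector projected through the genus–genus Spearman
matrix); the raw-profile alternative is a flag.

## Permutation conventions

Every permutation test includes the observed statistic in its null
(p = (count + 1)/(n_perm + 1) ≥ 1/(n_perm + 1)) and takes an explicit
seed. Defaults are 999 permutations; the calibration tests in the
acceptance suite use 199 per replicate, which leaves the α = 0.05
rejection rate exactly calibrated while fitting 500-replicate loops in
the test budget.

## Analysis problem sizes

The drivers and the acceptance script analyse a survey of 24 sites × 3
layers × 600 taxa × 2000 reads with 299 null iterations and 499
permutations — large enough that every depth-gradient signal is
comfortably detected, small enough to run end-to-end in well under a
minute. The generator's own defaults mirror the emulated study (66
profiles × 3 layers, 2000 taxa, 16,611 reads) for users who want
field-scale data volumes.

## Known limitations

* The tip-shuffle null and the RC-bray null are the canonical
  configurations of this framework, but other randomizations
  (within-clade shuffles, fixed-richness occupancy swaps) are not
  implemented.
* Per-clade (binned) process attribution and alpha-level NRI/NTI are out
  of scope.
* PLS-PM significance is bootstrap-based only; no covariance-based SEM.
* The biotic distance construction is one defensible reading of an
  under-specified method; conclusions that hinge on it should be checked
  against the raw-profile alternative.
* Amplicon-specific artifacts (compositionality, copy-number variation)
  are neither simulated nor corrected for.
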