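# Methods

This note documents the statistical procedures implemented by `coralnet`,
the assumptions behind them, the defaults and why they were chosen, and the
known limits of what the bundled synthetic data can demonstrate.

## Data model and normalization

The canonical containers are a samples × OTUs integer count matrix, a
per-sample design table (genus; species nested in genus; site; time) with
per-site decimal coordinates, and an OTU → lineage taxonomy map. Factor
levels are ordered by first appearance in the metadata, which fixes level
ordering everywhere downstream (term design matrices, tie-breaks,
reported tables) and keeps permutation streams reproducible.

Library-size correction uses median-of-ratios size factors
`s_j = median_i (c_ji / g_i)`. Two reference policies are exposed:

- `all-positive-reference` (classical): `g_i` is the geometric mean across
  all samples, taken over OTUs with no zero anywhere. Sparse 16S tables
  often have no such OTU, in which case the code raises an error that names
  the alternative rather than silently switching.
- `pseudo-geomean` (default in the pipeline): `g_i` is the geometric mean
  over positive entries only and each sample's median runs over the OTUs it
  actually contains. This is the practical estimator for sparse tables and
  the one the pipeline uses by default.

Size factors are reported as computed (no global rescaling); they are
identified only up to a common constant, so all downstream statistics are
invariant to that constant. Presence/absence quantities (prevalence, core
membership) are computed on raw counts; abundance-weighted quantities
(class profiles, SIMPER, Bray-Curtis, correlations) on normalized values,
so the ordination, the dissimilarity decomposition and the network all see
the same matrix.

## Core microbiome

An OTU is in a host group's core when its prevalence is **strictly greater**
than the threshold (default 0.95). The strict inequality matters at the
boundary: prevalence exactly 0.95 is excluded. The threshold is a parameter
because the literature also works with 90% and 75% tiers. Core composition
is summarized as class-level relative abundance of the core OTUs only,
renormalized to sum to one within the group; missing taxonomy ranks are
rendered as `unclassified_<deepest named parent>` so aggregation conserves
total abundance.

## PERMANOVA

Sequential (Type-I) partitioning in the McArdle–Anderson form. Squared
distances are Gower-centered (`G = C(−½ d²)C`); for ordered terms the k-th
sum of squares is `tr((H_k − H_{k−1})G)` where `H_k` projects onto the
column space of the intercept plus terms 1..k. Term design matrices are
plain cell indicators of the crossed factors the term references, so
degrees of freedom are *realized* projector-rank increments: nesting
(`Species(Genus)` contributes 3 df after `Genus` in a 6-species/3-genus
design) and missing design cells are handled without explicit constraints,
and a term fully aliased by its predecessors raises an error naming it.
Rank detection uses an SVD cutoff of 1e−8 relative to the largest singular
value.

Significance comes from free permutation of the distance matrix's sample
labels, identically for every term. This matches common practice for
distance-based MANOVA but means p-values for nested or whole-plot terms are
not exact under restricted exchangeability; the caveat applies equally to
all terms and the calibration check below covers the exchangeable case.
The p-value convention is `(1 + #{F* ≥ F})/(1 + n_perm)`, which cannot
return zero; permutation ties count as exceedances. Pairwise post-hoc tests
run the one-factor model on each level pair and adjust across pairs with
Holm's step-down (`adj_(i) = min(1, max_{j≤i}(m−j+1)p_(j))`).

A structural note on small groups: any permutation that maps the two-group
partition onto itself reproduces the observed F exactly, so the attainable
minimum p-value for a pairwise test is bounded below by the fraction of
partition-preserving permutations — negligible for group sizes around ten
or more, but visible for groups of five or fewer.

## Distance decay and ANCOVA

For each genus and unordered site pair, the mean and standard error of
Bray-Curtis dissimilarity over all cross-site sample pairs (time points
pooled), with the pair's great-circle (haversine, Earth radius 6371 km)
distance. The decay model is a sequential ANCOVA of log mean dissimilarity
on log distance, genus, and their interaction, in that order; effect sizes
are `η² = SS_term/SS_total` and the fit is unweighted least squares on the
site-pair means. Monte-Carlo significance shuffles the (distance, genus)
rows jointly against the dissimilarities — preserving the empirical
distance-genus pairing — and reports `p = #{F* ≥ F}/n_perm` (this
proportion rule, unlike the PERMANOVA convention, can return 0). Independent
shuffling of distance and genus is available via `shuffle="independent"`.
An exact power-law fit drives the residual mean square to zero; the F
statistic is then capped at 1e15 rather than reported as infinite.

## Correlation network

Pearson correlation between every pair of samples' normalized abundance
vectors. Homophily (heterophily) of a factor is the mean correlation over
unordered same-level (different-level) sample pairs, self-pairs excluded.
Negative correlations must be removed before modularity and centrality are
meaningful; the default policy truncates them to zero, with `shift`
((r+1)/2) and `absolute` (|r|) as alternatives.

Community detection is Newman's leading-eigenvector method: recursive
spectral bisection by the sign of the dominant eigenvector of the
generalized modularity matrix `B_ij − δ_ij Σ_{k∈g} B_ik`, accepting a split
only when the leading eigenvalue is positive and the split strictly
increases Q. No Kernighan–Lin refinement is applied; on the planted and
small benchmark graphs used in the tests the method attains the exhaustive
optimum. Module ids are canonicalized by decreasing module size (ties by
smallest member index).

The modularity null shuffles each sample's off-diagonal correlations within
strata — by default the sample's host genus, optionally per individual row —
re-symmetrizes by averaging the two shuffled copies of each pair, rebuilds
the graph under the same negative-weight policy, re-detects communities,
and reports the proportion of null modularities at or above the observed
one. Module-factor association uses the Pearson chi-square statistic
(no continuity correction) with `(levels−1)(modules−1)` df; the
classification rate labels each module with its majority level (ties to the
earliest metadata level) and reports the correctly-classified fraction.

Eigenvector centrality is computed by power iteration on `W + I` (the added
identity damps oscillation on bipartite-like graphs without changing the
eigenvector), uniform start, convergence tolerance 1e−10, on the largest
connected component; other nodes score 0 and scores are scaled to max 1.
Group-level differences are assessed with pairwise Welch t-tests,
Holm-adjusted — one defensible choice among several for comparing mean
centralities.

## Synthetic-data generator

The generator emulates a repeated-measures reef survey: by default 3 genera
× 2 species × 4 sites × 3 time points with 4 colonies per species-site cell
(96 colonies, each colony resampled at all three times, 288 samples). The
default site coordinates are four reefs spanning ~24 km of coastline, so
distance-decay analyses run on realistic 0.5–24 km scales.

Per-OTU log-intensity is
`base_i + g[genus,i] + s[site,i] + t[time,i] + ε`, with

| parameter | default | meaning |
|---|---|---|
| `sigma_base` | 1.0 | sd of baseline log-abundance across OTUs |
| `sigma_genus` | 1.0 | host-genus effect sd (dominant, by design) |
| `sigma_site` | 0.5 | site effect sd |
| `sigma_time` | 0.25 | time effect sd |
| `sigma_noise` | 0.6 | per-sample residual sd |
| `spatial_range_km` | 5.0 | e-folding range of site-effect correlation |
| `depth_log_mean/sd` | ln 10⁴ / 0.5 | log-normal sequencing depth |
| `dispersion` | 0.5 | NB size k (variance = μ + μ²/k) |
| `core_otus_per_genus` | 10 | planted core set size |
| `core_occupancy` | 0.97 | prevalence floor for planted core OTUs |

The effect-scale ordering genus ≫ site > time encodes the survey regime the
package targets — host identity dominating spatial, and spatial dominating
temporal, environmental heterogeneity — and is fixed once; parameter-recovery
checks ask whether the pipeline *recovers* this ordering, not whether it can
be tuned to. Site effects are drawn from a multivariate normal across sites
with covariance `σ_s² exp(−d/ρ)` on haversine distance, which is what makes
dissimilarity increase with distance; setting `spatial_range_km` to `None`
gives independent site effects and no decay. Counts are negative-binomial
with shared dispersion (Dirichlet-multinomial by flag); depths are
log-normal. Planted core OTUs get a +2.5 log-abundance lift within their
genus and a post-hoc occupancy floor: zeros are seeded to 1 until the
genus-level prevalence target is met. Effects are drawn once per config
(a fixed-effects world) and recorded in `SimulationTruth`.

What the generator does **not** emulate: compositional coupling beyond the
shared denominator, OTU-OTU interaction structure, phylogenetic correlation
among OTUs, colony-level random effects, sequencing error or chimeras, and
taxon-specific dispersion. Passing parameter-recovery tests therefore shows
the pipeline recovers additive log-scale structure under overdispersed
sampling — not that it is robust to every artifact of real amplicon data.

## Calibration and recovery experiments (`coralnet.benchmarks`)

- **Type-I error**: 500 null surveys (all effect scales zero; 24 samples ×
  40 OTUs — small on purpose, since each of the 500 simulations runs a full
  199-permutation test) for the PERMANOVA genus term, and 500 null
  distance-decay tables for the ANCOVA distance term. Both rejection rates
  at α = 0.05 are required to land in [0.03, 0.07], the two-sigma band of a
  binomial(500, 0.05) proportion.
- **Parameter recovery**: 50 surveys at generator defaults with problem size
  reduced to 2 colonies per cell (144 samples) and 120 OTUs; the modularity
  null uses 99 shuffles per replicate. Five readouts (R² ordering, homophily
  ordering, module purity, modularity-null significance, positive decay
  slope) must each succeed in ≥ 90% of replicates.

Problem sizes here are the package's own choices balancing Monte-Carlo
resolution against wall time; all distributional parameters are the
generator defaults above.

## Numerical choices and degenerate inputs

- Rank tolerance 1e−8 (relative) in all projector computations; Gower
  centering validates symmetry and zero self-distance.
- Bray-Curtis rejects zero-sum samples (dissimilarity undefined);
  correlation rejects constant samples, naming them.
- SIMPER on two identical groups returns all-zero contributions with zero
  total (percentages defined as 0 rather than 0/0).
- An empty core set is returned with a warning, not an error.
- Chi-square uses the asymptotic distribution; with 6×6 tables and ~100
  samples some expected cells are small, so borderline p-values should be
  read qualitatively.
- The modularity-null re-symmetrization (averaging the two shuffled copies)
  shrinks the null correlation variance slightly relative to shuffling
  unordered pairs directly; since the same graph-building policy is applied
  to observed and null matrices, the comparison remains like-for-like.

## Known limitations

- Free permutation for nested terms (see above); restricted/split-plot
  permutation schemes are out of scope.
- Leading-eigenvector bisection is greedy; global optimality is verified
  only on the small oracle graphs.
- The ANCOVA treats the 18 site-pair means as independent observations;
  the Monte-Carlo shuffle addresses, but does not fully remove, the
  non-independence induced by shared sites and shared samples.
- BIOM support covers the JSON (v1.0) dialect, dense and sparse; HDF5
  (v2.1) files are not read.
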