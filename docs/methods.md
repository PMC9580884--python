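# Methods

## Model and procedure

`divcom` treats a group comparison as a two-stage, purely distance-based
procedure on a sample dissimilarity matrix.

**Distances.**  The default dissimilarity is generalized UniFrac.  For a
rooted phylogeny with branch lengths b_i and per-sample descending
abundance proportions p_i, the distance between samples A and B is

    d^(a)(A,B) = [ sum_i b_i (p_i^A + p_i^B)^a |p_i^A - p_i^B| / (p_i^A + p_i^B) ]
               / [ sum_i b_i (p_i^A + p_i^B)^a ]

with the sums restricted to branches where p_i^A + p_i^B > 0 (the limit
convention) and the root's stem edge excluded (its proportion is always 1
for both samples).  The exponent a in [0, 1] interpolates between
unweighted- and weighted-UniFrac-like behavior; the default a = 0.5 is the
community-standard compromise that downweights neither rare nor dominant
lineages.  Distances depend only on within-sample proportions, so raw and
normalized tables give identical matrices (this invariance is tested).
Alternatively the user supplies any precomputed dissimilarity matrix.

**Stage 1 — distances-based analysis.**  The reference group is clustered
with PAM (k-medoids) on its distance submatrix.  One representative point
per cluster is retained: the medoid (default), or a per-taxon mean/median
pseudo-profile whose distances to all samples are recomputed with
generalized UniFrac (pseudo-profile modes need the table and tree, so
they are unavailable in the precomputed-matrix workflow).  Every test
sample is assigned to its closest representative; its nearest distance is
the quantity all downstream comparisons use.  The automated statistics
are: two-sided Wilcoxon rank-sum contrasts between the reference distance
distribution and each test group's nearest distances (plus all pairwise
test-group contrasts); chi-square tests on the contingency of reference
cluster membership vs each test group's assignment counts and vs the
other mapping variables; and, for context, whole-matrix
PERMANOVA/PERMDISP/ANOSIM between every pair of groups.  p-values are
Benjamini–Hochberg adjusted within each family of tests produced by one
stage, never across stages.

**Stage 2 — de novo clustering analysis (optional).**  Each test group is
itself PAM-clustered with a user-supplied k.  Each test subcluster is
paired with the reference cluster minimizing the *median* of its members'
distances to that cluster's representative, and that median is reported;
the pairing rule uses the median because the reported quantity is a
median level of dissimilarity and the minimizer should be the quantity
reported.  Member distances are contrasted against the reference
distribution (Wilcoxon, BH-adjusted) and subcluster membership is
cross-tabulated against the mapping variables.  If per-group k values are
absent or exceed the group size, the stage is skipped with a warning —
never an error.

**Before/after distance shift.**  For paired designs, the per-subject
difference Δ = d_after − d_before of nearest-representative distances is
computed, arm means are reported, and the two arms are compared with a
Wilcoxon rank-sum test.  Subjects missing a timepoint or an arm label are
excluded with a warning.

## Reference distance distribution

A reference sample's "distance to representative" is its distance to the
representative of its own cluster.  In medoid mode the medoids themselves
sit at distance exactly 0 by construction; these structural zeros would
deflate the reference distribution, so medoid samples are excluded from
it (they remain in all output tables, flagged `is_medoid`).  If k equals
the reference size, every sample is a medoid and the exclusion is waived.

## Choosing the number of clusters

Five instruments are computed for k in [k_min, k_max] (defaults 2 and
min(10, n−1)) on PAM solutions:

* **Calinski–Harabasz**, from the distance-based decomposition
  SS_total = (1/n)·Σ_{i<j} d²_ij, SS_within = Σ_g (1/n_g)·Σ_{i<j∈g} d²_ij,
  CH = [SS_between/(k−1)]/[SS_within/(n−k)]; vote: argmax.
* **Mean silhouette width** (singletons contribute 0); vote: argmax.
* **WSS**, Σ d(sample, its medoid)²; vote: the elbow, taken as the argmax
  of the discrete curvature w(k−1) − 2w(k) + w(k+1) with the curve
  extended down to k = 1.  Any automated elbow rule is a package
  decision — the curve itself is what the report shows.
* **Prediction strength**: repeated random half-splits (50 by default),
  PAM on both halves, test-half samples classified to the nearest
  training medoid; per repetition the score is the worst per-cluster
  proportion of test pairs co-assigned to one training medoid.  Vote: the
  largest k with mean score ≥ 0.8 (the conventional threshold band),
  falling back to k_min when none qualifies.  ps(1) = 1 by convention.
* **Gaussian-mixture BIC** on the first 2 MDS axes, fitted by EM for six
  covariance structures (spherical/diagonal/full × equal/varying across
  components), components 1..k_max.  BIC = 2·loglik − params·log(n)
  (higher is better).  If the globally best cell has one component the
  group is declared homogeneous and one cluster is proposed, overriding
  the votes.

The consensus is the modal vote of the four index votes; ties resolve to
the Calinski–Harabasz vote.  A fully automatic mode (`auto_ch_only`,
used when the pipeline resolves `k_reference="auto"`) short-circuits to
the CH argmax alone.

Mixture-fit safeguards: the covariance floor is scaled to the data
variance (1e-6 of the mean axis variance) and a component whose effective
size drops below d+1 points makes that fit fail — collapsed near-singular
components otherwise inflate the likelihood arbitrarily.  Failed cells
are recorded as missing and the scan continues.

## Statistical tests

* **Wilcoxon rank-sum**: exact enumeration when the pooled size is ≤ 20
  without ties, otherwise the normal approximation with tie and
  continuity corrections.  Fully constant data return p = 1 with a
  warning.
* **Chi-square**: Pearson statistic without continuity correction (the
  2×2 Yates correction is a flag); zero margins are errors; expected
  counts below 5 raise a warning flag.
* **PERMANOVA**: pseudo-F from the same distance-based SS decomposition
  as the CH index; p by uniform random label permutations.
* **PERMDISP**: principal-coordinate embedding keeping every axis
  (negative-eigenvalue axes as an imaginary block), per-sample dispersion
  z = sqrt(max(0, d_real² − d_imag²)) to the group center (centroid by
  default; a spatial-median option computes the center by Weiszfeld
  iteration on the real block, an approximation), one-way ANOVA F on z,
  p by permuting the z values among groups.
* **ANOSIM**: R = (mean between-group rank − mean within-group rank)/(M/2)
  on the ranked condensed distances.
* All permutation p-values use the +1/+1 rule,
  p = (1 + #{stat_perm ≥ stat_obs})/(1 + n_perm), so p ≥ 1/(1+n_perm);
  999 permutations by default; every test is bit-reproducible given its
  seed.  Note that for tiny equal-sized groups the attainable floor is
  higher: with 3 vs 3 samples the mirrored relabeling always reproduces
  the observed statistic, so the exact permutation p cannot fall below
  2/20.

## Ordination

Classical (Torgerson) MDS: double-center −D²/2, eigendecompose, keep the
axes with positive eigenvalues.  Negative eigenvalues are reported (their
total magnitude is available) but their axes discarded; no Cailliez or
Lingoes correction is applied by default because corrections change the
distances being displayed.  Variance explained is computed over the
positive-eigenvalue total.

## PAM

Classic BUILD + SWAP on the dissimilarity matrix.  BUILD seeds the first
medoid at the sample minimizing total distance and then greedily adds the
candidate with the largest total-cost decrease; gain ties break toward
the more central candidate (smaller total distance), then the smaller
sample id.  SWAP repeatedly applies the best single medoid/non-medoid
exchange while the objective strictly decreases (tolerance 1e-12).  All
remaining ties break toward the lexicographically smaller sample id, so
results are fully deterministic; the `seed` parameter is accepted for API
stability but unused.  Like every single-start local search, BUILD+SWAP
can converge to a local optimum on unstructured data (we observe ~10% of
small random point clouds, identical to the reference R implementation on
the same instances); in the tool's intended regime — well-separated
subclusters with at least a few members each — it recovers the global
optimum essentially always (measured 100% over 1600 planted instances).

## Synthetic data

Two scenario generators emulate the classic confounds on Euclidean data
(n = 50 per group, 2-D, by default):

* *dispersion*: two isotropic Gaussian groups sharing a mean, reference
  SD 1 and test SD equal to the dispersion ratio (default 3); the
  generator also returns each point's distance to the reference
  centroid.
* *substructure*: two unit-SD Gaussian subclusters separated by 8
  within-SD units (values below 6 are rejected as not well separated);
  both groups draw from the same subclusters at reversed mixing
  proportions (0.8/0.2 vs 0.2/0.8).  Subcluster counts are the rounded
  expected counts rather than Bernoulli draws, so the planted
  representation is exact and the per-seed structure deterministic.

The microbiome fixture generator emits a counts table, tree, and mapping
with planted structure: a pure-birth random bifurcating topology with
i.i.d. Exponential(1) branch lengths; a shared log-normal baseline
composition; cluster centers obtained by independent log-normal
perturbations of scale 2.0 (a strong, ~7-fold median effect) of that
baseline; per-sample compositions Dirichlet-distributed around the
cluster center with concentration 100; counts multinomial at depth 5000;
120 taxa and 30 samples per cluster by default.  Samples alternate
between two exchangeable group labels within each cluster.  All
generators are pure functions of their configuration including the seed.

What the generators do *not* emulate: real microbiome sparsity patterns,
taxon-taxon correlations, compositional zero-inflation, sequencing-error
profiles, or realistic phylogenetic signal in the effect structure.
Passing recovery tests therefore demonstrates correctness of the
machinery under the stated generative model, not performance guarantees
on real communities.

## Numerical choices and degenerate inputs

* Distances are computed in double precision; matrices are symmetric by
  construction (upper triangle computed once) and clipped to [0, 1].
* Input distance matrices may be asymmetric up to 1e-8 (symmetrized by
  averaging with a warning); any nonzero diagonal is an error.
* Normalization targets the minimum column sum by default, keeping
  values count-like; zero-total samples are hard errors naming the
  sample.
* Unrooted input trees (root with more than two children) are
  midpoint-rooted; missing branch lengths are errors unless a default is
  supplied, because silent zeros distort distances.
* Nearest-representative ties break toward the lower cluster id and are
  logged; harmonization drops are logged with sample ids.
* Exit codes of the CLI: 0 success (including a skipped optional stage),
  2 validation error, 3 runtime error.

## Problem sizes used in the verification suite

The test batteries run at desk scale: 50 random 8-taxon/6-sample
instances for the UniFrac oracle comparison; 200 planted-cluster
instances (n ≤ 9, k ≤ 3) for PAM vs exhaustive enumeration; 1000 null
simulations at n = 30 with 199 permutations each for type-I calibration;
complete enumeration at n = 7 against 9999-draw Monte-Carlo p-values;
10 seeds per planted k ∈ {1, 2, 3} at the generator defaults for
cluster-number recovery; and 20 seeds of the substructure scenario for
the confound-resolution check.  These sizes were chosen so the full suite
completes in a few minutes while keeping the binomial acceptance margins
meaningful.

## Known limitations

* Only the generalized UniFrac family is built in; other beta-diversity
  metrics enter via the precomputed-matrix route.
* The precomputed-matrix workflow cannot use mean/median representatives
  (no table/tree to recompute distances from).
* PERMDISP's spatial-median center is a Weiszfeld approximation on the
  real coordinate block rather than the exact corrected-distance
  minimizer.
* PAM is a single-start local search (see above); no CLARA/FasterPAM
  large-n variants are provided.
* The de novo stage requires user-supplied k per test group; it does not
  auto-select them.
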