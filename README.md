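# divcom

Divide-and-compare beta-diversity analysis of groups of microbial profiles.

## The problem

Comparing groups of microbiome samples usually means computing a
beta-diversity dissimilarity matrix and running whole-group multivariate
tests (PERMANOVA, ANOSIM).  Two situations routinely defeat that recipe:

* **Unequal dispersions.**  Two groups sharing a center but differing in
  spread look identical to location tests (PERMANOVA p is large) even
  though their structures clearly differ — only a dispersion test
  (PERMDISP) notices.
* **Hidden substructure.**  When both groups are mixtures of the same
  subcommunities sampled at different proportions (think enterotypes),
  PERMANOVA rejects strongly even though every sample is exchangeable
  given its subcommunity — the "difference" is an artifact of uneven
  representation.

`divcom` addresses both by making the comparison *distance- and
structure-based*: the reference group is partitioned into its intrinsic
subclusters with PAM (k-medoids) on generalized UniFrac distances, one
representative point (medoid by default) is kept per subcluster, and
every test sample is characterized by its distance to its closest
representative.  Groups are then compared on those scalar distances
(Wilcoxon rank-sum) and on how their samples distribute across the
reference clusters (chi-square), with Benjamini–Hochberg adjustment
within each test family.

The core distance is generalized UniFrac,

d^(α)(A,B) = Σᵢ bᵢ (pᵢᴬ+pᵢᴮ)^α |pᵢᴬ−pᵢᴮ|/(pᵢᴬ+pᵢᴮ) / Σᵢ bᵢ (pᵢᴬ+pᵢᴮ)^α,

summing over tree branches i with length bᵢ and per-sample descending
proportions pᵢ (α = 0.5 by default).  The number of reference clusters can
be chosen automatically from five instruments: Calinski–Harabasz,
silhouette, within sum of squares, prediction strength, and a
six-structure Gaussian-mixture BIC scan on MDS coordinates that flags
homogeneous (single-cluster) groups.

## Worked example

Simulate a planted two-cluster community fixture and run the full
analysis with the bundled CLI:

```sh
divcom simulate fixture --k 2 --taxa 40 --per-cluster 8 --seed 2 --out fix/
divcom run --table fix/table.tsv --tree fix/tree.nwk --map fix/mapping.tsv \
    --reference G1 --k-ref auto --k-test "G2:2" --n-perm 99 --seed 7 --out results/
```

which prints

```
wrote fixture with 40 taxa, 2 clusters to fix/
k_reference = 2; wrote 12 files to results/
```

`k_reference = 2` is the automatically selected number of reference
subclusters (Calinski–Harabasz argmax over the candidate range) — it
matches the planted truth.  `results/` then contains, among others:

* `assignments.tsv` — each test sample's nearest reference cluster and
  its distance to that cluster's medoid;
* `distances.tsv` — the per-sample distance table for reference and test
  samples (medoids flagged);
* `tests.tsv` — every statistical contrast with raw and BH-adjusted
  p-values (Wilcoxon on distances, chi-square on assignment counts,
  whole-matrix PERMANOVA/PERMDISP/ANOSIM per group pair);
* `kselect.tsv`, `denovo_pairs.tsv`, `mds.tsv` and PNG plots (MDS
  scatter, distance boxplots, assignment barplots).

In this fixture the two groups are interleaved halves of the same
communities, so the Wilcoxon contrast in `tests.tsv` is non-significant
(`reference vs G2`, p = 0.852 at seed 7) — the expected null behavior.
The same library surface is available programmatically
(`divcom.distances_based_analysis`, `divcom.denovo_analysis`,
`divcom.distance_shift`, `divcom.recommend_k`, ...).

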