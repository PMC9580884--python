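"""Synthetic data generators for testing every analysis stage offline.

Two families of generators are provided.  The Euclidean *scenario*
generators reproduce the two classic confounds of whole-group multivariate
testing: (a) two groups sharing a center but differing in dispersion,
where PERMANOVA/ANOSIM stay silent while the structure differs, and (b)
two groups drawn from the same two well-separated subclusters at reversed
mixing proportions, where PERMANOVA rejects although every sample is
exchangeable given its subcluster.  The *microbiome fixture* generator
emits a full input triple (counts table, phylogenetic tree, mapping) with
planted cluster structure: a random pure-birth tree with exponential
branch lengths, log-normally perturbed cluster center compositions, and
Dirichlet-multinomial sampling of counts.

All generators are pure functions of their configuration (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from .io import AbundanceTable, ValidationError

__all__ = [
    "ScenarioConfig",
    "FixtureConfig",
    "ScenarioData",
    "scenario_dispersion",
    "scenario_substructure",
    "synth_microbiome",
]


@dataclass
class ScenarioConfig:
    n_per_group: int = 50
    dims: int = 2
    dispersion_ratio: float = 3.0
    subcluster_separation: float = 8.0
    mixing: tuple = ((0.8, 0.2), (0.2, 0.8))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 10:
            raise ValidationError("n_per_group must be at least 10")
        for pair in self.mixing:
            if abs(sum(pair) - 1.0) > 1e-9:
                raise ValidationError("mixing proportions must sum to 1")


@dataclass
class ScenarioData:
    points: np.ndarray
    groups: list
    D: DistanceMatrix
    ref_center_distances: np.ndarray = None
    subclusters: np.ndarray = None

    @property
    def sample_ids(self) -> list:
        return list(self.D.ids)


def _distance_matrix(points: np.ndarray, ids) -> DistanceMatrix:
    return DistanceMatrix(squareform(pdist(points)), ids=list(ids))


def scenario_dispersion(cfg: ScenarioConfig | None = None) -> ScenarioData:
    """Two isotropic Gaussian groups sharing a mean, SDs in a given ratio.

    The reference group has unit SD, the test group SD equal to
    ``dispersion_ratio``.  Also returns each point's Euclidean distance to
    the reference group's (sample) centroid, the quantity the
    reference-distance comparison operates on.
    """
    cfg = cfg or ScenarioConfig()
    if cfg.dispersion_ratio <= 1:
        raise ValidationError("dispersion_ratio must exceed 1")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_per_group
    ref = rng.normal(0.0, 1.0, size=(n, cfg.dims))
    test = rng.normal(0.0, cfg.dispersion_ratio, size=(n, cfg.dims))
    points = np.vstack([ref, test])
    ids = [f"R{i:03d}" for i in range(n)] + [f"T{i:03d}" for i in range(n)]
    groups = ["Reference"] * n + ["Test"] * n
    centroid = ref.mean(axis=0)
    dist_to_center = np.sqrt(((points - centroid) ** 2).sum(axis=1))
    return ScenarioData(
        points=points,
        groups=groups,
        D=_distance_matrix(points, ids),
        ref_center_distances=dist_to_center,
    )


def scenario_substructure(cfg: ScenarioConfig | None = None) -> ScenarioData:
    """Two groups built from the same two subclusters at reversed mixing.

    Both groups sample the SAME two unit-SD Gaussian subclusters (centers
    separated by ``subcluster_separation`` within-SD units) but with the
    two stated mixing proportions; subcluster counts are the rounded
    expected counts, so the planted representation is exact.  True
    subcluster identity is returned for verification.
    """
    cfg = cfg or ScenarioConfig()
    if cfg.subcluster_separation < 6:
        raise ValidationError("subcluster separation below 6 SD is not well separated")
    rng = np.random.default_rng(cfg.seed)
    centers = np.zeros((2, cfg.dims))
    centers[1, 0] = cfg.subcluster_separation
    n = cfg.n_per_group
    points, groups, subclusters, ids = [], [], [], []
    for g, (label, prefix, mix) in enumerate(
        [("Reference", "R", cfg.mixing[0]), ("Test", "T", cfg.mixing[1])]
    ):
        n0 = int(round(n * mix[0]))
        counts = [n0, n - n0]
        i = 0
        for sub, c in enumerate(counts):
            pts = rng.normal(0.0, 1.0, size=(c, cfg.dims)) + centers[sub]
            points.append(pts)
            subclusters.extend([sub] * c)
            for _ in range(c):
                ids.append(f"{prefix}{i:03d}")
                groups.append(label)
                i += 1
    points = np.vstack(points)
    return ScenarioData(
        points=points,
        groups=groups,
        D=_distance_matrix(points, ids),
        subclusters=np.asarray(subclusters),
    )


@dataclass
class FixtureConfig:
    n_taxa: int = 120
    k_true: int = 3
    samples_per_cluster: int = 30
    sequencing_depth: int = 5000
    dirichlet_concentration: float = 100.0
    effect_scale: float = 2.0
    branch_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_taxa, self.k_true, self.samples_per_cluster,
               self.sequencing_depth) < 1 or self.n_taxa < 2:
            raise ValidationError("fixture sizes must be positive (>= 2 taxa)")
        if min(self.dirichlet_concentration, self.effect_scale,
               self.branch_rate) <= 0:
            raise ValidationError("fixture rates/scales must be positive")


def _random_tree(n_tips: int, rng, branch_rate: float) -> TreeNode:
    """Pure-birth random bifurcating topology, exponential branch lengths."""
    root = TreeNode()
    tips = []
    for _ in range(2):
        child = TreeNode()
        root.append(child)
        tips.append(child)
    while len(tips) < n_tips:
        node = tips.pop(int(rng.integers(len(tips))))
        for _ in range(2):
            child = TreeNode()
            node.append(child)
            tips.append(child)
    for i, tip in enumerate(root.tips()):
        tip.name = f"OTU_{i + 1}"
    for node in root.postorder(include_self=False):
        node.length = float(rng.exponential(1.0 / branch_rate))
    return root


def synth_microbiome(cfg: FixtureConfig | None = None):
    """Planted-cluster microbiome fixture: counts table + tree + mapping.

    ``k_true`` cluster center compositions are built by applying
    independent log-normal perturbations of scale ``effect_scale`` to a
    shared baseline composition; each sample's composition is Dirichlet
    around its cluster center with the stated concentration, and counts
    are multinomial at ``sequencing_depth``.  The mapping records a group
    label (samples alternate between G1 and G2 within each cluster, so
    the two groups are exchangeable) and the true cluster.
    """
    cfg = cfg or FixtureConfig()
    rng = np.random.default_rng(cfg.seed)
    tree = _random_tree(cfg.n_taxa, rng, cfg.branch_rate)
    taxa = [t.name for t in tree.tips()]
    baseline = rng.lognormal(0.0, 1.0, size=cfg.n_taxa)
    baseline /= baseline.sum()
    centers = []
    for _ in range(cfg.k_true):
        center = baseline * np.exp(rng.normal(0.0, cfg.effect_scale, cfg.n_taxa))
        centers.append(center / center.sum())
    columns, sample_ids, meta_rows = {}, [], []
    s = 0
    for c, center in enumerate(centers, start=1):
        for j in range(cfg.samples_per_cluster):
            comp = rng.dirichlet(cfg.dirichlet_concentration * center)
            counts = rng.multinomial(cfg.sequencing_depth, comp)
            sid = f"S{s + 1:03d}"
            columns[sid] = counts
            sample_ids.append(sid)
            meta_rows.append({"Group": f"G{j % 2 + 1}", "Cluster": f"C{c}"})
            s += 1
    table = AbundanceTable(pd.DataFrame(columns, index=taxa))
    metadata = pd.DataFrame(meta_rows, index=sample_ids)
    metadata.index.name = "#SampleId"
    return table, tree, metadata
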