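"""Generalized UniFrac distances and classical multidimensional scaling.

Generalized UniFrac (Chen et al.'s :math:`d^{(\\alpha)}` family) weights
every branch of the phylogeny by its length and a power ``alpha`` of the
combined taxon proportions carried by that branch:

.. math::

    d^{(\\alpha)}(A, B) =
      \\frac{\\sum_i b_i\\,(p_i^A + p_i^B)^{\\alpha}\\,
             \\left|p_i^A - p_i^B\\right| / (p_i^A + p_i^B)}
            {\\sum_i b_i\\,(p_i^A + p_i^B)^{\\alpha}},

where ``b_i`` is the length of branch *i* and ``p_i^X`` the fraction of
sample *X*'s total abundance descending from that branch.  Branches with
``p_i^A + p_i^B = 0`` are excluded from both sums (the limit convention),
and the root's stem edge is never counted.  ``alpha`` interpolates between
unweighted- and weighted-UniFrac-like behavior; 0.5 is the community
default and the default here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .io import AbundanceTable, ValidationError

__all__ = [
    "BranchTable",
    "GUniFracConfig",
    "branch_partition",
    "gunifrac",
    "Ordination",
    "classical_mds",
    "full_embedding",
]


@dataclass
class GUniFracConfig:
    """Configuration of the generalized UniFrac exponent alpha in [0, 1]."""

    alpha: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must lie in [0, 1]")


@dataclass
class BranchTable:
    """Per-edge decomposition of a rooted tree.

    ``membership[e, t]`` is True when taxon ``taxon_ids[t]`` descends from
    edge ``e``; ``lengths[e]`` is that edge's branch length.  One record per
    edge of the tree, root stem excluded.
    """

    lengths: np.ndarray
    membership: np.ndarray  # (n_edges, n_taxa) bool
    taxon_ids: list = field(default_factory=list)

    @property
    def tip_sets(self) -> list:
        taxa = np.asarray(self.taxon_ids, dtype=object)
        return [frozenset(taxa[row]) for row in self.membership]


def branch_partition(tree: TreeNode, taxon_ids=None) -> BranchTable:
    """Decompose a rooted tree into (branch length, descendant tip set) records.

    Computed in a single post-order traversal.  ``taxon_ids`` fixes the
    column order of the membership matrix (default: tree tip order).
    """
    if len(tree.children) == 0:
        raise ValidationError("tree has no edges")
    if taxon_ids is None:
        taxon_ids = [t.name for t in tree.tips()]
    index = {name: i for i, name in enumerate(taxon_ids)}
    n_taxa = len(taxon_ids)
    lengths, rows = [], []
    tip_masks: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            mask = np.zeros(n_taxa, dtype=bool)
            if node.name not in index:
                raise ValidationError(f"tree tip {node.name!r} not among taxa")
            mask[index[node.name]] = True
        else:
            mask = np.zeros(n_taxa, dtype=bool)
            for child in node.children:
                mask |= tip_masks[id(child)]
        tip_masks[id(node)] = mask
        lengths.append(0.0 if node.length is None else float(node.length))
        rows.append(mask)
    return BranchTable(
        lengths=np.asarray(lengths, dtype=float),
        membership=np.asarray(rows, dtype=bool),
        taxon_ids=list(taxon_ids),
    )


def gunifrac(
    table: AbundanceTable,
    tree: TreeNode,
    cfg: GUniFracConfig | None = None,
) -> DistanceMatrix:
    """Pairwise generalized UniFrac distances between all samples.

    Inputs must be harmonized (table taxa == tree tips) and every sample
    must have positive total abundance.  Distances depend only on
    per-sample proportions, so raw and normalized tables give identical
    results.
    """
    cfg = cfg or GUniFracConfig()
    values = table.values
    totals = values.sum(axis=0)
    if (totals <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValidationError("zero-total sample(s): " + ", ".join(map(str, bad)))
    props = values / totals
    branches = branch_partition(tree, taxon_ids=table.taxon_ids)
    # branch proportions: (n_edges, n_samples)
    P = branches.membership.astype(float) @ props
    b = branches.lengths
    n = len(table.sample_ids)
    D = np.zeros((n, n))
    for i in range(n):
        pa = P[:, i]
        for j in range(i + 1, n):
            pb = P[:, j]
            s = pa + pb
            occupied = s > 0
            ss = s[occupied]
            w = b[occupied] * ss ** (cfg.alpha - 1.0)
            den = float(np.sum(w * ss))
            if den == 0.0:
                d = 0.0
            else:
                d = float(np.sum(w * np.abs(pa[occupied] - pb[occupied])) / den)
            D[i, j] = D[j, i] = min(max(d, 0.0), 1.0)
    return DistanceMatrix(D, ids=list(table.sample_ids))


@dataclass
class Ordination:
    """Principal-coordinate embedding of a distance matrix.

    ``coordinates`` holds one row per sample on the retained positive-
    eigenvalue axes; ``eigenvalues`` lists all eigenvalues in descending
    order (negative ones are reported but their axes discarded);
    ``variance_explained`` is each retained axis' share of the positive
    eigenvalue total.
    """

    sample_ids: list
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray

    @property
    def negative_magnitude(self) -> float:
        neg = self.eigenvalues[self.eigenvalues < 0]
        return float(-neg.sum())


def _center_and_decompose(D: DistanceMatrix):
    d2 = np.asarray(D.data, dtype=float) ** 2
    n = d2.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ d2 @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    return eigvals[order], eigvecs[:, order]


def classical_mds(D: DistanceMatrix, m: int = 2) -> Ordination:
    """Classical (Torgerson) MDS / principal coordinates analysis.

    Double-centers ``-D**2 / 2``, eigendecomposes, and returns coordinates
    on the top ``m`` nonnegative-eigenvalue axes.  When the matrix is
    Euclidean-embeddable, inter-row Euclidean distances of the coordinates
    reproduce the input distances exactly at full rank.  No Cailliez or
    Lingoes correction is applied; negative eigenvalues are reported so
    the user can judge the embedding quality.
    """
    if m < 1:
        raise ValidationError("number of MDS axes must be at least 1")
    n = len(D.ids)
    if m > n - 1:
        m = n - 1
    eigvals, eigvecs = _center_and_decompose(D)
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    pos = eigvals > tol
    keep = min(m, int(pos.sum()))
    lam = eigvals[:keep].clip(min=0.0)
    coords = eigvecs[:, :keep] * np.sqrt(lam)
    pos_total = eigvals[pos].sum() if pos.any() else 1.0
    return Ordination(
        sample_ids=list(D.ids),
        coordinates=coords,
        eigenvalues=eigvals,
        variance_explained=lam / pos_total,
    )


def full_embedding(D: DistanceMatrix):
    """Full principal-coordinate embedding keeping negative axes.

    Returns ``(real, imag)`` coordinate blocks: axes with positive
    eigenvalues scaled by ``sqrt(lambda)`` and axes with negative
    eigenvalues scaled by ``sqrt(-lambda)``.  Squared distances in the
    original matrix equal ``||dr||^2 - ||di||^2`` between rows, which is
    what dispersion analysis on non-Euclidean dissimilarities needs.
    """
    eigvals, eigvecs = _center_and_decompose(D)
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    pos = eigvals > tol
    neg = eigvals < -tol
    real = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    imag = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    return real, imag
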