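"""Partitioning Around Medoids and representative-point machinery.

PAM is the classic BUILD + SWAP k-medoids local search on a dissimilarity
matrix: BUILD greedily seeds medoids (first the sample minimizing total
distance to all others, then whichever candidate maximizes the decrease in
total cost), SWAP repeatedly applies the best single medoid/non-medoid
exchange while the objective strictly decreases.  All ties break toward
the lexicographically smaller sample id, so the algorithm is fully
deterministic; the ``seed`` argument is kept in the signature for API
stability but unused.

Representative points of the reference clusters are the medoids by
default; per-taxon mean or median pseudo-profiles are the alternative
(they require the abundance table and tree, since distances to a
pseudo-profile must be recomputed with generalized UniFrac).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .distance import GUniFracConfig, gunifrac
from .io import AbundanceTable, ValidationError, normalize

logger = logging.getLogger("divcom")

__all__ = ["ClusteringResult", "RepresentativeSet", "pam", "representatives",
           "assign_to_nearest"]


@dataclass
class ClusteringResult:
    """A PAM partition: labels 1..k, medoid ids, and the total cost.

    ``objective`` is the sum over samples of the distance to the medoid of
    their cluster.  Cluster ids are assigned in lexicographic order of the
    medoid ids, and each medoid's own label equals its cluster id.
    """

    sample_ids: list
    k: int
    labels: np.ndarray
    medoid_ids: list
    objective: float

    def members(self, cluster: int) -> list:
        return [s for s, l in zip(self.sample_ids, self.labels) if l == cluster]


def _id_order(ids) -> np.ndarray:
    """Indices sorted by lexicographic sample id (deterministic tie order)."""
    return np.asarray(sorted(range(len(ids)), key=lambda i: str(ids[i])), dtype=int)


def pam(D: DistanceMatrix, k: int, seed: int | None = None) -> ClusteringResult:
    """Cluster samples into ``k`` groups around medoids (BUILD + SWAP)."""
    ids = list(D.ids)
    n = len(ids)
    if k < 1 or k > n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    d = np.asarray(D.data, dtype=float)
    order = _id_order(ids)

    # BUILD: greedy seeding.
    totals = d.sum(axis=1)
    medoids = [int(order[np.argmin(totals[order])])]
    nearest = d[medoids[0]].copy()
    while len(medoids) < k:
        candidates = order[~np.isin(order, medoids)]
        gains = np.maximum(nearest[None, :] - d[candidates], 0.0).sum(axis=1)
        # ties: prefer the more central candidate, then the smaller id
        tied = candidates[gains >= gains.max() - 1e-12]
        best = int(tied[np.argmin(totals[tied])])
        medoids.append(best)
        nearest = np.minimum(nearest, d[best])

    # SWAP: best-improvement local search with strict decrease.
    medoids = sorted(medoids, key=lambda i: str(ids[i]))
    while True:
        med = np.asarray(medoids, dtype=int)
        dmed = d[med]  # (k, n)
        which = np.argmin(dmed, axis=0)
        d1 = dmed[which, np.arange(n)]
        if k > 1:
            tmp = dmed.copy()
            tmp[which, np.arange(n)] = np.inf
            d2 = tmp.min(axis=0)
        else:
            d2 = np.full(n, np.inf)
        candidates = order[~np.isin(order, medoids)]
        best_delta, best_swap = -1e-12, None
        for mpos, mi in enumerate(medoids):  # medoids already in id order
            mask = which == mpos
            if len(candidates) == 0:
                break
            Dh = d[candidates]  # (H, n)
            loss = np.where(
                mask[None, :],
                np.minimum(Dh, d2[None, :]) - d1[None, :],
                np.minimum(Dh - d1[None, :], 0.0),
            ).sum(axis=1)
            j = int(np.argmin(loss))
            if loss[j] < best_delta:
                best_delta = float(loss[j])
                best_swap = (mpos, int(candidates[j]))
        if best_swap is None:
            break
        mpos, h = best_swap
        medoids[mpos] = h
        medoids = sorted(medoids, key=lambda i: str(ids[i]))

    med = np.asarray(medoids, dtype=int)
    dmed = d[med]
    labels = np.argmin(dmed, axis=0) + 1  # np.argmin: first (lowest cluster id) wins
    objective = float(dmed[labels - 1, np.arange(n)].sum())
    return ClusteringResult(
        sample_ids=ids,
        k=k,
        labels=labels.astype(int),
        medoid_ids=[ids[i] for i in medoids],
        objective=objective,
    )


@dataclass
class RepresentativeSet:
    """One representative point per reference cluster plus all distances.

    ``rep_distances`` has one row per analyzed sample (reference and test)
    and one column per cluster id; in medoid mode the columns are read
    straight from the full distance matrix, in mean/median mode they are
    generalized UniFrac distances to the pseudo-profiles.
    """

    mode: str
    cluster_ids: list
    rep_ids: list | None
    profiles: pd.DataFrame | None
    rep_distances: pd.DataFrame


def representatives(
    clustering: ClusteringResult,
    D: DistanceMatrix,
    mode: str = "medoid",
    table: AbundanceTable | None = None,
    tree: TreeNode | None = None,
    cfg: GUniFracConfig | None = None,
) -> RepresentativeSet:
    """Determine the representative point of every reference cluster.

    ``D`` must cover all analyzed samples (reference and test); the
    clustering was computed on the reference subset.
    """
    clusters = list(range(1, clustering.k + 1))
    if mode == "medoid":
        cols = {}
        all_ids = list(D.ids)
        for c, mid in zip(clusters, clustering.medoid_ids):
            j = D.index(mid)
            cols[c] = np.asarray(D.data)[:, j]
        rep_distances = pd.DataFrame(cols, index=all_ids)
        return RepresentativeSet(
            mode=mode,
            cluster_ids=clusters,
            rep_ids=list(clustering.medoid_ids),
            profiles=None,
            rep_distances=rep_distances,
        )
    if mode not in ("mean", "median"):
        raise ValidationError(f"unknown representative mode {mode!r}")
    if table is None or tree is None:
        raise ValidationError(
            "mean/median representatives need the abundance table and tree; "
            "with a precomputed distance matrix use medoid mode"
        )
    agg = {"mean": np.mean, "median": np.median}[mode]
    pseudo = {}
    for c in clusters:
        members = clustering.members(c)
        pseudo[f"_REP{c}_"] = agg(table.df[members].to_numpy(dtype=float), axis=1)
    augmented = table.df.copy()
    for name, profile in pseudo.items():
        augmented[name] = profile
    aug_table = normalize(AbundanceTable(augmented), "min")
    aug_D = gunifrac(aug_table, tree, cfg)
    data = pd.DataFrame(aug_D.data, index=list(aug_D.ids), columns=list(aug_D.ids))
    real = [s for s in aug_D.ids if not s.startswith("_REP")]
    rep_distances = pd.DataFrame(
        {c: data.loc[real, f"_REP{c}_"] for c in clusters}, index=real
    )
    profiles = pd.DataFrame(
        {c: aug_table.df[f"_REP{c}_"] for c in clusters}, index=table.taxon_ids
    )
    return RepresentativeSet(
        mode=mode,
        cluster_ids=clusters,
        rep_ids=None,
        profiles=profiles,
        rep_distances=rep_distances,
    )


def assign_to_nearest(reps: RepresentativeSet, test_ids) -> pd.DataFrame:
    """Assign each test sample to its closest representative point.

    Returns a frame indexed by sample id with ``nearest_cluster`` and
    ``nearest_distance``; exact ties break toward the lower cluster id and
    are logged.
    """
    missing = [t for t in test_ids if t not in reps.rep_distances.index]
    if missing:
        raise ValidationError(
            "samples missing from representative distances: " + ", ".join(missing)
        )
    sub = reps.rep_distances.loc[list(test_ids)]
    values = sub.to_numpy(dtype=float)
    pos = np.argmin(values, axis=1)  # first minimum -> lower cluster id
    ties = (values == values[np.arange(len(values)), pos][:, None]).sum(axis=1) > 1
    for sid in np.asarray(list(test_ids), dtype=object)[ties]:
        logger.warning("tied representative distances for %s; keeping lower cluster id", sid)
    clusters = np.asarray(reps.cluster_ids, dtype=int)
    return pd.DataFrame(
        {
            "nearest_cluster": clusters[pos],
            "nearest_distance": values[np.arange(len(values)), pos],
        },
        index=list(test_ids),
    )
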