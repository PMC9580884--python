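"""Cluster-number selection: five instruments and a consensus rule.

For each candidate k the reference distance matrix is PAM-clustered and
four indices are evaluated — Calinski-Harabasz (distance-based variance
ratio), mean silhouette width, within sum of squares (WSS, distances to
medoids squared), and Tibshirani-Walther prediction strength.  A fifth
instrument fits Gaussian mixtures on the first MDS axes for six covariance
structures and scans BIC; if the best model has a single component the
data are flagged homogeneous and one cluster is proposed.  Otherwise each
index votes for a k and the modal vote wins, with ties resolved by the
Calinski-Harabasz index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from skbio import DistanceMatrix
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .clustering import ClusteringResult, pam
from .distance import Ordination, classical_mds
from .io import ValidationError

logger = logging.getLogger("divcom")

__all__ = [
    "KSelectConfig",
    "KRecommendation",
    "ch_index",
    "silhouette_mean",
    "wss",
    "prediction_strength",
    "gmm_bic_scan",
    "consensus_vote",
    "recommend_k",
    "GMM_STRUCTURES",
]

GMM_STRUCTURES = (
    "spherical-equal",
    "spherical-varying",
    "diag-equal",
    "diag-varying",
    "full-equal",
    "full-varying",
)


@dataclass
class KSelectConfig:
    k_min: int = 2
    k_max: int | None = None  # default min(10, n - 1)
    ps_threshold: float = 0.8
    ps_reps: int = 50
    gmm_axes: int = 2
    seed: int = 0

    def resolve_k_max(self, n: int) -> int:
        k_max = self.k_max if self.k_max is not None else min(10, n - 1)
        if not (2 <= self.k_min <= k_max < n):
            raise ValidationError(
                f"invalid k range [{self.k_min}, {k_max}] for n = {n}"
            )
        if not 0 < self.ps_threshold <= 1:
            raise ValidationError("prediction-strength threshold must be in (0, 1]")
        return k_max


@dataclass
class KRecommendation:
    per_index_optimum: dict
    index_curves: pd.DataFrame
    gmm_best_components: int | None
    homogeneous: bool
    consensus_k: int
    gmm_bic: pd.DataFrame | None = None


def _groups_from_labels(labels):
    labels = np.asarray(labels)
    return [np.flatnonzero(labels == g) for g in np.unique(labels)]


def ch_index(D: DistanceMatrix, labels) -> float:
    """Calinski-Harabasz index from the distance-based SS decomposition.

    SS_total = (1/n) sum_{i<j} d_ij^2, SS_within = sum_g (1/n_g)
    sum_{i<j in g} d_ij^2, CH = [SS_between/(k-1)] / [SS_within/(n-k)].
    """
    d2 = np.asarray(D.data, dtype=float) ** 2
    n = d2.shape[0]
    groups = _groups_from_labels(labels)
    k = len(groups)
    if k < 2:
        raise ValidationError("Calinski-Harabasz index needs at least 2 clusters")
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = sum(
        d2[np.ix_(g, g)].sum() / (2.0 * len(g)) for g in groups if len(g) > 1
    )
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf
    return float((ss_between / (k - 1)) / (ss_within / (n - k)))


def silhouette_mean(D: DistanceMatrix, labels) -> float:
    """Mean silhouette width on a precomputed dissimilarity matrix.

    Singleton clusters contribute s(i) = 0 by convention.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("silhouette needs at least 2 clusters")
    return float(silhouette_score(np.asarray(D.data), labels, metric="precomputed"))


def wss(D: DistanceMatrix, clustering: ClusteringResult) -> float:
    """Within sum of squares: sum over samples of d(sample, its medoid)^2."""
    d = np.asarray(D.data, dtype=float)
    med_idx = [D.index(m) for m in clustering.medoid_ids]
    rows = np.asarray(med_idx)[np.asarray(clustering.labels) - 1]
    return float((d[rows, np.arange(d.shape[0])] ** 2).sum())


def prediction_strength(D: DistanceMatrix, k: int,
                        cfg: KSelectConfig | None = None) -> float:
    """Prediction strength of a k-cluster solution by repeated half-splits.

    Each repetition splits the samples in random halves, PAM-clusters both,
    classifies the test half to the nearest training medoid, and records
    the worst per-cluster proportion of test pairs co-assigned to one
    training medoid; the mean over repetitions is returned.  ps(1) = 1 by
    convention.
    """
    cfg = cfg or KSelectConfig()
    ids = list(D.ids)
    n = len(ids)
    if n < 4:
        raise ValidationError("prediction strength needs at least 4 samples")
    if k == 1:
        return 1.0
    if k > n // 2:
        raise ValidationError(f"k = {k} exceeds half the sample count")
    d = np.asarray(D.data, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, k, 7919]))
    scores = []
    for _ in range(cfg.ps_reps):
        perm = rng.permutation(n)
        half = n // 2
        train, test = np.sort(perm[:half]), np.sort(perm[half:])
        train_cl = pam(D.filter([ids[i] for i in train]), k)
        test_cl = pam(D.filter([ids[i] for i in test]), k)
        med_idx = np.asarray([ids.index(m) for m in train_cl.medoid_ids])
        closest = np.argmin(d[np.ix_(test, med_idx)], axis=1)
        worst = 1.0
        found = False
        for c in range(1, k + 1):
            members = np.flatnonzero(np.asarray(test_cl.labels) == c)
            if len(members) < 2:
                continue
            found = True
            assigned = closest[members]
            same = (assigned[:, None] == assigned[None, :])
            n_pairs = len(members) * (len(members) - 1) / 2
            agree = (np.triu(same, 1).sum()) / n_pairs
            worst = min(worst, agree)
        scores.append(worst if found else 1.0)
    return float(np.mean(scores))


class _EMFailure(RuntimeError):
    pass


def _cov_params(structure: str, k: int, d: int) -> int:
    return {
        "spherical-equal": 1,
        "spherical-varying": k,
        "diag-equal": d,
        "diag-varying": k * d,
        "full-equal": d * (d + 1) // 2,
        "full-varying": k * d * (d + 1) // 2,
    }[structure]


def _m_step_covs(X, resp, means, structure, reg):
    n, d = X.shape
    k = means.shape[0]
    nk = resp.sum(axis=0)
    covs = np.empty((k, d, d))
    if structure == "full-varying" or structure == "full-equal":
        for g in range(k):
            diff = X - means[g]
            covs[g] = (resp[:, g, None] * diff).T @ diff / nk[g]
        if structure == "full-equal":
            pooled = (covs * nk[:, None, None]).sum(axis=0) / n
            covs[:] = pooled
    elif structure in ("diag-varying", "diag-equal"):
        var = np.empty((k, d))
        for g in range(k):
            diff = X - means[g]
            var[g] = (resp[:, g, None] * diff ** 2).sum(axis=0) / nk[g]
        if structure == "diag-equal":
            var[:] = (var * nk[:, None]).sum(axis=0) / n
        for g in range(k):
            covs[g] = np.diag(var[g])
    else:  # spherical
        s2 = np.empty(k)
        for g in range(k):
            diff = X - means[g]
            s2[g] = (resp[:, g] * (diff ** 2).sum(axis=1)).sum() / (nk[g] * d)
        if structure == "spherical-equal":
            s2[:] = (s2 * nk).sum() / n
        for g in range(k):
            covs[g] = np.eye(d) * s2[g]
    covs += np.eye(d) * reg
    return covs


def _log_gaussians(X, means, covs):
    n, d = X.shape
    k = means.shape[0]
    out = np.empty((n, k))
    for g in range(k):
        try:
            chol = np.linalg.cholesky(covs[g])
        except np.linalg.LinAlgError as exc:
            raise _EMFailure("singular covariance") from exc
        diff = X - means[g]
        y = np.linalg.solve(chol, diff.T)
        maha = (y ** 2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        out[:, g] = -0.5 * (d * np.log(2 * np.pi) + logdet + maha)
    return out


def _fit_gmm(X, k, structure, seed, n_init=3, max_iter=300, tol=1e-7, reg=1e-6):
    """EM fit of a k-component Gaussian mixture under a covariance constraint.

    Returns (loglik, n_params).  Raises _EMFailure on degenerate fits.
    """
    n, d = X.shape
    if k > n:
        raise _EMFailure("more components than samples")
    # scale-free covariance floor; also reject components with fewer
    # effective points than a d-dimensional Gaussian needs (collapsed
    # components otherwise blow up the likelihood)
    reg = reg * float(X.var(axis=0).mean() + 1e-12)
    min_support = d + 1
    best_ll = -np.inf
    for init in range(n_init):
        rs = int(np.random.SeedSequence([seed, k, init]).generate_state(1)[0] % (2**31))
        km = KMeans(n_clusters=k, n_init=1, random_state=rs).fit(X)
        resp = np.zeros((n, k))
        resp[np.arange(n), km.labels_] = 1.0
        ll_prev = -np.inf
        try:
            for _ in range(max_iter):
                nk = resp.sum(axis=0)
                if (nk < min_support).any():
                    raise _EMFailure("component support too small")
                weights = nk / n
                means = resp.T @ X / nk[:, None]
                covs = _m_step_covs(X, resp, means, structure, reg)
                logp = _log_gaussians(X, means, covs) + np.log(weights)
                norm = logsumexp(logp, axis=1)
                ll = float(norm.sum())
                resp = np.exp(logp - norm[:, None])
                if abs(ll - ll_prev) < tol * (abs(ll) + 1.0):
                    break
                ll_prev = ll
        except _EMFailure:
            continue
        if not np.isfinite(ll):
            continue
        best_ll = max(best_ll, ll)
    if not np.isfinite(best_ll):
        raise _EMFailure("EM failed for all initializations")
    n_params = (k - 1) + k * d + _cov_params(structure, k, d)
    return best_ll, n_params


def gmm_bic_scan(ordination: Ordination, cfg: KSelectConfig | None = None,
                 k_max: int | None = None):
    """Scan Gaussian-mixture BIC over component counts and six structures.

    Mixtures are fitted by EM on the first ``cfg.gmm_axes`` MDS axes; BIC
    is 2*loglik - params*log(n) (higher is better).  A failed EM cell is
    recorded as missing and the scan continues.  Returns the BIC table and
    the component count of the globally best cell (ties toward fewer
    components).
    """
    cfg = cfg or KSelectConfig()
    coords = ordination.coordinates
    if coords.shape[1] < cfg.gmm_axes:
        raise ValidationError(
            f"ordination retains {coords.shape[1]} axes, "
            f"fewer than the {cfg.gmm_axes} requested for the mixture fit"
        )
    X = np.asarray(coords[:, : cfg.gmm_axes], dtype=float)
    n = X.shape[0]
    if k_max is None:
        k_max = cfg.resolve_k_max(n)
    table = pd.DataFrame(
        np.nan, index=range(1, k_max + 1), columns=list(GMM_STRUCTURES)
    )
    for k in range(1, k_max + 1):
        for structure in GMM_STRUCTURES:
            try:
                ll, n_params = _fit_gmm(X, k, structure, cfg.seed)
            except _EMFailure:
                logger.warning("GMM EM failed for k=%d structure=%s", k, structure)
                continue
            table.loc[k, structure] = 2.0 * ll - n_params * np.log(n)
    if table.isna().all().all():
        raise ValidationError("every mixture fit failed")
    per_k_best = table.max(axis=1)
    best_components = int(per_k_best.idxmax())  # idxmax: first/smallest k on ties
    return table, best_components


def _wss_elbow(wss_curve: dict, k_min: int, k_max: int) -> int:
    """Elbow of the WSS curve: argmax of the discrete second difference."""
    curvature = {}
    for k in range(k_min, k_max + 1):
        if (k - 1) in wss_curve and (k + 1) in wss_curve:
            curvature[k] = wss_curve[k - 1] - 2 * wss_curve[k] + wss_curve[k + 1]
    if not curvature:
        return k_min
    best = max(sorted(curvature), key=lambda k: curvature[k])
    return best


def consensus_vote(votes: dict) -> int:
    """Modal k over the per-index votes; ties resolve to the CH proposal."""
    counts = pd.Series(list(votes.values())).value_counts()
    top = counts[counts == counts.max()].index
    return int(votes["CH"]) if len(top) > 1 else int(top[0])


def recommend_k(D: DistanceMatrix, cfg: KSelectConfig | None = None,
                auto_ch_only: bool = False) -> KRecommendation:
    """Automated optimal-k recommendation.

    Each index proposes a k: CH and silhouette by argmax, WSS by the elbow
    of its curve, prediction strength by the largest k meeting the
    threshold (falling back to k_min).  The modal vote wins; ties go to
    the Calinski-Harabasz proposal.  If the mixture BIC scan prefers a
    single component the data are declared homogeneous and one cluster is
    recommended.  ``auto_ch_only`` short-circuits everything to the CH
    argmax (the main script's fully automatic mode).
    """
    cfg = cfg or KSelectConfig()
    n = len(D.ids)
    if n < 4:
        raise ValidationError("k selection needs at least 4 samples")
    k_max = cfg.resolve_k_max(n)
    clusterings = {k: pam(D, k) for k in range(1, min(k_max + 2, n) + 1)}
    ch_curve, sil_curve, wss_curve, ps_curve = {}, {}, {}, {}
    for k, cl in clusterings.items():
        wss_curve[k] = wss(D, cl)
        if cfg.k_min <= k <= k_max:
            ch_curve[k] = ch_index(D, cl.labels)
            sil_curve[k] = silhouette_mean(D, cl.labels)
    ch_vote = max(sorted(ch_curve), key=lambda k: ch_curve[k])
    if auto_ch_only:
        curves = pd.DataFrame({"CH": pd.Series(ch_curve)})
        return KRecommendation(
            per_index_optimum={"CH": ch_vote},
            index_curves=curves,
            gmm_best_components=None,
            homogeneous=False,
            consensus_k=ch_vote,
        )
    for k in range(cfg.k_min, k_max + 1):
        if k <= n // 2:
            ps_curve[k] = prediction_strength(D, k, cfg)
    sil_vote = max(sorted(sil_curve), key=lambda k: sil_curve[k])
    wss_vote = _wss_elbow(wss_curve, cfg.k_min, k_max)
    ps_ok = [k for k, v in ps_curve.items() if v >= cfg.ps_threshold]
    ps_vote = max(ps_ok) if ps_ok else cfg.k_min
    votes = {
        "CH": ch_vote,
        "silhouette": sil_vote,
        "WSS": wss_vote,
        "prediction_strength": ps_vote,
    }
    consensus = consensus_vote(votes)

    ordination = classical_mds(D, m=max(cfg.gmm_axes, 2))
    bic_table, best_components = gmm_bic_scan(ordination, cfg, k_max=k_max)
    homogeneous = best_components == 1
    if homogeneous:
        consensus = 1
    curves = pd.DataFrame(
        {
            "CH": pd.Series(ch_curve),
            "silhouette": pd.Series(sil_curve),
            "WSS": pd.Series({k: wss_curve[k] for k in range(cfg.k_min, k_max + 1)}),
            "prediction_strength": pd.Series(ps_curve),
        }
    )
    return KRecommendation(
        per_index_optimum=votes,
        index_curves=curves,
        gmm_best_components=best_components,
        homogeneous=homogeneous,
        consensus_k=int(consensus),
        gmm_bic=bic_table,
    )
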