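"""Hypothesis tests used throughout the comparisons.

Continuous contrasts use the two-sided Wilcoxon rank-sum test, categorical
contingency uses Pearson's chi-square, and whole-matrix group comparisons
use the distance-based permutation tests PERMANOVA (location), PERMDISP
(dispersion) and ANOSIM (rank-based).  Permutation p-values follow the
+1/+1 rule, p = (1 + #{permuted statistic >= observed}) / (1 + n_perm), so
they are never zero and bottom out at 1/(1+n_perm).  All p-values within a
family of related tests are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.stats
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .distance import full_embedding
from .io import ValidationError

logger = logging.getLogger("divcom")

__all__ = [
    "TestResult",
    "wilcoxon_rank_sum",
    "chi_square",
    "permanova",
    "permdisp",
    "anosim",
    "bh_adjust",
]

DEFAULT_PERMUTATIONS = 999


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    n_permutations: int | None = None
    p_adjusted: float | None = None
    warning: str | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "p_adjusted": self.p_adjusted,
            "warning": self.warning or "",
        }


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the pooled size is at most 20 and there are no
    ties; normal approximation with tie and continuity correction
    otherwise.  Completely constant data give p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        logger.warning("all values identical in both samples; p = 1")
        return TestResult("wilcoxon", float(len(x) * len(y) / 2), 1.0,
                          warning="constant data")
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("wilcoxon", float(res.statistic), float(min(res.pvalue, 1.0)))


def chi_square(contingency, yates_2x2: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction by default (``yates_2x2`` enables it for 2x2
    tables).  Any zero row or column margin is a hard error; expected
    counts below 5 raise a warning flag.
    """
    obs = np.asarray(contingency, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValidationError("contingency table entries must be nonnegative")
    if obs.sum() <= 0:
        raise ValidationError("contingency table is empty")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValidationError("contingency table has a zero margin")
    correction = yates_2x2 and obs.shape == (2, 2)
    stat, p, dof, expected = scipy.stats.chi2_contingency(obs, correction=correction)
    warning = None
    if (expected < 5).any():
        warning = "expected count < 5"
        logger.warning("chi-square: some expected counts are below 5")
    return TestResult("chi-square", float(stat), float(p), warning=warning)


def _group_indices(labels):
    labels = np.asarray(labels)
    groups = []
    for g in pd_unique(labels):
        groups.append(np.flatnonzero(labels == g))
    return groups


def pd_unique(values):
    """Unique values in order of first appearance."""
    seen, out = set(), []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def _ss_decomposition(d2: np.ndarray, groups) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for idx in groups:
        if len(idx) > 1:
            ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss_total, ss_within


def _pseudo_f(d2: np.ndarray, groups) -> float:
    n = d2.shape[0]
    a = len(groups)
    ss_total, ss_within = _ss_decomposition(d2, groups)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def _check_groups(labels, n):
    labels = np.asarray(labels)
    if len(labels) != n:
        raise ValidationError("label vector length does not match matrix")
    groups = _group_indices(labels)
    if len(groups) < 2:
        raise ValidationError("at least two groups required")
    if any(len(g) < 2 for g in groups):
        raise ValidationError("every group needs at least two samples")
    return labels, groups


def permanova(D: DistanceMatrix, labels, n_perm: int = DEFAULT_PERMUTATIONS,
              seed: int | None = None) -> TestResult:
    """Permutational multivariate analysis of variance (location test).

    Pseudo-F from the distance-based sums-of-squares decomposition
    SS_total = (1/N) sum_{i<j} d_ij^2, SS_within = sum_g (1/n_g)
    sum_{i<j in g} d_ij^2; the p-value comes from random label
    permutations.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be at least 1")
    d2 = np.asarray(D.data, dtype=float) ** 2
    labels, groups = _check_groups(labels, d2.shape[0])
    f_obs = _pseudo_f(d2, groups)
    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    count = 0
    n = d2.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        start, pgroups = 0, []
        for s in sizes:
            pgroups.append(perm[start:start + s])
            start += s
        if _pseudo_f(d2, pgroups) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return TestResult("PERMANOVA", float(f_obs), float(p), n_permutations=n_perm)


def _anova_f(z: np.ndarray, groups) -> float:
    grand = z.mean()
    ss_between = sum(len(g) * (z[g].mean() - grand) ** 2 for g in groups)
    ss_within = sum(((z[g] - z[g].mean()) ** 2).sum() for g in groups)
    a, n = len(groups), len(z)
    if ss_within <= 0:
        return np.inf if ss_between > 0 else np.nan
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def _spatial_median(coords: np.ndarray, n_iter: int = 200, tol: float = 1e-10):
    """Weiszfeld iteration for the geometric median of coordinate rows."""
    center = coords.mean(axis=0)
    for _ in range(n_iter):
        delta = coords - center
        dist = np.sqrt((delta ** 2).sum(axis=1))
        if (dist < 1e-12).any():
            return center
        w = 1.0 / dist
        new = (coords * w[:, None]).sum(axis=0) / w.sum()
        if np.abs(new - center).max() < tol:
            return new
        center = new
    return center


def permdisp(D: DistanceMatrix, labels, n_perm: int = DEFAULT_PERMUTATIONS,
             seed: int | None = None, center: str = "centroid") -> TestResult:
    """Permutational test of homogeneity of multivariate dispersions.

    The matrix is embedded by principal coordinates keeping every axis
    (positive-eigenvalue block real, negative block imaginary); each
    sample's dispersion is its corrected distance to the group center,
    z = sqrt(max(0, d_real^2 - d_imag^2)).  A one-way ANOVA F on the z
    values is assessed by permuting them among groups.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be at least 1")
    if center not in ("centroid", "spatial_median"):
        raise ValidationError(f"unknown center type {center!r}")
    n = len(D.ids)
    labels, groups = _check_groups(labels, n)
    real, imag = full_embedding(D)
    z = np.zeros(n)
    for idx in groups:
        if center == "centroid":
            cr = real[idx].mean(axis=0)
            ci = imag[idx].mean(axis=0) if imag.size else np.zeros(0)
        else:
            cr = _spatial_median(real[idx])
            ci = imag[idx].mean(axis=0) if imag.size else np.zeros(0)
        dr2 = ((real[idx] - cr) ** 2).sum(axis=1)
        di2 = ((imag[idx] - ci) ** 2).sum(axis=1) if imag.size else 0.0
        z[idx] = np.sqrt(np.maximum(dr2 - di2, 0.0))
    f_obs = _anova_f(z, groups)
    if np.isnan(f_obs):
        logger.warning("all dispersions identical; PERMDISP undefined, p = 1")
        return TestResult("PERMDISP", 0.0, 1.0, n_permutations=n_perm,
                          warning="degenerate dispersions")
    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        start, pgroups = 0, []
        for s in sizes:
            pgroups.append(perm[start:start + s])
            start += s
        f_perm = _anova_f(z, pgroups)
        if not np.isnan(f_perm) and f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return TestResult("PERMDISP", float(f_obs), float(p), n_permutations=n_perm)


def anosim(D: DistanceMatrix, labels, n_perm: int = DEFAULT_PERMUTATIONS,
           seed: int | None = None) -> TestResult:
    """Analysis of similarities: rank-based between- vs within-group test.

    R = (mean rank of between-group distances - mean rank of within-group
    distances) / (M/2) with M = n(n-1)/2; R is 1 when every between-group
    distance outranks every within-group one.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be at least 1")
    d = np.asarray(D.data, dtype=float)
    n = d.shape[0]
    labels, groups = _check_groups(labels, n)
    iu = np.triu_indices(n, 1)
    ranks = scipy.stats.rankdata(d[iu])
    m = len(ranks)

    def r_stat(lab):
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    labels = np.asarray(labels)
    r_obs = r_stat(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if r_stat(labels[rng.permutation(n)]) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return TestResult("ANOSIM", float(r_obs), float(p), n_permutations=n_perm)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_bh(results: list[TestResult]) -> list[TestResult]:
    """BH-adjust one family of test results in place (and return it)."""
    if results:
        adjusted = bh_adjust([r.p_value for r in results])
        for r, q in zip(results, adjusted):
            r.p_adjusted = float(q)
    return results
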