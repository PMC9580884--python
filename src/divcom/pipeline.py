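"""The two analysis stages, the before/after distance-shift analysis, and
report writing.

Stage 1 ("distances-based") clusters only the reference group, selects one
representative point per reference cluster, measures every test sample's
distance to those representatives, assigns each test sample to its closest
reference cluster, and runs the automated statistics: Wilcoxon rank-sum
contrasts on the distance distributions, chi-square on the assignment
contingencies, and whole-matrix PERMANOVA/PERMDISP/ANOSIM between group
pairs for context.  Stage 2 ("de novo clustering") additionally clusters
every test group and pairs each test subcluster with the reference cluster
minimizing the median member distance.  The distance-shift analysis
compares per-subject changes in nearest-representative distance between
two intervention arms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from . import stats as st
from .clustering import (ClusteringResult, RepresentativeSet, assign_to_nearest,
                         pam, representatives)
from .distance import GUniFracConfig, Ordination, classical_mds, gunifrac
from .io import AbundanceTable, ValidationError, write_table
from .kselect import KRecommendation, KSelectConfig, recommend_k

logger = logging.getLogger("divcom")

__all__ = [
    "RunConfig",
    "Dataset",
    "DistancesReport",
    "DeNovoReport",
    "distances_based_analysis",
    "denovo_analysis",
    "distance_shift",
    "render_reports",
]


@dataclass
class RunConfig:
    reference_groups: list
    test_groups: list | None = None  # None: every other group in the mapping
    group_col: str = "Group"
    k_reference: int | str = "auto"
    k_per_test_group: dict | None = None
    representative_mode: str = "medoid"
    alpha: float = 0.5
    n_perm: int = 999
    seed: int = 42
    output_dir: str | None = None
    plot_format: str = "png"

    def __post_init__(self) -> None:
        if self.test_groups is not None:
            overlap = set(self.reference_groups) & set(self.test_groups)
            if overlap:
                raise ValidationError(
                    "groups cannot be both reference and test: "
                    + ", ".join(sorted(overlap))
                )
        if self.k_reference != "auto" and int(self.k_reference) < 1:
            raise ValidationError("k_reference must be >= 1 or 'auto'")


@dataclass
class Dataset:
    """Harmonized analysis inputs plus the sample distance matrix."""

    D: DistanceMatrix
    metadata: pd.DataFrame
    table: AbundanceTable | None = None
    tree: TreeNode | None = None

    @classmethod
    def from_inputs(cls, table, tree, metadata, alpha: float = 0.5,
                    matrix: DistanceMatrix | None = None) -> "Dataset":
        if matrix is not None:
            ids = [s for s in matrix.ids if s in set(metadata.index)]
            if not ids:
                raise ValidationError("no shared samples between matrix and mapping")
            return cls(D=matrix.filter(ids), metadata=metadata.loc[ids],
                       table=table, tree=tree)
        if table is None or tree is None:
            raise ValidationError("need a table and tree, or a distance matrix")
        D = gunifrac(table, tree, GUniFracConfig(alpha))
        return cls(D=D, metadata=metadata.loc[list(D.ids)], table=table, tree=tree)


@dataclass
class DistancesReport:
    config: RunConfig
    k_reference: int
    kselect: KRecommendation | None
    clustering: ClusteringResult
    representatives: RepresentativeSet
    assignment: pd.DataFrame
    sample_distances: pd.DataFrame
    reference_distances: pd.Series
    tests: pd.DataFrame
    ordination: Ordination
    assignment_counts: pd.DataFrame


@dataclass
class DeNovoReport:
    clusterings: dict
    pairs: pd.DataFrame
    tests: pd.DataFrame
    crosstabs: dict = field(default_factory=dict)


def _groups_of(data: Dataset, cfg: RunConfig):
    col = data.metadata[cfg.group_col]
    if col.isna().any():
        bad = list(data.metadata.index[col.isna()])
        raise ValidationError("missing group labels for: " + ", ".join(bad))
    present = list(dict.fromkeys(col))
    missing_ref = [g for g in cfg.reference_groups if g not in present]
    if missing_ref:
        raise ValidationError("reference group(s) absent: " + ", ".join(missing_ref))
    test_groups = (cfg.test_groups if cfg.test_groups is not None
                   else [g for g in present if g not in cfg.reference_groups])
    ref_ids = [s for s in data.D.ids if col[s] in cfg.reference_groups]
    test_ids = {g: [s for s in data.D.ids if col[s] == g] for g in test_groups}
    if len(ref_ids) < 2:
        raise ValidationError("reference group needs at least 2 samples")
    return ref_ids, test_groups, test_ids


def _tests_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(
        rows,
        columns=["family", "contrast", "method", "statistic", "p_value",
                 "p_adjusted", "n_permutations", "warning"],
    )
    for col in ("statistic", "p_value", "p_adjusted", "n_permutations"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def _result_rows(family, named_results):
    results = [r for _, r in named_results]
    st.attach_bh(results)
    rows = []
    for (name, r) in named_results:
        rows.append([family, name, r.method, r.statistic, r.p_value,
                     r.p_adjusted, r.n_permutations, r.warning or ""])
    return rows


def distances_based_analysis(data: Dataset, cfg: RunConfig) -> DistancesReport:
    """Stage 1: reference clustering, representatives, distances, statistics."""
    ref_ids, test_groups, test_ids = _groups_of(data, cfg)
    D_ref = data.D.filter(ref_ids)
    ks_rec = None
    if cfg.k_reference == "auto":
        ks_rec = recommend_k(D_ref, KSelectConfig(seed=cfg.seed), auto_ch_only=True)
        k_ref = ks_rec.consensus_k
        logger.warning("auto-selected k_reference = %d", k_ref)
    else:
        k_ref = int(cfg.k_reference)
    if k_ref > len(ref_ids):
        raise ValidationError("k_reference exceeds reference group size")
    clustering = pam(D_ref, k_ref)
    reps = representatives(
        clustering, data.D, mode=cfg.representative_mode,
        table=data.table, tree=data.tree, cfg=GUniFracConfig(cfg.alpha),
    )
    all_test = [s for g in test_groups for s in test_ids[g]]
    assignment = assign_to_nearest(reps, all_test) if all_test else pd.DataFrame(
        columns=["nearest_cluster", "nearest_distance"])
    group_col = data.metadata[cfg.group_col]
    if len(assignment):
        assignment.insert(0, "group", [group_col[s] for s in assignment.index])

    # Reference samples: distance to their own cluster's representative.
    medoid_set = set(clustering.medoid_ids) if reps.mode == "medoid" else set()
    ref_rows = []
    for sid, label in zip(clustering.sample_ids, clustering.labels):
        dist = float(reps.rep_distances.loc[sid, int(label)])
        ref_rows.append((sid, group_col[sid], "reference", int(label), dist,
                         sid in medoid_set))
    test_rows = [
        (sid, row["group"], "test", int(row["nearest_cluster"]),
         float(row["nearest_distance"]), False)
        for sid, row in assignment.iterrows()
    ]
    sample_distances = pd.DataFrame(
        ref_rows + test_rows,
        columns=["sample", "group", "role", "cluster", "distance", "is_medoid"],
    ).set_index("sample")
    reference_distances = sample_distances.query(
        "role == 'reference' and not is_medoid")["distance"]
    if reference_distances.empty:  # k == n_ref corner: every sample a medoid
        reference_distances = sample_distances.query("role == 'reference'")["distance"]

    rows = []
    # Family 1: Wilcoxon on distance distributions.
    named = []
    for g in test_groups:
        dist_g = assignment.query("group == @g")["nearest_distance"]
        if len(dist_g):
            named.append((f"reference vs {g}",
                          st.wilcoxon_rank_sum(reference_distances, dist_g)))
    for i, g1 in enumerate(test_groups):
        for g2 in test_groups[i + 1:]:
            d1 = assignment.query("group == @g1")["nearest_distance"]
            d2 = assignment.query("group == @g2")["nearest_distance"]
            if len(d1) and len(d2):
                named.append((f"{g1} vs {g2}", st.wilcoxon_rank_sum(d1, d2)))
    rows += _result_rows("distances-wilcoxon", named)

    # Family 2: chi-square on assignment contingencies.
    clusters = reps.cluster_ids
    ref_counts = pd.Series(clustering.labels).value_counts().reindex(
        clusters, fill_value=0)
    counts = {"reference": ref_counts}
    for g in test_groups:
        counts[g] = assignment.query("group == @g")["nearest_cluster"] \
            .value_counts().reindex(clusters, fill_value=0)
    assignment_counts = pd.DataFrame(counts, index=clusters).T
    named = []
    for g in test_groups:
        table2 = assignment_counts.loc[["reference", g]].to_numpy()
        try:
            named.append((f"assignment: reference vs {g}", st.chi_square(table2)))
        except ValidationError as exc:
            logger.warning("chi-square skipped for %s: %s", g, exc)
    for var in data.metadata.columns:
        if var == cfg.group_col:
            continue
        ref_meta = data.metadata.loc[ref_ids, var]
        ct = pd.crosstab(pd.Series(clustering.labels, index=ref_ids), ref_meta)
        if ct.shape[0] >= 2 and ct.shape[1] >= 2:
            try:
                named.append((f"reference clusters vs {var}",
                              st.chi_square(ct.to_numpy())))
            except ValidationError as exc:
                logger.warning("chi-square skipped for %s: %s", var, exc)
    rows += _result_rows("assignment-chisq", named)

    # Family 3: whole-matrix tests between each pair of groups (context).
    all_groups = [("reference", ref_ids)] + [(g, test_ids[g]) for g in test_groups]
    for method, fn in (("PERMANOVA", st.permanova), ("PERMDISP", st.permdisp),
                       ("ANOSIM", st.anosim)):
        named = []
        for i, (g1, ids1) in enumerate(all_groups):
            for g2, ids2 in all_groups[i + 1:]:
                if len(ids1) < 2 or len(ids2) < 2:
                    continue
                sub = data.D.filter(ids1 + ids2)
                labels = [g1] * len(ids1) + [g2] * len(ids2)
                named.append((f"{g1} vs {g2}",
                              fn(sub, labels, cfg.n_perm, cfg.seed)))
        rows += _result_rows(f"whole-matrix-{method}", named)

    ordination = classical_mds(data.D, m=2)
    return DistancesReport(
        config=cfg,
        k_reference=k_ref,
        kselect=ks_rec,
        clustering=clustering,
        representatives=reps,
        assignment=assignment,
        sample_distances=sample_distances,
        reference_distances=reference_distances,
        tests=_tests_frame(rows),
        ordination=ordination,
        assignment_counts=assignment_counts,
    )


def denovo_analysis(data: Dataset, cfg: RunConfig,
                    report: DistancesReport | None = None) -> DeNovoReport | None:
    """Stage 2: cluster each test group, pair subclusters with reference
    clusters by minimum median member distance.

    Returns None (with a warning) when ``k_per_test_group`` is absent — the
    stage is optional and its omission is not an error.
    """
    if not cfg.k_per_test_group:
        logger.warning("no k per test group provided; de novo stage omitted")
        return None
    if report is None:
        report = distances_based_analysis(data, cfg)
    reps = report.representatives
    _, test_groups, test_ids = _groups_of(data, cfg)
    clusterings, pair_rows, named, crosstabs = {}, [], [], {}
    for g in test_groups:
        k_g = cfg.k_per_test_group.get(g)
        if k_g is None:
            logger.warning("no k for test group %s; skipped", g)
            continue
        ids_g = test_ids[g]
        if int(k_g) > len(ids_g):
            logger.warning("k = %s exceeds size of group %s; skipped", k_g, g)
            continue
        cl = pam(data.D.filter(ids_g), int(k_g))
        clusterings[g] = cl
        for c in range(1, cl.k + 1):
            members = cl.members(c)
            med_by_ref = reps.rep_distances.loc[members].median(axis=0)
            nearest_ref = int(med_by_ref.idxmin())
            member_dists = reps.rep_distances.loc[members, nearest_ref]
            pair_rows.append([g, c, len(members), nearest_ref,
                              float(med_by_ref.min())])
            named.append((f"{g} subcluster {c} vs reference distances",
                          st.wilcoxon_rank_sum(member_dists,
                                               report.reference_distances)))
        for var in data.metadata.columns:
            if var == cfg.group_col:
                continue
            ct = pd.crosstab(pd.Series(cl.labels, index=ids_g),
                             data.metadata.loc[ids_g, var])
            crosstabs[(g, var)] = ct
            if ct.shape[0] >= 2 and ct.shape[1] >= 2:
                try:
                    named.append((f"{g} subclusters vs {var}",
                                  st.chi_square(ct.to_numpy())))
                except ValidationError as exc:
                    logger.warning("chi-square skipped (%s, %s): %s", g, var, exc)
    pairs = pd.DataFrame(
        pair_rows,
        columns=["group", "subcluster", "size", "nearest_reference_cluster",
                 "median_distance"],
    )
    return DeNovoReport(
        clusterings=clusterings,
        pairs=pairs,
        tests=_tests_frame(_result_rows("denovo", named)),
        crosstabs=crosstabs,
    )


def distance_shift(report: DistancesReport, pairing: dict, arms: dict):
    """Before/after change in nearest-representative distance per subject.

    ``pairing`` maps subject -> (before sample id, after sample id); arms
    maps subject -> intervention arm.  The per-subject difference is
    d_after - d_before; arm means are reported and the two arms compared
    with a two-sided Wilcoxon rank-sum test.  Subjects missing a timepoint
    are excluded with a warning.
    """
    dist = report.sample_distances["distance"]
    rows = []
    for subject, (before, after) in pairing.items():
        if before not in dist.index or after not in dist.index:
            logger.warning("subject %s missing a timepoint; excluded", subject)
            continue
        if subject not in arms:
            logger.warning("subject %s has no arm label; excluded", subject)
            continue
        d_b, d_a = float(dist[before]), float(dist[after])
        rows.append([subject, arms[subject], before, after, d_b, d_a, d_a - d_b])
    table = pd.DataFrame(
        rows, columns=["subject", "arm", "before", "after",
                       "distance_before", "distance_after", "delta"],
    ).set_index("subject")
    arm_names = sorted(table["arm"].unique())
    if len(arm_names) != 2:
        raise ValidationError(
            f"distance-shift comparison needs exactly two arms, got {arm_names}"
        )
    x = table.loc[table["arm"] == arm_names[0], "delta"]
    y = table.loc[table["arm"] == arm_names[1], "delta"]
    result = st.wilcoxon_rank_sum(x, y)
    logger.info("mean delta per arm: %s",
                {a: float(table.query("arm == @a")["delta"].mean())
                 for a in arm_names})
    return result, table


def _plot_reports(report: DistancesReport, outdir: Path, fmt: str) -> list:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    coords = report.ordination.coordinates
    ids = report.ordination.sample_ids
    groups = report.sample_distances.loc[ids, "group"]
    fig, ax = plt.subplots(figsize=(6, 5))
    for g in dict.fromkeys(groups):
        mask = (groups == g).to_numpy()
        ax.scatter(coords[mask, 0], coords[mask, 1], label=str(g), s=25, alpha=0.8)
    ve = report.ordination.variance_explained
    ax.set_xlabel(f"MDS1 ({ve[0]:.1%})" if len(ve) > 0 else "MDS1")
    ax.set_ylabel(f"MDS2 ({ve[1]:.1%})" if len(ve) > 1 else "MDS2")
    ax.legend()
    path = outdir / f"mds.{fmt}"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(6, 5))
    sd = report.sample_distances
    order = list(dict.fromkeys(sd["group"]))
    data = [sd.query("group == @g and not is_medoid")["distance"] for g in order]
    ax.boxplot(data, tick_labels=[str(g) for g in order])
    ax.set_ylabel("distance to nearest reference representative")
    path = outdir / f"distances_boxplot.{fmt}"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(6, 5))
    report.assignment_counts.plot.bar(ax=ax)
    ax.set_ylabel("samples assigned")
    ax.legend(title="reference cluster")
    path = outdir / f"assignment_barplot.{fmt}"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written


def render_reports(report: DistancesReport, cfg: RunConfig,
                   denovo: DeNovoReport | None = None,
                   shift: tuple | None = None) -> list:
    """Write every result table as TSV (plots are best-effort PNGs)."""
    if cfg.output_dir is None:
        raise ValidationError("output_dir is not set")
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(df: pd.DataFrame, name: str):
        path = outdir / name
        write_table(df, path)
        written.append(path)

    _write(report.assignment, "assignments.tsv")
    _write(report.sample_distances, "distances.tsv")
    tests = report.tests
    if denovo is not None:
        tests = pd.concat([tests, denovo.tests], ignore_index=True)
    _write(tests, "tests.tsv")
    _write(report.assignment_counts, "assignment_counts.tsv")
    coords = pd.DataFrame(
        report.ordination.coordinates,
        index=report.ordination.sample_ids,
        columns=[f"MDS{i + 1}" for i in range(report.ordination.coordinates.shape[1])],
    )
    _write(coords, "mds.tsv")
    membership = pd.DataFrame(
        {"cluster": report.clustering.labels,
         "is_medoid": [s in set(report.clustering.medoid_ids)
                       for s in report.clustering.sample_ids]},
        index=report.clustering.sample_ids,
    )
    _write(membership, "reference_clusters.tsv")
    if report.kselect is not None:
        _write(report.kselect.index_curves, "kselect.tsv")
    if denovo is not None:
        _write(denovo.pairs.set_index("group"), "denovo_pairs.tsv")
    if shift is not None:
        _write(shift[1], "shift.tsv")
    resolved = {
        "reference_groups": list(cfg.reference_groups),
        "test_groups": cfg.test_groups,
        "group_col": cfg.group_col,
        "k_reference": report.k_reference,
        "k_per_test_group": cfg.k_per_test_group,
        "representative_mode": cfg.representative_mode,
        "alpha": cfg.alpha,
        "n_perm": cfg.n_perm,
        "seed": cfg.seed,
    }
    cfg_path = outdir / "run_config.json"
    cfg_path.write_text(json.dumps(resolved, indent=2, sort_keys=True) + "\n")
    written.append(cfg_path)
    try:
        written += _plot_reports(report, outdir, cfg.plot_format)
    except Exception as exc:  # plots are best effort; tables already written
        logger.warning("plot rendering failed: %s", exc)
    return written
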