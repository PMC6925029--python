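"""Per-patient preprocessing, clustering, metaclustering and concordance.

The statistical pipeline mirrors standard single-cell morphometry practice:

* per-patient preprocessing: shift each feature to positive support, fit a
  maximum-likelihood Box-Cox transform, drop zero-variance features, center
  and scale (each patient block ends with mean 0 / sd 1 columns);
* complete-linkage euclidean hierarchical clustering of each patient's cells,
  with clusters defined by branch-level cuts (L recursive splits of the root,
  so at most 2^L clusters — third-level branching is the default cell-cluster
  definition, second-level branching defines the main metaclusters);
* metaclustering: cluster the per-patient cluster mean-profiles and report the
  composition table (metacluster x patient presence, percent of total cells);
* liquid-solid concordance: per patient, min-max scale each raw feature over
  that patient's cells, average per compartment, and correlate the compartment
  profiles (Pearson);
* one-way random-effects ICC with the unbalanced group-size correction;
* per-feature two-tailed Welch t-tests between compartments, with
  Benjamini-Hochberg adjusted p-values reported alongside the raw ones;
* Spearman feature-feature correlation ordered by hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.decomposition import PCA

from .catalog import ANNOTATION_COLUMNS
from .synthetic import CohortTable

__all__ = [
    "PreprocessedTable",
    "ClusterAssignment",
    "MetaclusterReport",
    "preprocess_per_patient",
    "pca_embed",
    "cluster_cells",
    "cut_branch_level",
    "assign_patient_clusters",
    "metacluster",
    "concordance_r",
    "icc_oneway",
    "feature_tests",
    "feature_correlation",
]


# --------------------------------------------------------------------------- #
# preprocessing
# --------------------------------------------------------------------------- #


@dataclass
class PreprocessedTable:
    """Per-patient Box-Cox / center / scale result.

    ``data`` keeps the annotation columns and the retained feature columns
    (mean 0, sd 1 within each patient block); ``transforms`` records, per
    (patient, feature), the shift, the fitted lambda, and center/scale;
    ``dropped`` records zero-variance features per patient (never silently
    absent: a feature dropped for any patient is excluded for all, so the
    matrix stays rectangular, and the record says why).
    """

    data: pd.DataFrame
    transforms: pd.DataFrame
    dropped: dict[str, list[str]]

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ANNOTATION_COLUMNS]

    def patient_matrix(self, patient_id: str) -> np.ndarray:
        block = self.data[self.data["patient_id"] == patient_id]
        return block[self.feature_names].to_numpy(float)


def preprocess_per_patient(cohort: CohortTable) -> PreprocessedTable:
    """Box-Cox (MLE lambda), zero-variance drop, center, scale — per patient."""
    dropped: dict[str, list[str]] = {}
    records = []
    names = cohort.feature_names

    # features with zero variance in any patient block are dropped globally
    to_drop: set[str] = set()
    for patient in cohort.patients:
        block = cohort.patient_block(patient)
        if len(block) < 2:
            raise ValueError(f"patient {patient!r} has fewer than 2 cells")
        variances = block[names].var(ddof=1)
        zero = [f for f in names if not np.isfinite(variances[f]) or variances[f] <= 0]
        if zero:
            dropped[patient] = zero
            to_drop.update(zero)
    kept = [f for f in names if f not in to_drop]

    blocks = []
    for patient in cohort.patients:
        block = cohort.patient_block(patient).copy()
        for feature in kept:
            x = block[feature].to_numpy(float)
            shift = 1.0 - x.min() if x.min() <= 0 else 0.0
            y, lam = stats.boxcox(x + shift)
            center, scale = y.mean(), y.std(ddof=1)
            block[feature] = (y - center) / scale
            records.append(
                {
                    "patient_id": patient,
                    "feature": feature,
                    "shift": shift,
                    "lambda": lam,
                    "center": center,
                    "scale": scale,
                }
            )
        blocks.append(block[list(ANNOTATION_COLUMNS) + kept])

    return PreprocessedTable(
        data=pd.concat(blocks, ignore_index=True),
        transforms=pd.DataFrame(records),
        dropped=dropped,
    )


def pca_embed(
    table: PreprocessedTable | pd.DataFrame,
    exclude_features: set[str] | Sequence[str] = (),
    n_components: int = 2,
):
    """Centered PCA scores on the preprocessed features.

    ``exclude_features`` supports cross-cohort comparisons where one staining
    channel differs between samples and every measurement based on it must be
    removed (substring match on channel names is the caller's job: pass the
    explicit column set).
    """
    if isinstance(table, PreprocessedTable):
        names = [f for f in table.feature_names if f not in set(exclude_features)]
        matrix = table.data[names].to_numpy(float)
    else:
        names = [c for c in table.columns if c not in set(exclude_features)]
        matrix = table[names].to_numpy(float)
    if len(names) < 2:
        raise ValueError("need at least 2 features after exclusion")
    pca = PCA(n_components=min(n_components, len(names)))
    scores = pca.fit_transform(matrix)
    return scores, pca.explained_variance_ratio_, pca


# --------------------------------------------------------------------------- #
# hierarchical clustering and branch-level cuts
# --------------------------------------------------------------------------- #


def cluster_cells(
    matrix: np.ndarray,
    metric: str = "euclidean",
    method: str = "complete",
) -> np.ndarray:
    """Agglomerative dendrogram (scipy linkage matrix) of the rows.

    Deterministic for a fixed row order; callers sort cells by stable ids
    before clustering so repeated runs agree byte-for-byte.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 cells to cluster")
    return linkage(matrix, method=method, metric=metric)


def cut_branch_level(dendrogram: np.ndarray, level: int) -> np.ndarray:
    """Cluster labels after ``level`` recursive splits of the root.

    Level 0 is a single cluster; each level splits every current cluster at
    its top merge (leaves cannot split), yielding at most 2^level clusters.
    Labels are 0-based consecutive integers ordered by the lowest leaf index
    in each cluster.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    z = np.asarray(dendrogram)
    n = z.shape[0] + 1

    def children(node: int) -> tuple[int, int] | None:
        if node < n:
            return None
        left, right = int(z[node - n, 0]), int(z[node - n, 1])
        return left, right

    clusters: list[int] = [2 * n - 2] if n > 1 else [0]
    for _ in range(level):
        nxt: list[int] = []
        for node in clusters:
            kids = children(node)
            if kids is None:
                nxt.append(node)
            else:
                nxt.extend(kids)
        clusters = nxt

    def leaves(node: int) -> list[int]:
        stack, out = [node], []
        while stack:
            cur = stack.pop()
            kids = children(cur)
            if kids is None:
                out.append(cur)
            else:
                stack.extend(kids)
        return out

    labels = np.empty(n, dtype=int)
    members = sorted((sorted(leaves(node)) for node in clusters), key=lambda m: m[0])
    for idx, leaf_set in enumerate(members):
        labels[leaf_set] = idx
    return labels


@dataclass
class ClusterAssignment:
    """Per-patient dendrograms and branch-level cluster labels."""

    level: int
    labels: pd.Series  # index aligned with the preprocessed table rows
    dendrograms: dict[str, np.ndarray] = field(default_factory=dict)


def assign_patient_clusters(
    table: PreprocessedTable,
    level: int = 3,
    metric: str = "euclidean",
    method: str = "complete",
) -> ClusterAssignment:
    """Cluster each patient's cells and cut at ``level`` (3rd-level branching
    defines cell clusters by default)."""
    labels = pd.Series(index=table.data.index, dtype=object)
    dendrograms: dict[str, np.ndarray] = {}
    for patient in pd.unique(table.data["patient_id"]):
        idx = table.data.index[table.data["patient_id"] == patient]
        matrix = table.data.loc[idx, table.feature_names].to_numpy(float)
        z = cluster_cells(matrix, metric=metric, method=method)
        dendrograms[patient] = z
        cut = cut_branch_level(z, level)
        labels.loc[idx] = [f"{patient}:{c}" for c in cut]
    return ClusterAssignment(level=level, labels=labels, dendrograms=dendrograms)


# --------------------------------------------------------------------------- #
# metaclustering
# --------------------------------------------------------------------------- #


@dataclass
class MetaclusterReport:
    """Main metaclusters ("clusters of clusters") and their composition."""

    cluster_means: pd.DataFrame  # one row per patient-cluster
    main_labels: pd.Series  # patient-cluster -> metacluster id (level-2 cut)
    sub_labels: pd.Series  # patient-cluster -> sublabel (level-3 cut)
    cell_labels: pd.Series  # per cell metacluster id
    composition: pd.DataFrame  # metacluster x (patients..., percent_of_cells)
    dendrogram: np.ndarray = None


def metacluster(
    assignment: ClusterAssignment,
    table: PreprocessedTable,
    main_level: int = 2,
    sub_level: int = 3,
    metric: str = "euclidean",
    method: str = "complete",
) -> MetaclusterReport:
    """Cluster per-patient cluster mean-profiles; cut at level 2 for the main
    metaclusters (level 3 for sublabels) and report the composition table."""
    df = table.data.copy()
    df["_cluster"] = assignment.labels
    means = (
        df.groupby("_cluster", sort=True)[table.feature_names].mean().sort_index()
    )
    if means.shape[0] < 2:
        raise ValueError("need at least 2 patient-clusters to metacluster")
    z = cluster_cells(means.to_numpy(float), metric=metric, method=method)
    main = cut_branch_level(z, main_level)
    sub = cut_branch_level(z, sub_level)
    main_labels = pd.Series(main, index=means.index, name="metacluster")
    sub_labels = pd.Series(sub, index=means.index, name="submetacluster")

    cell_labels = assignment.labels.map(main_labels)

    patients = list(pd.unique(df["patient_id"]))
    rows = []
    total = len(df)
    for mc in sorted(main_labels.unique()):
        cells = df[cell_labels == mc]
        row = {"metacluster": mc}
        for patient in patients:
            row[patient] = bool((cells["patient_id"] == patient).any())
        row["percent_of_cells"] = 100.0 * len(cells) / total
        rows.append(row)
    composition = pd.DataFrame(rows).set_index("metacluster")
    composition = composition.sort_values("percent_of_cells", ascending=False)

    return MetaclusterReport(
        cluster_means=means,
        main_labels=main_labels,
        sub_labels=sub_labels,
        cell_labels=cell_labels,
        composition=composition,
        dendrogram=z,
    )


# --------------------------------------------------------------------------- #
# concordance, ICC, tests, feature correlation
# --------------------------------------------------------------------------- #


def compartment_profiles(
    cohort: CohortTable, patient_id: str
) -> pd.DataFrame:
    """Min-max scale each raw feature over the patient's cells (features with
    zero range are dropped), then average per compartment: one profile per
    compartment over the retained features."""
    block = cohort.patient_block(patient_id)
    features = block[cohort.feature_names].to_numpy(float)
    lo, hi = np.nanmin(features, axis=0), np.nanmax(features, axis=0)
    keep = hi > lo
    scaled = (features[:, keep] - lo[keep]) / (hi[keep] - lo[keep])
    kept_names = [f for f, k in zip(cohort.feature_names, keep) if k]
    scaled_df = pd.DataFrame(scaled, columns=kept_names, index=block.index)
    scaled_df["compartment"] = block["compartment"].to_numpy()
    return scaled_df.groupby("compartment", sort=True).mean()


def concordance_r(cohort: CohortTable, patient_id: str) -> pd.DataFrame:
    """Pearson correlation matrix of the compartment profiles of one patient.

    A constant profile (zero variance over features) yields NaN entries with
    the reason recorded in ``DataFrame.attrs['missing']``.
    """
    profiles = compartment_profiles(cohort, patient_id)
    if profiles.shape[0] < 2:
        raise ValueError(f"patient {patient_id!r} has fewer than 2 compartments")
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 features with nonzero range")
    comps = list(profiles.index)
    out = pd.DataFrame(np.eye(len(comps)), index=comps, columns=comps)
    missing: list[str] = []
    for i, a in enumerate(comps):
        for j in range(i + 1, len(comps)):
            b = comps[j]
            pa, pb = profiles.loc[a].to_numpy(), profiles.loc[b].to_numpy()
            if pa.std() == 0 or pb.std() == 0:
                out.loc[a, b] = out.loc[b, a] = np.nan
                missing.append(f"{a}~{b}: constant profile")
            else:
                out.loc[a, b] = out.loc[b, a] = float(np.corrcoef(pa, pb)[0, 1])
    out.attrs["missing"] = missing
    return out


def icc_oneway(values: Sequence[float], groups: Sequence) -> float:
    """One-way random-effects intraclass correlation ICC(1).

    ICC(1) = (MSB - MSW) / (MSB + (k_bar - 1) MSW) with the unbalanced-design
    group-size correction k_bar = (N - sum(n_i^2)/N) / (a - 1). Returns NaN
    for degenerate input (zero total variance).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    uniq, inverse = np.unique(groups, return_inverse=True)
    a = len(uniq)
    n_total = len(values)
    if a < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(inverse)
    if counts.max() < 2:
        raise ValueError("need at least 2 observations in some group")
    grand = values.mean()
    if np.allclose(values, grand):
        return float("nan")
    group_means = np.array([values[inverse == g].mean() for g in range(a)])
    ss_between = float(np.sum(counts * (group_means - grand) ** 2))
    ss_within = float(np.sum((values - group_means[inverse]) ** 2))
    ms_between = ss_between / (a - 1)
    df_within = n_total - a
    ms_within = ss_within / df_within if df_within > 0 else float("nan")
    k_bar = (n_total - np.sum(counts**2) / n_total) / (a - 1)
    denom = ms_between + (k_bar - 1.0) * ms_within
    if denom == 0:
        return float("nan")
    return (ms_between - ms_within) / denom


def feature_tests(
    cohort: CohortTable,
    patient_id: str,
    group_a: str = "liquid",
    group_b: str | Sequence[str] = ("metastasis", "primary"),
) -> pd.DataFrame:
    """Per-feature two-tailed Welch t-tests between two compartment groups of
    one patient, with Benjamini-Hochberg adjusted p-values alongside.

    Zero variance on both sides with equal means gives p = 1 by convention.
    """
    from statsmodels.stats.multitest import multipletests

    block = cohort.patient_block(patient_id)
    groups_b = [group_b] if isinstance(group_b, str) else list(group_b)
    xa = block[block["compartment"] == group_a]
    xb = block[block["compartment"].isin(groups_b)]
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need at least 2 cells per side")
    rows = []
    for feature in cohort.feature_names:
        a = xa[feature].to_numpy(float)
        b = xb[feature].to_numpy(float)
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            t, p = (np.inf if a.mean() != b.mean() else 0.0), (
                0.0 if a.mean() != b.mean() else 1.0
            )
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "feature": feature,
                "mean_a": a.mean(),
                "mean_b": b.mean(),
                "t": float(t),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["p_bh"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def feature_correlation(
    cohort: CohortTable, method: str = "complete"
) -> pd.DataFrame:
    """Spearman correlation of features over all cells, rows/columns ordered
    by complete-linkage clustering of the distance 1 - |rho|."""
    names = cohort.feature_names
    if len(names) < 3:
        raise ValueError("need at least 3 features")
    matrix = cohort.data[names].to_numpy(float)
    rho, _ = stats.spearmanr(matrix)
    rho = np.atleast_2d(rho)
    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)
    from scipy.spatial.distance import squareform

    z = linkage(squareform(dist, checks=False), method=method)
    order = leaves_list(z)
    ordered = [names[i] for i in order]
    return pd.DataFrame(rho, index=names, columns=names).loc[ordered, ordered]
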