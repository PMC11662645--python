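"""Consensus k-means phenotypic profiling with within-cluster ordering.

Features are the 8 per-gene (screen x readout) medians of the biological-
replicate log2 relative-growth values.  SUBTEL and TEL columns are
half-weighted by scaling the values; genes with any missing feature are
dropped before clustering.  Cluster labels are aligned across repeated
k-means runs by maximal-overlap matching and each gene takes its most
frequent label; gene order within a cluster comes from hierarchical
agglomeration on Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from hetscreen import READOUTS, SCREENS
from hetscreen.errors import ConfigError, DegenerateDataError

DEFAULT_WEIGHTS = {"CEN": 1.0, "MAT": 1.0, "SUBTEL": 0.5, "TEL": 0.5}


@dataclass
class FeatureMatrix:
    genes: list[str]
    features: list[tuple[str, str]]  # (screen, readout)
    values: np.ndarray               # weighted values, genes x features
    weights: np.ndarray              # per-column weight actually applied
    dropped: pd.DataFrame            # gene, reason

    def frame(self) -> pd.DataFrame:
        cols = [f"{s}_{r}" for s, r in self.features]
        return pd.DataFrame(self.values, index=self.genes, columns=cols)


def build_feature_matrix(
    log2_bio: pd.DataFrame,
    genes: list[str] | None = None,
    weights: dict[str, float] | None = None,
    gene_col: str = "gene_name",
) -> FeatureMatrix:
    """Median-over-replicates feature matrix with column weighting.

    ``log2_bio`` is keyed by (gene, screen, readout, bio_rep) with a
    ``log2_value`` column.  Weighting multiplies each column by its screen
    weight (weight-by-scaling).
    """
    weights = DEFAULT_WEIGHTS if weights is None else weights
    med = (
        log2_bio.groupby([gene_col, "screen", "readout"], sort=False)["log2_value"]
        .median()
        .reset_index()
    )
    features = [(s, r) for s in SCREENS for r in READOUTS]
    wide = med.pivot_table(index=gene_col, columns=["screen", "readout"],
                           values="log2_value", dropna=False)
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(features))
    if genes is not None:
        wide = wide.reindex(index=genes)

    incomplete = wide.isna().any(axis=1)
    dropped = pd.DataFrame({"gene": wide.index[incomplete], "reason": "missing feature value"})
    wide = wide[~incomplete]
    if wide.empty:
        raise DegenerateDataError("all genes dropped: no complete feature rows")

    w = np.array([weights.get(s, 1.0) for s, _ in features], dtype=float)
    if np.any(w <= 0):
        raise ConfigError("feature weights must be positive")
    return FeatureMatrix(
        genes=list(wide.index),
        features=features,
        values=wide.to_numpy(dtype=float) * w,
        weights=w,
        dropped=dropped.reset_index(drop=True),
    )


def _align_labels(ref: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Relabel ``labels`` to maximize overlap with ``ref`` (Hungarian matching)."""
    overlap = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(k):
            overlap[i, j] = int(np.sum((labels == i) & (ref == j)))
    row, col = linear_sum_assignment(-overlap)
    mapping = dict(zip(row, col))
    return np.array([mapping[l] for l in labels])


def kmeans_consensus(
    matrix: FeatureMatrix | np.ndarray,
    k: int,
    n_runs: int = 20,
    seed: int = 0,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Repeated k-means with label alignment and majority-vote assignment.

    Runs k-means ``n_runs`` times with distinct sub-seeds, aligns each run's
    labels to the first run, and assigns each gene its most frequent aligned
    label (ties broken toward the lower cluster id).  Returns a DataFrame
    (gene, cluster, support) with 1-based cluster ids; deterministic given
    ``seed``.
    """
    if isinstance(matrix, FeatureMatrix):
        X, genes = matrix.values, matrix.genes
    else:
        X = np.asarray(matrix, dtype=float)
        genes = list(range(X.shape[0])) if genes is None else genes
    n = X.shape[0]
    if k < 1:
        raise ConfigError("k must be >= 1")
    if k > n:
        raise ConfigError(f"k={k} exceeds number of rows ({n})")
    if n_runs < 1:
        raise ConfigError("n_runs must be >= 1")

    sub_seeds = np.random.SeedSequence(seed).generate_state(n_runs)
    all_labels = np.empty((n_runs, n), dtype=int)
    for i, s in enumerate(sub_seeds):
        km = KMeans(n_clusters=k, n_init=10, random_state=int(s) % (2**32 - 1))
        all_labels[i] = km.fit_predict(X)
    ref = all_labels[0]
    for i in range(1, n_runs):
        all_labels[i] = _align_labels(ref, all_labels[i], k)

    votes = np.zeros((n, k), dtype=int)
    for i in range(n_runs):
        np.add.at(votes, (np.arange(n), all_labels[i]), 1)
    assigned = votes.argmax(axis=1)  # argmax takes the lowest index on ties
    support = votes[np.arange(n), assigned] / n_runs
    return pd.DataFrame({"gene": genes, "cluster": assigned + 1, "support": support})


def hierarchical_order(rows: np.ndarray, linkage: str = "complete") -> list[int]:
    """Dendrogram leaf order for one cluster's rows (Euclidean distance)."""
    X = np.atleast_2d(np.asarray(rows, dtype=float))
    if X.shape[0] == 0:
        raise DegenerateDataError("empty cluster")
    if X.shape[0] == 1:
        return [0]
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method=linkage)
    return list(hierarchy.leaves_list(Z))


def cluster_profiles(
    matrix: FeatureMatrix,
    k: int,
    n_runs: int = 20,
    seed: int = 0,
    linkage: str = "complete",
    overrides: dict[str, int] | None = None,
) -> dict:
    """Consensus k-means plus within-cluster hierarchical leaf orders.

    ``overrides`` maps gene -> cluster id for manual reassignment of
    ambiguous genes; overridden genes get support NaN.
    """
    assign = kmeans_consensus(matrix, k=k, n_runs=n_runs, seed=seed)
    if overrides:
        for gene, cid in overrides.items():
            if not 1 <= cid <= k:
                raise ConfigError(f"override cluster {cid} for {gene!r} out of range")
            sel = assign["gene"] == gene
            assign.loc[sel, "cluster"] = cid
            assign.loc[sel, "support"] = np.nan
    gene_idx = {g: i for i, g in enumerate(matrix.genes)}
    leaf_orders: dict[int, list[str]] = {}
    for cid, grp in assign.groupby("cluster"):
        members = grp["gene"].tolist()
        order = hierarchical_order(matrix.values[[gene_idx[g] for g in members]], linkage=linkage)
        leaf_orders[int(cid)] = [members[i] for i in order]
    return {"assignments": assign, "leaf_orders": leaf_orders, "dropped": matrix.dropped}
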