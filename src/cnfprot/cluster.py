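"""Hierarchical clustering of samples on protein profiles.

Samples are clustered agglomeratively with complete linkage (inter-cluster
distance = maximum pairwise distance, which makes merge heights monotone)
on Euclidean distances over log-transformed, optionally per-protein
z-scored, complete-case protein profiles. A two-cluster tissue-purity score
summarizes how cleanly tumors separate from the matched skin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator

from .io import ProteinQuantMatrix, SampleTable


@dataclass
class Dendrogram:
    """Binary merge tree over sample leaves (scipy linkage encoding)."""

    linkage: np.ndarray  # (n-1, 4): left, right, height, size
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage shape inconsistent with leaf count")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def cut(self, k: int) -> dict[str, int]:
        """Assign each leaf to one of k flat clusters."""
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.leaf_ids, labels.tolist()))

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.leaf_ids[i] for i in order]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        root = tree
        left = walk(root.left, root.dist)
        right = walk(root.right, root.dist)
        return f"({left},{right});"


def prepare_cluster_matrix(
    matrix: ProteinQuantMatrix, scaling: str = "zscore_log"
) -> pd.DataFrame:
    """Sample × protein grid: complete-case proteins, log scale, optional z-score."""
    if scaling not in ("zscore_log", "log_only"):
        raise ValueError(f"scaling must be 'zscore_log' or 'log_only', got {scaling!r}")
    complete = matrix.quantities.dropna(axis=0, how="any")
    if complete.shape[0] < 2:
        raise ValueError(
            f"need at least 2 complete-case proteins, got {complete.shape[0]}"
        )
    logq = np.log(complete)
    if scaling == "zscore_log":
        sd = logq.std(axis=1, ddof=0)
        sd = sd.replace(0.0, 1.0)  # constant proteins stay at 0 after centering
        logq = logq.sub(logq.mean(axis=1), axis=0).div(sd, axis=0)
    return logq.T  # samples x proteins


def cluster_samples(
    prepared: pd.DataFrame, linkage: str = "complete", metric: str = "euclidean"
) -> Dendrogram:
    """Agglomerative clustering of the prepared sample × protein grid."""
    if prepared.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    values = prepared.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in prepared matrix")
    dist = pdist(values, metric=metric)
    Z = hierarchy.linkage(dist, method=linkage)
    return Dendrogram(Z, list(prepared.index))


def tissue_bipartition_score(dendrogram: Dendrogram, samples: SampleTable) -> float:
    """Purity of the two-cluster cut with respect to tissue labels, in [0.5, 1]."""
    tissue = samples.data.set_index("sample_id")["tissue"]
    present = {t for s in dendrogram.leaf_ids for t in [tissue.get(s)]}
    if "cNF" not in present or "skin" not in present:
        raise ValueError("both tissues must be present among the clustered samples")
    assignment = dendrogram.cut(2)
    total = 0
    for cluster in set(assignment.values()):
        members = [s for s, c in assignment.items() if c == cluster]
        counts = tissue.loc[members].value_counts()
        total += int(counts.max())
    return total / dendrogram.n_leaves


def export_dendrogram(dendrogram: Dendrogram, path, format: str = "newick") -> None:
    """Write the tree as Newick (branch lengths = height differences) or a merge table."""
    if format == "newick":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(dendrogram.to_newick() + "\n")
    elif format == "merge_table":
        df = pd.DataFrame(
            dendrogram.linkage, columns=["left", "right", "height", "size"]
        )
        df["left"] = df["left"].astype(int)
        df["right"] = df["right"].astype(int)
        df["size"] = df["size"].astype(int)
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"format must be 'newick' or 'merge_table', got {format!r}")


def read_merge_table(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df[["left", "right", "height", "size"]].to_numpy(dtype=float)


class SampleClustering(BaseEstimator):
    """Complete-linkage sample clustering as a fit-style estimator.

    Parameters
    ----------
    scaling : {'zscore_log', 'log_only'}
    linkage : str
        Agglomeration rule; complete linkage by default.
    metric : str
        Pairwise distance metric on the prepared profiles.

    Attributes
    ----------
    dendrogram_ : Dendrogram
    labels_ : dict sample -> flat cluster at the two-cluster cut
    purity_ : float, tissue purity if a SampleTable was supplied to fit
    """

    def __init__(self, scaling: str = "zscore_log", linkage: str = "complete",
                 metric: str = "euclidean"):
        self.scaling = scaling
        self.linkage = linkage
        self.metric = metric

    def fit(self, X: ProteinQuantMatrix, y: SampleTable = None) -> "SampleClustering":
        prepared = prepare_cluster_matrix(X, self.scaling)
        self.dendrogram_ = cluster_samples(prepared, self.linkage, self.metric)
        self.labels_ = self.dendrogram_.cut(2)
        if y is not None:
            self.purity_ = tissue_bipartition_score(self.dendrogram_, y)
        return self


def cluster_per_patient(
    matrix: ProteinQuantMatrix,
    samples: SampleTable,
    scaling: str = "zscore_log",
    linkage: str = "complete",
    metric: str = "euclidean",
) -> dict[str, Dendrogram]:
    """Individual-wise clustering: one dendrogram per donor."""
    out = {}
    for pat in samples.patients:
        ids = list(
            samples.data.loc[samples.data["patient_id"] == pat, "sample_id"]
        )
        sub = matrix.subset_samples(ids)
        prepared = prepare_cluster_matrix(sub, scaling)
        out[pat] = cluster_samples(prepared, linkage, metric)
    return out
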