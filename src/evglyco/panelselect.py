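"""Lectin panel selection for the 3-group EV classification.

Two procedures: (i) agglomerative hierarchical clustering (Euclidean
distance, average linkage) of EV glycan profiles cut at two clusters, and
(ii) an exhaustive search over lectin subsets of size 3-5, each projected to
two principal components, ranked by inter-class distance under the
segregation criterion that the intra-class distance (largest mean
sample-to-own-center distance) stays below the inter-class distance
(smallest pairwise distance between class centers).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

__all__ = [
    "ALL_LECTINS",
    "CombinationReport",
    "hierarchical_two_cluster",
    "class_separation_2d",
    "select_panel",
]

ALL_LECTINS = ("ConA", "WGA", "RCA_I", "SBA", "UEA_I")


@dataclass
class CombinationReport:
    lectins: tuple
    intra: float
    inter: float
    feasible: bool
    scores_2d: np.ndarray
    centers: dict


def hierarchical_two_cluster(profiles: pd.DataFrame, columns=None,
                             method: str = "average") -> np.ndarray:
    """Cluster assignment (1 or 2) from bottom-up Euclidean clustering."""
    if columns is None:
        columns = [c for c in ALL_LECTINS if c in profiles.columns]
    X = profiles[list(columns)].to_numpy(dtype=float)
    if len(X) < 2:
        raise ValueError("need >= 2 samples to cluster")
    Z = linkage(X, method=method, metric="euclidean")
    return fcluster(Z, t=2, criterion="maxclust")


def class_separation_2d(X, labels, standardize: bool = True,
                        inter_aggregate: str = "min"):
    """(intra, inter) class distances after PCA to two components.

    intra: the largest, over classes, mean distance of samples to their own
    class center. inter: the smallest (or mean, by flag) pairwise distance
    between class centers. Rank-deficient input falls back to the available
    rank with a warning.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need >= 2 classes")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    n_comp = min(2, X.shape[1], len(X) - 1)
    if n_comp < 2:
        import warnings

        warnings.warn("input supports fewer than 2 principal components")
    Y = PCA(n_components=n_comp).fit_transform(X)
    centers = {c: Y[labels == c].mean(axis=0) for c in classes}
    intra = max(
        float(np.linalg.norm(Y[labels == c] - centers[c], axis=1).mean())
        for c in classes)
    pair_d = [float(np.linalg.norm(centers[a] - centers[b]))
              for a, b in combinations(classes, 2)]
    inter = float(min(pair_d) if inter_aggregate == "min" else np.mean(pair_d))
    return intra, inter, Y, centers


def select_panel(profiles: pd.DataFrame, label_col: str = "label",
                 lectins=None, min_size: int = 3, max_size: int = 5,
                 standardize: bool = True,
                 inter_aggregate: str = "min") -> list[CombinationReport]:
    """Evaluate every lectin subset of size min..max and rank the feasible
    ones by inter-class distance, descending. For 5 lectins at sizes 3-5
    exactly C(5,3)+C(5,4)+C(5,5) = 16 subsets are evaluated."""
    if lectins is None:
        lectins = [c for c in ALL_LECTINS if c in profiles.columns]
    if len(lectins) < min_size:
        raise ValueError(f"need >= {min_size} measured lectins")
    labels = profiles[label_col].to_numpy()
    reports = []
    for size in range(min_size, min(max_size, len(lectins)) + 1):
        for subset in combinations(lectins, size):
            X = profiles[list(subset)].to_numpy(dtype=float)
            intra, inter, Y, centers = class_separation_2d(
                X, labels, standardize=standardize,
                inter_aggregate=inter_aggregate)
            reports.append(CombinationReport(
                lectins=subset, intra=intra, inter=inter,
                feasible=intra < inter, scores_2d=Y, centers=centers))
    feasible = sorted((r for r in reports if r.feasible),
                      key=lambda r: -r.inter)
    infeasible = [r for r in reports if not r.feasible]
    if not feasible:
        import logging

        logging.getLogger(__name__).info(
            "no lectin combination satisfies the segregation criterion")
    return feasible + infeasible


def ranking_table(reports: list[CombinationReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {"lectins": ["+".join(r.lectins) for r in reports],
         "n_lectins": [len(r.lectins) for r in reports],
         "intra": [r.intra for r in reports],
         "inter": [r.inter for r in reports],
         "feasible": [r.feasible for r in reports]})
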