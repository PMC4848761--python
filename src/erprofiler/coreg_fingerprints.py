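"""Coregulator-peptide interaction fingerprints and their clustering.

A peptide-microarray experiment probes a receptor's coactivator-binding
surface with a library of LxxLL-motif peptides (MARCoNI-style, ~154
peptides, replicated). Each compound's fingerprint is the per-peptide
modulation index MI = log2(mean(compound) / mean(vehicle)); fingerprints
are compared by hierarchical agglomerative clustering, by default with
correlation distance (1 − Pearson r) and average linkage — the common
conventions for such arrays; both are configurable.

The agglomeration is implemented directly (naive O(n³)) so merge order is
fully deterministic, with ties broken by the lowest index pair; the merge
history uses the standard linkage-matrix encoding (scipy-compatible:
columns item_i, item_j, height, cluster size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


class FingerprintError(ValueError):
    pass


@dataclass
class FingerprintMatrix:
    """Compound × peptide modulation indices (replicates already averaged)."""

    compounds: list[str]
    peptides: list[str]
    values: pd.DataFrame
    replicate_count: int = 1

    def __post_init__(self) -> None:
        if len(self.compounds) < 2 or len(self.peptides) < 2:
            raise FingerprintError("need >= 2 compounds and >= 2 peptides")
        if self.replicate_count < 1:
            raise FingerprintError("replicate_count must be >= 1")
        if list(self.values.index) != self.compounds or list(self.values.columns) != self.peptides:
            raise FingerprintError("values frame does not match compound/peptide lists")


@dataclass
class ClusterTree:
    """Merge history (linkage matrix) and deterministic leaf order."""

    linkage: np.ndarray  # (n-1, 4) scipy-style
    labels: list[str]
    leaf_order: list[int] = field(default_factory=list)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> list[int]:
        """Flat cluster membership (0..k-1) from cutting the tree into k groups."""
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(self.linkage, t=k, criterion="maxclust")
        return [int(x) - 1 for x in labels]


def modulation_index(
    compound_signals: Sequence[float], vehicle_signals: Sequence[float]
) -> float:
    """MI = log2(mean(compound)/mean(vehicle)); replicates averaged first.

    Signals are fluorescence-scale and must have positive means.
    """
    c = np.asarray(compound_signals, dtype=float)
    v = np.asarray(vehicle_signals, dtype=float)
    if c.size < 1 or v.size < 1:
        raise FingerprintError("need >= 1 replicate per condition")
    mc, mv = float(np.mean(c)), float(np.mean(v))
    if mc <= 0 or mv <= 0:
        raise FingerprintError(f"non-positive mean signal: compound {mc}, vehicle {mv}")
    return float(np.log2(mc / mv))


def fingerprint_from_signals(
    signals: pd.DataFrame, vehicle: str, replicate_col: str | None = "replicate"
) -> FingerprintMatrix:
    """Build an MI matrix from a long table (compound, peptide[, replicate], signal).

    The vehicle compound's rows define the per-peptide reference means; the
    vehicle itself is dropped from the output (its MI is identically 0).
    """
    required = {"compound", "peptide", "signal"}
    if not required.issubset(signals.columns):
        raise FingerprintError(f"long table needs columns {sorted(required)}")
    reps = signals.groupby(["compound", "peptide"])["signal"]
    n_rep = int(reps.size().max())
    means = reps.mean().unstack("peptide")
    if vehicle not in means.index:
        raise FingerprintError(f"vehicle compound {vehicle!r} absent")
    veh = means.loc[vehicle]
    if (means <= 0).any().any():
        raise FingerprintError("non-positive mean signal encountered")
    mi = np.log2(means.div(veh, axis=1)).drop(index=vehicle)
    return FingerprintMatrix(
        compounds=list(mi.index), peptides=list(mi.columns),
        values=mi, replicate_count=n_rep,
    )


def _distance_matrix(X: np.ndarray, metric: str) -> np.ndarray:
    if metric == "correlation":
        if np.any(np.ptp(X, axis=1) == 0):
            raise FingerprintError("constant row: correlation distance undefined")
        return squareform(pdist(X, metric="correlation"))
    if metric == "euclidean":
        return squareform(pdist(X, metric="euclidean"))
    raise FingerprintError(f"unknown metric {metric!r} (use 'correlation' or 'euclidean')")


def hierarchical_cluster(
    matrix: FingerprintMatrix,
    axis: str = "compounds",
    metric: str = "correlation",
    linkage: str = "average",
) -> ClusterTree:
    """Agglomerative clustering of compounds or peptides.

    Deterministic: at each step the pair at minimal linkage distance is
    merged, ties broken by the lowest (i, j) index pair; average / single /
    complete linkage update rules. Leaf order follows the merge history
    (left subtree = earlier-created cluster).
    """
    if axis == "compounds":
        X = matrix.values.to_numpy(dtype=float)
        labels = list(matrix.compounds)
    elif axis == "peptides":
        X = matrix.values.to_numpy(dtype=float).T
        labels = list(matrix.peptides)
    else:
        raise FingerprintError(f"axis must be 'compounds' or 'peptides', got {axis!r}")
    if np.isnan(X).any():
        raise FingerprintError("missing values on the clustered axis; mask rows first")
    n = X.shape[0]
    if n < 2:
        raise FingerprintError("need >= 2 items to cluster")

    D = _distance_matrix(X, metric)
    if linkage not in ("average", "single", "complete"):
        raise FingerprintError(f"unknown linkage {linkage!r}")

    # naive deterministic agglomeration; clusters keyed by scipy-style ids
    active: dict[int, list[int]] = {i: [i] for i in range(n)}  # id -> member leaves
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    Z = np.zeros((n - 1, 4))
    children: dict[int, tuple[int, int]] = {}
    next_id = n
    for step in range(n - 1):
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        members = active[i] + active[j]
        # linkage update against every other active cluster
        new_dist = {}
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            if linkage == "single":
                d = min(dik, djk)
            elif linkage == "complete":
                d = max(dik, djk)
            else:  # average (UPGMA)
                ni, nj = len(active[i]), len(active[j])
                d = (ni * dik + nj * djk) / (ni + nj)
            new_dist[(k, next_id)] = d
        del active[i], active[j]
        dist = {
            (a, b): v for (a, b), v in dist.items() if a not in (i, j) and b not in (i, j)
        }
        dist.update(new_dist)
        active[next_id] = members
        Z[step] = [i, j, h, len(members)]
        children[next_id] = (i, j)
        next_id += 1

    def leaves(cid: int) -> list[int]:
        if cid < n:
            return [cid]
        a, b = children[cid]
        return leaves(a) + leaves(b)

    return ClusterTree(linkage=Z, labels=labels, leaf_order=leaves(next_id - 1))


def linkage_table(tree: ClusterTree) -> str:
    """Merge-history TSV (standard linkage table) plus the leaf order."""
    lines = ["cluster_i\tcluster_j\theight\tsize"]
    for row in tree.linkage:
        lines.append(f"{int(row[0])}\t{int(row[1])}\t{row[2]!r}\t{int(row[3])}")
    ordered = ",".join(tree.labels[i] for i in tree.leaf_order)
    lines.append(f"# leaf_order\t{ordered}")
    return "\n".join(lines) + "\n"
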