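"""Co-cluster mean models, their two-state restriction, and ANOVA R².

Given a row (locus) clustering and a column (cell-type) partition, the grid
of co-clusters approximates the binary matrix M by replacing each co-cluster
with its mean (the model M~).  A more restrictive two-state model forces the
co-clusters of one locus cluster to share one of two values, representing an
inaccessible and an accessible chromatin state; the optimal value pair and
state assignment are an exact 1-D weighted 2-means, found by scanning the
k-1 contiguous splits of the sorted co-cluster means.

The ANOVA decomposition reports, per locus cluster, the fraction of total
variation captured by the model (R²_total) and the fraction of cell-type
associated variation — the variation of the column means — captured by the
column clustering (R²_celltype); overall values are unweighted averages
across locus clusters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CoClusterModel",
    "TwoStateModel",
    "AccessibilityCoCluster",
    "AnovaResult",
    "fit_means",
    "fit_two_state",
    "accessibility_coclusters",
    "anova",
]


def _group_indices(labels: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    ids = np.unique(labels)
    return ids, [np.nonzero(labels == g)[0] for g in ids]


@dataclass
class CoClusterModel:
    """Grid of co-cluster means m[j, i], locus cluster j x cell cluster i."""

    means: np.ndarray
    row_cluster_ids: np.ndarray
    row_counts: np.ndarray       # rows per locus cluster
    col_counts: np.ndarray       # columns per cell cluster

    def values_for(self, j_index: int) -> np.ndarray:
        return self.means[j_index]

    def expand(self, row_labels: np.ndarray, col_labels: np.ndarray) -> np.ndarray:
        """Full-size approximation M~ with each entry its co-cluster mean."""
        rpos = np.searchsorted(self.row_cluster_ids, row_labels)
        return self.means[np.ix_(rpos, np.asarray(col_labels))]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("locus_cluster\t" + "\t".join(
                f"cell_cluster_{i}" for i in range(self.means.shape[1])) + "\n")
            for j, row in zip(self.row_cluster_ids, self.means):
                fh.write(str(j) + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def fit_means(M_rows: np.ndarray, row_labels: np.ndarray,
              col_labels: np.ndarray) -> CoClusterModel:
    """Co-cluster means: m[j, i] = mean of entries in locus cluster j x cell cluster i."""
    M = np.asarray(M_rows, dtype=np.float64)
    row_labels = np.asarray(row_labels)
    col_labels = np.asarray(col_labels)
    rids, rgroups = _group_indices(row_labels)
    cids, cgroups = _group_indices(col_labels)
    if not np.array_equal(cids, np.arange(len(cids))):
        raise ValueError("column labels must be 0..k-1")
    means = np.empty((len(rids), len(cids)))
    for a, ridx in enumerate(rgroups):
        sub = M[ridx]
        for b, cidx in enumerate(cgroups):
            means[a, b] = sub[:, cidx].mean()
    return CoClusterModel(means=means, row_cluster_ids=rids,
                          row_counts=np.array([len(g) for g in rgroups]),
                          col_counts=np.array([len(g) for g in cgroups]))


@dataclass
class TwoStateModel:
    """Two-level restriction of a co-cluster model.

    Per locus cluster j: low value a0[j], high value a1[j] (a0 <= a1) and a
    boolean accessible-state flag per cell cluster.  Degenerate locus
    clusters (all co-cluster means equal) have a0 == a1 and every state
    inaccessible, and are flagged.
    """

    a0: np.ndarray
    a1: np.ndarray
    states: np.ndarray           # bool (J, k): True = accessible
    row_cluster_ids: np.ndarray
    degenerate: np.ndarray       # bool per locus cluster

    def values(self) -> np.ndarray:
        """Per-co-cluster fitted values on the (J, k) grid."""
        return np.where(self.states, self.a1[:, None], self.a0[:, None])

    def expand(self, row_labels: np.ndarray, col_labels: np.ndarray) -> np.ndarray:
        rpos = np.searchsorted(self.row_cluster_ids, row_labels)
        return self.values()[np.ix_(rpos, np.asarray(col_labels))]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("locus_cluster\ta0\ta1\tstates\n")
            for i, j in enumerate(self.row_cluster_ids):
                st = "".join("a" if s else "i" for s in self.states[i])
                fh.write(f"{j}\t{self.a0[i]:.6g}\t{self.a1[i]:.6g}\t{st}\n")


def _best_split(means: np.ndarray, weights: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Exact weighted 1-D 2-means over co-cluster means.

    Scans the k-1 contiguous split points of the sorted means; ties prefer
    fewer clusters in the high state.  Returns (a0, a1, accessible_mask).
    """
    k = len(means)
    order = np.argsort(means, kind="stable")
    v = means[order]
    w = weights[order].astype(np.float64)
    if v[0] == v[-1]:
        return float(v.mean()), float(v.mean()), np.zeros(k, dtype=bool)
    best = (np.inf, None)
    for t in range(1, k):  # low group = first t sorted means
        wl, wh = w[:t], w[t:]
        vl, vh = v[:t], v[t:]
        a0 = float((wl * vl).sum() / wl.sum())
        a1 = float((wh * vh).sum() / wh.sum())
        sse = float((wl * (vl - a0) ** 2).sum() + (wh * (vh - a1) ** 2).sum())
        # <= : among ties keep the largest t, i.e. fewest clusters accessible
        if sse <= best[0] + 1e-15:
            best = (sse, (t, a0, a1))
    t, a0, a1 = best[1]
    acc = np.zeros(k, dtype=bool)
    acc[order[t:]] = True
    return a0, a1, acc


def fit_two_state(model: CoClusterModel) -> TwoStateModel:
    """SSE-optimal two-state restriction of each locus cluster's means.

    Weights are co-cluster entry counts, so the fitted values are the
    entry-weighted means of the member co-clusters and the solution equals
    the brute-force optimum over all two-state assignments.
    """
    J, k = model.means.shape
    a0 = np.empty(J)
    a1 = np.empty(J)
    states = np.zeros((J, k), dtype=bool)
    degenerate = np.zeros(J, dtype=bool)
    for j in range(J):
        weights = model.row_counts[j] * model.col_counts
        lo, hi, acc = _best_split(model.means[j], weights)
        a0[j], a1[j], states[j] = lo, hi, acc
        degenerate[j] = not acc.any()
    return TwoStateModel(a0=a0, a1=a1, states=states,
                         row_cluster_ids=model.row_cluster_ids,
                         degenerate=degenerate)


@dataclass
class AccessibilityCoCluster:
    """A locus cluster paired with the cell types in its accessible state."""

    locus_cluster: int
    cell_clusters: list[int]
    cell_types: frozenset[str]
    degenerate: bool = False


def accessibility_coclusters(two_state: TwoStateModel,
                             col_labels: np.ndarray,
                             cell_types: list[str]) -> list[AccessibilityCoCluster]:
    """One record per locus cluster: union of cell types over accessible clusters."""
    col_labels = np.asarray(col_labels)
    cells = np.asarray(cell_types)
    out = []
    for i, j in enumerate(two_state.row_cluster_ids):
        acc_clusters = np.nonzero(two_state.states[i])[0]
        members = frozenset(cells[np.isin(col_labels, acc_clusters)])
        out.append(AccessibilityCoCluster(
            locus_cluster=int(j), cell_clusters=[int(c) for c in acc_clusters],
            cell_types=members, degenerate=not len(acc_clusters)))
    return out


@dataclass
class AnovaResult:
    row_cluster_ids: np.ndarray
    mu: np.ndarray
    r2_total: np.ndarray
    r2_celltype: np.ndarray
    constant_flagged: np.ndarray

    @property
    def overall_r2_total(self) -> float:
        return float(self.r2_total.mean())

    @property
    def overall_r2_celltype(self) -> float:
        return float(self.r2_celltype.mean())

    def to_json(self, path=None):
        obj = {
            "per_locus_cluster": [
                {"cluster": int(j), "mu": float(m), "r2_total": float(a),
                 "r2_celltype": float(b)}
                for j, m, a, b in zip(self.row_cluster_ids, self.mu,
                                      self.r2_total, self.r2_celltype)
            ],
            "overall_r2_total": self.overall_r2_total,
            "overall_r2_celltype": self.overall_r2_celltype,
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=1)
        return obj


def anova(M_rows: np.ndarray, row_labels: np.ndarray, col_labels: np.ndarray,
          model: CoClusterModel | TwoStateModel) -> AnovaResult:
    """Per-locus-cluster R²_total and R²_celltype of a fitted co-cluster model.

    R²_total compares the full model expansion to M; R²_celltype compares
    the predicted co-cluster value of each column to the column's mean
    within the locus cluster.  A zero denominator (constant sub-matrix or
    constant column means) yields R² = 1 and a flag.
    """
    M = np.asarray(M_rows, dtype=np.float64)
    row_labels = np.asarray(row_labels)
    col_labels = np.asarray(col_labels)
    values = model.means if isinstance(model, CoClusterModel) else model.values()
    rids = model.row_cluster_ids
    J = len(rids)
    mu = np.empty(J)
    r2_tot = np.empty(J)
    r2_cell = np.empty(J)
    flagged = np.zeros(J, dtype=bool)
    for a, j in enumerate(rids):
        sub = M[row_labels == j]
        mu[a] = sub.mean()
        pred_cols = values[a][col_labels]          # predicted value per column
        sse = ((sub - pred_cols[None, :]) ** 2).sum()
        sst = ((sub - mu[a]) ** 2).sum()
        if sst == 0:
            r2_tot[a] = 1.0
            flagged[a] = True
        else:
            r2_tot[a] = 1.0 - sse / sst
        colmeans = sub.mean(axis=0)
        num = ((colmeans - pred_cols) ** 2).sum()
        den = ((colmeans - mu[a]) ** 2).sum()
        if den == 0:
            r2_cell[a] = 1.0
            flagged[a] = True
        else:
            r2_cell[a] = 1.0 - num / den
    return AnovaResult(row_cluster_ids=np.asarray(rids), mu=mu, r2_total=r2_tot,
                       r2_celltype=r2_cell, constant_flagged=flagged)
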