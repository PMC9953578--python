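"""Sørensen dissimilarities, Ward clustering and elevation x period groups."""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def sorensen_matrix(incidence: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Sørensen dissimilarity (b+c)/(2a+b+c) of binary rows.

    Equals Bray-Curtis on presence/absence data.  A pair of all-empty rows
    has no defined dissimilarity; it is set to 0 with a warning.
    """
    vals = np.asarray(incidence, dtype=float)
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("incidence matrix must be binary (0/1)")
    a = vals @ vals.T  # shared species
    totals = vals.sum(axis=1)
    denom = totals[:, None] + totals[None, :]  # 2a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(denom > 0, 2.0 * a / denom, 1.0)
    empty_pairs = denom == 0
    np.fill_diagonal(empty_pairs, False)
    if empty_pairs.any():
        logger.warning(
            "sorensen_matrix: %d unit pair(s) share no species at all; "
            "dissimilarity set to 0", int(empty_pairs.sum()) // 2,
        )
        d[empty_pairs] = 0.0
    np.fill_diagonal(d, 0.0)
    ids = list(incidence.index)
    return pd.DataFrame(d, index=ids, columns=ids)


def check_dissimilarity(d: pd.DataFrame) -> np.ndarray:
    arr = np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-10):
        raise ValueError("dissimilarity matrix must have zero diagonal")
    return arr


@dataclasses.dataclass
class Dendrogram:
    """Agglomeration result in scipy linkage layout.

    ``merges`` has one row per merge: (cluster_i, cluster_j, height, size)
    with leaves numbered ``0..n-1`` and merge ``k`` creating cluster
    ``n + k``.  Heights are reported exactly as produced by the chosen Ward
    variant (square-rooted for ``ward_d2``).
    """

    merges: np.ndarray
    labels: list[str]
    variant: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2].copy()

    def to_newick(self) -> str:
        """Ultrametric Newick string; leaf depth is half the merge height."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for k, (i, j, h, _s) in enumerate(self.merges):
            i, j = int(i), int(j)
            hi, hj = height[i], height[j]
            bi = (h - hi) / 2.0
            bj = (h - hj) / 2.0
            node[n + k] = f"({node[i]}:{bi:.10g},{node[j]}:{bj:.10g})"
            height[n + k] = h
        return node[n + len(self.merges) - 1] + ";"


def ward_cluster(dissim: pd.DataFrame, variant: str = "ward_d") -> Dendrogram:
    """Ward minimum-variance agglomeration via Lance-Williams updates.

    ``ward_d`` applies the Ward update directly to the dissimilarities;
    ``ward_d2`` applies it to squared dissimilarities and reports
    square-rooted merge heights.  Ties are broken by the smallest (i, j)
    pair in current-cluster index order, so results are reproducible.
    """
    if variant not in ("ward_d", "ward_d2"):
        raise ValueError(f"unknown Ward variant {variant!r}")
    arr = check_dissimilarity(dissim)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least two units")
    d = arr.copy() if variant == "ward_d" else arr**2

    active = list(range(n))
    size = {i: 1 for i in range(n)}
    # current working matrix indexed by cluster id
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (min(i, j), max(i, j))
                val = dist[key]
                if best is None or val < best[0] - 1e-15:
                    best = (val, i, j)
        val, i, j = best
        ni, nj = size[i], size[j]
        new = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            nk = size[k]
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dij = val
            upd = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
            dist[(k, new)] = upd
        active = [k for k in active if k not in (i, j)] + [new]
        size[new] = ni + nj
        h = val if variant == "ward_d" else np.sqrt(val)
        merges[step] = (i, j, h, size[new])
    return Dendrogram(
        merges=merges, labels=[str(x) for x in dissim.index], variant=variant
    )


def cut_tree(dendrogram: Dendrogram, height: float) -> pd.Series:
    """Cluster labels after removing merges with height above the cut.

    Clusters are labeled ``A``, ``B``, ... in order of first appearance
    along the leaf order of the input.
    """
    if height < 0:
        raise ValueError("cut height must be non-negative")
    n = dendrogram.n_leaves
    parent = list(range(n + len(dendrogram.merges)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (i, j, h, _s) in enumerate(dendrogram.merges):
        if h <= height:
            for child in (int(i), int(j)):
                parent[find(child)] = find(n + k)
        # cluster node still exists as its own root otherwise

    roots: dict[int, str] = {}
    labels = []
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = chr(ord("A") + len(roots))
        labels.append(roots[r])
    return pd.Series(labels, index=dendrogram.labels, name="cluster")


@dataclasses.dataclass
class ClusterGroups:
    """Elevation-cluster, period, and crossed group labels per unit."""

    table: pd.DataFrame  # index unit id; columns cluster, period, group
    summary: pd.DataFrame  # per crossed group: size, median elevation

    @property
    def group(self) -> pd.Series:
        return self.table["group"]


def cross_with_period(
    labels: pd.Series,
    units: pd.DataFrame,
    periods: Mapping[str, tuple[int, ...]] | None = None,
) -> ClusterGroups:
    """Cross elevation-cluster labels with the sampling period of each unit.

    ``units`` must carry ``year`` and ``mean_elev`` columns indexed by unit
    id (see :meth:`records.IncidenceMatrix.unit_table`).
    """
    periods = periods or {"1935/1936": (1935, 1936), "2020": (2020,)}
    year_to_period = {y: p for p, ys in periods.items() for y in ys}
    rows = []
    for uid, cluster in labels.items():
        year = int(units.loc[uid, "year"])
        if year not in year_to_period:
            raise ValueError(f"unit {uid}: year {year} not in a declared period")
        period = year_to_period[year]
        rows.append(
            {
                "id": uid,
                "cluster": cluster,
                "period": period,
                "group": f"{period} {cluster}",
                "mean_elev": float(units.loc[uid, "mean_elev"]),
            }
        )
    table = pd.DataFrame(rows).set_index("id")
    summary = (
        table.groupby("group")
        .agg(n_units=("cluster", "size"), median_elev=("mean_elev", "median"))
        .reset_index()
    )
    cluster_summary = (
        table.groupby("cluster")["mean_elev"].median().rename("median_elev")
    )
    logger.info(
        "cross_with_period: cluster median elevations: %s",
        cluster_summary.to_dict(),
    )
    return ClusterGroups(table=table[["cluster", "period", "group"]], summary=summary)
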