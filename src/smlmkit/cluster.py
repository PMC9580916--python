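"""Density-based clustering (DBSCAN) of localization point clouds.

A point is *core* when at least ``min_points`` localizations (the point
itself included, by the standard convention — configurable) lie within
radius eps; *edge* when not core but within eps of a core point; *noise*
otherwise.  Clusters are the connected components of the core-core
adjacency graph, with edge points attached to an adjacent core's cluster.
Frames are ignored: clustering pools localizations over the whole movie.

Label assignment is fully deterministic: components are numbered by the
smallest row index they contain, and an edge point adjacent to several
clusters joins the lowest-labeled one.  The classic order-dependence of
DBSCAN edge assignment is thereby removed.  Expansion uses an iterative
worklist (equivalent to the textbook recursion, without stack limits).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_io import LocalizationTable

__all__ = ["DbscanParams", "ClusterResult", "dbscan", "summarize_clusters"]

NOISE = -1


@dataclass(frozen=True)
class DbscanParams:
    """``eps``: neighbourhood radius, in the unit given by ``unit``
    ('px' or 'nm'; nm uses the table's pixel size); ``min_points``: minimum
    neighbour count to form a core point; ``count_self``: whether the point
    itself counts towards min_points (standard DBSCAN does)."""

    eps: float
    min_points: int
    unit: str = "px"
    count_self: bool = True

    def __post_init__(self) -> None:
        if not self.eps > 0:
            raise ValueError("eps must be > 0")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")
        if self.unit not in ("px", "nm"):
            raise ValueError("unit must be 'px' or 'nm'")


@dataclass
class ClusterResult:
    """Per-localization cluster label (>= 0, or -1 for noise) and role
    ('core' / 'edge' / 'noise'); ``unit`` records the distance unit used."""

    labels: np.ndarray
    roles: np.ndarray
    n_clusters: int
    unit: str


def dbscan(table: LocalizationTable, params: DbscanParams) -> ClusterResult:
    pts = table.xy()
    if params.unit == "nm":
        pts = pts * table.pixel_size_nm
    n = len(pts)
    if n == 0:
        return ClusterResult(np.empty(0, dtype=np.int64), np.empty(0, dtype=object), 0, params.unit)

    tree = cKDTree(pts)
    neighbors = tree.query_ball_point(pts, params.eps)  # includes the point itself
    counts = np.array([len(nb) for nb in neighbors])
    if not params.count_self:
        counts = counts - 1
    core = counts >= params.min_points

    labels = np.full(n, NOISE, dtype=np.int64)
    label = 0
    for start in range(n):
        if not core[start] or labels[start] != NOISE:
            continue
        # BFS over core points reachable from `start`
        labels[start] = label
        queue = deque([start])
        while queue:
            p = queue.popleft()
            for q in neighbors[p]:
                if core[q] and labels[q] == NOISE:
                    labels[q] = label
                    queue.append(q)
        label += 1

    roles = np.full(n, "noise", dtype=object)
    roles[core] = "core"
    # edge points: non-core within eps of a core point -> lowest adjacent label
    for i in range(n):
        if core[i]:
            continue
        adj = [labels[q] for q in neighbors[i] if core[q]]
        if adj:
            labels[i] = min(adj)
            roles[i] = "edge"
    return ClusterResult(labels, roles, label, params.unit)


def summarize_clusters(result: ClusterResult, table: LocalizationTable) -> pd.DataFrame:
    """Per-cluster point count, centroid, radius of gyration and bounding
    box (noise excluded), in the unit the clustering used."""
    if len(result.labels) != len(table):
        raise ValueError("result does not align with table")
    pts = table.xy()
    if result.unit == "nm":
        pts = pts * table.pixel_size_nm
    rows = []
    for cid in range(result.n_clusters):
        sel = result.labels == cid
        p = pts[sel]
        centroid = p.mean(axis=0)
        rg = float(np.sqrt(np.mean(np.sum((p - centroid) ** 2, axis=1))))
        rows.append(
            {
                "cluster": cid,
                "n_points": int(sel.sum()),
                "centroid_x": centroid[0],
                "centroid_y": centroid[1],
                "radius_of_gyration": rg,
                "xmin": p[:, 0].min(), "xmax": p[:, 0].max(),
                "ymin": p[:, 1].min(), "ymax": p[:, 1].max(),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cluster", "n_points", "centroid_x", "centroid_y",
                 "radius_of_gyration", "xmin", "xmax", "ymin", "ymax"],
    )
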