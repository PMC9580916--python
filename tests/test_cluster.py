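"""DBSCAN: oracle equivalence, determinism, monotonicity, summaries."""

import numpy as np
import pytest

import smlmkit as sk
from smlmkit.cluster import DbscanParams, dbscan, summarize_clusters


def table_of(points):
    pts = np.atleast_2d(points)
    return sk.LocalizationTable.from_arrays(np.zeros(len(pts), int), pts[:, 0], pts[:, 1])


def brute_force_oracle(points, eps, min_points, count_self=True):
    """Independent reference: dense neighbour matrix + BFS over core points
    (components in row order), then edge attachment to the lowest adjacent
    label."""
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    adj = d <= eps
    counts = adj.sum(axis=1) if count_self else adj.sum(axis=1) - 1
    core = counts >= min_points
    labels = np.full(n, -1)
    label = 0
    for s in range(n):
        if not core[s] or labels[s] != -1:
            continue
        stack = [s]
        labels[s] = label
        while stack:
            p = stack.pop()
            for q in range(n):
                if adj[p, q] and core[q] and labels[q] == -1:
                    labels[q] = label
                    stack.append(q)
        label += 1
    roles = np.where(core, "core", "noise").astype(object)
    for i in range(n):
        if core[i]:
            continue
        adj_labels = [labels[q] for q in range(n) if adj[i, q] and core[q]]
        if adj_labels:
            labels[i] = min(adj_labels)
            roles[i] = "edge"
    return labels, roles


def test_three_mutual_neighbours_one_cluster():
    res = dbscan(table_of([(0, 0), (0.5, 0), (0, 0.5)]), DbscanParams(1.0, 3))
    assert (res.labels == 0).all()
    assert (res.roles == "core").all()
    assert res.n_clusters == 1


def test_isolated_point_is_noise():
    res = dbscan(table_of([(0, 0)]), DbscanParams(1.0, 2))
    assert res.labels.tolist() == [-1]
    assert res.roles.tolist() == ["noise"]


def test_edge_point_classification():
    # three mutually close core points + one boundary point with a single
    # core neighbour (too few neighbours to be core itself)
    pts = [(0, 0), (0.5, 0), (0.25, 0.4), (1.4, 0)]
    res = dbscan(table_of(pts), DbscanParams(1.0, 3))
    assert res.roles.tolist() == ["core", "core", "core", "edge"]
    assert res.labels.tolist() == [0, 0, 0, 0]


def test_empty_table():
    res = dbscan(sk.LocalizationTable.empty(), DbscanParams(1.0, 3))
    assert res.n_clusters == 0
    assert len(res.labels) == 0


@pytest.mark.parametrize("trial", range(20))
def test_oracle_equivalence_random_instances(trial):
    rng = np.random.default_rng(trial)
    n = int(rng.integers(50, 200))
    pts = rng.uniform(0, 10, size=(n, 2))
    eps = float(rng.uniform(0.2, 1.2))
    min_points = int(rng.integers(2, 8))
    res = dbscan(table_of(pts), DbscanParams(eps, min_points))
    labels, roles = brute_force_oracle(pts, eps, min_points)
    assert res.labels.tolist() == labels.tolist()
    assert res.roles.tolist() == roles.tolist()


def test_agreement_with_sklearn_partition():
    # independent cross-check: sklearn's DBSCAN agrees on the partition into
    # clusters and the core/noise sets (sklearn labels border points as part
    # of a cluster but does not expose the core/edge distinction directly)
    sklearn = pytest.importorskip("sklearn.cluster")
    rng = np.random.default_rng(42)
    pts = np.vstack([rng.normal(c, 0.2, size=(40, 2)) for c in ((2, 2), (6, 6), (2, 7))]
                    + [rng.uniform(0, 9, size=(20, 2))])
    eps, mp = 0.5, 5
    ours = dbscan(table_of(pts), DbscanParams(eps, mp))
    ref = sklearn.DBSCAN(eps=eps, min_samples=mp).fit(pts)
    core_ref = np.zeros(len(pts), bool)
    core_ref[ref.core_sample_indices_] = True
    assert ((ours.roles == "core") == core_ref).all()
    assert ((ours.labels == -1) == (ref.labels_ == -1)).all()
    # same partition up to relabeling, for points labelled by both
    both = ours.labels >= 0
    pairs = set(zip(ours.labels[both].tolist(), ref.labels_[both].tolist()))
    assert len(pairs) == ours.n_clusters


def test_permutation_changes_only_labels_not_partition(rng):
    pts = rng.uniform(0, 5, size=(120, 2))
    perm = rng.permutation(len(pts))
    a = dbscan(table_of(pts), DbscanParams(0.5, 4))
    b = dbscan(table_of(pts[perm]), DbscanParams(0.5, 4))
    # roles are a pointwise property: invariant under permutation
    assert a.roles[perm].tolist() == b.roles.tolist()
    # cluster partition identical up to label renaming for core points
    core = a.roles[perm] == "core"
    mapping = {}
    for la, lb in zip(a.labels[perm][core], b.labels[core]):
        assert mapping.setdefault(la, lb) == lb


def test_increasing_eps_preserves_core_points(rng):
    pts = rng.uniform(0, 5, size=(150, 2))
    core1 = dbscan(table_of(pts), DbscanParams(0.4, 4)).roles == "core"
    core2 = dbscan(table_of(pts), DbscanParams(0.7, 4)).roles == "core"
    assert (core2 | ~core1).all()  # core1 implies core2


def test_count_self_flag():
    pts = [(0, 0), (0.5, 0)]
    with_self = dbscan(table_of(pts), DbscanParams(1.0, 2, count_self=True))
    without = dbscan(table_of(pts), DbscanParams(1.0, 2, count_self=False))
    assert (with_self.roles == "core").all()
    assert (without.roles == "noise").all()


def test_nm_unit_uses_pixel_size():
    t = sk.LocalizationTable.from_arrays([0, 0], [0.0, 0.3], [0.0, 0.0], pixel_size_nm=100.0)
    res_nm = dbscan(t, DbscanParams(50.0, 2, unit="nm"))  # 0.3 px = 30 nm <= 50 nm
    assert (res_nm.roles == "core").all()
    res_nm2 = dbscan(t, DbscanParams(20.0, 2, unit="nm"))
    assert (res_nm2.roles == "noise").all()


class TestSummary:
    def test_unit_square_cluster_closed_form(self):
        pts = [(0, 0), (1, 0), (0, 1), (1, 1)]
        res = dbscan(table_of(pts), DbscanParams(1.5, 2))
        summary = summarize_clusters(res, table_of(pts))
        assert len(summary) == 1
        row = summary.iloc[0]
        assert row["n_points"] == 4
        assert row["centroid_x"] == pytest.approx(0.5)
        assert row["centroid_y"] == pytest.approx(0.5)
        assert row["radius_of_gyration"] == pytest.approx(np.sqrt(0.5))

    def test_no_clusters_empty_summary(self):
        pts = [(0, 0), (5, 5)]
        res = dbscan(table_of(pts), DbscanParams(0.5, 2))
        assert len(summarize_clusters(res, table_of(pts))) == 0

    def test_simulated_gaussian_clusters_recovered(self):
        rng = np.random.default_rng(77)
        centers = np.array([(i % 5 * 10 + 5, i // 5 * 10 + 5) for i in range(10)], float)
        pts = np.vstack([rng.normal(c, 0.3, size=(30, 2)) for c in centers]
                        + [rng.uniform(0, 50, size=(30, 2))])
        t = table_of(pts)
        res = dbscan(t, DbscanParams(0.8, 8))
        summary = summarize_clusters(res, t)
        assert len(summary) == 10
        # counts close to the truth (30 per cluster) up to edge/noise ambiguity
        assert (np.abs(summary["n_points"] - 30) <= 5).all()
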