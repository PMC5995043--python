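"""Density estimation, downsampling, agglomeration, MST, up-sampling, QC."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

from cytoclust import synth
from cytoclust.clustering import (agglomerate_clusters, assess_uniformity,
                                  build_mst, cluster_events, density_downsample,
                                  estimate_density, filter_small_clusters,
                                  upsample_assign)
from cytoclust.preprocess import transform_arcsinh


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

def test_density_two_far_events():
    X = np.array([[0.0, 0.0], [100.0, 100.0]])
    assert estimate_density(X, neighborhood_scale=0.1).tolist() == [0, 0]


def test_density_identical_events():
    X = np.zeros((25, 3))
    assert (estimate_density(X) == 24).all()


def test_density_matches_bruteforce(rng):
    X = rng.normal(size=(200, 4))
    dens = estimate_density(X, neighborhood_scale=5.0, seed=0)
    # oracle: exhaustive pairwise L1 with the same radius definition
    nn = np.sort(cdist(X, X, "cityblock") + np.diag(np.full(200, np.inf)), axis=1)[:, 0]
    r = 5.0 * np.median(nn)
    D = cdist(X, X, "cityblock")
    expected = ((D <= r).sum(axis=1) - 1)
    np.testing.assert_array_equal(dens, expected)


def test_density_downsample_keeps_all_when_uniform(rng):
    d = np.full(500, 7.0)
    for tf in (1.0, 0.4):
        kept = density_downsample(d, target_fraction=tf, seed=1)
        assert kept.size == 500  # TD equals the common density: p_keep = 1


def test_density_downsample_rejects_bad_fraction():
    with pytest.raises(ValueError):
        density_downsample(np.ones(10), target_fraction=0.0)


def test_density_downsample_enriches_rare_population(rng):
    # 5% rare blob far from a 95% dense blob: its share among kept events
    # strictly increases, every seed
    X = np.vstack([rng.normal(0, 0.3, size=(950, 3)),
                   rng.normal(8, 0.3, size=(50, 3))])
    dens = estimate_density(X, seed=0)
    improved = 0
    for seed in range(20):
        kept = density_downsample(dens, target_fraction=0.4, seed=seed)
        share = (kept >= 950).mean()
        improved += share > 0.05
    assert improved == 20


# ---------------------------------------------------------------------------
# agglomeration
# ---------------------------------------------------------------------------

def test_agglomerate_extremes(rng):
    X = rng.normal(size=(12, 3))
    assert len(set(agglomerate_clusters(X, 12))) == 12  # singletons
    assert set(agglomerate_clusters(X, 1)) == {0}
    with pytest.raises(ValueError):
        agglomerate_clusters(X, 13)


def test_agglomerate_recovers_separated_blobs(rng):
    truth = np.repeat([0, 1, 2], 60)
    centers = np.array([[0, 0], [8, 0], [0, 8]], dtype=float)
    X = centers[truth] + rng.normal(0, 0.4, size=(180, 2))
    labels = agglomerate_clusters(X, 3)
    assert adjusted_rand_score(truth, labels) == 1.0


def test_end_to_end_recovery_with_majority_mapping(rng):
    # 8 well-separated populations, k_target = 50, majority-label mapping:
    # adjusted Rand index of mapped labels vs truth >= 0.9
    n_pop, per = 8, 400
    centers = rng.normal(0, 1, size=(n_pop, 6)) * 0 + \
        np.eye(n_pop, 6) * 8 + rng.normal(0, 0.5, size=(n_pop, 6))
    truth = np.repeat(np.arange(n_pop), per)
    X = centers[truth] + rng.normal(0, 0.35, size=(n_pop * per, 6))
    labels = agglomerate_clusters(X, 50)
    mapped = np.empty_like(labels)
    for c in np.unique(labels):
        sel = labels == c
        mapped[sel] = np.bincount(truth[sel]).argmax()
    assert adjusted_rand_score(truth, mapped) >= 0.9


# ---------------------------------------------------------------------------
# MST
# ---------------------------------------------------------------------------

def test_mst_two_and_triangle():
    m2 = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]])
    assert build_mst(m2) == [(0, 1, 5.0)]
    tri = pd.DataFrame([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
    edges = build_mst(tri)
    assert sum(w for *_ab, w in edges) == pytest.approx(3.0)
    assert {(a, b) for a, b, _ in edges} == {(0, 1), (0, 2)}


def test_mst_single_cluster_empty():
    assert build_mst(pd.DataFrame([[1.0, 2.0]])) == []


def test_mst_matches_exhaustive_minimum(rng):
    import networkx as nx
    M = rng.normal(size=(7, 3))
    edges = build_mst(pd.DataFrame(M))
    total = sum(w for *_ab, w in edges)
    g = nx.Graph()
    D = cdist(M, M)
    for i in range(7):
        for j in range(i + 1, 7):
            g.add_edge(i, j, weight=float(D[i, j]))
    best = min(
        sum(d["weight"] for *_e, d in tree.edges(data=True))
        for tree in nx.SpanningTreeIterator(g))
    assert total == pytest.approx(best, abs=1e-12)


# ---------------------------------------------------------------------------
# up-sampling
# ---------------------------------------------------------------------------

def test_upsample_exact_median_and_ties():
    medians = pd.DataFrame([[0.0, 0.0], [2.0, 2.0]], index=[3, 9])
    X = np.array([[2.0, 2.0],   # exactly at cluster 9's median
                  [1.0, 1.0]])  # equidistant: lowest id wins
    assert upsample_assign(X, medians).tolist() == [9, 3]


def test_upsample_matches_double_loop_oracle(rng):
    medians = pd.DataFrame(rng.normal(size=(6, 4)), index=[0, 1, 2, 5, 7, 8])
    X = rng.normal(size=(120, 4))
    got = upsample_assign(X, medians)
    ids = sorted(medians.index)
    expected = []
    for x in X:
        dists = [(np.abs(x - medians.loc[i].to_numpy()).sum(), i) for i in ids]
        best = min(d for d, _ in dists)
        expected.append(min(i for d, i in dists if d == best))
    assert got.tolist() == expected


# ---------------------------------------------------------------------------
# small-cluster filter
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_model(tiny_study):
    trans = [transform_arcsinh(t) for t in tiny_study.tables]
    from cytoclust.preprocess import auto_gating_config, gate_events
    cfg = auto_gating_config(trans, tiny_study.panel, seed=0)
    gated = [gate_events(t, tiny_study.panel, cfg).final for t in trans]
    model = cluster_events(gated, tiny_study.panel, k_target=25, seed=0)
    return model, gated


def test_filter_small_boundary(tiny_model):
    model, _ = tiny_model
    sizes = model.sizes
    cut = int(np.median(sizes))
    filtered = filter_small_clusters(model, min_cells=cut)
    expected_removed = set(sizes.index[sizes < cut])
    assert set(sizes.index) - set(filtered.sizes.index) == expected_removed
    # events of removed clusters flagged unassigned
    flagged = set(filtered.assignments.loc[filtered.assignments["cluster"] == -1]
                  .merge(model.assignments, on=["sample_id", "event_index"])
                  ["cluster_y"])
    assert flagged == expected_removed
    # MST spans exactly the survivors
    nodes = {a for a, _b, _w in filtered.mst_edges} | \
            {b for _a, b, _w in filtered.mst_edges}
    assert nodes <= set(filtered.sizes.index)
    assert len(filtered.mst_edges) == len(filtered.sizes) - 1


def test_filter_zero_keeps_everything(tiny_model):
    model, _ = tiny_model
    filtered = filter_small_clusters(model, min_cells=0)
    assert list(filtered.sizes.index) == list(model.sizes.index)


def test_filter_all_removed_is_error(tiny_model):
    model, _ = tiny_model
    with pytest.raises(ValueError):
        filter_small_clusters(model, min_cells=10 ** 9)


def test_assignments_cover_all_events_before_filter(tiny_model):
    model, gated = tiny_model
    assert (model.assignments["cluster"] >= 0).all()
    assert len(model.assignments) == sum(t.n_events for t in gated)
    assert int(model.sizes.sum()) == len(model.assignments)


# ---------------------------------------------------------------------------
# uniformity QC
# ---------------------------------------------------------------------------

def test_uniformity_flags(tiny_study, tiny_model):
    model, gated = tiny_model
    report = assess_uniformity(model, gated, tiny_study.panel,
                               n_null=100, seed=0)
    assert set(report.table.columns) == {"cluster", "marker", "dip", "pvalue", "iqr"}
    assert report.uniform.index.tolist() == model.cluster_ids
    assert ((report.table["dip"] >= 0) & (report.table["dip"] <= 0.25)).all()
    assert (report.table["iqr"] >= 0).all()
    # iqr_max = 0: any cluster with marker spread fails
    strict = assess_uniformity(model, gated, tiny_study.panel,
                               iqr_max=0.0, n_null=100, seed=0)
    spread = strict.table.groupby("cluster")["iqr"].max()
    assert not strict.uniform[spread > 0].any()


def test_merged_blobs_are_non_uniform(mini_panel, rng):
    # a "cluster" made of two well-separated modes on CD45 fails the dip test
    import pandas as pd
    from cytoclust.clustering import ClusterModel
    from cytoclust.data import EventTable

    n = 120
    cd45 = np.r_[rng.normal(0.5, 0.1, n // 2), rng.normal(4.5, 0.1, n // 2)]
    vals = np.column_stack([np.full(n, 3.8), np.full(n, 0.3),
                            np.full(n, 0.3), cd45])
    table = EventTable(sample_id="s1",
                       values=pd.DataFrame(vals, columns=[
                           c.channel_id for c in mini_panel.channels]),
                       scale="transformed")
    assignments = pd.DataFrame({"sample_id": "s1",
                                "event_index": np.arange(n), "cluster": 0})
    med = pd.DataFrame({"CD45": [np.median(cd45)]}, index=pd.Index([0], name="cluster"))
    model = ClusterModel(
        k_target=1, markers=["CD45"], assignments=assignments, medians=med,
        sample_medians=pd.DataFrame(
            {"CD45": [np.median(cd45)]},
            index=pd.MultiIndex.from_tuples([(0, "s1")], names=["cluster", "sample_id"])),
        sizes=pd.Series([n], index=pd.Index([0], name="cluster")),
        sample_counts=pd.DataFrame({"s1": [n]}, index=pd.Index([0], name="cluster")),
        mst_edges=[])
    report = assess_uniformity(model, [table], mini_panel, n_null=100, seed=0)
    assert not report.uniform.loc[0]
    assert report.table["pvalue"].iloc[0] <= 0.05
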