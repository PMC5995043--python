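"""SPADE-style clustering of pooled CD4 T-cell events.

The chain mirrors the density-normalized spanning-tree approach used for
mass cytometry: per-event local density (L1-ball counts) -> density-dependent
downsampling that equalizes dense and rare regions -> Ward agglomeration of
the kept events into a fixed number of clusters -> nearest-median
up-sampling of every gated event -> minimum spanning tree over cluster
medians. Small clusters are removed before phenotyping, and cluster
coherence is checked per marker with the dip test and the IQR.

All stochastic steps take explicit seeds; ties always resolve to the lowest
cluster id.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .data import EventTable, Panel
from .dip import dip_null_table, dip_statistic, dip_test_pvalue

__all__ = [
    "ClusterModel",
    "UniformityReport",
    "estimate_density",
    "density_downsample",
    "agglomerate_clusters",
    "build_mst",
    "upsample_assign",
    "filter_small_clusters",
    "assess_uniformity",
    "cluster_events",
]

log = logging.getLogger(__name__)


@dataclass
class ClusterModel:
    """Event-to-cluster assignments plus per-cluster summaries.

    ``assignments`` has one row per gated event: sample_id, event_index
    (row in the gated per-sample table), cluster (-1 = removed by the
    small-cluster filter). ``medians`` holds per-cluster medians over the
    clustering markers; ``sample_medians`` the per-(cluster, sample)
    medians used for phenotyping.
    """

    k_target: int
    markers: list[str]
    assignments: pd.DataFrame
    medians: pd.DataFrame                    # index: cluster, cols: markers
    sample_medians: pd.DataFrame             # index: (cluster, sample_id)
    sizes: pd.Series                         # index: cluster
    sample_counts: pd.DataFrame              # index: cluster, cols: sample_id
    mst_edges: list[tuple[int, int, float]]

    @property
    def cluster_ids(self) -> list[int]:
        return list(self.medians.index)

    def events_of(self, cluster: int, values: dict[str, np.ndarray]) -> np.ndarray:
        """Stack the marker rows of one cluster across samples.

        ``values`` maps sample_id -> (events x markers) array aligned with
        the assignment event indices.
        """
        rows = []
        for sid, grp in self.assignments.groupby("sample_id", sort=False):
            idx = grp.loc[grp["cluster"] == cluster, "event_index"].to_numpy()
            if idx.size:
                rows.append(values[sid][idx])
        if not rows:
            return np.empty((0, len(self.markers)))
        return np.vstack(rows)


# ---------------------------------------------------------------------------
# density-dependent downsampling
# ---------------------------------------------------------------------------

def estimate_density(events: np.ndarray, neighborhood_scale: float = 5.0,
                     seed: int = 0, nn_subsample: int = 2000,
                     max_reference: int | None = None) -> np.ndarray:
    """Per-event local density: count of other events within L1 distance r.

    r = ``neighborhood_scale`` x the median nearest-neighbor L1 distance of a
    random subsample (at most ``nn_subsample`` points). With
    ``max_reference`` set, counts are taken against a random reference
    subset of that size instead of all events (a Monte-Carlo estimate that
    leaves the density-downsampling quantile ratios unchanged); by default
    counts are exact.
    """
    X = np.asarray(events, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("density estimation requires at least 2 events")
    rng = np.random.default_rng(seed)

    sub = rng.choice(n, size=min(n, nn_subsample), replace=False)
    nn = np.empty(sub.size)
    chunk = max(1, int(4e7 // max(n, 1)))
    for start in range(0, sub.size, chunk):
        idx = sub[start:start + chunk]
        d = cdist(X[idx], X, metric="cityblock")
        d[np.arange(idx.size), idx] = np.inf  # exclude self
        nn[start:start + chunk] = d.min(axis=1)
    finite = nn[np.isfinite(nn)]
    med_nn = float(np.median(finite)) if finite.size else 0.0
    r = neighborhood_scale * med_nn

    if max_reference is not None and max_reference < n:
        ref = rng.choice(n, size=max_reference, replace=False)
    else:
        ref = np.arange(n)
    R = X[ref]
    in_ref = np.zeros(n, dtype=bool)
    in_ref[ref] = True

    counts = np.empty(n, dtype=np.int64)
    chunk = max(1, int(4e7 // max(R.shape[0], 1)))
    for start in range(0, n, chunk):
        d = cdist(X[start:start + chunk], R, metric="cityblock")
        counts[start:start + chunk] = (d <= r).sum(axis=1)
    counts -= in_ref.astype(np.int64)  # do not count the event itself
    return counts


def density_downsample(densities: np.ndarray, target_fraction: float = 0.40,
                       outlier_percentile: float = 1.0, seed: int = 0) -> np.ndarray:
    """Kept-event indices after density-dependent downsampling.

    Events below the ``outlier_percentile`` of the density distribution are
    removed as noise; the remaining events are kept with probability
    min(1, TD / density) where TD is the ``target_fraction`` quantile of the
    post-outlier densities. Dense regions are thinned toward TD while rare
    regions are kept almost entirely.
    """
    if not 0.0 < target_fraction <= 1.0:
        raise ValueError("target_fraction must be in (0, 1]")
    d = np.asarray(densities, dtype=float)
    rng = np.random.default_rng(seed)
    cutoff = np.percentile(d, outlier_percentile)
    candidates = np.flatnonzero(~(d < cutoff))
    td = np.quantile(d[candidates], target_fraction)
    with np.errstate(divide="ignore"):
        p_keep = np.minimum(1.0, np.where(d[candidates] > 0, td / d[candidates], 1.0))
    kept = candidates[rng.random(candidates.size) < p_keep]
    return kept


# ---------------------------------------------------------------------------
# agglomeration, MST, up-sampling
# ---------------------------------------------------------------------------

def agglomerate_clusters(events: np.ndarray, k_target: int) -> np.ndarray:
    """Ward hierarchical agglomeration cut at ``k_target`` clusters.

    Returns 0-based labels for every event.
    """
    X = np.asarray(events, dtype=float)
    if X.shape[0] < k_target:
        raise ValueError(
            f"{X.shape[0]} events cannot form {k_target} clusters; lower k_target")
    if k_target == 1:
        return np.zeros(X.shape[0], dtype=int)
    if k_target == X.shape[0]:
        return np.arange(X.shape[0])
    Z = linkage(X, method="ward")
    return fcluster(Z, t=k_target, criterion="maxclust") - 1


def build_mst(medians: pd.DataFrame | np.ndarray) -> list[tuple[int, int, float]]:
    """Minimum spanning tree of the clusters under Euclidean distance
    between median vectors; ties broken toward lexicographically smaller
    (id_a, id_b) edges. A single cluster yields an empty edge list."""
    if isinstance(medians, pd.DataFrame):
        ids = list(medians.index)
        M = medians.to_numpy(dtype=float)
    else:
        M = np.asarray(medians, dtype=float)
        ids = list(range(M.shape[0]))
    m = len(ids)
    if m <= 1:
        return []
    D = cdist(M, M, metric="euclidean")
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i in range(m):           # insertion in lexicographic (i, j) order:
        for j in range(i + 1, m):  # Kruskal's stable sort then breaks ties by it
            g.add_edge(ids[i], ids[j], weight=float(D[i, j]))
    edges = nx.minimum_spanning_edges(g, algorithm="kruskal", data=True)
    out = [(min(a, b), max(a, b), d["weight"]) for a, b, d in edges]
    return sorted(out)


def upsample_assign(events: np.ndarray, medians: pd.DataFrame) -> np.ndarray:
    """Assign every event (including those dropped during downsampling) to
    the cluster with the nearest median (L1); equidistant events go to the
    lowest cluster id."""
    X = np.asarray(events, dtype=float)
    ids = np.asarray(sorted(medians.index))
    M = medians.loc[ids].to_numpy(dtype=float)
    out = np.empty(X.shape[0], dtype=int)
    chunk = max(1, int(2e7 // max(M.shape[0] * M.shape[1], 1)))
    for start in range(0, X.shape[0], chunk):
        d = cdist(X[start:start + chunk], M, metric="cityblock")
        out[start:start + chunk] = ids[np.argmin(d, axis=1)]
    return out


# ---------------------------------------------------------------------------
# model assembly and filtering
# ---------------------------------------------------------------------------

def _summaries(assignments: pd.DataFrame, values: dict[str, np.ndarray],
               markers: list[str]) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.DataFrame]:
    frames = []
    for sid, grp in assignments.groupby("sample_id", sort=False):
        sel = grp[grp["cluster"] >= 0]
        df = pd.DataFrame(values[sid][sel["event_index"].to_numpy()], columns=markers)
        df["cluster"] = sel["cluster"].to_numpy()
        df["sample_id"] = sid
        frames.append(df)
    allev = pd.concat(frames, ignore_index=True)
    medians = allev.groupby("cluster")[markers].median()
    sample_medians = allev.groupby(["cluster", "sample_id"])[markers].median()
    sizes = allev.groupby("cluster").size()
    sizes.name = "n_cells"
    sample_counts = (
        allev.groupby(["cluster", "sample_id"]).size().unstack(fill_value=0))
    return medians, sample_medians, sizes, sample_counts


def cluster_events(tables: list[EventTable], panel: Panel, k_target: int = 350,
                   target_fraction: float = 0.40, outlier_percentile: float = 1.0,
                   neighborhood_scale: float = 5.0, seed: int = 0,
                   max_reference: int | None = 4000,
                   markers: list[str] | None = None,
                   discovery_tables: list[EventTable] | None = None) -> ClusterModel:
    """Full clustering stage.

    Cluster discovery pools the ``discovery_tables`` (typically the
    uniformly-downsampled samples; defaults to ``tables``): density
    downsampling keeps ~``target_fraction`` of the pool and Ward
    agglomeration cuts it at ``k_target`` clusters (clusters are
    cross-sample). Every event of every table in ``tables`` is then
    up-sampled onto the nearest cluster median, so summaries and abundances
    always cover the full gated data.
    """
    markers = list(markers) if markers is not None else panel.clustering_markers
    mats = [t.marker_array(panel, markers) for t in tables]
    if discovery_tables is None:
        pooled = np.vstack(mats)
    else:
        pooled = np.vstack([t.marker_array(panel, markers) for t in discovery_tables])
    dens = estimate_density(pooled, neighborhood_scale=neighborhood_scale,
                            seed=seed, max_reference=max_reference)
    kept = density_downsample(dens, target_fraction=target_fraction,
                              outlier_percentile=outlier_percentile, seed=seed + 1)
    labels_kept = agglomerate_clusters(pooled[kept], k_target)
    kept_df = pd.DataFrame(pooled[kept], columns=markers)
    kept_df["cluster"] = labels_kept
    medians = kept_df.groupby("cluster")[markers].median()

    values = {t.sample_id: m for t, m in zip(tables, mats)}
    rows = []
    for t, m in zip(tables, mats):
        lab = upsample_assign(m, medians)
        rows.append(pd.DataFrame({
            "sample_id": t.sample_id,
            "event_index": np.arange(m.shape[0]),
            "cluster": lab,
        }))
    assignments = pd.concat(rows, ignore_index=True)
    medians, sample_medians, sizes, sample_counts = _summaries(
        assignments, values, markers)
    return ClusterModel(
        k_target=k_target,
        markers=markers,
        assignments=assignments,
        medians=medians,
        sample_medians=sample_medians,
        sizes=sizes,
        sample_counts=sample_counts,
        mst_edges=build_mst(medians),
    )


def filter_small_clusters(model: ClusterModel, min_cells: int = 40) -> ClusterModel:
    """Remove clusters with fewer than ``min_cells`` cells in total.

    Their events are flagged unassigned (cluster -1) and the MST is
    recomputed over the surviving clusters.
    """
    keep = model.sizes.index[model.sizes >= min_cells]
    if len(keep) == 0:
        raise ValueError("min_cells filter removed every cluster")
    removed = set(model.sizes.index) - set(keep)
    assignments = model.assignments.copy()
    assignments.loc[assignments["cluster"].isin(removed), "cluster"] = -1
    medians = model.medians.loc[keep]
    return ClusterModel(
        k_target=model.k_target,
        markers=model.markers,
        assignments=assignments,
        medians=medians,
        sample_medians=model.sample_medians.loc[list(keep)],
        sizes=model.sizes.loc[keep],
        sample_counts=model.sample_counts.loc[keep],
        mst_edges=build_mst(medians),
    )


# ---------------------------------------------------------------------------
# uniformity QC
# ---------------------------------------------------------------------------

@dataclass
class UniformityReport:
    """Per-(cluster, marker) dip/IQR results and per-cluster uniform flags."""

    table: pd.DataFrame        # cluster, marker, dip, pvalue, iqr
    uniform: pd.Series         # index: cluster; True if every marker passes
    alpha: float
    iqr_max: float


#: subsample sizes for the dip QC; snapping cluster sizes to this grid lets
#: one uniform null table serve many clusters
_DIP_SIZE_GRID = (8, 16, 32, 64, 100)


def assess_uniformity(model: ClusterModel, tables: list[EventTable], panel: Panel,
                      alpha: float = 0.05, iqr_max: float = 2.0,
                      n_null: int = 200, seed: int = 0,
                      max_events: int = 100) -> UniformityReport:
    """Check phenotypic coherence of every cluster.

    A cluster is *uniform* when, for every clustering marker, the expression
    distribution is unimodal (dip-test p > ``alpha``) and tight
    (IQR < ``iqr_max`` on the transformed scale). Clusters with fewer than 4
    cells on a marker skip that marker with a warning. For the dip test each
    cluster-marker sample is subsampled to the largest grid size not above
    min(cluster size, ``max_events``), so a handful of shared uniform null
    tables calibrate every p-value. The IQR uses all cells.
    """
    values = {t.sample_id: t.marker_array(panel, model.markers) for t in tables}
    rng = np.random.default_rng(seed)
    null_tables: dict[int, np.ndarray] = {}
    records = []
    for cluster in model.cluster_ids:
        ev = model.events_of(cluster, values)
        for j, marker in enumerate(model.markers):
            x = ev[:, j]
            x = x[np.isfinite(x)]
            if x.size < 4:
                warnings.warn(
                    f"cluster {cluster}, marker {marker}: fewer than 4 cells, skipped")
                continue
            q75, q25 = np.percentile(x, [75, 25])
            cap = min(x.size, max_events)
            grid_ok = [g for g in _DIP_SIZE_GRID if g <= cap]
            n = grid_ok[-1] if grid_ok else cap
            xd = x if x.size == n else x[rng.choice(x.size, n, replace=False)]
            d = dip_statistic(xd)
            if n not in null_tables:
                null_tables[n] = dip_null_table(n, n_null=n_null, seed=seed + n)
            p = dip_test_pvalue(d, n, null_table=null_tables[n])
            records.append((cluster, marker, d, p, q75 - q25))
    table = pd.DataFrame(records, columns=["cluster", "marker", "dip", "pvalue", "iqr"])
    passes = (table["pvalue"] > alpha) & (table["iqr"] < iqr_max)
    uniform = pd.Series(
        passes.groupby(table["cluster"]).all(),
        name="uniform").reindex(model.cluster_ids, fill_value=False)
    return UniformityReport(table=table, uniform=uniform, alpha=alpha, iqr_max=iqr_max)
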