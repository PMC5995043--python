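"""Five-tier phenotype categorization and cluster profiling.

Cluster phenotypes are expressed relative to a parent population (all CD4
T cells): each marker's expression range is the 5th-95th percentile over
the parent events, divided into five equal-width tiers (1 = negative,
2 = low, 3 = medium, 4 = high, 5 = very high). Cluster-level summaries are
the mean over samples of per-sample medians, so no single donor dominates.
The categorical grid supports T-cell subset labeling (naive / central
memory / effector-memory from the CCR7 x CD45RA sign pattern), marker-based
cluster selection with exclusion rules (e.g. dropping myeloid contaminants),
complete-linkage ordering for heatmaps, and Kolmogorov-Smirnov phenotype
distances between a cluster and its parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.stats import ks_2samp

from .data import PanelError

__all__ = [
    "MarkerBounds",
    "SubsetConfig",
    "KSProfile",
    "marker_bounds",
    "categorize_values",
    "categorize_clusters",
    "label_tcell_subsets",
    "select_clusters_by_category",
    "hclust_order",
    "ks_profile",
]


@dataclass
class MarkerBounds:
    """Per-marker 5th/95th percentile range over the parent population."""

    q05: pd.Series
    q95: pd.Series

    def __post_init__(self) -> None:
        if (self.q05 > self.q95).any():
            raise ValueError("q05 > q95 for some marker")

    @property
    def degenerate(self) -> pd.Series:
        """Markers whose parent expression is constant (single-tier)."""
        return self.q05 >= self.q95

    def edges(self, marker: str) -> np.ndarray:
        """The 4 interior cut points dividing [q05, q95] uniformly."""
        lo, hi = float(self.q05[marker]), float(self.q95[marker])
        return lo + (hi - lo) * np.arange(1, 5) / 5.0


def marker_bounds(parent: pd.DataFrame | np.ndarray,
                  markers: Sequence[str] | None = None) -> MarkerBounds:
    """5th/95th percentiles per marker over the parent events
    (linear-interpolation quantile convention)."""
    if isinstance(parent, np.ndarray):
        if markers is None:
            raise ValueError("markers required with an array input")
        parent = pd.DataFrame(parent, columns=list(markers))
    if parent.empty:
        raise ValueError("parent population is empty")
    q = parent.quantile([0.05, 0.95], interpolation="linear")
    return MarkerBounds(q05=q.loc[0.05], q95=q.loc[0.95])


def categorize_values(v: np.ndarray, q05: float, q95: float) -> np.ndarray:
    """Map expression summaries onto tiers 1..5 within [q05, q95].

    The range is divided into five equal-width bins:
    category = 1 + floor(5 * (clip(v) - q05) / (q95 - q05)), with v = q95
    mapping to 5; a degenerate range puts everything in tier 1. Monotone in v.
    """
    v = np.asarray(v, dtype=float)
    if q95 <= q05:
        return np.ones(v.shape, dtype=int)
    frac = (np.clip(v, q05, q95) - q05) / (q95 - q05)
    return np.minimum(1 + np.floor(5.0 * frac).astype(int), 5)


def categorize_clusters(sample_medians: pd.DataFrame, bounds: MarkerBounds,
                        parent_name: str = "CD4") -> pd.DataFrame:
    """Clusters x markers grid of tiers 1..5.

    The cluster-level summary of a marker is the mean, over the samples with
    at least one cell in the cluster, of the per-sample medians; it is then
    binned against the parent-population bounds. The result carries the
    parent name in ``attrs`` for provenance.
    """
    summary = sample_medians.groupby(level="cluster").mean()
    out = pd.DataFrame(index=summary.index, columns=summary.columns, dtype=int)
    for m in summary.columns:
        out[m] = categorize_values(summary[m].to_numpy(),
                                   float(bounds.q05[m]), float(bounds.q95[m]))
    out.attrs["parent"] = parent_name
    return out


# ---------------------------------------------------------------------------
# subset labels and selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubsetConfig:
    """How tier 3 ("mid") counts in the +/- sign rule for subset labels.

    Tiers >= 4 are "+", <= 2 are "-"; mid maps per marker (default "+",
    matching the convention that CCR7^mid / CD45RA^mid clusters still fall
    into the named subsets).
    """

    ccr7_mid_positive: bool = True
    cd45ra_mid_positive: bool = True


def _sign(cat: int, mid_positive: bool) -> bool:
    return cat >= 4 or (cat == 3 and mid_positive)


def label_tcell_subsets(categories: pd.DataFrame,
                        config: SubsetConfig = SubsetConfig()) -> pd.Series:
    """T_N / T_CM / T_EffMem / T_other labels from CCR7 and CD45RA tiers.

    T_N = CCR7+ CD45RA+; T_CM = CCR7+ CD45RA-; T_EffMem = CCR7- CD45RA-;
    any other pattern is T_other. Deterministic function of the grid.
    """
    for m in ("CCR7", "CD45RA"):
        if m not in categories.columns:
            raise PanelError(f"subset labels require marker {m!r}")
    labels = {}
    for cluster, row in categories.iterrows():
        ccr7 = _sign(int(row["CCR7"]), config.ccr7_mid_positive)
        cd45ra = _sign(int(row["CD45RA"]), config.cd45ra_mid_positive)
        if ccr7 and cd45ra:
            lab = "T_N"
        elif ccr7 and not cd45ra:
            lab = "T_CM"
        elif not ccr7 and not cd45ra:
            lab = "T_EffMem"
        else:
            lab = "T_other"
        labels[cluster] = lab
    return pd.Series(labels, name="subset")


#: an exclusion rule: marker -> (op, tier) with op in {"<=", ">="}; the rule
#: matches when every predicate holds (conjunction)
ExcludeRule = Mapping[str, tuple[str, int]]

DEFAULT_MYELOID_RULES: list[ExcludeRule] = [
    {"CD3": ("<=", 2), "CD14": (">=", 4)},
    {"CD3": ("<=", 2), "HLA-DR": (">=", 4)},
]


def select_clusters_by_category(categories: pd.DataFrame, marker: str,
                                min_category: int = 4,
                                exclude_rules: Sequence[ExcludeRule] = ()) -> set[int]:
    """Clusters whose tier for ``marker`` is >= ``min_category``, minus any
    cluster matching an exclusion rule."""
    if marker not in categories.columns:
        raise PanelError(f"marker {marker!r} not in category matrix")
    for rule in exclude_rules:
        for m in rule:
            if m not in categories.columns:
                raise ValueError(f"exclusion rule references unknown marker {m!r}")
    selected = set(categories.index[categories[marker] >= min_category])

    def matches(row: pd.Series, rule: ExcludeRule) -> bool:
        for m, (op, tier) in rule.items():
            v = int(row[m])
            if op == "<=" and not v <= tier:
                return False
            if op == ">=" and not v >= tier:
                return False
            if op not in ("<=", ">="):
                raise ValueError(f"unknown operator {op!r} in exclusion rule")
        return True

    for cluster in list(selected):
        row = categories.loc[cluster]
        if any(matches(row, rule) for rule in exclude_rules):
            selected.discard(cluster)
    return selected


# ---------------------------------------------------------------------------
# heatmap ordering
# ---------------------------------------------------------------------------

def hclust_order(matrix: pd.DataFrame, axis: int = 0
                 ) -> tuple[list, list[tuple[int, int, float]]]:
    """Complete-linkage ordering of rows (axis=0) or columns (axis=1).

    Euclidean distances, complete linkage; the leaf order puts the smaller
    subtree first at every merge, breaking size ties toward the subtree
    containing the lowest id. Returns (ordered ids, merge list) where each
    merge is (node_a, node_b, height) in scipy convention (leaves 0..m-1).
    """
    M = matrix if axis == 0 else matrix.T
    ids = list(M.index)
    if len(ids) == 1:
        return ids, []
    Z = linkage(M.to_numpy(dtype=float), method="complete", metric="euclidean")
    m = len(ids)
    children: dict[int, tuple[int, int]] = {}
    for i, (a, b, _h, _n) in enumerate(Z):
        children[m + i] = (int(a), int(b))

    def leaves(node: int) -> list[int]:
        if node < m:
            return [node]
        a, b = children[node]
        la, lb = leaves(a), leaves(b)
        if (len(la), min(la)) <= (len(lb), min(lb)):
            return la + lb
        return lb + la

    order = [ids[i] for i in leaves(m + len(Z) - 1)]
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    return order, merges


# ---------------------------------------------------------------------------
# KS phenotype profile
# ---------------------------------------------------------------------------

@dataclass
class KSProfile:
    """Per-marker two-sample KS distances, sorted by descending distance."""

    distances: pd.Series          # index: marker, sorted descending
    threshold: float

    @property
    def flagged(self) -> list[str]:
        return list(self.distances.index[self.distances >= self.threshold])


def ks_profile(cluster_events: pd.DataFrame, reference_events: pd.DataFrame,
               threshold: float = 0.30) -> KSProfile:
    """KS distance per marker between a cluster's events and a reference
    population's events (sup of |ECDF difference| over the pooled points).

    Markers at or above ``threshold`` are the distinguishing phenotype.
    """
    markers = [m for m in cluster_events.columns if m in reference_events.columns]
    if not markers:
        raise ValueError("no shared markers between cluster and reference")
    out = {}
    for m in markers:
        a = cluster_events[m].to_numpy(dtype=float)
        b = reference_events[m].to_numpy(dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if a.size == 0 or b.size == 0:
            raise ValueError(f"empty sample for marker {m!r}: KS undefined")
        out[m] = float(ks_2samp(a, b, method="asymp").statistic)
    dist = pd.Series(out, name="ks").sort_values(ascending=False, kind="stable")
    return KSProfile(distances=dist, threshold=threshold)
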