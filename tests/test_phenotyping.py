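"""Five-tier categorization, subset labels, selection, ordering, KS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cytoclust.data import PanelError
from cytoclust.phenotyping import (SubsetConfig, categorize_clusters,
                                   categorize_values, hclust_order, ks_profile,
                                   label_tcell_subsets, marker_bounds,
                                   select_clusters_by_category)


# ---------------------------------------------------------------------------
# bounds
# ---------------------------------------------------------------------------

def test_bounds_on_integer_grid():
    parent = pd.DataFrame({"M": np.arange(101.0)})
    b = marker_bounds(parent)
    assert b.q05["M"] == pytest.approx(5.0)
    assert b.q95["M"] == pytest.approx(95.0)
    np.testing.assert_allclose(b.edges("M"), [23.0, 41.0, 59.0, 77.0])


def test_bounds_degenerate_constant_channel():
    parent = pd.DataFrame({"M": np.full(50, 2.5)})
    b = marker_bounds(parent)
    assert bool(b.degenerate["M"])
    assert categorize_values(np.array([0.0, 2.5, 9.9]), b.q05["M"], b.q95["M"]).tolist() \
        == [1, 1, 1]


def test_bounds_match_sort_based_quantile_oracle(rng):
    x = rng.normal(size=437)
    b = marker_bounds(pd.DataFrame({"M": x}))

    def oracle(q):
        s = np.sort(x)
        pos = q * (len(s) - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        return s[lo] + (pos - lo) * (s[hi] - s[lo])

    assert b.q05["M"] == pytest.approx(oracle(0.05), abs=1e-12)
    assert b.q95["M"] == pytest.approx(oracle(0.95), abs=1e-12)


# ---------------------------------------------------------------------------
# categorization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("v,expected", [
    (0.0, 1),    # v = q05 -> negative
    (10.0, 5),   # v = q95 -> very high
    (5.0, 3),    # middle -> medium
    (7.0, 4),    # midway through tier 4
    (-3.0, 1),   # below range clips
    (42.0, 5),   # above range clips
])
def test_categorize_boundaries(v, expected):
    assert categorize_values(np.array([v]), 0.0, 10.0)[0] == expected


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-5, 15), min_size=2, max_size=12))
def test_categorize_monotone(vs):
    v = np.sort(np.asarray(vs))
    cats = categorize_values(v, 0.0, 10.0)
    assert (np.diff(cats) >= 0).all()
    assert set(cats) <= {1, 2, 3, 4, 5}


def test_categorize_clusters_averages_sample_medians():
    idx = pd.MultiIndex.from_product([[0, 1], ["a", "b"]],
                                     names=["cluster", "sample_id"])
    sm = pd.DataFrame({"M": [2.0, 4.0, 9.0, 11.0]}, index=idx)
    bounds = marker_bounds(pd.DataFrame({"M": np.linspace(0, 10.0, 200)}))
    cats = categorize_clusters(sm, bounds, parent_name="CD4")
    # cluster 0 summary = 3.0 -> tier 2; cluster 1 summary = 10.0 -> tier 5
    assert cats.loc[0, "M"] == 2
    assert cats.loc[1, "M"] == 5
    assert cats.attrs["parent"] == "CD4"


# ---------------------------------------------------------------------------
# subset labels
# ---------------------------------------------------------------------------

def _grid(ccr7, cd45ra):
    return pd.DataFrame({"CCR7": [ccr7], "CD45RA": [cd45ra]}, index=[0])


@pytest.mark.parametrize("ccr7,cd45ra,expected", [
    (5, 5, "T_N"),
    (5, 1, "T_CM"),       # central memory: CCR7+ CD45RA-
    (1, 1, "T_EffMem"),
    (1, 5, "T_other"),    # uncovered pattern
    (3, 3, "T_N"),        # mid counts as + by default
])
def test_subset_labels(ccr7, cd45ra, expected):
    assert label_tcell_subsets(_grid(ccr7, cd45ra)).loc[0] == expected


def test_subset_mid_configurable():
    cfg = SubsetConfig(ccr7_mid_positive=False, cd45ra_mid_positive=False)
    assert label_tcell_subsets(_grid(3, 3), cfg).loc[0] == "T_EffMem"


def test_subset_requires_columns():
    with pytest.raises(PanelError):
        label_tcell_subsets(pd.DataFrame({"CCR7": [5]}))


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def test_select_by_category_rules():
    cats = pd.DataFrame({
        "CD32a": [1, 3, 4, 5],
        "CD3": [5, 5, 1, 5],
        "CD14": [1, 1, 5, 1],
    }, index=[10, 11, 12, 13])
    assert select_clusters_by_category(cats, "CD32a", 4) == {12, 13}
    # myeloid exclusion removes cluster 12 (CD3 <= 2 and CD14 >= 4)
    rule = {"CD3": ("<=", 2), "CD14": (">=", 4)}
    assert select_clusters_by_category(cats, "CD32a", 4, [rule]) == {13}
    assert select_clusters_by_category(cats, "CD32a", 1) == {10, 11, 12, 13}
    with pytest.raises(ValueError):
        select_clusters_by_category(cats, "CD32a", 4, [{"GHOST": (">=", 4)}])


# ---------------------------------------------------------------------------
# heatmap ordering
# ---------------------------------------------------------------------------

def test_hclust_near_rows_merge_first():
    m = pd.DataFrame([[0.0, 0.0], [0.0, 1.0], [10.0, 10.0]], index=["a", "b", "c"])
    order, merges = hclust_order(m)
    assert merges[0][2] == pytest.approx(1.0)   # (a, b) join first
    # smaller subtree (the singleton c) leads, then a before b (lowest id)
    assert order == ["c", "a", "b"]


def test_hclust_duplicates_merge_at_zero():
    m = pd.DataFrame([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]])
    _, merges = hclust_order(m)
    assert merges[0][2] == 0.0


def test_hclust_single_row_identity():
    m = pd.DataFrame([[1.0, 2.0]], index=["only"])
    order, merges = hclust_order(m)
    assert order == ["only"] and merges == []


def test_hclust_matches_naive_complete_linkage(rng):
    X = rng.normal(size=(6, 3))
    _, merges = hclust_order(pd.DataFrame(X))
    heights = sorted(h for *_ab, h in merges)

    # naive O(k^3) complete-linkage agglomeration
    clusters = [[i] for i in range(6)]
    naive = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(np.linalg.norm(X[a] - X[b])
                        for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        naive.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    np.testing.assert_allclose(heights, sorted(naive), rtol=1e-12)


def test_hclust_order_is_permutation(tiny_study):
    m = pd.DataFrame(np.random.default_rng(0).integers(1, 6, size=(9, 4)),
                     index=list("abcdefghi"))
    order, _ = hclust_order(m)
    assert sorted(order) == sorted(m.index)


# ---------------------------------------------------------------------------
# KS profile
# ---------------------------------------------------------------------------

def _df(**cols):
    return pd.DataFrame({k: np.asarray(v, float) for k, v in cols.items()})


def test_ks_identical_zero():
    a = _df(M=[1, 2, 3, 4.0])
    prof = ks_profile(a, a.copy())
    assert prof.distances["M"] == 0.0
    assert prof.flagged == []


def test_ks_disjoint_support_one():
    prof = ks_profile(_df(M=np.zeros(10)), _df(M=np.ones(10)))
    assert prof.distances["M"] == 1.0
    assert prof.flagged == ["M"]


def test_ks_half_overlap():
    prof = ks_profile(_df(M=[1, 2, 3, 4]), _df(M=[3, 4, 5, 6]))
    assert prof.distances["M"] == pytest.approx(0.5)


def test_ks_sorted_descending_and_threshold():
    prof = ks_profile(_df(A=[0, 0, 1, 1], B=[0, 1, 2, 3]),
                      _df(A=[5, 5, 6, 6], B=[0, 1, 2, 3.5]), threshold=0.30)
    assert list(prof.distances.index)[0] == "A"
    assert prof.flagged == ["A"]


def test_ks_matches_double_loop_oracle(rng):
    for _ in range(100):
        a = rng.normal(size=rng.integers(1, 20))
        b = rng.normal(size=rng.integers(1, 20))
        got = ks_profile(_df(M=a), _df(M=b)).distances["M"]
        pooled = np.concatenate([a, b])
        expected = max(abs((a <= t).mean() - (b <= t).mean()) for t in pooled)
        assert got == pytest.approx(expected, abs=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(-10, 10), min_size=1, max_size=15),
       st.lists(st.floats(-10, 10), min_size=1, max_size=15))
def test_ks_symmetric_bounded_transform_invariant(xs, ys):
    # coarse grid so exp() cannot collapse distinct values in float64
    xs = list(np.round(xs, 3))
    ys = list(np.round(ys, 3))
    a, b = _df(M=xs), _df(M=ys)
    d = ks_profile(a, b).distances["M"]
    assert 0.0 <= d <= 1.0
    assert d == pytest.approx(ks_profile(b, a).distances["M"], abs=1e-12)
    # strictly increasing transform leaves D unchanged
    ta, tb = _df(M=np.exp(0.3 * np.asarray(xs))), _df(M=np.exp(0.3 * np.asarray(ys)))
    assert d == pytest.approx(ks_profile(ta, tb).distances["M"], abs=1e-12)


def test_ks_empty_sample_errors():
    with pytest.raises(ValueError, match="M"):
        ks_profile(_df(M=[]), _df(M=[1.0]))
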