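"""Hartigan & Hartigan dip statistic of unimodality.

The dip of a sample is the smallest sup-norm distance between its empirical
distribution function F and any unimodal distribution function (nondecreasing,
convex up to a mode, concave after it, with an atom permitted at the mode).
It is 0 for a point mass, 1/(2n) for n distinct values in convex/concave
position, and approaches its maximum 1/4 for half the mass at each of two
points. It is invariant under strictly increasing transforms of the data.

Computation: writing l_j = F(t_j-) and u_j = F(t_j) for the unique sorted
values t_j, a unimodal fit within sup-distance s splits at a mode into a
convex piece (rising from 0) and a concave piece (rising to 1), each confined
to the band [u - s, l + s] at its points. For a candidate mode at t_c the
greatest convex minorant of the lower corners over [t_1, t_c] and the least
concave majorant of the upper corners over [t_c, t_k] give *necessary*
deviations (hull bounds): both must be <= 2s. When the jump room at the mode
(the mass at t_c) is at least max of the two hull bounds, the shifted hulls
are themselves a feasible fit and the bound is attained exactly. Otherwise
the two pieces couple through the mode (the convex piece's slope carries
into the junction) and the exact per-mode optimum is obtained by solving
the small linear program that encodes the convexity/concavity and band
constraints directly. Candidate modes are scanned in order of their hull
lower bound, so the LP is solved only for the few candidates that could
still improve on the best exact value; the result is the exact dip.

The p-value is calibrated by Monte Carlo against the uniform null, the
standard reference distribution for the test.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix

__all__ = ["dip_statistic", "dip_test_pvalue", "dip_null_table",
           "UndefinedStatisticError"]


class UndefinedStatisticError(ValueError):
    """Too few finite observations to compute the statistic."""


def _prepare(x) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    x = np.asarray(x, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise UndefinedStatisticError("dip requires at least 2 finite values")
    t, counts = np.unique(x, return_counts=True)
    c = np.cumsum(counts)
    n = x.size
    return t, (c - counts) / n, c / n, n


def _lower_hull(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vertex indices of the lower convex hull of (t_i, y_i), t increasing."""
    hull: list[int] = []
    for i in range(t.size):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (y[b] - y[a]) * (t[i] - t[a]) >= (y[i] - y[a]) * (t[b] - t[a]):
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def _prefix_devs(t: np.ndarray, l: np.ndarray, u: np.ndarray) -> np.ndarray:
    """LH[c] = max_{j<c} (u_j - hull_c(t_j)) with hull_c the greatest convex
    minorant of the lower corners over [0..c]; LH[0] = 0.

    Incremental hull; when adding a point pops vertices, the deviations over
    the affected span are re-evaluated (the hull only moves down, so the
    running max never decreases).
    """
    k = t.size
    LH = np.zeros(k)
    hull = [0]
    best = 0.0
    for c_idx in range(1, k):
        popped_from = c_idx
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (l[b] - l[a]) * (t[c_idx] - t[a]) >= (l[c_idx] - l[a]) * (t[b] - t[a]):
                popped_from = hull.pop()
            else:
                break
        a = hull[-1]
        if popped_from < c_idx:
            # hull segment a -> c_idx replaced vertices; rescan span (a, c_idx)
            span = np.arange(a + 1, c_idx)
            if span.size:
                hv = l[a] + (l[c_idx] - l[a]) * (t[span] - t[a]) / (t[c_idx] - t[a])
                best = max(best, float((u[span] - hv).max()))
        best = max(best, float(u[c_idx - 1] - np.interp(
            t[c_idx - 1], t[hull + [c_idx]], l[hull + [c_idx]])))
        hull.append(c_idx)
        LH[c_idx] = best
    return LH


def _mode_lp(t, l, u, c: int | None, gap_after: int | None) -> float:
    """Exact minimal 2*sup-distance for one mode placement, by LP.

    ``c``: mode at point t_c (atom allowed there); ``gap_after``: mode in the
    open interval after index gap_after (-1 = before all points). Far-off
    anchor points impose the 0 and 1 tail limits through the shape triples.
    """
    k = t.size
    BIG = 1e6 * (t[-1] - t[0] + 1.0)
    atom = c is not None
    split = c if atom else gap_after + 1  # first index of the concave piece
    nv = k + (1 if atom else 0)  # values v_0..v_{k-1} (+ w = G(t_c^-))
    iw = k
    rows, rhs = [], []

    def add(coeffs: dict[int, float], const: float) -> None:
        row = np.zeros(1 + nv)
        for idx, w in coeffs.items():
            row[1 + idx] += w
        rows.append(row)
        rhs.append(const)

    def band(idx: int, lo_c: float, hi_c: float) -> None:
        r = np.zeros(1 + nv); r[0] = -1.0; r[1 + idx] = -1.0
        rows.append(r); rhs.append(-lo_c)          # lo_c - D <= v
        r = np.zeros(1 + nv); r[0] = -1.0; r[1 + idx] = 1.0
        rows.append(r); rhs.append(hi_c)           # v <= hi_c + D

    for j in range(k):
        if atom and j == c:
            band(j, u[j], u[j])
        else:
            band(j, u[j], l[j])
    if atom:
        band(iw, l[c], l[c])

    # monotonicity
    order = list(range(k))
    if atom:
        order = list(range(c)) + [iw, c] + list(range(c + 1, k))
    for a, b in zip(order[:-1], order[1:]):
        add({a: 1.0, b: -1.0}, 0.0)

    # shape triples: convex piece (with left anchor value 0), concave piece
    left_pts = [(t[0] - BIG, None)] + [(t[j], j) for j in range(split)]
    if atom:
        left_pts.append((t[c], iw))
    right_pts = [(t[j], j) for j in range(split, k)] + [(t[-1] + BIG, None)]

    def triples(pts, convex: bool) -> None:
        for (ta, ia), (tb, ib), (tc, ic) in zip(pts, pts[1:], pts[2:]):
            w1, w2 = tc - tb, tb - ta
            coeffs: dict[int, float] = {}
            const = 0.0
            for idx, w in ((ia, -w1), (ib, w1 + w2), (ic, -w2)):
                s = w if convex else -w
                if idx is None:
                    const += s * (0.0 if convex else 1.0)
                else:
                    coeffs[idx] = coeffs.get(idx, 0.0) + s
            add(coeffs, -const)

    triples(left_pts, True)
    triples(right_pts, False)

    cvec = np.zeros(1 + nv)
    cvec[0] = 1.0
    res = linprog(cvec, A_ub=csr_matrix(np.array(rows)), b_ub=np.array(rhs),
                  bounds=[(0.0, None)] + [(0.0, 1.0)] * nv, method="highs")
    return 2.0 * float(res.fun) if res.success else np.inf


def dip_statistic(x) -> float:
    """Dip statistic D_n in [0, 0.25]."""
    t, l, u = _prepare(x)[:3]
    k = t.size
    if k == 1:
        return 0.0
    mass = u - l
    LH = _prefix_devs(t, l, u)
    # RH by mirror symmetry: reflect the sample (dip is reflection-invariant)
    RH = _prefix_devs(-t[::-1], (1.0 - u)[::-1], (1.0 - l)[::-1])[::-1]

    # candidates: (lower bound, kind, index); atoms first, then gap modes
    cands: list[tuple[float, str, int]] = []
    for c in range(k):
        cands.append((max(LH[c], RH[c]), "atom", c))
    Lfull = np.maximum(LH, mass)   # convex piece through point c inclusive
    Rfull = np.maximum(RH, mass)
    cands.append((Rfull[0], "gap", -1))
    cands.append((Lfull[k - 1], "gap", k - 1))
    for c in range(k - 1):
        cands.append((max(Lfull[c], Rfull[c + 1]), "gap", c))
    cands.sort(key=lambda z: z[0])

    best = np.inf
    for lb, kind, idx in cands:
        if lb >= best - 1e-13:
            break
        if kind == "atom" and mass[idx] >= lb - 1e-13:
            best = lb  # shifted hulls are a feasible witness: bound attained
        elif kind == "atom":
            best = min(best, _mode_lp(t, l, u, idx, None))
        else:
            best = min(best, _mode_lp(t, l, u, None, idx))
    return 0.5 * float(best)


def dip_null_table(n: int, n_null: int = 1000, seed: int = 0) -> np.ndarray:
    """Sorted dips of ``n_null`` uniform(0,1) samples of size n.

    The uniform is the standard calibration null for the dip test; a table
    can be shared across many tests at the same sample size.
    """
    rng = np.random.default_rng(seed)
    return np.sort([dip_statistic(rng.random(n)) for _ in range(n_null)])


def dip_test_pvalue(d: float, n: int, n_null: int = 1000, seed: int = 0,
                    null_table: np.ndarray | None = None) -> float:
    """Monte-Carlo p-value: fraction of uniform-null dips >= d, with
    add-one smoothing (count + 1) / (n_null + 1)."""
    if n < 4:
        raise UndefinedStatisticError("dip p-value requires n >= 4")
    if null_table is None:
        if n_null < 100:
            warnings.warn("n_null < 100 gives a coarse p-value", stacklevel=2)
        null_table = dip_null_table(n, n_null, seed)
    m = null_table.size
    count = int((null_table >= d - 1e-12).sum())
    return (count + 1) / (m + 1)
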