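"""Differential abundance and covariate correlation of cell clusters.

Cluster abundances are percentages of a parent population per sample
(either all CD4 T cells, or the selected CD32a+ CD4 subset). Differentially
abundant clusters (DACs) are called per condition pair with an unpaired
Student t-test on the percentages plus a fold-change rule (significant iff
p < p_max AND fold change >= fc_min). Correlated clusters (CCs) relate
abundance to a per-sample covariate (total HIV DNA, log10 copies per 1e6
PBMC; 0 = undetectable in uninfected donors) through the Pearson
coefficient with thresholds on |r| and p.

Raw per-cluster p-values are used by default (no multiplicity correction);
a Benjamini-Hochberg option is provided as a documented deviation switch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clustering import ClusterModel
from .data import SampleSheet

__all__ = [
    "AbundanceMatrix",
    "DACRecord",
    "CCRecord",
    "abundance_matrix",
    "students_ttest",
    "welch_ttest",
    "identify_dacs",
    "pearson_stats",
    "pearson_pvalue_from_r",
    "identify_ccs",
    "benjamini_hochberg",
]

log = logging.getLogger(__name__)


@dataclass
class AbundanceMatrix:
    """Clusters x samples percentages relative to a named parent population."""

    percent: pd.DataFrame          # index: cluster, columns: sample_id
    parent: str                    # e.g. "CD4" or "CD32a_CD4"
    parent_counts: pd.Series       # per-sample parent cell counts

    def __post_init__(self) -> None:
        vals = self.percent.to_numpy(dtype=float)
        if ((vals < -1e-9) | (vals > 100 + 1e-9)).any():
            raise ValueError("abundances must be percentages in [0, 100]")


def abundance_matrix(model: ClusterModel, sheet: SampleSheet,
                     parent_filter: set[int] | None = None,
                     parent_name: str | None = None) -> AbundanceMatrix:
    """Percent of parent cells in each cluster, per sample.

    ``parent_filter`` restricts both the rows and the per-sample denominator
    to the given cluster ids (e.g. the CD32a+ selection); with None the
    parent is every assigned cell (all CD4 T cells). Samples with zero
    parent cells are excluded with a warning.
    """
    counts = model.sample_counts.reindex(columns=sheet.sample_ids, fill_value=0)
    if parent_filter is not None:
        keep = [c for c in counts.index if c in parent_filter]
        counts = counts.loc[keep]
        parent = parent_name or "selected"
    else:
        parent = parent_name or "CD4"
    totals = counts.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        warnings.warn(f"samples with zero parent cells excluded: {zero}")
        counts = counts.drop(columns=zero)
        totals = totals.drop(index=zero)
    percent = 100.0 * counts.div(totals, axis=1)
    return AbundanceMatrix(percent=percent, parent=parent,
                           parent_counts=totals.astype(int))


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def students_ttest(a, b) -> tuple[float, float]:
    """Unpaired Student t-test (pooled variance), two-sided.

    Degenerate samples (zero pooled variance) give t = 0, p = 1 when the
    means agree and p = 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test requires at least 2 values per group")
    na, nb = a.size, b.size
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        log.warning("zero pooled variance with unequal means: degenerate t-test")
        return np.sign(diff) * np.inf, 0.0
    t = diff / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df=na + nb - 2)
    return float(t), float(p)


def welch_ttest(a, b) -> tuple[float, float]:
    """Welch (unequal-variance) alternative, available via configuration."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


@dataclass
class DACRecord:
    cluster: int
    condition_a: str
    condition_b: str
    mean_a: float
    mean_b: float
    fold_change: float           # max(ratio, 1/ratio) >= 1
    direction: str               # "up" or "down" in condition_a
    t: float
    p: float
    significant: bool


def identify_dacs(abund: AbundanceMatrix, sheet: SampleSheet,
                  pairs: list[tuple[str, str]], fc_min: float = 2.0,
                  p_max: float = 0.05, use_welch: bool = False,
                  fdr: bool = False) -> list[DACRecord]:
    """Differentially abundant clusters for each condition pair.

    Significant iff p < p_max and fold change >= fc_min. Fold change is the
    ratio of mean percentages (direction reported separately); if both means
    are 0 the fold change is 1, if one is 0 it is infinite and the call
    rests on the p-value alone. ``fdr`` switches the p threshold to
    Benjamini-Hochberg-adjusted values (off by default: raw per-cluster
    p-values are the convention here).
    """
    conditions = set(sheet.frame["condition"])
    for pair in pairs:
        for cond in pair:
            if cond not in conditions:
                raise ValueError(f"unknown condition {cond!r}")
    test = welch_ttest if use_welch else students_ttest
    records: list[DACRecord] = []
    for cond_a, cond_b in pairs:
        sa = [s for s in sheet.samples_in(cond_a) if s in abund.percent.columns]
        sb = [s for s in sheet.samples_in(cond_b) if s in abund.percent.columns]
        if len(sa) < 2 or len(sb) < 2:
            raise ValueError(f"need >= 2 samples per condition in ({cond_a}, {cond_b})")
        for cluster in abund.percent.index:
            a = abund.percent.loc[cluster, sa].to_numpy(dtype=float)
            b = abund.percent.loc[cluster, sb].to_numpy(dtype=float)
            t, p = test(a, b)
            ma, mb = float(a.mean()), float(b.mean())
            if ma == 0.0 and mb == 0.0:
                fc = 1.0
            elif ma == 0.0 or mb == 0.0:
                fc = np.inf
            else:
                ratio = ma / mb
                fc = max(ratio, 1.0 / ratio)
            records.append(DACRecord(
                cluster=int(cluster), condition_a=cond_a, condition_b=cond_b,
                mean_a=ma, mean_b=mb, fold_change=float(fc),
                direction="up" if ma >= mb else "down",
                t=t, p=p, significant=False))
    pvals = np.array([r.p for r in records])
    thresh = pvals < p_max
    if fdr:
        thresh = benjamini_hochberg(pvals) < p_max
    for r, ok in zip(records, thresh):
        r.significant = bool(ok and r.fold_change >= fc_min)
    return records


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def pearson_pvalue_from_r(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson coefficient via the t transform:
    t = r sqrt(n-2) / sqrt(1-r^2) with n-2 degrees of freedom."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def pearson_stats(x, y) -> tuple[float, float]:
    """Sample Pearson coefficient with its two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("Pearson correlation requires >= 3 paired finite values")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-12:   # exact linear dependence up to rounding
        r = float(np.sign(r))
    return r, pearson_pvalue_from_r(r, x.size)


@dataclass
class CCRecord:
    cluster: int
    r: float
    n: int
    p: float
    significant: bool


def identify_ccs(abund: AbundanceMatrix, covariate: pd.Series,
                 r_min: float = 0.65, p_max: float = 0.05) -> list[CCRecord]:
    """Clusters whose abundance correlates with the covariate.

    Uses the samples present in both the abundance matrix and the covariate;
    significant iff |r| > r_min and p < p_max (sign retained, so positive
    and negative correlates are distinguished).
    """
    samples = [s for s in abund.percent.columns if s in covariate.index]
    if len(samples) < 3:
        raise ValueError("correlation requires >= 3 samples with covariate")
    cov = covariate.loc[samples].to_numpy(dtype=float)
    if np.std(cov) == 0.0:
        raise ValueError("constant covariate: correlation undefined")
    out: list[CCRecord] = []
    for cluster in abund.percent.index:
        vals = abund.percent.loc[cluster, samples].to_numpy(dtype=float)
        if np.std(vals) == 0.0:
            log.warning("cluster %s has constant abundance; skipped", cluster)
            continue
        r, p = pearson_stats(vals, cov)
        out.append(CCRecord(cluster=int(cluster), r=r, n=len(samples), p=p,
                            significant=bool(abs(r) > r_min and p < p_max)))
    return out
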