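"""Validation harnesses: planted-effect recovery and null calibration.

These run the pipeline stages on synthetic studies where the ground truth
is known and score the outcome against it — the package's own way of
demonstrating that the analysis recovers what was planted and stays
calibrated when nothing was.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import clustering, phenotyping, preprocess, stats, synth
from .data import EventTable, Panel, SampleSheet
from .stats import AbundanceMatrix

__all__ = [
    "majority_labels",
    "RecoveryResult",
    "planted_effect_run",
    "null_dac_study",
    "truth_abundance_matrix",
]


def majority_labels(model: clustering.ClusterModel,
                    gated_truth: dict[str, np.ndarray]) -> pd.Series:
    """Majority ground-truth population per cluster.

    ``gated_truth`` maps sample_id -> per-gated-event truth label array
    aligned with the model's event indices.
    """
    votes: dict[int, dict[str, int]] = {}
    for sid, grp in model.assignments.groupby("sample_id", sort=False):
        labs = gated_truth[sid]
        for cluster, sub in grp.groupby("cluster"):
            if cluster < 0:
                continue
            counts = pd.Series(labs[sub["event_index"].to_numpy()]).value_counts()
            d = votes.setdefault(int(cluster), {})
            for name, c in counts.items():
                d[name] = d.get(name, 0) + int(c)
    return pd.Series({c: max(v, key=v.get) for c, v in votes.items()},
                     name="majority_population")


@dataclass
class RecoveryResult:
    seed: int
    dac_flagged: bool          # planted population called as DAC, right direction
    cc_flagged: bool           # planted population called as positive CC
    planted_clusters: list[int]
    best_r: float
    best_dac_p: float


def planted_effect_run(seed: int, events_per_sample: int = 5000,
                       discovery_cap: int = 700, k_target: int = 60,
                       fc_min: float = 2.0, p_max: float = 0.05,
                       r_min: float = 0.65) -> RecoveryResult:
    """One full recovery experiment on a study with a planted
    condition-dependent CD32a+ effector/memory population.

    Generates the study, gates CD4 T cells, clusters (discovery on a capped
    uniform downsample, up-sampling on all gated events), selects CD32a+
    clusters, and asks whether any cluster whose majority truth label is the
    planted population is (a) a significant DAC for primary-vs-healthy with
    direction "up", relative to the CD32a+ parent, and (b) a significant
    positive correlate of the HIV-DNA covariate, relative to the CD4 parent.
    """
    design = synth.paper_like_design(seed=seed, events_per_sample=events_per_sample)
    study = synth.generate_study(design)
    planted = design.planted_cc.population

    trans = [preprocess.transform_arcsinh(t, design.cofactor) for t in study.tables]
    gcfg = preprocess.auto_gating_config(trans, study.panel, seed=seed)
    gated: list[EventTable] = []
    gated_truth: dict[str, np.ndarray] = {}
    for raw, tt in zip(study.tables, trans):
        res = preprocess.gate_events(tt, study.panel, gcfg)
        gated.append(res.final)
        gated_truth[raw.sample_id] = study.truth.labels[raw.sample_id][res.kept["cd4_t"]]

    down = preprocess.downsample_uniform(gated, seed=seed, n_max=discovery_cap)
    model = clustering.cluster_events(gated, study.panel, k_target=k_target,
                                      seed=seed, discovery_tables=down)
    model = clustering.filter_small_clusters(model, min_cells=40)
    majority = majority_labels(model, gated_truth)
    planted_clusters = [c for c, lab in majority.items() if lab == planted]

    parent = pd.DataFrame(
        np.vstack([t.marker_array(study.panel, model.markers) for t in gated]),
        columns=model.markers)
    bounds = phenotyping.marker_bounds(parent)
    cats = phenotyping.categorize_clusters(model.sample_medians, bounds)
    rules = [r for r in phenotyping.DEFAULT_MYELOID_RULES
             if all(m in cats.columns for m in r)]
    selected = phenotyping.select_clusters_by_category(cats, "CD32a", 4, rules)

    dac_flagged = False
    best_dac_p = 1.0
    if selected:
        ab_sel = stats.abundance_matrix(model, study.sheet, parent_filter=selected,
                                        parent_name="CD32a_CD4")
        dacs = stats.identify_dacs(ab_sel, study.sheet,
                                   [("primary_HIV", "healthy")],
                                   fc_min=fc_min, p_max=p_max)
        for r in dacs:
            if r.cluster in planted_clusters:
                best_dac_p = min(best_dac_p, r.p)
                if r.significant and r.direction == "up":
                    dac_flagged = True

    ab_cd4 = stats.abundance_matrix(model, study.sheet)
    ccs = stats.identify_ccs(ab_cd4, study.sheet.covariate(),
                             r_min=r_min, p_max=p_max)
    cc_flagged = False
    best_r = 0.0
    for r in ccs:
        if r.cluster in planted_clusters:
            if abs(r.r) > abs(best_r):
                best_r = r.r
            if r.significant and r.r > 0:
                cc_flagged = True
    return RecoveryResult(seed=seed, dac_flagged=dac_flagged, cc_flagged=cc_flagged,
                          planted_clusters=planted_clusters, best_r=best_r,
                          best_dac_p=best_dac_p)


def truth_abundance_matrix(study: synth.SyntheticStudy) -> AbundanceMatrix:
    """Abundance matrix built from the ground-truth labels (populations play
    the role of clusters) — used for calibration runs that need no
    clustering."""
    ab = study.truth.abundances
    percent = 100.0 * ab.copy()
    percent.index = pd.Index(range(len(ab.index)), name="cluster")
    counts = pd.Series(
        {t.sample_id: t.n_events for t in study.tables}, name="parent")
    return AbundanceMatrix(percent=percent, parent="CD4",
                           parent_counts=counts.loc[percent.columns])


def null_dac_study(seed: int, events_per_sample: int = 150) -> float:
    """Fraction of (cluster, pair) DAC calls on one null study at
    p < 0.05 with no fold-change requirement (fc_min = 1)."""
    design = synth.null_design(seed=seed, events_per_sample=events_per_sample)
    study = synth.generate_study(design)
    abund = truth_abundance_matrix(study)
    conds = list(design.conditions)
    pairs = [(a, b) for i, a in enumerate(conds) for b in conds[i + 1:]]
    dacs = stats.identify_dacs(abund, study.sheet, pairs, fc_min=1.0, p_max=0.05)
    return sum(r.significant for r in dacs) / len(dacs)
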