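"""Translate cluster medians into the five-tier phenotype grid.

Each marker's 5th-95th percentile range over all CD4 T cells is split into
five equal tiers (negative / low / medium / high / very high); cluster
summaries (mean over samples of per-sample medians) are binned against it.
CD32a+ clusters are the tiers-4-and-5 column entries, and the CCR7 x CD45RA
pattern names the T-cell subsets.
"""

import numpy as np
import pandas as pd

from cytoclust import (auto_gating_config, categorize_clusters, cluster_events,
                       gate_events, generate_study, ks_profile,
                       label_tcell_subsets, marker_bounds,
                       select_clusters_by_category, tiny_design,
                       transform_arcsinh)

study = generate_study(tiny_design(seed=1))
trans = [transform_arcsinh(t) for t in study.tables]
cfg = auto_gating_config(trans, study.panel, seed=0)
gated = [gate_events(t, study.panel, cfg).final for t in trans]
model = cluster_events(gated, study.panel, k_target=25, seed=0)

markers = model.markers
parent = pd.DataFrame(np.vstack([t.marker_array(study.panel, markers)
                                 for t in gated]), columns=markers)
bounds = marker_bounds(parent)
cats = categorize_clusters(model.sample_medians, bounds)
print("category grid (rows = clusters, tiers 1..5):")
print(cats.head(8).to_string())

subsets = label_tcell_subsets(cats)
print("\nsubset composition:", subsets.value_counts().to_dict())

selected = select_clusters_by_category(cats, "CD32a", min_category=4)
print(f"CD32a+ clusters (tier >= 4): {sorted(selected)}")

if selected:
    c = sorted(selected)[0]
    values = {t.sample_id: t.marker_array(study.panel, markers) for t in gated}
    cluster_ev = pd.DataFrame(model.events_of(c, values), columns=markers)
    prof = ks_profile(cluster_ev, parent, threshold=0.30)
    print(f"\nKS profile of cluster {c} vs all CD4 T cells "
          f"(markers with D >= 0.30 distinguish it):")
    print(prof.distances.round(3).to_string())
# High KS markers are the ones a sorter would use to isolate the subset.
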