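"""Study-directory input/output.

A study directory holds one CSV event table per sample (header = channel
ids, one row per event, raw dual counts), ``sample_sheet.csv``
(sample_id, subject_id, condition, hiv_dna_log10), ``panel.csv``
(channel, marker, role) and, for synthetic studies, ``truth.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .data import EventTable, Panel, SampleSheet
from .synth import StudyTruth, SyntheticStudy

__all__ = ["write_study", "read_study", "events_filename"]

FLOAT_FORMAT = "%.10g"


def events_filename(sample_id: str) -> str:
    return f"events_{sample_id}.csv"


def write_study(study: SyntheticStudy, out_dir: str | Path) -> Path:
    """Write every sample file, the sheet, the panel and the truth.

    Output is byte-identical for identical studies (fixed float format,
    fixed column order).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for table in study.tables:
        table.values.to_csv(out / events_filename(table.sample_id),
                            index=False, float_format=FLOAT_FORMAT)
    study.sheet.frame.to_csv(out / "sample_sheet.csv", index=False,
                             float_format=FLOAT_FORMAT)
    study.panel.to_frame().to_csv(out / "panel.csv", index=False)
    (out / "truth.json").write_text(study.truth.to_json())
    return out


def read_study(study_dir: str | Path
               ) -> tuple[list[EventTable], SampleSheet, Panel, StudyTruth | None]:
    """Load a study directory written by :func:`write_study` (or assembled
    by hand in the same dialect)."""
    root = Path(study_dir)
    panel_path = root / "panel.csv"
    sheet_path = root / "sample_sheet.csv"
    if not panel_path.exists():
        raise FileNotFoundError(f"missing panel file: {panel_path}")
    if not sheet_path.exists():
        raise FileNotFoundError(f"missing sample sheet: {sheet_path}")
    panel = Panel.from_frame(pd.read_csv(panel_path))
    sheet = SampleSheet(pd.read_csv(sheet_path))
    tables = []
    for sid in sheet.sample_ids:
        path = root / events_filename(sid)
        if not path.exists():
            raise FileNotFoundError(f"missing event table for sample {sid!r}: {path}")
        values = pd.read_csv(path)
        missing = set(panel.channel_ids) - set(values.columns)
        if missing:
            raise ValueError(f"sample {sid!r} lacks channels {sorted(missing)}")
        tables.append(EventTable(sample_id=sid, values=values[panel.channel_ids]))
    truth = None
    truth_path = root / "truth.json"
    if truth_path.exists():
        truth = StudyTruth.from_json(truth_path.read_text())
    return tables, sheet, panel, truth


# ---------------------------------------------------------------------------
# intermediate stage artifacts (for the stage-wise CLI)
# ---------------------------------------------------------------------------

def write_gated(tables: list[EventTable], panel: Panel, sheet: SampleSheet,
                out_dir: str | Path, gate_counts: dict | None = None) -> Path:
    """Persist gated, transformed per-sample tables plus panel and sheet."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for t in tables:
        t.values.to_csv(out / f"gated_{t.sample_id}.csv", index=False,
                        float_format=FLOAT_FORMAT)
    panel.to_frame().to_csv(out / "panel.csv", index=False)
    sheet.frame.to_csv(out / "sample_sheet.csv", index=False,
                       float_format=FLOAT_FORMAT)
    meta = {"scale": "transformed"}
    if gate_counts is not None:
        meta["gate_counts"] = gate_counts
    (out / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return out


def read_gated(gated_dir: str | Path
               ) -> tuple[list[EventTable], SampleSheet, Panel]:
    root = Path(gated_dir)
    panel = Panel.from_frame(pd.read_csv(root / "panel.csv"))
    sheet = SampleSheet(pd.read_csv(root / "sample_sheet.csv"))
    scale = json.loads((root / "meta.json").read_text())["scale"]
    tables = [EventTable(sample_id=sid,
                         values=pd.read_csv(root / f"gated_{sid}.csv"),
                         scale=scale)
              for sid in sheet.sample_ids]
    return tables, sheet, panel


def write_model(model, out_dir: str | Path) -> Path:
    from .clustering import ClusterModel  # local import to avoid a cycle
    assert isinstance(model, ClusterModel)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model.assignments.to_csv(out / "assignments.csv", index=False)
    model.medians.to_csv(out / "medians.csv", float_format=FLOAT_FORMAT)
    model.sample_medians.to_csv(out / "sample_medians.csv",
                                float_format=FLOAT_FORMAT)
    model.sizes.to_frame().to_csv(out / "sizes.csv")
    model.sample_counts.to_csv(out / "sample_counts.csv")
    pd.DataFrame(model.mst_edges,
                 columns=["cluster_a", "cluster_b", "weight"]).to_csv(
        out / "mst_edges.csv", index=False, float_format=FLOAT_FORMAT)
    (out / "model_meta.json").write_text(json.dumps(
        {"k_target": model.k_target, "markers": model.markers}, indent=2))
    return out


def read_model(model_dir: str | Path):
    from .clustering import ClusterModel
    root = Path(model_dir)
    meta = json.loads((root / "model_meta.json").read_text())
    mst = [tuple(r) for r in pd.read_csv(root / "mst_edges.csv")
           .itertuples(index=False)]
    return ClusterModel(
        k_target=int(meta["k_target"]),
        markers=list(meta["markers"]),
        assignments=pd.read_csv(root / "assignments.csv"),
        medians=pd.read_csv(root / "medians.csv", index_col="cluster"),
        sample_medians=pd.read_csv(root / "sample_medians.csv",
                                   index_col=["cluster", "sample_id"]),
        sizes=pd.read_csv(root / "sizes.csv", index_col="cluster")["n_cells"],
        sample_counts=pd.read_csv(root / "sample_counts.csv", index_col="cluster"),
        mst_edges=[(int(a), int(b), float(w)) for a, b, w in mst],
    )
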