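"""Bead normalization, arcsinh transform, gating, uniform downsampling."""

import numpy as np
import pandas as pd
import pytest

from cytoclust import synth
from cytoclust.data import TRANSFORMED, EventTable
from cytoclust.preprocess import (NormalizationError, auto_gating_config,
                                  bead_normalize, downsample_uniform,
                                  gate_events, identify_beads,
                                  inverse_transform, transform_arcsinh)
from conftest import make_table


def _bead_table(n=400, n_channels=3, bead_every=10, second_half_factor=1.0):
    """Events with interleaved bright beads on every channel."""
    rng = np.random.default_rng(0)
    vals = np.abs(rng.normal(100, 5, size=(n, n_channels)))
    # one extra first-half bead keeps the global bead median at the
    # first-half level when the second half is rescaled
    bead_idx = np.r_[np.arange(0, n, bead_every), n // 4 + 1]
    vals[bead_idx] = 500.0
    vals[n // 2:] *= second_half_factor
    cols = [f"C{i}" for i in range(n_channels)]
    return make_table(vals, cols), bead_idx


def test_constant_beads_leave_events_unchanged():
    table, beads = _bead_table()
    out = bead_normalize(table, beads, window=100, drop_beads=False)
    np.testing.assert_allclose(out.values.to_numpy(), table.values.to_numpy(),
                               rtol=1e-12)


def test_doubled_second_half_scaled_by_half():
    table, beads = _bead_table(second_half_factor=2.0)
    out = bead_normalize(table, beads, window=200, drop_beads=False)
    np.testing.assert_allclose(out.values.to_numpy()[200:],
                               table.values.to_numpy()[200:] / 2.0, rtol=1e-9)
    np.testing.assert_allclose(out.values.to_numpy()[:200],
                               table.values.to_numpy()[:200], rtol=1e-9)


def test_normalization_removes_synthetic_drift():
    # multiplicative ramp 1 -> 1.5 over acquisition: per-window bead medians
    # have CV >= 0.1 before normalization and < 0.02 after
    design = synth.tiny_design(seed=3)
    design.signal_drift = 0.5
    design.artifact_rates = (0.1, 0.0, 0.0)
    table, truth = synth.generate_sample(design, "healthy", 0, seed=2)
    beads = np.flatnonzero(truth["labels"].astype(str) == "bead")
    bead_ch = design.panel.bead_channel
    window = 100

    def window_cv(tab, bead_idx):
        vals = tab.values[bead_ch].to_numpy()
        win = np.asarray(tab.acquisition_index) // window
        meds = [np.median(vals[bead_idx[win[bead_idx] == w]])
                for w in np.unique(win[bead_idx])]
        return np.std(meds) / np.mean(meds)

    assert window_cv(table, beads) >= 0.1
    out = bead_normalize(table, beads, window=window, drop_beads=False)
    assert window_cv(out, beads) < 0.02


def test_bead_normalize_idempotent():
    table, beads = _bead_table(second_half_factor=1.7)
    once = bead_normalize(table, beads, window=100, drop_beads=False)
    twice = bead_normalize(once, beads, window=100, drop_beads=False)
    np.testing.assert_allclose(twice.values.to_numpy(), once.values.to_numpy(),
                               rtol=1e-9)


def test_empty_bead_index_is_an_error():
    table, _ = _bead_table()
    with pytest.raises(NormalizationError):
        bead_normalize(table, np.array([], dtype=int))


def test_beadless_window_borrows_nearest_factor(caplog):
    table, beads = _bead_table(n=400, bead_every=10, second_half_factor=2.0)
    beads = beads[beads < 300]  # last window has no beads
    out = bead_normalize(table, beads, window=100, drop_beads=False)
    # last window borrowed the factor of window 3 (same doubled intensity)
    np.testing.assert_allclose(out.values.to_numpy()[300:],
                               table.values.to_numpy()[300:] / 2.0, rtol=1e-9)


def test_arcsinh_closed_form_and_ranks(rng):
    cols = ["C0", "C1"]
    vals = rng.exponential(50, size=(200, 2))
    vals[0] = [0.0, 5.0]
    table = make_table(vals, cols)
    out = transform_arcsinh(table, cofactor=5.0)
    assert out.scale == TRANSFORMED
    assert out.values.iloc[0, 0] == 0.0
    assert out.values.iloc[0, 1] == pytest.approx(np.arcsinh(1.0))
    for c in cols:  # monotone: per-channel ranks preserved
        assert (np.argsort(out.values[c]) == np.argsort(table.values[c])).all()
    back = inverse_transform(out, cofactor=5.0)
    np.testing.assert_allclose(back.values.to_numpy(), vals, rtol=1e-9)


def test_transform_rejects_bad_cofactor_and_double_transform():
    table = make_table([[1.0]], ["C0"])
    with pytest.raises(ValueError):
        transform_arcsinh(table, cofactor=0.0)
    once = transform_arcsinh(table)
    with pytest.raises(ValueError):
        transform_arcsinh(once)


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def gated_tiny():
    study = synth.generate_study(synth.tiny_design(seed=2))
    trans = [transform_arcsinh(t) for t in study.tables]
    cfg = auto_gating_config(trans, study.panel, seed=0)
    results = [gate_events(t, study.panel, cfg) for t in trans]
    return study, results


def test_gate_nesting(gated_tiny):
    _, results = gated_tiny
    for res in results:
        counts = [res.counts[g] for g in res.GATES]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_gating_recall_precision(gated_tiny):
    study, results = gated_tiny
    cd4_pops = {p.name for p in study.design.populations if p.name.startswith("cd4")}
    recalls, precisions = [], []
    for table, res in zip(study.tables, results):
        labels = study.truth.labels[table.sample_id].astype(str)
        is_cd4 = np.isin(labels, list(cd4_pops))
        kept = np.zeros(len(labels), bool)
        kept[res.kept["cd4_t"]] = True
        tp = (kept & is_cd4).sum()
        recalls.append(tp / is_cd4.sum())
        precisions.append(tp / max(kept.sum(), 1))
    assert np.mean(recalls) >= 0.95
    assert np.mean(precisions) >= 0.95


def test_doublets_removed_at_singlet_gate(gated_tiny):
    study, results = gated_tiny
    for table, res in zip(study.tables, results):
        labels = study.truth.labels[table.sample_id].astype(str)
        doublets = set(np.flatnonzero(labels == "doublet"))
        assert doublets.isdisjoint(res.kept["singlets"])


def test_identify_beads_finds_planted_beads(gated_tiny):
    study, _ = gated_tiny
    trans = transform_arcsinh(study.tables[0])
    cfg = auto_gating_config([trans], study.panel, seed=0)
    found = set(identify_beads(study.tables[0], study.panel,
                               bead_min=cfg.bead_max, dna_low=cfg.dna_low))
    truth = set(np.flatnonzero(
        study.truth.labels[study.tables[0].sample_id].astype(str) == "bead"))
    jaccard = len(found & truth) / max(len(found | truth), 1)
    assert jaccard >= 0.9


def test_all_bead_input_gates_to_zero(mini_panel):
    # bright bead channel, near-zero DNA: everything dies at the singlet gate
    vals = np.column_stack([
        np.full(50, 0.2),      # DNA ~ 0
        np.full(50, 400.0),    # bead channel bright
        np.full(50, 1.0),
        np.full(50, 1.0),
    ])
    table = make_table(vals, [c.channel_id for c in mini_panel.channels])
    from cytoclust.preprocess import GatingConfig
    cfg = GatingConfig(dna_low=2.5, dna_high=4.5, bead_max=2.0,
                       viability_max=2.0, cd45_min=1.5, cd3_min=1.5,
                       cd19_max=1.5, cd4_min=1.5, cd8_max=1.5)
    # panel lacks lineage markers on purpose: expect a panel error
    from cytoclust.data import PanelError
    with pytest.raises(PanelError):
        gate_events(transform_arcsinh(table), mini_panel, cfg)


# ---------------------------------------------------------------------------
# uniform downsampling
# ---------------------------------------------------------------------------

def _tables_of_sizes(sizes, rng):
    return [make_table(rng.normal(size=(s, 2)) ** 2, ["C0", "C1"],
                       sample_id=f"s{i}") for i, s in enumerate(sizes)]


def test_downsample_to_minimum(rng):
    tables = _tables_of_sizes([50, 200, 120], rng)
    out = downsample_uniform(tables, seed=0)
    assert [t.n_events for t in out] == [50, 50, 50]


def test_downsample_equal_sizes_keep_all(rng):
    tables = _tables_of_sizes([100, 100], rng)
    out = downsample_uniform(tables, seed=0)
    for orig, new in zip(tables, out):
        assert sorted(map(tuple, new.values.to_numpy())) == \
            sorted(map(tuple, orig.values.to_numpy()))


def test_downsample_deterministic(rng):
    tables = _tables_of_sizes([80, 150], rng)
    a = downsample_uniform(tables, seed=42)
    b = downsample_uniform(tables, seed=42)
    for x, y in zip(a, b):
        assert x.values.equals(y.values)


def test_downsample_cap(rng):
    tables = _tables_of_sizes([80, 150], rng)
    out = downsample_uniform(tables, seed=0, n_max=30)
    assert [t.n_events for t in out] == [30, 30]


def test_downsample_rejects_empty(rng):
    tables = _tables_of_sizes([10], rng)
    tables.append(make_table(np.empty((0, 2)), ["C0", "C1"], sample_id="empty"))
    with pytest.raises(ValueError, match="empty"):
        downsample_uniform(tables, seed=0)
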