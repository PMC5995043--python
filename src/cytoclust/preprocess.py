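"""Signal normalization, transformation, and CD4 T-cell gating.

The preprocessing chain mirrors standard CyTOF practice:

1. windowed bead normalization of raw dual counts (drift correction from
   spiked-in polystyrene beads), then bead removal;
2. arcsinh transform with cofactor 5;
3. a sequential gating hierarchy isolating live singlet CD4 T cells:
   DNA singlets -> non-bead -> live -> CD45+ leukocytes ->
   CD3+ CD19- CD4+ CD8- T cells.

Gate thresholds can be supplied manually or derived from the data
(two-component Gaussian-mixture midpoints per gating channel).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .data import RAW, TRANSFORMED, EventTable, Panel, PanelError

__all__ = [
    "GatingConfig",
    "GateResult",
    "NormalizationError",
    "bead_normalize",
    "identify_beads",
    "transform_arcsinh",
    "inverse_transform",
    "auto_gating_config",
    "gate_events",
    "downsample_uniform",
]

log = logging.getLogger(__name__)

DEFAULT_COFACTOR = 5.0
DEFAULT_WINDOW = 500

# doublets carry twice the DNA-intercalator signal; on the arcsinh scale a
# 2x raw shift is ~log(2), so the singlet/doublet midpoint sits ~log(2)/2
# above the singlet mode
_DOUBLET_SHIFT = float(np.log(2.0))
# arcsinh-scale background of an unstained channel (generator convention and
# fallback reference when a gating channel is not bimodal)
_BACKGROUND = 0.3


class NormalizationError(ValueError):
    """Bead normalization cannot be performed."""


# ---------------------------------------------------------------------------
# bead normalization
# ---------------------------------------------------------------------------

def bead_normalize(events: EventTable, bead_index: np.ndarray,
                   window: int = DEFAULT_WINDOW, *,
                   drop_beads: bool = True,
                   min_bead_signal: float = 25.0) -> EventTable:
    """Correct acquisition drift using the bead events' signal.

    For every channel and every window of ``window`` consecutive events (in
    acquisition order), the scaling factor is

        global median bead intensity / window median bead intensity,

    and all events in the window are multiplied by it. Only channels on
    which the beads carry genuine signal (global bead median >=
    ``min_bead_signal`` raw counts) contribute their own factor; the other
    (plain antibody) channels borrow the median factor of the
    bead-informative channels, since instrument drift is common to all
    channels and background-level bead medians would only inject noise.
    Windows without any
    bead are assigned the factor of the nearest bead-containing window (a
    warning is logged). Bead events are removed from the returned table
    unless ``drop_beads`` is false.
    """
    if events.scale != RAW:
        raise ValueError("bead_normalize expects a raw-scale table")
    bead_index = np.asarray(bead_index, dtype=int)
    if bead_index.size == 0:
        raise NormalizationError("no bead events: normalization impossible")
    if window < 1:
        raise ValueError("window must be >= 1")

    values = events.values.to_numpy(dtype=float).copy()
    n = len(values)
    win_of = np.arange(n) // window
    n_win = int(win_of.max()) + 1 if n else 0

    is_bead = np.zeros(n, dtype=bool)
    is_bead[bead_index] = True
    bead_vals = values[is_bead]
    global_med = np.median(bead_vals, axis=0)

    eps = 1e-12
    informative = global_med >= min_bead_signal
    if not informative.any():
        log.warning("no bead-informative channel (all bead medians < %g); "
                    "factors left at 1", min_bead_signal)

    # per-window, per-channel factors
    factors = np.full((n_win, values.shape[1]), np.nan)
    has_bead = np.zeros(n_win, dtype=bool)
    bead_win = win_of[is_bead]
    for w in range(n_win):
        sel = bead_vals[bead_win == w]
        if len(sel) == 0:
            continue
        has_bead[w] = True
        med = np.median(sel, axis=0)
        f = np.ones(values.shape[1])
        ok = informative & (med > eps)
        f[ok] = global_med[ok] / med[ok]
        if informative.sum() and (~informative).any():
            f[~informative] = np.median(f[informative])
        factors[w] = f

    if not has_bead.all():
        missing = np.flatnonzero(~has_bead)
        log.warning("windows without beads: %s; borrowing nearest factors",
                    missing.tolist())
        with_bead = np.flatnonzero(has_bead)
        for w in missing:
            nearest = with_bead[np.argmin(np.abs(with_bead - w))]
            factors[w] = factors[nearest]

    values *= factors[win_of]
    out = events.replace_values(
        pd.DataFrame(values, columns=events.values.columns))
    if drop_beads:
        out = out.take(np.flatnonzero(~is_bead))
    return out


def identify_beads(events: EventTable, panel: Panel, *,
                   bead_min: float, dna_low: float,
                   cofactor: float = DEFAULT_COFACTOR) -> np.ndarray:
    """Indices of bead events: high bead-channel signal and near-zero DNA.

    Thresholds are on the transformed scale; the table may be raw (it is
    transformed internally for the comparison only).
    """
    bead = np.arcsinh(events.values[panel.bead_channel].to_numpy(float) / cofactor) \
        if events.scale == RAW else events.values[panel.bead_channel].to_numpy(float)
    dna = events.values[panel.dna_channels[0]].to_numpy(float)
    if events.scale == RAW:
        dna = np.arcsinh(dna / cofactor)
    return np.flatnonzero((bead > bead_min) & (dna < dna_low))


# ---------------------------------------------------------------------------
# transform
# ---------------------------------------------------------------------------

def transform_arcsinh(events: EventTable, cofactor: float = DEFAULT_COFACTOR) -> EventTable:
    """Apply x -> asinh(x / cofactor) to every channel (monotone per channel)."""
    if cofactor <= 0:
        raise ValueError("cofactor must be > 0")
    if events.scale != RAW:
        raise ValueError("transform_arcsinh expects a raw-scale table")
    vals = np.arcsinh(events.values.to_numpy(dtype=float) / cofactor)
    return events.replace_values(
        pd.DataFrame(vals, columns=events.values.columns), scale=TRANSFORMED)


def inverse_transform(events: EventTable, cofactor: float = DEFAULT_COFACTOR) -> EventTable:
    if cofactor <= 0:
        raise ValueError("cofactor must be > 0")
    if events.scale != TRANSFORMED:
        raise ValueError("inverse_transform expects a transformed table")
    vals = np.sinh(events.values.to_numpy(dtype=float)) * cofactor
    return events.replace_values(
        pd.DataFrame(vals, columns=events.values.columns), scale=RAW)


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------

@dataclass
class GatingConfig:
    """Thresholds on the transformed scale for the gating hierarchy."""

    dna_low: float
    dna_high: float
    bead_max: float
    viability_max: float
    cd45_min: float
    cd3_min: float
    cd19_max: float
    cd4_min: float
    cd8_max: float

    def validate(self) -> None:
        if not self.dna_low < self.dna_high:
            raise ValueError("dna_low must be < dna_high")
        for name, v in self.__dict__.items():
            if not np.isfinite(v):
                raise ValueError(f"threshold {name} is not finite")


@dataclass
class GateResult:
    """Nested kept-event index sets along the gating hierarchy."""

    sample_id: str
    kept: dict[str, np.ndarray]  # gate name -> indices into the input table
    final: EventTable

    GATES = ("singlets", "non_bead", "live", "cd45_pos", "cd4_t")

    @property
    def counts(self) -> dict[str, int]:
        return {g: int(len(self.kept[g])) for g in self.GATES}


def _bimodal_midpoint(x: np.ndarray, rng: np.random.Generator,
                      max_events: int = 5000) -> float:
    """Midpoint of a 2-component 1-D Gaussian fit; falls back to the midpoint
    between the reference background level and the dominant mode when the two
    components do not separate (effectively unimodal channel)."""
    x = np.asarray(x, float)
    if x.size > max_events:
        x = x[rng.choice(x.size, max_events, replace=False)]
    gm = GaussianMixture(n_components=2, random_state=int(rng.integers(2 ** 31)),
                         n_init=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(x.reshape(-1, 1))
    mu = np.sort(gm.means_.ravel())
    sd = np.sqrt(gm.covariances_.ravel().mean())
    sep = (mu[1] - mu[0]) / max(sd, 1e-9)
    if sep < 2.0:
        return float((_BACKGROUND + mu[1]) / 2.0)
    return float(mu.mean())


def auto_gating_config(tables: list[EventTable], panel: Panel,
                       seed: int = 0) -> GatingConfig:
    """Data-driven default thresholds from pooled transformed events.

    DNA singlet interval: the doublet mode sits ~log(2) above the singlet
    mode on the arcsinh scale, so the upper bound is the singlet median plus
    half that shift; the lower bound excludes DNA-negative debris/beads.
    Other gates use two-component Gaussian-mixture midpoints.
    """
    for t in tables:
        if t.scale != TRANSFORMED:
            raise ValueError("auto_gating_config expects transformed tables")
    rng = np.random.default_rng(seed)
    pooled = pd.concat([t.values for t in tables], ignore_index=True)

    dna = pooled[panel.dna_channels[0]].to_numpy(float)
    dna_med = float(np.median(dna))
    dna_low = dna_med - 1.0
    dna_high = dna_med + _DOUBLET_SHIFT / 2.0

    def chan(marker: str) -> np.ndarray:
        return pooled[panel.channel_for(marker)].to_numpy(float)

    bead_max = _bimodal_midpoint(pooled[panel.bead_channel].to_numpy(float), rng)
    viability_max = _bimodal_midpoint(pooled[panel.viability_channel].to_numpy(float), rng)
    return GatingConfig(
        dna_low=dna_low,
        dna_high=dna_high,
        bead_max=bead_max,
        viability_max=viability_max,
        cd45_min=_bimodal_midpoint(chan("CD45"), rng),
        cd3_min=_bimodal_midpoint(chan("CD3"), rng),
        cd19_max=_bimodal_midpoint(chan("CD19"), rng),
        cd4_min=_bimodal_midpoint(chan("CD4"), rng),
        cd8_max=_bimodal_midpoint(chan("CD8"), rng),
    )


def gate_events(events: EventTable, panel: Panel, cfg: GatingConfig) -> GateResult:
    """Run the sequential gating hierarchy; returns nested index sets.

    Gates, in order: (1) DNA singlets (one Iridium level, interval gate);
    (2) bead removal; (3) live cells (viability stain negative);
    (4) CD45+ leukocytes; (5) CD3+ CD19- CD4+ CD8- T cells.
    """
    if events.scale != TRANSFORMED:
        raise ValueError("gate_events expects a transformed table")
    cfg.validate()
    for m in ("CD45", "CD3", "CD19", "CD4", "CD8"):
        if m not in panel:
            raise PanelError(f"gating requires marker {m!r}")

    def col(ch: str) -> np.ndarray:
        return events.values[ch].to_numpy(float)

    dna = col(panel.dna_channels[0])
    masks = {
        "singlets": (dna > cfg.dna_low) & (dna < cfg.dna_high),
        "non_bead": col(panel.bead_channel) < cfg.bead_max,
        "live": col(panel.viability_channel) < cfg.viability_max,
        "cd45_pos": col(panel.channel_for("CD45")) > cfg.cd45_min,
        "cd4_t": (col(panel.channel_for("CD3")) > cfg.cd3_min)
        & (col(panel.channel_for("CD19")) < cfg.cd19_max)
        & (col(panel.channel_for("CD4")) > cfg.cd4_min)
        & (col(panel.channel_for("CD8")) < cfg.cd8_max),
    }
    kept: dict[str, np.ndarray] = {}
    running = np.ones(events.n_events, dtype=bool)
    for gate in GateResult.GATES:
        running = running & masks[gate]
        kept[gate] = np.flatnonzero(running)
    final = events.take(kept["cd4_t"])
    return GateResult(sample_id=events.sample_id, kept=kept, final=final)


# ---------------------------------------------------------------------------
# uniform downsampling
# ---------------------------------------------------------------------------

def downsample_uniform(tables: list[EventTable], seed: int = 0,
                       n_max: int | None = None) -> list[EventTable]:
    """Randomly select the same number of events from every sample.

    The common size is the smallest event count across the tables (matching
    the convention of equalizing to the poorest sample); ``n_max`` caps it
    further, which bounds the cost of cluster discovery on large studies
    without affecting abundance quantification (up-sampling assigns every
    gated event afterwards). Sampling is without replacement and
    deterministic given the seed.
    """
    for t in tables:
        if t.n_events == 0:
            raise ValueError(f"sample {t.sample_id!r} has no events")
    n_min = min(t.n_events for t in tables)
    if n_max is not None:
        n_min = min(n_min, n_max)
    rng = np.random.default_rng(seed)
    out = []
    for t in tables:
        idx = np.sort(rng.choice(t.n_events, size=n_min, replace=False))
        out.append(t.take(idx))
    return out
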