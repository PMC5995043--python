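"""Core containers shared across the pipeline.

Mass-cytometry (CyTOF) data is event-level: one row per detected cell (or
bead, or doublet), one column per metal-isotope channel. A *panel* maps each
channel to the antibody/marker it carries and to the role it plays in the
analysis (clustering input, gating input, DNA intercalator, viability stain,
normalization bead, or excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: allowed channel roles
ROLES = ("clustering", "gating", "excluded", "dna", "viability", "bead")

RAW = "raw"
TRANSFORMED = "transformed"


class PanelError(ValueError):
    """Panel is malformed or missing a required channel/marker."""


@dataclass(frozen=True)
class ChannelDef:
    """One channel of the antibody panel.

    channel_id is the metal-mass tag (e.g. ``"Ce140"``); marker is the
    biological name (e.g. ``"CD32a"``).
    """

    channel_id: str
    marker: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise PanelError(f"unknown role {self.role!r} for channel {self.channel_id}")


class Panel:
    """Ordered collection of :class:`ChannelDef` with lookup helpers."""

    def __init__(self, channels: Iterable[ChannelDef]):
        self.channels: list[ChannelDef] = list(channels)
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate channel ids in panel")
        if len([c for c in self.channels if c.role == "bead"]) != 1:
            raise PanelError("panel must define exactly one bead channel")
        if not [c for c in self.channels if c.role == "dna"]:
            raise PanelError("panel must define at least one DNA channel")
        self._by_marker = {c.marker: c for c in self.channels}
        self._by_channel = {c.channel_id: c for c in self.channels}

    # -- lookups -----------------------------------------------------------
    @property
    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.channels]

    @property
    def bead_channel(self) -> str:
        return next(c.channel_id for c in self.channels if c.role == "bead")

    @property
    def dna_channels(self) -> list[str]:
        return [c.channel_id for c in self.channels if c.role == "dna"]

    @property
    def viability_channel(self) -> str:
        try:
            return next(c.channel_id for c in self.channels if c.role == "viability")
        except StopIteration:
            raise PanelError("panel has no viability channel") from None

    def markers(self, role: str | None = None) -> list[str]:
        return [c.marker for c in self.channels if role is None or c.role == role]

    @property
    def clustering_markers(self) -> list[str]:
        return self.markers("clustering")

    def channel_for(self, marker: str) -> str:
        try:
            return self._by_marker[marker].channel_id
        except KeyError:
            raise PanelError(f"marker {marker!r} not in panel") from None

    def marker_for(self, channel_id: str) -> str:
        try:
            return self._by_channel[channel_id].marker
        except KeyError:
            raise PanelError(f"channel {channel_id!r} not in panel") from None

    def __contains__(self, marker: str) -> bool:
        return marker in self._by_marker

    def __len__(self) -> int:
        return len(self.channels)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Panel) and other.channels == self.channels

    # -- serialization -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": [c.channel_id for c in self.channels],
                "marker": [c.marker for c in self.channels],
                "role": [c.role for c in self.channels],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Panel":
        return cls(
            ChannelDef(str(r.channel), str(r.marker), str(r.role))
            for r in df.itertuples(index=False)
        )


@dataclass
class EventTable:
    """Per-sample events x channels matrix.

    ``values`` columns are channel ids (matching a :class:`Panel`);
    ``acquisition_index`` is the 0-based acquisition order used by
    windowed bead normalization. ``scale`` records whether the arcsinh
    transform has been applied (it is applied at most once).
    """

    sample_id: str
    values: pd.DataFrame
    scale: str = RAW
    acquisition_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.scale not in (RAW, TRANSFORMED):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.acquisition_index is None:
            self.acquisition_index = np.arange(len(self.values))
        else:
            self.acquisition_index = np.asarray(self.acquisition_index)
        if self.scale == RAW and len(self.values) and (self.values.to_numpy() < 0).any():
            raise ValueError("raw-scale event table contains negative intensities")

    @property
    def n_events(self) -> int:
        return len(self.values)

    def marker_array(self, panel: Panel, markers: Sequence[str]) -> np.ndarray:
        """Events x markers array in the given marker order."""
        cols = [panel.channel_for(m) for m in markers]
        return self.values[cols].to_numpy(dtype=float)

    def marker_series(self, panel: Panel, marker: str) -> np.ndarray:
        return self.values[panel.channel_for(marker)].to_numpy(dtype=float)

    def take(self, index: np.ndarray | Sequence[int]) -> "EventTable":
        idx = np.asarray(index)
        return EventTable(
            sample_id=self.sample_id,
            values=self.values.iloc[idx].reset_index(drop=True),
            scale=self.scale,
            acquisition_index=np.asarray(self.acquisition_index)[idx],
        )

    def replace_values(self, values: pd.DataFrame, scale: str | None = None) -> "EventTable":
        return EventTable(
            sample_id=self.sample_id,
            values=values,
            scale=self.scale if scale is None else scale,
            acquisition_index=np.asarray(self.acquisition_index).copy(),
        )


@dataclass
class SampleSheet:
    """Sample-level metadata: subject, condition, covariate.

    ``hiv_dna_log10`` is total HIV DNA in log10 copies / 1e6 PBMC; healthy
    (uninfected) samples carry 0 (undetectable).
    """

    frame: pd.DataFrame  # columns: sample_id, subject_id, condition, hiv_dna_log10

    REQUIRED = ("sample_id", "subject_id", "condition", "hiv_dna_log10")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if self.frame["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in sample sheet")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def condition_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return str(row["condition"].iloc[0])

    def samples_in(self, condition: str) -> list[str]:
        return list(self.frame.loc[self.frame["condition"] == condition, "sample_id"])

    def covariate(self) -> pd.Series:
        return self.frame.set_index("sample_id")["hiv_dna_log10"].astype(float)
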