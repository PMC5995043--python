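import numpy as np
import pandas as pd
import pytest

from cytoclust import synth
from cytoclust.data import ChannelDef, EventTable, Panel


@pytest.fixture(scope="session")
def tiny_study():
    """One small synthetic study shared by read-only tests."""
    return synth.generate_study(synth.tiny_design(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def mini_panel():
    """Four-channel panel for hand-built event tables."""
    return Panel([
        ChannelDef("Ir191", "DNA1", "dna"),
        ChannelDef("Ce140", "Bead", "bead"),
        ChannelDef("Rh103", "Viability", "viability"),
        ChannelDef("Sm154", "CD45", "gating"),
    ])


def make_table(values: np.ndarray, columns, sample_id="s1", scale="raw") -> EventTable:
    return EventTable(sample_id=sample_id,
                      values=pd.DataFrame(np.asarray(values, float), columns=list(columns)),
                      scale=scale)
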