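import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from danpipe import load_connectome


def edges_frame(rows):
    return pd.DataFrame(rows, columns=["pre_id", "post_id", "synapse_count"])


def ann_frame(rows):
    """rows: (neuron_id, neuron_class[, dan_cluster, modality, hemisphere, pair_id])"""
    full = []
    for r in rows:
        r = list(r) + ["none", "none", "unknown", ""][len(r) - 2:]
        full.append((r[0], r[0], r[1], r[2], r[3], r[4], r[5]))
    return pd.DataFrame(full, columns=[
        "neuron_id", "name", "neuron_class", "dan_cluster",
        "sensory_modality", "hemisphere", "pair_id",
    ])


@pytest.fixture
def tiny_pathway():
    """One qualifying pathway s1 ->(5) i1 ->(4) d1 plus spectator input."""
    edges = edges_frame([
        ("s1", "i1", 5),
        ("s2", "i1", 5),     # second sensory partner
        ("x1", "i1", 10),    # non-sensory input to i1: total_input(i1) = 20
        ("i1", "d1", 4),
        ("k1", "d1", 16),    # KC input: total_input(d1) = 20
    ])
    ann = ann_frame([
        ("s1", "sensory", "none", "ORN"),
        ("s2", "sensory", "none", "ACa"),
        ("x1", "other"),
        ("i1", "interneuron"),
        ("k1", "KC"),
        ("d1", "DAN", "DL1"),
    ])
    return load_connectome(edges, ann), edges, ann
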