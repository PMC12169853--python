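"""Independent brute-force oracles operating on the raw tables.

Every function here recomputes a quantity by direct row scans or triple
loops over the edge/annotation DataFrames, deliberately sharing no code
with the graph-based implementation it checks.
"""

from __future__ import annotations

import pandas as pd


def row_scan_total_input(edges: pd.DataFrame, neuron_id: str) -> int:
    return int(edges.loc[edges.post_id == neuron_id, "synapse_count"].sum())


def row_scan_sensory_fraction(
    edges: pd.DataFrame, ann: pd.DataFrame, neuron_id: str, theta_sensory: int = 1
) -> float:
    cls = dict(zip(ann.neuron_id, ann.neuron_class))
    inbound = edges[edges.post_id == neuron_id]
    tot = inbound.synapse_count.sum()
    if tot == 0:
        return 0.0
    sens = sum(
        int(r.synapse_count)
        for r in inbound.itertuples()
        if cls.get(r.pre_id) == "sensory" and r.synapse_count >= theta_sensory
    )
    return sens / tot


def triple_loop_pathways(
    edges: pd.DataFrame,
    ann: pd.DataFrame,
    dan_ids: list[str],
    theta_dan: int = 3,
    theta_sensory: int = 1,
) -> dict[str, set[str]]:
    """Enumerate all (sensory, interneuron, DAN) triples by brute force."""
    cls = dict(zip(ann.neuron_id, ann.neuron_class))
    sensory = [n for n, c in cls.items() if c == "sensory"]
    inter = [n for n, c in cls.items() if c == "interneuron"]
    w = {(r.pre_id, r.post_id): int(r.synapse_count) for r in edges.itertuples()}
    out: dict[str, set[str]] = {}
    for d in dan_ids:
        qual = set()
        for i in inter:
            if w.get((i, d), 0) < theta_dan:
                continue
            for s in sensory:
                if w.get((s, i), 0) >= theta_sensory:
                    qual.add(i)
                    break
        out[d] = qual
    return out


def brute_force_hub_table(
    edges: pd.DataFrame,
    ann: pd.DataFrame,
    dan_ids: list[str],
    theta_dan: int = 3,
    theta_sensory: int = 1,
    cutoff: float = 0.001,
) -> list[tuple[str, str, float, bool]]:
    """(dan, interneuron, score, highlighted) in the canonical order."""
    pathways = triple_loop_pathways(edges, ann, dan_ids, theta_dan, theta_sensory)
    rows = []
    for d in dan_ids:
        scored = []
        for i in pathways[d]:
            sf = row_scan_sensory_fraction(edges, ann, i, theta_sensory)
            tot_d = row_scan_total_input(edges, d)
            w_id = int(
                edges.loc[
                    (edges.pre_id == i) & (edges.post_id == d), "synapse_count"
                ].sum()
            )
            score = sf * (w_id / tot_d if tot_d else 0.0)
            scored.append((i, score))
        scored.sort(key=lambda t: (-t[1], t[0]))
        rows.extend((d, i, s, s >= cutoff) for i, s in scored)
    return rows


def row_scan_decomposition(
    edges: pd.DataFrame,
    ann: pd.DataFrame,
    dan_id: str,
    s2d: set[str],
    theta_dan: int = 3,
) -> dict[str, float]:
    cls = dict(zip(ann.neuron_id, ann.neuron_class))
    tot = row_scan_total_input(edges, dan_id)
    acc = {"s2d": 0, "other_in": 0, "KC": 0, "MBON": 0, "uncl": 0}
    for r in edges[edges.post_id == dan_id].itertuples():
        if r.synapse_count < theta_dan:
            continue
        c = cls.get(r.pre_id)
        if c == "interneuron":
            acc["s2d" if r.pre_id in s2d else "other_in"] += int(r.synapse_count)
        elif c in ("KC", "MBON"):
            acc[c] += int(r.synapse_count)
        else:
            acc["uncl"] += int(r.synapse_count)
    return {k: (100.0 * v / tot if tot else 0.0) for k, v in acc.items()}


def row_scan_composition(
    edges: pd.DataFrame,
    ann: pd.DataFrame,
    interneuron_ids: set[str],
    theta_sensory: int = 1,
) -> dict[str, float]:
    cls = dict(zip(ann.neuron_id, ann.neuron_class))
    mod = dict(zip(ann.neuron_id, ann.sensory_modality))
    acc: dict[str, int] = {}
    for r in edges.itertuples():
        if r.post_id not in interneuron_ids or cls.get(r.pre_id) != "sensory":
            continue
        if r.synapse_count < theta_sensory:
            continue
        acc[mod[r.pre_id]] = acc.get(mod[r.pre_id], 0) + int(r.synapse_count)
    tot = sum(acc.values())
    return {m: 100.0 * v / tot for m, v in acc.items()} if tot else {}
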