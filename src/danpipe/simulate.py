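"""Seeded synthetic-data generators with recorded ground truth.

Three generators emulate the three kinds of input the analysis stages
consume, each carrying a truth record so recovery can be checked:

* :func:`simulate_connectome` — an annotated synaptic graph with the
  larval node classes (sensory by modality, interneurons, Kenyon cells,
  MBONs, DANs in the DL1 and pPAM clusters), sparse weak background
  edges with heavy-tailed integer synapse counts, and planted
  sensory -> interneuron -> DAN motifs whose synapse counts sit well
  above the analysis thresholds.  The truth record lists the planted
  hub interneurons and their expected hub scores, computed by direct
  row arithmetic on the emitted edge table.
* :func:`simulate_behavior` — reciprocal-conditioning plate counts with
  a chosen true performance index theta per group: each of 30 larvae
  lands on side1/side2/neutral by one three-outcome draw whose side
  probabilities make the expected PI equal theta exactly.
* :func:`simulate_traces` — raw fluorescence at 30 Hz,
  F(t) = F0 (1 + A k(t)) + noise, where k rises linearly to a plateau
  of exactly 1 inside the stimulus window and decays after offset; the
  planted dF/F amplitude A is the truth.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import AnalysisConfig


class SimConfigError(ValueError):
    """Raised on inconsistent simulation configurations."""


# default class sizes loosely follow the first-instar larval brain:
# ~8 mushroom-body DANs in two clusters, ~110 KCs and ~24 MBONs per
# hemisphere, 35 sensory-to-DAN interneurons, sensory neurons spread
# over gustatory compartments, ORNs, thermo- and mechanosensors
DEFAULT_SENSORY = {
    "ORN": 21, "ACa": 10, "AVa": 8, "ACal": 6, "ACp": 6, "ACpl": 4,
    "VM": 6, "TD_CO2": 2, "thermo": 4, "mechano": 6,
}
DEFAULT_DANS = {"DL1": 4, "pPAM": 4}


@dataclass(frozen=True)
class PlantedMotif:
    """One planted sensory -> interneuron -> DAN pathway.

    ``sensory_idx`` indexes the flattened sensory list, ``interneuron_idx``
    the interneuron list and ``dan_idx`` the (sorted) DAN list; the same
    ``signal_count`` is written on every edge of the motif.
    """

    sensory_idx: tuple[int, ...]
    interneuron_idx: int
    dan_idx: int
    signal_count: int = 20


@dataclass(frozen=True)
class EdgeFamily:
    """Background connectivity of one pre-class -> post-class family.

    ``p`` is the per-ordered-pair edge probability; synapse counts are
    drawn as 1 + Geometric(geom_p), a heavy-tailed integer law in which
    most electron-microscopy edges are weak.
    """

    p: float
    geom_p: float


# background defaults emulate the first-instar circuit's composition:
# DANs draw most of their input from many weak Kenyon-cell edges (the
# real DANs get 36-49% of input from 60+ KCs), interneurons draw mostly
# on other interneurons, and direct sensory input onto any given
# interneuron is sparse and weak — which is what keeps the hub score of
# unplanted pathways well below the 0.001 highlight cutoff
DEFAULT_FAMILIES = {
    "sensory->interneuron": EdgeFamily(p=0.005, geom_p=0.97),
    "interneuron->interneuron": EdgeFamily(p=0.55, geom_p=0.20),
    "interneuron->DAN": EdgeFamily(p=0.08, geom_p=0.85),
    "KC->DAN": EdgeFamily(p=0.60, geom_p=0.25),
    "MBON->DAN": EdgeFamily(p=0.08, geom_p=0.70),
}


@dataclass(frozen=True)
class ConnectomeSimConfig:
    n_sensory_per_modality: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SENSORY)
    )
    n_interneurons: int = 35
    n_kc: int = 110
    n_mbon: int = 24
    n_dan_per_cluster: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_DANS)
    )
    planted_motifs: tuple[PlantedMotif, ...] = ()
    families: dict[str, EdgeFamily] = field(
        default_factory=lambda: dict(DEFAULT_FAMILIES)
    )
    background_scale: float = 1.0     # multiplies every family's edge probability
    bilateral: bool = False           # emit L/R homologs sharing a pair_id
    seed: int = 0


@dataclass
class ConnectomeTruth:
    """Planted ground truth carried alongside a simulated connectome."""

    planted_interneurons: list[str]
    planted_pairs: list[tuple[str, str]]          # (interneuron_id, dan_id)
    expected_hub_scores: dict[str, float]         # "i->d" -> score
    thresholds: tuple[int, int]                   # (theta_dan, theta_sensory)

    def to_dict(self) -> dict:
        return {
            "planted_interneurons": self.planted_interneurons,
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "expected_hub_scores": self.expected_hub_scores,
            "theta_dan": self.thresholds[0],
            "theta_sensory": self.thresholds[1],
        }


def _expected_hub_score(edges: pd.DataFrame, ann: pd.DataFrame,
                        interneuron: str, dan: str) -> float:
    """Row-scan hub arithmetic on the raw tables (independent of the graph)."""
    sensory = set(ann.loc[ann.neuron_class == "sensory", "neuron_id"])
    into_i = edges[edges.post_id == interneuron]
    tot_i = into_i.synapse_count.sum()
    sens_i = into_i[into_i.pre_id.isin(sensory)].synapse_count.sum()
    into_d = edges[edges.post_id == dan]
    tot_d = into_d.synapse_count.sum()
    i_to_d = into_d[into_d.pre_id == interneuron].synapse_count.sum()
    if tot_i == 0 or tot_d == 0:
        return 0.0
    return (sens_i / tot_i) * (i_to_d / tot_d)


def simulate_connectome(
    config: ConnectomeSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, ConnectomeTruth]:
    """Generate (edge table, annotation table, truth record)."""
    rng = np.random.default_rng(config.seed)

    sensory_ids: list[str] = []
    ann_rows: list[tuple] = []
    for modality in sorted(config.n_sensory_per_modality):
        for k in range(config.n_sensory_per_modality[modality]):
            nid = f"SN-{modality}-{k:02d}"
            sensory_ids.append(nid)
            ann_rows.append((nid, nid, "sensory", "none", modality, "unknown", ""))
    inter_ids = [f"IN-{k:02d}" for k in range(config.n_interneurons)]
    kc_ids = [f"KC-{k:03d}" for k in range(config.n_kc)]
    mbon_ids = [f"MBON-{k:02d}" for k in range(config.n_mbon)]
    dan_ids: list[str] = []
    for cluster in sorted(config.n_dan_per_cluster):
        for k in range(config.n_dan_per_cluster[cluster]):
            dan_ids.append(f"DAN-{cluster}-{k}")
    for nid in inter_ids:
        ann_rows.append((nid, nid, "interneuron", "none", "none", "unknown", ""))
    for nid in kc_ids:
        ann_rows.append((nid, nid, "KC", "none", "none", "unknown", ""))
    for nid in mbon_ids:
        ann_rows.append((nid, nid, "MBON", "none", "none", "unknown", ""))
    for nid in dan_ids:
        cluster = nid.split("-")[1]
        ann_rows.append((nid, nid, "DAN", cluster, "none", "unknown", ""))

    for m in config.planted_motifs:
        if not (0 <= m.interneuron_idx < len(inter_ids)):
            raise SimConfigError(f"interneuron index {m.interneuron_idx} out of range")
        if not (0 <= m.dan_idx < len(dan_ids)):
            raise SimConfigError(f"DAN index {m.dan_idx} out of range")
        for s in m.sensory_idx:
            if not (0 <= s < len(sensory_ids)):
                raise SimConfigError(f"sensory index {s} out of range")
        if m.signal_count < 1:
            raise SimConfigError("planted signal_count must be >= 1")

    def one_hemisphere(suffix: str) -> tuple[dict[tuple[str, str], int], list[tuple[str, str]]]:
        """Background + planted edges; ids get `suffix` appended."""
        edges: dict[tuple[str, str], int] = {}

        def draw_background(pres: list[str], posts: list[str], fam: EdgeFamily) -> None:
            p = min(1.0, fam.p * config.background_scale)
            for pre in pres:
                hit = rng.random(len(posts)) < p
                counts = 1 + rng.geometric(fam.geom_p, size=len(posts))
                for post, h, c in zip(posts, hit, counts):
                    if h and pre != post:
                        edges[(pre + suffix, post + suffix)] = int(c)

        fams = config.families
        draw_background(sensory_ids, inter_ids, fams["sensory->interneuron"])
        draw_background(inter_ids, inter_ids, fams["interneuron->interneuron"])
        draw_background(inter_ids, dan_ids, fams["interneuron->DAN"])
        draw_background(kc_ids, dan_ids, fams["KC->DAN"])
        draw_background(mbon_ids, dan_ids, fams["MBON->DAN"])

        planted_pairs: list[tuple[str, str]] = []
        for m in config.planted_motifs:
            i_id = inter_ids[m.interneuron_idx] + suffix
            d_id = dan_ids[m.dan_idx] + suffix
            for s in m.sensory_idx:
                edges[(sensory_ids[s] + suffix, i_id)] = m.signal_count
            edges[(i_id, d_id)] = m.signal_count
            planted_pairs.append((i_id, d_id))
        return edges, planted_pairs

    if config.bilateral:
        edges_l, pairs_l = one_hemisphere("_L")
        edges_r, pairs_r = one_hemisphere("_R")
        all_edges = {**edges_l, **edges_r}
        planted_pairs = pairs_l + pairs_r
        rows = []
        for nid, name, cls, cluster, modality, _, _ in ann_rows:
            rows.append((nid + "_L", name, cls, cluster, modality, "L", nid))
            rows.append((nid + "_R", name, cls, cluster, modality, "R", nid))
        ann_rows = rows
    else:
        all_edges, planted_pairs = one_hemisphere("")

    edge_df = pd.DataFrame(
        sorted((pre, post, c) for (pre, post), c in all_edges.items()),
        columns=["pre_id", "post_id", "synapse_count"],
    )
    ann_df = pd.DataFrame(ann_rows, columns=[
        "neuron_id", "name", "neuron_class", "dan_cluster",
        "sensory_modality", "hemisphere", "pair_id",
    ])

    defaults = AnalysisConfig()
    truth = ConnectomeTruth(
        planted_interneurons=sorted({i for i, _ in planted_pairs}),
        planted_pairs=sorted(planted_pairs),
        expected_hub_scores={
            f"{i}->{d}": _expected_hub_score(edge_df, ann_df, i, d)
            for i, d in planted_pairs
        },
        thresholds=(defaults.theta_dan, defaults.theta_sensory),
    )
    return edge_df, ann_df, truth


# ---------------------------------------------------------------------------
# behavior


@dataclass(frozen=True)
class BehaviorSimConfig:
    """Reciprocal-conditioning simulation with true PI theta per group."""

    theta_by_group: dict[str, float] = field(
        default_factory=lambda: {"experimental": -0.3, "control": 0.0}
    )
    neutral_p: float = 0.1
    larvae_per_plate: int = 30
    replicates: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.neutral_p < 1:
            raise SimConfigError("neutral_p must be in [0, 1)")
        for g, theta in self.theta_by_group.items():
            if abs(theta) > 1 - self.neutral_p + 1e-12:
                raise SimConfigError(
                    f"group {g!r}: |theta| = {abs(theta)} exceeds 1 - neutral_p "
                    f"= {1 - self.neutral_p}; no valid side probabilities exist"
                )
        if self.larvae_per_plate < 1 or self.replicates < 1:
            raise SimConfigError("larvae_per_plate and replicates must be >= 1")


def simulate_behavior(
    config: BehaviorSimConfig,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Generate (counts table, truth record {group: theta}).

    Each larva independently lands on side1, side2 or the neutral zone.
    For the group trained Odor2+ the side2 probability exceeds side1 by
    theta, and vice versa for the reciprocal group, so the expected PREF
    of each role — and hence the expected PI — equals theta exactly.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for group in sorted(config.theta_by_group):
        theta = config.theta_by_group[group]
        p_side = 1.0 - config.neutral_p
        for role, diff in (("O1_O2plus", theta), ("O1plus_O2", -theta)):
            # PREF(O1/O2+) = p2 - p1, PREF(O1+/O2) = p1 - p2
            p2 = (p_side + diff) / 2.0
            p1 = p_side - p2
            probs = np.clip([p1, p2, config.neutral_p], 0.0, 1.0)
            probs = probs / probs.sum()
            for rep in range(1, config.replicates + 1):
                n1, n2, nn = rng.multinomial(config.larvae_per_plate, probs)
                rows.append(("sim", "synthetic", group, rep, role,
                             int(n1), int(n2), int(nn)))
    counts = pd.DataFrame(rows, columns=[
        "experiment", "genotype", "group", "replicate", "role",
        "n_side1", "n_side2", "n_neutral",
    ])
    return counts, dict(config.theta_by_group)


# ---------------------------------------------------------------------------
# calcium traces


@dataclass(frozen=True)
class TraceSimConfig:
    """Calcium-trace simulation with planted dF/F amplitude A."""

    f0: float = 100.0            # baseline fluorescence, raw units
    noise_sd: float = 2.0        # additive Gaussian noise on raw F
    amplitude: float = 0.5       # planted dF/F amplitude, may be negative
    rise_s: float = 0.0          # linear rise to plateau, s; 0 = rectangular pulse
    decay_s: float = 1.5         # exponential decay time constant, s
    pre_s: float = 15.0          # recording before stimulus onset, s
    stimulus_s: float = 10.0     # stimulus duration, within [5, 10] s
    washout_s: float = 15.0      # recording after offset, s
    rate_hz: float = 30.0
    n_larvae: int = 6
    stimulus_label: str = "NaCl_1M"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise SimConfigError("baseline f0 must be positive")
        if not 5.0 <= self.stimulus_s <= 10.0:
            raise SimConfigError("stimulus duration must be within [5, 10] s")
        if self.pre_s < 10.0:
            raise SimConfigError("pre-stimulus recording must cover the 10 s baseline")


def response_kernel(times: np.ndarray, onset: float, offset: float,
                    rise_s: float, decay_s: float) -> np.ndarray:
    """Rise/plateau/decay kernel, exactly 1 on the plateau."""
    k = np.zeros_like(times, dtype=float)
    stim = (times >= onset) & (times <= offset)
    if rise_s <= 0:
        k[stim] = 1.0
        k_off = 1.0
    else:
        k[stim] = np.minimum(1.0, (times[stim] - onset) / rise_s)
        k_off = min(1.0, (offset - onset) / rise_s)
    post = times > offset
    k[post] = k_off * np.exp(-(times[post] - offset) / max(decay_s, 1e-9))
    return k


def simulate_traces(
    config: TraceSimConfig,
) -> tuple[pd.DataFrame, dict]:
    """Generate (long-format trace table, truth record).

    F(t) = F0 (1 + A k(t)) + N(0, noise_sd) per sample; the truth record
    stores the planted amplitude A.
    """
    rng = np.random.default_rng(config.seed)
    onset = config.pre_s
    offset = config.pre_s + config.stimulus_s
    t_end = offset + config.washout_s
    times = np.arange(0.0, t_end, 1.0 / config.rate_hz)
    kernel = response_kernel(times, onset, offset, config.rise_s, config.decay_s)
    stim_on = ((times >= onset) & (times <= offset)).astype(int)

    frames = []
    for k in range(config.n_larvae):
        noise = rng.normal(0.0, config.noise_sd, size=times.size)
        f = config.f0 * (1.0 + config.amplitude * kernel) + noise
        frames.append(pd.DataFrame({
            "larva_id": f"larva-{k:02d}",
            "stimulus_label": config.stimulus_label,
            "time_s": times,
            "fluorescence": f,
            "stimulus_on": stim_on,
        }))
    table = pd.concat(frames, ignore_index=True)
    truth = {
        "amplitude": config.amplitude,
        "stimulus_onset_s": onset,
        "stimulus_offset_s": offset,
        "n_larvae": config.n_larvae,
    }
    return table, truth
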