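"""Annotated synaptic graph and the single-hop sensory-to-DAN analysis.

The larval mushroom-body dopaminergic neurons (DANs) receive no direct
sensory input; sensory information reaches them through interneurons in a
single hop (sensory -> interneuron -> DAN).  This module builds a weighted
directed synaptic graph from an edge list plus a neuron annotation table
and implements the thresholded pathway analysis on top of it:

* identification of sensory-to-DAN interneurons (synaptic thresholds:
  interneuron->DAN edges count from 3 synapses, sensory->interneuron
  edges from 1 synapse),
* decomposition of each DAN's total synaptic input into partner
  categories (sensory-to-DAN interneurons, other interneurons, Kenyon
  cells, MBONs, unclassified),
* a hub score per (interneuron, DAN) pair — the fraction of the
  interneuron's total input that comes from sensory neurons multiplied by
  the fraction of the DAN's total input that comes from that interneuron,
* the sensory-modality composition of the input to a set of interneurons,
* DL1 / pPAM cluster specificity of the interneuron layer,
* optional merging of bilateral homolog pairs into single nodes.

All "total input" denominators are computed on the unthresholded graph;
the thresholds gate only which pathways and partners qualify.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

NEURON_CLASSES = frozenset({"sensory", "interneuron", "KC", "MBON", "DAN", "other"})
DAN_CLUSTERS = frozenset({"DL1", "pPAM", "none"})


class ConnectomeError(ValueError):
    """Raised on malformed connectome inputs or unknown neuron lookups."""


@dataclass(frozen=True)
class NeuronRecord:
    """Annotation of a single neuron."""

    neuron_id: str
    name: str = ""
    neuron_class: str = "other"
    dan_cluster: str = "none"
    sensory_modality: str = "none"
    hemisphere: str = "unknown"
    pair_id: str | None = None

    def __post_init__(self) -> None:
        if self.neuron_class not in NEURON_CLASSES:
            raise ConnectomeError(
                f"{self.neuron_id}: unknown neuron_class {self.neuron_class!r}"
            )
        if self.dan_cluster not in DAN_CLUSTERS:
            raise ConnectomeError(
                f"{self.neuron_id}: unknown dan_cluster {self.dan_cluster!r}"
            )
        if self.dan_cluster != "none" and self.neuron_class != "DAN":
            raise ConnectomeError(
                f"{self.neuron_id}: dan_cluster set on non-DAN neuron"
            )
        if self.sensory_modality != "none" and self.neuron_class != "sensory":
            raise ConnectomeError(
                f"{self.neuron_id}: sensory_modality set on non-sensory neuron"
            )


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the thresholded single-hop analysis.

    theta_dan
        Minimum synapse count for an interneuron->DAN edge to count as a
        connection (default 3).
    theta_sensory
        Minimum synapse count for a sensory->interneuron edge (default 1,
        i.e. every anatomical synapse counts).
    hub_cutoff
        Hub scores at or above this value are highlighted (default 0.001).
    pair_mode
        "per_neuron" analyses each neuron separately; "per_pair" merges
        bilateral homologs (see :func:`aggregate_pairs`) first.
    thresholded_denominator
        If True, input-decomposition percentages are taken relative to the
        thresholded input (only partners with >= theta_dan synapses)
        instead of the full unthresholded input.
    """

    theta_dan: int = 3
    theta_sensory: int = 1
    hub_cutoff: float = 0.001
    pair_mode: str = "per_neuron"
    thresholded_denominator: bool = False

    def __post_init__(self) -> None:
        if self.theta_dan < 1 or self.theta_sensory < 1:
            raise ConnectomeError("synaptic thresholds must be >= 1")
        if self.hub_cutoff < 0:
            raise ConnectomeError("hub_cutoff must be >= 0")
        if self.pair_mode not in ("per_neuron", "per_pair"):
            raise ConnectomeError(f"unknown pair_mode {self.pair_mode!r}")


@dataclass
class ConnectomeGraph:
    """Weighted directed synaptic graph with per-neuron annotations.

    ``graph`` is a :class:`networkx.DiGraph` whose edge attribute
    ``weight`` holds the (aggregated) synapse count; ``neurons`` maps
    neuron_id to its :class:`NeuronRecord`.  Self-edges are excluded and
    at most one edge exists per ordered (pre, post) pair.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    neurons: dict[str, NeuronRecord] = field(default_factory=dict)

    def require(self, neuron_id: str) -> NeuronRecord:
        try:
            return self.neurons[neuron_id]
        except KeyError:
            raise ConnectomeError(f"unknown neuron id {neuron_id!r}") from None

    def neuron_class(self, neuron_id: str) -> str:
        return self.require(neuron_id).neuron_class

    def synapse_count(self, pre_id: str, post_id: str) -> int:
        """Synapse count on the pre->post edge, 0 if absent."""
        data = self.graph.get_edge_data(pre_id, post_id)
        return 0 if data is None else int(data["weight"])

    def ids_of_class(self, neuron_class: str) -> list[str]:
        return sorted(
            nid for nid, rec in self.neurons.items()
            if rec.neuron_class == neuron_class
        )

    def dan_ids(self, cluster: str | None = None) -> list[str]:
        return sorted(
            nid for nid, rec in self.neurons.items()
            if rec.neuron_class == "DAN"
            and (cluster is None or rec.dan_cluster == cluster)
        )

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (u, v, int(d["weight"]))
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["pre_id", "post_id", "synapse_count"])

    def annotation_table(self) -> pd.DataFrame:
        rows = [
            (r.neuron_id, r.name, r.neuron_class, r.dan_cluster,
             r.sensory_modality, r.hemisphere, r.pair_id or "")
            for r in (self.neurons[n] for n in sorted(self.neurons))
        ]
        return pd.DataFrame(rows, columns=[
            "neuron_id", "name", "neuron_class", "dan_cluster",
            "sensory_modality", "hemisphere", "pair_id",
        ])


@dataclass(frozen=True)
class HubRecord:
    """Hub score of one (interneuron, DAN) connection."""

    interneuron_id: str
    dan_id: str
    sensory_fraction: float
    dan_fraction: float
    hub_score: float
    highlighted: bool


@dataclass(frozen=True)
class DecompositionRecord:
    """Partition of a DAN's synaptic input into partner categories."""

    dan_id: str
    pct_sensory_interneurons: float
    pct_other_interneurons: float
    pct_KC: float
    pct_MBON: float
    pct_unclassified: float
    n_sensory_interneurons: int
    n_other_interneurons: int
    n_KC: int
    n_MBON: int


@dataclass(frozen=True)
class PathwayResult:
    """Qualifying single-hop pathways into a set of DANs."""

    interneurons_by_dan: dict[str, frozenset[str]]
    sensory_by_dan: dict[str, frozenset[str]]
    interneuron_union: frozenset[str]


@dataclass(frozen=True)
class SpecificityReport:
    """DL1 / pPAM cluster specificity of the sensory-to-DAN interneurons."""

    n_total: int
    n_dl1_only: int
    n_ppam_only: int
    n_shared: int
    labels: dict[str, str]  # interneuron_id -> "DL1-only" | "pPAM-only" | "shared"


# ---------------------------------------------------------------------------
# construction


def _annotation_from_row(row: pd.Series) -> NeuronRecord:
    def clean(value, default):
        if value is None or (isinstance(value, float) and pd.isna(value)):
            return default
        s = str(value).strip()
        return s if s else default

    pair = clean(row.get("pair_id"), "")
    return NeuronRecord(
        neuron_id=str(row["neuron_id"]),
        name=clean(row.get("name"), ""),
        neuron_class=clean(row.get("neuron_class"), "other"),
        dan_cluster=clean(row.get("dan_cluster"), "none"),
        sensory_modality=clean(row.get("sensory_modality"), "none"),
        hemisphere=clean(row.get("hemisphere"), "unknown"),
        pair_id=pair or None,
    )


def load_connectome(
    edge_table: pd.DataFrame, annotation_table: pd.DataFrame
) -> ConnectomeGraph:
    """Build a :class:`ConnectomeGraph` from raw tables.

    Duplicate (pre, post) rows are summed, self-edges dropped with a
    warning, and edge endpoints missing from the annotation table are
    created with class ``other`` (also with a warning).

    Raises
    ------
    ConnectomeError
        On non-positive or non-integer synapse counts (the offending row
        is named) and on duplicate neuron_id in the annotations.
    """
    required = {"pre_id", "post_id", "synapse_count"}
    if not required.issubset(edge_table.columns):
        raise ConnectomeError(
            f"edge table must have columns {sorted(required)}"
        )
    dup = annotation_table["neuron_id"].astype(str).duplicated()
    if dup.any():
        bad = annotation_table.loc[dup, "neuron_id"].astype(str).tolist()
        raise ConnectomeError(f"duplicate neuron_id in annotations: {bad}")

    cg = ConnectomeGraph()
    for _, row in annotation_table.iterrows():
        rec = _annotation_from_row(row)
        cg.neurons[rec.neuron_id] = rec
        cg.graph.add_node(rec.neuron_id)

    for idx, row in edge_table.iterrows():
        count = row["synapse_count"]
        if pd.isna(count) or float(count) != int(count) or int(count) < 1:
            raise ConnectomeError(
                f"edge row {idx}: synapse_count must be a positive integer, "
                f"got {count!r}"
            )
        pre, post, count = str(row["pre_id"]), str(row["post_id"]), int(count)
        if pre == post:
            logger.warning("dropping self-edge %s->%s (%d synapses)", pre, post, count)
            continue
        for nid in (pre, post):
            if nid not in cg.neurons:
                logger.warning(
                    "edge endpoint %s not annotated; assigning class 'other'", nid
                )
                cg.neurons[nid] = NeuronRecord(neuron_id=nid)
                cg.graph.add_node(nid)
        if cg.graph.has_edge(pre, post):
            cg.graph[pre][post]["weight"] += count
        else:
            cg.graph.add_edge(pre, post, weight=count)
    return cg


def aggregate_pairs(cg: ConnectomeGraph) -> ConnectomeGraph:
    """Merge bilateral homologs (shared pair_id) into single nodes.

    Synapse counts on parallel edges are summed; annotations are
    inherited from the left-hemisphere member (or the lexicographically
    first member when hemispheres are not annotated).  Edges internal to
    a pair become self-edges of the merged node and are dropped.
    Unpaired neurons pass through unchanged.

    Raises
    ------
    ConnectomeError
        If members of one pair differ in neuron_class.
    """
    by_pair: dict[str, list[NeuronRecord]] = {}
    for rec in cg.neurons.values():
        if rec.pair_id:
            by_pair.setdefault(rec.pair_id, []).append(rec)

    merged_id: dict[str, str] = {}
    out = ConnectomeGraph()
    for pair_id, members in by_pair.items():
        classes = {m.neuron_class for m in members}
        if len(classes) > 1:
            raise ConnectomeError(
                f"pair {pair_id!r} mixes neuron classes {sorted(classes)}"
            )
        members.sort(key=lambda m: (m.hemisphere != "L", m.neuron_id))
        rep = members[0]
        for m in members:
            merged_id[m.neuron_id] = pair_id
        out.neurons[pair_id] = replace(
            rep, neuron_id=pair_id, hemisphere="unknown", pair_id=pair_id
        )
        out.graph.add_node(pair_id)
    for rec in cg.neurons.values():
        if not rec.pair_id:
            merged_id[rec.neuron_id] = rec.neuron_id
            out.neurons[rec.neuron_id] = rec
            out.graph.add_node(rec.neuron_id)

    for u, v, d in cg.graph.edges(data=True):
        mu, mv = merged_id[u], merged_id[v]
        if mu == mv:
            logger.warning(
                "dropping intra-pair edge %s->%s (%d synapses)", u, v, d["weight"]
            )
            continue
        if out.graph.has_edge(mu, mv):
            out.graph[mu][mv]["weight"] += int(d["weight"])
        else:
            out.graph.add_edge(mu, mv, weight=int(d["weight"]))
    return out


# ---------------------------------------------------------------------------
# input fractions


def total_input(cg: ConnectomeGraph, neuron_id: str) -> int:
    """Total synaptic input (sum of inbound counts, unthresholded)."""
    cg.require(neuron_id)
    return int(sum(d["weight"] for _, _, d in cg.graph.in_edges(neuron_id, data=True)))


def input_fraction(cg: ConnectomeGraph, post_id: str, pre_id: str) -> float:
    """Fraction of post's total input contributed by pre (0 if no edge)."""
    cg.require(pre_id)
    tot = total_input(cg, post_id)
    if tot == 0:
        return 0.0
    return cg.synapse_count(pre_id, post_id) / tot


def sensory_input_fraction(
    cg: ConnectomeGraph, neuron_id: str, config: AnalysisConfig = AnalysisConfig()
) -> float:
    """Fraction of a neuron's total input arriving from sensory neurons.

    Only sensory edges with at least ``theta_sensory`` synapses count in
    the numerator; the denominator is the unthresholded total input.
    """
    tot = total_input(cg, neuron_id)
    if tot == 0:
        return 0.0
    num = sum(
        d["weight"]
        for pre, _, d in cg.graph.in_edges(neuron_id, data=True)
        if cg.neurons[pre].neuron_class == "sensory"
        and d["weight"] >= config.theta_sensory
    )
    return num / tot


# ---------------------------------------------------------------------------
# single-hop pathways


def find_sensory_to_dan_interneurons(
    cg: ConnectomeGraph,
    dan_ids: list[str] | None = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> PathwayResult:
    """Enumerate qualifying sensory -> interneuron -> DAN pathways.

    An interneuron i qualifies for DAN d iff i's class is interneuron,
    the i->d edge carries at least ``theta_dan`` synapses, and at least
    one sensory neuron synapses onto i with at least ``theta_sensory``
    synapses.  Also records, per DAN, the sensory neurons reaching it
    through its qualifying interneurons.
    """
    if dan_ids is None:
        dan_ids = cg.dan_ids()
    for d in dan_ids:
        if cg.neuron_class(d) != "DAN":
            raise ConnectomeError(f"{d!r} is not annotated as a DAN")

    interneurons_by_dan: dict[str, frozenset[str]] = {}
    sensory_by_dan: dict[str, frozenset[str]] = {}
    union: set[str] = set()
    for d in dan_ids:
        qual: set[str] = set()
        sens_all: set[str] = set()
        for i, _, data in cg.graph.in_edges(d, data=True):
            if cg.neurons[i].neuron_class != "interneuron":
                continue
            if data["weight"] < config.theta_dan:
                continue
            sens = {
                s
                for s, _, sd in cg.graph.in_edges(i, data=True)
                if cg.neurons[s].neuron_class == "sensory"
                and sd["weight"] >= config.theta_sensory
            }
            if sens:
                qual.add(i)
                sens_all |= sens
        interneurons_by_dan[d] = frozenset(qual)
        sensory_by_dan[d] = frozenset(sens_all)
        union |= qual
    return PathwayResult(interneurons_by_dan, sensory_by_dan, frozenset(union))


def input_decomposition(
    cg: ConnectomeGraph,
    dan_id: str,
    s2d_interneurons: frozenset[str] | set[str],
    config: AnalysisConfig = AnalysisConfig(),
) -> DecompositionRecord:
    """Decompose a DAN's input into partner categories.

    Pre-partners with at least ``theta_dan`` synapses are partitioned
    into sensory-to-DAN interneurons (membership given by
    ``s2d_interneurons``), other interneurons, Kenyon cells, MBONs and
    unclassified; each category's percentage is its synapse count over
    the DAN's total input (unthresholded by default).
    """
    tot = total_input(cg, dan_id)
    syn = {k: 0 for k in ("s2d", "other_in", "KC", "MBON", "uncl")}
    cnt = {k: 0 for k in ("s2d", "other_in", "KC", "MBON")}
    thresholded_total = 0
    for pre, _, data in cg.graph.in_edges(dan_id, data=True):
        w = int(data["weight"])
        if w < config.theta_dan:
            continue
        thresholded_total += w
        cls = cg.neurons[pre].neuron_class
        if cls == "interneuron":
            key = "s2d" if pre in s2d_interneurons else "other_in"
        elif cls in ("KC", "MBON"):
            key = cls
        else:
            key = "uncl"
        syn[key] += w
        if key != "uncl":
            cnt[key] += 1
    denom = thresholded_total if config.thresholded_denominator else tot
    if denom == 0:
        logger.warning("DAN %s has zero synaptic input; percentages set to 0", dan_id)
        pct = dict.fromkeys(syn, 0.0)
    else:
        pct = {k: 100.0 * v / denom for k, v in syn.items()}
    return DecompositionRecord(
        dan_id=dan_id,
        pct_sensory_interneurons=pct["s2d"],
        pct_other_interneurons=pct["other_in"],
        pct_KC=pct["KC"],
        pct_MBON=pct["MBON"],
        pct_unclassified=pct["uncl"],
        n_sensory_interneurons=cnt["s2d"],
        n_other_interneurons=cnt["other_in"],
        n_KC=cnt["KC"],
        n_MBON=cnt["MBON"],
    )


# ---------------------------------------------------------------------------
# hub scores


def hub_score(
    cg: ConnectomeGraph,
    interneuron_id: str,
    dan_id: str,
    config: AnalysisConfig = AnalysisConfig(),
) -> HubRecord:
    """Hub score of one (interneuron, DAN) connection.

    The score is the interneuron's sensory input fraction multiplied by
    the fraction of the DAN's total input that comes from this
    interneuron; scores at or above ``hub_cutoff`` are highlighted.
    """
    sf = sensory_input_fraction(cg, interneuron_id, config)
    df_ = input_fraction(cg, dan_id, interneuron_id)
    score = sf * df_
    return HubRecord(
        interneuron_id=interneuron_id,
        dan_id=dan_id,
        sensory_fraction=sf,
        dan_fraction=df_,
        hub_score=score,
        highlighted=score >= config.hub_cutoff,
    )


def hub_table(
    cg: ConnectomeGraph,
    dan_ids: list[str] | None = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> list[HubRecord]:
    """Hub scores for every qualifying (interneuron, DAN) pair.

    Sorted by DAN id, then descending score, ties broken by interneuron
    id, so the output is deterministic.
    """
    if dan_ids is None:
        dan_ids = cg.dan_ids()
    paths = find_sensory_to_dan_interneurons(cg, dan_ids, config)
    records: list[HubRecord] = []
    for d in dan_ids:
        recs = [hub_score(cg, i, d, config) for i in paths.interneurons_by_dan[d]]
        recs.sort(key=lambda r: (-r.hub_score, r.interneuron_id))
        records.extend(recs)
    return records


def hub_table_frame(records: list[HubRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.dan_id, r.interneuron_id, r.sensory_fraction, r.dan_fraction,
             r.hub_score, r.highlighted)
            for r in records
        ],
        columns=["dan_id", "interneuron_id", "sensory_fraction", "dan_fraction",
                 "hub_score", "highlighted"],
    )


# ---------------------------------------------------------------------------
# sensory composition and cluster specificity


def sensory_composition(
    cg: ConnectomeGraph,
    interneuron_ids: set[str] | frozenset[str],
    config: AnalysisConfig = AnalysisConfig(),
) -> dict[str, float]:
    """Modality percentages of the sensory input to a set of interneurons.

    Considers every sensory->interneuron edge into the set with at least
    ``theta_sensory`` synapses; other (non-sensory) input is ignored so
    the percentages describe the distribution of sensory origins and sum
    to 100.  Empty sensory input yields an empty mapping with a warning.
    """
    syn_by_modality: dict[str, int] = {}
    for i in interneuron_ids:
        cg.require(i)
        for s, _, data in cg.graph.in_edges(i, data=True):
            rec = cg.neurons[s]
            if rec.neuron_class != "sensory":
                continue
            if data["weight"] < config.theta_sensory:
                continue
            syn_by_modality[rec.sensory_modality] = (
                syn_by_modality.get(rec.sensory_modality, 0) + int(data["weight"])
            )
    total = sum(syn_by_modality.values())
    if total == 0:
        logger.warning("no sensory input into the given interneuron set")
        return {}
    return {m: 100.0 * v / total for m, v in sorted(syn_by_modality.items())}


def cluster_specificity(
    cg: ConnectomeGraph,
    dl1_ids: list[str],
    ppam_ids: list[str],
    config: AnalysisConfig = AnalysisConfig(),
) -> SpecificityReport:
    """Label sensory-to-DAN interneurons by the DAN cluster(s) they reach."""
    if set(dl1_ids) & set(ppam_ids):
        raise ConnectomeError("DL1 and pPAM DAN id sets overlap")
    dl1 = find_sensory_to_dan_interneurons(cg, dl1_ids, config).interneuron_union
    ppam = find_sensory_to_dan_interneurons(cg, ppam_ids, config).interneuron_union
    labels: dict[str, str] = {}
    for i in sorted(dl1 | ppam):
        if i in dl1 and i in ppam:
            labels[i] = "shared"
        elif i in dl1:
            labels[i] = "DL1-only"
        else:
            labels[i] = "pPAM-only"
    values = list(labels.values())
    return SpecificityReport(
        n_total=len(labels),
        n_dl1_only=values.count("DL1-only"),
        n_ppam_only=values.count("pPAM-only"),
        n_shared=values.count("shared"),
        labels=labels,
    )
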