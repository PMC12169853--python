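"""Unit and property tests for the single-hop sensory-to-DAN analysis."""

import dataclasses
import logging

import numpy as np
import pytest

from danpipe import (
    AnalysisConfig,
    ConnectomeSimConfig,
    PlantedMotif,
    aggregate_pairs,
    cluster_specificity,
    find_sensory_to_dan_interneurons,
    hub_score,
    hub_table,
    input_decomposition,
    input_fraction,
    load_connectome,
    sensory_composition,
    sensory_input_fraction,
    simulate_connectome,
    total_input,
)
from danpipe.connectome import ConnectomeError

from conftest import ann_frame, edges_frame
from oracles import (
    brute_force_hub_table,
    row_scan_composition,
    row_scan_decomposition,
    row_scan_sensory_fraction,
    row_scan_total_input,
    triple_loop_pathways,
)


def random_graph(seed, dense=True):
    """Small random connectome (~30 nodes) for oracle comparisons."""
    cfg = ConnectomeSimConfig(
        n_sensory_per_modality={"ORN": 4, "ACa": 3, "VM": 2},
        n_interneurons=8, n_kc=5, n_mbon=3,
        n_dan_per_cluster={"DL1": 2, "pPAM": 2},
        background_scale=8.0 if dense else 1.0,
        planted_motifs=(PlantedMotif((0, 1), 2, 1, signal_count=15),),
        seed=seed,
    )
    edges, ann, truth = simulate_connectome(cfg)
    return load_connectome(edges, ann), edges, ann, truth


class TestLoader:
    def test_duplicate_edges_summed_and_self_edges_dropped(self, caplog):
        edges = edges_frame([("A", "B", 2), ("A", "B", 3), ("B", "B", 5)])
        ann = ann_frame([("A", "other"), ("B", "other")])
        with caplog.at_level(logging.WARNING):
            cg = load_connectome(edges, ann)
        assert cg.synapse_count("A", "B") == 5
        assert cg.graph.number_of_edges() == 1
        assert "self-edge" in caplog.text

    def test_empty_edge_table(self):
        cg = load_connectome(edges_frame([]), ann_frame([("a", "other")] * 0 or
                                                        [(f"n{i}", "other") for i in range(4)]))
        assert len(cg.neurons) == 4
        assert cg.graph.number_of_edges() == 0

    def test_unannotated_endpoint_gets_class_other(self, caplog):
        edges = edges_frame([("A", "X", 2), ("A", "B", 1), ("B", "A", 3),
                             ("X", "B", 1), ("A", "B", 2)])
        ann = ann_frame([("A", "sensory", "none", "ORN"), ("B", "interneuron")])
        with caplog.at_level(logging.WARNING):
            cg = load_connectome(edges, ann)
        assert cg.neurons["X"].neuron_class == "other"
        assert len(cg.neurons) == 3
        assert "not annotated" in caplog.text

    @pytest.mark.parametrize("bad_count", [0, -1, 2.5])
    def test_invalid_synapse_count_names_row(self, bad_count):
        edges = edges_frame([("A", "B", 3), ("B", "C", bad_count)])
        ann = ann_frame([("A", "other"), ("B", "other"), ("C", "other")])
        with pytest.raises(ConnectomeError, match="row 1"):
            load_connectome(edges, ann)

    def test_duplicate_annotation_rejected(self):
        ann = ann_frame([("A", "other"), ("A", "sensory", "none", "ORN")])
        with pytest.raises(ConnectomeError, match="duplicate"):
            load_connectome(edges_frame([]), ann)

    def test_invariant_cluster_requires_dan_class(self):
        ann = ann_frame([("A", "interneuron", "DL1")])
        with pytest.raises(ConnectomeError, match="dan_cluster"):
            load_connectome(edges_frame([]), ann)


class TestInputFractions:
    def test_total_input_sums_inbound(self):
        edges = edges_frame([("a", "c", 10), ("b", "c", 40), ("c", "a", 7)])
        ann = ann_frame([("a", "other"), ("b", "other"), ("c", "other")])
        cg = load_connectome(edges, ann)
        assert total_input(cg, "c") == 50
        assert total_input(cg, "b") == 0

    def test_unknown_neuron_raises(self, tiny_pathway):
        cg, _, _ = tiny_pathway
        with pytest.raises(ConnectomeError, match="unknown"):
            total_input(cg, "nope")

    def test_input_fraction_direct_and_absent(self, tiny_pathway):
        cg, _, _ = tiny_pathway
        assert input_fraction(cg, "d1", "i1") == pytest.approx(4 / 20)
        assert input_fraction(cg, "d1", "s1") == 0.0

    def test_fractions_normalize(self, tiny_pathway):
        cg, _, _ = tiny_pathway
        for node in ("i1", "d1"):
            s = sum(input_fraction(cg, node, pre) for pre in cg.neurons)
            assert s == pytest.approx(1.0, abs=1e-9)

    def test_sensory_fraction_tiny(self, tiny_pathway):
        cg, _, _ = tiny_pathway
        # 10 of 20 synapses into i1 are sensory
        assert sensory_input_fraction(cg, "i1") == pytest.approx(0.5)
        assert sensory_input_fraction(cg, "d1") == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_totals_and_sensory_fraction_match_row_scan(self, seed):
        cg, edges, ann, _ = random_graph(seed)
        for nid in list(cg.neurons)[::3]:
            assert total_input(cg, nid) == row_scan_total_input(edges, nid)
            assert sensory_input_fraction(cg, nid) == pytest.approx(
                row_scan_sensory_fraction(edges, ann, nid), abs=1e-12
            )


class TestPathways:
    def build(self, i_to_d):
        edges = edges_frame([("s", "i", 5), ("i", "d", i_to_d)])
        ann = ann_frame([("s", "sensory", "none", "ORN"), ("i", "interneuron"),
                         ("d", "DAN", "DL1")])
        return load_connectome(edges, ann)

    def test_qualifying_pathway_found(self):
        cg = self.build(4)
        res = find_sensory_to_dan_interneurons(cg, ["d"])
        assert res.interneurons_by_dan["d"] == {"i"}
        assert res.sensory_by_dan["d"] == {"s"}

    def test_edge_below_dan_threshold_excluded(self):
        # the 3-synapse cutoff for interneuron->DAN edges
        cg = self.build(2)
        res = find_sensory_to_dan_interneurons(cg, ["d"])
        assert res.interneurons_by_dan["d"] == frozenset()

    def test_non_dan_target_rejected(self, tiny_pathway):
        cg, _, _ = tiny_pathway
        with pytest.raises(ConnectomeError, match="not annotated as a DAN"):
            find_sensory_to_dan_interneurons(cg, ["i1"])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop_oracle(self, seed):
        cg, edges, ann, _ = random_graph(seed)
        dans = cg.dan_ids()
        res = find_sensory_to_dan_interneurons(cg, dans)
        oracle = triple_loop_pathways(edges, ann, dans)
        assert {d: set(v) for d, v in res.interneurons_by_dan.items()} == oracle

    def test_monotonicity_in_thresholds(self):
        cg, _, _, _ = random_graph(11)
        dans = cg.dan_ids()
        base = find_sensory_to_dan_interneurons(cg, dans, AnalysisConfig())
        for theta_dan, theta_sensory in [(4, 1), (3, 2), (6, 3)]:
            stricter = find_sensory_to_dan_interneurons(
                cg, dans, AnalysisConfig(theta_dan=theta_dan,
                                         theta_sensory=theta_sensory))
            for d in dans:
                assert stricter.interneurons_by_dan[d] <= base.interneurons_by_dan[d]


class TestDecomposition:
    def test_constructed_percentages(self):
        # DAN with total input 100: 17 synapses from 2 qualifying
        # interneurons, 41 from 3 KCs, remainder spread elsewhere
        edges = edges_frame([
            ("s", "i1", 3), ("s", "i2", 3),
            ("i1", "d", 9), ("i2", "d", 8),
            ("k1", "d", 20), ("k2", "d", 11), ("k3", "d", 10),
            ("m1", "d", 5), ("u1", "d", 37),
        ])
        ann = ann_frame([
            ("s", "sensory", "none", "ORN"), ("i1", "interneuron"),
            ("i2", "interneuron"), ("k1", "KC"), ("k2", "KC"), ("k3", "KC"),
            ("m1", "MBON"), ("u1", "other"), ("d", "DAN", "DL1"),
        ])
        cg = load_connectome(edges, ann)
        s2d = find_sensory_to_dan_interneurons(cg, ["d"]).interneurons_by_dan["d"]
        rec = input_decomposition(cg, "d", s2d)
        assert total_input(cg, "d") == 100
        assert rec.pct_sensory_interneurons == pytest.approx(17.0)
        assert rec.pct_KC == pytest.approx(41.0)
        assert rec.pct_MBON == pytest.approx(5.0)
        assert (rec.n_sensory_interneurons, rec.n_KC) == (2, 3)

    def test_single_kc_partner(self):
        edges = edges_frame([("k", "d", 30)])
        ann = ann_frame([("k", "KC"), ("d", "DAN", "pPAM")])
        cg = load_connectome(edges, ann)
        rec = input_decomposition(cg, "d", frozenset())
        assert rec.pct_KC == pytest.approx(100.0)
        assert rec.pct_sensory_interneurons == 0.0

    def test_zero_input_dan_warns(self, caplog):
        ann = ann_frame([("d", "DAN", "DL1")])
        cg = load_connectome(edges_frame([]), ann)
        with caplog.at_level(logging.WARNING):
            rec = input_decomposition(cg, "d", frozenset())
        assert rec.pct_KC == 0.0
        assert "zero synaptic input" in caplog.text

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_row_scan(self, seed):
        cg, edges, ann, _ = random_graph(seed)
        for d in cg.dan_ids():
            s2d = find_sensory_to_dan_interneurons(cg, [d]).interneurons_by_dan[d]
            rec = input_decomposition(cg, d, s2d)
            oracle = row_scan_decomposition(edges, ann, d, set(s2d))
            assert rec.pct_sensory_interneurons == pytest.approx(oracle["s2d"])
            assert rec.pct_other_interneurons == pytest.approx(oracle["other_in"])
            assert rec.pct_KC == pytest.approx(oracle["KC"])
            assert rec.pct_MBON == pytest.approx(oracle["MBON"])
            assert rec.pct_unclassified == pytest.approx(oracle["uncl"])


class TestHubScore:
    def test_printed_formula(self, tiny_pathway):
        cg, _, _ = tiny_pathway
        # sensory fraction 0.5, dan fraction 4/20 = 0.2 -> score 0.1
        rec = hub_score(cg, "i1", "d1")
        assert rec.hub_score == pytest.approx(0.5 * 0.2)
        assert rec.hub_score == pytest.approx(rec.sensory_fraction * rec.dan_fraction)
        assert rec.highlighted

    def test_no_sensory_input_scores_zero(self):
        edges = edges_frame([("x", "i", 10), ("i", "d", 5)])
        ann = ann_frame([("x", "other"), ("i", "interneuron"), ("d", "DAN", "DL1")])
        cg = load_connectome(edges, ann)
        rec = hub_score(cg, "i", "d")
        assert rec.hub_score == 0.0
        assert not rec.highlighted

    def test_highlight_boundary_at_cutoff(self):
        # score 0.001 is highlighted, 0.0009 is not
        def graph_with_score(i_to_d, total_d):
            edges = edges_frame([
                ("s", "i", 1), ("x", "i", 99),          # sensory fraction 0.01
                ("i", "d", i_to_d), ("k", "d", total_d - i_to_d),
            ])
            ann = ann_frame([("s", "sensory", "none", "ORN"), ("x", "other"),
                             ("i", "interneuron"), ("k", "KC"), ("d", "DAN", "DL1")])
            return load_connectome(edges, ann)

        at = hub_score(graph_with_score(10, 100), "i", "d")      # 0.01 * 0.1
        assert at.hub_score == pytest.approx(0.001)
        assert at.highlighted
        below = hub_score(graph_with_score(9, 100), "i", "d")    # 0.01 * 0.09
        assert below.hub_score == pytest.approx(0.0009)
        assert not below.highlighted

    def test_table_single_pair(self, tiny_pathway):
        cg, _, _ = tiny_pathway
        table = hub_table(cg)
        assert len(table) == 1
        assert (table[0].interneuron_id, table[0].dan_id) == ("i1", "d1")

    def test_table_tie_broken_by_id(self):
        edges = edges_frame([
            ("s", "i1", 5), ("s", "i2", 5), ("x", "i1", 5), ("x", "i2", 5),
            ("i1", "d", 4), ("i2", "d", 4), ("k", "d", 12),
        ])
        ann = ann_frame([("s", "sensory", "none", "ORN"), ("x", "other"),
                         ("i1", "interneuron"), ("i2", "interneuron"),
                         ("k", "KC"), ("d", "DAN", "DL1")])
        cg = load_connectome(edges, ann)
        table = hub_table(cg)
        assert [r.interneuron_id for r in table] == ["i1", "i2"]
        assert table[0].hub_score == table[1].hub_score

    @pytest.mark.parametrize("seed", range(5))
    def test_table_matches_brute_force(self, seed):
        cg, edges, ann, _ = random_graph(seed)
        dans = cg.dan_ids()
        mine = [(r.dan_id, r.interneuron_id, r.hub_score, r.highlighted)
                for r in hub_table(cg, dans)]
        oracle = brute_force_hub_table(edges, ann, dans)
        assert [(d, i, h) for d, i, _, h in mine] == [(d, i, h) for d, i, _, h in oracle]
        for m, o in zip(mine, oracle):
            assert m[2] == pytest.approx(o[2], abs=1e-12)

    def test_planted_hubs_top_ranked(self):
        motifs = tuple(PlantedMotif((3 * j, 3 * j + 1, 3 * j + 2), j, j, 25)
                       for j in range(5))
        edges, ann, truth = simulate_connectome(
            ConnectomeSimConfig(planted_motifs=motifs, seed=7))
        cg = load_connectome(edges, ann)
        table = sorted(hub_table(cg), key=lambda r: -r.hub_score)
        top = {r.interneuron_id for r in table[:5]}
        assert top == set(truth.planted_interneurons)


class TestCompositionAndSpecificity:
    def test_two_modalities(self):
        edges = edges_frame([("o", "i", 30), ("a", "i", 70)])
        ann = ann_frame([("o", "sensory", "none", "ORN"),
                         ("a", "sensory", "none", "ACa"), ("i", "interneuron")])
        cg = load_connectome(edges, ann)
        assert sensory_composition(cg, {"i"}) == {"ACa": 70.0, "ORN": 30.0}

    def test_single_modality_and_empty(self, caplog):
        edges = edges_frame([("o", "i", 12)])
        ann = ann_frame([("o", "sensory", "none", "VM"), ("i", "interneuron"),
                         ("j", "interneuron")])
        cg = load_connectome(edges, ann)
        assert sensory_composition(cg, {"i"}) == {"VM": 100.0}
        with caplog.at_level(logging.WARNING):
            assert sensory_composition(cg, {"j"}) == {}
        assert "no sensory input" in caplog.text

    @pytest.mark.parametrize("seed", range(4))
    def test_composition_matches_row_scan_and_normalizes(self, seed):
        cg, edges, ann, _ = random_graph(seed)
        inter = set(cg.ids_of_class("interneuron"))
        comp = sensory_composition(cg, inter)
        oracle = row_scan_composition(edges, ann, inter)
        assert comp.keys() == oracle.keys()
        for m in comp:
            assert comp[m] == pytest.approx(oracle[m], abs=1e-9)
        if comp:
            assert sum(comp.values()) == pytest.approx(100.0, abs=1e-9)

    def specificity_graph(self):
        edges = edges_frame([
            ("s", "i_dl1", 5), ("s", "i_shared", 5), ("s", "i_ppam", 5),
            ("i_dl1", "d_dl1", 4),
            ("i_shared", "d_dl1", 3), ("i_shared", "d_ppam", 3),
            ("i_ppam", "d_ppam", 6),
        ])
        ann = ann_frame([
            ("s", "sensory", "none", "ORN"),
            ("i_dl1", "interneuron"), ("i_shared", "interneuron"),
            ("i_ppam", "interneuron"),
            ("d_dl1", "DAN", "DL1"), ("d_ppam", "DAN", "pPAM"),
        ])
        return load_connectome(edges, ann)

    def test_labels_and_counts(self):
        cg = self.specificity_graph()
        rep = cluster_specificity(cg, ["d_dl1"], ["d_ppam"])
        assert rep.labels == {"i_dl1": "DL1-only", "i_shared": "shared",
                              "i_ppam": "pPAM-only"}
        assert (rep.n_total, rep.n_dl1_only, rep.n_ppam_only, rep.n_shared) == (3, 1, 1, 1)
        assert rep.n_dl1_only + rep.n_ppam_only + rep.n_shared == rep.n_total

    def test_overlapping_clusters_rejected(self):
        cg = self.specificity_graph()
        with pytest.raises(ConnectomeError, match="overlap"):
            cluster_specificity(cg, ["d_dl1"], ["d_dl1"])

    def test_planted_label_recovery(self):
        # one motif per cluster plus one interneuron wired to both
        motifs = (PlantedMotif((0, 1), 0, 0, 25),   # DAN-DL1-0
                  PlantedMotif((2, 3), 1, 4, 25),   # DAN-pPAM-0
                  PlantedMotif((4, 5), 2, 1, 25))
        edges, ann, truth = simulate_connectome(
            ConnectomeSimConfig(planted_motifs=motifs, seed=3))
        extra = edges_frame([("IN-02", "DAN-pPAM-1", 25)])
        import pandas as pd
        edges = pd.concat([edges, extra], ignore_index=True)
        cg = load_connectome(edges, ann)
        rep = cluster_specificity(cg, cg.dan_ids("DL1"), cg.dan_ids("pPAM"))
        assert rep.labels["IN-00"] == "DL1-only"
        assert rep.labels["IN-01"] == "pPAM-only"
        assert rep.labels["IN-02"] == "shared"


class TestAggregatePairs:
    def test_pair_edges_summed(self):
        edges = edges_frame([("iL", "d", 2), ("iR", "d", 2), ("iL", "iR", 7)])
        ann = ann_frame([
            ("iL", "interneuron", "none", "none", "L", "pair_i"),
            ("iR", "interneuron", "none", "none", "R", "pair_i"),
            ("d", "DAN", "DL1"),
        ])
        merged = aggregate_pairs(load_connectome(edges, ann))
        assert merged.synapse_count("pair_i", "d") == 4
        assert "pair_i" in merged.neurons
        # intra-pair edge dropped
        assert merged.graph.number_of_edges() == 1

    def test_identity_without_pairs(self, tiny_pathway):
        cg, _, _ = tiny_pathway
        merged = aggregate_pairs(cg)
        assert set(merged.neurons) == set(cg.neurons)
        assert merged.edge_table().equals(cg.edge_table())

    def test_class_conflict_rejected(self):
        ann = ann_frame([
            ("aL", "interneuron", "none", "none", "L", "p"),
            ("aR", "KC", "none", "none", "R", "p"),
        ])
        with pytest.raises(ConnectomeError, match="mixes neuron classes"):
            aggregate_pairs(load_connectome(edges_frame([]), ann))

    def test_synapse_conservation_on_bilateral_graph(self):
        cfg = ConnectomeSimConfig(
            n_sensory_per_modality={"ORN": 3, "VM": 2}, n_interneurons=6,
            n_kc=4, n_mbon=2, n_dan_per_cluster={"DL1": 1, "pPAM": 1},
            background_scale=8.0, bilateral=True, seed=5,
            planted_motifs=(PlantedMotif((0,), 1, 0, 10),),
        )
        edges, ann, _ = simulate_connectome(cfg)
        cg = load_connectome(edges, ann)
        merged = aggregate_pairs(cg)
        pair_of = {r.neuron_id: r.pair_id for r in cg.neurons.values()}
        intra = sum(int(d["weight"]) for u, v, d in cg.graph.edges(data=True)
                    if pair_of[u] == pair_of[v])
        total = lambda g: sum(int(d["weight"]) for _, _, d in g.graph.edges(data=True))
        assert total(merged) == total(cg) - intra


class TestScaleInvariance:
    @pytest.mark.parametrize("k", [2, 7])
    def test_fractions_and_scores_unchanged_under_count_scaling(self, k):
        cg, edges, ann, _ = random_graph(13)
        scaled_edges = edges.assign(synapse_count=edges.synapse_count * k)
        scaled = load_connectome(scaled_edges, ann)
        cfg = AnalysisConfig()
        scaled_cfg = AnalysisConfig(theta_dan=cfg.theta_dan * k,
                                    theta_sensory=cfg.theta_sensory * k)
        base_tab = hub_table(cg, cg.dan_ids(), cfg)
        scaled_tab = hub_table(scaled, scaled.dan_ids(), scaled_cfg)
        assert [(r.dan_id, r.interneuron_id) for r in base_tab] == \
               [(r.dan_id, r.interneuron_id) for r in scaled_tab]
        for a, b in zip(base_tab, scaled_tab):
            assert a.hub_score == pytest.approx(b.hub_score, rel=1e-12)
        inter = set(cg.ids_of_class("interneuron"))
        c1 = sensory_composition(cg, inter, cfg)
        c2 = sensory_composition(scaled, inter, scaled_cfg)
        assert c1.keys() == c2.keys()
        for m in c1:
            assert c1[m] == pytest.approx(c2[m], rel=1e-12)
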