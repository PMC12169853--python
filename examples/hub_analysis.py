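"""Sensory-to-DAN hub analysis on a synthetic connectome.

Generates an annotated synaptic graph with five planted
sensory -> interneuron -> DAN motifs, then runs the thresholded
single-hop analysis: hub scores per (interneuron, DAN) connection,
input decomposition of one DAN, and DL1/pPAM cluster specificity.
"""

from danpipe import (
    ConnectomeSimConfig,
    PlantedMotif,
    cluster_specificity,
    find_sensory_to_dan_interneurons,
    hub_table,
    input_decomposition,
    load_connectome,
    sensory_composition,
    simulate_connectome,
)

motifs = tuple(
    PlantedMotif(sensory_idx=(3 * j, 3 * j + 1, 3 * j + 2),
                 interneuron_idx=j, dan_idx=j % 8, signal_count=25)
    for j in range(5)
)
edges, annotations, truth = simulate_connectome(
    ConnectomeSimConfig(planted_motifs=motifs, seed=42))
graph = load_connectome(edges, annotations)

print(f"graph: {len(graph.neurons)} neurons, {len(edges)} edges")
print(f"planted hub interneurons: {truth.planted_interneurons}\n")

# hub table: sensory fraction x DAN input fraction per qualifying pair;
# scores >= 0.001 are highlighted as hubs
print("top hub records (score = sensory_fraction x dan_fraction):")
for rec in sorted(hub_table(graph), key=lambda r: -r.hub_score)[:7]:
    flag = "HUB" if rec.highlighted else "   "
    print(f"  {flag} {rec.interneuron_id} -> {rec.dan_id}: "
          f"score {rec.hub_score:.4f} "
          f"({rec.sensory_fraction:.3f} x {rec.dan_fraction:.3f})")

# input decomposition of the first DL1 DAN: percentage of its total
# synaptic input per partner category
dan = graph.dan_ids("DL1")[0]
paths = find_sensory_to_dan_interneurons(graph, [dan])
rec = input_decomposition(graph, dan, paths.interneurons_by_dan[dan])
print(f"\n{dan} input decomposition (% of total input):")
print(f"  sensory-to-DAN interneurons: {rec.pct_sensory_interneurons:.1f}% "
      f"({rec.n_sensory_interneurons} cells)")
print(f"  other interneurons: {rec.pct_other_interneurons:.1f}% "
      f"({rec.n_other_interneurons} cells)")
print(f"  Kenyon cells: {rec.pct_KC:.1f}% ({rec.n_KC} cells)")
print(f"  MBONs: {rec.pct_MBON:.1f}% ({rec.n_MBON} cells)")

# which sensory modalities feed the hub layer, and how interneurons
# split between the punishment (DL1) and reward (pPAM) DAN clusters
comp = sensory_composition(graph, paths.interneuron_union)
print(f"\nsensory composition of {dan}'s hub input:",
      {m: round(p, 1) for m, p in comp.items()})
spec = cluster_specificity(graph, graph.dan_ids("DL1"), graph.dan_ids("pPAM"))
print(f"cluster specificity: {spec.n_dl1_only} DL1-only, "
      f"{spec.n_ppam_only} pPAM-only, {spec.n_shared} shared "
      f"of {spec.n_total} interneurons")
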