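"""PPI network statistics: LCC significance, RWR expansion, disease proximity.

Plants a dense 10-protein module in a 1,000-node scale-free interactome,
then treats the module as a dysregulated-protein seed set: scores its
connectivity against random sets, expands it by random walk with restart,
and screens a 50-disease catalogue (one disease overlapping the module) by
Jaccard index and degree-matched network proximity.
"""

from liveromics import network as net, synth

graph, truth = synth.gen_ppi(n_nodes=1000, planted_modules=((10, 0.9),), seed=3)
module = truth.index[truth["module"] == 0].tolist()
print(f"graph: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges")

seeds = net.map_seeds(module, graph)
lcc = net.lcc_zscore(seeds, graph, n_random=1000, seed=0)
print(f"module LCC: {lcc.observed}/{len(module)} connected, "
      f"z={lcc.z:.1f}, empirical p={lcc.p_empirical:.4f}")

expansion = net.rwr_expand(graph, seeds, alpha=0.9, target_coverage=0.9)
print(f"RWR expansion (alpha=0.9): {len(expansion.added)} node(s) added to "
      f"connect {expansion.coverage:.0%} of the seeds")

catalog, _ = synth.gen_disease_catalog(
    50, sorted(graph.nodes), overlap_spec={0: (module, 5)}, seed=4
)
screen = net.disease_screen(module, catalog, graph, n_random=200, seed=5)
top = screen.sort_values("p_adjusted").head(3)
print("\nmost proximal diseases (D001 shares 5 of 10 module genes):")
print(top[["jaccard", "d_c", "z", "p_adjusted"]].round(3).to_string())
# A z far below 0 and a small adjusted p mean the disease genes sit closer
# to the module than degree-matched random sets -- expected for D001 only.
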