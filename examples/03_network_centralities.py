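"""Rank genes of the largest sub-network by the four centrality measures.

Degree counts direct neighbours; betweenness counts shortest paths through a
gene (a high value marks putative switches between network regions);
closeness is reported both as total distance (farness) and its normalized
inverse; average neighbour degree describes a gene's context.
"""

import xylemnet as xn

counts, _ = xn.simulate_series(xn.SimulationConfig(rng_seed=1))
vst = xn.vst_transform(counts, xn.compute_size_factors(counts))
vst = vst.subset_genes(xn.filter_expressed(vst))
clr = xn.clr_transform(xn.mutual_information(vst))
net = xn.build_network(vst, clr, 3.5)
sub = xn.largest_subnetwork(net)

table = xn.centralities(sub)
print(f"centralities over {len(table)} genes of the largest sub-network")
top = xn.rank_table(table, "betweenness")[:5]
print("top 5 by betweenness (candidate developmental switches):")
print(table.loc[top].to_string())
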