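"""Recover the loop topology of a trefoil knot with Mapper.

The trefoil knot is a closed 3-D curve, so a faithful shape graph should
contain at least one independent cycle.
"""

import networkx as nx

from neuromapper import MapperConfig, run_mapper, trefoil_knot

data, angles = trefoil_knot(n=200, noise_sd=0.0)
config = MapperConfig(metric="euclidean", geodesic=False,
                      lens_algorithm="CMDS", lens_dim=2,
                      resolution=4, gain=33, cluster_method="linkage")
result = run_mapper(data, config)

G = result.graph.to_networkx()
rank = G.number_of_edges() - G.number_of_nodes() + \
    nx.number_connected_components(G)
print(f"shape graph: {result.graph.n_nodes} nodes, "
      f"{len(result.graph.edges)} edges")
print(f"cycle rank (edges - nodes + components): {rank}")
print("A cycle rank >= 1 means the graph contains a loop, matching the"
      " knot's true topology.")
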