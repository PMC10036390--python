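"""Topology metrics and hub/mediator traits for one lake's network.

Hubs are the most connected traits (high degree, then closeness) —
candidates for the centre of whole-plant phenotypic coordination.
Mediators (high betweenness) bridge otherwise separate trait modules.
"""

from ptnet import (
    SyntheticConfig,
    build_network,
    generate,
    identify_hubs,
    node_metrics,
    pearson_with_pvalues,
    topology_metrics,
)

ds = generate(SyntheticConfig(seed=42))
lake = ds.trait_matrix.groups[-1]  # the nutrient-rich end of the gradient
net = build_network(pearson_with_pvalues(ds.trait_matrix, lake))

topo = topology_metrics(net)
print(f"{lake}: ED={topo.edge_density:.3f}  AL={topo.average_path_length:.3f}  "
      f"AC={topo.average_clustering:.3f}  Q={topo.modularity:.3f}  "
      f"modules={topo.n_modules}")

report = identify_hubs(node_metrics(net), top_n=3)
print("\nhub traits (degree, closeness):")
for _, row in report.hubs.iterrows():
    print(f"  {row['trait']:5} k={row['k']:2.0f}  C={row['C']:.3f}")
print("mediator traits (betweenness):")
for _, row in report.mediators.iterrows():
    print(f"  {row['trait']:5} B={row['B']:.2f}")
print("\nHigh-degree traits sit at the centre of the correlation network; "
      "high-betweenness traits carry the shortest paths between modules.")
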