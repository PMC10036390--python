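"""Simulate a multi-lake trait study and build one network per lake.

Seven water bodies, 30 individuals each, 18 traits with three planted
correlation modules; within-module correlation strengthens along the
nutrient gradient. Each lake's network connects trait pairs whose
Pearson correlation is significant at alpha = 0.05.
"""

from ptnet import SyntheticConfig, build_network, generate, pearson_with_pvalues

ds = generate(SyntheticConfig(seed=42))
tm = ds.trait_matrix

print(f"{tm.n_individuals} individuals, {tm.n_traits} traits, "
      f"{len(tm.groups)} water bodies\n")
print("group   TP(mg/L)  DO(mg/L)  rho_in  edges  density")
for g in tm.groups:
    net = build_network(pearson_with_pvalues(tm, g), alpha=0.05)
    env = ds.env_table.data.loc[g]
    rho = ds.truth["rho_in"][g]
    n_possible = net.n_traits * (net.n_traits - 1) // 2
    print(f"{g:6}  {env['TP']:.3f}     {env['DO']:5.2f}     {rho:.2f}   "
          f"{net.n_edges:4d}   {net.n_edges / n_possible:.3f}")

print("\nEdge density rises along the gradient because stronger "
      "within-module correlation makes more trait pairs significant.")
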