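# ptnet — plant trait networks for submerged macrophytes

`ptnet` analyses the coordination of plant functional traits as a
network. Given a matrix of per-individual trait measurements grouped by
water body (lake or channel section), it builds one **plant trait
network (PTN)** per water body: traits are nodes, and an undirected
edge joins two traits exactly when their Pearson correlation is
statistically significant (two-sided p < α, default α = 0.05). The
binary network deliberately discards correlation sign and magnitude —
it encodes only which traits vary together.

From each network the package computes:

- **node parameters** — degree *k* (number of correlated partners),
  closeness *C* (reciprocal of the *mean* shortest-path length to
  reachable traits), and betweenness *B* (shortest paths through the
  trait, fractional credit for ties). High-*k* traits are **hub
  traits**; high-*B* traits are **mediator traits** bridging modules;
- **topology metrics** — edge density ED = 2|E|/(n(n−1)), average path
  length AL (mean shortest-path distance over connected pairs), average
  clustering coefficient AC, and modularity Q of the module partition
  found by deterministic greedy modularity maximisation;
- **trait variability** — coefficient of variation CV = s/x̄ per trait
  and group, group mean CVs, and variability rankings;
- **drivers** — linear regressions of node metrics on trait CV, and the
  two-stage environmental workflow: Pearson screening of topology
  metrics against environmental variables (TP, DO, …) followed by
  backward multiple regression (predictors dropped while p > 0.10).

A synthetic-data module generates trait matrices with planted
correlation modules (within-module correlation ρ_in, between-module
ρ_out) linked to a nutrient gradient, so the whole pipeline is testable
without field data.

## Worked example

`examples/01_simulate_and_build_networks.py` simulates seven water
bodies (30 individuals × 18 traits each) whose within-module trait
correlation strengthens with total phosphorus, then builds the seven
networks:

```
group   TP(mg/L)  DO(mg/L)  rho_in  edges  density
WB1     0.014     11.96     0.30     27   0.176
WB2     0.020     11.00     0.38     43   0.281
WB3     0.028      9.90     0.47     46   0.301
WB4     0.035      9.11     0.55     45   0.294
WB5     0.040      8.09     0.63     66   0.431
WB6     0.047      7.01     0.72     60   0.392
WB7     0.055      6.14     0.80     53   0.346
```

Edge density climbs along the gradient: tighter trait coordination
produces a denser network. `examples/03_variability_and_environment.py`
closes the loop — screening finds TP and DO significantly correlated
with ED and AL, and backward regression yields, for the same seed,

```
ED = 0.60 - 0.03*DO  (R2=0.65; F=9.10; P=0.0295)
AL = 0.87 + 0.17*DO  (R2=0.64; F=8.79; P=0.0314)
```

i.e. networks are denser and shorter-pathed at the nutrient-rich,
low-oxygen end — the planted structure, recovered from the simulated
measurements alone. `examples/02_metrics_and_hub_traits.py` ranks hub
and mediator traits, and `examples/04_full_pipeline.py` runs everything
end-to-end, writing edge lists, GraphML files, metric tables,
regression reports, and a JSON manifest.

The same pipeline runs from a shell:

```bash
ptnet run-all --synthetic --seed 42 --out results/demo
ptnet run-all --trait-csv traits.csv --env-csv env.csv --group-column lake
```

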