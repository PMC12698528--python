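# streamnet

Resilience analysis of stream-biofilm bacterial communities under drying and
rewetting, built around microbial co-occurrence networks. The package is
aimed at microbial ecologists running factorial mesocosm (or field)
experiments who have an OTU count table and sample metadata and want a
reproducible route from counts to: α/β-diversity statistics, Spearman
co-occurrence networks, keystone-taxon roles, and network stability metrics
— plus a synthetic-data generator with known ground truth so every stage of
the pipeline can be validated before touching real data.

## What it computes

**α-diversity.** Per-sample taxon richness S (number of taxa with count
> 0) and the Shannon–Wiener index H = −Σᵢ pᵢ ln pᵢ.

**β-diversity.** Bray–Curtis dissimilarity d(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)
and Euclidean distance; ANOSIM on the ranked dissimilarities,

    R = (r̄_between − r̄_within) / (M/2),  M = n(n−1)/2,

with a seeded label-permutation p-value p = (b+1)/(N+1); nonmetric
multidimensional scaling (NMDS) minimising Kruskal stress-1 via isotonic
regression and SMACOF updates; Bonferroni control and partial η²
effect-size labelling.

**Co-occurrence networks.** All-pairs Spearman screen retaining
|ρ| > 0.7 with p < 0.001 (two-sided t approximation, or seeded
permutation); edges carry ρ, its sign and weight |ρ|. Topology metrics
(nodes, edges, connectance = graph density = 2E/(N(N−1)), average degree
2E/N, average clustering coefficient), modularity maximisation (exact on
tiny graphs, seeded Louvain restarts otherwise), and the Zi–Pi role
cartography: Zi = (k_is − mean_s)/sd_s (within-module degree,
standardised), Pi = 1 − Σ_t (k_it/k_i)², with peripherals / connectors /
module hubs / network hubs split at Zi = 2.5 and Pi = 0.62. Module hubs,
connectors and network hubs are the keystone taxa.

**Stability.** Global efficiency E_glob = ⟨1/d_ij⟩ over ordered pairs
(0 for disconnected pairs); vulnerability
V = maxᵢ (E_glob − E_glob(G−i))/E_glob; robustness = expected proportion of
the original taxa still connected (degree ≥ 1) after random removal of a
fixed fraction of nodes, with an exhaustive-enumeration oracle for small
graphs.

**Synthetic experiments.** `datagen` emulates a drying/rewetting mesocosm
experiment (3 habitat-heterogeneity levels × 2 hydrology treatments × 8
replicates in 4 spatial blocks, 4 sampling days = 192 samples) with a
Gaussian copula: a latent multivariate normal with block-structured
correlations (planted network modules) is pushed through negative-binomial
marginals and a multinomial depth rescaling. Drought lowers richness
(random taxon loss) and raises evenness (mean flattening), rewetting mixes
parameters back toward control — so the directional response and the true
edge set are both known and recoverable.

## Worked example

```python
import streamnet as sn

design, truth, table = sn.simulate_experiment(
    seed=7, truth_kwargs={"n_taxa": 60, "n_modules": 4})

summ = sn.diversity_summary(table, design)
d38 = summ[summ.day == 38].groupby("hydrology")[["richness", "shannon"]].mean()
print(d38.round(3))

dm = sn.distance_matrix(table.subset_samples(
    design.loc[design.day == 38, "sample_id"]), "bray_curtis")
labels = design.set_index("sample_id").loc[dm.sample_ids, "hydrology"]
res = sn.anosim(dm, labels, n_permutations=999, seed=1)
print(f"ANOSIM: R = {res.R:.3f}, p = {res.p:.3g}")

ctrl = design.loc[design.hydrology == "control", "sample_id"]
core = sn.select_core_taxa(table, 0.3, ctrl.tolist())
cands = sn.spearman_screen(core, rho_min=0.7, alpha=0.001)
net = sn.build_network(cands, name="control")
part = sn.detect_modules(net, seed=2)
rec = sn.evaluate_edge_recovery({(c.taxon_a, c.taxon_b) for c in cands}, truth)
print(f"network: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges, "
      f"Q = {part.q:.3f}; recovery precision = {rec['precision']:.2f}, "
      f"recall = {rec['recall']:.2f}")
```

prints

```
           richness  shannon
hydrology
control      48.167    2.469
drying       40.000    2.922
ANOSIM: R = 0.074, p = 0.024
network: 60 nodes, 387 edges, Q = 0.747; recovery precision = 1.00, recall = 0.92
```

Reading the output: at the late-drought sampling day the drying mesocosms
have lost taxa (richness 40 vs 48) yet are *more* even, so Shannon
diversity is higher (2.92 vs 2.47) — the drought signature the generator
plants. ANOSIM confirms the community compositions separate by hydrology
(p < 0.05). The control-stratum network recovers the four planted modules
almost perfectly: every retained edge is a true edge (precision 1.00) and
92% of planted edges are found; Q ≈ 0.75 is the theoretical modularity of
four equal, disconnected modules.

The same pipeline runs from the shell:

```bash
streamnet run-all --seed 7 --out results/run7
```

which writes counts, design, per-stratum networks (GraphML + edge lists),
role tables, stability reports and a checksum manifest; rerunning with the
same seed reproduces every checksum.

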