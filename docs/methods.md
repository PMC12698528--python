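# Methods

This note documents the models, algorithms and numerical choices behind
streamnet, in the order the pipeline applies them.

## The synthetic experiment

`datagen` emulates a Before-After-Control-Impact stream-mesocosm study. The
default design crosses three substrate-heterogeneity levels (low, medium,
high) with two hydrology treatments (control, drying), eight replicate
mesocosms per combination arranged as two replicates in each of four
spatial blocks, sampled on days 23 (end of colonization, pre-impact), 26
and 38 (during the drought) and 61 (after rewetting): 48 mesocosms, 192
sample rows. Day levels are mapped to phases by position — first day =
colonization, interior days = drought, last day = rewetting — so reduced
designs degrade gracefully (a single-day design is all pre-impact).

Counts are drawn through a Gaussian copula with negative-binomial
marginals:

1. A block-structured latent correlation matrix places every taxon in one
   of `n_modules` modules; within-module pairs share correlation ρ_w
   (default 0.9), between-module pairs ρ_b (default 0). If the block
   construction is indefinite (possible for negative ρ_b), it is repaired
   by eigenvalue clipping at 1e-8 followed by re-normalisation to unit
   diagonal. The ground-truth edge set is the pairs with |latent
   correlation| ≥ 0.7, matching the downstream screen's cutoff.
2. Per sample, a multivariate-normal draw is mapped through Φ to uniforms
   and then through negative-binomial quantile functions with per-taxon
   means. Because the map is monotone per taxon, Spearman correlations —
   which see only ranks — inherit the latent structure; this is why the
   planted network is recoverable by a rank-based screen.
3. The negative-binomial counts are rescaled to a fixed library depth by a
   multinomial draw, making the data compositional like real amplicon
   libraries (column sums equal the depth exactly).

Base mean abundances are log-normal across taxa (σ = 1.5, heavy-tailed as
in real communities) and scaled so they sum to the library depth. This
scaling matters: with O(1) means most counts are 0 or 1, rank ties at zero
dominate, and the copula's correlation signal is destroyed. The
negative-binomial size parameter defaults to 0.5 (strongly overdispersed,
typical for amplicon data); it also damps the spurious compositional
correlations that the fixed-depth closure would otherwise induce between
abundant taxa.

Treatment effects are generative and directional. In drought-phase drying
samples each taxon is independently zeroed with probability
`p_loss_drying` (default 0.3) — richness decreases — and surviving means
are flattened by raising them to `evenness_exponent` (default 0.5) and
rescaling — evenness, hence Shannon diversity, increases. A
`persistent_loss` switch draws the zeroing mask once per mesocosm instead
of per sample, for stricter realism. Rewetting-phase drying samples use a
convex mix of control and drought parameters with weight `recovery_mix`
(default 0.9 toward control: strong but incomplete recovery). Depth
defaults to 10,000 reads and the default community has 150 taxa in 4
modules. With all effect parameters neutral (loss 0, exponent 1, mix 1)
drying samples are distributionally identical to controls, which the test
suite exploits as a null check.

What the generator does *not* emulate: taxonomic identity, real
phylogenetic or functional structure, spatial structure within mesocosms,
and — importantly — any drought-induced *increase* in network complexity.
Random taxon loss weakens pairwise correlations, so simulated drought
networks are sparser than controls; passing tests demonstrate correct
recovery of planted structure and effect directions, not that the
generator reproduces every empirical pattern of real drying communities.

## Filters and α-diversity

Singleton filtering drops taxa whose total count across the dataset is
≤ 1 (including all-zero taxa); it is idempotent. The abundance filter
keeps taxa whose share of total reads strictly exceeds a threshold
(default 1%), either dataset-wide or within at least one group. Richness
counts taxa with count > 0; Shannon uses the natural log by default with a
base-2 switch, since historical amplicon pipelines differ and the choice
is a units convention (H scales by ln 2). No rarefaction is applied by
default; diversity is computed on raw (optionally filtered) counts.

## β-diversity statistics

ANOSIM ranks all M = n(n−1)/2 dissimilarities ascending with mid-ranks for
ties and computes R = (r̄_between − r̄_within)/(M/2) ∈ [−1, 1]. The p-value
is a seeded permutation test with the add-one estimator p = (b+1)/(N+1)
(the observed labelling counts as one permutation; p is never 0; default
N = 999). A constant distance matrix yields R = 0 with a warning. ANOSIM
defaults to Bray–Curtis input; NMDS defaults to Euclidean. Bonferroni
adjustment multiplies p by the number of tests (capped at 1) and rejects
when the raw p is strictly below α/m.

NMDS minimises Kruskal stress-1,
√(Σ(d_ij − d̂_ij)² / Σ d_ij²), where d are configuration distances and d̂
is the isotonic (pool-adjacent-violators) regression of d on the input
dissimilarity order. The configuration update is the nonmetric SMACOF
(Guttman-transform) iteration rather than raw gradient descent: the
majorization step is what guarantees the monotone stress decrease that the
API reports, and is the standard choice in mature ordination software. An
iteration that fails to lower the normalised stress terminates the start
(keeping the best configuration), so the reported stress trace is
non-increasing by construction. Defaults: 20 seeded random starts, 300
iterations, tolerance 1e-7; the best start is returned and
non-convergence flags the result instead of raising.

Partial η² = SS_effect/(SS_effect + SS_error) accepts sums of squares from
any external linear-model fit (the MANOVA itself is standard statistics
and out of scope) and attaches the conventional labels: < 0.01 very
small, ≥ 0.01 small, ≥ 0.06 medium, ≥ 0.14 large.

## Co-occurrence networks

The screen computes all-pairs Spearman ρ (mid-ranks, then Pearson on the
ranks, via scipy) and retains |ρ| > 0.7 with p < 0.001. The absolute-value
reading is deliberate: drought-era networks contain negative associations,
and a signed-only switch is provided. p defaults to the two-sided t
approximation t = ρ√((n−2)/(1−ρ²)); a seeded permutation p is available
for small n. No multiple-testing correction is applied by default (the
conventional raw cutoff); a Benjamini–Hochberg flag exists. Zero-variance
taxa are skipped with a log entry, and fewer than 5 samples is an error —
a rank test on 4 points is meaningless.

Before screening, `select_core_taxa` keeps taxa present in ≥ 30% of the
stratum's samples (configurable). Rationale: mostly-zero taxa tie at rank
zero for most samples, making their ρ estimates unstable; the prevalence
filter is a variance screen, not an abundance judgement.

Modularity uses the Newman–Girvan Q on edge counts (unweighted by default
so hand-computable values hold exactly; |ρ|-weighted behind a flag).
Graphs with ≤ 8 nodes are solved exactly by enumerating all set
partitions (Bell(8) = 4140, instantaneous) — this makes tiny-graph results
provably optimal; larger graphs use seeded Louvain restarts (default 16)
keeping the best Q. Module labels are renumbered by smallest member node
so identical partitions always serialise identically; this matters because
module labels feed Zi–Pi.

Zi standardises the within-module degree with the module's **population**
standard deviation (the original role-cartography convention); a module
whose members all have identical within-degree has sd 0 and Zi is defined
as 0. Pi = 1 − Σ_t (k_it/k_i)²; isolated nodes get Pi = 0. Role thresholds
are Zi = 2.5 and Pi = 0.62, with boundary equality assigned upward (to the
hub/connector side) — strict inequalities on both sides would leave the
boundary unclassified. A descriptive power-law exponent of the degree
distribution (continuous MLE with x_min = 1) is available as an optional
output; it never participates in edge filtering.

## Stability metrics

Global efficiency uses unweighted shortest paths by default (a
1/|ρ|-length weighted variant is behind a flag), with 1/d = 0 for
disconnected pairs and E_glob = 0 for N ≤ 1. Vulnerability evaluates every
single-node deletion, normalising the residual graph by its own N − 1;
per-node contributions (which may be negative) are returned alongside the
maximum. An edge-deletion analogue is provided.

Robustness removes ⌊fN⌋ nodes uniformly at random per repetition
(default f = 0.5, 100 repetitions, both always recorded in the report so
values are interpretable) and counts survivors with degree ≥ 1 against the
*original* N — the proportion of the original community remaining; a
survivors-denominator variant is switchable. A deterministic
`removal_sets` argument and an exhaustive-enumeration expectation
(`robustness_expectation`) exist for validation: on enumerable graphs the
seeded Monte-Carlo mean lands within sampling error of the exact value.

"Complexity" has no single formula in the literature; the stability report
exposes the full metric bundle and designates average degree as the
headline complexity scalar, since complexity claims in this setting are
operationalised as more nodes/edges and higher AD/connectance/avgCC/GD.

## Pipeline and reproducibility

Every stochastic stage receives `derive_seed(global_seed, stage_name,
stratum_label)` — a SHA-256-based hash folded below 2³¹ — so adding a
stratum never perturbs another stratum's draws, and results are identical
across processes and platforms. The run directory contains the verbatim
config and a manifest with SHA-256 checksums of every artifact; rerunning
a config reproduces the checksums byte-for-byte. Networks are exported as
GraphML (node attributes: module, Zi, Pi, role, taxonomy) and flat CSV
edge lists; count tables as TSV or BIOM 1.0 JSON (the text flavour of the
BIOM standard).

Default stratification builds one network per hydrology × day cell.
The exact sample grouping behind any particular published network design
is study-specific, so strata are user-configurable rather than hard-coded.

## Problem sizes used in validation

The test suite and acceptance script use the full 192-sample default
design for effect-direction and determinism checks; planted-structure
recovery uses 20 taxa in 4 modules over 96 neutral samples (small enough
that the truth is unambiguous, large enough that ρ estimates are stable);
oracle-equivalence checks run on 50 random instances with ≤ 12 nodes or
taxa where brute force is exact; ANOSIM calibration uses 500 simulations
of 199 permutations on a 20-sample matrix. These sizes were chosen so each
property is measured with adequate Monte-Carlo precision while the whole
suite remains quick to run.

## Known limitations

- Spearman screens ignore compositionality; the fixed-depth closure can
  induce spurious correlations (damped here by overdispersion, visible at
  low dispersion in small communities). Compositionality-aware inference
  (SparCC-style) is explicitly out of scope.
- The t approximation for Spearman p is asymptotic; at n < ~10 prefer the
  permutation option.
- Louvain is a heuristic above 8 nodes; Q is a lower bound on the optimum.
- Vulnerability is O(N · (N + E)·N) from repeated all-pairs BFS; fine for
  the hundreds-of-nodes networks this targets, slow beyond ~10⁴ nodes.
- The generator's drought effect weakens co-occurrence signal; it cannot
  be used to study complexity *increases* under drought.
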