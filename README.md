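# assemblyscape

Community-assembly inference for depth-stratified soil microbiomes.

Soil bacterial communities along environmental gradients are shaped by a
mix of deterministic processes (environmental selection) and stochastic
ones (dispersal and ecological drift), and the balance is known to shift
with soil depth. `assemblyscape` implements the statistical toolkit used
to quantify that balance from an amplicon survey — a site-by-taxon count
table, a phylogeny, and per-sample environmental data — together with a
ground-truthed synthetic-data generator that emulates a grassland soil
survey (sites along a south–north precipitation gradient, three depth
layers per site, phylogenetically conserved environmental niches). It is
aimed at microbial ecologists who want these analyses as tested,
reproducible, seedable library code rather than a collection of scripts.

## What it computes

**Null-model process classification.** For every pair of communities the
abundance-weighted β-mean-nearest-taxon-distance

βMNTD(k,l) = ½ [ Σ_{i∈k} f_ik · min_{j∈l} d(i,j) + Σ_{j∈l} f_jl · min_{i∈k} d(j,i) ]

is compared against a null that shuffles taxon labels across the tips of
the phylogeny, giving the z-score **βNTI**. The Bray–Curtis-based
Raup–Crick metric **RC-bray** ranks the observed dissimilarity within a
probabilistic null that reassembles each community preserving its richness
and reads (occurrence ∝ regional occupancy, abundance ∝ regional relative
abundance), rescaled to [−1, 1]. Pairs are classified:

| condition | process |
|---|---|
| βNTI < −2 | homogeneous selection |
| βNTI > 2 | variable selection |
| \|βNTI\| < 2, RC < −0.95 | homogeneous dispersal |
| \|βNTI\| < 2, RC > 0.95 | dispersal limitation |
| \|βNTI\| < 2, \|RC\| ≤ 0.95 | drift |

**Sloan neutral community model.** Occurrence frequency vs mean relative
abundance is fit with f(p) = 1 − BetaCDF(1/N; N·m·p, N·m·(1−p)),
estimating the immigration rate m and the neutral fit R².

**Diversity.** Sobs, bias-corrected Chao1, Shannon (nats), Pielou, Good's
coverage, Faith's PD; Bray–Curtis and normalized weighted UniFrac;
non-metric MDS; ANOSIM and PERMANOVA with seeded permutation tests.

**Networks.** Genus-level co-occurrence networks (Spearman, |ρ| > 0.8,
p < 0.05, restricted to >1%-abundance phyla and the top 200 genera) with
degree / clustering / path-length / modularity summaries, plus bipartite
genus–environment networks (p < 0.01).

**Distance-decay.** ln C = α + β ln(E/G) for geographic (haversine) and
environmental (z-scored Euclidean) distance, with Mantel-style permutation
inference.

**Attribution.** Multiple regression on distance matrices (MRM) and PLS
path modeling (mode A, centroid scheme; GOF = √(mean communality × mean
R²)) decompose βNTI variation into environmental, spatial and biotic
components.

## Worked example

```python
from assemblyscape import (SimConfig, simulate_dataset, beta_nti, rc_bray,
                           classify_processes)

cfg = SimConfig(n_taxa=600, n_sites=24, n_layers=3, reads_per_sample=2000,
                regime="mixed", migration=0.05, seed=1)
table, tree, env, truth = simulate_dataset(cfg)
work = table.drop_empty_taxa()

z = beta_nti(work, tree, n_null=299, seed=1)
rc = rc_bray(work, n_null=299, seed=2)
res = classify_processes(z, rc, groups=work.metadata["layer"])
print(res.fractions.round(2))
```

On the mixed-regime survey (strong selection in topsoil, weakened
selection in the middle layer, dispersal-limited drift in the subsoil)
the analysis drivers print, per layer:

```
layer T: median betaNTI = -2.41, 79% of pairs < -2
layer M: median betaNTI = -0.39, 1% of pairs < -2
layer S: median betaNTI = +0.10, 0% of pairs < -2
```

i.e. homogeneous selection dominates topsoil pairs (βNTI below −2) while
middle and subsoil pairs fall in the stochastic band, resolved by RC-bray
into dispersal limitation and drift. The per-layer neutral-model fits
show the matching dispersal story — m declines with depth:

```
        m        Nm      R2
T  0.1375  275.0292  0.4852
M  0.0888  177.6303  0.1941
S  0.0217   43.3546  0.6728
```

The numbered scripts under `analysis/` run the full survey analysis in
order (simulate → diversity → assembly → neutral model → networks →
distance-decay → attribution), writing tables under `results/`. The same
stages are available programmatically via `run_pipeline(RunConfig(...))`
and from the shell via the `assemblyscape` command.

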