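# mesoscope

Meso-scale community structure of weighted brain networks — and of any
weighted network — beyond the assumption that communities are assortative.

Most community-detection work on connectomes maximizes modularity and
therefore can only find *assortative* communities: node groups that are
internally dense and externally sparse. `mesoscope` implements the
complementary blockmodel view and the statistics needed to compare the two:

- **Sparse weighted stochastic blockmodel (WSBM).** Each dyad between
  communities *r*, *s* exists with probability θ<sup>e</sup><sub>rs</sub>
  (Bernoulli) and, when present, carries a weight ~
  Normal(μ<sub>rs</sub>, σ²<sub>rs</sub>). The two factors are combined with
  a mixing weight α (default 0.5) and the model is fit by mean-field
  variational Bayes with conjugate priors, best-of-restarts
  (`mesoscope.fit_wsbm`).
- **Fixed-K modularity maximization.** Q = (1/2m) Σ<sub>ij</sub> [A<sub>ij</sub> −
  γ k<sub>i</sub>k<sub>j</sub>/2m] δ(z<sub>i</sub>, z<sub>j</sub>), maximized by a
  greedy single-node-switch algorithm at a fixed number of communities
  (`mesoscope.greedy_fixed_k`).
- **Comparison statistics.** Variation of information (bits); community
  assortativity 𝒜<sub>r</sub> = ω<sub>rr</sub> − max<sub>s≠r</sub> ω<sub>rs</sub>
  and its node-level analogue φ<sub>i</sub>, where ω<sub>rs</sub> is the mean
  connection weight between communities; the *maximally assortative set*
  (the largest community subset whose minimum within-density exceeds its
  maximum mutual between-density); the weighted rich-club coefficient
  φ<sup>w</sup>(k) = W<sub>&gt;k</sub>/W<sup>max</sup> with degree-preserving
  rewired nulls.
- **Community morphospace.** Every community pair is a point
  (ω<sub>rr</sub>, ω<sub>ss</sub>, ω<sub>rs</sub>) classified as assortative
  (min(ω<sub>rr</sub>, ω<sub>ss</sub>) > ω<sub>rs</sub>), core–periphery
  (ω<sub>rr</sub> > ω<sub>rs</sub> > ω<sub>ss</sub>), or disassortative
  (ω<sub>rs</sub> > max(ω<sub>rr</sub>, ω<sub>ss</sub>)); node-level motif
  participation and its entropy, the *diversity index*
  H<sub>r</sub> = −Σ P<sub>m</sub> log₂ P<sub>m</sub> ∈ [0, 2] bits.
- **Group statistics.** Curve-difference permutation tests
  (functional-data style), within/between-community metadata contrasts,
  system-level permutation tests, strength-binned motif dominance, and the
  Spearman diversity–behavior correlation with total-weight partialing and
  BH-FDR.
- **Synthetic planted networks** (`mesoscope.synthgen`) so every stage is
  testable without data: block-structured Bernoulli × truncated-normal
  generators with presets planting each motif, plus the two null models
  (Maslov–Sneppen degree-preserving rewiring that carries edge weights, and
  uniform partition-label permutation).

## Worked example

```python
import mesoscope as ms

# a planted two-block core-periphery network: 100 nodes, dense core
spec = ms.motif_preset("core_periphery")          # theta: 0.6 / 0.35 / 0.05
net, planted = ms.sample_planted_network(spec, seed=11)

fit = ms.fit_wsbm(net, K=2, restarts=5, seed=0)
print(ms.variation_of_information(fit.map_partition, planted))
# 0.0                      <- planted structure recovered exactly
print(fit.params.edge_theta.round(3))
# [[0.603 0.349]
#  [0.349 0.066]]          <- recovered block ordering theta_cc > theta_cp > theta_pp

bdm = ms.block_densities(net, fit.map_partition)
pt = ms.morphospace_points(bdm)[0]
print(pt.motif.value, pt.core)
# core_periphery 1         <- the dyad classified; community 1 is the core
```

A modularity fit on the same network behaves differently — that contrast is
the scientific point:

```python
q = ms.greedy_fixed_k(net, 2, ms.ModularityConfig(restarts=5), seed=0)
print(round(q.q, 3))
# 0.082                    <- barely modular: a core-periphery network has no
#                             internally-dense, externally-sparse split to find
```

The numbered scripts under `analysis/` run the full narrative on a planted
mixed-motif network (simulate → fit both methods across K → VI agreement →
assortativity and maximally assortative set → morphospace and diversity →
rich club → group statistics), writing tables under `results/`. Run them in
order from the repository root:

```bash
python analysis/01_simulate_networks.py
python analysis/02_fit_communities.py
# ... through 07
```

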