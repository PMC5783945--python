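# Methods

This note records the models, algorithmic choices and their rationale, in
enough detail to reimplement the package from it.

## Networks and partitions

A network is an N×N nonnegative weight matrix with zero diagonal
(`WeightedNetwork`); undirected networks are stored as full symmetric
matrices. Binary degree k_i counts nonzero off-diagonal entries; strength
s_i is the row sum. Partitions are label vectors z ∈ {1..K}^N, always
stored canonically (labels renumbered 1..K by first appearance). All
metrics in the package are invariant to relabeling, so canonical storage
loses nothing and makes file round-trips exact.

## Sparse weighted stochastic blockmodel

**Model.** For communities r = z_i, s = z_j, the dyad (i, j) exists with
probability θ^e_rs; an existing edge carries a weight drawn from
Normal(μ_rs, σ²_rs). A zero entry means "no connection", never "weight
zero", so absent dyads enter only the Bernoulli factor. The two factors
are combined as α·(Bernoulli log-likelihood over all dyads) +
(1−α)·(normal weight kernel over existing edges), α ∈ [0, 1], default 0.5
(equal importance of existence and weight). Convention: the Bernoulli
factor keeps its full log-pmf, so α = 1 reduces exactly to the binary
blockmodel likelihood; the weight factor is the normal kernel without its
−½log(2πσ²) normalizer. The argmax over partitions at fixed α is
unaffected by these constant conventions.

**Inference.** Mean-field variational Bayes with conjugate priors:
Beta(1, 1) on each θ^e_rs and Normal–Gamma(m0 = sample mean of positive
weights, κ0 = 1, a0 = 1, b0 = sample variance of positive weights) on
(μ_rs, precision), flat prior over labels. α enters as factor exponents 2α
and 2(1−α), which preserves conjugacy and makes α = 0.5 the exact
untempered posterior. Each iteration updates node responsibilities
*sequentially* (each row update is an exact coordinate-ascent step, so the
evidence lower bound is monotone non-decreasing — asserted in tests) and
then the block-parameter posteriors in closed form. Convergence: absolute
ELBO change < 1e-6 (default), max 500 iterations; non-converged restarts
are flagged and the best-so-far bound returned. Reported point parameters
are posterior means (θ̂ = p/(p+q), μ̂ = m, σ̂² = b/a).

**Initialization (a design point that matters).** When block parameters
are re-estimated from responsibilities, their between-block contrast is
*quadratic* in the responsibilities' alignment with any real structure.
Consequently the symmetric "all blocks equal" fixed point has a large
basin: on the assortative preset (θ 0.4/0.1, N = 100) the alignment must
exceed roughly 0.7 before coordinate ascent amplifies it, while random
responsibility draws start at ~N^(−1/2) ≈ 0.1 and collapse. Purely random
initialization therefore essentially never escapes the uninformative
optimum. Each restart instead initializes from a randomized k-means
(k-means++ seeding) clustering of the rows of the weight matrix — nodes'
connectivity profiles — softened to responsibilities 0.95/0.05. Different
restarts see different k-means draws and land in different local optima;
a plain Dirichlet(1) draw remains available (`init="dirichlet"`) for
studying exactly this failure mode. Restart seed streams are split from
the master seed, so fits are bit-reproducible.

Directed fitting is not implemented (the target application's networks are
undirected); the standalone likelihood functions accept directed networks
over ordered dyads.

## Fixed-K modularity maximization

Q = (1/2m) Σ_ij [A_ij − γ·k_i k_j/2m]·δ(z_i, z_j), configuration-model
null, γ = 1 default. The 1/2m normalization is included (the standard,
cross-network-comparable convention); it never changes the maximizing
partition. "Degree" in the null is weighted strength by default (the
metric is applied to weighted matrices); a binary-degree mode exists. The
maximizer starts from a uniformly random K-labeling, proposes (node, new
label) switches uniformly at random (10 000 per restart by default),
accepts only strict improvements (ties rejected, guaranteeing
termination of improvement), and keeps the best of 250 restarts
(desk-scale profile: 25). ΔQ is computed incrementally from maintained
node-to-community weight sums; incremental and from-scratch Q agree to
1e-9 (tested). Communities may empty out; no repair step is applied and
the effective K is reported. Note one honest property of this algorithm:
strictly-greedy single-node switches have genuine local optima (e.g., all
nodes in one community), which trap a minority (~13% measured on a
two-clique toy) of random initializations — hence the restarts.

## Partition comparison

VI(P1, P2) = H(P1) + H(P2) − 2I(P1, P2) from the label contingency table,
log base 2 throughout (only comparisons matter; bits are the convention
everywhere else in the package). Partitions are compared only at equal K.
The within- vs between-technique comparison reports all pairwise VI values
and one-tailed Welch t-tests (within < between); the pairwise values share
partitions and are not independent, which the result object flags — null
simulations show the test is nevertheless close to nominal (slightly
conservative).

## Block densities, assortativity, maximally assortative set

ω_rs = (1/(n_r n_s)) Σ_{i∈r, j∈s} A_ij over ordered pairs. The
within-community formula is applied literally — the zero diagonal is
included and the denominator is n_r² — because either convention is
defensible and this one is the printed definition; an exclude-diagonal
mode (denominator n_r(n_r−1)) is provided, and the motif classifications
of the planted presets agree under both. Community assortativity
𝒜_r = ω_rr − max_{s≠r} ω_rs; regional φ_i = a_{i z_i} − max_{r≠z_i} a_ir
with a_ir the mean weight from node i into community r. Singleton
communities yield NaN (excluded), never zero. Directed networks use the
conservative reading: own-community density is the lesser of in/out, the
subtrahend the greater of the in/out maxima.

The maximally assortative set is found by exhaustive search over all
2^K − K − 1 subsets of ≥ 2 communities (K ≤ 20 guard), keeping subsets
with min-within > max-between and maximizing total node count; ties break
by larger margin, then lexicographically. Size-1 subsets are excluded (a
"set of interacting communities" needs a between-term); this is
configurable.

## Community morphospace and diversity

Each community pair is classified by the piecewise rule (assortative /
core–periphery with an identified core / disassortative). Exact ties
cannot occur for continuous weights but do on toy inputs; they resolve by
the precedence assortative > core–periphery > disassortative and carry a
tie flag. Node participation counts the four roles (assortative, core,
periphery, disassortative) of a node's community, normalized by the total
motif count K(K−1)/2 (K(K−1) directed); community-level motif
probabilities use that community's own K−1 interactions. Both
normalizations are computed because they answer different questions (share
of the whole motif budget vs composition of one community's interactions);
the diversity entropy H_r = −Σ P log₂ P ∈ [0, 2] bits uses the
community-level probabilities and is assigned to all member nodes.

## Rich club

φ^w(k) = W_{>k}/W^max: club = nodes with binary degree strictly > k
(a ≥ mode exists), W_{>k} the weight among them over E_{>k} edges, W^max
the sum of the E_{>k} largest weights anywhere. Significance against 100
degree-preserving rewirings; p(k) = fraction of nulls with φ^w ≥ observed
(inclusive — conservative at 100 nulls; add-one correction available).
The 20–80 split ranks by binary degree with strength then node-index
tie-breaks (deterministic); a strength-ranked mode exists since either
ranking is defensible.

## Null models

Degree-preserving rewiring: Maslov–Sneppen double-edge swaps, default 10
attempted swaps per edge; proposals creating self-loops or multi-edges are
rejected (and still count as attempts). Weights travel with their edges,
so the binary degree sequence, edge count, and weight multiset are
preserved exactly. Label permutation: a uniform permutation of the label
vector, preserving community sizes exactly.

## Permutation and group statistics

Curve comparisons pool (x, value) samples to per-x means, interpolate
linearly on the union grid inside both supports, and use the summed
pointwise difference as the statistic; no smoothing basis is imposed.
Permutation p-values use the add-one convention (b+1)/(n_perm+1) — exact
under exchangeability, never zero. System-level tests permute node values
(equivalent under exchangeability to permuting labels), report one-sided
p in both directions, BH-FDR across systems. The degree-standardized
regional assortativity z-scores observed mean φ_i against degree-preserving
rewired ensembles — one defensible reading of "corrected for degree", and
labeled as such. The diversity–behavior operation residualizes per-region
diversity on subjects' total connection weight (least squares with
intercept) and Spearman-correlates residuals with the composite accuracy
score, BH-FDR across regions.

## Synthetic data: what it does and does not emulate

The generator draws block-structured networks with Bernoulli existence and
truncated-normal weights (truncation at 0, since connectome weights are
nonnegative; presets keep μ ≥ 3σ so truncation is negligible and the
normal model is effectively exact). Preset densities (assortative 0.4/0.1;
core–periphery 0.6/0.35/0.05; disassortative 0.05/0.4; all μ = 1,
σ² = 0.04) put expected block densities at least 3 sampling standard
errors on the correct side of every classification boundary at the default
sizes (50+50 nodes) — undersized requests are rejected. The mixed
four-block preset (120 nodes) plants all three motifs at once with a
globally dense core, so that even coarse 2-community merges are
non-assortative; this is what makes the modularity-vs-blockmodel contrast
hold at every K from 2 to 6.

What passing tests on these networks shows: the estimators and tests
recover exactly the structures they are defined to measure, at realistic
sizes and densities (N ≈ 100–250, density 0.2–0.6, as in the target
application). What they do not show: behavior under spatially embedded
wiring, streamline-count noise, distance-dependent thresholding, or
heavy-tailed weight distributions — none of which the generator models.
Real connectome weights are strongly right-skewed; the normal weight model
is the model under study, not a claim about data.

## Problem sizes and profiles

Fits default to 250 restarts per K (the "paper" profile); the "desk"
profile (25 restarts) is the analysis default, since restart count affects
only how reliably each fit reaches its objective's optimum, not the
definition of any quantity. The validation battery uses 20 seeds for
recovery, 200 seeds for motif recovery, 25 restarts × K = 2..6 for the
method contrast, 500 replicates for test calibration, and 100 nulls for
rich-club significance.

## Known limitations

- The WSBM weight family is normal only; heavy-tailed families are out of
  scope.
- No degree correction in the blockmodel; high-degree nodes can be grouped
  by degree rather than profile on networks with broad degree
  distributions.
- Model selection over K is deliberately absent (results are reported as a
  function of K).
- The exhaustive maximally-assortative-set search is exponential in K
  (fine for K ≤ 20, the intended regime).
- The greedy fixed-K maximizer is the simple single-switch algorithm by
  design; it is not a substitute for Louvain/Leiden when only the best
  modularity partition matters.
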