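# Methods

## Model

A hypergraph on N nodes carries hyperedges of order d (d + 1 nodes each).
Per order, the generalized degree K^(d)_i counts the d-hyperedges at node
i and the adjacency A^(d)_ij counts those shared by i and j. The order-d
Laplacian is L^(d) = diag(K^(d)) − A^(d)/d, and diffusion through all
orders up to D is generated by the multiorder Laplacian
L^[D] = Σ_{d∈𝒟} (γ_d/⟨K^(d)⟩) L^(d), summed over the existing orders
𝒟 = {d ≤ D : ⟨K^(d)⟩ > 0}. The coupling weights γ_d default to 1
everywhere (they are exposed as a parameter but never varied here). L^[D]
is symmetric, positive semidefinite, with zero row sums; its null space is
the connectivity structure.

The network state at diffusion time τ is the Gibbs-like density matrix
ρ_τ^[d] = e^(−τL^[d])/Z with Z = Tr e^(−τL^[d]). Its eigenvalues
μ_i = e^(−τλ_i)/Z form a probability vector over diffusion modes; the von
Neumann entropy S = −Σ μ_i log μ_i runs from 0 (pure state, τ → ∞ on a
connected structure) to log N (isolated nodes or τ → 0).

Truncation at order d is model selection: the full structure ρ_τ^[d_max]
is the data, ρ_{τ'(d)}^[d] the model, and the cost is

    𝓛(d) = D_KL(ρ_τ^[d_max] | ρ_{τ'(d)}^[d]) + C(ρ_{τ'(d)}^[d]),

with complexity C(ρ) = log N − S(ρ) = D_KL(ρ | I/N), the entropic
deviation from a gas of isolated nodes. The complexity is evaluated at the
rescaled time τ'(d) (see below); a switch to evaluate it at the bare τ is
not provided because the rescaled form is the one that makes
proportional-Laplacian structures exactly flat. The optimal order d_opt is
the smallest minimizer of 𝓛; reducibility is
χ = (d_max − d_opt)/(d_max − 1). Inputs with d_max = 1 are flagged
`pairwise_input` and report χ = 1 by convention.

A quantum Jensen–Shannon divergence
JSD(ρ, σ) = S((ρ+σ)/2) − (S(ρ)+S(σ))/2 is provided as an alternative
distinguishability measure; the KL cost above is the one used by every
driver in this package.

## Diffusion-time rescaling

Comparing truncations at a single τ conflates two effects: fewer orders
and weaker accumulated flow. The per-order rescaling τ'(d) = (d_max/d)·τ
removes the second: for structures whose order Laplacians are proportional
(complete hypergraphs; the periodic triangular lattice, where
A^(2) = 2A^(1) and B(2) = ⟨K^(2)⟩/⟨K^(1)⟩ = 1) it makes
ρ_{τ'(d)}^[d] = ρ_τ^[d_max] exactly, hence a flat cost curve.

When orders are missing the order index is replaced by the count of
existing orders: τ'(d) = |𝒟(d_max)|/|𝒟(d)| · τ with 𝒟(x) the existing
orders ≤ x. This reduces to d_max/d when all orders exist and keeps
τ'(d_max) = τ, so the self-divergence at the top order is identically
zero; substituting the order count only in the numerator would not.

Drivers default to τ = τ_short = 1/λ_max of L^[d_max] (a local probing
scale); τ_long = 1/λ_min-nonzero probes global structure. For random
ensembles τ_short is re-derived per realization from that realization's
spectrum.

## Hyperring oracle

The hyperring — n nodes on a ring with first-neighbor pairs and
consecutive triples — is rotationally invariant, so all its Laplacians and
density matrices are circulant and commute. With θ_k = 2πk/n its
multiorder spectra are λ_k^[1] = 1 − cos θ_k and
λ_k^[2] = 2 − (5/3)cos θ_k − (1/3)cos 2θ_k, and the information loss and
complexity reduce to classical expressions over the mode weights. These
closed forms are implemented in `hyperring_analytic` and serve as the
independent oracle for the generic numerical pipeline (agreement to
≤ 1e−8 across a log-τ grid is asserted in the tests). The sign of
Δ𝓛(τ) = 𝓛(2) − 𝓛(1) maps where the hyperring is reducible; it vanishes at
both τ extremes, which are uninformative probing scales. The curve is
computed and reported as is — no particular sign is hard-coded for the
short-τ regime.

Note the generator declares exactly the two stated edge families: the
(i−1, i+1) chord of each triple is *not* added as a pairwise edge, so
K^(1) = 2 — the value the closed-form pairwise spectrum requires. Downward
closure would change that spectrum; it is intentionally not applied, even
though the structure is otherwise described as nested.

## Synthetic generators

Random hypergraphs include each (d+1)-subset independently with
probability p_d; the implementation draws the per-order count from
Binomial(C(n, d+1), p_d) and samples that many distinct subsets uniformly
— the same distribution without enumerating C(100, 5) subsets. Random
simplicial complexes close the result downward. Ensemble drivers default
to the study conditions N = 100, p_d = 50/N^d for d = 1..4 (mean pairwise
degree ≈ 50, progressively sparser higher orders).

`nested_contact_surrogate` emulates face-to-face contact data, which
combines strong nestedness with gregarious hubs: hyperedges of sizes 2–4
are sampled with Pareto-distributed node weights (shape 2.0, N = 80,
60/60/15 top-level edges before closure — group sizes and edge/node ratios
in the range of published contact datasets) and closed downward. It
reproduces the features the null-model analysis needs — simplicial
fraction 1, cross-order degree correlation ≈ 0.97, heavy-tailed degrees —
but not the temporal aggregation, community structure, or exact size
distribution of real contact data, so tests passing on it show the
*mechanisms* (what each randomization preserves and destroys), not
dataset-level numbers.

## Null models

All three randomizations act independently per order and preserve N and
per-order hyperedge counts. The configuration model matches degree stubs
into groups of d + 1 distinct nodes (degree *sequences* preserved
exactly); collisions are repaired by local stub swaps with a bounded retry
budget and a full reshuffle fallback; duplicate hyperedges are allowed and
logged. The node swap, at each order d > 1, ranks nodes by K^(d) with a
fresh random tie-breaking permutation per order, pairs rank r with rank
N−1−r (high with low), and exchanges the pair's order-d memberships:
degree *multisets* are preserved, degree–node assignments are not. On
heavy-tailed degree sequences this collapses the positive cross-order
degree correlation (to scattered values at or below zero); on homogeneous
degree sequences it instead flips its sign — the destruction claim is a
property of heterogeneous, contact-like structures. The shuffle replaces
each hyperedge with probability p_shuffle by a uniformly random
non-existing same-size subset (rejection sampling against the evolving
edge set), preserving only the counts.

## Metrics

Density is M/N on deduplicated hyperedges. The simplicial fraction is the
share of size ≥ 3 hyperedges whose every subface of size ≥ 2 is present
(undefined, and flagged, without such hyperedges). Cross-order degree
correlation is the Pearson correlation of K^(1) and K^(2) (undefined on
constant sequences — the hyperring is this case). Degree heterogeneity
(K_max − ⟨K⟩)/K_max defaults to the mean of the per-order values, which is
zero for structures regular at every order and exactly invariant under the
configuration model and the node swap; "pooled" (one multiset of all
per-order degrees) and "total" (K_i = Σ_d K^(d)_i) aggregates are
switches. Maximum degree and the spectral radius use the total aggregates
(max_i Σ_d K^(d)_i and the largest absolute eigenvalue of Σ_d A^(d)).

Note that at dense wiring the simplicial fraction of a fully shuffled (or
purely random) hypergraph is *not* near zero: with pairwise density p a
random triple is closed by chance with probability ~p³, which at the
default ensemble density (p ≈ 0.8 after closure) leaves SF ≈ 0.4. Near-zero
SF under shuffling is a sparse-regime property.

## Numerical choices

Dense symmetric eigendecomposition throughout (`numpy.linalg.eigh`);
the target systems (N up to a few thousand) do not warrant sparse
iterative solvers, and the density matrices are dense regardless.
Eigenvalues below a relative tolerance of 1e−12·max(1, λ_max) count as
zero (connectivity null space vs round-off); tiny negatives are clipped.
Partition functions are computed on spectra shifted by their minimum
eigenvalue (log-sum-exp), so extreme τ neither under- nor overflows.
Cross-entropies use the exact Gibbs identity
−Tr(ρ log σ) = τ_σ·Tr(ρ L_σ) + log Z_σ instead of a matrix logarithm;
KL round-off below −1e−10 raises, smaller negatives are clipped to 0.
The d_opt tie-break takes the smallest order within a relative 1e−9
(absolute floor 1e−12) of the curve minimum, so exactly flat curves
resolve to d_opt = 1.

Degenerate inputs: empty hypergraphs and nonpositive τ raise; isolated
nodes are kept and contribute zero Laplacian rows; duplicate hyperedges
are deduplicated by readers by default but respected (with multiplicity)
by the decomposition when present.

## Problem sizes and reproducibility

Ensemble drivers and tests use 10–30 realizations at N = 100 (the modal
statistics are already unanimous at that size); the acceptance script uses
30. All randomness flows through `numpy.random.SeedSequence` spawns of a
single user seed; every output table carries the seed and package version
in its attributes.

## Limitations

Temporal, weighted, directed, and attributed hyperedges are out of scope,
as are normalized/random-walk Laplacian variants and sparse eigensolvers.
The JSD operation is provided but no JSD-based experiment driver. The
empirical-dataset pipeline (`dataset_summary`) reads xgi-data JSON but the
preprocessing behind published contact-dataset edge counts (temporal
aggregation, dedup conventions) is not fully specified upstream; results
on raw downloads may differ from published tables depending on that
aggregation.
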