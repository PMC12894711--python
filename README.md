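# hyperreduce

**Functional reducibility of higher-order networks.**

Many complex systems — face-to-face contacts, metabolic reactions, drug
co-prescriptions, coauthorships — are naturally modeled as *hypergraphs*,
where a hyperedge of order *d* connects *d* + 1 nodes at once. Keeping
every interaction order makes models richer but also more complex and
expensive. `hyperreduce` answers a practical question: **up to which order
must the interactions be kept for diffusion on the structure to remain
functionally faithful?**

## The method

Diffusion through hyperedges of order up to *D* is governed by the
multiorder Laplacian

```
L^[D] = Σ_{d ∈ 𝒟} (γ_d / ⟨K^(d)⟩) L^(d),      L^(d)_ij = K^(d)_i δ_ij − A^(d)_ij / d,
```

where K^(d) are generalized degrees, A^(d) per-order adjacencies, and the
sum runs over the orders 𝒟 that actually exist. At a diffusion time τ the
network state is encoded in the density matrix **ρ**_τ^[d] = e^(−τL^[d]) / Z,
whose eigenvalues μ_i = e^(−τλ_i)/Z weight the diffusion modes. Treating
the full structure **ρ**_τ^[d_max] as *data* and each truncation
**ρ**_{τ'(d)}^[d] as a *model*, every order d is scored by the cost

```
𝓛(d) = D_KL( ρ_τ^[d_max] | ρ_{τ'(d)}^[d] )  +  C( ρ_{τ'(d)}^[d] ),
```

information loss plus model complexity C = log N − S (the entropic
deviation from N isolated nodes), with the per-order rescaling
τ'(d) = (d_max/d)·τ that makes proportional-Laplacian structures exactly
cost-flat. The smallest minimizer is the optimal order d_opt, and

```
χ = (d_max − d_opt) / (d_max − 1)  ∈ [0, 1]
```

is the reducibility: χ = 1 means the structure collapses to its pairwise
skeleton, χ = 0 means every order carries functional information.

The package also provides synthetic generators (random hypergraphs, random
simplicial complexes, hyperrings, complete hypergraphs, triangular-lattice
simplicial complexes, nested contact surrogates), an exact circulant
oracle for the hyperring, three null-model randomizations (configuration
model, node swap, hyperedge shuffling), and structural metrics (density,
simplicial fraction, cross-order degree correlation, degree heterogeneity,
spectral radius).

## Worked example

Score a nested, heterogeneous contact-like hypergraph at the short
diffusion timescale τ_short = 1/λ_max:

```python
from hyperreduce.generators import nested_contact_surrogate
from hyperreduce import reducibility, timescales
from hyperreduce.metrics import metric_report

H = nested_contact_surrogate(seed=3)
tau_short, tau_long = timescales(H)
res = reducibility(H, tau_short)
print(f"N = {H.num_nodes}, M = {H.num_edges}, d_max = {res.curve.d_max}")
for d, dkl, c, cost in zip(res.curve.orders, res.curve.info_loss,
                           res.curve.complexity, res.curve.cost):
    print(f"  d = {d}:  D_KL = {dkl:.4f}   C = {c:.4f}   cost = {cost:.4f}")
print(f"d_opt = {res.d_opt}, chi = {res.chi:.2f}")
```

prints

```
N = 80, M = 403, d_max = 3
  d = 1:  D_KL = 0.0022   C = 0.0127   cost = 0.0149
  d = 2:  D_KL = 0.0009   C = 0.0141   cost = 0.0150
  d = 3:  D_KL = 0.0000   C = 0.0160   cost = 0.0160
```

Truncating at d = 1 loses a little information (D_KL rises) but pays less
complexity, and the total cost is lowest there: d_opt = 1, χ = 1 — this
strongly nested structure is functionally reducible to its pairwise
skeleton at the short timescale. An uncorrelated random hypergraph at the
same size instead yields d_opt = d_max (χ = 0): every order adds genuinely
new spectral content.

The same pipeline is scriptable from the shell:

```sh
hyperreduce generate --kind hyperring --n 100 --out ring.json
hyperreduce reduce --input ring.json --tau short
hyperreduce metrics --input ring.json
hyperreduce hyperring-scan --n 100 --out scan.csv
```

Input files are xgi-data-dialect JSON or plain hyperedge lists (one edge
per line). Empirical hypergraph datasets in this dialect are available
from the public xgi-data collection on Zenodo
(https://zenodo.org/communities/xgi/); place downloaded files under
`data/empirical/` to run the empirical spot checks in the test suite.

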